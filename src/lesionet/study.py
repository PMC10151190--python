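"""End-to-end study runner.

From one configuration: simulate a cohort, derive behavioural factors, fit
the LOOCV lesion-load models, build lesion-aware FC/SC feature matrices, fit
the elastic-net connectivity models (FC, SC and both concatenated), compare
modalities on squared prediction error, model the lesion residuals with
connectivity, summarize model weights as networks, and score top-node
overlap with healthy-control seed networks. Every requested cell of the
report is either filled or explicitly marked failed with its reason; an
identical configuration reproduces the report bit-for-bit.

Stage randomness is fanned out from the global seed through a fixed counter
scheme (``SeedSequence([seed, stage_index])``), so each stage is reproducible
on its own and no stage's draws shift another's.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import compare_squared_errors, residual_targets
from .connectivity import (
    ConnectivityMatrix,
    FeatureMatrix,
    build_feature_matrix,
    detrend_bandpass,
    fc_matrix,
    lesion_mask_fc,
    pair_index,
    symmetrize_and_mask_sc,
)
from .enet import EnetConfig, loocv_predict, permutation_pvalue_enet
from .factors import fit_varimax_pca, normalize_battery, project_factor_scores
from .image import VolumeImage
from .network import average_weights_z, nodal_degree, top_nodes
from .results import PredictionResult
from .seeds import (
    estimate_fwhm,
    group_tmap,
    montecarlo_cluster_threshold,
    node_overlap,
    seed_fc_map,
    threshold_group_map,
)
from .simulate import SimConfig, control_volume4d, simulate_cohort
from .vbcm import VBCMConfig, loocv_lesion_model, stability_map

logger = logging.getLogger(__name__)

CONNECTIVITY_MODALITIES = ("FC", "SC", "FCSC")


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([global_seed, stage_index])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class StudyConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    vbcm: VBCMConfig = field(default_factory=VBCMConfig)
    enet: EnetConfig = field(default_factory=EnetConfig)
    modalities: tuple = ("T1", "FC", "SC", "FCSC")
    targets: tuple | None = None        # 0-based factor indices; None = all retained
    connectivity_subset: int | None = None  # patients with imaging (first m); None = all
    seed: int = 0
    output_dir: str | None = None
    run_residual_models: bool = True
    run_seed_networks: bool = True
    stability_fraction: float = 0.8     # fold fraction defining the stable seed
    mc_n_sims: int = 1000
    seed_voxel_p: float = 0.001
    seed_cluster_p: float = 0.05
    top_k_nodes: int = 10

    def validate(self) -> None:
        if not self.modalities:
            raise ValueError("modality list must be non-empty")
        bad = [m for m in self.modalities if m not in ("T1",) + CONNECTIVITY_MODALITIES]
        if bad:
            raise ValueError(f"unknown modalities: {bad}")
        self.sim.validate()
        self.vbcm.validate()
        self.enet.validate()

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        raw = json.loads(Path(path).read_text())
        sim = SimConfig(**raw.pop("sim", {}))
        vbcm = VBCMConfig(**raw.pop("vbcm", {}))
        enet_raw = raw.pop("enet", {})
        if "alpha_grid" in enet_raw:
            enet_raw["alpha_grid"] = np.asarray(enet_raw["alpha_grid"], dtype=float)
        enet = EnetConfig(**enet_raw)
        for key in ("modalities", "targets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, vbcm=vbcm, enet=enet, **raw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        payload = json.dumps(
            {"sim": asdict(self.sim), "vbcm": asdict(self.vbcm),
             "enet": asdict(self.enet), "modalities": self.modalities,
             "targets": self.targets, "seed": self.seed},
            sort_keys=True, default=default,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    provenance: dict
    targets: list
    cells: dict
    comparisons: dict
    residual_models: dict
    seed_networks: dict
    timing_s: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=_json_default))

    def cells_table(self) -> pd.DataFrame:
        rows = []
        for target, per_mod in self.cells.items():
            for modality, cell in per_mod.items():
                rows.append({"target": target, "modality": modality, **{
                    k: v for k, v in cell.items() if not isinstance(v, (list, dict))
                }})
        return pd.DataFrame(rows)

    @property
    def n_connectivity_models(self) -> int:
        return sum(
            1
            for per_mod in self.cells.values()
            for m, cell in per_mod.items()
            if m in CONNECTIVITY_MODALITIES and cell.get("status") == "ok"
        )


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    return str(o)


def _safe(value: float | None):
    if value is None:
        return None
    return None if np.isnan(value) else float(value)


# ---------------------------------------------------------------------------
# feature building


def build_fc_features(cohort, n_subjects: int | None = None) -> FeatureMatrix:
    """Detrend/band-pass each patient's ROI series, correlate, lesion-mask."""
    cfg = cohort.config
    m = cfg.n_patients if n_subjects is None else min(n_subjects, cfg.n_patients)
    mats = []
    for i in range(m):
        filtered = detrend_bandpass(cohort.patient_timeseries[i], cfg.tr_seconds)
        fc = fc_matrix(filtered)
        fc = lesion_mask_fc(fc, cohort.lesion_masks[i], cohort.atlas)
        mats.append(fc)
    return build_feature_matrix(mats, "FC")


def build_sc_features(cohort, n_subjects: int | None = None) -> FeatureMatrix:
    cfg = cohort.config
    m = cfg.n_patients if n_subjects is None else min(n_subjects, cfg.n_patients)
    mats = [
        symmetrize_and_mask_sc(cohort.structural[i], cohort.lesion_masks[i], cohort.atlas)
        for i in range(m)
    ]
    return build_feature_matrix(mats, "SC")


def combine_features(fc: FeatureMatrix, sc: FeatureMatrix) -> FeatureMatrix:
    """Column-concatenated FC+SC features run through the identical pipeline."""
    return FeatureMatrix(
        np.hstack([fc.values, sc.values]), list(fc.pairs) + list(sc.pairs), "FCSC"
    )


# ---------------------------------------------------------------------------
# study stages


def _connectivity_cell(features: FeatureMatrix, y: np.ndarray, enet_cfg: EnetConfig,
                       top_k: int) -> tuple[dict, PredictionResult]:
    result = loocv_predict(features.values, y, enet_cfg)
    result.perm_p = permutation_pvalue_enet(features.values, y, enet_cfg)
    weights = [fm.weights for fm in result.fold_artifacts]
    wmap = average_weights_z(weights, features.pairs)
    summary = nodal_degree(wmap)
    top = top_nodes(summary, top_k)
    cell = {
        "status": "ok",
        "n": result.n_subjects,
        "accuracy_r": _safe(result.accuracy_r),
        "perm_p": result.perm_p,
        "mean_alpha": result.notes.get("mean_alpha"),
        "n_significant_connections": int(wmap.significant.sum()),
        "top_nodes": [int(t) for t in top],
    }
    return cell, result


def run_study(config: StudyConfig) -> StudyReport:
    """Execute all requested stages in dependency order; never raises per-cell."""
    config.validate()
    t_start = time.time()
    timing: dict = {}

    sim = SimConfig(**{**asdict(config.sim), "seed": stage_seed(config.seed, 0)})
    vbcm_cfg = VBCMConfig(**{**asdict(config.vbcm), "seed": stage_seed(config.seed, 1)})
    enet_kwargs = asdict(config.enet)
    enet_kwargs["alpha_grid"] = np.asarray(config.enet.alpha_grid, dtype=float)
    enet_cfg = EnetConfig(**{**enet_kwargs, "seed": stage_seed(config.seed, 2)})

    t0 = time.time()
    cohort, truth = simulate_cohort(sim)
    timing["simulate"] = time.time() - t0

    t0 = time.time()
    scaled = normalize_battery(cohort.battery)
    factor_model = fit_varimax_pca(scaled)
    scores = project_factor_scores(factor_model, scaled)
    timing["factors"] = time.time() - t0

    available = list(range(factor_model.n_retained))
    wanted = list(config.targets) if config.targets is not None else available
    target_idx = [t for t in wanted if t in available]
    target_names = [f"factor_{t + 1}" for t in target_idx]

    cells: dict = {name: {} for name in target_names}
    comparisons: dict = {name: {} for name in target_names}
    residual_models: dict = {name: {} for name in target_names}
    seed_nets: dict = {}

    # ---- lesion (T1) models ------------------------------------------------
    lesion_results: dict = {}
    stability: dict = {}
    if "T1" in config.modalities:
        t0 = time.time()
        for t, name in zip(target_idx, target_names):
            y = scores.iloc[:, t].values
            try:
                res = loocv_lesion_model(cohort.abnormality, y, vbcm_cfg)
                roisets = [a[0] for a in res.fold_artifacts]
                smap = stability_map(roisets, shape=cohort.atlas.shape,
                                     voxel_size_mm=sim.voxel_size_mm)
                lesion_results[name] = res
                stability[name] = smap
                cells[name]["T1"] = {
                    "status": "ok",
                    "n": res.n_subjects,
                    "accuracy_r": _safe(res.accuracy_r),
                    "perm_p": res.perm_p,
                    "n_empty_folds": res.notes.get("n_empty_folds"),
                }
            except Exception as exc:  # keep independent cells alive
                logger.exception("T1 model failed for %s", name)
                cells[name]["T1"] = {"status": "failed", "reason": str(exc)}
        timing["lesion_models"] = time.time() - t0

    # ---- connectivity features --------------------------------------------
    # the imaging subset mirrors studies where only some patients have
    # connectivity data: the first m patients carry FC/SC, comparisons
    # restrict to this intersection with the lesion sample
    n_conn = sim.n_patients if config.connectivity_subset is None else min(
        config.connectivity_subset, sim.n_patients
    )
    features: dict = {}
    conn_requested = [m for m in config.modalities if m in CONNECTIVITY_MODALITIES]
    if conn_requested:
        t0 = time.time()
        try:
            fc = build_fc_features(cohort, n_conn) if {"FC", "FCSC"} & set(conn_requested) else None
            sc = build_sc_features(cohort, n_conn) if {"SC", "FCSC"} & set(conn_requested) else None
            if "FC" in conn_requested:
                features["FC"] = fc
            if "SC" in conn_requested:
                features["SC"] = sc
            if "FCSC" in conn_requested:
                features["FCSC"] = combine_features(fc, sc)
        except Exception as exc:
            logger.exception("feature construction failed")
            for name in target_names:
                for m in conn_requested:
                    cells[name][m] = {"status": "failed", "reason": str(exc)}
            features = {}
        timing["features"] = time.time() - t0

    # ---- connectivity models ----------------------------------------------
    conn_results: dict = {name: {} for name in target_names}
    if features:
        t0 = time.time()
        for t, name in zip(target_idx, target_names):
            y = scores.iloc[:, t].values[:n_conn]
            for modality, feats in features.items():
                try:
                    cell, res = _connectivity_cell(feats, y, enet_cfg, config.top_k_nodes)
                    cells[name][modality] = cell
                    conn_results[name][modality] = res
                except Exception as exc:
                    logger.exception("%s model failed for %s", modality, name)
                    cells[name][modality] = {"status": "failed", "reason": str(exc)}
        timing["connectivity_models"] = time.time() - t0

    # mark unrequested cells explicitly
    for name in target_names:
        for m in ("T1",) + CONNECTIVITY_MODALITIES:
            if m not in config.modalities:
                cells[name][m] = {"status": "not-requested"}

    # ---- comparisons -------------------------------------------------------
    t0 = time.time()
    for name in target_names:
        if name not in lesion_results:
            continue
        lesion_res = lesion_results[name]
        for modality, res in conn_results.get(name, {}).items():
            # restrict to the subject intersection of the two samples
            try:
                m = min(len(lesion_res.predicted), len(res.predicted))
                comp = compare_squared_errors(
                    np.asarray(lesion_res.predicted)[:m],
                    np.asarray(res.predicted)[:m],
                    np.asarray(lesion_res.actual)[:m],
                    label_a="T1", label_b=modality,
                )
                comparisons[name][f"T1_vs_{modality}"] = {
                    "status": "ok",
                    "wilcoxon_z": comp.wilcoxon_z,
                    "wilcoxon_p": comp.wilcoxon_p,
                    "n_pairs": comp.n_pairs,
                    "median_sq_error_t1": comp.median_sq_error_a,
                    f"median_sq_error_{modality.lower()}": comp.median_sq_error_b,
                }
            except Exception as exc:
                comparisons[name][f"T1_vs_{modality}"] = {
                    "status": "failed", "reason": str(exc)
                }
    timing["comparisons"] = time.time() - t0

    # ---- residual-target connectivity models -------------------------------
    if config.run_residual_models and features:
        t0 = time.time()
        for name in target_names:
            if name not in lesion_results:
                continue
            try:
                resid = residual_targets(lesion_results[name])[:n_conn]
            except Exception as exc:
                residual_models[name] = {"status": "failed", "reason": str(exc)}
                continue
            for modality, feats in features.items():
                try:
                    res = loocv_predict(feats.values, resid, enet_cfg)
                    p = permutation_pvalue_enet(feats.values, resid, enet_cfg)
                    residual_models[name][modality] = {
                        "status": "ok",
                        "accuracy_r": _safe(res.accuracy_r),
                        "perm_p": p,
                        "n": res.n_subjects,
                    }
                except Exception as exc:
                    residual_models[name][modality] = {
                        "status": "failed", "reason": str(exc)
                    }
        timing["residual_models"] = time.time() - t0

    # ---- healthy seed networks ---------------------------------------------
    if config.run_seed_networks and stability and cohort.config.n_controls >= 3:
        t0 = time.time()
        grey = VolumeImage(np.ones(cohort.atlas.shape, dtype=bool), sim.voxel_size_mm)
        for name in target_names:
            if name not in stability:
                continue
            try:
                smap = stability[name]
                n_folds = sim.n_patients
                seed_mask = smap.data >= config.stability_fraction * n_folds
                if not seed_mask.any():
                    seed_nets[name] = {"status": "failed",
                                       "reason": "no stable lesion cluster to seed"}
                    continue
                seed_roi = VolumeImage(seed_mask, sim.voxel_size_mm)
                zmaps = []
                for c in range(sim.n_controls):
                    vol4d = control_volume4d(sim, cohort.atlas,
                                             cohort.control_timeseries, c)
                    zmaps.append(seed_fc_map(seed_roi, vol4d, grey))
                tmap, _ = group_tmap(zmaps)
                zstack = np.stack([m.data for m in zmaps])
                resid_maps = zstack - zstack.mean(axis=0)
                fwhm = estimate_fwhm(resid_maps, grey.data)
                thr = montecarlo_cluster_threshold(
                    cohort.atlas.shape, grey.data, fwhm,
                    voxel_p=config.seed_voxel_p, cluster_p=config.seed_cluster_p,
                    n_sims=max(500, config.mc_n_sims),
                    seed=stage_seed(config.seed, 7),
                )
                net = threshold_group_map(tmap, df=sim.n_controls - 1,
                                          voxel_p=config.seed_voxel_p,
                                          cluster_size_thr=thr,
                                          cluster_p=config.seed_cluster_p)
                entry = {
                    "status": "ok",
                    "estimated_fwhm_vox": fwhm,
                    "cluster_size_thr": thr,
                    "network_voxels": int(net.suprathreshold.data.sum()),
                }
                fc_cell = cells[name].get("FC", {})
                if fc_cell.get("status") == "ok":
                    count, flags = node_overlap(
                        fc_cell["top_nodes"], cohort.atlas, net.suprathreshold
                    )
                    entry["fc_top_node_overlap"] = count
                    entry["fc_top_node_total"] = len(flags)
                seed_nets[name] = entry
            except Exception as exc:
                logger.exception("seed-network stage failed for %s", name)
                seed_nets[name] = {"status": "failed", "reason": str(exc)}
        timing["seed_networks"] = time.time() - t0

    timing["total"] = time.time() - t_start
    import numba
    import scipy
    report = StudyReport(
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": {str(i): stage_seed(config.seed, i) for i in range(8)},
            "n_retained_factors": factor_model.n_retained,
            "eigenvalues": factor_model.eigenvalues.tolist(),
            "versions": {
                "lesionet": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "numba": numba.__version__,
            },
        },
        targets=target_names,
        cells=cells,
        comparisons=comparisons,
        residual_models=residual_models,
        seed_networks=seed_nets,
        timing_s=timing,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "study_report.json")
        report.cells_table().to_csv(out / "study_cells.tsv", sep="\t", index=False)
        for name, smap in stability.items():
            smap.save(out / f"stability_{name}.nii.gz")
    return report
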