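"""Behavioural component scores from a neuropsychological test battery.

Raw test scores are converted to percentages of each test's maximum (the
observed group maximum where no maximum is recorded), then submitted to a
principal component analysis of the correlation matrix. Components with
eigenvalue >= 1 are retained (Kaiser rule), varimax-rotated, and subject-level
factor scores are obtained by the regression method — for the fitting sample
these have mean 0 and unit variance per factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

logger = logging.getLogger(__name__)


@dataclass
class Battery:
    """Subjects x tests score table with per-test maxima (NaN = unstated)."""

    scores: pd.DataFrame
    maxima: pd.Series

    def __post_init__(self) -> None:
        self.maxima = self.maxima.reindex(self.scores.columns)
        if (self.scores.values < 0).any():
            raise ValueError("battery scores must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Battery":
        table = pd.read_csv(path, sep="\t", index_col=0)
        if "__maximum__" not in table.index:
            raise ValueError("battery TSV must contain a '__maximum__' row")
        maxima = table.loc["__maximum__"]
        scores = table.drop(index="__maximum__")
        return cls(scores=scores.astype(float), maxima=maxima.astype(float))


@dataclass
class FactorModel:
    """Varimax-rotated principal components of a standardized battery."""

    loadings: np.ndarray        # tests x retained factors (rotated)
    eigenvalues: np.ndarray     # all eigenvalues, descending
    coefficients: np.ndarray    # tests x factors projection (regression method)
    n_retained: int
    rotation: np.ndarray        # retained x retained orthogonal matrix
    test_names: list[str]
    column_means: np.ndarray    # of the scaled battery used for fitting
    column_sds: np.ndarray

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)


def normalize_battery(battery: Battery) -> pd.DataFrame:
    """Convert raw scores to percentages of each test's maximum.

    Tests without a stated maximum use the observed group maximum. A test
    whose effective maximum is zero is degenerate (all-zero scores) and
    raises.
    """
    scores = battery.scores.astype(float)
    maxima = battery.maxima.copy().astype(float)
    observed_max = scores.max(axis=0)
    missing = maxima.isna()
    maxima[missing] = observed_max[missing]
    if (maxima <= 0).any():
        bad = list(maxima.index[maxima <= 0])
        raise ValueError(f"degenerate tests with maximum <= 0: {bad}")
    over = scores.gt(maxima, axis=1)
    if over.any().any():
        raise ValueError("scores exceed the stated maximum for some tests")
    return scores.div(maxima, axis=1) * 100.0


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of the variance of squared loadings."""
    sq = np.asarray(loadings) ** 2
    return float(np.sum(sq.var(axis=0)))


def fit_varimax_pca(scaled: pd.DataFrame | np.ndarray, kaiser_threshold: float = 1.0) -> FactorModel:
    """PCA of the correlation matrix with Kaiser retention and varimax rotation.

    Zero-variance tests are dropped with a warning. Each retained factor is
    sign-flipped so that its largest-|loading| test loads positively.
    """
    if isinstance(scaled, pd.DataFrame):
        names = list(scaled.columns)
        x = scaled.values.astype(float)
    else:
        x = np.asarray(scaled, dtype=float)
        names = [f"test_{i + 1:02d}" for i in range(x.shape[1])]
    n, m = x.shape
    if m < 2 or n < 3:
        raise ValueError("need at least 2 tests and 3 subjects")

    sds = x.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [names[i] for i in np.where(~keep)[0]]
        logger.warning("dropping zero-variance tests: %s", dropped)
        x, names = x[:, keep], [names[i] for i in np.where(keep)[0]]
        sds = sds[keep]
    means = x.mean(axis=0)
    z = (x - means) / sds

    corr = (z.T @ z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(-eigval)
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    n_ret = int(np.sum(eigval >= kaiser_threshold))
    if n_ret == 0:
        raise ValueError("no component reaches the Kaiser eigenvalue threshold")
    unrotated = eigvec[:, :n_ret] * np.sqrt(eigval[:n_ret])

    if n_ret == 1:
        rotated, rot = unrotated.copy(), np.eye(1)
    else:
        rotated, rot = rotate_factors(unrotated, "varimax", tol=1e-8, max_tries=2000)

    # deterministic orientation: the dominant test of each factor loads positively
    for j in range(n_ret):
        i_max = int(np.argmax(np.abs(rotated[:, j])))
        if rotated[i_max, j] < 0:
            rotated[:, j] *= -1
            rot[:, j] *= -1

    # regression-method projection: W = V diag(1/sqrt(ev)) T
    coeff = eigvec[:, :n_ret] @ np.diag(1.0 / np.sqrt(eigval[:n_ret])) @ rot
    return FactorModel(
        loadings=rotated,
        eigenvalues=eigval,
        coefficients=coeff,
        n_retained=n_ret,
        rotation=rot,
        test_names=names,
        column_means=means,
        column_sds=sds,
    )


def project_factor_scores(
    model: FactorModel, scaled: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Project (percentage-scaled) battery rows onto the retained factors.

    Standardizes with the fitting sample's means/SDs, then multiplies by the
    projection coefficients; on the fitting sample scores have zero mean and
    unit variance per factor.
    """
    if isinstance(scaled, pd.DataFrame):
        missing = [t for t in model.test_names if t not in scaled.columns]
        if missing:
            raise ValueError(f"battery is missing tests: {missing}")
        x = scaled[model.test_names].values.astype(float)
        index = scaled.index
    else:
        x = np.asarray(scaled, dtype=float)
        if x.shape[1] != len(model.test_names):
            raise ValueError(
                f"expected {len(model.test_names)} tests, got {x.shape[1]}"
            )
        index = pd.RangeIndex(x.shape[0])
    z = (x - model.column_means) / model.column_sds
    scores = z @ model.coefficients
    cols = [f"factor_{j + 1}" for j in range(model.n_retained)]
    return pd.DataFrame(scores, index=index, columns=cols)


def write_factor_outputs(model: FactorModel, scores: pd.DataFrame, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"factor_{j + 1}" for j in range(model.n_retained)]
    pd.DataFrame(model.loadings, index=model.test_names, columns=cols).to_csv(
        out / "loadings.tsv", sep="\t"
    )
    pd.Series(model.eigenvalues, name="eigenvalue").to_csv(
        out / "eigenvalues.tsv", sep="\t", index_label="component"
    )
    scores.to_csv(out / "factor_scores.tsv", sep="\t")
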