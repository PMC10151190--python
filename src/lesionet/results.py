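"""Shared cross-validated prediction result container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def pearson_accuracy(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Pearson r between out-of-fold predictions and true targets.

    NaN when either vector is (numerically) constant — e.g. every fold fell
    back to the training mean — so a meaningless accuracy is never reported.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    sp, sa = predicted.std(), actual.std()
    if sp <= 1e-12 * max(1.0, np.abs(predicted).max()) or sa == 0:
        return float("nan")
    return float(np.corrcoef(predicted, actual)[0, 1])


@dataclass
class PredictionResult:
    """Out-of-fold predictions of one cross-validated model."""

    predicted: np.ndarray
    actual: np.ndarray
    accuracy_r: float
    perm_p: float | None = None
    fold_artifacts: list = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.actual) - np.asarray(self.predicted)

    @property
    def n_subjects(self) -> int:
        return len(self.actual)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "predicted": np.asarray(self.predicted).tolist(),
            "actual": np.asarray(self.actual).tolist(),
            "residuals": self.residuals.tolist(),
            "accuracy_r": None if np.isnan(self.accuracy_r) else self.accuracy_r,
            "perm_p": self.perm_p,
            "notes": {k: v for k, v in self.notes.items() if _jsonable(v)},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictionResult":
        payload = json.loads(Path(path).read_text())
        return cls(
            predicted=np.asarray(payload["predicted"], dtype=float),
            actual=np.asarray(payload["actual"], dtype=float),
            accuracy_r=float("nan") if payload["accuracy_r"] is None else payload["accuracy_r"],
            perm_p=payload.get("perm_p"),
            notes=payload.get("notes", {}),
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
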