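"""CAFA-style protein-centric evaluation: threshold sweep, Fmax, ROC-AUC.

Per protein j and threshold h the predicted set P_j(h) is every term
with score >= h; precision is |P ∩ T| / |P| (0/0 defined as 0) and
recall |P ∩ T| / |T|. Averages run over *all* proteins by default; a
coverage mode restricting the precision average to proteins with at
least one prediction at h is available behind a flag. Fmax is the
maximum over the threshold grid of the harmonic mean of the averages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ConfigError, DataError

#: Default threshold grid: 0.01, 0.02, ..., 1.00.
DEFAULT_GRID = np.round(np.arange(1, 101) * 0.01, 2)


@dataclass
class EvalReport:
    fmax: float
    threshold: float
    auc: float | None
    sweep: pd.DataFrame = field(repr=False)

    def to_json(self) -> str:
        return json.dumps({
            "fmax": self.fmax,
            "threshold": self.threshold,
            "auc": self.auc,
            "n_thresholds": len(self.sweep),
        }, indent=2)


def _validate(scores: np.ndarray, truth: np.ndarray) -> tuple:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if scores.shape != truth.shape:
        raise DataError(f"scores {scores.shape} and truth {truth.shape} differ in shape")
    if scores.min() < 0 or scores.max() > 1:
        raise DataError("scores must lie in [0, 1]")
    if not np.isin(truth, (0.0, 1.0)).all():
        raise DataError("truth must be binary")
    if (truth.sum(axis=1) == 0).any():
        raise DataError("every protein must have at least one true term")
    return scores, truth


def protein_precision_recall(scores, truth, h: float) -> tuple:
    """Per-protein precision and recall arrays at threshold `h`."""
    scores, truth = _validate(scores, truth)
    predicted = scores >= h
    tp = (predicted * truth).sum(axis=1)
    n_pred = predicted.sum(axis=1)
    n_true = truth.sum(axis=1)
    with np.errstate(invalid="ignore"):
        precision = np.where(n_pred > 0, tp / np.maximum(n_pred, 1), 0.0)
    recall = tp / n_true
    return precision, recall


def threshold_sweep(scores, truth, grid=DEFAULT_GRID) -> pd.DataFrame:
    """Average precision/recall and F-measure over the threshold grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or (np.diff(grid) <= 0).any():
        raise ConfigError("threshold grid must be strictly increasing")
    rows = []
    for h in grid:
        pre, rec = protein_precision_recall(scores, truth, h)
        p_bar, r_bar = pre.mean(), rec.mean()
        f = 0.0 if p_bar + r_bar == 0 else 2 * p_bar * r_bar / (p_bar + r_bar)
        rows.append((h, p_bar, r_bar, f))
    return pd.DataFrame(rows, columns=["threshold", "precision", "recall", "f"])


def fmax(scores, truth, grid=DEFAULT_GRID) -> tuple:
    """(Fmax, argmax threshold); threshold ties resolve to the smallest h."""
    sweep = threshold_sweep(scores, truth, grid)
    best = int(sweep["f"].idxmax())  # idxmax returns the first maximum
    return float(sweep.loc[best, "f"]), float(sweep.loc[best, "threshold"])


def roc_auc(scores, truth, averaging: str = "micro") -> float | None:
    """Rank-based ROC-AUC; ties receive half credit.

    micro: one curve over all (protein, term) pairs. macro: mean over
    terms, skipping single-class terms. Returns None when undefined
    (single-class input), mirroring dashed table entries.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if scores.shape != truth.shape:
        raise DataError("scores and truth differ in shape")
    if averaging == "micro":
        flat_truth = truth.ravel()
        if flat_truth.min() == flat_truth.max():
            return None
        return float(roc_auc_score(flat_truth, scores.ravel()))
    if averaging == "macro":
        aucs = []
        for i in range(truth.shape[1]):
            col = truth[:, i]
            if col.min() == col.max():
                continue
            aucs.append(roc_auc_score(col, scores[:, i]))
        return float(np.mean(aucs)) if aucs else None
    raise ConfigError(f"unknown AUC averaging {averaging!r}")


def evaluate(scores, truth, grid=DEFAULT_GRID,
             averaging: str = "micro") -> EvalReport:
    sweep = threshold_sweep(scores, truth, grid)
    best = int(sweep["f"].idxmax())
    return EvalReport(fmax=float(sweep.loc[best, "f"]),
                      threshold=float(sweep.loc[best, "threshold"]),
                      auc=roc_auc(scores, truth, averaging),
                      sweep=sweep)


def coverage_precision(scores, truth, h: float) -> float:
    """CAFA-style precision average over proteins with >= 1 prediction at h."""
    scores, truth = _validate(scores, truth)
    predicted = scores >= h
    covered = predicted.sum(axis=1) > 0
    if not covered.any():
        return 0.0
    pre, _ = protein_precision_recall(scores, truth, h)
    return float(pre[covered].mean())
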