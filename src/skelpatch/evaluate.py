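"""Evaluation metrics: patch-level classification panel (accuracy,
sensitivity, specificity, PPV, NPV), per-case Dice similarity, and the
size-stratified breakdown (< 5 mm, 5–10 mm, > 10 mm).

Metrics are reported on the 0–1 scale; multiply by 100 for percentage
presentation (``as_percent``). Zero-denominator metrics are reported as
``None`` (undefined), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinaryMask

SIZE_STRATA = (("<5 mm", 0.0, 5.0), ("5-10 mm", 5.0, 10.0), (">10 mm", 10.0, np.inf))


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_patches(predictions, labels) -> ConfusionCounts:
    """Count TP/FP/TN/FN from patch-level binary decisions.

    ``predictions`` are 0/1 decisions (or booleans); ``labels`` the ground
    truth patch labels."""
    preds = [int(bool(p)) for p in predictions]
    labs = [int(bool(l)) for l in labels]
    if len(preds) != len(labs):
        raise ValueError("predictions and labels differ in length")
    if not preds:
        raise ValueError("empty evaluation set")
    c = ConfusionCounts()
    for p, l in zip(preds, labs):
        if p and l:
            c.tp += 1
        elif p and not l:
            c.fp += 1
        elif not p and l:
            c.fn += 1
        else:
            c.tn += 1
    return c


def _ratio(num: int, den: int, what: str) -> float | None:
    if den == 0:
        return None
    return num / den


def metric_panel(c: ConfusionCounts, as_percent: bool = False) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV from confusion counts."""
    panel = {
        "accuracy": _ratio(c.tp + c.tn, c.total, "accuracy"),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity"),
        "ppv": _ratio(c.tp, c.tp + c.fp, "ppv"),
        "npv": _ratio(c.tn, c.tn + c.fn, "npv"),
    }
    if as_percent:
        panel = {k: (None if v is None else 100.0 * v) for k, v in panel.items()}
    return panel


def dsc(gt: BinaryMask | np.ndarray, pred: BinaryMask | np.ndarray) -> float:
    """Dice similarity coefficient 2|A ∩ B| / (|A| + |B|).

    Defined for mask pairs with at least one nonempty member; the both-empty
    case is undefined (raises) — case-level reporting excludes it."""
    a = gt.astype_bool() if isinstance(gt, BinaryMask) else np.asarray(gt).astype(bool)
    b = pred.astype_bool() if isinstance(pred, BinaryMask) else np.asarray(pred).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("DSC undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class SegScores:
    """Per-case Dice with the mean ± std summary used in case-level
    reporting; cases where both ground truth and prediction are empty are
    excluded (DSC undefined), tracked in ``n_excluded``."""

    per_case_dsc: list[float]
    case_ids: list[str]
    n_excluded: int = 0

    @property
    def mean_dsc(self) -> float:
        return float(np.mean(self.per_case_dsc)) if self.per_case_dsc else np.nan

    @property
    def std_dsc(self) -> float:
        return float(np.std(self.per_case_dsc)) if self.per_case_dsc else np.nan

    def summary(self) -> str:
        return f"{self.mean_dsc:.3f} ± {self.std_dsc:.3f} (n={len(self.per_case_dsc)})"


def seg_scores(cases: list[tuple[str, BinaryMask | np.ndarray, BinaryMask | np.ndarray]]) -> SegScores:
    """Per-case DSC over (case_id, ground truth, prediction) triples."""
    vals, ids, excluded = [], [], 0
    for cid, gt, pred in cases:
        a = gt.astype_bool() if isinstance(gt, BinaryMask) else np.asarray(gt).astype(bool)
        b = pred.astype_bool() if isinstance(pred, BinaryMask) else np.asarray(pred).astype(bool)
        if not a.any() and not b.any():
            excluded += 1
            continue
        vals.append(dsc(a, b))
        ids.append(cid)
    return SegScores(vals, ids, excluded)


def stratum_of(diameter_mm: float) -> str:
    for label, lo, hi in SIZE_STRATA:
        if lo <= diameter_mm < hi:
            return label
    raise ValueError(f"diameter {diameter_mm} outside all strata")


def stratified_report(
    case_metrics: pd.DataFrame, diameters_mm: dict[str, float]
) -> pd.DataFrame:
    """Bin per-case metrics by maximum aneurysm diameter.

    ``case_metrics`` needs a ``case_id`` column plus numeric metric columns;
    strata with no members appear with count 0 and NaN metrics (empty, not
    zero). Cases without a diameter annotation are excluded with a warning.
    """
    import warnings

    df = case_metrics.copy()
    known = df["case_id"].map(diameters_mm.__contains__)
    if not known.all():
        missing = df.loc[~known, "case_id"].tolist()
        warnings.warn(f"cases without diameter annotation excluded: {missing}")
        df = df[known]
    df["stratum"] = df["case_id"].map(lambda c: stratum_of(diameters_mm[c]))
    metric_cols = [c for c in df.columns if c not in ("case_id", "stratum")]
    rows = []
    for label, _, _ in SIZE_STRATA:
        sub = df[df["stratum"] == label]
        row = {"stratum": label, "n_cases": len(sub)}
        for c in metric_cols:
            row[c] = float(sub[c].mean()) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
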