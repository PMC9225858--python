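"""Segmentation evaluation: confusion counts and the eight derived metrics.

From per-pixel tallies TP, TN, FP, FN (TP = liver pixels predicted liver):

    SE  = TP / (TP + FN)            sensitivity / recall
    SP  = TN / (TN + FP)            specificity
    ACC = (TP + TN) / total         accuracy
    P   = TP / (TP + FP)            precision
    FPR = 1 - SP                    false-positive rate
    FNR = 1 - SE                    false-negative rate
    DSC = 2 TP / (FP + 2 TP + FN)   Dice coefficient (= foreground F1)
    JSI = DSC / (2 - DSC)           Jaccard index (intersection over union)

Ratios with a zero denominator are reported as NaN with the metric name
flagged in ``undefined``, never as silent zeros.  Aggregation supports both
averaging per-unit metrics ("mean_of_metrics") and recomputing from pooled
counts ("pooled_counts"); the two differ in general and are labelled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "report",
    "jsi_from_dsc",
    "aggregate",
    "reports_to_dataframe",
    "METRIC_COLUMNS",
]

#: CSV layout: percent for the first six columns, fractions for the rates
METRIC_COLUMNS = ["DSC%", "JSI%", "ACC%", "Precision%", "SE%", "SP%", "FNR", "FPR"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ConfigError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    se: float
    sp: float
    acc: float
    precision: float
    fpr: float
    fnr: float
    jsi: float
    dsc: float
    counts: ConfusionCounts | None = None
    id: str = ""
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"se": self.se, "sp": self.sp, "acc": self.acc,
                "precision": self.precision, "fpr": self.fpr, "fnr": self.fnr,
                "jsi": self.jsi, "dsc": self.dsc}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact per-pixel confusion tallies of two binary grids."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DataError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.all(np.isin(np.unique(arr), (0, 1))):
            raise DataError(f"{name} is not binary")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def report(counts: ConfusionCounts, id: str = "") -> MetricsReport:
    """All eight metrics from confusion counts.

    Zero-denominator ratios come back NaN and are listed in ``undefined``.
    """
    if counts.total == 0:
        raise DataError("cannot compute metrics from all-zero counts")
    undefined: list[str] = []
    se = _ratio(counts.tp, counts.tp + counts.fn, "se", undefined)
    sp = _ratio(counts.tn, counts.tn + counts.fp, "sp", undefined)
    acc = (counts.tp + counts.tn) / counts.total
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", undefined)
    dsc = _ratio(2 * counts.tp, counts.fp + 2 * counts.tp + counts.fn,
                 "dsc", undefined)
    jsi = dsc / (2.0 - dsc) if not math.isnan(dsc) else math.nan
    if math.isnan(jsi) and "dsc" in undefined:
        undefined.append("jsi")
    fpr = 1.0 - sp
    fnr = 1.0 - se
    if math.isnan(sp):
        undefined.append("fpr")
    if math.isnan(se):
        undefined.append("fnr")
    return MetricsReport(se=se, sp=sp, acc=acc, precision=precision, fpr=fpr,
                         fnr=fnr, jsi=jsi, dsc=dsc, counts=counts, id=id,
                         undefined=tuple(undefined))


def jsi_from_dsc(dsc: float) -> float:
    """Jaccard index from Dice: JSI = DSC / (2 - DSC)."""
    if not 0.0 <= dsc <= 1.0:
        raise ConfigError(f"dsc must lie in [0, 1]; got {dsc}")
    return dsc / (2.0 - dsc)


def aggregate(reports: list[MetricsReport],
              mode: str = "pooled_counts") -> MetricsReport:
    """Combine per-unit reports across slices/volumes/datasets.

    'pooled_counts' sums the confusion counts and recomputes every metric;
    'mean_of_metrics' averages each metric across units (NaN entries are
    excluded with a warning).  The two coincide only for equal-size units.
    """
    if not reports:
        raise ConfigError("cannot aggregate an empty report list")
    if mode == "pooled_counts":
        if any(r.counts is None for r in reports):
            raise ConfigError("pooled_counts requires counts on every report")
        total = reports[0].counts
        for r in reports[1:]:
            total = total + r.counts
        out = report(total, id="pooled")
        return out
    if mode == "mean_of_metrics":
        means = {}
        for name in ("se", "sp", "acc", "precision", "fpr", "fnr", "jsi", "dsc"):
            values = np.array([getattr(r, name) for r in reports], dtype=float)
            defined = values[~np.isnan(values)]
            if len(defined) < len(values):
                warnings.warn(
                    f"{name}: {len(values) - len(defined)} undefined unit(s) "
                    "excluded from the mean", stacklevel=2)
            means[name] = float(defined.mean()) if len(defined) else math.nan
        return MetricsReport(**means, counts=None, id="mean",
                             undefined=tuple(k for k, v in means.items()
                                             if math.isnan(v)))
    raise ConfigError(f"unknown aggregation mode {mode!r}")


def reports_to_dataframe(reports: list[MetricsReport]):
    """Tabulate reports with the standard column layout (percent for the
    first six metrics, fractions for FNR/FPR)."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append({
            "id": r.id,
            "DSC%": 100.0 * r.dsc,
            "JSI%": 100.0 * r.jsi,
            "ACC%": 100.0 * r.acc,
            "Precision%": 100.0 * r.precision,
            "SE%": 100.0 * r.se,
            "SP%": 100.0 * r.sp,
            "FNR": r.fnr,
            "FPR": r.fpr,
        })
    return pd.DataFrame(rows, columns=["id"] + METRIC_COLUMNS)
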