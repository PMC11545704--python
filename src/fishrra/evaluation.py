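"""Classification metrics and per-dekad accuracy reports for RRA maps.

Besides the usual accuracy / precision / recall / F1 (positive class =
high RRA), predictions are summarised per dekad with three rates: the share
of predicted-low cells that are truly low, the share of predicted-high cells
that are truly high (per-class precisions), and overall accuracy. A rate
whose denominator is zero — e.g. no high cells predicted early in the
season — is reported as undefined (None), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; the positive class is high RRA."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None


def metrics(cm: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall and F1 from confusion counts.

    Components with a zero denominator are returned as None rather than
    silently coerced to zero.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    f1 = f1_from_pr(precision, recall)
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def f1_from_pr(precision: float | None, recall: float | None) -> float | None:
    """Harmonic mean of precision and recall; None when undefined."""
    if precision is None or recall is None or (precision + recall) == 0:
        return None
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class DekadReport:
    """Per-dekad prediction rates; None marks an undefined denominator."""

    dekad: str
    counts: ConfusionCounts
    low_acc: float | None  # correct low predictions / predicted low
    high_acc: float | None  # correct high predictions / predicted high
    overall_acc: float


def _confusion(pred: np.ndarray, obs: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(((pred == "high") & (obs == "high")).sum()),
        fp=int(((pred == "high") & (obs == "low")).sum()),
        fn=int(((pred == "low") & (obs == "high")).sum()),
        tn=int(((pred == "low") & (obs == "low")).sum()),
    )


def per_dekad_report(
    predictions: pd.DataFrame,
    observations: pd.DataFrame,
    pred_col: str = "pred_label",
    obs_col: str = "rra_label",
) -> list[DekadReport]:
    """One report per dekad shared by the prediction and observation tables.

    Tables are joined on (i, j, dekad); a key present in one table but not
    the other raises with the offending keys listed.
    """
    keys = ["i", "j", "dekad"]
    merged = predictions[keys + [pred_col]].merge(
        observations[keys + [obs_col]], on=keys, how="outer", indicator=True
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        missing = bad[keys].to_records(index=False).tolist()
        raise ValueError(f"unmatched (cell, dekad) keys: {missing[:20]}")

    reports = []
    for dekad, grp in merged.groupby("dekad", sort=True):
        pred = grp[pred_col].to_numpy(dtype=str)
        obs = grp[obs_col].to_numpy(dtype=str)
        cm = _confusion(pred, obs)
        n_pred_low = cm.tn + cm.fn
        n_pred_high = cm.tp + cm.fp
        reports.append(
            DekadReport(
                dekad=str(dekad),
                counts=cm,
                low_acc=cm.tn / n_pred_low if n_pred_low else None,
                high_acc=cm.tp / n_pred_high if n_pred_high else None,
                overall_acc=(cm.tp + cm.tn) / cm.total,
            )
        )
    return reports


def reports_frame(reports: Sequence[DekadReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dekad": r.dekad,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "tn": r.counts.tn,
                "low_acc": r.low_acc,
                "high_acc": r.high_acc,
                "overall_acc": r.overall_acc,
            }
            for r in reports
        ]
    )


@dataclass(frozen=True)
class SeasonSummary:
    counts: ConfusionCounts
    metrics: Metrics
    monthly_high_counts: dict[str, int]  # predicted-high cells per "YYYY-MM"
    monthly_high_ratio_to_january: dict[str, float | None]


def season_summary(reports: Sequence[DekadReport]) -> SeasonSummary:
    """Pool per-dekad counts over a season and summarise monthly high-RRA extent.

    Monthly counts are predicted-high cells summed over each month's dekads;
    ratios are relative to the season's January count (None when January has
    no predicted-high cells or is absent).
    """
    if not reports:
        raise ValueError("no reports to summarise")
    pooled = ConfusionCounts(0, 0, 0, 0)
    monthly: dict[str, int] = {}
    for r in reports:
        pooled = pooled + r.counts
        month = r.dekad[:7]  # "YYYY-MM"
        monthly[month] = monthly.get(month, 0) + r.counts.tp + r.counts.fp
    jan = next((v for k, v in monthly.items() if k.endswith("-01")), None)
    ratios = {
        m: (v / jan if jan else None)
        for m, v in monthly.items()
    }
    return SeasonSummary(
        counts=pooled,
        metrics=metrics(pooled),
        monthly_high_counts=monthly,
        monthly_high_ratio_to_january=ratios,
    )
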