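"""Performance metrics, leakage filtering and stratified reports.

The metric suite covers Matthews correlation coefficient, accuracy, F1,
Fowlkes-Mallows index, sensitivity and specificity computed from a binary
confusion matrix, plus a rank-based (Mann-Whitney) ROC AUC.  Stratified
reports break performance down by four CNV length bins (boundaries at
10 kb, 100 kb, 1 Mb, 10 Mb) and by gain/loss type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import CNVType, PathogenicityLabel
from .popfreq import reciprocal_overlap

DEFAULT_RO_LEAK = 0.5

#: length-bin upper edges in bp; bins are left-open, right-closed
LENGTH_BIN_EDGES = (10_000, 100_000, 1_000_000, 10_000_000)
LENGTH_BIN_NAMES = ("0-10kb", "10kb-100kb", "100kb-1Mb", "1Mb-10Mb")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    mcc: float
    accuracy: float
    f1: float
    fowlkes_mallows: float
    sensitivity: float
    specificity: float
    auc: Optional[float] = None
    stratum: str = "all"
    n: int = 0
    counts: Optional[ConfusionCounts] = None
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "stratum": self.stratum,
            "n": self.n,
            "mcc": self.mcc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "fowlkes_mallows": self.fowlkes_mallows,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.flags:
            d["flags"] = list(self.flags)
        return d


def _safe_div(num: float, den: float):
    return num / den if den else float("nan")


def confusion_metrics(c: ConfusionCounts) -> MetricsReport:
    """MCC, accuracy, F1, Fowlkes-Mallows, sensitivity and specificity.

    MCC's denominator vanishes whenever a margin of the confusion matrix is
    empty; by convention the metric is then reported as 0 with a flag.
    Undefined ratios (empty positive or negative class) come back as NaN
    with a flag rather than an arbitrary number.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion matrix")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    flags = []

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        mcc = 0.0
        flags.append("mcc_zero_denominator")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den

    accuracy = (tp + tn) / (tp + tn + fn + fp)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    fm = math.sqrt(_safe_div(tp, tp + fp) * _safe_div(tp, tp + fn)) \
        if (tp + fp) and (tp + fn) else float("nan")
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    for name, v in (("f1", f1), ("fowlkes_mallows", fm),
                    ("sensitivity", sens), ("specificity", spec)):
        if isinstance(v, float) and math.isnan(v):
            flags.append(f"{name}_undefined")
    return MetricsReport(
        mcc=mcc, accuracy=accuracy, f1=f1, fowlkes_mallows=fm,
        sensitivity=sens, specificity=spec, n=c.total, counts=c, flags=flags,
    )


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must align")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: the Mann-Whitney statistic with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class LeakageReport:
    retained: list
    dropped: list

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def leakage_filter(train: Sequence, validation: Sequence,
                   ro_min: float = DEFAULT_RO_LEAK) -> LeakageReport:
    """Drop training CNVs sharing >= ro_min reciprocal overlap with validation.

    The comparison is type-agnostic (a gain and a loss over the same segment
    still constitute shared information about the region), so this drops
    conservatively.
    """
    from collections import defaultdict
    from intervaltree import IntervalTree

    trees = defaultdict(IntervalTree)
    for v in validation:
        trees[v.chrom].addi(v.start, v.end + 1, v)
    retained, dropped = [], []
    for t in train:
        leaky = any(
            reciprocal_overlap(t, hit.data) >= ro_min
            for hit in trees[t.chrom].overlap(t.start, t.end + 1)
        )
        (dropped if leaky else retained).append(t)
    return LeakageReport(retained=retained, dropped=dropped)


def collapse_to_binary(labels5) -> list:
    """Five-tier -> binary: pathogenic-side 1, benign-side 0, uncertain None."""
    out = []
    for v in labels5:
        lab = PathogenicityLabel.coerce(v)
        if lab in (PathogenicityLabel.PATHOGENIC, PathogenicityLabel.LIKELY_PATHOGENIC):
            out.append(1)
        elif lab in (PathogenicityLabel.BENIGN, PathogenicityLabel.LIKELY_BENIGN):
            out.append(0)
        else:
            out.append(None)
    return out


def length_bin(length_bp: int) -> Optional[str]:
    """Left-open right-closed length bins tiling (0, 10 Mb]."""
    lo = 0
    for hi, name in zip(LENGTH_BIN_EDGES, LENGTH_BIN_NAMES):
        if lo < length_bp <= hi:
            return name
        lo = hi
    return None


def stratified_report(records, y_true, y_pred, scores=None) -> list:
    """Metrics for all CNVs, the four length bins, and gain/loss strata.

    ``records`` supply length and type per row; ``y_true``/``y_pred`` are
    binary.  An empty stratum yields a flagged placeholder report.  When
    ``scores`` are given, AUC is included for strata containing both classes.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if not (len(records) == len(y_true) == len(y_pred)):
        raise ValueError("records, y_true and y_pred must align")
    scores = None if scores is None else np.asarray(scores, dtype=float)

    strata = {"all": np.ones(len(records), dtype=bool)}
    lengths = np.asarray([r.length for r in records])
    lo = 0
    for hi, name in zip(LENGTH_BIN_EDGES, LENGTH_BIN_NAMES):
        strata[name] = (lengths > lo) & (lengths <= hi)
        lo = hi
    types = np.asarray([CNVType.coerce(r.cnv_type) is CNVType.GAIN for r in records])
    strata["gain"] = types
    strata["loss"] = ~types

    reports = []
    for name, mask in strata.items():
        if not mask.any():
            reports.append(MetricsReport(
                mcc=float("nan"), accuracy=float("nan"), f1=float("nan"),
                fowlkes_mallows=float("nan"), sensitivity=float("nan"),
                specificity=float("nan"), stratum=name, n=0,
                flags=["empty_stratum"],
            ))
            continue
        rep = confusion_metrics(confusion_from_predictions(y_true[mask], y_pred[mask]))
        rep.stratum = name
        if scores is not None and len(np.unique(y_true[mask])) == 2:
            rep.auc = roc_auc(scores[mask], y_true[mask])
        reports.append(rep)
    return reports


def relative_improvement(a: float, b: float) -> float:
    """(a - b) / |b| * 100; undefined for b == 0."""
    if b == 0:
        raise ValueError("relative improvement is undefined for a zero baseline")
    return (a - b) / abs(b) * 100.0
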