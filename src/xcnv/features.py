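"""Thirty-column CNV feature matrix.

Features fall in four groups:

* universal (4): CNV length, CNV type (gain=1 / loss=0), and the carrier
  frequency looked up in the reference population database, split into a
  gain-PAF and a loss-PAF column (the query's frequency lands in the column
  of its own type, the other is 0);
* coding (13): nine SNV-level deleteriousness aggregates (FATHMM, LR, LRT,
  MutationAssessor, MutationTaster, PolyPhen2, RadialSVM, SIFT, VEST3),
  three gene-level haploinsufficiency scores (pLI, Episcore, GHIS), and the
  number of overlapped protein-coding genes;
* noncoding (8): overlap with the six ENCODE cCRE classes plus the fraction
  of covered bases under the genome-wide 1% and 5% CDTS percentiles;
* genome-wide (5): per-base aggregates of CADD, GERP, phyloP 100-way,
  phyloP 46-way and SiPhy 29-way.

Positional scores aggregate as the mean over covered (scored) bases inside
the CNV; a CNV overlapping no scored base is missing for that feature and
is later imputed with the training-set column minimum.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import Interval, CNVType, normalize_chrom
from .popfreq import AFDatabase, lookup_af

# ---------------------------------------------------------------- schema

UNIVERSAL_FEATURES = ["length", "cnv_type", "gain_PAF", "loss_PAF"]
CODING_TRACK_FEATURES = [
    "FATHMM", "LR", "LRT", "MutationAssessor", "MutationTaster",
    "PolyPhen2", "RadialSVM", "SIFT", "VEST3",
]
GENE_SCORE_FEATURES = ["pLI", "Episcore", "GHIS"]
CODING_FEATURES = CODING_TRACK_FEATURES + GENE_SCORE_FEATURES + ["n_coding_genes"]
CCRE_CLASSES = ["PLS", "pELS", "dELS", "CTCF-bound", "CTCF-only", "DNase-H3K4me3"]
NONCODING_FEATURES = CCRE_CLASSES + ["CDTS_1pct", "CDTS_5pct"]
GENOMEWIDE_FEATURES = ["CADD", "GERP", "phyloP_100way", "phyloP_46way", "SiPhy_29way"]

FEATURE_GROUPS = {
    "universal": UNIVERSAL_FEATURES,
    "coding": CODING_FEATURES,
    "noncoding": NONCODING_FEATURES,
    "genome_wide": GENOMEWIDE_FEATURES,
}
FEATURE_SCHEMA = (
    UNIVERSAL_FEATURES + CODING_FEATURES + NONCODING_FEATURES + GENOMEWIDE_FEATURES
)
assert len(FEATURE_SCHEMA) == 30

#: default genome-wide CDTS percentile thresholds (standard-normal scale of
#: the synthetic tracks); real tracks supply their own via AnnotationBundle.
DEFAULT_CDTS_THRESHOLDS = {1: -2.3263478740408408, 5: -1.6448536269514722}


# ---------------------------------------------------------------- containers

class ScoreTrack:
    """Sparse per-position score track (chrom, 1-based position) -> value."""

    def __init__(self, name: str, positions=None):
        self.name = name
        self._pos = {}
        self._score = {}
        if positions:
            self._build(positions)

    def _build(self, positions):
        by_chrom = defaultdict(list)
        for (chrom, pos), score in positions.items():
            if not np.isfinite(score):
                raise ValueError(f"non-finite score in track {self.name!r}")
            by_chrom[normalize_chrom(chrom)].append((int(pos), float(score)))
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            if len(np.unique(pos)) != len(pos):
                raise ValueError(f"duplicate positions in track {self.name!r}")
            self._pos[chrom] = pos
            self._score[chrom] = np.array([s for _, s in pairs], dtype=float)

    @classmethod
    def from_arrays(cls, name, chroms, positions, scores) -> "ScoreTrack":
        t = cls(name)
        order = np.lexsort((np.asarray(positions), np.asarray(chroms, dtype=object)))
        chroms = np.asarray(chroms, dtype=object)[order]
        positions = np.asarray(positions, dtype=np.int64)[order]
        scores = np.asarray(scores, dtype=float)[order]
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"non-finite score in track {name!r}")
        for chrom in pd.unique(chroms):
            m = chroms == chrom
            pos = positions[m]
            if len(np.unique(pos)) != len(pos):
                raise ValueError(f"duplicate positions in track {name!r}")
            c = normalize_chrom(chrom)
            t._pos[c] = pos
            t._score[c] = scores[m]
        return t

    @classmethod
    def from_chrom_arrays(cls, name, per_chrom) -> "ScoreTrack":
        """Build from {chrom: (positions, scores)}; duplicates keep the last
        value (later writes win), mirroring dict construction."""
        t = cls(name)
        for chrom, (pos, scores) in per_chrom.items():
            pos = np.asarray(pos, dtype=np.int64)
            scores = np.asarray(scores, dtype=float)
            if not np.all(np.isfinite(scores)):
                raise ValueError(f"non-finite score in track {name!r}")
            c = normalize_chrom(chrom)
            if pos.size == 0:
                t._pos[c] = pos
                t._score[c] = scores
                continue
            order = np.argsort(pos, kind="stable")
            pos, scores = pos[order], scores[order]
            # keep the last of each run of equal positions
            keep = np.r_[pos[1:] != pos[:-1], True]
            t._pos[c] = pos[keep]
            t._score[c] = scores[keep]
        return t

    def values_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores at positions inside [start, end] (1-based inclusive)."""
        chrom = normalize_chrom(chrom)
        pos = self._pos.get(chrom)
        if pos is None:
            return np.empty(0)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return self._score[chrom][lo:hi]

    def __len__(self):
        return sum(len(p) for p in self._pos.values())

    def items(self):
        for chrom in sorted(self._pos):
            for p, s in zip(self._pos[chrom], self._score[chrom]):
                yield chrom, int(p), float(s)


class GeneScoreTable:
    """Gene intervals with one score per gene (e.g. pLI, Episcore, GHIS)."""

    def __init__(self, name: str, rows=None):
        # rows: iterable of (chrom, start, end, gene, score)
        self.name = name
        self.rows = []
        self._trees = defaultdict(IntervalTree)
        for chrom, start, end, gene, score in rows or []:
            self.add(chrom, start, end, gene, score)

    def add(self, chrom, start, end, gene, score):
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for gene {gene!r} in {self.name!r}")
        iv = Interval(chrom, int(start), int(end))
        self.rows.append((iv.chrom, iv.start, iv.end, str(gene), float(score)))
        self._trees[iv.chrom].addi(iv.start, iv.end + 1, (str(gene), float(score)))

    def overlapping(self, chrom, start, end):
        chrom = normalize_chrom(chrom)
        return [hit.data for hit in self._trees[chrom].overlap(start, end + 1)]


class RegionSet:
    """Named set of genomic regions (e.g. one cCRE class)."""

    def __init__(self, name: str, intervals=None):
        self.name = name
        self.intervals = []
        self._trees = defaultdict(IntervalTree)
        for chrom, start, end in intervals or []:
            self.add(chrom, start, end)

    def add(self, chrom, start, end):
        iv = Interval(chrom, int(start), int(end))
        self.intervals.append(iv)
        self._trees[iv.chrom].addi(iv.start, iv.end + 1)

    def covered_bp(self, chrom, start, end) -> int:
        """Bases of [start, end] covered by the union of regions."""
        chrom = normalize_chrom(chrom)
        hits = sorted(
            (max(h.begin, start), min(h.end - 1, end))
            for h in self._trees[chrom].overlap(start, end + 1)
        )
        covered, cur_lo, cur_hi = 0, None, None
        for lo, hi in hits:
            if cur_lo is None:
                cur_lo, cur_hi = lo, hi
            elif lo <= cur_hi + 1:
                cur_hi = max(cur_hi, hi)
            else:
                covered += cur_hi - cur_lo + 1
                cur_lo, cur_hi = lo, hi
        if cur_lo is not None:
            covered += cur_hi - cur_lo + 1
        return covered

    def overlapping_total_bp(self, chrom, start, end) -> int:
        """Total length of regions that touch [start, end] (not clipped)."""
        chrom = normalize_chrom(chrom)
        return sum(
            h.end - h.begin for h in self._trees[chrom].overlap(start, end + 1)
        )


@dataclass
class AnnotationBundle:
    """All annotation sources keyed by feature name."""

    tracks: dict = field(default_factory=dict)        # name -> ScoreTrack
    gene_tables: dict = field(default_factory=dict)   # name -> GeneScoreTable
    region_sets: dict = field(default_factory=dict)   # name -> RegionSet
    cdts_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_CDTS_THRESHOLDS)
    )


@dataclass
class FeatureMatrix:
    """CNVs x 30 features with an explicit missingness mask."""

    data: pd.DataFrame
    mask: pd.DataFrame  # True where the value was missing pre-imputation
    imputed: bool = False

    def __post_init__(self):
        if list(self.data.columns) != FEATURE_SCHEMA:
            raise ValueError(
                f"feature matrix must have exactly the {len(FEATURE_SCHEMA)} "
                "schema columns in order"
            )
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")

    @property
    def columns(self):
        return list(self.data.columns)

    def __len__(self):
        return len(self.data)


# ---------------------------------------------------------------- operations

def aggregate_positional(cnv, track: ScoreTrack, denominator: str = "covered"):
    """Aggregate a per-position track over a CNV.

    With ``denominator='covered'`` (default) this is the mean score over
    scored bases inside the CNV; with ``'total'`` the sum is divided by the
    full CNV length.  Returns NaN when no scored base falls inside.
    """
    if denominator not in ("covered", "total"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    vals = track.values_in(cnv.chrom, cnv.start, cnv.end)
    if vals.size == 0:
        return float("nan")
    denom = vals.size if denominator == "covered" else (cnv.end - cnv.start + 1)
    return float(vals.sum() / denom)


def gene_score(cnv, table: GeneScoreTable, mode: str = "max"):
    """Reduce scores of genes overlapping the CNV; NaN when none overlap."""
    if mode not in ("max", "mean"):
        raise ValueError(f"unknown gene-score mode {mode!r}")
    scores = [s for _, s in table.overlapping(cnv.chrom, cnv.start, cnv.end)]
    if not scores:
        return float("nan")
    return float(max(scores) if mode == "max" else np.mean(scores))


def region_fraction(cnv, rs: RegionSet, mode: str = "overlap_fraction") -> float:
    """Score a CNV against a region set.

    ``overlap_fraction`` (default): covered bp / CNV length, in [0, 1].
    ``length_ratio``: CNV length / total length of touched regions (0 when
    nothing overlaps) — an unbounded alternative kept for comparability.
    """
    if mode not in ("overlap_fraction", "length_ratio"):
        raise ValueError(f"unknown region mode {mode!r}")
    length = cnv.end - cnv.start + 1
    if mode == "overlap_fraction":
        return rs.covered_bp(cnv.chrom, cnv.start, cnv.end) / length
    total = rs.overlapping_total_bp(cnv.chrom, cnv.start, cnv.end)
    return length / total if total else 0.0


def cdts_feature(cnv, cdts: ScoreTrack, percentile: int, thresholds: dict):
    """Fraction of a CNV's scored bases under the genome-wide CDTS percentile.

    Low CDTS marks sequence depleted of variation (constrained); the feature
    is the share of covered bases below the 1% or 5% genome-wide threshold.
    NaN when no scored base falls inside the CNV.
    """
    if percentile not in thresholds:
        raise ValueError(
            f"no CDTS threshold for percentile {percentile} "
            f"(have {sorted(thresholds)})"
        )
    vals = cdts.values_in(cnv.chrom, cnv.start, cnv.end)
    if vals.size == 0:
        return float("nan")
    return float(np.mean(vals < thresholds[percentile]))


def universal_features(cnv, afdb: Optional[AFDatabase], ro_min: float = 0.7):
    """(length, type gain=1/loss=0, gain-PAF, loss-PAF) for one CNV."""
    af = lookup_af(cnv, afdb, ro_min) if afdb is not None else 0.0
    is_gain = CNVType.coerce(cnv.cnv_type) is CNVType.GAIN
    return (
        float(cnv.end - cnv.start + 1),
        1.0 if is_gain else 0.0,
        af if is_gain else 0.0,
        0.0 if is_gain else af,
    )


def impute_missing(
    m: FeatureMatrix, reference: Optional[FeatureMatrix] = None
) -> FeatureMatrix:
    """Replace missing cells by per-column minima of the training matrix.

    At training time ``reference`` is None and minima come from ``m`` itself;
    at prediction time pass the training matrix (or reuse its stored minima)
    so new batches are imputed consistently.
    """
    ref = reference if reference is not None else m
    minima = column_minima(ref)
    return impute_with_minima(m, minima)


def column_minima(m: FeatureMatrix) -> pd.Series:
    """Per-column minima over non-missing cells; error on an all-missing column."""
    observed = m.data.where(~m.mask)
    minima = observed.min(axis=0, skipna=True)
    bad = minima.index[minima.isna()]
    if len(bad):
        raise ValueError(
            "cannot impute: column(s) entirely missing in training data: "
            + ", ".join(bad)
        )
    return minima


def impute_with_minima(m: FeatureMatrix, minima: pd.Series) -> FeatureMatrix:
    data = m.data.copy()
    for col in data.columns:
        data.loc[m.mask[col], col] = minima[col]
    if not np.isfinite(data.to_numpy()).all():
        raise ValueError("non-finite values remain after imputation")
    return FeatureMatrix(
        data=data, mask=pd.DataFrame(False, index=data.index, columns=data.columns),
        imputed=True,
    )


def build_feature_matrix(
    cnvs: list,
    bundle: AnnotationBundle,
    afdb: Optional[AFDatabase] = None,
    ro_min: float = 0.7,
    gene_mode: str = "max",
    region_mode: str = "overlap_fraction",
    denominator: str = "covered",
) -> FeatureMatrix:
    """Assemble the 30-column feature matrix for a list of CNVs.

    Every track, gene table and region set named by the schema must be
    present in the bundle; a missing source raises an error naming it.
    Row order follows the input order.
    """
    needed_tracks = CODING_TRACK_FEATURES + GENOMEWIDE_FEATURES + ["CDTS"]
    for name in needed_tracks:
        if name not in bundle.tracks:
            raise ValueError(f"annotation bundle is missing score track {name!r}")
    for name in GENE_SCORE_FEATURES:
        if name not in bundle.gene_tables:
            raise ValueError(f"annotation bundle is missing gene table {name!r}")
    for name in CCRE_CLASSES:
        if name not in bundle.region_sets:
            raise ValueError(f"annotation bundle is missing region set {name!r}")

    rows = []
    gene_universe = bundle.gene_tables[GENE_SCORE_FEATURES[0]]
    for cnv in cnvs:
        row = {}
        (row["length"], row["cnv_type"], row["gain_PAF"], row["loss_PAF"]) = (
            universal_features(cnv, afdb, ro_min)
        )
        for name in CODING_TRACK_FEATURES:
            row[name] = aggregate_positional(cnv, bundle.tracks[name], denominator)
        for name in GENE_SCORE_FEATURES:
            row[name] = gene_score(cnv, bundle.gene_tables[name], gene_mode)
        row["n_coding_genes"] = float(
            len(gene_universe.overlapping(cnv.chrom, cnv.start, cnv.end))
        )
        for name in CCRE_CLASSES:
            row[name] = region_fraction(cnv, bundle.region_sets[name], region_mode)
        cdts = bundle.tracks["CDTS"]
        row["CDTS_1pct"] = cdts_feature(cnv, cdts, 1, bundle.cdts_thresholds)
        row["CDTS_5pct"] = cdts_feature(cnv, cdts, 5, bundle.cdts_thresholds)
        for name in GENOMEWIDE_FEATURES:
            row[name] = aggregate_positional(cnv, bundle.tracks[name], denominator)
        rows.append(row)

    data = pd.DataFrame(rows, columns=FEATURE_SCHEMA, dtype=float)
    if data.empty:
        data = pd.DataFrame(columns=FEATURE_SCHEMA, dtype=float)
    mask = data.isna()
    return FeatureMatrix(data=data, mask=mask)
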