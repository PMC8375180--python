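"""Synthetic CNV populations, annotation bundles and five-tier labels.

The generator emulates the structure of public CNV repositories and
annotation resources so every pipeline stage is exercisable without
downloads:

* a small diploid genome (two 6 Mb chromosomes by default);
* "true" CNVs placed on a slot grid so that distinct events are always
  separated by more than the unification window, each carrying a latent
  liability z ~ N(0, 1);
* carrier samples drawn across nine population groups, with carrier counts
  tied to -z (pathogenic CNVs are rare, mirroring purifying selection), and
  each carrier's call replicated with Normal breakpoint jitter to mimic
  platform discordance;
* sparse per-position score tracks whose within-CNV means shift with z,
  gene tables with liability-linked haploinsufficiency scores, and cCRE
  region sets preferentially placed over high-liability CNVs;
* five-tier labels from quantile bands of a noisy linear function of the
  latent liability — the band edges are recorded as ground truth for
  cutoff-recovery tests.

Setting ``effect_size=0`` severs every feature-label link, giving the null
condition used for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .core import CNVRecord, CNVType, EthnicGroup, Interval, PathogenicityLabel, LABEL_ORDER
from .features import (
    AnnotationBundle,
    CCRE_CLASSES,
    CODING_TRACK_FEATURES,
    GENE_SCORE_FEATURES,
    GENOMEWIDE_FEATURES,
    DEFAULT_CDTS_THRESHOLDS,
    GeneScoreTable,
    RegionSet,
    ScoreTrack,
)
from .popfreq import AFDatabase, build_af_database
from .unify import unify


def _default_chroms():
    return {"1": 6_000_000, "2": 6_000_000}


def _default_groups():
    return {"NFE": 100, "EAS": 60, "AFR": 40}


@dataclass
class SimConfig:
    """Generator parameters; defaults define the standard study conditions."""

    chrom_lengths: dict = field(default_factory=_default_chroms)
    n_samples_per_group: dict = field(default_factory=_default_groups)
    n_true_cnvs: int = 500
    length_log10_range: tuple = (3.0, 4.7)   # 1 kb .. ~50 kb
    gain_fraction: float = 0.4
    jitter_sd: float = 20.0                  # bp, breakpoint discordance
    max_replicates_per_carrier: int = 2
    effect_size: float = 1.0                 # global feature-liability coupling
    af_effect: float = 1.5                   # liability -> rarity coupling
    label_noise_sd: float = 0.3
    coverage: float = 0.02                   # fraction of CNV bases scored
    max_positions_per_cnv: int = 40
    track_dropout: float = 0.1               # P(no scored base for a CNV/track)
    background_positions_per_chrom: int = 200
    band_quantiles: tuple = (0.30, 0.40, 0.60, 0.70)
    seed: int = 0

    def __post_init__(self):
        if self.n_true_cnvs < 1 or not self.chrom_lengths:
            raise ValueError("need at least one CNV and one chromosome")
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if any(n <= 0 for n in self.n_samples_per_group.values()):
            raise ValueError("group sample counts must be positive")

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_group.values())


@dataclass
class TrueCNV:
    idx: int
    interval: Interval
    cnv_type: CNVType
    z: float  # latent pathogenicity liability

    @property
    def record(self) -> CNVRecord:
        return CNVRecord(
            self.interval.chrom, self.interval.start, self.interval.end,
            self.cnv_type, source="truth",
        )


@dataclass
class SimulatedDataset:
    """Everything one run of the generator produces."""

    config: SimConfig
    true_cnvs: list
    samples: list                 # (sample_id, EthnicGroup)
    observed: list                # jittered replicate CNVRecords
    observed_truth: list          # observed index -> true CNV index
    bundle: AnnotationBundle
    afdb: AFDatabase
    records: list                 # one labeled query CNVRecord per true CNV
    labels: list                  # PathogenicityLabel per true CNV
    latent: np.ndarray
    band_edges: np.ndarray        # latent quantile boundaries (ground truth)


# ------------------------------------------------------------- population

def _sample_roster(cfg: SimConfig):
    samples = []
    for group, n in cfg.n_samples_per_group.items():
        g = EthnicGroup.coerce(group)
        samples.extend((f"{g.value}_{i:04d}", g) for i in range(n))
    return samples


def simulate_true_cnvs(cfg: SimConfig, rng: np.random.Generator) -> list:
    """Place true CNVs on a per-chromosome slot grid with latent liabilities.

    Slot placement guarantees same-chromosome starts differ by well over the
    100 bp unification window, so distinct true events never merge.  A CNV
    that would run off its chromosome is truncated (never below 100 bp).
    """
    total_len = sum(cfg.chrom_lengths.values())
    alloc, rem = {}, cfg.n_true_cnvs
    chroms = sorted(cfg.chrom_lengths)
    for i, chrom in enumerate(chroms):
        if i == len(chroms) - 1:
            alloc[chrom] = rem
        else:
            n = round(cfg.n_true_cnvs * cfg.chrom_lengths[chrom] / total_len)
            alloc[chrom] = min(n, rem)
            rem -= alloc[chrom]

    lo10, hi10 = cfg.length_log10_range
    out = []
    idx = 0
    margin = 300  # keeps adjacent jittered starts > GW apart
    for chrom in chroms:
        n = alloc[chrom]
        if n == 0:
            continue
        slot = cfg.chrom_lengths[chrom] // n
        if slot <= margin:
            raise ValueError(
                f"chromosome {chrom} too short for {n} well-separated CNVs"
            )
        for k in range(n):
            start = k * slot + 1 + int(rng.integers(0, slot - margin))
            length = int(round(10 ** rng.uniform(lo10, hi10)))
            end = min(start + length - 1, cfg.chrom_lengths[chrom])
            end = max(end, start + 99)
            cnv_type = CNVType.GAIN if rng.random() < cfg.gain_fraction else CNVType.LOSS
            out.append(TrueCNV(idx, Interval(chrom, start, end), cnv_type, float(rng.normal())))
            idx += 1
    return out


def simulate_cnv_population(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Emit observed (replicated, jittered) calls for a simulated population.

    Returns ``(true_cnvs, samples, observed, observed_truth)`` where
    ``observed_truth[i]`` is the index of the true CNV behind observed call
    ``i``.  Carrier counts fall with liability z (rarity of pathogenic
    variants); each carrier's call appears 1..max_replicates times with
    independent Normal(0, jitter_sd) endpoint jitter, truncated so that
    start stays >= 1 and start <= end.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    true_cnvs = simulate_true_cnvs(cfg, rng)
    samples = _sample_roster(cfg)
    observed, truth = [], []
    n_samples = len(samples)
    for t in true_cnvs:
        p = float(expit(-1.2 - cfg.af_effect * t.z))
        n_carriers = 1 + int(rng.binomial(min(30, n_samples - 1), p))
        carrier_idx = rng.choice(n_samples, size=n_carriers, replace=False)
        for ci in carrier_idx:
            sid, group = samples[ci]
            n_rep = int(rng.integers(1, cfg.max_replicates_per_carrier + 1))
            for _ in range(n_rep):
                ds, de = np.round(rng.normal(0, cfg.jitter_sd, size=2)).astype(int)
                s = max(1, t.interval.start + int(ds))
                e = max(s, t.interval.end + int(de))
                observed.append(CNVRecord(
                    t.interval.chrom, s, e, t.cnv_type,
                    sample_id=sid, group=group, source="sim",
                ))
                truth.append(t.idx)
    return true_cnvs, samples, observed, truth


# ------------------------------------------------------------- annotations

#: per-track liability coupling weights (multiplied by cfg.effect_size);
#: CDTS is negative because constrained sequence has *low* scores
_TRACK_WEIGHTS = {name: 0.8 for name in CODING_TRACK_FEATURES}
_TRACK_WEIGHTS.update({name: 0.6 for name in GENOMEWIDE_FEATURES})
_TRACK_WEIGHTS["CDTS"] = -0.8

#: cCRE classes whose placement probability rises with liability
_SIGNAL_CCRE = {"PLS", "CTCF-bound"}

_GENE_WEIGHTS = {"pLI": 1.5, "Episcore": 1.2, "GHIS": 1.0}
_GENE_NOISE = {"pLI": 0.7, "Episcore": 0.9, "GHIS": 1.0}


def simulate_annotation_bundle(
    cfg: SimConfig, true_cnvs: list, rng: Optional[np.random.Generator] = None
) -> AnnotationBundle:
    """Sparse score tracks, gene tables and cCRE region sets with known signal.

    Within each true CNV, track scores are Normal(w * effect_size * z, 1)
    at a sparse subset of bases; per-CNV/per-track dropout leaves some CNVs
    without coverage so missing-value paths are exercised.  Background
    positions across the genome score Normal(0, 1).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    track_names = list(_TRACK_WEIGHTS)
    # name -> chrom -> ([pos arrays], [score arrays]); later entries win on ties
    chunks = {name: {} for name in track_names}

    def _append(name, chrom, pos, vals):
        per_chrom = chunks[name].setdefault(chrom, ([], []))
        per_chrom[0].append(pos)
        per_chrom[1].append(vals)

    # background positions, shared grid per chromosome, per-track values
    for chrom, clen in sorted(cfg.chrom_lengths.items()):
        n_bg = min(cfg.background_positions_per_chrom, clen)
        bg_pos = rng.choice(clen, size=n_bg, replace=False) + 1
        for name in track_names:
            _append(name, chrom, bg_pos, rng.normal(0, 1, size=n_bg))

    for t in true_cnvs:
        length = t.interval.length
        n_pos = min(cfg.max_positions_per_cnv, max(2, int(cfg.coverage * length)))
        for name in track_names:
            if rng.random() < cfg.track_dropout:
                continue
            pos = rng.choice(length, size=min(n_pos, length), replace=False) + t.interval.start
            mu = _TRACK_WEIGHTS[name] * cfg.effect_size * t.z
            _append(name, t.interval.chrom, pos, rng.normal(mu, 1, size=len(pos)))

    tracks = {
        name: ScoreTrack.from_chrom_arrays(name, {
            chrom: (np.concatenate(ps), np.concatenate(vs))
            for chrom, (ps, vs) in per_chrom.items()
        })
        for name, per_chrom in chunks.items()
    }

    gene_tables = {name: GeneScoreTable(name) for name in GENE_SCORE_FEATURES}
    for t in true_cnvs:
        if rng.random() >= 0.7:
            continue  # CNV hits no annotated gene -> gene features missing
        length = t.interval.length
        g_len = max(50, int(length * rng.uniform(0.1, 0.5)))
        g_start = t.interval.start + int(rng.integers(0, max(1, length - g_len)))
        g_end = min(g_start + g_len - 1, t.interval.end)
        gene = f"G{t.idx:05d}"
        for name in GENE_SCORE_FEATURES:
            raw = _GENE_WEIGHTS[name] * cfg.effect_size * t.z + rng.normal(0, _GENE_NOISE[name])
            gene_tables[name].add(t.interval.chrom, g_start, g_end, gene, float(expit(raw)))

    region_sets = {name: RegionSet(name) for name in CCRE_CLASSES}
    for name in CCRE_CLASSES:
        rs = region_sets[name]
        for chrom, clen in sorted(cfg.chrom_lengths.items()):
            for _ in range(50):  # background regulatory elements
                s = int(rng.integers(1, clen - 2000))
                rs.add(chrom, s, s + int(rng.integers(100, 2000)))
        for t in true_cnvs:
            if name in _SIGNAL_CCRE:
                p_place = float(expit(-1.0 + 0.8 * cfg.effect_size * t.z))
            else:
                p_place = 0.2
            if rng.random() < p_place:
                length = t.interval.length
                r_len = max(50, int(length * rng.uniform(0.05, 0.2)))
                r_start = t.interval.start + int(rng.integers(0, max(1, length - r_len)))
                rs.add(t.interval.chrom, r_start, min(r_start + r_len - 1, t.interval.end))

    return AnnotationBundle(
        tracks=tracks, gene_tables=gene_tables, region_sets=region_sets,
        cdts_thresholds=dict(DEFAULT_CDTS_THRESHOLDS),
    )


# ------------------------------------------------------------- labels

def assign_labels(
    true_cnvs: list, cfg: SimConfig, rng: Optional[np.random.Generator] = None
):
    """Five-tier labels from quantile bands of a noisy latent score.

    latent = effect_size * z + Normal(0, label_noise_sd); with zero effect
    size the latent is pure Normal(0, 1) noise, independent of every
    feature.  Returns (labels, latent, band_edges); band edges are the
    latent quantiles that generated the labels.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    z = np.array([t.z for t in true_cnvs])
    if cfg.effect_size > 0:
        latent = cfg.effect_size * z + rng.normal(0, cfg.label_noise_sd, size=len(z))
    else:
        latent = rng.normal(0, 1.0, size=len(z))
    edges = np.quantile(latent, cfg.band_quantiles)
    ranks = np.searchsorted(edges, latent, side="right")
    labels = [LABEL_ORDER[r] for r in ranks]
    return labels, latent, edges


# ------------------------------------------------------------- one-stop

def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Run the full generator: population, annotations, AF database, labels.

    The AF database is produced by the package's own pipeline — observed
    calls are unified at the default 100 bp window and carrier frequencies
    computed per group — so query CNVs meet a database with realistic
    breakpoint noise.
    """
    rng = np.random.default_rng(cfg.seed)
    true_cnvs, samples, observed, truth = simulate_cnv_population(cfg, rng)
    bundle = simulate_annotation_bundle(cfg, true_cnvs, rng)
    labels, latent, edges = assign_labels(true_cnvs, cfg, rng)

    group_sizes = {
        EthnicGroup.coerce(g): n for g, n in cfg.n_samples_per_group.items()
    }
    unified = unify(observed, group_sizes=group_sizes)
    afdb = build_af_database(unified, group_sizes)

    records = [
        CNVRecord(
            t.interval.chrom, t.interval.start, t.interval.end, t.cnv_type,
            label=lab, source="query",
        )
        for t, lab in zip(true_cnvs, labels)
    ]
    return SimulatedDataset(
        config=cfg,
        true_cnvs=true_cnvs,
        samples=samples,
        observed=observed,
        observed_truth=truth,
        bundle=bundle,
        afdb=afdb,
        records=records,
        labels=labels,
        latent=latent,
        band_edges=edges,
    )
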