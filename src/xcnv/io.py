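"""Readers, writers and run configuration.

Internal coordinates are 1-based inclusive.  BED is converted on read
(start+1, end) and back on write; VCF structural-variant records span
POS+1..END (the anchor base at POS is not part of the affected segment),
with SVTYPE DEL -> loss and DUP -> gain.  TSV is the lossless native
format.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import CNVRecord, CNVType, EthnicGroup, Interval, PathogenicityLabel
from .features import (
    AnnotationBundle,
    FEATURE_SCHEMA,
    FeatureMatrix,
    GeneScoreTable,
    RegionSet,
    ScoreTrack,
    DEFAULT_CDTS_THRESHOLDS,
)
from .popfreq import AFDatabase, AFEntry

logger = logging.getLogger("xcnv")


@dataclass
class RunConfig:
    """All pipeline thresholds in one place (defaults are the study values)."""

    gw: int = 100                  # unification genomic window, bp
    ro_af: float = 0.7             # reciprocal overlap for AF lookup
    ro_leak: float = 0.5           # reciprocal overlap for leakage filtering
    length_gate: int = 10_000_000  # bp; longer CNVs are not scored
    cv_repeats: int = 100
    cv_folds: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def header_lines(self) -> list:
        return [f"## {k}={v}" for k, v in asdict(self).items()]


# ------------------------------------------------------------- CNV readers

def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    return {".bed": "bed", ".vcf": "vcf"}.get(suffix, "tsv")


def read_cnvs(path, fmt: Optional[str] = None) -> list:
    """Read CNV calls from BED, native TSV, or VCF.

    BED columns: chrom, start(0-based), end, type, [sample_id], [group],
    [label].  TSV needs a header with at least chrom/start/end/cnv_type
    (1-based inclusive).  VCF needs SVTYPE and END; records with an
    unrecognized SVTYPE are skipped with a warning.
    """
    fmt = fmt or _infer_format(path)
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown CNV format {fmt!r}")


def _read_bed(path) -> list:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: BED row needs chrom,start,end,type"
                )
            try:
                start0, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from None
            records.append(CNVRecord(
                parts[0], start0 + 1, end, CNVType.coerce(parts[3]),
                sample_id=parts[4] if len(parts) > 4 and parts[4] != "." else None,
                group=parts[5] if len(parts) > 5 and parts[5] != "." else None,
                label=parts[6] if len(parts) > 6 and parts[6] != "." else None,
                source=str(path),
            ))
    if not records:
        warnings.warn(f"no CNV records read from {path}")
    return records


def _read_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    type_col = "cnv_type" if "cnv_type" in df.columns else "type"
    needed = {"chrom", "start", "end", type_col}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: TSV must have columns {sorted(needed)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(CNVRecord(
            d["chrom"], int(d["start"]), int(d["end"]), CNVType.coerce(d[type_col]),
            sample_id=_opt(d.get("sample_id")),
            group=_opt(d.get("group")),
            label=_opt(d.get("label")),
            source=_opt(d.get("source")) or str(path),
        ))
    if not records:
        warnings.warn(f"no CNV records read from {path}")
    return records


def _opt(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v in (".", ""):
        return None
    return v


def _read_vcf(path) -> list:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            try:
                cnv_type = {"DEL": CNVType.LOSS, "DUP": CNVType.GAIN}[svtype]
            except KeyError:
                warnings.warn(
                    f"{path}: skipping record at {rec.chrom}:{rec.pos} "
                    f"with SVTYPE={svtype!r}"
                )
                continue
            end = rec.stop  # pysam: 0-based exclusive == 1-based inclusive END
            sample_id = rec.samples.keys()[0] if rec.samples else None
            records.append(CNVRecord(
                rec.chrom, rec.pos + 1, end, cnv_type,
                sample_id=sample_id, source=str(path),
            ))
    if not records:
        warnings.warn(f"no CNV records read from {path}")
    return records


def write_cnvs(records, path, fmt: Optional[str] = None) -> None:
    """Write CNVs as BED (0-based half-open) or native TSV."""
    fmt = fmt or _infer_format(path)
    path = Path(path)
    if fmt == "bed":
        with open(path, "w") as fh:
            for r in records:
                fields = [r.chrom, str(r.start - 1), str(r.end), r.cnv_type.value,
                          r.sample_id or ".", r.group.value if r.group else ".",
                          r.label.value if r.label else "."]
                fh.write("\t".join(fields) + "\n")
    elif fmt == "tsv":
        rows = [{
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "cnv_type": r.cnv_type.value,
            "sample_id": r.sample_id or "",
            "group": r.group.value if r.group else "",
            "label": r.label.value if r.label else "",
            "source": r.source,
        } for r in records]
        pd.DataFrame(rows, columns=[
            "chrom", "start", "end", "cnv_type", "sample_id", "group", "label", "source",
        ]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"cannot write CNV format {fmt!r}")


# ------------------------------------------------------------- AF database

def write_afdb(db: AFDatabase, path) -> None:
    groups = [g.value for g in EthnicGroup]
    with open(path, "w") as fh:
        for g, n in sorted(db.group_sizes.items(), key=lambda kv: kv[0].value):
            fh.write(f"## group_size\t{g.value}\t{n}\n")
        fh.write("chrom\tstart\tend\ttype\taf_overall\t"
                 + "\t".join(f"af_{g}" for g in groups) + "\n")
        for e in db.entries:
            afs = [f"{e.af_by_group.get(EthnicGroup(g), 0.0):.6g}" for g in groups]
            fh.write(f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}\t"
                     f"{e.cnv_type.value}\t{e.af_overall:.6g}\t" + "\t".join(afs) + "\n")


def read_afdb(path) -> AFDatabase:
    group_sizes = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("## group_size"):
            _, g, n = line.strip().split("\t")
            group_sizes[EthnicGroup.coerce(g)] = int(n)
            body_start = i + 1
        else:
            break
    header = lines[body_start].rstrip("\n").split("\t")
    entries = []
    for line in lines[body_start + 1:]:
        if not line.strip():
            continue
        vals = dict(zip(header, line.rstrip("\n").split("\t")))
        af_by_group = {
            EthnicGroup(c[3:]): float(vals[c])
            for c in header if c.startswith("af_") and c != "af_overall"
        }
        entries.append(AFEntry(
            interval=Interval(vals["chrom"], int(vals["start"]), int(vals["end"])),
            cnv_type=CNVType.coerce(vals["type"]),
            af_overall=float(vals["af_overall"]),
            af_by_group=af_by_group,
        ))
    return AFDatabase(entries=entries, group_sizes=group_sizes)


def write_unified(unified, db_group_sizes, path) -> None:
    """Unified-CNV TSV: representative, member/sample counts, frequencies."""
    groups = [g.value for g in EthnicGroup]
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tn_members\tn_samples\taf_overall\t"
                 + "\t".join(f"af_{g}" for g in groups) + "\tmember_ids\n")
        for u in unified:
            afs = [f"{u.af_by_group.get(EthnicGroup(g), 0.0):.6g}" for g in groups]
            members = ";".join(
                f"{m.chrom}:{m.start}-{m.end}/{m.sample_id or '.'}" for m in u.members
            )
            fh.write(
                f"{u.representative.chrom}\t{u.representative.start}\t"
                f"{u.representative.end}\t{u.cnv_type.value}\t{u.n_members}\t"
                f"{u.n_carriers}\t{u.af_overall:.6g}\t" + "\t".join(afs)
                + f"\t{members}\n"
            )


# ------------------------------------------------------------- annotations

def write_track(track: ScoreTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tscore\n")
        for chrom, pos, score in track.items():
            fh.write(f"{chrom}\t{pos}\t{score:.6g}\n")


def read_track(name, path) -> ScoreTrack:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "pos" in cols:
        return ScoreTrack.from_arrays(
            name, df["chrom"].astype(str), df["pos"].astype(int), df["score"].astype(float)
        )
    # bedGraph-like: chrom, start(0-based), end, score — expand per base
    chroms, positions, scores = [], [], []
    for row in df.itertuples(index=False):
        for p in range(int(row.start) + 1, int(row.end) + 1):
            chroms.append(str(row.chrom))
            positions.append(p)
            scores.append(float(row.score))
    return ScoreTrack.from_arrays(name, chroms, positions, scores)


def write_gene_table(table: GeneScoreTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgene\tscore\n")
        for chrom, start, end, gene, score in sorted(table.rows):
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\t{score:.6g}\n")


def read_gene_table(name, path) -> GeneScoreTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return GeneScoreTable(name, [
        (str(r.chrom), int(r.start), int(r.end), str(r.gene), float(r.score))
        for r in df.itertuples(index=False)
    ])


def write_region_set(rs: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(rs.intervals):
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{rs.name}\n")


def read_region_set(name, path) -> RegionSet:
    rs = RegionSet(name)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rs.add(parts[0], int(parts[1]) + 1, int(parts[2]))
    return rs


def write_bundle(bundle: AnnotationBundle, outdir) -> Path:
    """Write every annotation source plus a YAML manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"sources": {}, "cdts_thresholds": {
        str(k): float(v) for k, v in bundle.cdts_thresholds.items()
    }}
    for name, track in bundle.tracks.items():
        fn = f"track_{name}.tsv"
        write_track(track, outdir / fn)
        manifest["sources"][name] = {"path": fn, "type": "positional"}
    for name, table in bundle.gene_tables.items():
        fn = f"genes_{name}.tsv"
        write_gene_table(table, outdir / fn)
        manifest["sources"][name] = {"path": fn, "type": "gene"}
    for name, rs in bundle.region_sets.items():
        fn = f"regions_{name}.bed"
        write_region_set(rs, outdir / fn)
        manifest["sources"][name] = {"path": fn, "type": "region"}
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest))
    return manifest_path


def load_bundle(manifest_path) -> AnnotationBundle:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    bundle = AnnotationBundle(
        cdts_thresholds={
            int(k): float(v)
            for k, v in (manifest.get("cdts_thresholds") or DEFAULT_CDTS_THRESHOLDS).items()
        }
    )
    for name, src in manifest["sources"].items():
        path = base / src["path"]
        kind = src["type"]
        if kind == "positional":
            bundle.tracks[name] = read_track(name, path)
        elif kind == "gene":
            bundle.gene_tables[name] = read_gene_table(name, path)
        elif kind == "region":
            bundle.region_sets[name] = read_region_set(name, path)
        else:
            raise ValueError(f"unknown annotation source type {kind!r} for {name!r}")
    return bundle


# ------------------------------------------------------------- features/preds

def write_features(records, fm: FeatureMatrix, path) -> None:
    id_cols = pd.DataFrame({
        "chrom": [r.chrom for r in records],
        "start": [r.start for r in records],
        "end": [r.end for r in records],
        "type": [r.cnv_type.value for r in records],
    })
    out = pd.concat([id_cols, fm.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_features(path):
    """Returns (records, FeatureMatrix); missing cells are NA in the file."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    records = [
        CNVRecord(str(r.chrom), int(r.start), int(r.end), CNVType.coerce(r.type))
        for r in df.itertuples(index=False)
    ]
    data = df[FEATURE_SCHEMA].astype(float)
    return records, FeatureMatrix(data=data, mask=data.isna())


def write_labels(labels, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\n")
        for lab in labels:
            fh.write(f"{PathogenicityLabel.coerce(lab).value}\n")


def read_labels(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [PathogenicityLabel.coerce(v) for v in df["label"]]


def write_predictions(records, scores, categories, flags, path) -> None:
    """Prediction TSV: coordinates, MVP to 6 decimals, category, flags.

    ``scores``/``categories`` entries may be None (e.g. length-gated CNVs);
    those rows carry an empty MVP/category and their flag.
    """
    n = len(records)
    if not (len(scores) == len(categories) == len(flags) == n):
        raise ValueError("records, scores, categories and flags must align")
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tlength\tMVP\tcategory\tflags\n")
        for r, s, c, f in zip(records, scores, categories, flags):
            mvp = "" if s is None else f"{float(s):.6f}"
            cat = "" if c is None else PathogenicityLabel.coerce(c).value
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.cnv_type.value}\t"
                     f"{r.length}\t{mvp}\t{cat}\t{f or ''}\n")


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_report(reports, path) -> None:
    payload = {rep.stratum: rep.as_dict() for rep in reports}
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))
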