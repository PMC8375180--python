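"""Core domain types and interval primitives.

All genomic coordinates in this package are 1-based and inclusive on both
ends (the dbVar convention), so a single base is ``start == end`` and
``length = end - start + 1``.  BED input (0-based, half-open) is converted
on read and back on write by :mod:`xcnv.io`.  Chromosome names are stored
without the ``chr`` prefix so that calls from different sources compare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class CNVType(str, Enum):
    """Copy-number change direction: a duplication (gain) or deletion (loss)."""

    GAIN = "gain"
    LOSS = "loss"

    @classmethod
    def coerce(cls, value) -> "CNVType":
        if isinstance(value, cls):
            return value
        v = str(value).strip().lower()
        aliases = {
            "gain": cls.GAIN, "dup": cls.GAIN, "duplication": cls.GAIN,
            "loss": cls.LOSS, "del": cls.LOSS, "deletion": cls.LOSS,
        }
        try:
            return aliases[v]
        except KeyError:
            raise ValueError(f"unknown CNV type: {value!r}") from None


class EthnicGroup(str, Enum):
    """Nine population groups used for carrier-based allele frequencies."""

    AFR = "AFR"  # African / African American
    AMR = "AMR"  # Latino / Admixed American
    ASJ = "ASJ"  # Ashkenazi Jewish
    EAS = "EAS"  # East Asian
    FIN = "FIN"  # Finnish
    NFE = "NFE"  # Non-Finnish European
    SAS = "SAS"  # South Asian
    OTH = "OTH"  # other
    UKN = "UKN"  # unknown

    @classmethod
    def coerce(cls, value) -> "EthnicGroup":
        """Map a value to a group code; anything unrecognized becomes UKN."""
        if value is None:
            return cls.UKN
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            return cls.UKN


class PathogenicityLabel(str, Enum):
    """Five-tier ACMG-style pathogenicity classes, ordered benign -> pathogenic."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    UNCERTAIN = "uncertain"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"

    @classmethod
    def coerce(cls, value) -> "PathogenicityLabel":
        if isinstance(value, cls):
            return value
        v = str(value).strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {"vus": "uncertain", "uncertain_significance": "uncertain"}
        return cls(aliases.get(v, v))


#: benign -> pathogenic ordering used for cutoff derivation and band labels
LABEL_ORDER = (
    PathogenicityLabel.BENIGN,
    PathogenicityLabel.LIKELY_BENIGN,
    PathogenicityLabel.UNCERTAIN,
    PathogenicityLabel.LIKELY_PATHOGENIC,
    PathogenicityLabel.PATHOGENIC,
)


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix; keep the rest verbatim."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if not s:
        raise ValueError("empty chromosome name")
    return s


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CNVRecord:
    """One CNV call.

    Parameters
    ----------
    chrom, start, end
        1-based inclusive coordinates; ``chr`` prefixes are stripped.
    cnv_type
        ``gain`` or ``loss`` (aliases DUP/DEL accepted).
    sample_id
        Carrier sample, when known; distinct samples are counted once per
        unified CNV when computing allele frequencies.
    group
        One of the nine population codes; unknown values map to ``UKN``.
    label
        Optional five-tier pathogenicity class.
    source
        Free-text provenance tag (call set / database of origin).
    """

    chrom: str
    start: int
    end: int
    cnv_type: CNVType
    sample_id: Optional[str] = None
    group: Optional[EthnicGroup] = None
    label: Optional[PathogenicityLabel] = None
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "cnv_type", CNVType.coerce(self.cnv_type))
        if self.group is not None:
            object.__setattr__(self, "group", EthnicGroup.coerce(self.group))
        if self.label is not None:
            object.__setattr__(self, "label", PathogenicityLabel.coerce(self.label))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class UnifiedCNV:
    """A set of CNV calls deemed mutually identical, with one representative.

    ``carriers_by_group`` counts distinct carrier samples per population
    group; allele frequencies are carrier fractions (carriers / group size)
    and are filled in when group sizes are known.
    """

    representative: Interval
    cnv_type: CNVType
    members: list = field(default_factory=list)
    carriers_by_group: dict = field(default_factory=dict)
    af_by_group: dict = field(default_factory=dict)
    af_overall: float = 0.0

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_carriers(self) -> int:
        return sum(self.carriers_by_group.values())


def cnv_length(r) -> int:
    """Length in bp of a record or interval (inclusive convention)."""
    return r.end - r.start + 1


def overlap_bp(a, b) -> int:
    """Shared bases between two intervals; 0 if on different chromosomes."""
    if normalize_chrom(a.chrom) != normalize_chrom(b.chrom):
        return 0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    return max(ov, 0)
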