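"""Domain types shared by every pipeline stage.

One TE insertion event moves through three representations: a caller-level
:class:`TECall`, a two-caller :class:`ConsensusInsertion`, and finally a
patient-level :class:`ClassifiedInsertion`.  Annotation containers
(:class:`GeneSet`, :class:`RepeatSet`) hold the genomic context against
which insertions and methylation probes are placed.

Coordinate conventions: every external 1-based interface (VCF, GFF3, probe
manifests) is converted at the I/O boundary; all internal interval
arithmetic is 0-based half-open.  ``pos`` fields on calls remain 1-based
because they are point coordinates carried to and from VCF.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field


class TEFamily(str, enum.Enum):
    """The four currently active human retrotransposon groups."""

    LINE1 = "LINE1"
    ALU = "ALU"
    SVA = "SVA"
    HERVK = "HERVK"


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class Caller(str, enum.Enum):
    #: precise insertion sites plus TSD strings (MELT-style output)
    PRIMARY = "primary_caller"
    #: imprecise sites plus a confidence interval (Mobster-style output)
    SECONDARY = "secondary_caller"


class PatientClass(str, enum.Enum):
    GERMLINE = "germline"
    TUMOR_SOMATIC = "tumor_somatic"
    NORMAL_SOMATIC = "normal_somatic"


#: probe region annotations in decreasing priority order
REGION_PRIORITY = ("TSS1500", "TSS200", "5UTR", "FirstExon", "Body", "3UTR")

_TSD_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class TECall:
    """One insertion call from a single caller in a single sample."""

    patient_id: str
    sample_id: str
    tissue: Tissue
    chrom: str
    pos: int  # 1-based insertion coordinate
    te_family: TEFamily
    subfamily: str | None = None
    tsd_sequence: str | None = None
    caller: Caller = Caller.PRIMARY
    ci_lo: int | None = None
    ci_hi: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if (self.ci_lo is None) != (self.ci_hi is None):
            raise ValueError("ci_lo and ci_hi must be given together")
        if self.ci_lo is not None and not (self.ci_lo <= self.pos <= self.ci_hi):
            raise ValueError(
                f"confidence interval [{self.ci_lo}, {self.ci_hi}] "
                f"does not contain pos {self.pos}"
            )
        if self.tsd_sequence is not None and not _TSD_RE.match(self.tsd_sequence):
            raise ValueError(f"TSD sequence {self.tsd_sequence!r} is not [ACGTN]+")


@dataclass(frozen=True)
class ConsensusInsertion:
    """A call supported by both callers; the primary caller's position wins."""

    patient_id: str
    sample_id: str
    tissue: Tissue
    chrom: str
    final_pos: int  # == primary caller's pos
    te_family: TEFamily
    subfamily: str | None
    tsd_sequence: str | None
    primary_pos: int
    secondary_pos: int

    def __post_init__(self) -> None:
        if self.final_pos != self.primary_pos:
            raise ValueError("final_pos must equal the primary caller's position")


@dataclass(frozen=True)
class ClassifiedInsertion:
    """A patient-specific consensus insertion with its germline/somatic call."""

    patient_id: str
    chrom: str
    final_pos: int
    te_family: TEFamily
    subfamily: str | None
    tsd_sequence: str | None
    patient_class: PatientClass
    patient_specific: bool = True
    #: for germline pairs, the matched normal-tissue position
    partner_pos: int | None = None


@dataclass
class Transcript:
    transcript_id: str
    start: int  # 0-based half-open genomic span
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        self.exons.sort()
        self.cds.sort()
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )


@dataclass
class Gene:
    gene_id: str
    name: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def representative(self) -> Transcript:
        """Transcript of maximal genomic span; ties break to the smallest id."""
        return max(self.transcripts, key=lambda t: (t.span, _neg_id(t.transcript_id)))


class _neg_id:
    """Orders string ids descending so max() picks the lexicographic minimum."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg_id") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_id) and self.s == other.s


@dataclass
class GeneSet:
    genes: list[Gene]

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]


_FAMILY_PREFIXES = (
    ("L1", TEFamily.LINE1),
    ("Alu", TEFamily.ALU),
    ("FLAM", TEFamily.ALU),
    ("FRAM", TEFamily.ALU),
    ("SVA", TEFamily.SVA),
    ("HERVK", TEFamily.HERVK),
    ("HERV-K", TEFamily.HERVK),
)


def family_from_subfamily(subfamily: str) -> TEFamily | None:
    """Infer the TE family from a RepeatMasker-style subfamily name.

    Returns None for names outside the four active groups (``other`` in the
    repeat table).
    """
    for prefix, fam in _FAMILY_PREFIXES:
        if subfamily.startswith(prefix):
            return fam
    return None


@dataclass(frozen=True)
class RepeatElement:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    subfamily: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"repeat {self.subfamily} at {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def family(self) -> TEFamily | None:
        return family_from_subfamily(self.subfamily)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatSet:
    elements: list[RepeatElement]

    def __iter__(self):
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    chrom: str
    pos: int  # 1-based CpG coordinate
    region_annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.region_annotations) - set(REGION_PRIORITY)
        if bad:
            raise ValueError(
                f"probe {self.probe_id}: unknown region annotations {sorted(bad)}"
            )


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    efs_time: float  # days until event or censoring
    event: int  # 1 = event observed, 0 = censored
    age_dx: float
    disease_status_dx: str
    primary_site: str

    def __post_init__(self) -> None:
        if self.efs_time <= 0:
            raise ValueError(f"patient {self.patient_id}: efs_time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"patient {self.patient_id}: event must be 0 or 1")


@dataclass
class CoxFit:
    """Per-feature hazard ratios plus the global likelihood-ratio test."""

    table: "object"  # DataFrame: coef, HR, se, z, p per feature
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    n: int
    n_events: int
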