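"""Core domain types shared across the pipeline.

Coordinate convention: all in-memory coordinates are 0-based half-open on a
single contig. GFF3 (1-based inclusive) is converted at the I/O boundary;
BEDGraph is already 0-based half-open and is taken as-is.

A "TSS" is a single genomic position: the 5'-most transcribed base of an
mRNA. For a minus-strand gene "upstream" means *higher* genome coordinates,
so its TSS is the high end of the UTR interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

STRANDS = ("+", "-")

#: Flags a candidate can accumulate as it moves through the filters.
CANDIDATE_FLAGS = frozenset(
    {
        "passed_comparable",
        "passed_length",
        "prioritized",
        "excluded_overlap",
        "excluded_short_after_race",
        "confirmed_rtpcr",
    }
)


@dataclass
class GeneModel:
    """One annotated gene: the anchor against which upstream transcription
    is measured."""

    gene_id: str
    strand: str
    cds_start: int  # 0-based inclusive
    cds_end: int  # 0-based exclusive
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not self.cds_start < self.cds_end:
            raise ValueError(
                f"{self.gene_id}: cds_start ({self.cds_start}) must be < cds_end ({self.cds_end})"
            )

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start

    def translation_start(self) -> int:
        """Genome coordinate of the first translated base (strand-aware)."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1


@dataclass
class CoverageTrack:
    """Strand-specific per-base read depth over the whole genome."""

    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise ValueError("plus and minus tracks must be 1-D and equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("coverage depths must be non-negative")

    @property
    def genome_length(self) -> int:
        return int(self.plus.shape[0])

    def strand(self, strand: str) -> np.ndarray:
        return self.plus if strand == "+" else self.minus


@dataclass
class UtrCandidate:
    """A called 5'UTR: one row of the final candidate table.

    ``utr_start``/``utr_end`` are 0-based half-open; the interval abuts the
    translation-proximal CDS boundary of ``gene_id`` and ``tss`` is its
    strand-distal end.
    """

    gene_id: str
    strand: str
    tss: int
    utr_start: int
    utr_end: int
    mean_utr_depth: float = 0.0
    mean_cds_depth: float = 0.0
    expression_ratio: float = 0.0
    flags: set = field(default_factory=set)
    product: str = ""
    rfam_family: Optional[str] = None
    conservation: Optional[str] = None
    transcript_stress_de: Optional[str] = None
    protein_stress_de: Optional[str] = None
    gfp_stress_response: Optional[set] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        if self.length < 1:
            raise ValueError(f"{self.gene_id}: UTR interval must span >= 1 nt")
        if self.expression_ratio < 0:
            raise ValueError("expression_ratio must be >= 0")
        unknown = self.flags - CANDIDATE_FLAGS
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")
        distal = self.utr_start if self.strand == "+" else self.utr_end - 1
        if self.tss != distal:
            raise ValueError(
                f"{self.gene_id}: tss ({self.tss}) must be the strand-distal end "
                f"of [{self.utr_start}, {self.utr_end})"
            )

    @property
    def length(self) -> int:
        return self.utr_end - self.utr_start

    @property
    def utr_interval(self) -> tuple:
        return (self.utr_start, self.utr_end)


@dataclass
class PlantedUtr:
    """Ground-truth record for one simulated 5'UTR."""

    gene_id: str
    tss: int
    length: int
    expression_ratio: float  # UTR depth relative to CDS depth

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("planted UTR length must be >= 1")
        if self.expression_ratio < 0:
            raise ValueError("planted expression ratio must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything a round-trip test needs to score the pipeline."""

    genes: list  # list[GeneModel]
    utrs: list  # list[PlantedUtr]
    screen_truth: dict = field(default_factory=dict)  # (strain, condition) -> median
    qpcr_truth: dict = field(default_factory=dict)  # condition -> fold vs control
    seed: int = 0

    def __post_init__(self) -> None:
        by_id = {g.gene_id: g for g in self.genes}
        if len(by_id) != len(self.genes):
            raise ValueError("gene_id values must be unique")
        for u in self.utrs:
            gene = by_id.get(u.gene_id)
            if gene is None:
                raise ValueError(f"planted UTR references unknown gene {u.gene_id}")
            # the UTR must abut the CDS start on the gene's strand
            if gene.strand == "+":
                if u.tss + u.length != gene.cds_start:
                    raise ValueError(f"{u.gene_id}: UTR does not abut CDS start")
            else:
                if u.tss - u.length + 1 != gene.cds_end:
                    raise ValueError(f"{u.gene_id}: UTR does not abut CDS start")

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def utr_interval(self, utr: PlantedUtr) -> tuple:
        gene = self.gene(utr.gene_id)
        if gene.strand == "+":
            return (utr.tss, gene.cds_start)
        return (gene.cds_end, utr.tss + 1)


@dataclass
class RaceRead:
    """One 5'RACE read: adapter followed by transcript 5' sequence."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("RACE read sequence must be non-empty")
        bad = set(self.sequence.upper()) - set("ACGTUN")
        if bad:
            raise ValueError(f"invalid characters in read {self.read_id}: {sorted(bad)}")


@dataclass
class RtPcrResult:
    """Gel read-out for one candidate.

    Primer set A spans from within the putative UTR into the CDS (detects
    contiguity); set B lies wholly within the CDS (detects that the mRNA is
    expressed at all); the no-RT negative control detects genomic DNA
    contamination.
    """

    gene_id: str
    band_A: bool
    band_B: bool
    band_negative_control: bool


@dataclass
class AnnotationJoin:
    """External annotation for one gene (Rfam family, conservation label,
    stress differential-expression calls) consumed as a table row."""

    gene_id: str
    rfam_family: Optional[str] = None
    conservation: Optional[str] = None
    transcript_stress_de: Optional[str] = None
    protein_stress_de: Optional[str] = None


@dataclass
class TssCall:
    """Outcome of RACE-based TSS refinement for one gene."""

    gene_id: str
    tss: Optional[int]
    status: str  # "called" | "no_call"
    reason: str = ""
    support: int = 0
    n_reads_mapped: int = 0

    @property
    def called(self) -> bool:
        return self.status == "called"


@dataclass
class ScreenSample:
    """Per-event fluorescence for one strain x condition x replicate."""

    strain: str
    condition: str
    replicate: int
    events: np.ndarray

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size < 1:
            raise ValueError("events must be non-empty")
        if (self.events < 0).any():
            raise ValueError("fluorescence values must be >= 0")


@dataclass
class QpcrMeasurement:
    """Ct values for a target and a reference gene under two conditions."""

    target_ct_treated: np.ndarray
    reference_ct_treated: np.ndarray
    target_ct_control: np.ndarray
    reference_ct_control: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "target_ct_treated",
            "reference_ct_treated",
            "target_ct_control",
            "reference_ct_control",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size < 1:
                raise ValueError(f"{name}: need >= 1 replicate")
            if not np.all(np.isfinite(arr)) or (arr <= 0).any():
                raise ValueError(f"{name}: Ct values must be finite and > 0")
            setattr(self, name, arr)
        if self.target_ct_treated.shape != self.reference_ct_treated.shape:
            raise ValueError("treated target/reference replicate counts differ")
        if self.target_ct_control.shape != self.reference_ct_control.shape:
            raise ValueError("control target/reference replicate counts differ")


@dataclass
class WesternLane:
    """One densitometry lane: target band and internal-control band."""

    target_intensity: float
    normalizer_intensity: float
    condition: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.normalizer_intensity <= 0:
            raise ValueError("normalizer_intensity must be > 0")


@dataclass
class ReporterInsert:
    """A Golden-Gate-ready UTR + 90 nt CDS-prefix insert for the GFP fusion."""

    utr_sequence: str
    cds_prefix: str
    flank_left: str
    flank_right: str

    def __post_init__(self) -> None:
        if len(self.cds_prefix) != 90:
            raise ValueError("cds_prefix must be exactly 90 nt")

    @property
    def insert(self) -> str:
        return self.utr_sequence + self.cds_prefix

    @property
    def full_sequence(self) -> str:
        return self.flank_left + self.insert + self.flank_right
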