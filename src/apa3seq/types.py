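"""Core domain records shared across the pipeline.

All in-memory coordinates are 0-based, half-open, on the genome forward
strand; transcript orientation is carried by the ``strand`` field.
Conversions to 1-based formats (SAM, WIG) happen only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Interval = tuple[int, int]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure, CDS and annotated 3' UTR.

    ``exons`` are non-overlapping, sorted by genomic coordinate.  ``utr3``
    is the annotated (pre-extension) 3' UTR; cleavage sites up to
    ``utr_extension`` nt downstream of it still count as 3'-UTR sites.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]
    utr3: Interval
    cds: Interval | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"{self.transcript_id}: exons not sorted")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tx_end(self) -> int:
        """Genomic coordinate of the annotated transcript 3' end (last base +strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def extended_utr3(self, extension: int) -> Interval:
        """3' UTR extended ``extension`` nt downstream in transcript orientation."""
        s, e = self.utr3
        return (s, e + extension) if self.strand == "+" else (s - extension, e)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated transcript: its cleavage-site loci and
    per-condition usage weights (summing to 1 over sites)."""

    transcript_id: str
    cs_positions: tuple[int, ...]  # genomic position of first untemplated base
    cs_region: tuple[str, ...]  # 'utr3' or 'intron' per position
    usage_weights: dict[str, tuple[float, ...]]  # condition -> weights

    def __post_init__(self) -> None:
        for cond, w in self.usage_weights.items():
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.transcript_id}/{cond}: weights sum {sum(w)} != 1"
                )
            if len(w) != len(self.cs_positions):
                raise ValueError(f"{self.transcript_id}: weight/position length mismatch")


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely aligned 3'-Seq read.

    ``seq`` is always in transcript-sense orientation: the 3' terminus of
    ``seq`` is the poly(A)-proximal end regardless of genomic strand.
    ``start``/``end`` delimit the aligned (templated) genomic span; any
    untemplated tail extends past it downstream in transcript orientation.
    """

    read_id: str
    sample: str
    chrom: str
    strand: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.read_id}: empty aligned span")
        if not self.seq:
            raise ValueError(f"{self.read_id}: empty sequence")


@dataclass(frozen=True)
class TailEvidence:
    """An untemplated poly(A) tail detected on one read: a single-read vote
    for a cleavage at ``cleavage_pos`` (first untemplated base, 0-based)."""

    read_id: str
    sample: str
    chrom: str
    strand: str
    cleavage_pos: int
    stretch_len: int
    mismatches_in_first8: int


@dataclass
class CleavageSite:
    """A called poly(A) cleavage site with per-sample read support."""

    chrom: str
    strand: str
    position: int
    support: dict[str, int]
    region: str = "unassigned"  # utr3 | intron | cds | intergenic
    transcript_id: str | None = None

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass
class Peak:
    """A merged run of 5-nt bins; the unit of usage quantification.

    ``levels`` holds E_j, the per-sample count of cleavage positions inside
    the interval; ``ordinal_j`` is the 1-based 5'->3' index of the peak
    among its transcript's 3'-UTR peaks (the j of the usage statistics).
    """

    chrom: str
    strand: str
    start: int
    end: int
    levels: dict[str, int] = field(default_factory=dict)
    sites: list[CleavageSite] = field(default_factory=list)
    transcript_id: str | None = None
    ordinal_j: int | None = None

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance(self, pos: int) -> int:
        if self.contains(pos):
            return 0
        return self.start - pos if pos < self.start else pos - (self.end - 1)
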