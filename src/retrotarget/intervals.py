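"""Core coordinate and feature types.

Every coordinate in the package is 0-based, half-open, on an explicitly
named contig.  Format readers convert at the boundary (GFF3 is 1-based
inclusive, BED is 0-based half-open, tRNAscan-SE tabular is 1-based
inclusive with begin>end encoding the minus strand).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded span on a contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.contig, self.start + offset, self.end + offset, self.strand)


@dataclass
class TrnaGene:
    """A tRNA gene; ``location`` spans the mature coding sequence.

    ``location.start`` is the first nucleotide of the mature coding
    sequence for a plus-strand gene (mirrored on minus); all element
    distances are measured against these boundaries.  Predicted introns
    stay inside ``location`` and are recorded separately.
    """

    id: str
    location: GenomicInterval
    isotype: str = "Undet"
    anticodon: str = "NNN"
    intron_spans: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in self.intron_spans:
            if not self.location.contains(iv):
                raise ValueError(f"intron {iv} outside tRNA gene {self.id}")


@dataclass
class ConsensusElement:
    """A retroelement consensus sequence with structural metadata.

    ``ltr_spans`` are the two terminal direct repeats (consensus
    coordinates, 0-based half-open) for LTR-class elements; ``orf_spans``
    are (start, end) DNA spans of the open reading frames, in frame with
    ``start``; ``domain_annotations`` are (name, (aa_start, aa_end))
    protein-coordinate spans supplied as library metadata.
    """

    name: str
    sequence: str
    element_class: str = "LTR"  # "LTR" | "nonLTR"
    ltr_spans: Optional[tuple] = None  # ((s1,e1), (s2,e2))
    orf_spans: list = field(default_factory=list)  # [(start, end), ...]
    domain_annotations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.element_class not in ("LTR", "nonLTR"):
            raise ValueError(f"element_class must be LTR or nonLTR, got {self.element_class!r}")
        n = len(self.sequence)
        if self.ltr_spans is not None:
            for s, e in self.ltr_spans:
                if not (0 <= s < e <= n):
                    raise ValueError(f"LTR span ({s},{e}) outside consensus {self.name}")
        for s, e in self.orf_spans:
            if not (0 <= s < e <= n):
                raise ValueError(f"ORF span ({s},{e}) outside consensus {self.name}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class HomologyHit:
    """One local-alignment hit of a consensus query against the genome."""

    query: str
    subject: GenomicInterval
    query_span: tuple  # (start, end) on the consensus, 0-based half-open
    percent_identity: float
    score: float
    e_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.e_value is not None and self.e_value < 0:
            raise ValueError("e-value must be >= 0")
        qs, qe = self.query_span
        if not (0 <= qs < qe):
            raise ValueError(f"invalid query span {self.query_span}")


def merge_spans(spans: Sequence[tuple]) -> list:
    """Merge overlapping/adjacent (start, end) spans into a sorted union."""
    if not spans:
        return []
    out = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union_length(spans: Sequence[tuple]) -> int:
    return sum(e - s for s, e in merge_spans(spans))
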