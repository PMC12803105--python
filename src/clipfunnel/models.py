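"""Shared lightweight containers for gene models.

All coordinates are 0-based, half-open, genomic. GTF input/output is converted
at the I/O boundary (see :mod:`clipfunnel.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: region precedence used when a position overlaps several annotated features
REGION_PRECEDENCE = ("3UTR", "5UTR", "CDS", "intron")

#: mapping between GTF feature types and internal region labels
FEATURE_TO_REGION = {
    "three_prime_utr": "3UTR",
    "five_prime_utr": "5UTR",
    "CDS": "CDS",
    "intron": "intron",
}
REGION_TO_FEATURE = {v: k for k, v in FEATURE_TO_REGION.items()}


@dataclass
class GeneModel:
    """A single-isoform gene: strand-pure, non-overlapping feature intervals."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    five_prime_utr: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)
    three_prime_utr: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty gene span [{self.start}, {self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def regions(self) -> dict[str, list[tuple[int, int]]]:
        return {
            "3UTR": self.three_prime_utr,
            "5UTR": self.five_prime_utr,
            "CDS": self.cds,
            "intron": self.introns,
        }

    def region_of(self, pos: int) -> str:
        """Region label of a genomic position; precedence 3UTR > 5UTR > CDS > intron."""
        for label in REGION_PRECEDENCE:
            for s, e in self.regions()[label]:
                if s <= pos < e:
                    return label
        return "other"

    def utr3_interval(self) -> tuple[int, int] | None:
        """Genomic extent of the 3'UTR (single block in this package's models)."""
        if not self.three_prime_utr:
            return None
        starts = [s for s, _ in self.three_prime_utr]
        ends = [e for _, e in self.three_prime_utr]
        return (min(starts), max(ends))


def genomic_to_utr3_local(gene: GeneModel, gstart: int, gend: int) -> tuple[int, int] | None:
    """Map a genomic interval, clipped to the gene's 3'UTR, to transcript-local
    coordinates within the 3'UTR (0 = first transcribed UTR base).

    Returns None when the interval does not overlap the UTR.
    """
    utr = gene.utr3_interval()
    if utr is None:
        return None
    u0, u1 = utr
    o0, o1 = max(gstart, u0), min(gend, u1)
    if o0 >= o1:
        return None
    if gene.strand == "+":
        return (o0 - u0, o1 - u0)
    return (u1 - o1, u1 - o0)
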