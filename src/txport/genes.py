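"""Strand-aware gene models anchored on TSS and polyA site.

Coordinates are 0-based half-open throughout (BED native). For a
plus-strand gene the TSS is the interval start and the polyA site the
end; on the minus strand they swap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    tss: int
    pa: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}")
        if self.tss == self.pa:
            raise ValidationError(f"gene {self.gene_id!r}: zero length")
        if self.strand == "+" and not self.tss < self.pa:
            raise ValidationError(
                f"gene {self.gene_id!r}: + strand requires tss < pa")
        if self.strand == "-" and not self.tss > self.pa:
            raise ValidationError(
                f"gene {self.gene_id!r}: - strand requires tss > pa")

    @property
    def length(self) -> int:
        return abs(self.pa - self.tss)

    @property
    def start(self) -> int:
        """Leftmost coordinate (half-open interval start)."""
        return min(self.tss, self.pa)

    @property
    def end(self) -> int:
        """Rightmost coordinate (half-open interval end)."""
        return max(self.tss, self.pa)

    @classmethod
    def from_bed_fields(cls, chrom: str, start: int, end: int, name: str,
                        strand: str) -> "GeneModel":
        if end <= start:
            raise ValidationError(
                f"gene {name!r}: empty interval [{start}, {end})")
        if strand == "+":
            return cls(name, chrom, "+", tss=start, pa=end)
        if strand == "-":
            return cls(name, chrom, "-", tss=end, pa=start)
        raise ValidationError(
            f"gene {name!r}: strand {strand!r} (strand is required)")


def check_non_overlapping(genes: list[GeneModel]) -> None:
    """Raise if any two genes on the same contig overlap."""
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig, gs in by_contig.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"genes {a.gene_id!r} and {b.gene_id!r} overlap on "
                    f"{contig}")
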