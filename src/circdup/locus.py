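"""Core domain objects: loci, gene models and planted features.

All coordinates throughout the package are 0-based, half-open. Conversion to
1-based happens only in the GFF3/BED writers (:mod:`circdup.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Locus",
    "GeneModel",
    "PlantedFeature",
    "revcomp",
    "validate_dna",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMP)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first offending position if *seq* is
    empty or contains characters outside A, C, G, T, N."""
    if not seq:
        raise ValueError(f"{name} is empty")
    for pos, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise ValueError(
                f"{name} contains invalid character {ch!r} at position {pos} "
                "(alphabet is ACGTN)"
            )


@dataclass(frozen=True)
class PlantedFeature:
    """A ground-truth feature written into a simulated locus.

    ``kind`` is one of ``motif``, ``inverted_repeat``, ``repeat_fragment``,
    ``decoy_insertion``. Coordinates refer to the locus the feature lives on.
    """

    kind: str
    start: int
    end: int
    sequence: str
    label: str = ""
    locus_id: str = ""

    def shifted(self, offset: int) -> "PlantedFeature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of a gene on a locus.

    ``exons`` are non-overlapping ``(start, end)`` intervals in locus
    coordinates, strictly increasing. An intron of length 0 encodes two exons
    that are genomically adjacent without an intron. The CDS begins at
    ``exons[cds_start_exon_index].start + cds_start_offset`` and ends
    (exclusive, stop codon included) at
    ``exons[cds_end_exon_index].start + cds_end_offset``.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_exon_index: int
    cds_start_offset: int
    cds_end_exon_index: int
    cds_end_offset: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise ValueError(f"exon ({start},{end}) has length < 1")
            if prev_end is not None and start < prev_end:
                raise ValueError("exons overlap or are not increasing")
            prev_end = end
        if not (0 <= self.cds_start_exon_index <= self.cds_end_exon_index
                < len(self.exons)):
            raise ValueError("CDS exon indices out of range")

    # -- derived geometry ------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def intron_lengths(self) -> list[int]:
        return [self.exons[i + 1][0] - self.exons[i][1]
                for i in range(len(self.exons) - 1)]

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    def cds_genomic_start(self) -> int:
        return self.exons[self.cds_start_exon_index][0] + self.cds_start_offset

    def cds_genomic_end(self) -> int:
        return self.exons[self.cds_end_exon_index][0] + self.cds_end_offset

    def mrna_coord(self, genomic_pos: int) -> int:
        """Map a genomic position inside an exon to spliced-mRNA coordinates."""
        acc = 0
        for start, end in self.exons:
            if start <= genomic_pos <= end:
                return acc + (genomic_pos - start)
            acc += end - start
        raise ValueError(f"position {genomic_pos} is not exonic")

    def cds_mrna_span(self) -> tuple[int, int]:
        """CDS interval in spliced-mRNA coordinates (stop codon included)."""
        return (self.mrna_coord(self.cds_genomic_start()),
                self.mrna_coord(self.cds_genomic_end()))

    # -- sequence extraction ---------------------------------------------

    def spliced_mrna(self, locus_seq: str) -> str:
        return "".join(locus_seq[s:e] for s, e in self.exons)

    def spliced_cds(self, locus_seq: str) -> str:
        mrna = self.spliced_mrna(locus_seq)
        cs, ce = self.cds_mrna_span()
        return mrna[cs:ce]

    def shifted(self, offset: int, from_pos: int = 0) -> "GeneModel":
        """Shift all exon coordinates at or beyond *from_pos* by *offset*
        (used when sequence is inserted upstream of / inside the locus)."""
        new_exons = tuple(
            (s + offset if s >= from_pos else s,
             e + offset if e > from_pos else e)
            for s, e in self.exons
        )
        return replace(self, exons=new_exons)


@dataclass
class Locus:
    """A named DNA sequence with optional gene annotation and ground-truth
    planted features — the unit every analysis stage operates on."""

    id: str
    seq: str
    gene: GeneModel | None = None
    features: list[PlantedFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        validate_dna(self.seq, name=f"locus {self.id!r}")

    def with_insertion(self, pos: int, insert: str) -> "Locus":
        """Return a copy with *insert* placed at *pos*; the gene model and all
        downstream features are shifted consistently."""
        if not (0 <= pos <= len(self.seq)):
            raise ValueError(
                f"insertion position {pos} outside locus {self.id!r} "
                f"(length {len(self.seq)})"
            )
        new_seq = self.seq[:pos] + insert + self.seq[pos:]
        gene = self.gene
        if gene is not None:
            gene = gene.shifted(len(insert), from_pos=pos)
        feats = [f.shifted(len(insert)) if f.start >= pos else f
                 for f in self.features]
        return Locus(self.id, new_seq, gene=gene, features=feats)
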