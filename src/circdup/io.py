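"""Readers and writers for the standard interchange formats.

FASTA goes through Biopython; GFF3 and BED are emitted directly (the subset
written here is read back only by this package). All in-memory coordinates
are 0-based half-open; GFF3 output is 1-based inclusive, BED stays 0-based.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import GeneModel, Locus

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_gff3_gene",
    "write_bed",
    "write_json",
]


def write_fasta(loci: list[Locus] | Locus, path) -> None:
    if isinstance(loci, Locus):
        loci = [loci]
    records = [SeqRecord(Seq(l.seq), id=l.id, description="") for l in loci]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[Locus]:
    return [Locus(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_gff3(locus: Locus, path) -> None:
    """Write the locus' gene model as GFF3 (gene / exon / CDS rows)."""
    gene = locus.gene
    if gene is None:
        raise ValueError(f"locus {locus.id!r} has no gene model")
    lines = ["##gff-version 3"]

    def row(ftype, start, end, attrs):
        # GFF3 is 1-based, end-inclusive
        return "\t".join([locus.id, "circdup", ftype, str(start + 1),
                          str(end), ".", gene.strand, ".", attrs])

    gs, ge = gene.span
    attrs = (f"ID={gene.gene_id};cds_start_exon={gene.cds_start_exon_index};"
             f"cds_start_offset={gene.cds_start_offset};"
             f"cds_end_exon={gene.cds_end_exon_index};"
             f"cds_end_offset={gene.cds_end_offset}")
    lines.append(row("gene", gs, ge, attrs))
    for i, (s, e) in enumerate(gene.exons):
        lines.append(row("exon", s, e,
                         f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}"))
    cs, ce = gene.cds_genomic_start(), gene.cds_genomic_end()
    for s, e in gene.exons:
        lo, hi = max(s, cs), min(e, ce)
        if lo < hi:
            lines.append(row("CDS", lo, hi, f"Parent={gene.gene_id}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_gene(path) -> GeneModel:
    """Read back a gene model written by :func:`write_gff3`."""
    exons: list[tuple[int, int]] = []
    gene_attrs: dict[str, str] = {}
    strand = "+"
    gene_id = "gene"
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        ftype, start, end, attrs = cols[2], int(cols[3]) - 1, int(cols[4]), cols[8]
        kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
        if ftype == "gene":
            gene_attrs = kv
            strand = cols[6]
            gene_id = kv.get("ID", gene_id)
        elif ftype == "exon":
            exons.append((start, end))
    exons.sort()
    return GeneModel(
        gene_id=gene_id,
        strand=strand,
        exons=tuple(exons),
        cds_start_exon_index=int(gene_attrs["cds_start_exon"]),
        cds_start_offset=int(gene_attrs["cds_start_offset"]),
        cds_end_exon_index=int(gene_attrs["cds_end_exon"]),
        cds_end_offset=int(gene_attrs["cds_end_offset"]),
    )


def write_bed(intervals, path) -> None:
    """Write ``(chrom, start, end, name)`` tuples as BED4."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True)
                          + "\n")
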