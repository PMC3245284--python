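"""Synthetic locus and duplication-event generator with recoverable truth.

The simulator emulates the structural situation the downstream analysis is
built for: a multi-exon gene sitting on a source locus that gets duplicated
into a distant target locus either by a direct DNA copy, by
excision → circularization → re-linearization at a shifted cut point →
insertion (leaving a cyclically rotated segment order in the duplicate), or
by reverse transcription of the spliced mRNA (a retrocopy, recognizable by
the loss of every intron). Point mutations are applied i.i.d. per site to
the inserted copy only; breakpoint motifs, short inverted repeats and
labelled repeat-element fragments can be planted around the event, and a
post-duplication decoy insertion into the source emulates sequence that
arrived in the source footprint after the duplication.

Background sequence is i.i.d. uniform A/C/G/T — the analysis needs anchor
uniqueness, not compositional realism. All randomness is driven by a single
integer seed; identical arguments and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .locus import GeneModel, Locus, PlantedFeature, revcomp

__all__ = [
    "TruthRecord",
    "SimulatedPair",
    "make_gene_locus",
    "make_random_locus",
    "simulate_duplication",
    "insert_decoy",
    "plant_breakpoint_features",
    "simulate_scenario",
]

MECHANISMS = ("direct", "circular_intermediate", "retrocopy")

_BASES = np.array(list("ACGT"))
_STOPS = set(standard_dna_table.stop_codons)
_SENSE_CODONS = sorted(standard_dna_table.forward_table)  # 61 sense codons
_STOP_CODONS = sorted(_STOPS)


@dataclass
class TruthRecord:
    """Ground truth of one simulated duplication event."""

    mechanism: str
    excision_interval: tuple[int, int] | None
    circle_cut_offset: int | None
    insertion_point: int
    mutation_rate: float
    n_mutations: int = 0
    planted_features: list[PlantedFeature] = field(default_factory=list)

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.circle_cut_offset is not None and self.excision_interval:
            length = self.excision_interval[1] - self.excision_interval[0]
            if not (0 <= self.circle_cut_offset < length):
                raise ValueError("circle_cut_offset outside excised segment")


@dataclass
class SimulatedPair:
    """Source locus, target locus before/after insertion, and the truth."""

    source_locus: Locus
    target_locus_before: Locus
    target_locus_after: Locus
    truth: TruthRecord
    gene: GeneModel | None = None


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_random_locus(length: int, seed: int, locus_id: str = "locus") -> Locus:
    rng = np.random.default_rng(seed)
    return Locus(locus_id, _random_dna(rng, length))


def make_gene_locus(
    n_exons: int = 24,
    exon_len_range: tuple[int, int] = (80, 200),
    intron_len_range: tuple[int, int] = (400, 800),
    flank_len: int = 3000,
    seed: int = 0,
    locus_id: str = "source",
    gene_id: str = "gene1",
) -> tuple[Locus, GeneModel]:
    """Generate a locus carrying a random multi-exon gene.

    The default 24-exon layout mirrors a gene with 22 coding exons plus a
    5'-UTR exon and a 3'-UTR exon: translation starts inside the second exon
    and the stop codon sits inside the second-to-last exon, with the 3'-UTR
    continuing onto the final exon. Introns begin with GT and end with AG;
    the spliced CDS starts with ATG, contains no internal stop, ends with a
    stop codon and has length divisible by 3.
    """
    if n_exons < 2:
        raise ValueError("n_exons must be >= 2")
    e_lo, e_hi = exon_len_range
    i_lo, i_hi = intron_len_range
    if e_lo < 10 or e_lo > e_hi:
        raise ValueError(f"infeasible exon length range {exon_len_range} "
                         "(need min >= 10 to host CDS boundaries)")
    if i_lo < 4 or i_lo > i_hi:
        raise ValueError(f"infeasible intron length range {intron_len_range} "
                         "(need min >= 4 for GT..AG boundaries)")
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")

    rng = np.random.default_rng(seed)
    exon_lens = rng.integers(e_lo, e_hi + 1, n_exons)
    intron_lens = rng.integers(i_lo, i_hi + 1, n_exons - 1)

    # CDS bounds: inside exon 1 and exon n-2 (0-based) for n >= 3, so the
    # first and last exons carry UTR; for n == 2 the CDS spans both exons.
    if n_exons >= 3:
        cds_start_exon, cds_end_exon = 1, n_exons - 2
    else:
        cds_start_exon, cds_end_exon = 0, 1
    start_room = int(exon_lens[cds_start_exon])
    end_room = int(exon_lens[cds_end_exon])
    cds_start_offset = int(rng.integers(1, max(2, start_room // 2)))
    cds_end_offset = int(end_room - rng.integers(1, max(2, end_room // 3)))

    def cds_len(so, eo):
        if cds_start_exon == cds_end_exon:
            return eo - so
        total = exon_lens[cds_start_exon] - so
        total += sum(exon_lens[cds_start_exon + 1:cds_end_exon])
        return int(total + eo)

    # nudge the end offset so the spliced CDS length is a codon multiple
    rem = cds_len(cds_start_offset, cds_end_offset) % 3
    cds_end_offset -= rem
    if cds_end_offset < 3:
        raise ValueError("exon too short to host CDS boundaries; widen "
                         "exon_len_range")
    n_codons = cds_len(cds_start_offset, cds_end_offset) // 3
    if n_codons < 3:
        raise ValueError("CDS shorter than 3 codons; widen ranges")

    # spliced mRNA: 5'UTR + ATG + sense codons + stop + 3'UTR
    coding = ["ATG"]
    coding += [_SENSE_CODONS[i]
               for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)]
    coding.append(_STOP_CODONS[rng.integers(0, len(_STOP_CODONS))])
    cds_seq = "".join(coding)

    mrna_len = int(exon_lens.sum())
    utr5_len = int(sum(exon_lens[:cds_start_exon]) + cds_start_offset)
    utr3_len = mrna_len - utr5_len - len(cds_seq)
    mrna = _random_dna(rng, utr5_len) + cds_seq + _random_dna(rng, utr3_len)

    # lay the mRNA into exons separated by GT..AG introns
    parts = [_random_dna(rng, flank_len)]
    exons = []
    pos = flank_len
    consumed = 0
    for i in range(n_exons):
        elen = int(exon_lens[i])
        parts.append(mrna[consumed:consumed + elen])
        exons.append((pos, pos + elen))
        consumed += elen
        pos += elen
        if i < n_exons - 1:
            ilen = int(intron_lens[i])
            parts.append("GT" + _random_dna(rng, ilen - 4) + "AG")
            pos += ilen
    parts.append(_random_dna(rng, flank_len))

    locus = Locus(locus_id, "".join(parts))
    gene = GeneModel(
        gene_id=gene_id,
        strand="+",
        exons=tuple(exons),
        cds_start_exon_index=cds_start_exon,
        cds_start_offset=cds_start_offset,
        cds_end_exon_index=cds_end_exon,
        cds_end_offset=cds_end_offset,
    )
    assert gene.spliced_mrna(locus.seq) == mrna
    return locus, gene


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            indel_rate: float = 0.0) -> tuple[str, int]:
    """Apply i.i.d. per-site substitutions (and optional indels) to *seq*."""
    if rate == 0 and indel_rate == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[rng.integers(0, 3)].encode()
    out = arr.tobytes().decode()
    n = len(hits)
    if indel_rate > 0:
        chars = list(out)
        sites = np.nonzero(rng.random(len(chars)) < indel_rate)[0]
        for i in reversed(sites):
            if rng.random() < 0.5 and len(chars) > 1:
                del chars[i]
            else:
                chars.insert(i, str(_BASES[rng.integers(0, 4)]))
            n += 1
        out = "".join(chars)
    return out, n


def simulate_duplication(
    source: Locus,
    gene: GeneModel,
    target: Locus,
    mechanism: str,
    excision_interval: tuple[int, int] | None = None,
    circle_cut_offset: int | None = None,
    insertion_point: int = 0,
    mutation_rate: float = 0.0,
    seed: int = 0,
    reverse_complement: bool = False,
    indel_rate: float = 0.0,
) -> SimulatedPair:
    """Duplicate (part of) *source* into *target* by the chosen mechanism.

    direct: the excised segment is copied verbatim.
    circular_intermediate: the excised segment is cyclically rotated by
    ``circle_cut_offset`` — ``excised[cut:] + excised[:cut]`` — before
    insertion, as if it had circularized and re-linearized at a new cut.
    retrocopy: the spliced mRNA is inserted instead (introns lost).

    Mutations hit the inserted copy only; the source keeps its sequence.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if not (0 <= insertion_point <= len(target)):
        raise ValueError(f"insertion point {insertion_point} outside target "
                         f"locus (length {len(target)})")

    gs, ge = gene.span
    if mechanism == "retrocopy":
        inserted = gene.spliced_mrna(source.seq)
        excision_interval = None
        circle_cut_offset = None
    else:
        if excision_interval is None:
            raise ValueError("excision_interval required for DNA-mediated "
                             "mechanisms")
        s, e = excision_interval
        if not (0 <= s < e <= len(source)):
            raise ValueError("excision interval outside source locus")
        if not (s <= gs and ge <= e):
            raise ValueError("excision interval must contain the whole gene")
        excised = source.seq[s:e]
        if mechanism == "circular_intermediate":
            if circle_cut_offset is None:
                raise ValueError("circle_cut_offset required for "
                                 "circular_intermediate")
            if not (0 <= circle_cut_offset < len(excised)):
                raise ValueError(
                    f"circle_cut_offset {circle_cut_offset} out of range "
                    f"[0, {len(excised)})")
            inserted = (excised[circle_cut_offset:]
                        + excised[:circle_cut_offset])
        else:
            circle_cut_offset = None
            inserted = excised

    if target.id == source.id and excision_interval is not None:
        s, e = excision_interval
        if s <= insertion_point <= e:
            raise ValueError("insertion point inside the source gene region "
                             "is rejected to keep events interpretable")

    rng = np.random.default_rng(seed)
    if reverse_complement:
        inserted = revcomp(inserted)
    inserted, n_mut = _mutate(inserted, mutation_rate, rng,
                              indel_rate=indel_rate)

    target_after = target.with_insertion(insertion_point, inserted)
    truth = TruthRecord(
        mechanism=mechanism,
        excision_interval=excision_interval,
        circle_cut_offset=circle_cut_offset,
        insertion_point=insertion_point,
        mutation_rate=mutation_rate,
        n_mutations=n_mut,
    )
    return SimulatedPair(
        source_locus=source,
        target_locus_before=target,
        target_locus_after=target_after,
        truth=truth,
        gene=gene,
    )


def insert_decoy(
    source_locus: Locus,
    interval_between: tuple[int, int],
    decoy_seq: str,
    flanking_motif: str | None = None,
    motif_copies: int = 3,
) -> Locus:
    """Insert a decoy segment into the source between two previously
    duplicated segments (emulating sequence that arrived in the source
    footprint after the duplication).

    The insertion point is the midpoint of *interval_between*. When
    *flanking_motif* is given, *motif_copies* copies are planted immediately
    adjacent to the insertion. Gene-model and feature coordinates downstream
    are shifted consistently.
    """
    a, b = interval_between
    pos = (a + b) // 2
    if not (0 <= pos <= len(source_locus)):
        raise ValueError(f"insertion position {pos} outside locus")
    left = right = ""
    feats = []
    if flanking_motif:
        k_left = (motif_copies + 1) // 2
        k_right = motif_copies - k_left
        left = flanking_motif * k_left
        right = flanking_motif * k_right
        m = len(flanking_motif)
        for i in range(k_left):
            feats.append(PlantedFeature("motif", pos + i * m, pos + (i + 1) * m,
                                        flanking_motif, label=flanking_motif,
                                        locus_id=source_locus.id))
        off = pos + len(left) + len(decoy_seq)
        for i in range(k_right):
            feats.append(PlantedFeature("motif", off + i * m, off + (i + 1) * m,
                                        flanking_motif, label=flanking_motif,
                                        locus_id=source_locus.id))
    insert = left + decoy_seq + right
    out = source_locus.with_insertion(pos, insert)
    out.features.append(PlantedFeature(
        "decoy_insertion", pos, pos + len(insert), insert,
        label="decoy", locus_id=source_locus.id))
    out.features.extend(feats)
    return out


def plant_breakpoint_features(
    pair: SimulatedPair,
    inverted_repeat_len: int | None = 8,
    repeat_fragment: tuple[str, str] | None = None,
    seed: int = 0,
) -> SimulatedPair:
    """Write an inverted-repeat pair at the two source-side excision
    boundaries (one copy just left of the excision start, its reverse
    complement just right of the excision end) and, optionally, a labelled
    repeat-element fragment on the outer flank of the left boundary."""
    if pair.truth.excision_interval is None:
        raise ValueError("pair has no recorded excision geometry")
    s, e = pair.truth.excision_interval
    seq = pair.source_locus.seq
    feats = list(pair.truth.planted_features)
    rng = np.random.default_rng(seed)

    ir_len = inverted_repeat_len or 0
    if ir_len:
        if s - ir_len < 0 or e + ir_len > len(seq):
            raise ValueError("inverted repeat longer than available flank")
        ir = _random_dna(rng, ir_len)
        seq = seq[:s - ir_len] + ir + seq[s:]
        seq = seq[:e] + revcomp(ir) + seq[e + ir_len:]
        feats.append(PlantedFeature("inverted_repeat", s - ir_len, s, ir,
                                    label="site_A", locus_id=pair.source_locus.id))
        feats.append(PlantedFeature("inverted_repeat", e, e + ir_len,
                                    revcomp(ir), label="site_D",
                                    locus_id=pair.source_locus.id))
    if repeat_fragment is not None:
        label, frag = repeat_fragment
        lo = s - ir_len - len(frag)
        if lo < 0:
            raise ValueError("repeat fragment longer than available flank")
        seq = seq[:lo] + frag + seq[lo + len(frag):]
        feats.append(PlantedFeature("repeat_fragment", lo, lo + len(frag),
                                    frag, label=label,
                                    locus_id=pair.source_locus.id))

    source = Locus(pair.source_locus.id, seq, gene=pair.source_locus.gene,
                   features=list(pair.source_locus.features))
    truth = replace(pair.truth, planted_features=feats)
    return replace(pair, source_locus=source, truth=truth)


def simulate_scenario(
    mechanism: str,
    seed: int,
    n_exons: int = 24,
    exon_len_range: tuple[int, int] = (80, 200),
    intron_len_range: tuple[int, int] = (400, 800),
    flank_len: int = 8000,
    excision_len: int | None = None,
    excision_len_range: tuple[int, int] = (20_000, 30_000),
    circle_cut_offset: int | None = None,
    mutation_rate: float = 0.0,
    target_len: int = 12_000,
    decoy_len: int = 0,
    decoy_motif: str | None = None,
) -> SimulatedPair:
    """One-call construction of a full study condition: a gene locus, a
    random target locus, and a duplication event of the requested mechanism.

    The excision interval is placed uniformly among positions that contain
    the whole gene; the circle cut point is uniform over the excised segment
    unless given. ``decoy_len > 0`` additionally inserts a decoy into the
    source between the duplicated segments after the duplication (the
    post-duplication source-insertion scenario).
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))

    source, gene = make_gene_locus(
        n_exons=n_exons, exon_len_range=exon_len_range,
        intron_len_range=intron_len_range, flank_len=flank_len, seed=sub(),
        locus_id="source")
    target = make_random_locus(target_len, sub(), locus_id="target")
    gs, ge = gene.span

    exc = None
    cut = None
    if mechanism != "retrocopy":
        elen = excision_len
        if elen is None:
            elen = int(rng.integers(excision_len_range[0],
                                    excision_len_range[1] + 1))
        lo = max(0, ge - elen)
        hi = min(gs, len(source) - elen)
        if hi < lo:
            raise ValueError("excision length does not fit around the gene; "
                             "increase flank_len or shrink the excision")
        s = int(rng.integers(lo, hi + 1))
        exc = (s, s + elen)
        if mechanism == "circular_intermediate":
            cut = (circle_cut_offset if circle_cut_offset is not None
                   else int(rng.integers(0, elen)))

    ins = int(rng.integers(0, target_len + 1))
    pair = simulate_duplication(
        source, gene, target, mechanism,
        excision_interval=exc, circle_cut_offset=cut,
        insertion_point=ins, mutation_rate=mutation_rate, seed=sub())

    if decoy_len > 0 and exc is not None:
        s, e = exc
        if mechanism == "circular_intermediate" and cut:
            at = s + cut          # the rotation junction on the source
        else:
            at = (s + e) // 2
        decoy = _random_dna(np.random.default_rng(sub()), decoy_len)
        new_source = insert_decoy(pair.source_locus, (at, at), decoy,
                                  flanking_motif=decoy_motif)
        pair = replace(pair, source_locus=new_source)
    return pair
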