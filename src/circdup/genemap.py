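"""Spliced mapping of an mRNA onto a locus and reading-frame diagnostics.

``splice_map`` anchors the mRNA to the locus with exact matches, chains the
best collinear path and converts diagonal jumps into introns, resolving
exon boundaries at GT..AG-consistent positions. ``check_orf`` translates
the mapped CDS and records premature stops; ``exon_skip_rescue``
exhaustively searches small exon-skip sets that restore an intact ORF —
the computational form of asking whether a damaged duplicate could still
make a short splice isoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .anchors import Anchor, find_anchors
from .locus import Locus

__all__ = [
    "ExonCall",
    "SplicedAlignment",
    "OrfReport",
    "splice_map",
    "compare_intron_status",
    "check_orf",
    "exon_skip_rescue",
    "percent_identity",
]


@dataclass(frozen=True)
class ExonCall:
    """One exon of the spliced alignment: matched mRNA and genomic
    intervals (equal length unless a small indel was absorbed)."""

    exon_index: int
    genomic_start: int
    genomic_end: int
    mrna_start: int
    mrna_end: int
    identity: float


@dataclass
class SplicedAlignment:
    """Exon-by-exon mapping of an mRNA onto a locus."""

    locus_id: str
    mrna_len: int
    exon_calls: list[ExonCall] = field(default_factory=list)
    intron_lengths: list[int] = field(default_factory=list)
    overall_identity: float = 0.0
    mapped: bool = True
    splice_site_warnings: list[str] = field(default_factory=list)
    missing_mrna_segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_exons(self) -> int:
        return len(self.exon_calls)


@dataclass
class OrfReport:
    """Frame and stop-codon diagnostics of a mapped CDS."""

    frame_ok_per_exon: list[bool] = field(default_factory=list)
    premature_stops: list[tuple[int, int]] = field(default_factory=list)
    is_intact: bool = False
    rescue_sets: list[tuple[int, ...]] = field(default_factory=list)
    cds_mrna_span: tuple[int, int] = (0, 0)


_MAX_INTRON = 100_000
_BOUNDARY_SEARCH = 10  # bp each side when placing a splice boundary


def _best_chain(anchors: list[Anchor]) -> list[Anchor]:
    """Collinear chain of + strand anchors maximizing summed anchor length.

    Transitions allow bounded mRNA overlap (anchor overextension), small
    negative diagonal shifts (deletions in the locus copy) and diagonal
    gains up to the maximum intron length.
    """
    plus = sorted((a for a in anchors if a.strand == "+"),
                  key=lambda a: (a.src_start, a.tgt_start))
    n = len(plus)
    if n == 0:
        return []
    score = [a.length for a in plus]
    prev = [-1] * n
    for j in range(n):
        aj = plus[j]
        for i in range(j):
            ai = plus[i]
            m_gap = aj.src_start - ai.src_end       # mRNA axis
            g_gap = aj.tgt_start - ai.tgt_end       # genomic axis
            if m_gap < -min(ai.length, aj.length) + 1:
                continue
            if g_gap - m_gap < -50 or g_gap - m_gap > _MAX_INTRON:
                continue
            if g_gap < m_gap - 50:
                continue
            cand = score[i] + aj.length
            if cand > score[j]:
                score[j] = cand
                prev[j] = i
    best = max(range(n), key=lambda t: (score[t], -plus[t].src_start))
    chain = []
    t = best
    while t != -1:
        chain.append(plus[t])
        t = prev[t]
    chain.reverse()
    return chain


def _identity(mrna: str, locus: str, ms: int, me: int, gs: int, ge: int) -> float:
    a = mrna[ms:me]
    b = locus[gs:ge]
    n = min(len(a), len(b))
    if max(len(a), len(b)) == 0:
        return 0.0
    matches = sum(1 for t in range(n) if a[t] == b[t])
    return matches / max(len(a), len(b))


def splice_map(mrna: str, locus: Locus,
               min_exon_anchor: int = 18) -> SplicedAlignment:
    """Map *mrna* exon-by-exon onto *locus*.

    Consecutive chained anchors whose diagonal jump is >= 4 bp open an
    intron; the exon boundary is placed at the GT..AG-consistent split
    nearest the anchor junction (searched within ±10 bp), preferring the
    mRNA tiling. A diagonal jump that admits no GT..AG split is still
    reported as an intron but logged as a splice-site warning (degraded
    sites in pseudogene copies). Diagonal losses are absorbed as small
    deletions within the exon. Intron length 0 is reported where consecutive
    exons are genomically adjacent. If nothing anchors at all, an unmapped
    result is returned rather than an exception raised.
    """
    if len(mrna) < 3 * min_exon_anchor:
        raise ValueError("mRNA shorter than 3x min_exon_anchor")
    seq = locus.seq
    anchors = find_anchors(mrna, seq, min_len=min_exon_anchor,
                           src_id="mrna", tgt_id=locus.id)
    chain = _best_chain(anchors)
    if not chain:
        return SplicedAlignment(locus.id, len(mrna), mapped=False)

    warnings: list[str] = []

    def g_of(m: int, diag: int) -> int:
        return m - diag  # anchor diagonal = src(mRNA) - tgt(genomic)

    # split the chain into exon groups at diagonal jumps; an exon group keeps
    # its first and last diagonals so absorbed indels show up in its genomic
    # interval length
    exon_bounds: list[tuple[int, int, int, int]] = []  # (ms, me, d_first, d_last)
    cur_start = chain[0].src_start
    first_diag = cur_diag = chain[0].diagonal
    cur_end = chain[0].src_end

    introns: list[int] = []
    for nxt in chain[1:]:
        jump = cur_diag - nxt.diagonal  # genomic gain across the junction
        if jump >= 4:
            # an intron: place the boundary at a GT..AG consistent split
            lo = min(cur_end, nxt.src_start) - _BOUNDARY_SEARCH
            hi = max(cur_end, nxt.src_start) + _BOUNDARY_SEARCH
            lo = max(lo, cur_start + 1)
            hi = min(hi, nxt.src_end - 1, len(mrna) - 1)
            best_p = None
            for p in sorted(range(lo, hi + 1),
                            key=lambda q: (abs(q - cur_end), q)):
                ge1 = g_of(p, cur_diag)
                gs2 = g_of(p, nxt.diagonal)
                if ge1 + 2 <= len(seq) and gs2 - 2 >= 0 \
                        and seq[ge1:ge1 + 2] == "GT" \
                        and seq[gs2 - 2:gs2] == "AG":
                    best_p = p
                    break
            if best_p is None:
                best_p = max(cur_start + 1, min(cur_end, len(mrna) - 1))
                warnings.append(
                    f"no GT..AG-consistent boundary near mRNA position "
                    f"{cur_end}; splice sites may be degraded")
            exon_bounds.append((cur_start, best_p, first_diag, cur_diag))
            introns.append(jump)
            cur_start = best_p
            first_diag = cur_diag = nxt.diagonal
            cur_end = nxt.src_end
        else:
            # same exon: absorb small indels / mutation-split anchors
            cur_diag = nxt.diagonal
            cur_end = max(cur_end, nxt.src_end)
    exon_bounds.append((cur_start, cur_end, first_diag, cur_diag))

    # extend the terminal exons along their diagonals to tile the full mRNA
    ms0, me0, df0, dl0 = exon_bounds[0]
    ext0 = min(ms0, g_of(ms0, df0))
    exon_bounds[0] = (ms0 - ext0, me0, df0, dl0)
    msl, mel, dfl, dll = exon_bounds[-1]
    extl = min(len(mrna) - mel, len(seq) - g_of(mel, dll))
    exon_bounds[-1] = (msl, mel + extl, dfl, dll)

    calls: list[ExonCall] = []
    for idx, (ms, me, d_first, d_last) in enumerate(exon_bounds):
        gs, ge = g_of(ms, d_first), g_of(me, d_last)
        calls.append(ExonCall(idx, gs, ge, ms, me,
                              _identity(mrna, seq, ms, me, gs, ge)))

    total = sum(c.mrna_end - c.mrna_start for c in calls)
    matched = sum(c.identity * max(c.mrna_end - c.mrna_start,
                                   c.genomic_end - c.genomic_start)
                  for c in calls)
    missing = []
    covered_to = 0
    for c in calls:
        if c.mrna_start > covered_to:
            missing.append((covered_to, c.mrna_start))
        covered_to = max(covered_to, c.mrna_end)
    if covered_to < len(mrna):
        missing.append((covered_to, len(mrna)))

    return SplicedAlignment(
        locus_id=locus.id,
        mrna_len=len(mrna),
        exon_calls=calls,
        intron_lengths=introns,
        overall_identity=matched / total if total else 0.0,
        mapped=True,
        splice_site_warnings=warnings,
        missing_mrna_segments=missing,
    )


def percent_identity(spliced: SplicedAlignment) -> float:
    """Matched bases over total aligned mRNA bases across exon calls."""
    if not spliced.exon_calls:
        raise ValueError("no exon calls")
    return spliced.overall_identity


def _intron_at(alignment: SplicedAlignment, mrna_pos: int,
               tol: int = 3) -> int | None:
    """Intron length at an mRNA boundary position: 0 if the position falls
    inside an exon call (merged exons), None if unmapped."""
    for i, call in enumerate(alignment.exon_calls):
        if call.mrna_start + tol <= mrna_pos <= call.mrna_end - tol:
            return 0
        if i < len(alignment.exon_calls) - 1 \
                and abs(call.mrna_end - mrna_pos) <= tol:
            return alignment.intron_lengths[i]
    return None


def compare_intron_status(a: SplicedAlignment,
                          b: SplicedAlignment) -> pd.DataFrame:
    """Per-intron presence table between two alignments of the same mRNA.

    Rows follow the introns of *a* (the reference locus); an intron is
    absent in *b* when its mRNA boundary position falls inside a single
    exon call of *b* or the reported intron length is 0.
    """
    if a.mrna_len != b.mrna_len:
        raise ValueError("alignments are against different mRNAs "
                         f"(lengths {a.mrna_len} vs {b.mrna_len})")
    rows = []
    for i, call in enumerate(a.exon_calls[:-1]):
        pos = call.mrna_end
        len_a = a.intron_lengths[i]
        len_b = _intron_at(b, pos)
        rows.append({
            "intron_index": i,
            "mrna_pos": pos,
            "length_a": len_a,
            "length_b": len_b if len_b is not None else pd.NA,
            "present_a": len_a > 0,
            "present_b": bool(len_b) if len_b is not None else False,
        })
    return pd.DataFrame(rows)


def _spliced_genomic(spliced: SplicedAlignment, locus: Locus,
                     skip: frozenset[int] = frozenset()) -> tuple[str, list[int]]:
    """Concatenated genomic exon sequence and cumulative exon end offsets."""
    parts = []
    ends = []
    total = 0
    for c in spliced.exon_calls:
        if c.exon_index in skip:
            continue
        parts.append(locus.seq[c.genomic_start:c.genomic_end])
        total += c.genomic_end - c.genomic_start
        ends.append(total)
    return "".join(parts), ends


def _map_mrna_to_spliced(spliced: SplicedAlignment, mrna_pos: int,
                         skip: frozenset[int] = frozenset()) -> int:
    """Map an mRNA coordinate into the concatenated genomic exon sequence."""
    offset = 0
    for c in spliced.exon_calls:
        glen = c.genomic_end - c.genomic_start
        if c.exon_index in skip:
            continue
        if c.mrna_start <= mrna_pos < c.mrna_end or \
                (mrna_pos == c.mrna_end and c is spliced.exon_calls[-1]):
            within = min(mrna_pos - c.mrna_start, glen)
            return offset + within
        offset += glen
    raise ValueError(f"mRNA position {mrna_pos} not covered by exon calls")


_STOPS = {"TAA", "TAG", "TGA"}


def check_orf(spliced: SplicedAlignment, locus: Locus,
              cds_mrna_span: tuple[int, int]) -> OrfReport:
    """Translate the mapped CDS and report frame and stop diagnostics.

    *cds_mrna_span* is the CDS interval in mRNA coordinates (stop codon
    included), e.g. from :meth:`GeneModel.cds_mrna_span` of the reference
    gene. Frame bookkeeping compares the cumulative mapped exon lengths to
    the mRNA tiling: an exon whose genomic length differs from its mRNA
    length by a non-multiple of 3 shifts the frame from that exon on.
    """
    cs, ce = cds_mrna_span
    if not spliced.exon_calls or spliced.exon_calls[0].mrna_start > cs:
        raise ValueError("exon calls do not cover the CDS start")

    genomic, _ = _spliced_genomic(spliced, locus)
    g_cs = _map_mrna_to_spliced(spliced, cs)
    try:
        g_ce = _map_mrna_to_spliced(spliced, ce)
    except ValueError:
        g_ce = len(genomic)
    cds = genomic[g_cs:g_ce]

    # per-exon frame: cumulative coding length in the copy vs in the mRNA
    frame_ok = []
    cum_copy = 0
    cum_mrna = 0
    for c in spliced.exon_calls:
        m_lo, m_hi = max(c.mrna_start, cs), min(c.mrna_end, ce)
        coding_mrna = max(0, m_hi - m_lo)
        glen = c.genomic_end - c.genomic_start
        mlen = c.mrna_end - c.mrna_start
        coding_copy = max(0, coding_mrna + (glen - mlen))
        cum_copy += coding_copy
        cum_mrna += coding_mrna
        frame_ok.append((cum_copy - cum_mrna) % 3 == 0)

    stops: list[tuple[int, int]] = []
    for codon_idx in range(len(cds) // 3):
        codon = cds[3 * codon_idx:3 * codon_idx + 3]
        if codon in _STOPS:
            g_pos = g_cs + 3 * codon_idx
            exon_idx = _exon_of_spliced_pos(spliced, g_pos)
            stops.append((exon_idx, codon_idx))

    internal = [s for s in stops if s[1] < len(cds) // 3 - 1]
    terminal_ok = (len(cds) >= 3 and len(cds) % 3 == 0
                   and cds[-3:] in _STOPS)
    return OrfReport(
        frame_ok_per_exon=frame_ok,
        premature_stops=internal,
        is_intact=not internal and terminal_ok,
        cds_mrna_span=cds_mrna_span,
    )


def _exon_of_spliced_pos(spliced: SplicedAlignment, pos: int,
                         skip: frozenset[int] = frozenset()) -> int:
    offset = 0
    for c in spliced.exon_calls:
        if c.exon_index in skip:
            continue
        glen = c.genomic_end - c.genomic_start
        if pos < offset + glen:
            return c.exon_index
        offset += glen
    return spliced.exon_calls[-1].exon_index


def exon_skip_rescue(report: OrfReport, spliced: SplicedAlignment,
                     locus: Locus, max_skip: int = 2) -> list[tuple[int, ...]]:
    """Minimal sets of <= *max_skip* internal coding exons whose omission
    from splicing restores an intact ORF (no internal stop, terminal stop,
    length a codon multiple) — the short-isoform rescue question.

    Every subset is tested by exhaustive re-splicing and re-translation.
    Raises if the input ORF is already intact.
    """
    from itertools import combinations

    if report.is_intact:
        raise ValueError("ORF is already intact; nothing to rescue")
    cs, ce = report.cds_mrna_span
    coding = [c.exon_index for c in spliced.exon_calls
              if max(c.mrna_start, cs) < min(c.mrna_end, ce)]
    internal = coding[1:-1] if len(coding) > 2 else []

    found: list[tuple[int, ...]] = []
    for size in range(1, max_skip + 1):
        for subset in combinations(internal, size):
            if any(set(f) <= set(subset) for f in found):
                continue  # not minimal
            skip = frozenset(subset)
            genomic, _ = _spliced_genomic(spliced, locus, skip)
            try:
                g_cs = _map_mrna_to_spliced(spliced, cs, skip)
            except ValueError:
                continue
            # CDS end: same trailing geometry, shifted by skipped lengths
            skipped_before_end = sum(
                c.genomic_end - c.genomic_start
                for c in spliced.exon_calls if c.exon_index in skip)
            try:
                g_ce = _map_mrna_to_spliced(spliced, ce)
            except ValueError:
                g_ce = None
            if g_ce is None:
                cds = genomic[g_cs:]
            else:
                cds = genomic[g_cs:g_ce - skipped_before_end]
            if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:] in _STOPS \
                    and not _has_internal_stop(cds):
                found.append(tuple(sorted(subset)))
    found.sort(key=lambda s: (len(s), s))
    return found


def _has_internal_stop(cds: str) -> bool:
    return any(cds[3 * i:3 * i + 3] in _STOPS
               for i in range(len(cds) // 3 - 1))
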