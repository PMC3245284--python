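"""Breakpoint neighborhood characterization.

Extract fixed windows around breakpoints, search paired flanks for short
inverted (or direct) repeats, scan for IUPAC motifs, and annotate flanks
against a user-supplied repeat-element library. The default motif panel
carries the two classical circular-intermediate candidates, GCAAAC and
CAGGG; the default flank window is 100 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import re

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .anchors import chain_blocks, find_anchors
from .locus import Locus, revcomp, validate_dna

__all__ = [
    "FlankPair",
    "RepeatHit",
    "MotifHit",
    "RepeatAnnotation",
    "DEFAULT_MOTIF_PANEL",
    "DEFAULT_FLANK_WINDOW",
    "extract_flanks",
    "find_inverted_repeats",
    "scan_motif",
    "annotate_repeats",
]

DEFAULT_MOTIF_PANEL = ("GCAAAC", "CAGGG")
DEFAULT_FLANK_WINDOW = 100


@dataclass(frozen=True)
class FlankPair:
    """Sequence windows immediately left and right of a breakpoint."""

    site_label: str
    left: str
    right: str
    window: int
    locus_id: str
    center: int


@dataclass(frozen=True)
class RepeatHit:
    """A short repeat shared between two sequences; for kind 'inverted' the
    substring at *a* equals the reverse complement of the one at *b*, up to
    the recorded mismatches."""

    kind: str
    seq_a_interval: tuple[int, int]
    seq_b_interval: tuple[int, int]
    length: int
    mismatches: int


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int
    strand: str


@dataclass(frozen=True)
class RepeatAnnotation:
    label: str
    interval: tuple[int, int]
    identity: float
    strand: str


def extract_flanks(locus: Locus, center: int,
                   window: int = DEFAULT_FLANK_WINDOW,
                   site_label: str = "") -> FlankPair:
    """Windows of up to *window* bp on each side of *center*, truncated at
    the locus ends."""
    n = len(locus.seq)
    if not (0 <= center <= n):
        raise ValueError(f"center {center} outside locus {locus.id!r} "
                         f"(length {n})")
    return FlankPair(
        site_label=site_label,
        left=locus.seq[max(0, center - window):center],
        right=locus.seq[center:min(n, center + window)],
        window=window,
        locus_id=locus.id,
        center=center,
    )


def _maximal_hits(a: str, b2: str, min_len: int, max_mismatch: int):
    """Maximal >=min_len windows with <=max_mismatch mismatches along every
    diagonal of a x b2, as (i, j2, length, mismatches)."""
    la, lb = len(a), len(b2)
    out = []
    for diag in range(-(lb - 1), la):
        i0 = max(0, diag)
        j0 = i0 - diag
        run = min(la - i0, lb - j0)
        if run < min_len:
            continue
        mism = [1 if a[i0 + t] != b2[j0 + t] or a[i0 + t] == "N" else 0
                for t in range(run)]
        # two-pointer maximal windows with mismatch budget
        left = 0
        cnt = 0
        right = 0
        prev_right = -1
        while left < run:
            if right < left:
                right = left
                cnt = 0
            while right < run and cnt + mism[right] <= max_mismatch:
                cnt += mism[right]
                right += 1
            if right - left >= min_len and right > prev_right:
                out.append((i0 + left, j0 + left, right - left,
                            sum(mism[left:right])))
                prev_right = right
            cnt -= mism[left]
            left += 1
    return out


def find_inverted_repeats(seq_a: str, seq_b: str, min_len: int = 8,
                          max_mismatch: int = 0,
                          kind: str = "inverted") -> list[RepeatHit]:
    """All maximal pairs (i in a, j in b, length >= min_len) where
    ``a[i:i+len]`` matches ``revcomp(b[j:j+len])`` (kind 'inverted') or
    ``b[j:j+len]`` itself (kind 'direct') with at most *max_mismatch*
    mismatches. Sorted by length descending, then position."""
    if min_len < 4:
        raise ValueError("min_len < 4 is below the noise floor")
    validate_dna(seq_a, "seq_a")
    validate_dna(seq_b, "seq_b")
    if kind not in ("inverted", "direct"):
        raise ValueError("kind must be 'inverted' or 'direct'")
    b2 = revcomp(seq_b) if kind == "inverted" else seq_b
    hits = []
    for i, j2, length, mism in _maximal_hits(seq_a, b2, min_len,
                                             max_mismatch):
        if kind == "inverted":
            b_iv = (len(seq_b) - (j2 + length), len(seq_b) - j2)
        else:
            b_iv = (j2, j2 + length)
        hits.append(RepeatHit(kind, (i, i + length), b_iv, length, mism))
    hits.sort(key=lambda h: (-h.length, h.seq_a_interval, h.seq_b_interval))
    return hits


_IUPAC = {k: v for k, v in ambiguous_dna_values.items() if k != "X"}


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif:
        vals = _IUPAC.get(ch.upper())
        if vals is None:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif")
        parts.append(ch.upper() if len(vals) == 1 else f"[{vals}]")
    return "".join(parts)


def scan_motif(seq: str, motif: str,
               allow_revcomp: bool = False) -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences; IUPAC codes honored in
    the motif. Minus-strand hits are reported when *allow_revcomp*."""
    if len(motif) < 3:
        raise ValueError("motif length must be >= 3")
    fwd = _iupac_regex(motif)
    hits = [MotifHit(motif, m.start(), "+")
            for m in re.finditer(f"(?=({fwd}))", seq.upper())]
    if allow_revcomp:
        rc_motif = str(Seq(motif.upper()).reverse_complement())
        if rc_motif != motif.upper():
            rc = _iupac_regex(rc_motif)
            hits += [MotifHit(motif, m.start(), "-")
                     for m in re.finditer(f"(?=({rc}))", seq.upper())]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def annotate_repeats(flank: str, repeat_library: list[tuple[str, str]],
                     min_fragment: int = 30,
                     min_identity: float = 0.8) -> list[RepeatAnnotation]:
    """Report fragments of library elements found in *flank* on either
    strand at >= *min_identity* over >= *min_fragment* bp, via exact-match
    anchoring and chaining against each library entry."""
    if not repeat_library:
        return []
    validate_dna(flank, "flank")
    anchor_len = max(8, min(12, min_fragment // 2))
    out: list[RepeatAnnotation] = []
    for label, entry in repeat_library:
        anchors = find_anchors(flank, entry, min_len=anchor_len,
                               src_id="flank", tgt_id=label)
        blocks = chain_blocks(anchors, max_gap=min_fragment,
                              min_block_len=min_fragment)
        for b in blocks:
            if b.src_span >= min_fragment and b.identity >= min_identity:
                out.append(RepeatAnnotation(
                    label, (b.src_start, b.src_end),
                    round(b.identity, 4), b.strand))
    out.sort(key=lambda r: (r.interval, r.label))
    return out
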