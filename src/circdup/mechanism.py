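"""Duplication-mechanism classification from block-order permutations.

A duplicate created through a circular DNA intermediate carries the
ancestral segment order cyclically rotated by the re-linearization cut
point; a direct copy preserves the order; a retrocopy loses every intron.
This module reads the permutation of synteny blocks between the ancestral
locus and a duplicate, classifies the mechanism, infers breakpoints and
estimates the circular intermediate's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .anchors import SyntenyBlock

__all__ = [
    "PermutationSignature",
    "MechanismCall",
    "UnsupportedMechanismError",
    "order_signature",
    "is_cyclic_rotation",
    "classify_mechanism",
    "infer_breakpoints",
    "estimate_circle_length",
]


class UnsupportedMechanismError(ValueError):
    """Raised when an operation is asked about a mechanism it cannot treat."""


@dataclass(frozen=True)
class PermutationSignature:
    """Block order evidence: ``perm[i]`` is the source-order rank of the
    i-th block in target order. Gaps are between consecutive blocks in each
    coordinate system."""

    perm: tuple[int, ...]
    strands: tuple[str, ...]
    src_gaps: tuple[int, ...]
    tgt_gaps: tuple[int, ...]
    blocks: tuple[SyntenyBlock, ...] = field(default_factory=tuple, repr=False)

    def __post_init__(self):
        n = len(self.perm)
        if sorted(self.perm) != list(range(n)):
            raise ValueError("perm is not a permutation of 0..n-1")
        if len(self.strands) != n or len(self.src_gaps) != max(n - 1, 0) \
                or len(self.tgt_gaps) != max(n - 1, 0):
            raise ValueError("strands/gaps inconsistent with n")


@dataclass
class MechanismCall:
    """Classification of one duplicate locus with its evidence.

    ``rotation_offset`` is the inferred re-linearization cut in base pairs
    from the start of the duplicated source footprint (present and non-zero
    only for circular_intermediate); ``rotation_offset_blocks`` is the same
    rotation in block ranks. ``circle_length`` is present for direct and
    circular calls.
    """

    mechanism: str
    rotation_offset: int | None = None
    rotation_offset_blocks: int | None = None
    circle_length: int | None = None
    breakpoints_src: list[int] = field(default_factory=list)
    breakpoints_tgt: list[int] = field(default_factory=list)
    evidence: PermutationSignature | None = None
    notes: list[str] = field(default_factory=list)


def order_signature(blocks: list[SyntenyBlock]) -> PermutationSignature:
    """Sort blocks by target start and record the permutation of their
    source-order ranks, per-block strands and inter-block gaps."""
    if not blocks:
        raise ValueError("order_signature needs at least one block")
    ids = {(b.src_id, b.tgt_id) for b in blocks}
    if len(ids) > 1:
        raise ValueError(f"blocks from mixed comparisons: {sorted(ids)}")
    tgt_order = sorted(blocks, key=lambda b: b.tgt_start)
    src_order = sorted(blocks, key=lambda b: b.src_start)
    rank = {id(b): r for r, b in enumerate(src_order)}
    perm = tuple(rank[id(b)] for b in tgt_order)
    strands = tuple(b.strand for b in tgt_order)
    src_gaps = tuple(src_order[i + 1].src_start - src_order[i].src_end
                     for i in range(len(blocks) - 1))
    tgt_gaps = tuple(tgt_order[i + 1].tgt_start - tgt_order[i].tgt_end
                     for i in range(len(blocks) - 1))
    return PermutationSignature(perm, strands, src_gaps, tgt_gaps,
                                blocks=tuple(tgt_order))


def is_cyclic_rotation(perm) -> tuple[bool, int | None]:
    """True iff ``perm[i] = (i + k) mod n`` for some offset k (identity is
    k = 0); returns the unique k, or (False, None)."""
    perm = tuple(perm)
    n = len(perm)
    if sorted(perm) != list(range(n)):
        raise ValueError("not a permutation of 0..n-1")
    k = perm[0]
    for i in range(n):
        if perm[i] != (i + k) % n:
            return False, None
    return True, k


def classify_mechanism(
    signature: PermutationSignature,
    intron_report=None,
    max_src_gap: int = 50_000,
    tgt_slack: int = 1000,
) -> MechanismCall:
    """Classify the duplication mechanism from a block-order signature.

    Decision order: (1) a duplicate in which every intron is absent is a
    retrocopy — intron loss is decisive; (2) a single block cannot
    distinguish a direct copy from a circular intermediate and is reported
    ``single_block``; (3) co-oriented blocks tiling the target whose source
    order is a non-identity rotation → ``circular_intermediate``; (4) the
    identity rotation with contiguous spans → ``direct``; (5) anything else
    (strand mixtures, non-rotation permutations, target-side gaps) is
    ``complex``. Source gaps may exceed target gaps by up to *max_src_gap*
    before forcing complex — sequence inserted into the source after the
    duplication lives inside the ancestral footprint — and a note records
    when that tolerance was used.

    *intron_report* is a sequence of per-intron presence flags for the
    duplicate (True = intron retained), e.g. from
    :func:`circdup.genemap.compare_intron_status`.
    """
    notes: list[str] = []
    if intron_report is not None:
        flags = list(intron_report)
        if flags and not any(flags):
            return MechanismCall("retrocopy", evidence=signature,
                                 notes=["all introns absent in duplicate"])

    blocks = signature.blocks
    n = len(signature.perm)
    if n == 1:
        return MechanismCall(
            "single_block", evidence=signature,
            notes=["one block: direct-like, but order carries no signal to "
                   "separate direct from circular"])

    if any(s != "+" for s in signature.strands):
        return MechanismCall("complex", evidence=signature,
                             notes=["strand-inconsistent blocks (possible "
                                    "inversion); rotation test not applied"])

    if any(g > tgt_slack for g in signature.tgt_gaps):
        return MechanismCall("complex", evidence=signature,
                             notes=[f"target gaps exceed slack ({tgt_slack} "
                                    "bp): duplicate footprint not contiguous"])
    if any(g > max_src_gap for g in signature.src_gaps):
        return MechanismCall("complex", evidence=signature,
                             notes=[f"source gap exceeds max_src_gap "
                                    f"({max_src_gap} bp)"])
    if any(tgt_slack < g <= max_src_gap for g in signature.src_gaps):
        notes.append("source gap tolerance used: sequence inserted into the "
                     "source footprint after duplication")

    ok, k = is_cyclic_rotation(signature.perm)
    if not ok:
        return MechanismCall("complex", evidence=signature,
                             notes=notes + ["block order is not a cyclic "
                                            "rotation of the source order"])
    if k == 0:
        call = MechanismCall("direct", rotation_offset_blocks=0,
                             evidence=signature, notes=notes)
    else:
        src_min = min(b.src_start for b in blocks)
        cut_bp = blocks[0].src_start - src_min  # target-first block's offset
        call = MechanismCall("circular_intermediate", rotation_offset=cut_bp,
                             rotation_offset_blocks=k, evidence=signature,
                             notes=notes)
    call.circle_length = estimate_circle_length(call, list(blocks))
    return call


def estimate_circle_length(call: MechanismCall,
                           blocks: list[SyntenyBlock]) -> int:
    """Length in bp of the duplicated source footprint (for a circular
    intermediate: the circle length).

    For a rotation the blocks lie on exactly two diagonals
    (src_start − tgt_start) whose difference equals the circle length; that
    difference is insensitive to the ±few-bp jitter that maximal-match
    overextension puts on block spans. Any positive source gap at the
    rotation junction (sequence inserted into the source after the
    duplication) is subtracted, so only the duplicated footprint is counted.
    Direct copies use the contiguous target footprint, which likewise
    excludes source-only insertions.
    """
    if call.mechanism not in ("direct", "circular_intermediate"):
        raise UnsupportedMechanismError(
            f"circle length undefined for mechanism {call.mechanism!r}")
    if not blocks:
        raise ValueError("no blocks")
    if call.mechanism == "direct" or len(blocks) == 1:
        tgt_lo = min(b.tgt_start for b in blocks)
        tgt_hi = max(b.tgt_end for b in blocks)
        return int(tgt_hi - tgt_lo)

    src_order = sorted(blocks, key=lambda b: b.src_start)
    # the rotation junction is the unique consecutive source-order pair
    # whose target order goes backwards
    junction = None
    for i in range(len(src_order) - 1):
        if src_order[i + 1].tgt_start < src_order[i].tgt_start:
            junction = (src_order[i], src_order[i + 1])
            break
    if junction is None:  # degenerate: fall back to the footprint hull
        return int(max(b.src_end for b in blocks)
                   - min(b.src_start for b in blocks))
    left, right = junction
    diag_jump = right.diagonal - left.diagonal
    src_gap = right.src_start - left.src_end
    return int(diag_jump - max(0, src_gap))


def _xdrop(src: str, tgt: str, x: int, y: int, direction: int,
           xdrop: int = 12, match: int = 1, mismatch: int = -3,
           max_steps: int = 5000) -> int:
    """Ungapped extension along a diagonal; returns the number of steps from
    (x, y) to the position that maximizes the running score."""
    best = cur = 0
    best_t = 0
    t = 0
    while t < max_steps:
        i = x + direction * t
        j = y + direction * t
        if direction > 0:
            if i >= len(src) or j >= len(tgt):
                break
        else:
            if i < 0 or j < 0:
                break
        a, b = src[i], tgt[j]
        cur += match if (a == b and a != "N") else mismatch
        t += 1
        if cur > best:
            best = cur
            best_t = t
        if cur < best - xdrop:
            break
    return best_t


def _refine_block(b: SyntenyBlock, src: str, tgt: str) -> SyntenyBlock:
    """Sharpen a (+ strand) block's four boundary coordinates by X-drop
    extension along its end diagonals, robust to sparse point mutations."""
    if b.strand != "+" or not b.anchors:
        return b
    first = min(b.anchors, key=lambda a: a.src_start)
    last = max(b.anchors, key=lambda a: a.src_end)
    back = min(5, first.length)
    lt = _xdrop(src, tgt, first.src_start + back - 1,
                first.tgt_start + back - 1, -1)
    src_start = first.src_start + back - lt
    tgt_start = first.tgt_start + back - lt
    back = min(5, last.length)
    rt = _xdrop(src, tgt, last.src_end - back, last.tgt_end - back, +1)
    src_end = last.src_end - back + rt
    tgt_end = last.tgt_end - back + rt
    return replace(b, src_start=src_start, src_end=src_end,
                   tgt_start=tgt_start, tgt_end=tgt_end)


def infer_breakpoints(call: MechanismCall, blocks: list[SyntenyBlock],
                      src_seq: str | None = None,
                      tgt_seq: str | None = None) -> MechanismCall:
    """Fill breakpoint coordinates on both loci from block boundaries.

    Source breakpoints are the outermost block boundaries (the excision
    sites) plus the internal junction boundaries; target breakpoints are the
    insertion-site boundaries plus the internal junction where the rotated
    halves meet. When the sequences are supplied, every boundary is refined
    by ungapped X-drop extension along the block diagonal, which recovers
    breakpoints to within a few bases even when point mutations erode the
    exact-match anchors near the boundary.
    """
    if call.mechanism not in ("direct", "circular_intermediate"):
        raise UnsupportedMechanismError(
            f"breakpoints undefined for mechanism {call.mechanism!r}")
    if not blocks:
        raise ValueError("no blocks")
    if src_seq is not None and tgt_seq is not None:
        blocks = [_refine_block(b, src_seq, tgt_seq) for b in blocks]

    src_order = sorted(blocks, key=lambda b: b.src_start)
    bp_src: list[int] = [src_order[0].src_start]
    for i in range(len(src_order) - 1):
        bp_src.append(src_order[i].src_end)
        bp_src.append(src_order[i + 1].src_start)
    bp_src.append(src_order[-1].src_end)

    tgt_order = sorted(blocks, key=lambda b: b.tgt_start)
    bp_tgt: list[int] = [tgt_order[0].tgt_start]
    for i in range(len(tgt_order) - 1):
        bp_tgt.append(tgt_order[i].tgt_end)
        bp_tgt.append(tgt_order[i + 1].tgt_start)
    bp_tgt.append(tgt_order[-1].tgt_end)

    out = replace(call)
    out.breakpoints_src = sorted(set(bp_src))
    out.breakpoints_tgt = sorted(set(bp_tgt))
    if call.mechanism == "circular_intermediate":
        src_min = src_order[0].src_start
        first_tgt = tgt_order[0]
        out.rotation_offset = first_tgt.src_start - src_min
        out.circle_length = estimate_circle_length(call, blocks)
    return out
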