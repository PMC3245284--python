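"""Exact-match anchors and collinear synteny blocks.

``find_anchors`` reports every maximal exact match of at least ``min_len``
between two sequences on both strands — the computational form of a dotplot.
``chain_blocks`` greedily chains co-strand, co-diagonal anchors into synteny
blocks: each block is one "box" of the dotplot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .locus import revcomp, validate_dna

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "find_anchors",
    "chain_blocks",
    "export_dotplot",
    "read_dotplot",
]


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match. For strand '-', the source substring equals
    the reverse complement of the target substring."""

    src_start: int
    src_end: int
    tgt_start: int
    tgt_end: int
    strand: str
    src_id: str = "src"
    tgt_id: str = "tgt"

    @property
    def length(self) -> int:
        return self.src_end - self.src_start

    @property
    def diagonal(self) -> int:
        return self.src_start - self.tgt_start


@dataclass
class SyntenyBlock:
    """A chained run of collinear anchors; spans are the hull of members."""

    block_id: int
    src_start: int
    src_end: int
    tgt_start: int
    tgt_end: int
    strand: str
    n_anchors: int
    identity: float
    src_id: str = "src"
    tgt_id: str = "tgt"
    anchors: tuple[Anchor, ...] = field(default_factory=tuple, repr=False)

    @property
    def src_span(self) -> int:
        return self.src_end - self.src_start

    @property
    def tgt_span(self) -> int:
        return self.tgt_end - self.tgt_start

    @property
    def diagonal(self) -> int:
        return self.src_start - self.tgt_start


def _forward_mems(src: str, tgt: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal exact matches of length >= k between src and tgt
    (forward orientation), as (src_start, tgt_start, length)."""
    index: dict[str, list[int]] = {}
    for i in range(len(src) - k + 1):
        kmer = src[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    mems: list[tuple[int, int, int]] = []
    # per diagonal, src_end of the last MEM found (seeds arrive in
    # increasing tgt order, hence increasing src order per diagonal)
    covered: dict[int, int] = {}
    n_src, n_tgt = len(src), len(tgt)
    for j in range(n_tgt - k + 1):
        kmer = tgt[j:j + k]
        if "N" in kmer:
            continue
        for i in index.get(kmer, ()):
            diag = i - j
            if covered.get(diag, -1) >= i + k:
                continue
            # extend left
            si, tj = i, j
            while si > 0 and tj > 0 and src[si - 1] == tgt[tj - 1] \
                    and src[si - 1] != "N":
                si -= 1
                tj -= 1
            # extend right
            se, te = i + k, j + k
            while se < n_src and te < n_tgt and src[se] == tgt[te] \
                    and src[se] != "N":
                se += 1
                te += 1
            if covered.get(diag, -1) >= se:
                continue
            covered[diag] = se
            mems.append((si, tj, se - si))
    return mems


def find_anchors(src_seq: str, tgt_seq: str, min_len: int = 20,
                 src_id: str = "src", tgt_id: str = "tgt") -> list[Anchor]:
    """All maximal exact matches of length >= *min_len* on both strands,
    sorted by source start. N never matches anything, including N."""
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    validate_dna(src_seq, "src_seq")
    validate_dna(tgt_seq, "tgt_seq")

    anchors = [
        Anchor(si, si + L, tj, tj + L, "+", src_id, tgt_id)
        for si, tj, L in _forward_mems(src_seq, tgt_seq, min_len)
    ]
    rc = revcomp(tgt_seq)
    n_tgt = len(tgt_seq)
    for si, tj, L in _forward_mems(src_seq, rc, min_len):
        anchors.append(Anchor(si, si + L, n_tgt - tj - L, n_tgt - tj, "-",
                              src_id, tgt_id))
    anchors.sort(key=lambda a: (a.src_start, a.tgt_start, a.strand))
    return anchors


def _gaps(a: Anchor, b: Anchor) -> tuple[int, int]:
    """(src_gap, tgt_gap) from a to b along the strand direction."""
    src_gap = b.src_start - a.src_end
    if a.strand == "+":
        tgt_gap = b.tgt_start - a.tgt_end
    else:
        tgt_gap = a.tgt_start - b.tgt_end
    return src_gap, tgt_gap


def _chainable(a: Anchor, b: Anchor, max_gap: int, slack: int) -> bool:
    if a.strand != b.strand:
        return False
    src_gap, tgt_gap = _gaps(a, b)
    if src_gap < -slack or src_gap > max_gap:
        return False
    if tgt_gap < -slack or tgt_gap > max_gap:
        return False
    return abs(src_gap - tgt_gap) <= max_gap


def chain_blocks(anchors: list[Anchor], max_gap: int = 2000,
                 min_block_len: int = 500) -> list[SyntenyBlock]:
    """Greedy highest-score chaining of co-strand anchors into blocks.

    Chains are extracted best-first (score = summed anchor length, ties
    broken by leftmost target start); every anchor joins at most one block.
    Gaps on source and target and the diagonal drift between consecutive
    members must each stay within *max_gap*. Blocks whose target span is
    below *min_block_len* are dropped, as are blocks overlapping a
    higher-scoring block on the target by more than *max_gap*.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    pool = sorted(anchors, key=lambda a: (a.src_start, a.tgt_start))
    slack = 50  # tolerated overlap between consecutive members
    chains: list[list[Anchor]] = []
    while pool:
        n = len(pool)
        score = [a.length for a in pool]
        prev = [-1] * n
        for jdx in range(n):
            for idx in range(jdx):
                if _chainable(pool[idx], pool[jdx], max_gap, slack):
                    cand = score[idx] + pool[jdx].length
                    if cand > score[jdx]:
                        score[jdx] = cand
                        prev[jdx] = idx
        best = max(range(n), key=lambda t: score[t])
        # tie-break on leftmost target start of the chain
        best_candidates = [t for t in range(n) if score[t] == score[best]]
        if len(best_candidates) > 1:
            def chain_tgt_start(t):
                while prev[t] != -1:
                    t = prev[t]
                return pool[t].tgt_start
            best = min(best_candidates, key=chain_tgt_start)
        members = []
        t = best
        while t != -1:
            members.append(pool[t])
            t = prev[t]
        members.reverse()
        chains.append(members)
        taken = set(id(a) for a in members)
        pool = [a for a in pool if id(a) not in taken]

    blocks: list[SyntenyBlock] = []
    for members in chains:
        src_start = min(a.src_start for a in members)
        src_end = max(a.src_end for a in members)
        tgt_start = min(a.tgt_start for a in members)
        tgt_end = max(a.tgt_end for a in members)
        if tgt_end - tgt_start < min_block_len:
            continue
        matched = _union_length([(a.tgt_start, a.tgt_end) for a in members])
        span = max(src_end - src_start, tgt_end - tgt_start)
        blocks.append(SyntenyBlock(
            block_id=-1, src_start=src_start, src_end=src_end,
            tgt_start=tgt_start, tgt_end=tgt_end,
            strand=members[0].strand, n_anchors=len(members),
            identity=matched / span if span else 0.0,
            src_id=members[0].src_id, tgt_id=members[0].tgt_id,
            anchors=tuple(members)))

    # best-first overlap filter on the target
    blocks.sort(key=lambda b: (-(b.identity * b.tgt_span), b.tgt_start))
    kept: list[SyntenyBlock] = []
    for b in blocks:
        overlap = max((min(b.tgt_end, k.tgt_end) - max(b.tgt_start, k.tgt_start)
                       for k in kept), default=0)
        if overlap <= max_gap:
            kept.append(b)
    kept.sort(key=lambda b: (b.tgt_start, b.src_start))
    for i, b in enumerate(kept):
        b.block_id = i
    return kept


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


_DOTPLOT_COLS = ["src_start", "src_end", "tgt_start", "tgt_end", "strand",
                 "length"]


def export_dotplot(anchors: list[Anchor], path, plot_path=None) -> None:
    """Write anchors as a TSV dotplot table; optionally render a plot."""
    df = pd.DataFrame(
        [(a.src_start, a.src_end, a.tgt_start, a.tgt_end, a.strand, a.length)
         for a in anchors],
        columns=_DOTPLOT_COLS)
    df.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for a in anchors:
            ys = ((a.tgt_start, a.tgt_end) if a.strand == "+"
                  else (a.tgt_end, a.tgt_start))
            ax.plot([a.src_start, a.src_end], ys,
                    color="k" if a.strand == "+" else "r", lw=1)
        ax.set_xlabel("source position (bp)")
        ax.set_ylabel("target position (bp)")
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)


def read_dotplot(path) -> list[Anchor]:
    df = pd.read_csv(path, sep="\t")
    return [Anchor(int(r.src_start), int(r.src_end), int(r.tgt_start),
                   int(r.tgt_end), str(r.strand))
            for r in df.itertuples()]
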