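"""Synonymous divergence (Nei–Gojobori 1986) and molecular-clock dating.

Synonymous and nonsynonymous sites are counted per codon over the nine
single-nucleotide neighbors (stop-codon neighbors excluded from the
denominator at their position); differences between codon pairs are
averaged over all minimal mutational pathways that avoid stop codons. The
observed proportions are corrected for multiple hits with the Jukes–Cantor
formula d = −(3/4)·ln(1 − (4/3)p). Dating divides Ks by a synonymous
substitution rate per year; the default convention is T = Ks / r, with the
textbook per-lineage convention T = Ks / (2r) available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "KsEstimate",
    "DivergenceEstimate",
    "DEFAULT_CLOCK_RATE",
    "codon_align",
    "ng86_sites",
    "ng86_estimate",
    "jc_correct",
    "ks_to_time",
    "estimate_divergence",
]

DEFAULT_CLOCK_RATE = 5.5e-9  # synonymous substitutions per site per year

_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class KsEstimate:
    """NG86 site and difference counts with Jukes–Cantor-corrected
    distances. ``ds`` is the synonymous distance (Ks); ``dn`` the
    nonsynonymous one. ``ds``/``dn`` are ``nan`` with the corresponding
    flag set when the observed proportion reaches the JC ceiling of 3/4."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ds: float
    dn: float
    n_codons: int
    ds_defined: bool = True
    dn_defined: bool = True


@dataclass
class DivergenceEstimate:
    """Clock-converted age of a divergence."""

    ks: float
    clock_rate: float
    convention: str
    time_years: float


def _aa(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _TABLE[codon]


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) sites of a sense codon.

    At each of the three positions the synonymous fraction is taken over
    the non-stop single-nucleotide neighbors; the position contributes that
    fraction to S and its complement to N, so S + N = 3.
    """
    codon = codon.upper()
    if codon in _STOPS:
        raise ValueError(f"{codon} is a stop codon")
    if codon not in _TABLE:
        raise ValueError(f"{codon!r} is not a sense codon of the standard "
                         "code")
    aa = _TABLE[codon]
    syn = 0.0
    for pos in range(3):
        syn_count = 0
        denom = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            if nb in _STOPS:
                continue
            denom += 1
            if _TABLE[nb] == aa:
                syn_count += 1
        if denom:
            syn += syn_count / denom
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal mutational pathways; pathways passing through
    a stop codon are excluded (all pathways are used if every one is
    blocked)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != c2:
                through_stop = True
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if through_stop else valid).append((syn, nonsyn))
    paths = valid if valid else blocked
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Codon pairs from a protein-level global alignment of two CDS.

    Both sequences are translated and aligned globally (match 1, mismatch
    0, gap −1; deterministic tie-breaking), the alignment is back-mapped to
    codons, and columns containing a gap, a stop codon or an ambiguous base
    are dropped.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) < 3 or len(cds_b) < 3:
        raise ValueError("coding sequences must be at least one codon long")
    pa = str(Seq(cds_a[:len(cds_a) // 3 * 3]).translate())
    pb = str(Seq(cds_b[:len(cds_b) // 3 * 3]).translate())
    if "*" in pa[:-1] and "*" in pb[:-1]:
        raise ValueError(
            "internal stop codons in both sequences — check the reading "
            "frame (e.g. with a spliced mapping of the mRNA)")

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(pa, pb)[0]

    pairs: list[tuple[str, str]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            ca = cds_a[3 * (a0 + off):3 * (a0 + off) + 3]
            cb = cds_b[3 * (b0 + off):3 * (b0 + off) + 3]
            if len(ca) < 3 or len(cb) < 3:
                continue
            if ca in _STOPS or cb in _STOPS:
                continue
            if any(ch not in _BASES for ch in ca + cb):
                continue
            pairs.append((ca, cb))
    return pairs


def ng86_estimate(pairs: list[tuple[str, str]]) -> KsEstimate:
    """NG86 synonymous/nonsynonymous estimate over aligned codon pairs.

    Sites are averaged over the two sequences; ps = Sd/S and pn = Nd/N are
    Jukes–Cantor corrected into ds and dn. By construction the estimate is
    symmetric in its two sequences.
    """
    if not pairs:
        raise ValueError("no codon pairs")
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds_, dn_ = _pair_diffs(ca, cb)
        Sd += ds_
        Nd += dn_
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ds_defined = ps < 0.75
    dn_defined = pn < 0.75
    return KsEstimate(
        syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd,
        ps=ps, pn=pn,
        ds=jc_correct(ps) if ds_defined else math.nan,
        dn=jc_correct(pn) if dn_defined else math.nan,
        n_codons=len(pairs),
        ds_defined=ds_defined, dn_defined=dn_defined,
    )


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction −(3/4)·ln(1 − (4/3)p)."""
    if not 0 <= p < 0.75:
        raise ValueError(f"proportion {p} outside [0, 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ks_to_time(ks: float, rate: float = DEFAULT_CLOCK_RATE,
               convention: str = "ks_over_r") -> float:
    """Convert a synonymous distance into years.

    ``ks_over_r`` (default): T = Ks / r, treating the rate as accumulating
    over the pair. ``ks_over_2r``: T = Ks / (2r), the per-lineage
    convention.
    """
    if ks < 0:
        raise ValueError("ks must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if convention == "ks_over_r":
        return ks / rate
    if convention == "ks_over_2r":
        return ks / (2 * rate)
    raise ValueError(f"unknown convention {convention!r}")


def estimate_divergence(cds_a: str, cds_b: str,
                        rate: float = DEFAULT_CLOCK_RATE,
                        convention: str = "ks_over_r"
                        ) -> tuple[KsEstimate, DivergenceEstimate]:
    """Codon-align two CDS, estimate Ks and convert it to an age."""
    est = ng86_estimate(codon_align(cds_a, cds_b))
    ks = est.ds if est.ds_defined else math.nan
    div = DivergenceEstimate(
        ks=ks, clock_rate=rate, convention=convention,
        time_years=ks_to_time(ks, rate, convention) if est.ds_defined
        else math.nan)
    return est, div
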