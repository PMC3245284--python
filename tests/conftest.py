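"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive expected results by exhaustive enumeration and
never share code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from circdup.locus import revcomp
from circdup.simulate import make_gene_locus

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


# ---------------------------------------------------------------- oracles

def brute_force_mems(src: str, tgt: str, min_len: int):
    """All maximal exact matches on both strands by per-diagonal run-length
    scanning, O(|s|·|t|)."""
    def one_strand(s, t):
        out = []
        for diag in range(-(len(t) - 1), len(s)):
            i = max(0, diag)
            j = i - diag
            run_start = None
            pos = 0
            length = min(len(s) - i, len(t) - j)
            for off in range(length + 1):
                match = (off < length and s[i + off] == t[j + off]
                         and s[i + off] != "N")
                if match and run_start is None:
                    run_start = off
                elif not match and run_start is not None:
                    if off - run_start >= min_len:
                        out.append((i + run_start, j + run_start,
                                    off - run_start))
                    run_start = None
        return out

    fwd = [(si, tj, L, "+") for si, tj, L in one_strand(src, tgt)]
    rc = revcomp(tgt)
    rev = [(si, len(tgt) - tj - L, L, "-")
           for si, tj, L in one_strand(src, rc)]
    return sorted(fwd + rev)


def brute_force_repeats(a: str, b: str, min_len: int, max_mismatch: int,
                        kind: str):
    """All maximal (i, j, length) pairs with <= max_mismatch mismatches by
    direct enumeration of every start pair and length."""
    b2 = revcomp(b) if kind == "inverted" else b

    def mism(i, j, ln):
        return sum(1 for t in range(ln)
                   if a[i + t] != b2[j + t] or a[i + t] == "N")

    hits = set()
    for i in range(len(a)):
        for j in range(len(b2)):
            max_ln = min(len(a) - i, len(b2) - j)
            for ln in range(min_len, max_ln + 1):
                if mism(i, j, ln) > max_mismatch:
                    break
                # maximal: cannot extend left or right within budget
                left_ok = (i == 0 or j == 0
                           or mism(i - 1, j - 1, ln + 1) > max_mismatch)
                right_ok = (ln == max_ln
                            or mism(i, j, ln + 1) > max_mismatch)
                if left_ok and right_ok:
                    hits.add((i, j, ln, mism(i, j, ln)))
    out = []
    for i, j2, ln, mm in hits:
        if kind == "inverted":
            b_iv = (len(b) - (j2 + ln), len(b) - j2)
        else:
            b_iv = (j2, j2 + ln)
        out.append(((i, i + ln), b_iv, ln, mm))
    return sorted(out)


def brute_force_rotation(perm):
    """Try every offset k explicitly."""
    n = len(perm)
    for k in range(max(n, 1)):
        if all(perm[i] == (i + k) % n for i in range(n)):
            return True, k
    return False, None


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def default_gene():
    """The default 24-exon simulated gene (seed 1)."""
    locus, gene = make_gene_locus(seed=1)
    return locus, gene


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
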