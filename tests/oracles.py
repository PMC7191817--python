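"""Independent oracles used to cross-check the alignment engine.

These deliberately share no code with the implementation: local alignment
scores come from exhaustive enumeration of alignment paths (tiny strings)
and from Biopython's PairwiseAligner (longer strings); lambda comes from a
plain bisection loop on the defining expectation equation.
"""

from __future__ import annotations

import math

from Bio import Align

_ACGT = frozenset("ACGT")


def enumerate_local_score(
    a: str, b: str, match: int, mismatch: int, go: int, ge: int
) -> int:
    """Best local alignment score by exhaustive path enumeration.

    Walks every alignment path that starts with an aligned-pair column (with
    strictly positive gap costs an optimal local alignment never starts or
    ends in a gap, so this restriction loses nothing), tracking the running
    score and recording the maximum seen at any aligned-pair column.  A gap
    of length L costs go + (L-1)*ge.  Exponential: strings must be tiny.
    """
    n, m = len(a), len(b)
    best = 0

    def s(x: str, y: str) -> int:
        return match if (x == y and x in _ACGT) else mismatch

    def walk(i: int, j: int, score: int, state: int) -> None:
        # state: 0 = last column aligned pair, 1 = gap in b, 2 = gap in a
        nonlocal best
        if state == 0 and score > best:
            best = score
        if i < n and j < m:
            walk(i + 1, j + 1, score + s(a[i], b[j]), 0)
        if i < n:
            walk(i + 1, j, score - (ge if state == 1 else go), 1)
        if j < m:
            walk(i, j + 1, score - (ge if state == 2 else go), 2)

    for i in range(n):
        for j in range(m):
            walk(i + 1, j + 1, s(a[i], b[j]), 0)
    return best


def biopython_local_score(
    a: str, b: str, match: int, mismatch: int, go: int, ge: int
) -> int:
    """Local alignment score from Bio.Align.PairwiseAligner (same gap model:
    the first gapped base pays the opening cost)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -go
    aligner.extend_gap_score = -ge
    return int(aligner.score(a, b))


def bisect_lambda(
    match: int, mismatch: int, background=(0.25, 0.25, 0.25, 0.25),
    tol: float = 1e-12,
) -> float:
    """Plain bisection on sum_ij p_i p_j exp(lambda s_ij) = 1."""
    p_match = sum(x * x for x in background)
    p_mis = 1.0 - p_match

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * match)
            + p_mis * math.exp(lam * mismatch)
            - 1.0
        )

    lo, hi = 1e-12, 1.0
    while f(hi) <= 0:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
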