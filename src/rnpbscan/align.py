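"""Local alignment engine and alignment statistics.

Affine-gap Smith-Waterman (full and banded), k-mer seeding with diagonal
clustering, and the standard Karlin-Altschul statistics (lambda, bitscore,
E-value) used to rank and filter hits.

Scoring conventions
-------------------
* A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the first
  gapped base pays the opening cost).
* IUPAC ambiguity codes always score as a mismatch, including against
  themselves (N vs N is a mismatch) — conservative and deterministic.
* The optimal local alignment under strictly positive gap costs neither
  starts nor ends in a gap column, so the DP optimum is taken over
  match-state cells.
* Traceback tie-break: diagonal over up over left; among equally scoring
  maximal cells the alignment with the smallest (target_start, ref_start,
  target_end, ref_end) wins.  Output is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .refdb import ReferenceDB

_NEG = -(1 << 60)

# nucleotide -> small integer; every ambiguity code collapses to 4 so that
# the kernel's "equal and < 4" match rule scores it as a mismatch
_ENCODE = bytes.maketrans(
    b"ACGTRYSWKMBDHVN",
    bytes([0, 1, 2, 3] + [4] * 11),
)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity codes complemented."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a normalised DNA string as int8 codes for the DP kernel."""
    return np.frombuffer(seq.encode("ascii").translate(_ENCODE), dtype=np.int8)


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/gap parameters plus Karlin-Altschul constants.

    Defaults follow common nucleotide-search practice (match +2,
    mismatch -3, gap open 5, gap extend 2).  ``lam`` is solved numerically
    from (match, mismatch, background); ``K`` is a configurable constant
    (exact gapped K is impractical to derive, and E-values are used for
    ranking and thresholding, not as calibrated probabilities).
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    K: float = 0.41
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.expected_score >= 0:
            raise ValueError(
                "expected per-position score must be negative "
                "(no positive lambda solution)"
            )

    @property
    def expected_score(self) -> float:
        p = self.background
        p_match = sum(x * x for x in p)
        return p_match * self.match + (1.0 - p_match) * self.mismatch

    @cached_property
    def lam(self) -> float:
        return karlin_lambda(self)


def karlin_lambda(scheme: ScoringScheme) -> float:
    """Solve the Karlin-Altschul equation for the scale parameter lambda.

    Finds the unique lambda > 0 with
    ``sum_ij p_i p_j exp(lambda * s_ij) = 1`` for the match/mismatch scoring
    matrix, to within 1e-9.  Requires a negative expected score (otherwise no
    positive root exists).
    """
    p = scheme.background
    p_match = sum(x * x for x in p)
    p_mis = 1.0 - p_match
    if p_match * scheme.match + p_mis * scheme.mismatch >= 0:
        raise ValueError("no positive solution: expected score non-negative")

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * scheme.match)
            + p_mis * math.exp(lam * scheme.mismatch)
            - 1.0
        )

    hi = 1.0
    while f(hi) <= 0:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=8.9e-16))


def bit_score(raw: int, lam: float, K: float) -> float:
    """Rescale a raw alignment score into bits: (lambda*S - ln K) / ln 2."""
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    return (lam * raw - math.log(K)) / math.log(2)


def e_value(bits: float, m: int, n: int) -> float:
    """Expected chance alignments at >= bits in an m*n search space."""
    if m < 1 or n < 1:
        raise ValueError("search-space sizes must be >= 1")
    return m * n * 2.0 ** (-bits)


@dataclass
class AlignmentResult:
    """One local alignment between a target and one reference sequence.

    Coordinates are 1-based inclusive.  ``target_start <= target_end``
    always; minus-strand hits are mapped back to forward coordinates by the
    scanning layer.  ``aligned_pairs`` holds one (target_pos, ref_pos) tuple
    per alignment column, with ``None`` marking the gapped side.
    """

    ref_id: Optional[str]
    raw_score: int
    target_start: int
    target_end: int
    ref_start: int
    ref_end: int
    n_matches: int
    n_mismatches: int
    n_gap_columns: int
    aligned_pairs: list[tuple[Optional[int], Optional[int]]]
    strand: str = "plus"
    bitscore: Optional[float] = None
    evalue: Optional[float] = None

    @property
    def n_columns(self) -> int:
        return self.n_matches + self.n_mismatches + self.n_gap_columns

    @property
    def is_empty(self) -> bool:
        return not self.aligned_pairs

    @property
    def percent_id(self) -> float:
        return percent_identity(self)


def percent_identity(aln: AlignmentResult) -> float:
    """100 * matches / alignment columns (gap columns in the denominator)."""
    cols = aln.n_columns
    if cols == 0:
        raise ValueError("percent identity undefined for an empty alignment")
    return 100.0 * aln.n_matches / cols


def rescore(
    aligned_pairs: Sequence[tuple[Optional[int], Optional[int]]],
    target: str,
    ref: str,
    scheme: ScoringScheme,
) -> int:
    """Recompute the raw score of an alignment path from scratch."""
    acgt = frozenset("ACGT")
    score = 0
    prev_gap = None  # "t" / "r" / None
    for tp, rp in aligned_pairs:
        if tp is not None and rp is not None:
            a, b = target[tp - 1], ref[rp - 1]
            score += scheme.match if (a == b and a in acgt) else scheme.mismatch
            prev_gap = None
        elif tp is None:
            score -= scheme.gap_extend if prev_gap == "t" else scheme.gap_open
            prev_gap = "t"
        else:
            score -= scheme.gap_extend if prev_gap == "r" else scheme.gap_open
            prev_gap = "r"
    return score


@njit(cache=True)
def _fill_affine(a, b, match, mismatch, go, ge, dlo, dhi):  # pragma: no cover
    """Fill local affine-gap DP matrices restricted to diagonals in [dlo,dhi].

    Diagonal of cell (i, j) is i - j (1-based DP indices).  Cells outside
    the band stay at a large negative sentinel; in-band match-state cells are
    clamped at 0 (local alignment restart).
    """
    n = a.shape[0]
    m = b.shape[0]
    neg = -(1 << 60)
    M = np.full((n + 1, m + 1), neg, np.int64)
    Ix = np.full((n + 1, m + 1), neg, np.int64)
    Iy = np.full((n + 1, m + 1), neg, np.int64)
    for i in range(1, n + 1):
        jlo = i - dhi
        if jlo < 1:
            jlo = 1
        jhi = i - dlo
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                s = match
            else:
                s = mismatch
            bp = 0
            if M[i - 1, j - 1] > bp:
                bp = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > bp:
                bp = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > bp:
                bp = Iy[i - 1, j - 1]
            v = bp + s
            if v < 0:
                v = 0
            M[i, j] = v
            x = M[i - 1, j] - go
            if Ix[i - 1, j] - ge > x:
                x = Ix[i - 1, j] - ge
            if x < neg:
                x = neg
            Ix[i, j] = x
            y = M[i, j - 1] - go
            if Iy[i, j - 1] - ge > y:
                y = Iy[i, j - 1] - ge
            if y < neg:
                y = neg
            Iy[i, j] = y
    return M, Ix, Iy


def _traceback(a_codes, b_codes, M, Ix, Iy, i, j, scheme):
    """Deterministic traceback from match-state cell (i, j).

    Preference at every step: diagonal (stay in / return to match state)
    over up (gap in reference) over left (gap in target).
    """
    match, mismatch = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    state = 0
    while True:
        if state == 0:
            s = match if (a_codes[i - 1] == b_codes[j - 1] and a_codes[i - 1] < 4) else mismatch
            pairs.append((i, j))
            prev = M[i, j] - s
            if prev <= 0:
                break
            if M[i - 1, j - 1] == prev:
                state = 0
            elif Ix[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            pairs.append((i, None))
            v = Ix[i, j]
            state = 0 if M[i - 1, j] - go == v else 1
            i -= 1
        else:
            pairs.append((None, j))
            v = Iy[i, j]
            state = 0 if M[i, j - 1] - go == v else 2
            j -= 1
    pairs.reverse()
    return pairs


def _empty_result(ref_id=None) -> AlignmentResult:
    return AlignmentResult(
        ref_id=ref_id,
        raw_score=0,
        target_start=0,
        target_end=0,
        ref_start=0,
        ref_end=0,
        n_matches=0,
        n_mismatches=0,
        n_gap_columns=0,
        aligned_pairs=[],
    )


def _result_from_pairs(pairs, a_codes, b_codes, raw, ref_id) -> AlignmentResult:
    n_match = n_mis = n_gap = 0
    for tp, rp in pairs:
        if tp is None or rp is None:
            n_gap += 1
        elif a_codes[tp - 1] == b_codes[rp - 1] and a_codes[tp - 1] < 4:
            n_match += 1
        else:
            n_mis += 1
    t_pos = [tp for tp, _ in pairs if tp is not None]
    r_pos = [rp for _, rp in pairs if rp is not None]
    return AlignmentResult(
        ref_id=ref_id,
        raw_score=raw,
        target_start=t_pos[0],
        target_end=t_pos[-1],
        ref_start=r_pos[0],
        ref_end=r_pos[-1],
        n_matches=n_match,
        n_mismatches=n_mis,
        n_gap_columns=n_gap,
        aligned_pairs=pairs,
    )


def _best_alignment(a_codes, b_codes, M, Ix, Iy, scheme, ref_id=None):
    mx = int(M.max())
    if mx <= 0:
        return _empty_result(ref_id)
    cells = np.argwhere(M == mx)
    best = None
    best_key = None
    for i, j in cells:
        pairs = _traceback(a_codes, b_codes, M, Ix, Iy, int(i), int(j), scheme)
        res = _result_from_pairs(pairs, a_codes, b_codes, mx, ref_id)
        key = (res.target_start, res.ref_start, res.target_end, res.ref_end)
        if best_key is None or key < best_key:
            best, best_key = res, key
    return best


def smith_waterman(
    target: str, ref: str, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal local alignment of ``target`` vs ``ref`` (full DP).

    Returns the maximal-scoring local alignment; an empty alignment with
    score 0 when every cell is negative.  Coordinates are 1-based inclusive
    on both sequences.
    """
    if not target or not ref:
        raise ValueError("empty input sequence")
    scheme = scheme or ScoringScheme()
    a = encode(target)
    b = encode(ref)
    M, Ix, Iy = _fill_affine(
        a, b, scheme.match, scheme.mismatch, scheme.gap_open,
        scheme.gap_extend, -len(b), len(a),
    )
    return _best_alignment(a, b, M, Ix, Iy, scheme)


def banded_smith_waterman(
    target: str,
    ref: str,
    scheme: ScoringScheme,
    dlo: int,
    dhi: int,
    ref_id: Optional[str] = None,
) -> AlignmentResult:
    """Local alignment restricted to diagonals ``target_i - ref_j`` in
    [dlo, dhi] (1-based DP indices).  Admissible: its score never exceeds
    the unrestricted optimum."""
    if not target or not ref:
        raise ValueError("empty input sequence")
    a = encode(target)
    b = encode(ref)
    M, Ix, Iy = _fill_affine(
        a, b, scheme.match, scheme.mismatch, scheme.gap_open,
        scheme.gap_extend, dlo, dhi,
    )
    return _best_alignment(a, b, M, Ix, Iy, scheme, ref_id=ref_id)


def _cluster_diagonals(hits: list[tuple[int, int]], band: int):
    """Group seed hits (diag, tpos) into clusters of nearby diagonals.

    Seeds whose diagonals differ by more than ``band`` start a new cluster.
    """
    hits = sorted(hits)
    clusters: list[list[tuple[int, int]]] = []
    for h in hits:
        if clusters and h[0] - clusters[-1][-1][0] <= band:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    return clusters


def seed_and_extend(
    target: str,
    db: ReferenceDB,
    scheme: ScoringScheme | None = None,
    band: int = 32,
    min_raw: int = 20,
) -> list[AlignmentResult]:
    """Heuristic genome-scale search: exact k-mer seeds, banded extension.

    Exact k-mer matches between the target and each reference are grouped by
    (reference, diagonal) with tolerance ``band``; each group is extended
    with a banded affine Smith-Waterman over the group's diagonal envelope
    (padded by ``band`` on each side).  Scores are admissible: they never
    exceed the full-DP score for the same pair, and equal it when the target
    contains an exact copy of the reference.

    Returns alignments with ``raw_score >= min_raw``, one per seed cluster
    (deduplicated), unsorted strand-naive coordinates on ``target``.
    """
    scheme = scheme or ScoringScheme()
    if band < 8:
        raise ValueError("band must be >= 8")
    k = db.k
    L = len(target)
    seeds: dict[int, list[tuple[int, int]]] = {}
    index = db.kmer_index
    for tpos in range(L - k + 1):
        postings = index.get(target[tpos : tpos + k])
        if postings is None:
            continue
        for ri, roff in postings:
            seeds.setdefault(ri, []).append((tpos - roff, tpos))

    results: list[AlignmentResult] = []
    seen: set[tuple] = set()
    for ri, hits in seeds.items():
        ref = db.records[ri]
        Lr = len(ref.sequence)
        for cluster in _cluster_diagonals(hits, band):
            dmin = cluster[0][0]
            dmax = cluster[-1][0]
            wstart = max(0, dmin - band)          # 0-based window start
            wend = min(L, dmax + band + Lr)
            window = target[wstart:wend]
            # diag of (i, j) within window: wstart + i - j must lie in
            # [dmin - band, dmax + band]
            aln = banded_smith_waterman(
                window,
                ref.sequence,
                scheme,
                dlo=dmin - band - wstart,
                dhi=dmax + band - wstart,
                ref_id=ref.id,
            )
            if aln.is_empty or aln.raw_score < min_raw:
                continue
            # shift window coordinates back to the full target
            aln.target_start += wstart
            aln.target_end += wstart
            aln.aligned_pairs = [
                (tp + wstart if tp is not None else None, rp)
                for tp, rp in aln.aligned_pairs
            ]
            key = (
                aln.ref_id, aln.target_start, aln.target_end,
                aln.ref_start, aln.ref_end,
            )
            if key in seen:
                continue
            seen.add(key)
            results.append(aln)
    return results
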