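"""Independent brute-force oracles used only by the test suite.

Textbook dynamic programs, written without reference to the package's
search engine: an affine-gap Smith-Waterman (local) scorer and a best
ungapped segment pair scorer, both exhaustive over the full DP matrix.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def protein_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def nt_score(a: str, b: str, match: int = 2, mismatch: int = -3) -> float:
    return float(match if (a == b and a in "ACGT") else mismatch)


def smith_waterman_affine(
    q: str, s: str, score_fn=protein_score, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Optimal local alignment score; gap of length g costs open + g*extend."""
    n, m = len(q), len(s)
    best = 0.0
    # M: match state, X: gap in s (consume q), Y: gap in q (consume s)
    prev_M = [0.0] * (m + 1)
    prev_X = [NEG] * (m + 1)
    prev_Y = [NEG] * (m + 1)
    for i in range(1, n + 1):
        cur_M = [0.0] * (m + 1)
        cur_X = [NEG] * (m + 1)
        cur_Y = [NEG] * (m + 1)
        for j in range(1, m + 1):
            cur_X[j] = max(
                prev_M[j] - gap_open - gap_extend, prev_X[j] - gap_extend
            )
            cur_Y[j] = max(
                cur_M[j - 1] - gap_open - gap_extend, cur_Y[j - 1] - gap_extend
            )
            diag = max(prev_M[j - 1], prev_X[j - 1], prev_Y[j - 1], 0.0)
            cur_M[j] = diag + score_fn(q[i - 1], s[j - 1])
            best = max(best, cur_M[j], cur_X[j], cur_Y[j])
        prev_M, prev_X, prev_Y = cur_M, cur_X, cur_Y
    return best


def best_ungapped_segment(q: str, s: str, score_fn=protein_score) -> tuple[float, int]:
    """Maximal-scoring ungapped segment pair over all diagonals.

    Returns (score, segment length in columns).
    """
    best = 0.0
    best_len = 0
    n, m = len(q), len(s)
    for diag in range(-(m - 1), n):
        run = 0.0
        run_len = 0
        i = max(0, diag)
        j = i - diag
        while i < n and j < m:
            run += score_fn(q[i], s[j])
            run_len += 1
            if run <= 0:
                run, run_len = 0.0, 0
            elif run > best:
                best, best_len = run, run_len
            i += 1
            j += 1
    return best, best_len


def tiling_bait_count(L: int, bait: int = 120, step: int = 60, max_overlap: int = 80) -> int:
    """Arithmetic enumeration of admissible bait placements: the regular
    step lattice, plus a terminal flush bait when its overlap with the
    last lattice bait is bounded."""
    if L < bait:
        return 0
    n_regular = (L - bait) // step + 1
    last_end = (n_regular - 1) * step + bait
    if last_end < L and last_end - (L - bait) <= max_overlap:
        return n_regular + 1
    return n_regular
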