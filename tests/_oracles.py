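"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available
(textbook dynamic programming, per-column counting, all-pairs distance
scans) so they share no code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

NEG_INF = float("-inf")


def _score_fn(matrix_name: str = "BLOSUM62"):
    m = substitution_matrices.load(matrix_name)

    def score(a: str, b: str) -> float:
        if a == "X" or b == "X":
            return 0.0
        return float(m[a, b])

    return score


def gotoh_global_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5,
    matrix_name: str = "BLOSUM62",
) -> float:
    """Quadratic-time affine-gap global alignment score (Gotoh DP).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps are
    penalised.  No heuristics, plain Python loops.
    """
    score = _score_fn(matrix_name)
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    M[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        F[i][0] = -(gap_open + (i - 1) * gap_extend)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = score(ai, b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + s
            E[i][j] = max(
                max(M[i][j - 1], F[i][j - 1]) - gap_open,
                E[i][j - 1] - gap_extend,
            )
            F[i][j] = max(
                max(M[i - 1][j], E[i - 1][j]) - gap_open,
                F[i - 1][j] - gap_extend,
            )
    return max(M[n][m], E[n][m], F[n][m])


def consensus_by_counting(
    rows: list[str], upper: float = 0.5, lower: float = 0.25
) -> str:
    """Per-column plurality tally with alphabetical tie-break."""
    out = []
    for j in range(len(rows[0])):
        col = [r[j] for r in rows if r[j] != "-"]
        best, best_count = None, -1
        for aa in sorted(set(col)):
            c = col.count(aa)
            if c > best_count:
                best, best_count = aa, c
        f = best_count / len(col)
        if f >= upper:
            out.append(best.upper())
        elif f >= lower:
            out.append(best.lower())
        else:
            out.append("x")
    return "".join(out)


def removed_columns_by_counting(rows: list[str], threshold: float = 0.5) -> list[int]:
    """Columns whose non-gap fraction is below the occupancy threshold."""
    n = len(rows)
    return [
        j
        for j in range(len(rows[0]))
        if sum(1 for r in rows if r[j] != "-") / n < threshold
    ]


def footprint_all_pairs(
    target_residues: list[tuple[int, np.ndarray]],
    partner_coords: np.ndarray,
    cutoff: float,
) -> list[int]:
    """All-pairs O(n*m) distance scan: residue numbers within the cutoff."""
    hits = []
    for number, coords in target_residues:
        d2 = ((coords[:, None, :] - partner_coords[None, :, :]) ** 2).sum(axis=2)
        if np.sqrt(d2.min()) <= cutoff:
            hits.append(number)
    return sorted(set(hits))
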