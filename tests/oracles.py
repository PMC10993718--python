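"""Independent brute-force oracles used to verify the optimised primitives.

These are deliberately written from the textbook definitions, without
reference to the package implementations.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def nw_affine_oracle(a, b, score, gap_open, gap_extend):
    """Global alignment score by the three-state (Gotoh) dynamic program.

    ``score(x, y)`` gives the substitution score; a gap of length L costs
    ``gap_open + L * gap_extend``.
    """
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    # M: a[i] aligned to b[j]; X: gap in b (a[i] consumed); Y: gap in a
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_cost - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -open_cost - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - open_cost,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - open_cost,
            )
            Y[i][j] = max(
                M[i][j - 1] - open_cost,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - open_cost,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def levenshtein_oracle(a: str, b: str) -> int:
    """Classic full-table edit-distance dynamic program."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]
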