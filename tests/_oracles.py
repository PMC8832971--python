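"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the alignment oracle is a
plain Gotoh dynamic program with exhaustive co-optimal traceback, and the
scanner oracle enumerates every window with a Python loop.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = -11.0  # score of the first residue of a gap
GAP_EXT = -1.0  # each further residue

NEG = -math.inf


def _sub(a: str, b: str) -> float:
    return float(_BLOSUM62[a][b])


def gotoh_matrices(a: str, b: str):
    """Global affine-gap DP (end gaps penalized), three-state Gotoh."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = GAP_OPEN + GAP_EXT * (i - 1)
    for j in range(1, m + 1):
        Iy[0][j] = GAP_OPEN + GAP_EXT * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + GAP_OPEN, Ix[i - 1][j] + GAP_EXT,
                           Iy[i - 1][j] + GAP_OPEN)
            Iy[i][j] = max(M[i][j - 1] + GAP_OPEN, Iy[i][j - 1] + GAP_EXT,
                           Ix[i][j - 1] + GAP_OPEN)
    return M, Ix, Iy


def optimal_score(a: str, b: str) -> float:
    M, Ix, Iy = gotoh_matrices(a, b)
    return max(M[len(a)][len(b)], Ix[len(a)][len(b)], Iy[len(a)][len(b)])


def _stats_from_columns(cols: list[tuple[str | None, str | None]]) -> tuple[float, float]:
    """(identity, coverage) under the package's definitions."""
    aligned_pairs = sum(1 for x, y in cols if x is not None and y is not None)
    lo = 0
    hi = len(cols)
    while lo < hi and (cols[lo][0] is None or cols[lo][1] is None):
        lo += 1
    while hi > lo and (cols[hi - 1][0] is None or cols[hi - 1][1] is None):
        hi -= 1
    core = cols[lo:hi]
    matches = sum(1 for x, y in core if x is not None and x == y)
    identity = matches / len(core) if core else 0.0
    n_a = sum(1 for x, _ in cols if x is not None)
    n_b = sum(1 for _, y in cols if y is not None)
    coverage = aligned_pairs / min(n_a, n_b) if min(n_a, n_b) else 0.0
    return identity, coverage


def enumerate_optimal_stats(
    a: str, b: str, max_paths: int = 20000, tol: float = 1e-9
) -> set[tuple[float, float]]:
    """(identity, coverage) of every co-optimal global alignment."""
    M, Ix, Iy = gotoh_matrices(a, b)
    n, m = len(a), len(b)
    best = max(M[n][m], Ix[n][m], Iy[n][m])
    out: set[tuple[float, float]] = set()
    stack: list[tuple[int, int, str, list]] = []
    for state, table in (("M", M), ("Ix", Ix), ("Iy", Iy)):
        if abs(table[n][m] - best) < tol:
            stack.append((n, m, state, []))
    count = 0
    while stack and count < max_paths:
        i, j, state, cols = stack.pop()
        if i == 0 and j == 0:
            count += 1
            out.add(
                tuple(round(v, 12) for v in _stats_from_columns(list(reversed(cols))))
            )
            continue
        if state == "M":
            s = _sub(a[i - 1], b[j - 1])
            target = M[i][j] - s
            col = (a[i - 1], b[j - 1])
            for prev, table in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if i >= 1 and j >= 1 and abs(table[i - 1][j - 1] - target) < tol:
                    stack.append((i - 1, j - 1, prev, cols + [col]))
        elif state == "Ix":
            col = (a[i - 1], None)
            if i == 0:
                continue
            if j == 0:  # leading gap run
                if i == 1 and abs(Ix[i][j] - GAP_OPEN) < tol:
                    stack.append((0, 0, "M", cols + [col]))
                if i > 1 and abs(Ix[i - 1][j] + GAP_EXT - Ix[i][j]) < tol:
                    stack.append((i - 1, 0, "Ix", cols + [col]))
                continue
            for prev, table, pen in (
                ("M", M, GAP_OPEN),
                ("Ix", Ix, GAP_EXT),
                ("Iy", Iy, GAP_OPEN),
            ):
                if abs(table[i - 1][j] + pen - Ix[i][j]) < tol:
                    stack.append((i - 1, j, prev, cols + [col]))
        else:  # Iy
            col = (None, b[j - 1])
            if j == 0:
                continue
            if i == 0:
                if j == 1 and abs(Iy[i][j] - GAP_OPEN) < tol:
                    stack.append((0, 0, "M", cols + [col]))
                if j > 1 and abs(Iy[i][j - 1] + GAP_EXT - Iy[i][j]) < tol:
                    stack.append((0, j - 1, "Iy", cols + [col]))
                continue
            for prev, table, pen in (
                ("M", M, GAP_OPEN),
                ("Iy", Iy, GAP_EXT),
                ("Ix", Ix, GAP_OPEN),
            ):
                if abs(table[i][j - 1] + pen - Iy[i][j]) < tol:
                    stack.append((i, j - 1, prev, cols + [col]))
    return out


def window_score(seq: str, profile, start: int) -> float:
    """Oracle score of one window (0-based start), plain Python summation."""
    from panta.profile_scan import AA_INDEX

    table = profile.scores_with_unknown()
    return sum(
        table[k][AA_INDEX.get(seq[start + k], 20)] for k in range(profile.length)
    )


def brute_force_best_window(seq: str, profile) -> tuple[int, float] | None:
    """Exhaustive window enumeration for the PSSM scanner (0-based start)."""
    L = profile.length
    if len(seq) < L:
        return None
    from panta.profile_scan import AA_INDEX

    table = profile.scores_with_unknown()
    best = None
    for start in range(len(seq) - L + 1):
        total = 0.0
        for k in range(L):
            aa = seq[start + k]
            total += table[k][AA_INDEX.get(aa, 20)]
        if best is None or total > best[1]:
            best = (start, total)
    return best
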