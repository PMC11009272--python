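"""Independent oracles used by the test suite.

These reimplement the checked quantities by a different route than the
package (plain-Python recurrences, closed-form formulas, exhaustive
backtracking) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def overlap_dp(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Plain nested-loop semi-global DP. Returns (H, best_score)."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    best = max(
        max(H[i][m] for i in range(n + 1)),
        max(H[n][j] for j in range(m + 1)),
    )
    return H, best


def optimal_overlap_identities(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Best overlap score and the set of identity percents attained by *all*
    optimal-score alignments (terminal gap columns excluded), found by
    exhaustive tie backtracking."""
    n, m = len(a), len(b)
    H, best = overlap_dp(a, b, match, mismatch, gap)
    eps = 1e-9

    cache: dict[tuple[int, int], set[tuple[int, int]]] = {}

    def tails(i: int, j: int) -> set[tuple[int, int]]:
        """(matches, columns) pairs over all locally-optimal paths back to a boundary."""
        if i == 0 or j == 0:
            return {(0, 0)}
        key = (i, j)
        if key in cache:
            return cache[key]
        out: set[tuple[int, int]] = set()
        s = match if a[i - 1] == b[j - 1] else mismatch
        if abs(H[i][j] - (H[i - 1][j - 1] + s)) < eps:
            hit = int(a[i - 1] == b[j - 1])
            out |= {(mt + hit, c + 1) for mt, c in tails(i - 1, j - 1)}
        if abs(H[i][j] - (H[i - 1][j] + gap)) < eps:
            out |= {(mt, c + 1) for mt, c in tails(i - 1, j)}
        if abs(H[i][j] - (H[i][j - 1] + gap)) < eps:
            out |= {(mt, c + 1) for mt, c in tails(i, j - 1)}
        cache[key] = out
        return out

    identities: set[float] = set()
    ends = [(i, m) for i in range(n + 1)] + [(n, j) for j in range(m + 1)]
    for i, j in ends:
        if abs(H[i][j] - best) < eps:
            for mt, c in tails(i, j):
                identities.add(100.0 * mt / c if c else 0.0)
    return best, identities


def ols_closed_form(x, y, with_intercept=True):
    """Textbook least-squares slope and r-squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if with_intercept:
        xc, yc = x - x.mean(), y - y.mean()
        slope = (xc * yc).sum() / (xc * xc).sum()
        r2 = ((xc * yc).sum() ** 2) / ((xc * xc).sum() * (yc * yc).sum())
        return slope, r2
    slope = (x * y).sum() / (x * x).sum()
    r2 = ((x * y).sum() ** 2) / ((x * x).sum() * (y * y).sum())
    return slope, r2


def piecewise_linear_average(depths, values) -> float:
    """Depth average of a piecewise-linear profile via exact segment antiderivatives."""
    depths = np.asarray(depths, dtype=float)
    values = np.asarray(values, dtype=float)
    integral = 0.0
    for k in range(len(depths) - 1):
        z0, z1 = depths[k], depths[k + 1]
        v0, v1 = values[k], values[k + 1]
        slope = (v1 - v0) / (z1 - z0)
        intercept = v0 - slope * z0
        antider = lambda z: intercept * z + 0.5 * slope * z * z
        integral += antider(z1) - antider(z0)
    return integral / (depths[-1] - depths[0])


def n50_brute_force(lengths) -> int:
    """N50 by scanning every candidate length."""
    total = sum(lengths)
    candidates = [
        L for L in sorted(set(lengths), reverse=True)
        if sum(x for x in lengths if x >= L) * 2 >= total
    ]
    return max(candidates)


def mutate(sequence: str, positions, rng) -> str:
    """Substitute a different base at each given position."""
    alphabet = "ACGT"
    out = list(sequence)
    for pos in positions:
        choices = [b for b in alphabet if b != out[pos]]
        out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)
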