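"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: plain Python
loops, scalar arithmetic and exact integer combinatorics, so that agreement
with the package is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from math import comb


def _collapse_value(v: int, diff_model: str) -> int:
    if diff_model == "allelic":
        return v
    if diff_model == "dominant":
        return int(v >= 1)
    if diff_model == "recessive":
        return int(v == 2)
    if diff_model == "heterozygote":
        return int(v == 1)
    raise ValueError(diff_model)


def naive_morf_weights(
    X,
    y,
    kind: str,
    k: int = 10,
    scale: float = 4.0,
    diff_model: str = "allelic",
    metric: str = "hamming",
):
    """Triple-loop Relief weight update with explicit scalar kernels."""
    n = len(X)
    a = len(X[0])
    Xc = [[_collapse_value(int(v), diff_model) for v in row] for row in X]

    def dist(i, j):
        if metric == "hamming":
            return sum(X[i][p] != X[j][p] for p in range(a))
        return sum(abs(int(X[i][p]) - int(X[j][p])) for p in range(a))

    D = [[dist(i, j) for j in range(n)] for i in range(n)]
    pairs = [D[i][j] for i in range(n) for j in range(i + 1, n)]
    t = sum(pairs) / len(pairs)
    u = math.sqrt(sum((d - t) ** 2 for d in pairs) / len(pairs))

    if kind == "relieff":
        t_hit, t_miss = [], []
        for i in range(n):
            hits = sorted(D[i][j] for j in range(n) if j != i and y[j] == y[i])
            misses = sorted(D[i][j] for j in range(n) if y[j] != y[i])
            t_hit.append(hits[min(k, len(hits)) - 1] if hits else -1)
            t_miss.append(misses[min(k, len(misses)) - 1] if misses else -1)

    def f(i, j):
        d = D[i][j]
        if kind == "relieff":
            thr = t_hit[i] if y[i] == y[j] else t_miss[i]
            return 1.0 if d <= thr else 0.0
        if kind == "surf":
            return 1.0 if d <= t else 0.0
        if kind == "surf_star":
            return 1.0 if d <= t else -1.0
        if kind == "swrf_star":
            return 2.0 / (1.0 + math.exp(-(t - d) / (u / scale))) - 1.0
        raise ValueError(kind)

    W = [0.0] * a
    for i in range(n):
        den = sum(abs(f(i, j)) for j in range(n) if j != i)
        if den == 0:
            continue
        for p in range(a):
            num = 0.0
            for j in range(n):
                if j == i:
                    continue
                c = 1.0 if y[i] != y[j] else -1.0
                diff = 1.0 if Xc[i][p] != Xc[j][p] else 0.0
                num += c * diff * f(i, j)
            W[p] += num / den
    return [w / n for w in W]


def naive_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration over the margins.

    Table weights C(r1, x) * C(r2, c1 - x) are exact integers; a table is
    included if its weight is at most the observed weight times (1 + 1e-7),
    the tie convention of standard implementations.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = comb(r1, a) * comb(r2, c)
    total = sum(weights)
    kept = sum(w for w in weights if w <= w_obs * (1 + 1e-7))
    return kept / total


def naive_power(flags) -> float:
    return sum(bool(f) for f in flags) / len(flags)
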