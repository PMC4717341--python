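"""Independent brute-force reimplementations used as test oracles.

Everything here is written as plain doubly/triply nested loops over pairs
and sites, deliberately ignoring the vectorised code paths in the
package, so the two routes can disagree if either is wrong.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

ACGT = set("ACGT")


def pair_diff(a: str, b: str) -> tuple[int, int]:
    """(differences, compared sites) for one pair under pairwise deletion."""
    d = c = 0
    for x, y in zip(a, b):
        if x in ACGT and y in ACGT:
            c += 1
            if x != y:
                d += 1
    return d, c


def brute_k_hat(seqs: list[str]) -> float:
    total = 0
    pairs = 0
    for a, b in combinations(seqs, 2):
        total += pair_diff(a, b)[0]
        pairs += 1
    return total / pairs


def brute_pi(seqs: list[str]) -> float:
    vals = []
    for a, b in combinations(seqs, 2):
        d, c = pair_diff(a, b)
        if c > 0:
            vals.append(d / c)
    return float(np.mean(vals)) if vals else float("nan")


def brute_segregating(seqs: list[str]) -> tuple[int, list[int]]:
    positions = []
    for site in range(len(seqs[0])):
        states = {s[site] for s in seqs if s[site] in ACGT}
        if len(states) >= 2:
            positions.append(site + 1)
    return len(positions), positions


def brute_singletons(seqs: list[str]) -> list[int]:
    n = len(seqs)
    _, seg = brute_segregating(seqs)
    U = [0] * n
    for pos in seg:
        site = pos - 1
        for i in range(n):
            x = seqs[i][site]
            if x not in ACGT:
                continue
            if all(seqs[j][site] != x for j in range(n) if j != i):
                U[i] += 1
    return U


def brute_tajimas_d(seqs: list[str]) -> float:
    n = len(seqs)
    S, _ = brute_segregating(seqs)
    if S == 0:
        return float("nan")
    k = brute_k_hat(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = k - S / a1
    if var == 0:
        return 0.0 if abs(num) < 1e-12 else float("nan")
    return num / math.sqrt(var)


def brute_r2(seqs: list[str]) -> float:
    n = len(seqs)
    S, _ = brute_segregating(seqs)
    if S == 0:
        return float("nan")
    U = brute_singletons(seqs)
    k = brute_k_hat(seqs)
    return math.sqrt(sum((u - k / 2) ** 2 for u in U) / n) / S


def random_alignment(
    rng: np.random.Generator,
    n: int,
    L: int,
    p_missing: float = 0.05,
    p_variant: float = 0.3,
) -> list[str]:
    """Random alignment with shared backbone, variants and missing symbols."""
    backbone = rng.choice(list("ACGT"), size=L)
    seqs = []
    for _ in range(n):
        row = backbone.copy()
        var = rng.random(L) < p_variant
        row[var] = rng.choice(list("ACGT"), size=int(var.sum()))
        miss = rng.random(L) < p_missing
        row[miss] = rng.choice(list("N-RYK"), size=int(miss.sum()))
        seqs.append("".join(row))
    return seqs


def brute_mst_weight(dist: np.ndarray) -> int:
    """Exhaustive minimum spanning-tree weight over all spanning trees."""
    H = dist.shape[0]
    if H == 1:
        return 0
    edges = [(i, j) for i in range(H) for j in range(i + 1, H)]
    best = None
    for subset in combinations(edges, H - 1):
        parent = list(range(H))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            w = sum(int(dist[i, j]) for i, j in subset)
            best = w if best is None else min(best, w)
    return best


def brute_spearman(x: list[float], y: list[float]) -> float:
    """Spearman rho with mid-ranks, from the Pearson-of-ranks definition."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = mid
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
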