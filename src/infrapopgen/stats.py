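"""Diversity statistics and neutrality tests on a single alignment.

Implements the per-species summary statistics used throughout the
analysis: mean pairwise differences (k̂), nucleotide diversity (π),
segregating sites (S), per-sequence singleton counts (U_i), Tajima's D
with a standard-normal p-value, and the Ramos-Onsins & Rozas R₂ statistic
with a lower-tail p-value from neutral coalescent simulations conditioned
on the observed n and S.

Missing data (gaps, N, IUPAC ambiguities) are handled by pairwise
deletion: a site contributes to a pair's comparison only when both
sequences carry an unambiguous A/C/G/T there, and a site is segregating
only if at least two distinct unambiguous bases occur in its column.
π uses per-pair compared-site denominators so it stays a per-site
quantity under missing data; with complete data it reduces to k̂/L.

Statistics that are undefined when S = 0 (D, R₂ and their p-values) are
returned as NaN, never imputed as zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError
from .io import Alignment

__all__ = [
    "DiversityStats",
    "CoalescentReplicate",
    "pairwise_differences",
    "nucleotide_diversity",
    "segregating_sites",
    "singleton_counts",
    "tajimas_d",
    "tajima_constants",
    "r2_statistic",
    "r2_from_singletons",
    "simulate_coalescent_fixed_S",
    "r2_pvalue",
    "compute_diversity_stats",
]


def _check_n(alignment: Alignment, minimum: int = 2) -> None:
    if alignment.n < minimum:
        raise InsufficientDataError(
            f"need >= {minimum} sequences, got {alignment.n}"
        )


def _pair_diff_and_compared(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair difference counts and compared-site counts (pairwise deletion)."""
    n = codes.shape[0]
    valid = codes != 255
    diffs = np.zeros((n, n), dtype=np.int64)
    compared = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        ne = (codes[i] != codes[i + 1 :]) & both
        d = ne.sum(axis=1)
        c = both.sum(axis=1)
        diffs[i, i + 1 :] = d
        diffs[i + 1 :, i] = d
        compared[i, i + 1 :] = c
        compared[i + 1 :, i] = c
    return diffs, compared


def pairwise_differences(alignment: Alignment) -> tuple[float, np.ndarray]:
    """Mean pairwise differences k̂ and the symmetric per-pair count matrix.

    k̂ = (sum of differences over all pairs) / C(n, 2); a site counts
    toward a pair only when both members are unambiguous there.
    """
    _check_n(alignment)
    diffs, _ = _pair_diff_and_compared(alignment.codes)
    n = alignment.n
    k_hat = diffs[np.triu_indices(n, 1)].sum() / (n * (n - 1) / 2)
    return float(k_hat), diffs


def nucleotide_diversity(alignment: Alignment) -> float:
    """π: mean over pairs of (differences / sites compared in that pair).

    Pairs sharing no compared site are excluded with a warning; NaN if
    every pair is excluded.
    """
    _check_n(alignment)
    diffs, compared = _pair_diff_and_compared(alignment.codes)
    iu = np.triu_indices(alignment.n, 1)
    d, c = diffs[iu], compared[iu]
    usable = c > 0
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} pair(s) share no compared site; excluded from π"
        )
    if not usable.any():
        return float("nan")
    return float(np.mean(d[usable] / c[usable]))


def _site_base_counts(codes: np.ndarray) -> np.ndarray:
    """(4, L) counts of unambiguous bases per column."""
    return np.stack([(codes == b).sum(axis=0) for b in range(4)])


def segregating_sites(alignment: Alignment) -> tuple[int, list[int]]:
    """Number and 1-based positions of segregating (polymorphic) sites.

    A site segregates iff >= 2 distinct unambiguous bases occur in its
    column.
    """
    _check_n(alignment)
    counts = _site_base_counts(alignment.codes)
    seg = (counts > 0).sum(axis=0) >= 2
    positions = (np.flatnonzero(seg) + 1).tolist()
    return int(seg.sum()), positions


def singleton_counts(alignment: Alignment) -> np.ndarray:
    """U_i: segregating sites where sequence i's base occurs in no other sequence."""
    _check_n(alignment)
    codes = alignment.codes
    counts = _site_base_counts(codes)
    seg = (counts > 0).sum(axis=0) >= 2
    n = codes.shape[0]
    U = np.zeros(n, dtype=np.int64)
    if not seg.any():
        return U
    sub = codes[:, seg]  # (n, S)
    subcounts = counts[:, seg]  # (4, S)
    valid = sub != 255
    # base count at (i, s) for sequence i's own base; 0 rows where missing
    own = np.zeros(sub.shape, dtype=np.int64)
    for b in range(4):
        mask = sub == b
        own[mask] = np.broadcast_to(subcounts[b], sub.shape)[mask]
    U[:] = ((own == 1) & valid).sum(axis=1)
    return U


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    if n < 2:
        raise InsufficientDataError("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _tajimas_d_from_summary(n: int, S: int, k_hat: float) -> tuple[float, float]:
    if S == 0:
        return float("nan"), float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    num = k_hat - S / c["a1"]
    if var == 0.0:
        # n = 2 degenerate case: e1 = e2 = 0 and the numerator is 0 too
        if abs(num) < 1e-12:
            return 0.0, 1.0
        return float("nan"), float("nan")
    D = num / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(D))
    return float(D), float(p)


def tajimas_d(alignment: Alignment) -> tuple[float, float]:
    """Tajima's D and its two-sided p-value under D ~ N(0, 1).

    D = (k̂ − S/a1) / sqrt(e1·S + e2·S(S−1)). NaN when S = 0 (undefined,
    not zero).
    """
    _check_n(alignment)
    S, _ = segregating_sites(alignment)
    k_hat, _ = pairwise_differences(alignment)
    return _tajimas_d_from_summary(alignment.n, S, k_hat)


def r2_from_singletons(U: np.ndarray, k_hat: float, S: int) -> float:
    """R₂ = sqrt(mean((U_i − k̂/2)²)) / S; NaN when S = 0."""
    if S == 0:
        return float("nan")
    return float(np.sqrt(np.mean((np.asarray(U, dtype=float) - k_hat / 2) ** 2)) / S)


def r2_statistic(alignment: Alignment) -> float:
    """Ramos-Onsins & Rozas R₂ on the alignment (NaN when S = 0).

    Low values indicate an excess of singletons relative to pairwise
    differences — the signature of recent population expansion.
    """
    _check_n(alignment)
    S, _ = segregating_sites(alignment)
    if S == 0:
        return float("nan")
    k_hat, _ = pairwise_differences(alignment)
    return r2_from_singletons(singleton_counts(alignment), k_hat, S)


@dataclass
class CoalescentReplicate:
    """One neutral constant-size coalescent genealogy with S mutations.

    Branches are stored as leaf-set bitmasks with lengths in coalescent
    units; the S mutations are placed multinomially on branches in
    proportion to length (infinite-sites: each mutation yields one
    biallelic site whose derived carriers are the leaves below it).
    """

    n: int
    S: int
    branch_masks: list[int]
    branch_lengths: np.ndarray
    site_counts: np.ndarray  # mutations per branch, sums to S
    _incidence: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_tree_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def incidence(self) -> np.ndarray:
        """(n, S) boolean derived-allele incidence matrix."""
        if self._incidence is None:
            inc = np.zeros((self.n, self.S), dtype=bool)
            col = 0
            for mask, c in zip(self.branch_masks, self.site_counts):
                if c == 0:
                    continue
                rows = [i for i in range(self.n) if mask >> i & 1]
                inc[np.ix_(rows, range(col, col + c))] = True
                col += c
            self._incidence = inc
        return self._incidence

    def summary(self) -> tuple[float, np.ndarray]:
        """(k̂, U) computed directly from branch masks, without the matrix."""
        n = self.n
        full = (1 << n) - 1
        pairsum = 0
        U = np.zeros(n, dtype=np.int64)
        for mask, c in zip(self.branch_masks, self.site_counts):
            if c == 0:
                continue
            d = mask.bit_count()
            pairsum += c * d * (n - d)
            if d == 1:
                U[mask.bit_length() - 1] += c
            elif d == n - 1:
                U[(full ^ mask).bit_length() - 1] += c
        k_hat = pairsum / (n * (n - 1) / 2)
        return float(k_hat), U

    def r2(self) -> float:
        k_hat, U = self.summary()
        return r2_from_singletons(U, k_hat, self.S)


def simulate_coalescent_fixed_S(
    n: int, S: int, rng: np.random.Generator
) -> CoalescentReplicate:
    """Neutral constant-size coalescent for n lineages with exactly S mutations.

    While j lineages remain, waiting time T_j ~ Exponential(rate j(j−1)/2)
    and a uniformly random pair merges; the S mutations are then dropped
    multinomially on branches with probability proportional to branch
    length. Every resulting site is polymorphic (derived count in 1..n−1).
    """
    if n < 2:
        raise InsufficientDataError("coalescent needs n >= 2")
    if S < 1:
        raise InsufficientDataError("fixed-S simulation needs S >= 1")
    js = np.arange(n, 1, -1)
    times = rng.exponential(1.0, size=n - 1) * (2.0 / (js * (js - 1)))
    picks = rng.random(size=(n - 1, 2))

    masks = [1 << i for i in range(n)]
    births = [0.0] * n
    branch_masks: list[int] = []
    lengths = np.empty(2 * (n - 1))
    t = 0.0
    k = n
    for step in range(n - 1):
        t += times[step]
        i = int(picks[step, 0] * k)
        j = int(picks[step, 1] * (k - 1))
        if j >= i:
            j += 1
        branch_masks.append(masks[i])
        branch_masks.append(masks[j])
        lengths[2 * step] = t - births[i]
        lengths[2 * step + 1] = t - births[j]
        merged = masks[i] | masks[j]
        # replace i with merged node, drop j (order within list is irrelevant)
        masks[i], births[i] = merged, t
        masks[j], births[j] = masks[k - 1], births[k - 1]
        del masks[k - 1], births[k - 1]
        k -= 1
    counts = rng.multinomial(S, lengths / lengths.sum())
    return CoalescentReplicate(n, S, branch_masks, lengths, counts)


def replicate_to_alignment(rep: CoalescentReplicate) -> Alignment:
    """Render a replicate as a two-state (A=ancestral, G=derived) alignment."""
    inc = rep.incidence
    seqs = ["".join("G" if x else "A" for x in row) for row in inc]
    return Alignment([f"sim{i}" for i in range(rep.n)], seqs)


def r2_pvalue(
    alignment: Alignment, reps: int = 1000, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """R₂ and its lower-tail Monte-Carlo p-value.

    The null conditions on the observed n and S (fixed-S mutation
    dropping on a neutral constant-size coalescent); p = (1 + #{R₂_sim ≤
    R₂_obs}) / (reps + 1). Low observed R₂ → small p → expansion signal.
    """
    if rng is None:
        rng = np.random.default_rng()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    S, _ = segregating_sites(alignment)
    if S == 0:
        return float("nan"), float("nan")
    r2_obs = r2_statistic(alignment)
    hits = 0
    for _ in range(reps):
        if simulate_coalescent_fixed_S(alignment.n, S, rng).r2() <= r2_obs:
            hits += 1
    return r2_obs, (1 + hits) / (reps + 1)


@dataclass
class DiversityStats:
    """Full per-alignment summary: n, L, S, k̂, π, D, R₂ and p-values."""

    n: int
    L: int
    S: int
    k_hat: float
    pi: float
    D: float
    p_D: float
    R2: float
    p_R2: float
    U: np.ndarray


def compute_diversity_stats(
    alignment: Alignment,
    r2_reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> DiversityStats:
    """All statistics for one alignment in a single pass.

    ``r2_reps=0`` skips the coalescent p-value (p_R2 = NaN), which is
    useful when only the point statistics are needed.
    """
    _check_n(alignment)
    S, _ = segregating_sites(alignment)
    k_hat, _ = pairwise_differences(alignment)
    pi = nucleotide_diversity(alignment)
    D, p_D = _tajimas_d_from_summary(alignment.n, S, k_hat)
    U = singleton_counts(alignment)
    R2 = r2_from_singletons(U, k_hat, S)
    p_R2 = float("nan")
    if S > 0 and r2_reps > 0:
        if rng is None:
            rng = np.random.default_rng()
        hits = 0
        for _ in range(r2_reps):
            if simulate_coalescent_fixed_S(alignment.n, S, rng).r2() <= R2:
                hits += 1
        p_R2 = (1 + hits) / (r2_reps + 1)
    return DiversityStats(
        n=alignment.n, L=alignment.length, S=S, k_hat=k_hat, pi=pi,
        D=D, p_D=p_D, R2=R2, p_R2=p_R2, U=U,
    )
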