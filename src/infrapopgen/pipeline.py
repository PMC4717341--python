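"""Resampling pipeline: one-mite-per-bird subsampling, weighted GLMs, ICC.

Mites within a bird are kin (vertical transmission), so treating them as
independent draws from the species gene pool underestimates species-wide
diversity. The headline procedure therefore builds many replicate
datasets, each keeping a single randomly chosen mite per bird, recomputes
π and the neutrality statistics per species, jitters each species' median
infrapopulation size M to Uniform(M/2, M) (the census counts may include
co-occurring mite species, so the true median lies somewhere in that
band), and fits a weighted Gaussian-identity GLM of π on the jittered
load in every iteration. Results are aggregated across iterations, and
per-species neutrality tests are classified by the percentage of
significant iterations.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, InsufficientDataError
from .io import SpeciesDataset
from .stats import compute_diversity_stats, nucleotide_diversity, segregating_sites

__all__ = [
    "subsample_one_per_bird",
    "jitter_load",
    "fit_wls_glm",
    "RegressionRecord",
    "run_pipeline",
    "RunSummary",
    "classify_significance",
    "icc_repeatability",
    "RepeatabilityResult",
    "infrapopulation_diversities",
    "robustness_checks",
]


def subsample_one_per_bird(
    dataset: SpeciesDataset, rng: np.random.Generator
) -> SpeciesDataset:
    """One uniformly chosen mite per bird; size = number of birds."""
    birds = dataset.birds()
    if len(birds) < 2:
        raise InsufficientDataError(
            f"{dataset.species}: needs >= 2 birds, has {len(birds)}"
        )
    chosen = [samples[rng.integers(len(samples))] for samples in birds.values()]
    meta = {m.sample_id: m for m in dataset.metadata}
    return SpeciesDataset(
        species=dataset.species,
        alignment=dataset.alignment.subset(chosen),
        metadata=[meta[c] for c in chosen],
        median_load=dataset.median_load,
    )


def jitter_load(M: float, rng: np.random.Generator) -> float:
    """Draw M* ~ Uniform(M/2, M), continuous."""
    if M <= 0:
        raise ConfigurationError(f"median load must be positive, got {M}")
    return float(rng.uniform(M / 2.0, M))


@dataclass
class RegressionRecord:
    """Weighted Gaussian-identity GLM of diversity on load."""

    slope: float
    intercept: float
    F: float
    p: float
    deviance_explained: float
    null_deviance: float
    resid_deviance: float
    n_obs: int
    df_resid: int


def fit_wls_glm(
    pi: np.ndarray, load: np.ndarray, weights: np.ndarray
) -> RegressionRecord:
    """Weighted least squares of π on load (Gaussian errors, identity link).

    Weights are the per-species mite sample sizes, giving more confidence
    to better-sampled species. Reports the weighted null and residual
    deviances, deviance_explained = 1 − resid/null, and the F test
    F = (null − resid) / (resid / (n − 2)) on (1, n − 2) df.
    """
    y = np.asarray(pi, dtype=float)
    x = np.asarray(load, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = y.size
    if n < 3:
        raise InsufficientDataError(f"regression needs >= 3 species, got {n}")
    if np.ptp(x) == 0:
        raise ConfigurationError("zero variance in load: singular fit")
    X = np.column_stack([np.ones(n), x])
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta
    resid_dev = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    null_dev = float(np.sum(w * (y - ybar) ** 2))
    df_resid = n - 2
    if resid_dev == 0.0:
        F, p = math.inf, 0.0
    else:
        F = (null_dev - resid_dev) / (resid_dev / df_resid)
        p = float(sps.f.sf(F, 1, df_resid))
    dev_expl = 1.0 - resid_dev / null_dev if null_dev > 0 else float("nan")
    return RegressionRecord(
        slope=float(beta[1]), intercept=float(beta[0]), F=float(F), p=p,
        deviance_explained=dev_expl, null_deviance=null_dev,
        resid_deviance=resid_dev, n_obs=n, df_resid=df_resid,
    )


def classify_significance(pct: float) -> str:
    """Map a percentage of significant iterations to its mark.

    Strictly more than 95% → "**" (significant); strictly more than 75%
    (up to 95) → "*" (marginally significant); otherwise "".
    """
    if not (0.0 <= pct <= 100.0):
        raise ConfigurationError(f"percentage out of [0, 100]: {pct}")
    if pct > 95.0:
        return "**"
    if pct > 75.0:
        return "*"
    return ""


def _species_rng(seed: int, iteration: int, species: str) -> np.random.Generator:
    # stable per-(iteration, species) substream: adding/removing one species
    # never perturbs another species' draws
    key = zlib.crc32(species.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(iteration, key))
    )


@dataclass
class RunSummary:
    """Aggregated output of the resampling pipeline."""

    species_summary: pd.DataFrame
    regression_summary: pd.DataFrame
    fixed_load_regression: RegressionRecord
    iterations: int
    alpha: float


def run_pipeline(
    datasets: list[SpeciesDataset],
    iterations: int = 100,
    alpha: float = 0.05,
    r2_reps: int = 1000,
    seed: int = 0,
    exclude_species: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, RunSummary]:
    """Run the full subsampling + GLM procedure.

    Per iteration and species: subsample one mite per bird, compute
    DiversityStats (``r2_reps=0`` skips the coalescent p-value), jitter
    the median load; then fit the weighted GLM of π on jittered load
    across species. Species with fewer than two birds are skipped with a
    warning. Returns (per-iteration-per-species records, per-iteration
    regression records, RunSummary). The summary also carries the
    fixed-load (non-jittered) regression of mean π on true median load as
    the secondary check.

    Deterministic given ``seed``; per-(iteration, species) substreams are
    derived so results are invariant to which other species are present.
    """
    datasets = [d for d in datasets if d.species not in set(exclude_species)]
    eligible = []
    for d in datasets:
        if d.n_birds < 2:
            warnings.warn(f"{d.species}: fewer than 2 birds; skipped")
        else:
            eligible.append(d)
    if len(eligible) < 3:
        raise InsufficientDataError(
            f"pipeline needs >= 3 eligible species, got {len(eligible)}"
        )

    rows = []
    reg_rows = []
    for it in range(iterations):
        pis, loads, wts = [], [], []
        for d in eligible:
            rng = _species_rng(seed, it, d.species)
            sub = subsample_one_per_bird(d, rng)
            st = compute_diversity_stats(sub.alignment, r2_reps=r2_reps, rng=rng)
            m_star = jitter_load(d.median_load, rng)
            rows.append({
                "iteration": it, "species": d.species, "n_sub": st.n,
                "S": st.S, "pi": st.pi, "D": st.D, "p_D": st.p_D,
                "R2": st.R2, "p_R2": st.p_R2, "load_jittered": m_star,
                "sampled_ids": ";".join(sub.alignment.ids),
            })
            pis.append(st.pi)
            loads.append(m_star)
            wts.append(d.n)  # weight = full per-species mite count
        reg = fit_wls_glm(np.array(pis), np.array(loads), np.array(wts))
        reg_rows.append({
            "iteration": it, "slope": reg.slope, "intercept": reg.intercept,
            "F": reg.F, "p": reg.p,
            "deviance_explained": reg.deviance_explained,
        })

    records = pd.DataFrame(rows)
    regressions = pd.DataFrame(reg_rows)

    sp_rows = []
    for d in eligible:
        sub = records[records["species"] == d.species]
        pct_r2 = float((sub["p_R2"] <= alpha).sum()) / iterations * 100.0
        pct_d = float((sub["p_D"] <= alpha).sum()) / iterations * 100.0
        S_full, _ = segregating_sites(d.alignment)
        sp_rows.append({
            "species": d.species, "n": d.n, "n_birds": d.n_birds,
            "S_full": S_full, "median_load": d.median_load,
            "mean_pi": float(np.nanmean(sub["pi"])),
            "mean_D": float(np.nanmean(sub["D"])) if sub["D"].notna().any() else float("nan"),
            "mean_R2": float(np.nanmean(sub["R2"])) if sub["R2"].notna().any() else float("nan"),
            "pct_sig_R2": pct_r2, "mark_R2": classify_significance(pct_r2),
            "pct_sig_D": pct_d, "mark_D": classify_significance(pct_d),
        })
    species_summary = pd.DataFrame(sp_rows)

    def _agg(col: str) -> dict[str, float]:
        v = regressions[col].to_numpy()
        return {
            "mean": float(np.mean(v)),
            "ci_lo": float(np.percentile(v, 2.5)),
            "ci_hi": float(np.percentile(v, 97.5)),
        }

    regression_summary = pd.DataFrame(
        {c: _agg(c) for c in ("slope", "F", "p", "deviance_explained")}
    ).T.reset_index(names="quantity")

    fixed = fit_wls_glm(
        species_summary["mean_pi"].to_numpy(),
        species_summary["median_load"].to_numpy(),
        species_summary["n"].to_numpy(),
    )
    summary = RunSummary(
        species_summary=species_summary,
        regression_summary=regression_summary,
        fixed_load_regression=fixed,
        iterations=iterations,
        alpha=alpha,
    )
    return records, regressions, summary


@dataclass
class RepeatabilityResult:
    """One-way ANOVA intraclass correlation with 95% CI."""

    R: float
    ci_lo: float
    ci_hi: float
    n_groups: int
    n_obs: int


def icc_repeatability(values: np.ndarray, groups: np.ndarray) -> RepeatabilityResult:
    """ICC (repeatability) of a measurement grouped by species.

    One-way random-effects ANOVA with the unbalanced-design correction
    n0 = (N − Σnᵢ²/N)/(a−1); R = (MSB − MSW)/(MSB + (n0 − 1)·MSW). The
    95% CI comes from F-distribution bounds on MSB/MSW (Searle), mapped
    to the ICC scale.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    a = labels.size
    N = values.size
    if a < 2 or N <= a:
        raise InsufficientDataError(
            f"ICC needs >= 2 groups with replication (a={a}, N={N})"
        )
    ni = np.bincount(inv).astype(float)
    grand = values.mean()
    gmeans = np.array([values[inv == g].mean() for g in range(a)])
    ssb = float(np.sum(ni * (gmeans - grand) ** 2))
    ssw = float(np.sum((values - gmeans[inv]) ** 2))
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    n0 = (N - np.sum(ni**2) / N) / (a - 1)
    if msw == 0.0:
        return RepeatabilityResult(1.0, 1.0, 1.0, a, N)
    R = (msb - msw) / (msb + (n0 - 1) * msw)
    F_obs = msb / msw
    f_lo = F_obs / sps.f.ppf(0.975, a - 1, N - a)
    f_hi = F_obs / sps.f.ppf(0.025, a - 1, N - a)
    lo = (f_lo - 1) / (f_lo + n0 - 1)
    hi = (f_hi - 1) / (f_hi + n0 - 1)
    return RepeatabilityResult(float(R), float(lo), float(hi), a, N)


def infrapopulation_diversities(
    dataset: SpeciesDataset, min_mites: int = 2
) -> dict[str, float]:
    """π of each infrapopulation (bird) with at least ``min_mites`` mites."""
    out = {}
    for bird, samples in dataset.birds().items():
        if len(samples) >= min_mites:
            out[bird] = nucleotide_diversity(dataset.alignment.subset(samples))
    return out


def robustness_checks(
    datasets: list[SpeciesDataset],
    species_summary: pd.DataFrame,
    exclude_localities: tuple[str, ...] = (),
    min_mites_per_bird: int = 2,
) -> dict:
    """Two sanity checks on the species-level diversity estimates.

    (a) Spearman rank correlation between the mean infrapopulation-level
    π per species and the species-level subsampled mean π — high ρ says
    the one-mite-per-bird estimates track within-host diversity.
    (b) Paired t-test of per-species π with vs. without samples from the
    designated localities (e.g. a distant sampling region); a
    non-significant t supports pooling localities. Skipped (reported as
    such) when the exclusion set is empty or fewer than 4 species qualify.
    """
    mean_sub_pi = dict(zip(species_summary["species"], species_summary["mean_pi"]))
    infra_means, sub_vals = [], []
    for d in datasets:
        if d.species not in mean_sub_pi:
            continue
        infra = infrapopulation_diversities(d, min_mites_per_bird)
        if len(infra) >= 2:
            infra_means.append(float(np.nanmean(list(infra.values()))))
            sub_vals.append(mean_sub_pi[d.species])
    spearman: dict = {"n": len(infra_means)}
    if len(infra_means) >= 4:
        rho, p = sps.spearmanr(infra_means, sub_vals)
        spearman.update(rho=float(rho), p=float(p))
    else:
        warnings.warn("fewer than 4 species for the Spearman check; skipped")
        spearman.update(rho=float("nan"), p=float("nan"))

    locality: dict = {"excluded": list(exclude_localities)}
    if not exclude_localities:
        locality.update(skipped=True, reason="empty exclusion set")
    else:
        excl = set(exclude_localities)
        full_pi, part_pi = [], []
        for d in datasets:
            keep = [m.sample_id for m in d.metadata if m.locality not in excl]
            if len(keep) < 2 or len(keep) == d.n:
                continue
            full_pi.append(nucleotide_diversity(d.alignment))
            part_pi.append(nucleotide_diversity(d.alignment.subset(keep)))
        if len(full_pi) < 4:
            warnings.warn("fewer than 4 species for the locality check; skipped")
            locality.update(skipped=True, reason="too few affected species",
                            n=len(full_pi))
        else:
            t, p = sps.ttest_rel(full_pi, part_pi)
            locality.update(skipped=False, t=float(t), p=float(p),
                            df=len(full_pi) - 1, n=len(full_pi))
    return {"spearman": spearman, "locality": locality}
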