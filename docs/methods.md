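# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Diversity statistics and missing data

All statistics treat gaps, `N` and IUPAC ambiguity codes as missing and use
**pairwise deletion**: a site enters a pair's comparison only when both
sequences carry an unambiguous A/C/G/T there, and a site is *segregating*
only when at least two distinct unambiguous bases occur in its column.
Complete deletion would discard most of a Sanger alignment for a single
ambiguous read; pairwise deletion keeps that information at the cost of
slightly different per-pair denominators. Consequently π is computed as the
mean over pairs of (differences / sites compared in that pair), which keeps
it a per-site quantity under missing data and reduces exactly to k̂/L when
data are complete. Pairs sharing no compared site are excluded with a
warning.

Sites are indexed 0-based internally and 1-based in every report.

## Tajima's D

D = (k̂ − S/a₁) / √(e₁S + e₂S(S−1)) with a₁ = Σ<sub>i=1</sub><sup>n−1</sup> 1/i,
a₂ = Σ 1/i², b₁ = (n+1)/(3(n−1)), b₂ = 2(n²+n+3)/(9n(n−1)),
c₁ = b₁ − 1/a₁, c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁², e₁ = c₁/a₁,
e₂ = c₂/(a₁²+a₂). The p-value is two-sided under D ~ N(0,1) — the
distributional assumption is approximate but standard. When S = 0, D is
reported as NaN (undefined), never imputed as 0, and every downstream layer
propagates the NaN. At n = 2 the variance constants vanish identically while
the numerator is also exactly zero (a₁ = 1 so k̂ = S); this 0/0 case is
defined as D = 0, p = 1.

## The R₂ test

R₂ = √((1/n) Σ<sub>i</sub> (U<sub>i</sub> − k̂/2)²) / S, where U<sub>i</sub>
counts segregating sites at which sequence i carries a base found in no
other sequence (so with n = 2 every segregating site is a singleton in both
sequences and R₂ = 1/2 exactly). Low R₂ — singletons scarcer than half the
pairwise differences would predict... strictly, per-sequence singleton
branch lengths shorter than expected — indicates recent expansion.

Significance is Monte-Carlo: the null is the neutral constant-size
coalescent **conditioned on the observed n and S** (fixed-S mutation
dropping: exponential coalescence times with rate j(j−1)/2, uniformly random
pair merges, S mutations placed multinomially in proportion to branch
length). Conditioning on S rather than on an estimated θ matches the
statistic's original calibration and requires no nuisance estimate. The
p-value is lower-tail with the (r+1)/(B+1) correction, so it is never 0 and
is exact in expectation; B = 1000 replicates by default. The simulator is
validated against the closed-form expectation E[total tree length] =
2Σ<sub>i=1</sub><sup>n−1</sup>1/i and its type-I error is checked to sit near
the nominal 5%. Under fixed-S conditioning Tajima's D retains its known
small negative bias; the calibration test allows mean D in (−0.2, 0.1).

## Haplotype networks

Sequences identical over their shared unambiguous positions are collapsed
into one haplotype, scanning in input order (first-occurrence numbering;
note the "identical modulo missing" relation is not transitive, so the
first-match rule is part of the definition). The network is a minimum
spanning tree on pairwise Hamming distances, built by Kruskal with edges
sorted by (weight, smaller index, larger index) for determinism. Every
non-tree pair whose distance equals the bottleneck (maximum edge weight on
its tree path) is reported as an *alternative link* rather than silently
dropped — these are the reticulations drawn in published networks; the
bottleneck-equality rule is this package's operational definition of an
equally good link.

`star_score` = fraction of non-hub haplotypes whose tree edge attaches
directly to the hub (the modal haplotype; NaN for a single-haplotype
network). It is an invented, clearly labelled diagnostic that quantifies the
qualitative star-like vs. reticulated contrast; it never enters any
regression.

## The resampling pipeline

Mites within a bird descend from few founders, so per-species diversity
computed on all mites is downward-biased and pseudo-replicated. Each of 100
iterations therefore:

1. keeps exactly one uniformly chosen mite per bird per species (species
   with fewer than two birds are skipped with a warning);
2. recomputes π, D (normal p) and R₂ (coalescent p) on the subsample;
3. draws a jittered load M* ~ Uniform(M/2, M) per species — the published
   load counts do not distinguish co-occurring mite species, so the focal
   species' true median lies between half and the full count;
4. fits a Gaussian-identity GLM of π on M*, weighted by the per-species
   number of sequenced mites n (the only stated sample-size measure),
   implemented as closed-form weighted least squares with weighted null and
   residual deviances, deviance explained = 1 − resid/null, and
   F = (null − resid)/(resid/(n_obs − 2)) on (1, n_obs − 2) df. The
   statsmodels Gaussian GLM with `var_weights` is the independent
   cross-check in the tests.

Aggregation: per-species means of π, D, R₂ over iterations; percentages of
iterations with p ≤ α (α = 0.05, the conventional reading) classified
strictly — pct > 95 → `**`, 75 < pct ≤ 95 → `*` (boundary values 95 and 75
get the weaker mark) — identically for R₂ and D; and the mean with 2.5/97.5
empirical percentiles (distribution-free "95% CI") of slope, F, p and
deviance explained. A fixed-load regression of per-species mean π on the
true medians is always reported as the secondary check. Species-exclusion
flags reproduce with/without-species analyses.

Randomness: one master seed; each (iteration, species) pair gets a
`SeedSequence(seed, spawn_key=(iteration, crc32(species)))` substream, so
runs are bit-reproducible and adding or removing one species never perturbs
another species' draws.

## Repeatability and robustness

ICC of infrapopulation-level π within species uses one-way random-effects
ANOVA with the unbalanced correction n₀ = (N − Σnᵢ²/N)/(a−1),
R = (MSB − MSW)/(MSB + (n₀−1)MSW), and a Searle-type 95% CI from
F-distribution bounds on MSB/MSW mapped to the ICC scale. Infrapopulations
need ≥ 2 mites to contribute.

Robustness: (a) Spearman rank correlation (mid-ranks) between per-species
mean infrapopulation π and the species-level subsampled mean π; (b) a
standard paired t-test of per-species π with vs. without samples from a
designated locality subset. A Welch-style unpaired comparison was considered
for (b) but rejected: the two values per species are computed from
overlapping samples, so the paired design is the defensible one. Both checks
are skipped with a warning below 4 usable species; an empty exclusion set
reports the locality check as skipped rather than degenerate.

## Synthetic data model

Each species is simulated in two phases:

1. **Within birds** — the m sampled mites of a bird are assigned uniformly
   at random to f founder lineages; within-bird coalescence is treated as
   instantaneous, so mites sharing a founder are identical. This captures
   the observed within-host haplotype sharing of vertically transmitted
   symbionts without a full two-timescale simulator. When f ≥ m each mite
   gets its own founder (distinct assignment), making f = m the exact
   unstructured coalescent baseline with E[π] = θ, which the tests verify by
   Monte Carlo.
2. **Across birds** — founder lineages follow a neutral constant-size
   coalescent with per-site scaled mutation rate θ(M) = θ₀·M^β. Expansion
   mode is a sudden g-fold expansion at time T before sampling: coalescence
   proceeds at the standard rate more recently than T and g times faster
   before it (equivalently, ancestral branch segments are compressed by g) —
   the simplest mechanism yielding star genealogies, excess singletons and
   low R₂. Defaults g = 20, T = 0.05 coalescent units.

Mutations are Poisson per branch (mean = length·θ/2·L) at distinct uniform
positions among the L = 507 sites, collisions redrawn (quasi-infinite
sites); back-mutation is not modelled, so the generator never produces
homoplasy.

Default preset: 17 species; median loads log-spaced 5–50 mites/bird (one
order of magnitude, anchored near the largest published feather-mite median
of ~49); 6–12 birds per species, 5 mites per bird, 2 founders per bird;
θ₀ = 3×10⁻⁴ and β = 1.18, chosen so preset π spans ≈ 0.002–0.03 per site —
the magnitude typical of within-species arthropod COI variation; the two
smallest-load species run in expansion mode. Placing the expansion species
at the low end keeps the preset's global load–diversity trend intact while
still providing the star-like contrast; in real systems an expansion species
can of course sit anywhere on the load axis — that departure is exactly what
the regression diagnostics are meant to reveal. All defaults are
illustrative, not estimates of any real mite system.

### What the generator does and does not emulate

Emulated: per-species infrapopulation-size differences, within-bird kin
structure, diversity scaling with load, recent-expansion species, a
two-locality sampling layout (ES/RU with p = 0.2), and monomorphic species
(θ → 0) that exercise every undefined-statistic code path. Not emulated:
sequencing error and ambiguity codes (real Sanger data contain them; the
statistics handle them, the generator does not produce them), homoplasy,
selection and sweeps, geographic structure, unequal mites-per-bird designs,
and any host phylogenetic signal. Passing tests therefore show the chain is
correct and well calibrated under a neutral, structured-sampling model —
not that any particular biological dataset satisfies that model.

## Problem sizes

The test suite and acceptance script use: 200 random alignments (n ≤ 10,
L ≤ 50) for oracle equivalence; 10,000 replicates for tree-length
calibration; 1000 neutral datasets (n = 20, S = 20) × 1000 null replicates
for type-I error; 100 independent 17-species systems × 100 pipeline
iterations for slope recovery (with the coalescent p-value disabled there,
since the recovered quantities — slope sign and the regression p — do not
involve it) and another 100 for the β = 0 false-positive rate (null
θ₀ = 4×10⁻³, matching the preset's central diversity); 50 paired systems for
the expansion contrast; and one full preset analysis at 100 iterations with
B = 200 coalescent replicates per R₂ test.

## Known limitations

- The R₂ null conditions on S; for very small S the p-value is coarse
  (granularity 1/(B+1) and a discrete statistic).
- Tajima's p relies on the N(0,1) approximation, which is crude for small n
  and S; the R₂ test is the primary expansion diagnostic.
- π's pairwise-deletion denominator makes per-pair contributions slightly
  heteroscedastic under heavy missingness.
- The weighted GLM assumes Gaussian errors for a quantity bounded below by
  0; with near-monomorphic species the residuals are right-skewed. The
  percentile aggregation across iterations does not repair this —
  conclusions lean on the robustness checks.
- Single-locus mtDNA: species-level π has large coalescent variance, which
  is why the preset ICC across infrapopulations is moderate (~0.2–0.4)
  rather than high.
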