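# Methods

This note documents the statistical models and procedures implemented in
chronomet, the assumptions they rest on, the defaults and why they were
chosen, and the places where the design was genuinely open.

## Study model and the time axis

A study consists of two in-clinic blocks separated by a break of weeks.
Each block has its own clock (minutes since the block's first scheduled
sample); the break is never represented as elapsed time. Where a single
monotone axis is needed (trajectories, windowed similarity), the blocks are
concatenated with a configurable spacer, default **720 min**. The spacer
only has to exceed the largest coupling window (120 min) so that windowed
matching can never pair points across blocks; its exact value is otherwise
irrelevant, and 720 min keeps plots readable.

The built-in design `humet56` is an *approximate* reconstruction of a
two-block, four-day challenge protocol: 56 plasma time points (16 with
urine), sampled every 15–240 min, with extended fasting (tested over
fasting hours 12–36), a breakfast recovery drink, two lunch drinks, an oral
glucose tolerance test (tested 0–2 h), an oral lipid tolerance test
(0–4 h), a 30-min exercise bout (0–30 min) and a cold stress test
(0–30 min). The exact published sampling table is not reproduced; all
algorithms are schedule-agnostic and accept any user design JSON, so the
built-in grid is a realistic default rather than a reference.

Missing values are absent keys in the long format and `NaN` in the internal
wide table; no sentinel numbers exist anywhere in the API.

## Preprocessing

**log2.** All statistics operate on log2-transformed abundances; raw values
must be strictly positive.

**Outlier screen.** A point is flagged when its log2 value lies outside
mean ± 4·SD for its metabolite and time point, where the mean is the
cross-subject mean at that time point. For the spread, two scopes exist:

- `sd_scope="timepoint"`: the SD across subjects at that single time point,
  candidate included, denominator n−1. This literal reading has a hard
  ceiling: for one deviant among n values, |x − mean|/SD ≤ (n−1)/√n, which
  is 3.61 at n = 15 — *below* 4, so a lone gross outlier can never be
  flagged at typical cohort sizes. The scope is kept for transparency.
- `sd_scope="metabolite"` (default): the SD is pooled over the metabolite's
  time points (root-mean-square of the per-time-point SDs). The per-time-
  point mean still tracks challenge responses, but the spread estimate no
  longer collapses onto the candidate point, so a 6-SD contamination is
  detected while the false-positive rate stays at the nominal ~P(|Z|>4)
  level under a homoscedastic null.

Points whose time point falls within the closed interval
[onset, onset + 30 min] after *any* challenge onset of the same block are
exempted (listed separately, never flagged): sharp post-challenge peaks are
biology, not error. Groups with fewer than 3 values or zero SD are
skipped. Flagging never removes data; `drop_flagged` does, explicitly,
mirroring a workflow in which flagged points are reviewed before exclusion.

The outlier injector used in testing shifts a point *away from the group
mean* by the requested multiple of the larger of the per-time-point and
pooled SD, and contaminates at most one subject per (metabolite, time
point) group — this makes "injected at 6 SD ⇒ recovered by a 4-SD rule"
true by construction rather than true on average.

**Missingness filter.** A metabolite is kept when its missing fraction —
over all scheduled (subject, time point) samples of its own fluid — is
strictly below 30%.

**Transforms.** `zscore` standardizes each metabolite over all non-missing
log2 values (zero-variance metabolites cannot be standardized and become
all-missing, with a warning). `log2fc_block` subtracts the subject's value
at the block's first time point; `log2fc_challenge` subtracts the subject's
value at the challenge baseline; a missing reference makes the derived
values missing.

**Imputation.** `impute_linear` interpolates per subject and block against
clock time, only between observed points (no extrapolation): it is exact
whenever the underlying signal is piecewise linear between observations.
`impute_knn` follows the correlation-preselected KNN family: for each
missing entry, other metabolites of the same fluid+platform are ranked by
|Pearson| with the target over complete pairs (at least 10 pairs required),
the top `n_preselect = 20` form the feature space, samples are compared by
Euclidean distance over the z-scored features restricted to coordinates
observed in both and divided by √(shared count) so unequal overlaps remain
comparable, and the imputed value is the unweighted mean of the target in
the `k = 10` nearest samples. The preselection size, overlap scaling,
unweighted mean and 10-pair minimum are package choices (configurable), set
to mirror common practice in metabolomics KNN imputation.

## Trajectory similarity

The **banded discrete Fréchet distance** is the discrete Fréchet dynamic
programme

    c(i,j) = max( d(i,j), min(c(i−1,j), c(i,j−1), c(i−1,j−1)) )

with point cost d(i,j) = |v_i − v_j| when |t_i − t_j| ≤ W and +∞ otherwise.
The window W is 30 min by default and 120 min when *either* time stamp lies
inside the extended-fasting span (permissive reading; sampling is sparse
there). Time therefore enters only through the band; the value axis is
z-score units. If no finite monotone coupling exists the distance is +∞.
With W = 0 on identical grids the band forces the diagonal coupling and the
distance equals the Chebyshev distance; both this and the full dynamic
programme are checked against exhaustive coupling enumeration in the tests.

Per-subject mode computes the chosen measure within each subject on the
time points where both metabolites are observed (subjects with fewer than
3 shared points are skipped — 2 would suffice for plain distances but is
degenerate for Pearson, and one rule keeps the modes comparable) and
averages over retained subjects. Mean-trajectory mode applies the measure
once to the cross-subject mean curves. Rankings sort ascending for
distances, descending for Pearson, ties by uid; candidates that fail the
overlap rules are listed last with a null score.

## Challenge statistics

Each scan tests, per metabolite and tested time point, the paired two-sided
t-test of log2 values against the challenge baseline over subjects with
both values observed. Fewer than 3 pairs, or zero-variance differences,
yield a null result (not an infinite t). Multiple-testing control is
*reactive*: the Bonferroni threshold is 0.05 divided by the number of
(metabolite × time point) tests in the submitted scan, and the
Benjamini–Hochberg adjustment runs over the scan's non-null p values. The
BH step-up is implemented directly (a dozen lines) and cross-checked
against statsmodels in the tests.

Effect sizes are paired Cohen's d = mean/SD of the differences (SD with
n−1), Hedges-corrected by (n−2)/(n−1.25). The sample-size solver finds the
smallest real n ≥ 2 with

    P( |T'_{n−1, ncp = d√n}| > t_{1−α/2, n−1} ) ≥ power

under the noncentral t, counting *both* rejection tails (the second tail is
negligible at any practical α but costs nothing to include), by bracketing
and Brent root finding with tolerance 10⁻⁵ in n; the returned fractional n
reproduces the requested power to better than 10⁻⁴. The solver is verified
against a 50,000-replicate paired-t simulation.

## Longitudinal Gaussian graphical model

`DynamicalGGM.fit()` estimates, for p metabolites on a complete
(subject × time point) grid:

1. **Time weights.** Trapezoid quadrature weights over the time grid —
   w₁ = (t₂−t₁)/2, interior w_k = (t_{k+1}−t_{k−1})/2, w_T = (t_T−t_{T−1})/2 —
   computed *per block* on block clocks and then jointly normalised to sum
   to 1. Each block is its own integration domain; a single trapezoid across
   the between-block break would hand the boundary samples the break's mass.
2. **Pooled dynamical covariance.** Per subject s, the weighted mean
   μ_s = Σ_k w_k x_{s,k} and covariance c_s(g,h) = Σ_k w_k (x_g−μ_g)(x_h−μ_h);
   C is the unweighted mean of c_s over subjects (inputs are
   imputed-complete, so subjects are exchangeable), and R its correlation.
3. **Shrinkage intensity.** λ\* = clip₀¹( Σ_{i<j} V̂ar(r_ij) / Σ_{i<j} r_ij² ),
   the Ledoit–Wolf/Schäfer–Strimmer form, with V̂ar(r_ij) the weighted
   variance of the per-(subject, time point) products of standardized
   residuals: observation weights ω_{s,k} = w_k/S (S subjects, Σω = 1) and
   variance factor h/(1−h), h = Σω². On uncorrelated data λ\* ≈ 1 (full
   shrinkage — correctly reporting that nothing is estimable); with real
   structure λ\* is small. R_shrunk = λ\*·I + (1−λ\*)·R.
4. **Partial correlations.** pcor_ij = −ω_ij/√(ω_ii ω_jj) with
   ω = R_shrunk⁻¹, diagonal set to 1. At λ = 0 this reproduces plain
   direct-inversion partial correlations (verified to 10⁻¹⁰ against an
   independent loop-based oracle); at λ = 1 all off-diagonals are exactly 0,
   and |pcor| is monotone non-increasing in a forced λ.
5. **Null model.** Edge p values come from the null density of a
   correlation coefficient, f₀(r; κ) = (1−r²)^((κ−3)/2) Γ(κ/2)/(√π Γ((κ−1)/2)),
   whose effective degrees of freedom κ absorb shrinkage, time weighting and
   autocorrelation. Two-sided p values use R₀² ~ Beta(½, (κ−1)/2); at κ = 3
   the density is uniform and p(r) = 1 − |r| (closed-form check). κ is
   fitted to the observed off-diagonal partial correlations. A plain MLE
   over all pairs is biased by the signal tail (true edges widen the
   apparent null and can wipe out every discovery), so the default fit is a
   **truncated MLE**: values beyond the current fit's (1 − 0.05) null
   quantile are excluded and the likelihood carries the matching truncation
   term, iterated until κ is stable. Under a pure null this is unbiased
   (verified by recovery of κ = 100 from 5,000 draws); under a mixture it
   tracks the null bulk. Full two-component mixture modelling of the pcor
   distribution is deliberately out of scope.
6. **Edges.** Cutoff mode keeps pairs with signed pcor ≥ c (an
   absolute-value option exists); significance mode keeps pairs whose pcor
   p value survives the chosen correction (raw 5%, Bonferroni or BH-FDR
   over the p(p−1)/2 tests) *and*, by default, whose plain pooled Pearson
   correlation is significant at 5% (the dual-significance rule). The
   Pearson test uses the pooled observation count n_eff = subjects × time
   points as its degrees of freedom; repeated measures make this df
   optimistic, which is documented rather than corrected because the gate
   is a secondary filter, and it can be disabled.

Multi-fluid merging takes the union of two disjoint fluid-specific networks
and adds one `same_metabolite` edge for every cross-network node pair whose
match key (display name, KEGG or HMDB accession; case-insensitive) agrees;
nodes matching several partners get one edge per partner. Exports: GraphML
(typed attributes, nulls omitted), edge TSV, JSON with provenance. Node
attributes `log2fc` and `neg_log10_p` come from a paired scan at a chosen
(challenge, time point).

## Network validation

Mappable pcor edges (both endpoints mapped to accessions present in the
compound graph; same-metabolite edges excluded) are scored by BFS
shortest-path length. Edges whose endpoints map to the same accession
(distance 0, e.g. the same compound on two platforms) are reported in their
own category and excluded from the distance-1 count. The bootstrap permutes
the accession assignment uniformly among the *mapped* nodes only (unmapped
nodes carry no information), keeps the topology fixed, recounts distance-1
edges per iteration, and reports the empirical p value with the standard +1
correction, (1 + #{null ≥ observed})/(n_iter + 1). On 4 nodes the sampled
null matches exhaustive enumeration over all 24 permutations.

## Synthetic data

The generator emulates the two-block challenge-study structure. The log2 signal is

    baseline_m + scale_{s,m} · template_m(t) + ρ_m · L_{module(m)}(s,t) + ε

with `scale ~ 1 + N(0, subject_variability²)` per subject and metabolite,
`L` a stationary unit-variance AR(1) process per (module, subject) across
the time grid, and `ε ~ N(0, noise_sd²)`. Abundance is 2^signal. Kinetic
templates: washout `A·e^(−t/τ)` resetting at each block start; postprandial
gamma kernels `(Δt/θ)^a e^(−Δt/θ)` (peak-normalised, amplitude per meal,
summed over the subject's preceding meals in the block — the simplest
smooth rise-and-fall, a package choice); a fasting ramp `A·Δt/(Δt+h)` with
exponential post-refeed decay; a circadian sinusoid; flat. Two same-module
metabolites with loading ρ have log2 correlation ρ²/(ρ²+noise_sd²) and
within-module partial correlation c/(1+(p_mod−2)c) under equicorrelation —
both verified against brute-force oracle simulation at 100× the sample
size.

Defaults are the study conditions: 15 subjects, the 56-point two-block
schedule, noise_sd 0.5 (log2 units), module loading 0.8, AR coefficient 0.6
(the within-subject serial correlation the dynamical estimator is built
for), subject variability 0.2, detection-limit censoring at the 5% quantile
of each metabolite's simulated abundances, plus 1% MCAR. Cross-platform
duplicates add an independent-noise copy calibrated so the expected Pearson
correlation equals the configured attenuation. Identical configurations
(including the seed) produce bit-identical output.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: batch/run-day structure and platform
drift, non-Gaussian heavy-tailed measurement error, informative (non-MCAR)
missingness beyond simple left-censoring, inter-metabolite correlation
that is not block-modular (real pathways overlap), urine osmolality
effects, and real pathway biology (metabolite names and the compound graph
used in validation tests are synthetic labels). Recovery results should be
read as "the estimators do what they claim under their own model", not as
field performance guarantees.

## Problem sizes and numerics

The test-suite and acceptance scales are package choices made to give each
check adequate statistical resolution: the Fréchet oracle sweep enumerates
all 255 curves on a 4-point grid (130,560 comparisons); type-I calibration
uses 10,000 *independent* tests (one tested time point per metabolite —
tests sharing a baseline are correlated and would need a far wider
acceptance band); GGM recovery runs five independent study replicates;
power checks use 50,000 Monte-Carlo replicates (binomial SE ≈ 0.002); the
relabeling bootstrap uses 1,000 iterations.

Numerical conventions: SDs use the n−1 denominator throughout; BH enforces
monotonicity and caps at 1; κ is optimised on log(κ−1) with bounded Brent
(absolute tolerance 10⁻¹⁰); partial-correlation inversion raises an
explicit error on singular input at λ = 0 and suggests a 10⁻⁶ floor;
similarity ties break lexicographically by uid; degenerate groups (too few
values, zero variance) are skipped and counted, never silently filled.

## Known limitations

- The dynamical estimator requires complete data; the CLI mean-fills
  residual gaps left by linear imputation (logged) — callers wanting strict
  behaviour should use the library API, which refuses incomplete input.
- Pearson edge significance uses pooled df (see above).
- The per-time-point outlier SD scope is provided but toothless at small n;
  the pooled scope assumes roughly constant within-time-point variance per
  metabolite on the log2 scale.
- Networks are undirected and contemporaneous; no time-lagged edges.
- One-sided tests and mixed-effects response models are out of scope.
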