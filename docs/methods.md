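# Methods

## The state-switching drift model

Weight traces are modelled on a uniform 10-day grid as
y_t = φ₀^{s_t} + y_{t−1} + ε_t^{s_t} with a K-state Markov chain s_t. Fixing
the lag-1 coefficient at 1 makes the model a random walk with state-dependent
drift, so the state intercept φ₀ˢ is directly interpretable as a rate of
weight change in grams per 10-day step; states are named growth, steady and
decline from the sign and magnitude of their mean drift η₀ₛ (largest →
growth, smallest → decline; an exact tie sends the smaller-noise state to
steady). The intercept is itself Gaussian, φ₀ˢ ~ N(η₀ₛ, σ²₀ₛ), capturing
drift heterogeneity beyond the step noise ε ~ N(0, σ²ₛ).

Working on first differences Δy_t removes the unit root: the model becomes a
Gaussian HMM over T−1 increments. Two inference variants are shipped because
the granularity of the intercept draw is a genuine modelling choice:

- **collapsed** (`mode="collapsed"`): the intercept is treated as redrawn at
  every step; marginalizing gives emission N(η₀ₛ, σ²₀ₛ + σ²ₛ) and exact EM
  applies. Only the total variance is identifiable here, so fits report
  σ²₀ = 0 with the total in σ². This variant is the reference oracle: its
  forward-backward pass is checked against exhaustive path enumeration and an
  independent HMM implementation.
- **random_intercept** (`mode="random_intercept"`, default): one intercept per
  animal per state, fitted by mean-field variational EM with Gaussian
  posteriors q(φ₀_{m,s}). The η₀ M-step maximizes the ELBO profiled over
  q(φ₀): each animal's γ-weighted mean increment ȳ_{ms} is marginally
  N(η₀ₛ, σ²₀ₛ + σ²ₛ/n_{ms}), so η₀ₛ is their precision-weighted mean. This
  update reduces exactly to the collapsed EM update as σ²₀ → 0, which the
  tests exploit as a limiting-equivalence check (agreement in η₀ to 1e−3 with
  σ²₀ pinned at 1e−10).

Numerical choices: forward-backward runs in log space (batched over traces of
equal length); emission variances are floored at 1e−6 g² to prevent collapse;
restarts (default 10) are initialized by k-means on the pooled increments with
jitter, a sticky transition matrix (0.9 diagonal) and uniform π₀, and compared
by the final objective (log-likelihood or ELBO); convergence is a relative
objective change below 1e−8 or 500 iterations; exact posterior ties in
decoding resolve to the lowest state index. Decoding uses the per-time argmax
of the smoothing marginals, not Viterbi, so the reported path matches the
per-time posterior probabilities that the traits weight by.

Model order is selected on held-out traces (70/30 split stratified by diet) by
a deviance information criterion, DIC = 2·E[D(θ)] − D(θ̂) with
D = −2 log p(held-out | θ). The parameter posterior is approximated by
Gaussian uncertainty on the drifts, Var(η₀ₛ) = (σ²₀ₛ+σ²ₛ)/N_s with N_s the
effective γ-count of state s in the training fit (20 draws). States barely
supported by the data get large drift uncertainty, which inflates the expected
held-out deviance and penalizes overfitted K — the same role the effective-
parameter term plays in the plug-in DIC.

## Trait catalog

Occupancies and transition frequencies are posterior-weighted: occupancy is
the window mean of γ, and the (i,j) transition frequency is Σξ_{ij}/Σγ_i over
steps starting in the window (rows of never-occupied states are missing, never
zero). Bouts and maximum rates use the MAP path: the longest bout is the
maximal run length × 10 days (ties → earliest), and the maximum rate is the
largest absolute increment among steps decoded to the state, converted to
grams/week (×7/10) and optionally normalized by the weight at the step's right
endpoint (fraction of body weight per week). Each animal yields one row per
phase (pre/post intervention at day 180) with 20 primary traits — 3
occupancies, 9 transition frequencies, 3 longest bouts, 3 bout onsets, 2
maximum rates — plus normalized auxiliary variants; a `drop` argument selects
subsets. Homeostasis is additionally binned: calendar bins of 6 × 30-day
months from birth to 1260 days, or deciles of the fraction of life lived
(censored animals are skipped in decile mode); per-bin stability is the
empirical probability Σξ_ss/Σγ_s of not leaving the state. Missing values
propagate explicitly and are never imputed as zeros.

## Stress adaptation

A recovery region opens where the steady-state posterior drops below 0.05 and
closes at the first non-increase after the climb begins, or where it crosses
0.95 while increasing; regions spanning under 30 days or fewer than 3 grid
points are discarded. Monotonicity is strict (any non-increase breaks the
climb) since no slack is physically motivated. λ is fitted by least squares
against 1 − e^(−λx), x in days from the region's first point, with λ bounded
in [1e−6, 10]/day; because the CDF saturates, the RSS is nearly flat in λ over
most of that range, so the minimum is bracketed on a 120-point log-spaced grid
before bounded scalar refinement — noiseless data is then recovered to
optimizer tolerance for any λ in the bracket. Regions are attributed to the
most recent assay within a 30-day lookback (a plumbing default, configurable)
and to (6–18) / (18–30)-month age bins by their start day.

## Survival

Follow-up is cut into start-stop episodes at every grid measurement and age-
bin boundary (default six 180-day bins over 180–1260 days). The bin-j trait
covariate carries the animal's bin-j value only while age lies in bin j — a
gated, not cumulative, interpretation, since a running sum would grow without
bound and contradict body weight's role as an internal time-varying covariate.
Body weight enters bin-gated as (w − 30)/5 with the latest measurement carried
forward, optionally interacted with diet dummies (ad libitum reference); trait
values are z-scored across animals within each bin by default so effects are
comparable across bins (a raw-percentage preset reproduces the
per-percentage-point hazard reading). Fitting maximizes the L2-penalized
partial likelihood with Efron ties via lifelines; the baseline hazard is left
unestimated. The ridge strength is chosen on an 80/20 animal-level split by a
start-stop concordance index: each death is compared against all episodes of
other animals spanning its time, ties counting one half; event-free validation
splits are redrawn with an incremented seed. The translation
100·(e^β − 1) converts a log proportional hazard to a percent change in the
instantaneous risk of death (β = 0.065 per percentage point of decline
occupancy ↦ +6.7%, ratio 1.0671).

## Genetics

The founder scan is a fixed-effect analogue of a mixed-model scan: per marker,
a likelihood-ratio test of the additive 8-founder-dosage model over the
covariate-only model (one founder column dropped — dosage rows sum to 2 —
LOD = LRT/(2 ln 10)), with p-values from an adaptive sequential permutation of
the phenotype vector: permute until 10 exceedances or 10⁴ permutations
(defaults, configurable), p = (1+exceedances)/(1+permutations). Heritability,
genotype×diet random effects and haplotype reconstruction are out of scope;
founder dosages are an input.

The genome-wide threshold controls FDR within phenotype clusters: per variant,
Benjamini–Hochberg across the cluster's phenotypes at α = 0.05; per variant,
one sampled p-value (from all phenotypes if none significant, from the
significant subset otherwise); BH across variants on the sampled vector; the
cluster threshold is the largest sampled p rejected. The study-wide threshold
is the minimum across clusters that reject at least one variant (0 only if
none do — a raw minimum would let an empty cluster void the study). BH is used
as the FDR method throughout; a helper clusters a trait correlation matrix
into two groups by average linkage.

Fine-mapping groups biallelic variants by founder-allele pattern: the minor
allele is the one carried by the smaller founder subset (a 4-vs-4 split
resolves to the lexicographically smaller set in fixed founder order, logged;
non-segregating variants are excluded), groups are ranked by the largest LOD
among their variants, and exact LOD ties break deterministically by pattern.

## The synthetic generator

`SimConfig` encodes the study conditions the pipeline assumes: enrollment at
day 60 at 20 ± 2 g, a 10-day grid to at most 1260 days, five equal diet
groups, a growth-dominant chain before the day-180 intervention and
diet-specific chains after (restricted diets steadier, ad libitum more growth
and late-life decline), drifts (+0.5, 0.0, −0.8) g per 10-day step with step
noise 0.25 g and intercept spread 0.05 g — chosen so the states are well
separated (≈2 noise SDs) as in the fitted model's clearly resolved states.
Annual month-long phenotyping blocks (days 300/660/1020) force a decline bout
of geometric length (mean ≈ 2.5 steps) followed by forced steady steps, so
event-induced recovery is generated through the latent chain rather than by
editing weights. Deaths are piecewise-exponential over 180-day bins with
log-hazard baseline 2e−4/day plus 0.065 per percentage point of true decline
occupancy; censoring is administrative at 1260 days. Founder dosages draw two
founders per animal per marker from a Dirichlet-perturbed frequency vector;
planted effects add effect×dosage to a trait. Everything is deterministic
under the master seed.

The generator's `intercept_mode` chooses between one intercept per animal
(default; the random-intercept generative model) and per-step redraws (the
collapsed model). Exact-model calibration checks use per-step intercepts with
a homogeneous chain (single diet, no events), because against the default
phase-switching cohort a homogeneous fitted model shows a deliberate
mismatch bias of ≈0.02 g/step in the growth drift — useful to know, but not a
parameter-recovery test. What passing tests show is therefore internal
consistency and correct calibration under the generator's assumptions; real
traces add features the generator omits (estrous/seasonal periodicity,
cage-level competition, litter structure, measurement outliers), so
performance there is not implied.

## Problem sizes and checks

The calibration suite runs, at sizes chosen to keep a desk-scale run brief:
drift recovery and >0.9 decoding accuracy on 200 traces of 120 points;
held-out DIC order selection on 10 replicate 40-animal cohorts (correct K = 3
in ≥7); λ recovery exact on noiseless CDFs and within 5% mean relative error
at noise SD 0.02; time-varying Cox recovery of a gated 0.065 log-hazard on 500
animals within 2 SE plus nominal 95% Wald coverage over 200 replicates of 60
animals; cluster-FDR null calibration on 100 replicates of 2000 × 10 uniform
p-value matrices with exact singleton-BH equivalence; deterministic FAP
grouping on a constructed 10-variant locus including the 4-vs-4 tie; and a
planted-founder scan whose minimum permutation p lands on the planted marker,
with null p-values passing a KS uniformity check. `scripts/acceptance.py`
recomputes all of these from scratch under a user-supplied seed.

## Known limitations

- Lag orders above 1, free φ₁, non-Gaussian emissions and diet-specific
  transition matrices at fit time are out of scope (one shared model is
  trained across diets).
- The collapsed variant cannot separate σ²₀ from σ²; the random-intercept
  variant can, but its ELBO convergence on large cohorts is slower than the
  collapsed EM's.
- The cluster-FDR procedure inherits BH's assumptions; dependence across
  variants is addressed only through the sampling construction.
- The time-varying Cox model assumes proportional hazards within bins, no
  frailty, and no competing risks.
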