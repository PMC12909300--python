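# bwdyn — body-weight dynamics in aging mice

`bwdyn` analyses lifelong body-weight trajectories of diversity outbred (DO)
mice under dietary interventions (ad libitum, one- and two-day weekly fasts,
20% and 40% calorie restriction). It is written for researchers studying
aging, homeostasis and resilience who have longitudinal weight records,
survival times and (optionally) founder-haplotype genotypes, and who want to
turn raw weighings into interpretable physiological-state traits and test how
those traits relate to lifespan and genetics.

## The model

Body weight is modelled as a random walk with a state-dependent drift: a
constrained lag-1 autoregressive hidden Markov model

y_t = φ₀^{s_t} + y_{t−1} + ε_t^{s_t},  φ₀^{s} ~ N(η₀ₛ, σ²₀ₛ),  ε^{s} ~ N(0, σ²ₛ),

where the latent state s_t ∈ {growth, steady, decline} follows a first-order
Markov chain (initial distribution π₀, transition matrix A) and the unit
autoregressive coefficient is fixed. On first differences Δy_t this is a
Gaussian HMM with emission N(η₀ₛ, σ²₀ₛ + σ²ₛ); states are labeled by the sign
and magnitude of their drift η₀ₛ. Two inference variants are provided: exact
EM on the collapsed model, and mean-field variational EM with a per-animal
random intercept; the number of states is chosen by deviance information
criterion on held-out traces and restarts by the training ELBO.

Downstream stages derive per-mouse traits (state occupancies, transition
frequencies, longest bouts, maximum weekly rates of change, per-age-bin
homeostasis), estimate stress-adaptation rates λ by fitting the exponential
CDF 1 − e^(−λx) to the steady-state posterior after phenotyping events, fit a
time-varying Cox proportional-hazards model with bin-gated covariates
(lifelines `CoxTimeVaryingFitter`, ridge penalty chosen by held-out
concordance), and post-process founder-dosage association scans: adaptive
sequential permutation p-values, a phenotype-cluster FDR genome-wide
threshold, and founder-allele-pattern (FAP) grouping for fine-mapping. A
synthetic-cohort generator with full ground truth drives all tests.

## Worked example

`examples/02_fit_and_decode.py` simulates 60 mice, fits the 3-state model on a
70% training split, selects the model order on the held-out traces and decodes
one mouse:

```
state labels: ('growth', 'steady', 'decline')
drift eta0 (g / 10 d): [ 0.461 -0.011 -0.805]  truth: (0.5, 0.0, -0.8)
held-out DIC by K: {2: 2336.5, 3: 2012.8, 4: 2023.7} -> chosen K = 3
decoding accuracy for M0000: 0.94
```

The recovered drifts sit near the generating values (growth ≈ +0.5 g per
10-day step, steady ≈ 0, decline ≈ −0.8), the held-out DIC is minimized at the
generating three states, and posterior decoding recovers 94% of the true state
path. `examples/05_survival_hazard.py` continues the pipeline into survival:

```
log hazard per unit in bin 0: 0.0840 (truth 0.065), se 0.0166, Wald p 4.23e-07
=> each unit raises the hazard by 8.8% (ratio 1.0877); c-index 0.684
```

A fitted log proportional hazard β translates to a percent change in the
instantaneous risk of death via 100·(e^β − 1); at the reference effect of
0.065 per percentage point of decline-state occupancy this is a 6.7% hazard
increase (ratio 1.0671). The remaining examples cover gridding
(`01_grid_and_split.py`), the trait catalog (`03_trait_catalog.py`),
stress-recovery rates (`04_stress_recovery.py`) and genetics
(`06_genetics.py`).

## Layout

- `src/bwdyn/preprocess.py` — gridding, exclusion, phase splitting, CSV I/O
- `src/bwdyn/arhmm.py` — the state-switching drift model: EM/VB fitting,
  forward-backward, decoding, DIC order selection
- `src/bwdyn/traits.py` — per-mouse trait catalog and binned homeostasis
- `src/bwdyn/stress.py` — recovery-region detection and λ estimation
- `src/bwdyn/survival.py` — episode construction, time-varying Cox fitting,
  penalty selection, hazard translation
- `src/bwdyn/genetics.py` — founder scans, adaptive permutation p-values,
  cluster-FDR threshold, FAP fine-mapping
- `src/bwdyn/simulate.py` — synthetic cohorts with ground truth
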