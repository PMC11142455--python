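# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of the package. It states nothing that the
test suite or `scripts/acceptance.py` does not itself compute.

## Parcellation and edge sets

The canonical layout has 430 ROIs — 400 cortical allocated over eight
networks (ECN, DMN, DAN, LN, SN, SMN, TP, VIS) plus 30 subcortical (SUB) —
ordered network-contiguously so FC matrices have intranetwork diagonal
blocks. `reduced_scheme(R)` shrinks the layout proportionally for
simulation studies while keeping every network at ≥3 ROIs, the minimum for
a defined intranetwork similarity. Edge sets: *global* = all R(R−1)/2
lower-triangle pairs; *intra:n* = both endpoints in n; *inter:n* = exactly
one endpoint in n. Every cross-network edge belongs to both endpoint
networks' inter sets, so Σ|intra| + ½Σ|inter| = |global| — asserted
exactly in the tests.

## Signal conditioning

* **Trimming.** The first 5 volumes of every run are discarded; event
  onsets are in seconds from the first retained volume; volume *t* spans
  [t·TR, (t+1)·TR).
* **HRF.** Double gamma sampled at the TR: response and undershoot gammas
  are parameterized by their modes (6 s and 16 s, dispersion 1 s each,
  undershoot ratio 1/6), so the kernel peak lands exactly at the stated
  peak time; peak-normalized to 1.
* **Task design.** One boxcar per event class — encoding (a single boxcar
  spanning all dots, 0.5 s per dot), maintenance, probe, response, pooled
  inter-trial fixation/blanks, and correct-/wrong-trial boxcars spanning
  the whole trial — convolved at 10× oversampling and sampled at volume
  onsets; each main regressor is paired with its first-difference temporal
  derivative. All-zero columns (e.g. the wrong-trial column of an
  error-free run) are dropped and logged. The correct/wrong boxcars span
  the whole trial (initial blank through probe offset) rather than only
  its active phases; spanning only the active phases would make
  correct + wrong exactly collinear with encoding + maintenance + probe.
* **Regression.** Task activation and nuisance series (6 motion
  parameters, global signal) enter one joint OLS model per task run; an
  intercept is always included, constant columns are dropped, and residual
  orthogonality to every retained regressor is verified to 1e-8. A
  sequential mode (`joint=False`) exists for sensitivity checks.
* **Rest band-pass + detrend.** Implemented as a single orthogonal
  projection onto the intersection of the in-band Fourier span
  (0.009–0.1 Hz) and the complement of the quadratic-trend space. A
  projection is zero-phase, has exact band edges, and is idempotent —
  re-running the rest pipeline on its own output changes nothing — which a
  fractional-gain cosine taper cannot be; `taper_hz > 0` switches to a
  tapered mask and is documented as trading idempotence for less ringing.
* **Block extraction.** A volume belongs to a load's block when its
  midpoint lies in [first trial onset, last trial probe offset]; this keeps
  within-block inter-trial blanks (they are trial structure) and discards
  the 4 s inter-block baselines. No hemodynamic-lag shift is applied: the
  activation regression already absorbs the evoked lag. Segments are
  mean-centered per run before cross-run concatenation (residuals are
  near-zero-mean anyway; centering removes run-level offsets).
* **FD.** Power's convention, FD_t = Σ|Δtrans| + 50 mm·Σ|Δrot|; the single
  FD definition stands in for both "relative motion" and "framewise
  displacement" summaries and is labeled as such. Maximum absolute
  displacement is the largest Euclidean translation from the first-volume
  reference.

## Connectivity and similarity

Pearson r per ROI pair, clipped to |r| ≤ 1 − 1e−7 before `atanh` so
degenerate fixtures stay finite; the diagonal is stored as 0 but excluded
from every edge set by construction, never by value inspection. Similarity
is the Pearson correlation of two matrices' edge-value vectors over an
edge set, clipped and z-transformed the same way; edge sets with fewer
than 3 edges yield an explicit missing record with a reason code. Per
subject this gives 3 pairs × (1 + 9 + 9) = 57 records per comparison type,
plus 3 global within-load records when that validation is enabled.

## Inference

* **`fixed_ols`** (default): fixed-effects OLS of
  `Y ~ age_group*load + sex + task_motion + rest_motion + scanner`, type-II
  F per term with denominator df = N − p. For a balanced 143-subject
  three-load table whose rest-motion column is identically zero (a
  task-only outcome) the informative design has 9 coefficients and the
  denominator df is 420. Covariates that are identically zero or
  single-level are dropped and logged; each subject's rows are treated as
  exchangeable, so between-subject terms are anticonservative when a
  subject random effect is present — which is why the recovery studies use
  the second mode.
* **`lmm_satterthwaite`**: random-intercept model (variance components via
  statsmodels REML) with marginal (sum-coded) term tests and Satterthwaite
  denominator df computed from the gradient of each contrast's variance
  with respect to (σ², τ²) and the inverse REML information, pooling
  multi-df terms per eigenvector as lmerTest does. It reproduces lmerTest
  `anova(type=3)` to 4 decimals on a reference dataset.
* **Tukey HSD**: all 15 pairwise contrasts of the 2×3 covariate-adjusted
  cell means on the studentized-range distribution (Tukey–Kramer).
* **Partial Spearman**: average-rank transform of x, y, and covariates;
  OLS residualization of the ranked x and y on ranked covariates +
  intercept; ρ = Pearson of residuals; p from t = ρ√((n−2−k)/(1−ρ²)). With
  zero covariates this reduces exactly to plain Spearman, and it is
  invariant to strictly monotone transforms of any input.
* **Bootstrap SE**: subjects resampled with replacement (the exchangeable
  unit), ρ recomputed per iteration (vectorized), SE = SD over
  non-degenerate iterations; >10% degenerate resamples raises a warning.
  Default 10,000 iterations; the calibration studies use 1,000.
* **Multiplicity**: global associations at uncorrected α = 0.05;
  network-level associations gated at 0.05/9 ≈ 0.0056. Association pairing
  follows the task logic: similarity pair dotℓ–rest or higher–lower maps
  to behavior at load ℓ (the higher load); rest-involving comparisons add
  mean rest FD as a covariate, the older group adds scanner.

## Synthetic cohort: what it emulates

Each group g has a block-structured resting covariance: unit diagonal,
w_g within network, b_g between (young w=0.35/b=0.05, old w=0.25/b=0.12 —
older adults are less segregated). The task covariance at load ℓ is the
convex mixture Σ = (1−λ)Σ_rest + λΣ_alt, where Σ_alt conjugates Σ_rest by
a fixed seeded ROI permutation: same spectrum (hence guaranteed positive
definite), genuinely different intra/inter topology — exactly the change
the similarity statistic must detect. λ defaults: young (0.10, 0.15,
0.20), old (0.25, 0.32, 0.40) across loads 1/3/5 — non-decreasing in load,
old ≥ young — with a per-subject offset δ ~ N(0, τ), τ = 0.12. τ is sized
so the planted similarity–accuracy coupling has partial-correlation
magnitude ≈ 0.3, the order reported for significant brain–behavior
associations in comparable cohorts; with τ much smaller the planted
association would be statistically invisible and the generator would fail
its purpose of providing recoverable ground truth.

Runs: rest = 5 lead-in + 235 volumes at TR 2 s; two task runs of ~170–180
volumes, each one 10-trial block per load in seeded-random order, trial
timing blank 1 s / fixation 0.5 s / encoding 0.5 s·dots / maintenance 3 s /
probe 2 s / jittered inter-trial blank 2.5–4.5 s, blocks separated by 4 s
baselines. Volumes are drawn i.i.d. in time from the segment's covariance
(baseline and lead-in volumes from Σ_rest). Added components: HRF-convolved
evoked activation (gain 1.0, random ROI loadings), quadratic drift (SD
0.5), and a rank-one FD-locked motion artifact (gain 0.3) whose spatial
loading is fixed per subject — motion corrupts the same regions in every
run, which is also what keeps the artifact from artificially destroying
rest–task similarity. Motion is a random-walk in the six rigid-body
parameters with a per-subject level drawn from N(0.05, 0.02) mm (young) or
N(0.07, 0.03) mm (old), matching the within-group spread real cohorts
show; without that spread, mean FD would be a deterministic group proxy
and the motion covariates would absorb the group effect.

Behavior: per trial, P(correct) = logistic(3.0 − 4.0·λ − load penalty
(0/0.7/1.4) − 0.5·[old] + ε), ε ~ N(0, 0.5) per subject; 20 trials per
load across the two runs; RTs lognormal, increasing in load and λ. Higher
λ (more reconfiguration) thus lowers both similarity and accuracy,
planting the positive similarity–accuracy association.

**What the generator does not emulate:** hemodynamic autocorrelation
(volumes are temporally white within a segment), physiological noise,
spatially structured activation topographies, scanner-upgrade effects
beyond the group-mean label, within-run λ dynamics, and realistic
distributions of wrong-trial RTs. Passing tests therefore demonstrate that
the pipeline recovers the planted covariance-level and behavioral
structure under realistic noise magnitudes — not that it would behave
identically on real BOLD data.

## Recovery and calibration studies (problem sizes)

* Group effect: 50 replicate cohorts of n = 40/40 at 60 ROIs; the
  age-group main effect on global rest–task similarity is tested in the
  random-intercept mode (each subject contributes three correlated rows).
  The null arm makes the groups exchangeable for the brain outcome by
  equalizing λ, w, b, and the motion level to the young values — equalizing
  λ alone leaves real group differences through segregation and motion, so
  it is not a null.
* Brain–behavior coupling: 100 replicates of n = 100 single-group cohorts
  at 30 ROIs; sign recovery of the dot3 partial Spearman, and a decoupled
  (a1 = 0) null arm for the significant fraction.
* Partial-Spearman type-I: 2,000 null simulations at n = 60 with 3
  covariates; bootstrap-SE calibration: 200 replicate bivariate-normal
  datasets (ρ = 0.3, n = 100) at 1,000 iterations.
* The acceptance script repeats these at reduced replicate counts
  (12/20/60) and reports the rates it measures.

## Known limitations

* `fixed_ols` is exactly the fixed-effects construction whose denominator
  df matches the headline F-statistics it reproduces; it is not the
  recommended inference for between-subject effects on repeated measures —
  use `lmm_satterthwaite` for those.
* Tukey contrasts use the Tukey–Kramer approximation on model-adjusted
  cell means; with strong covariate imbalance the family-wise control is
  approximate.
* The Satterthwaite information matrix is obtained by finite differences
  of the REML criterion; for boundary fits (τ̂² ≈ 0) the df fall back to
  the OLS residual df.
* Within-load FC matrices use single-run blocks (~50–60 volumes), so their
  similarity values are noisier than the cross-run load matrices; they are
  a stability control, not a primary outcome.
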