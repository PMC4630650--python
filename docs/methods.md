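# Methods

`dexmet` analyses a repeated-measures plasma metabolomics design: 20
healthy male subjects sampled at up to three fixed clock times on four
consecutive days, with a single oral glucocorticoid (dexamethasone)
dose after midday of day 3. Each subject contributes 7 untreated and 4
treated samples (+6, +18, +24, +30 h post dose), 220 samples in all,
over a panel of ~214 metabolites. This note records the models, the
generator that emulates the study, the numerical conventions, and the
limits of what the synthetic validation shows.

## Synthetic cohort generator

The generator is the ground-truth engine for every validation study.
On the log10 scale, subject *i*, metabolite *j*, slot *t*:

    y_ijt = mu_j + b_ij + c_j(daytime(t)) + d_j(t) + eps_ijt

* `mu_j` — baseline location, drawn once per metabolite from
  N(1.5, 0.7) (abundances spanning ~3 orders of magnitude, as typical
  for broad-profiling panels);
* `b_ij ~ N(0, subject_sd_j)` — a stable subject offset drawn once per
  (subject, metabolite): the "metabolic phenotype" when large;
* `c_j` — a monotone within-day trend given by two signed increments
  (morning→midday, midday→evening), applied identically on every day.
  Identical daily application means two untreated slots sharing a
  daytime have equal expectation, which is what licenses pooling them
  as a single reference group;
* `d_j(t)` — the log10 treatment effect at the slot's post-dose offset,
  exactly zero at untreated slots;
* `eps ~ N(0, noise_sd_j)` — residual (technical + short-term
  biological) noise.

Values are exponentiated (`10**y`), so all effects are multiplicative
on the measurement scale and the analysis ratios read out
`10**effect` directly. Pool reference samples are the per-metabolite
arithmetic mean of all study samples with log-scale noise `noise_sd/4`
(10 replicates by default; real designs interleave pools at a
vendor-specific cadence that is not modelled). Age and BMI are drawn
from N(25.5, 2.9) and N(23.3, 2.7), truncated to [18, 40] and
[17, 35]; by default they carry no metabolite effect, so the covariate
screen should find nothing beyond chance.

Default study conditions (fixed once, used by every test and by the
acceptance script): 214 metabolites; 78 circadian-increasing and 25
circadian-decreasing metabolites with per-step increments of
0.05–0.25 dex, including two steroid-like decreasers whose evening
levels are 16% and 34% of morning; 150 metabolites dose-affected on at
least one post-dose slot (9 on all four, the rest on 1–3 random
slots) with |effects| of 0.1–0.5 dex and 60% increases; `noise_sd` =
0.1 everywhere; `subject_sd` = 0.15 for ordinary metabolites and 0.4
for the 27 phenotype metabolites. The phenotype ratio
`subject_sd/noise_sd = 4` follows from the bivariate-normal closed
form tau = (2/pi)·asin(rho) with rho = r²/(r²+1): r = 4 gives an
expected pairwise tau of ~0.78, safely above the 0.6 selection rule,
whereas r near 2 sits at the selection boundary.

What the generator does **not** emulate: instrument drift and batch
order, missing values, heavy-tailed or skewed residuals, correlated
metabolite blocks (every metabolite is generated independently), and
subject-specific treatment response. Passing tests therefore show the
pipeline's statistics behave correctly under the design's assumed
structure — not that real acquisition artifacts are handled.

## Preprocessing

Study samples are divided by the per-metabolite **median of the pool
references** (dropping the pools), log10-transformed, and — for the
multivariate stages — **autoscaled** (centered, unit variance) per
metabolite. SD uses the n−1 denominator; whether the original
chemometrics software used n or n−1 is immaterial to every rank-level
result downstream. Scaling parameters are estimated over all 220
study samples jointly and stored so held-out samples can be projected
with training-fold parameters during cross-validation. Zero pool
medians, non-positive abundances and zero-variance metabolites are
hard errors naming the offending metabolite, not silent fixes.

## Time-matched mixed-effects ANOVA

Because ~half of the panel is circadian, each treated slot is compared
only against untreated slots of the same daytime, pooled: +18 h
morning vs day-2/3 mornings, +24 h midday vs day-1/2/3 middays, +6 h
and +30 h evenings vs day-1/2 evenings. Pooling is justified by a
pre-check: a paired per-subject comparison between two same-daytime
untreated slots, whose count of p < 0.05 metabolites should stay at
the chance level 0.05 × M (10.7 of 214).

Per metabolite, the model on log10 values is

    y ~ 1 + treatment + age + BMI + (1 | subject)

fitted by REML (statsmodels `MixedLM`). The treatment read-out is the
Wald t with inner-level residual df = n_obs − n_subjects − 1 (the
convention of the R mixed-model machinery this mirrors for a
within-subject factor); age/BMI, which vary only between subjects, are
tested at df = n_subjects − 3. Fits that fail or return a degenerate
standard error fall back to OLS with subject-clustered errors and are
flagged `ols_fallback` in the output, never dropped. Under null
simulation at 1000 metabolites the p-value distribution is uniform
(KS distance ~0.013), so the df convention is calibrated at this
design size.

Ratios are arithmetic means on the **linear** scale (group / matched
reference) — deliberately not back-transformed log means, so a ratio
of 0.16 means "16% of the reference level". BH step-up q-values are
computed across metabolites within each comparison; thresholds are
q < 0.05 for treatment and circadian calls and q < 0.1 for the
covariate screen. The BH implementation is the explicit step-up
formula and is cross-checked against statsmodels in the tests.

One model is fitted per comparison (not one joint 11-slot model):
the time-matched framing makes each contrast self-contained, at the
price of re-estimating variance components per comparison.

## STATIS

STATIS summarizes the K = 20 subject tables (11 time points × M
metabolites, rows of the globally autoscaled matrix) without using
class labels:

1. cross-products `W_k = X_k X_kᵀ / M` (the 1/M keeps the scale
   independent of panel size; it cancels in every normalized output);
2. interstructure `C_ij = ⟨W_i, W_j⟩_F / (‖W_i‖_F ‖W_j‖_F)` (RV
   coefficients);
3. weights = the leading eigenvector of C, sign-fixed non-negative
   (Perron–Frobenius guarantees sign-constancy), normalized to unit
   **Euclidean** norm. Equal similarity gives 1/√K ≈ 0.224 at K = 20,
   so weights read as "above/below average conformity". Sum-to-one
   normalization would put equal weights at 0.05 and is not used;
4. compromise `W = Σ α_k W_k`, eigendecomposed; time-point scores are
   `U diag(√λ)`; tiny negative eigenvalues (< 1e-8 of λ_max) are
   clipped, larger ones are an error;
5. subject trajectories `W_k u_a / √λ_a` — their α-weighted mean is
   exactly the compromise scores (with unit-norm weights, K identical
   tables give trajectories equal to the compromise scaled by 1/√K) —
   and metabolite loadings `X̄ᵀ u_a / √λ_a` from the α-weighted
   average table.

Cross-products are taken on globally autoscaled data without
per-subject recentering; the first compromise axis therefore absorbs
the shared profile level and treatment contrasts appear on the
following axes. A covariance (per-subject centered) variant would
move that variance out of axis 1; both orderings agree at rank level
on synthetic data, and the chosen convention is recorded in the
provenance log. Eigenvector signs are fixed by making each axis's
largest-magnitude entry positive. With K = 1 the whole construction
reduces to PCA of that table's cross-product, which the tests verify
against an SVD oracle.

## PLS-DA and leave-one-subject-out Q²

Two-class PLS1 (NIPALS) of the centered treated/untreated indicator
(140 untreated vs 80 treated samples, no reweighting) on autoscaled X.
With a single response the NIPALS weight step is exact, so each
component is one pass; X and y are deflated per component.

Cross-validation folds are subjects: all 11 samples of one subject are
held out together, otherwise within-subject correlation leaks across
folds and Q² is optimistic. Per component,
`Q²_a = 1 − PRESS_a / RSS_{a−1}` with PRESS_a the held-out prediction
error of the a-component model and RSS_{a−1} the full-data residual SS
of y after a−1 components (RSS_0 = centered total SS); cumulatively
`Q²cum_A = 1 − Π (PRESS_a / RSS_{a−1})`, the convention of the
commercial chemometrics software this mirrors. The plain
`1 − PRESS_A/SS_0` figure is written alongside in the output since the
proprietary bookkeeping is not published bit-for-bit. Folds whose
training set holds a single class are skipped and reported; class
prediction thresholds the predicted indicator at 0.5.

## Kendall rank-stability phenotyping

For every unordered pair of time points, Kendall tau-b over subjects
(scipy; tie correction is moot for continuous data); per metabolite
the mean and SD (n−1) over the 21 untreated pairs, selecting
metabolites with `mean − SD ≥ 0.6`. All untreated pairs are treated
identically whether within or across days. The same score over all 55
pairs of the full 11-slot design quantifies robustness to treatment:
a dose effect common to all subjects is a monotone (location) shift on
the log scale and provably leaves every tau unchanged; only
subject-specific responses can break selection. Pairs with undefined
tau (constant vectors — impossible for continuous data, possible for
degenerate inputs) are dropped from that metabolite's pair set,
decrementing `n_pairs` and counted in `n_failed_pairs`; a metabolite
with no valid pair is an error. Because tau is invariant under
strictly monotone transforms, the scores are identical on raw,
pool-normalized or log values.

## Pipeline, determinism, problem sizes

All randomness flows from one integer seed through numpy Generators
with fixed stream offsets per stage, so identical config + seed gives
byte-identical output CSVs (the run summary stores a SHA-256 per
file). The validation studies (`dexmet.validation`) use the study's
own dimensions — 20 subjects × 11 slots throughout — with metabolite
counts per study: 1000 for null p-value calibration, 214 per replicate
for the 200-cohort pre-check study, 100 label permutations for the Q²
null, and 1000 + 1000 (phenotype + iid-noise) metabolites for the
stability operating characteristics; these sizes put Monte-Carlo error
well inside each check's margin while keeping a full run around a
minute.

## Known limitations

* The mixed-model df convention is an approximation; exact
  denominator-df methods (Satterthwaite/Kenward–Roger) are not
  implemented. Calibration is demonstrated by simulation at this
  design's size, not claimed generally.
* Independent metabolites in the generator mean multivariate stages
  face no correlated-block structure; real panels are far from
  independent, and Q²/STATIS separations on real data will be lower
  than on the synthetic default cohort.
* Batch-wise pool normalization, drift correction and imputation are
  out of scope; the normalization assumes one homogeneous run.
* PCA of the raw autoscaled matrix (dominated by inter-subject
  variance) is not re-implemented; STATIS and PLS-DA are the two
  multivariate routes provided.
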