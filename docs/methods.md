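# Methods

## The model

The package treats longitudinal microbiome development as a supervised
regression problem. Given a reference set of samples (a control arm, or
samples declared healthy/typical), a regressor learns to predict a sample's
**time** (age, study week, ...) from its feature abundances. The prediction
for any sample is its **Microbiome Maturation Index (MMI)**, in the same
unit as time — the "microbiota-for-age" convention. A reference community at
time *t* has MMI ≈ *t*; a sample whose MMI runs ahead of or behind its true
time has an accelerated or delayed community.

The **trajectory** is the smooth curve of expected MMI versus time over the
reference samples, with a band around it. Samples outside the prediction
band are candidate anomalies; per-feature attributions explain which taxa
push a sample off the curve; an intervention simulation asks which feature
resets would bring it back.

### Compositional preprocessing

Sequencing abundances carry only relative information, so the pipeline works
on the simplex. Counts are closed to relative abundances, and the modelling
features are additive log-ratios: `ln((x_j + c) / (x_D + c))` with a single
denominator feature *D*, which removes the arbitrary per-sample scale. The
pseudocount *c* defaults to half the smallest non-zero value in the table
(zero when the table is strictly positive), a per-table constant.

Three denominator-selection strategies are provided:

* **crossings** — per candidate, the number of adjacent-time-bin sign flips
  of (binned-median trajectory of any other feature − candidate's), summed
  over features. A feature that few others cross is stable relative to the
  community. Binned medians use 10 equal-width bins by default; empty bins
  are compacted before counting flips. Note that when many features share
  the same baseline level, their noisy median trajectories interleave and
  the count favours strongly monotone candidates; the performance strategy
  is the more reliable default on such data.
* **ranking_low / ranking_high** — the extremes of a per-feature Spearman
  correlation between relative abundance and time ("differential ranking";
  the notion is operationalized here as rank correlation with time because
  no canonical formula exists for it).
* **performance** — for every candidate, log-ratio-transform the reference
  samples, score a named regressor by grouped cross-validated R² (folds
  split by subject), and keep the maximiser. Ties break lexicographically
  and are flagged. For any linear regressor the ALR bases are linear
  bijections of one another, so scores differ only through regularisation
  and CV noise; for non-linear models the choice matters more.

Feature filtering removes low-variance features (below a variance quantile)
and then, among pairs with |Pearson r| above a threshold, greedily drops the
lower-variance member scanning pairs by descending |r| — deterministic for
identical inputs. Filtered relative tables are re-closed (subcomposition
closure) so rows remain on the simplex.

The reference set itself can come from declared flags, a group label, or
isolation-based novelty detection: an Isolation Forest is fitted on the seed
set, the most anomalous `novelty_frac` tail of the seed set is expelled, and
non-seed samples whose scores fall inside the retained seed score range are
admitted. Using the *retained* range (not the raw min–max) keeps the
admission rule consistent with the expulsion rule.

## Trajectory fitting

`fit_mmi_model` trains the regressor on the reference samples and derives
the curve from **grouped out-of-fold predictions** of those same samples
(GroupKFold by subject). In-sample predictions of flexible regressors are
nearly residual-free, which would collapse the band to zero width;
out-of-fold residuals measure the generalization error that a new sample
actually exhibits, which is what a prediction interval must calibrate
against.

The curve is a cubic smoothing spline with the smoothing parameter chosen by
generalized cross-validation. Near-coincident abscissae (within 1/500 of the
observed range — jittered longitudinal designs produce them en masse) are
merged into weighted means first; merging at the weighted mean is exact for
straight-line data and prevents the GCV system from becoming numerically
singular. Fewer than five distinct time points degrade the fit to a
least-squares line.

The band is `curve(t) ± z · s(t)` where `s(t)` interpolates per-time-bin
residual scales with a shape-preserving (PCHIP) monotone interpolant. Each
bin's scale is a **10% upper-trimmed mean of absolute residuals** divided by
0.65735 (its expectation under a centred normal): consistent for the
residual SD under Gaussian noise, near-mean efficiency, and insensitive to a
modest fraction of gross outliers — the very samples the band is meant to
expose. Confidence bands divide the scale by √n of the local bin; prediction
bands do not. Default level 0.95; anomaly detection always uses the
prediction band.

The regressor registry ships twelve named models (linear, ridge, lasso,
elastic net, k-NN, SVR, decision tree, bagged trees, random forest, gradient
boosting, histogram gradient boosting, dummy). `compare_models` ranks them
by grouped-CV R² on identical folds (fold assignment is hashed so identity
can be asserted). The bagged-tree ensemble is the library default — robust
and fast to attribute — but on log-ratio features with roughly linear
time-signals the linear models are usually at the top of the leaderboard,
and the worked examples use the leaderboard winner.

## Attribution

Shapley values are computed by the permutation-sampling estimator with a
fixed background sample (default 25 training rows): for each sampled feature
ordering, features are revealed one at a time and credited with the change
in mean model output. Each ordering's credits telescope to
`f(x) − E_background[f]`, so local accuracy holds to machine precision
regardless of how many orderings are sampled (default 8, in antithetic
pairs); sampling noise only affects how credit is split among correlated
features. Attribution is interventional: hybrid rows off the data manifold
are probed, so strongly interacting non-additive models can leak credit
across complementary features — window-importance examples are therefore
cleanest with (near-)additive regressors.

Per-window importances are mean absolute attributions over the samples in
each half-open time window (the last window also admits its right edge).

## Group comparison

`compare_trajectories` tests whether two groups follow the same MMI-vs-time
curve.

* **linear** — OLS of `mmi ~ time + group + time:group`; the statistic is
  the F-test of the joint null (no offset, no slope difference).
* **spline_permutation** — the integrated squared difference between
  per-group smoothing splines on a 201-point grid over the shared time
  range. The null distribution permutes the group assignment of whole
  subjects (all samples of a subject move together), the exchangeability a
  longitudinal design actually supports; `p = (1 + #{null ≥ obs}) / (1 + B)`.
  One smoothing parameter is selected once from the observed per-group
  curves — interleaved 3-fold CV per group over a log-spaced grid, then the
  **1-SE rule** (largest parameter within one standard error of the CV
  minimum) — and reused for every permuted fit, so the statistic is
  identical under observed and null assignments. The 1-SE bias toward
  smoothness matters: an undersmoothed statistic is noise-dominated and
  loses its power.

## Anomaly detection and explanation

All detectors operate on trajectory residuals, not raw features.

* **interval** — outside the prediction band; score = |residual| / s(t).
* **lowpass** — residuals are time-ordered, the low-pass component is a
  centered rolling mean whose window shrinks *symmetrically* at the edges
  (so a linear drift detrends to exactly zero everywhere, edges included);
  the score is the detrended residual over a global robust scale
  (MAD × 1.4826 of the detrended series, SD fallback when the MAD
  degenerates). The scale is global rather than rolling because a window
  that contains the outlier cannot robustly estimate local scale. Subjects
  with at least `window` samples are processed per subject, the remainder
  globally. Defaults: window 5, threshold 3.
* **isolation** — an Isolation Forest over (residual, rolling mean, rolling
  SD) of the time-ordered series; exactly the top ⌈contamination·n⌉ samples
  by score are flagged (ties broken by series position). Default
  contamination 0.05.

`explain_outliers` fits a gradient-boosted classifier separating the outlier
set from a seeded subsample of the rest (floored at the outlier count,
capped at 3× it), reports stratified-CV AUROC, and ranks features by mean
absolute Shapley attribution over the outliers. Metadata columns join only
when listed explicitly, one-hot encoded; subject and time never do (leakage).

## Intervention simulation

Candidate features of an outlier (explicit, or top-k by per-sample
attribution with greedy k escalation up to `k_max` = 10) are reset to the
**time-local reference median** — the median among reference samples within
`time ± bandwidth`, bandwidth defaulting to a tenth of the time range and
doubling up to three times when data are sparse. The MMI is recomputed and
pre/post residuals and band membership reported. Unchanged features are
bit-identical; post-intervention rows are not re-normalized (log-ratio
features are scale-free; a closure switch is available in config). This is a
model-space what-if only — no causal claim.

The canonical anomaly/intervention workflow fits the reference model on the
reference data *before* anomalies are considered; monitored (possibly
anomalous) samples are then scored against the fixed trajectory. Fitting on
already-contaminated data attenuates exactly the feature coefficients an
anomaly loads on; the trimmed residual scale protects the band either way.

## Synthetic studies

The generator emulates a repeated-measures design (inspired by gnotobiotic
mouse cohorts sampled across a diet switch): `n_subjects` subjects sampled
at `samples_per_subject` equally spaced times with ±5% spacing jitter, over
a normalized study duration `time_range = (0, 1)`. Informative features'
log-abundances drift linearly at `±effect_size` nats per unit time (signs
alternate so both blooming and declining taxa exist); all features carry
i.i.d. Gaussian log-noise `noise_sd`; vectors are exponentiated and closed.
Defaults — 40 subjects × 8 samples, 30 features of which 5 informative,
effect size 1, noise 0.3 — give a per-sample maturation signal whose
Bayes-optimal recovery sits near Spearman 0.92, so the recovery checks probe
estimator efficiency, not head-room. A second arm (`group_shift`) evaluates
informative means at `t + shift`: a maturation offset, the natural alternative
hypothesis for trajectory comparison. Anomalies multiply one informative
feature of a random sample subset by `exp(magnitude · noise_sd)` before
re-closure.

What the generator does **not** emulate: zero inflation and sparsity,
overdispersed counts, subject-level random effects, phylogenetic or
interaction structure, unequal baseline abundances (all features share a
zero log-baseline, which is also why the crossings heuristic behaves
atypically on synthetic data). Passing checks therefore demonstrate the
machinery is correct and calibrated under a clean compositional log-normal
model, not that real studies will reach the same numbers.

## Numerical choices and degenerate inputs

* Relative rows must sum to 1 within 1e-9 (inference threshold 1e-6 when
  loading); value-kind inference: all-integers → counts, else row sums ≈ 1 →
  relative, else counts.
* Interval membership uses `|residual| ≤ half-width + 1e-12`; interval
  scores floor the scale at 1e-12.
* Orphan samples in table/metadata joins drop with a logged count; zero
  overlap errors.
* Constant features get differential ranking 0; grazing contact (a binned
  difference of exactly zero) does not count as a crossing.
* All stochastic steps take explicit seeds; the CLI writes the resolved
  config and seed next to every run, and CSV outputs contain no timestamps,
  so rerunning a config is byte-identical.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the default 320-sample study
for recovery/coverage/anomaly checks, 100-sample two-arm studies for the
comparison statistics (200 null replicates at 99 permutations for error
calibration, 40 replicates at 199 permutations for power), 50 replicates
for explanation fidelity, and 200–500 replicates for the null
false-discovery control — sizes at which every quantity above stabilizes to
well inside its stated tolerance band.

## Known limitations

* MMI is a purely predictive construct; deviations flag statistical
  atypicality, not mechanism.
* The interval bands assume roughly symmetric unimodal residuals within
  time bins.
* Interventional Shapley probes off-manifold feature combinations (see
  above); attribution rankings for heavily interacting models should be
  read qualitatively.
* The spline comparison assumes both groups share a common observed time
  range; disjoint ranges are an error, partially overlapping ranges are
  compared on the overlap only.
* BIOM support covers the v2.1 HDF5 table layout (ids + matrix); rich
  observation/sample metadata inside BIOM files is ignored.
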