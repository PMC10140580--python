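# Methods

## Outcome definition and its hourly adaptation

A ventilator-associated complication (VAC) is defined from the two
ventilator support settings: 48 h of stable or decreasing daily-minimum
FiO₂ and PEEP (the stability window) followed by 48 h in which the daily
minimum FiO₂ is at least 20 percentage points, or the daily minimum PEEP
at least 3 cm H₂O, above the stability baseline (the worsening window).
The transition hour is the onset. Surveillance practice uses calendar
days; an hourly label is incompatible with midnight-aligned days, so
`vacpred` evaluates every candidate hour `t` with rolling 24 h blocks
aligned to `t`:

* stability: blocks `[t-48, t-24)` and `[t-24, t)`; the per-block minima of
  **both** settings must be non-increasing (ties allowed — "stable or
  decreasing");
* baseline per setting: the minimum of its stability-block minima. The
  definition does not pin the reference value; the minimum is the most
  conservative choice (hardest to exceed by noise);
* worsening: blocks `[t, t+24)` and `[t+24, t+48)`; **every** block minimum
  of FiO₂ (or of PEEP) must be `>= baseline + threshold`. The threshold
  comparison is inclusive;
* a block with no observation makes `t` ineligible (a daily minimum is
  undefined there);
* one event per stay: the earliest qualifying hour. Patients ventilated
  less than 96 h are never at risk and are excluded.

FiO₂ is handled on the percent scale (21–100), so the 0.20 fraction
threshold is 20 percentage points. The PEEP threshold is 3 cm H₂O, the
unit PEEP is measured in.

The detector is verified against a brute-force implementation that
enumerates every candidate hour and re-tests the definition literally;
the two must agree exactly (this is part of the acceptance checks).

## Prediction task

One sample per patient. Positives: decision time = the VAC onset.
Features come from the 35 h window `[decision - 36 h, decision - 1 h]`, so
every prediction is made 1 h ahead with no data from the decision hour
itself. Negatives are non-VAC patients given a decision hour drawn
(seeded) from the empirical distribution of positive onset hours,
constrained to hours their own ventilation interval supports; the majority
class is trimmed at random to a 1:1 balance. Onsets always lie at least
48 h into ventilation, so the 36 h history always exists for positives.

## Preprocessing

* **Valid ranges** (inclusive bounds): HR 30–200 bpm, RR 6–50 /min,
  DBP 20–120 mmHg, SBP 50–220 mmHg, SpO₂ 80–100 %, PEEP 0–20 cm H₂O,
  FiO₂ 21–100 %. Outside values are removed (become missing, timestamps
  kept). Bounds are inclusive because a *valid range* naturally contains
  its endpoints; the boundary behaviour is pinned by test.
* **High-frequency channels** are reduced to 5-min bin medians (one point
  at each bin's right edge; empty bin = missing). On that grid, interior
  gaps of **more than 12** consecutive bins (i.e. longer than 1 h) are
  linearly interpolated between the bounding observations; gaps of at most
  12 bins are carried forward ("longer than 1 h" is read strictly, so the
  exact-1 h gap is carry-forward). Leading gaps are back-filled; trailing
  gaps, which have no right endpoint, are carried forward regardless of
  length. Interpolation is confined to a single historical feature window,
  all of which precedes the decision time, so causality is preserved at
  the level that matters — no information from after the prediction time
  is used.
* **Low-frequency channels** are resampled to an hourly grid anchored at
  the start of ventilation (the prediction task is indexed by ventilation
  hour): each hour takes its last observation; an empty hour immediately
  after an observed hour carries forward; hours missing for longer than
  1 h take the training-set mean of the variable. Training means are
  computed from an explicit, caller-controlled patient set
  (`compute_training_means`); the end-to-end convenience pipeline computes
  them over the whole cohort (imputation constants are label-free, so the
  leakage this admits is negligible; the label-using selection step is the
  one refit per fold, see below).
* **Sparsity screen**: variables with no observation in 40 % or more of
  sample windows (computed before imputation, boundary inclusive) are
  dropped.

## Features

PEEP and FiO₂ are deliberately **excluded** from the predictive variable
set: they define the outcome, and windows adjacent to an onset would leak
the label through them. The thirteen remaining channels (HR, RR, SBP, DBP,
MAP, SpO₂, temperature, airway pressure, pH, PaO₂, glucose, WBC, GCS) are
used.

* **Manual features**: the 35 h window is partitioned backward from its
  end into three 12 h blocks (earliest truncated to 11 h) and twelve 3 h
  blocks (earliest truncated to 2 h), so the most recent data always
  occupies complete blocks. Per variable and block: mean, variance
  (population, ddof 0), raw observation count (pre-imputation, which is
  the only coherent reading of a "number of measurements" feature), min,
  max and range. 13 variables × 6 summaries × 15 blocks = 1 170 features.
* **Static features**: age, gender (male = 1), neuromuscular-blocker flag,
  hours from ICU admission to the decision time, shock index (window mean
  HR / window mean SBP; well defined because SBP ≥ 50 after range
  filtering), and the total raw measurement count in the window.
* **Automated features**: a fixed, versioned catalog of functionals
  (moments, order statistics, changes, autocorrelation at lags 1–12, the
  first six FFT magnitude coefficients, db2 wavelet level energies, binned
  entropy, linear-trend slope and r). Functionals undefined on degenerate
  input (e.g. autocorrelation of a constant series) return the sentinel
  0.0 rather than a missing value, keeping the matrix complete. The
  catalog version is recorded in the feature provenance.

## Selection

* **Correlation pruning**: columns are walked in name order; a column is
  dropped when its absolute Pearson correlation with an earlier retained
  column is strictly above 0.95 (so a pair at exactly 0.95 survives). The
  keep-earlier-in-name-order rule is a deterministic tie-break.
  Zero-variance columns have undefined correlations and are retained with
  a logged notice.
* **Forward selection**: greedy; at each step every unselected candidate
  is scored by the likelihood-ratio p-value of the logistic model
  (selected + candidate) against (selected). A random forest supplies no
  native p-values, which is why a regression scorer is used. The best
  candidate is added while it clears the significance level; ties break by
  name order. The stopping level `alpha` (default 0.05) is applied
  **per step to the whole candidate family** (Bonferroni): with hundreds
  of candidates the smallest raw p-value is small by chance alone, and the
  corrected rule keeps the expected number of false selections near the
  nominal level — on permuted labels the selector typically keeps nothing.
  `correction="none"` restores the raw per-candidate rule.
* Candidate fits run on a batched Newton/IRLS logistic solver (all
  candidate models at one step share their base design and differ by one
  column, so the Hessians are built in a single einsum per iteration). A
  `1e-8` ridge keeps Hessians invertible; fits that fail to converge or
  diverge (separation) are refit with a `1e-3` penalty and logged. The
  solver's log-likelihoods and p-values are tested against statsmodels.

## Model and evaluation

Random forest: 500 trees, maximum depth 9, Gini criterion, `sqrt` feature
subsampling — reported to be near-optimal for this task and close to
library defaults. Evaluation is stratified 10-fold cross-validation;
AUROC, accuracy, AUPRC and PPV are reported per fold and as mean ±
variance across folds (sample variance, ddof 1). PPV needs a probability
cutoff; 0.5 is the documented default. Per-fold forest seeds derive
deterministically from the configuration seed.

Because forward selection uses labels, two modes exist:

* `nested` (default): pruning + selection are cloned and refit inside
  every training fold; held-out folds never influence selection.
* `pooled`: selection once on all data before CV — the order of operations
  the original analysis describes, which leaks selection information into
  the CV estimate. Provided for comparison; the report records which mode
  ran.

When selection retains **zero** features in a training fold (typical on
label-free data), the fold is scored by the intercept-only predictor (the
training prevalence), i.e. chance discrimination — the statistically
honest consequence of "nothing is informative". Training a forest on the
full unselected matrix instead was observed to produce high-variance,
cohort-dependent null AUROCs.

Impurity-based importances are summed across folds per feature name,
normalised to sum to one, and reported as a descending ranking with a
top-15 extract.

Grid search evaluates every grid point by k-fold mean AUROC with fold
assignments shared across points; exact ties break toward fewer trees,
then shallower depth.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not real physiology:

* baseline signals are stationary AR(1) processes around clinically
  plausible set-points (e.g. HR 85 ± 10 bpm, φ = 0.7 per charted step),
  clipped inside the valid ranges — the simplest process with realistic
  smoothness;
* charting is aperiodic-hourly for vitals (jittered within each hour),
  4–6-hourly for GCS and labs, exact-hourly for ventilator settings, and
  periodic (default 1 min) for optional high-frequency monitor channels.
  The default configuration emulates the nurse-charted low-frequency
  cohort; monitor channels are opt-in via `hf_channels`;
* ventilation durations are uniform on 96–336 h (all patients meet the
  96 h at-risk criterion; the mean matches reported ICU ventilation
  durations of roughly 200–240 h);
* VAC-negative patients fluctuate FiO₂ within 15 percentage points and
  PEEP within 2 cm H₂O — strictly below the escalation thresholds, so the
  definition provably never fires on them;
* injected episodes hold both settings at baseline through the stability
  window and raise the triggering setting(s) by at least one full
  threshold for the rest of the stay, so the definition fires exactly at
  the injected hour by construction;
* the pre-onset signal is a linear mean shift in MAP (−), HR (+), RR (+)
  and SpO₂ (−), ramping over the 36 h before onset to `drift_effect`
  standard deviations and holding afterwards. The real pre-decompensation
  dynamics are unknown; this drift is a controllable stand-in chosen
  because those four signals dominate the reported feature importances,
  and a tunable effect size is needed for power checks;
* missingness removes points in contiguous runs (geometric lengths, mean
  2 observations) at a configurable rate (default 5 %); outliers replace a
  configurable fraction (default 1 %) of points with values strictly
  outside the valid ranges, so the range filter must catch them.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: waveform morphology, cross-channel physiologic
coupling (MAP is simulated independently of SBP/DBP), non-stationary
baselines, informative missingness, charting-practice differences between
units, and real pre-VAC dynamics. Results on synthetic cohorts establish
that the pipeline recovers the structure it assumes, not that the assumed
structure matches any particular ICU.

## Problem sizes and numerical choices

The test suite and acceptance script use: 1 000 random 5–7-day setting
trajectories for the detector/oracle comparison; 200 clean patients for
injected-onset recovery; 50 repetitions of the planted-feature selection
experiment (effect 1.5 SD, n = 500, 50 noise columns); a 400-sample
drifting cohort and a 1 000-sample drift-free cohort for the end-to-end
discrimination checks (10-fold CV, nested selection capped at 10 features
per fold). All randomness flows from explicit integer seeds; repeated runs
are bytewise identical.

## Known limitations

* The hourly adaptation (rolling days, baseline = minimum of stability
  minima) is one defensible reading of the surveillance definition; other
  readings (calendar days, last-stability-day baseline) would shift onsets.
* Negative decision hours are drawn from the positive onset-hour
  distribution because no sampling scheme is prescribed; other schemes
  change the difficulty of the task.
* The pooled computation of imputation training means trades a negligible,
  label-free leak for a single preprocessing pass.
* Forward selection scores candidates with a logistic working model; a
  feature informative only through interactions can be missed even though
  the downstream forest could use it.
* The 35 h window length, subwindow sizes and drift shape are fixed design
  constants of the task, not tuned quantities.
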