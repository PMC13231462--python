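# Methods

This note records the models, conventions and numerical choices behind
`dyadaffect`, in the order the pipeline runs.

## Synthetic dyad generator

The generator produces the class of data the analysis assumes: six
contiguous 4-minute segments (baseline, four conversation scenarios in
randomized order, baseline) of four channels × two participants at
600 Hz.

**Cardiac.** A latent instantaneous-rate process at 8 Hz,

    rate(t) = HR0 + hr_mean_shift + hr_var_scale · 3 bpm · v(t)
              + coupling · 5 bpm · m(t),

where `v(t)` is per-participant band-limited (0.03–0.4 Hz) unit-variance
Gaussian noise and `m(t)` is the **shared modulator**: band-limited
(0.03–0.15 Hz) unit-variance noise drawn once per segment and fed to both
participants. Beat times are the unit crossings of the integrated rate;
the ECG is a train of Ricker (negative Gaussian second-derivative) pulses
at those times plus white noise. The pulse's dominant peak sits exactly at
the beat time, so detector oracles are exact. No P/T waves are modelled —
R-peak detection only needs a dominant deflection.

**Electrodermal.** Tonic level plus SCR transients at Poisson times
(`scr_rate` per minute). The transient is a difference of exponentials
(rise τ = 0.75 s, decay τ = 4 s) normalized to unit peak, with log-normal
amplitudes around 0.3 µS (σ_log = 0.4) — large enough that detection at
the 0.05 µS threshold is reliable but not trivial.

**Respiration.** A frequency-modulated oscillation at `resp_rate`/60 Hz
with 5% slow jitter (0.003–0.03 Hz) and the coupling-scaled modulator
(0.015 Hz per unit coupling) added to the instantaneous frequency.

**Temperature.** Baseline plus `temp_slope` °C/min linear drift plus
low-frequency (< 0.01 Hz) noise of 0.02 °C SD.

**Scenario encoding.** The study this task family comes from does not
publish physiological effect sizes per scenario, so the defaults are this
package's stated modelling assumptions, chosen once: arousal is encoded in
`hr_mean_shift` (15 vs 5 bpm), `hr_var_scale` (1.5 vs 0.9), `scr_rate`
(8 vs 3 /min) and `resp_rate` (18 vs 13 /min); valence in `coupling`
(0.7 positive vs 0.2 negative) and `temp_slope` (+0.02 vs −0.04 °C/min).
Baselines use no shift, coupling 0, SCR rate 1.5/min. Participant-level
offsets (5 bpm HR, 0.3 µS EDA, 0.3 °C temperature) and per-segment jitters
(1.5 bpm, 0.5 breaths/min, 0.03 °C/min slope, 20% log-scale SCR rate)
prevent any single feature from being a perfect class oracle, while
whole-session offsets cancel under baseline normalization. Under these
conditions the full pipeline recovers scenarios at or near ceiling on
cohorts of 10–30 dyads — deliberately well above chance; the pipeline's
discriminative calibration is checked against permutation nulls rather
than against an arbitrary intermediate accuracy.

**Questionnaires.** SAM valence/arousal and IIQ balance/valence answers
are drawn per participant per scenario from the published cohort's
per-scenario means/SDs and clipped to instrument ranges (SAM 1–9, IIQ
items 0–5); the four trait scores use the published cohort means/SDs and
ranges. The IIQ "amount" item has no published distribution; it defaults
to an uninformative 4.0 ± 1.0 across scenarios and can be dropped from
the self-report channel. Clipping biases the most skewed item (SAM
valence in PV-HA, mean 8.4, SD 0.8, ceiling 9) downward by ≈ 0.1; answers
are kept continuous rather than integer-valued since nothing downstream
depends on discreteness.

**What the simulator does not emulate:** realistic ECG morphology, motion
and electrode artifacts, nonstationary tonic EDA drift, circadian
temperature structure, or any dependence of self-reports on the
physiology. Passing tests therefore demonstrate that the pipeline's
machinery is correct and calibrated, not that real conversations are
classifiable at any particular accuracy.

## Preprocessing

* Butterworth lowpass: 5 Hz, 4th order, applied forward–backward
  (zero-phase) so event times are unbiased; the field's convention fixes
  filter family/order/cutoff but not phase handling.
* Peak detection: median-centred threshold at 50% of the 99.5th
  percentile with refractory periods of 0.25 s (R-waves) and 1.5 s
  (breaths). These detectors target clean, R-dominant signals like the
  simulator's output; they do no artifact rejection.
* Missed-beat rule: an interval > 1.8 × the running-median interval
  (11-interval centred window) marks missed events; one substitute event
  is placed at the midpoint, or round(gap/median) − 1 evenly spaced
  events for gaps beyond 2.8×. Substitutes are flagged `interpolated` and
  participate in all interval statistics, keeping the RR sequence
  contiguous. Breath detection returns a result from 2 peaks (slow
  breathing in a short window is not a failure); R-peak detection
  requires 3.
* SCR detection: local maxima with prominence ≥ half the 0.05 µS
  amplitude threshold; the trough is the last minimum within a 6.5-s
  look-back (bounded by the previous peak); rise time must lie in
  0.5–5 s and trough-to-peak amplitude ≥ 0.05 µS. All thresholds are
  keyword-exposed.
* Instantaneous rate: 60/interval at interval midpoints, linearly
  interpolated to a 4 Hz grid with edge hold. 4 Hz comfortably covers the
  HF HRV band (≤ 0.4 Hz).

## Individual features

Conventions that the definitions leave open, fixed here: "initial/final"
values are 5-s endpoint means (single samples would be noise-dominated);
dispersion statistics (SDNN, SCR-amplitude SD, breath-period SD) use the
population (ddof = 0) form so single-event cases are defined as 0; pNN50
counts successive differences strictly > 50 ms; min/max HR come from
beatwise 60/RR values (interpolated beats included), not the resampled
series, avoiding interpolation overshoot. Spectral HRV uses Welch's
method on the RR series resampled at 4 Hz (60-s Hann windows, 50%
overlap) with the standard absolute band powers in ms²: LF 0.04–0.15 Hz,
HF 0.15–0.40 Hz; the LF/HF ratio is reported missing (NaN) if HF power is
zero, and a non-finite feature invalidates the dyad.

## Synchrony features

All four metrics run on per-signal series resampled to a common 4 Hz
grid over the segment and z-scored within the segment; without this,
temperature's absolute scale would dominate the distance metrics.

* **DTW**: unconstrained symmetric dynamic programming with
  |x−y| local cost; the optimal path's total cost divided by its length
  (diagonal steps preferred on exact ties), making values comparable
  across signals. Verified against exhaustive path enumeration.
* **Nonlinear interdependence**: delay embedding with m = 3, τ = 1 s
  (4 samples), k = 5 neighbours, Theiler window 2 s. The directed index
  averages R_self/R_cross (mean squared distance to a point's own k
  nearest neighbours vs to the equal-time partners of the other
  trajectory's neighbours); the feature is the mean of both directions,
  which restores participant-exchange symmetry. Verified against a naive
  all-pairs implementation.
* **Coherence**: Welch magnitude-squared coherence (60-s windows, 50%
  overlap) averaged within signal-specific physiological bands — HR
  {0.04–0.15, 0.15–0.40}, respiration {0.05–0.40}, EDA {0.01–0.25},
  temperature {0.003–0.05} Hz — then across the signal's bands. With L
  independent windows the independence bias is ≈ 1/L, which the tests
  check.
* **Cross-correlation**: zero-lag Pearson; constant input returns 0 with
  a warning.

## Dataset assembly

Baseline normalization subtracts the first-baseline value of every
feature. Individual features are normalized per participant *before* the
dyad-level mean/absdiff combination: the mean is identical either way,
the absolute difference is not, and this package commits to the
per-participant-first order (it also makes whole-session participant
offsets cancel exactly). Synchrony features are normalized at dyad level
under the same subtraction rule. A quality failure in any segment
excludes the whole dyad (logged), mirroring dyad-level exclusion for
noisy recordings in human studies.

## Classification

Stages are (selector, classifier) pairs. ReliefF (10 neighbours, all
samples), greedy mRMR (mutual-information relevance minus mean
quartile-binned MI redundancy), chi-square on quartile-binned features,
k-NN mutual information, and bidirectional stepwise selection against a
one-hot linear fit (partial-F enter p < 0.05 / remove p > 0.10) are
implemented directly; classifiers are scikit-learn estimators with
standardization for the distance/margin-based ones (kNN, SVM).

Hyperparameters come from small documented grids (kNN neighbours
{5,3,7,11}; SVM C {1,0.1,10}; tree counts {100,300}; LDA svd/shrinkage;
NB smoothing) chosen by 3-fold dyad-grouped inner CV, evaluating at most
`hyperopt_budget` grid entries; the subset-size grid is handled the same
way. Serial architectures train stage-2 branches on the
ground-truth-labelled halves of the training data and route test rows by
stage 1's *prediction* — the standard hierarchical setup, and the one
under which stage-wise accuracies are recoverable from the overall
confusion matrix. Prediction ties resolve to the canonical label order
(PV-HA, PV-LA, NV-HA, NV-LA).

Leave-dyad-out CV re-runs selection, hyperparameter choice and fitting
inside every fold; nothing from the held-out dyad touches training (a
leakage audit is part of the test suite).

## Statistics

The permutation test shuffles labels within each dyad (preserving the
balanced design) and re-runs the full pipeline per replicate; p-values
use the add-one estimator. The omnibus comparison of approaches is the
Friedman test with dyads as blocks and midrank ties — the standard
nonparametric analogue of a repeated-measures ANOVA on ranks — with
all-pairs Wilcoxon signed-rank post hocs under Holm correction, since the
source convention ("RMANOVA on ranks + Tukey") names no formulas.
Stage-2 conditional accuracy is defined over stage-1-correct cases of the
requested valence sign; the test suite verifies that this definition
reproduces the published worked example from its printed 4×4 matrix
alone.

## Problem sizes and default analysis scale

The package's reference experiments run at desk scale, chosen as the
package's default: 20-dyad cohorts with 50 permutation replicates for
null calibration, 30-dyad cohorts × 5 seeds for recovery and
synchrony-ablation checks, with the reference configuration (serial
valence-first, ReliefF, gradient boosting, 10 features,
`hyperopt_budget=1`). The full nested subset-size/hyperparameter search
and the complete 27,000-combination serial enumeration remain available
(`n_features_grid`, `hyperopt_budget`, `grid_search_architectures(...,
budget_policy="all")`) for larger studies.

## Known limitations

* The detectors assume clean signals; there is no automated analogue of
  manual peak correction beyond the gap rule.
* Whether published LF/HF values used absolute or normalized power is
  unstated in this task family; absolute ms² is used.
* The exact coherence band sets and interdependence parameters of the
  cited prior methods are not published; the values above are this
  package's defaults, all config-exposed.
* Real-data accuracies (e.g. ~50% four-class performance on actual
  conversations) cannot be reproduced without the original recordings;
  the synthetic conditions validate machinery and calibration, not
  field performance.
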