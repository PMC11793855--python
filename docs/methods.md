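# Methods

This note documents the models, estimators and numerical choices behind
`neoperf`, and the limits of what its synthetic-cohort results demonstrate.

## Optical model

The modified Beer–Lambert law relates the change in optical density at
wavelength λ to the chromophore concentration changes:

    ΔOD(λ) = −log10(I_o(λ) / I_i(λ)) = (ε_HbO2(λ)·Δ[HbO2] + ε_Hb(λ)·Δ[Hb]) · L · B(λ)

Optical density is decadic (the OD convention); a natural-log variant would
only rescale every derived quantity. The two-wavelength system is inverted
per sample with the normal-equations form (1/L)(EᵀE)⁻¹Eᵀ·A rather than a QR
solve so the code mirrors the algebra exactly; for a 2×2 extinction matrix
the two are identical, and a condition-number guard (default 10⁸) rejects
degenerate extinction tables before inversion.

Choices and defaults:

* **Extinction coefficients** (packaged table, 1/(mM·cm)): 700 nm —
  ε_HbO2 0.290, ε_Hb 1.7943; 910 nm — ε_HbO2 1.2162, ε_Hb 0.7746. These are
  standard literature compilation values; users can substitute their own
  table. The wavelengths straddle the ~800 nm isosbestic point, which keeps
  the extinction matrix well conditioned (cond ≈ 2.7).
* **Pathlength factor** B(λ) = 1.0 per channel by default. The indexes are
  used comparatively across groups, so a constant factor rescales but never
  reorders them.
* **Source–detector distance** L = 1.0 cm (the probe's 10 mm LED–photodiode
  separation).
* **Incident intensity.** The device records only reflected light. Two
  referencing modes exist: `baseline` (default for real recordings) uses
  the mean detected intensity over the first second, making every Δ
  quantity a change from the trial's own start; `constant` divides by a
  configured incident value. Simulated cohorts are generated against a unit
  incident reference recorded in the manifest and are processed in
  `constant` mode, which keeps the recovered quantities on the calibration
  scale.
* **Degenerate StO₂ samples.** Δ[StO₂] divides by Δ[HbT]; samples with
  |Δ[HbT]| below 10⁻⁹ are marked missing (NaN) rather than emitted as ±∞,
  and missing samples are excluded from all window statistics. The
  saturation formula is applied to *changes*, as defined; the package does
  not reinterpret it as an absolute saturation.

## Protocol segmentation

Press epochs are maximal runs of the pressure signal above
`lo + 0.5·(hi − lo)`, where hi/lo are the 95th/5th percentiles — a robust,
affine-invariant threshold, since the sensor's gain and offset are
arbitrary. Runs separated by less than the 0.25 s debounce are merged and
shorter runs dropped, which absorbs sensor chatter near the threshold.
Exactly the configured number of cycles (3) must be found; detected press
and release durations outside ±20% of the nominal 5 s / 10 s attach
conformance warnings. The baseline window is the 3 s before the first
press onset (at least 1 s must exist). Conformance checking is timing-only:
the applied pressure magnitude is uncalibrated, so no contact-quality
criterion is enforced.

On simulated traces with trapezoidal pulses (0.5 s ramps) and 5% amplitude
noise, detected boundaries stay within 2 samples of the mid-ramp ground
truth at 20 Hz; the threshold sits mid-ramp where the slope is steepest,
which is what makes the detector this tight.

## Index estimators

The seven indexes are defined on one signal (HbT or StO₂) of one segmented
trial. The prose definitions leave the estimators open; the package uses:

* **I** — mean over the 3 s baseline window.
* **II** — mean of the *last 2 s* of each press, averaged over cycles.
* **III** — mean of the *last 3 s* of each release, averaged over cycles.
* **IV** — III − I (held exactly by construction).
* **V** — first-cycle press plateau minus the mean of the repeat plateaus.
* **VI** — ordinary-least-squares slope of the first 2 s after each
  release, averaged over cycles (units/s).
* **VII** — first-cycle recovery slope minus the mean of the repeat slopes.

End-of-epoch plateau windows avoid the occlusion/reperfusion transients;
the 2 s post-release fit captures the early reperfusion rate before the
signal plateaus. Averaging II, III and VI across all three cycles reduces
variance; V and VII deliberately isolate cycle 1 against cycles 2–3
(first-time versus repeated occlusion). All window lengths are config keys.
Whether the published "perfusion rate" index is a slope, a time constant or
an amplitude/time ratio is not derivable from its prose description; the
OLS slope is this package's recorded choice, not a claim about the
original authors' implementation.

The classifier features are the five indexes that separate the extreme
groups: [HbT-I, HbT-II, HbT-III, HbT-VI, StO₂-VII], z-scored with
training-split statistics before classification. Without scaling, the
Euclidean distances inside the Gaussian units would be dominated by
StO₂-VII, which is two orders of magnitude larger than the HbT indexes.

## RBF network

Architecture: N₀ = 5 inputs, N₁ = 64 Gaussian hidden units
φₖ(x) = exp(−‖x − cₖ‖²/2σ²), linear output y = Φᵀw. Training is two-stage:

* **Centers** — seeded Lloyd k-means run to assignment stability (max 300
  iterations), best of 8 restarts by within-cluster sum of squares. Empty
  clusters are re-seeded at the point farthest from its current center,
  which keeps training deterministic given the seed; with 64 centers for 70
  training points most clusters are singletons and the padding rule
  (sampling points with replacement, with a warning) covers k > n.
* **Width** — σ² defaults to the total variation of the training inputs
  (mean squared distance to their centroid), a literal reading of
  "estimated variation of the input datasets". The alternative rule — mean
  squared distance of points to their assigned centers — collapses to
  nearly zero when k ≈ n (singleton clusters), turning the units into delta
  functions that score every unseen point at 0; it remains available as
  `width="cluster"` (with a d²_max/2N₁ fallback) but is not the default.
* **Output weights** — normalized LMS: per presentation,
  w ← w + μ/(‖Φ‖² + ε)·(d − y)·Φ with μ = 0.05, ε = 10⁻⁸, 200 shuffled
  epochs, zero-initialized weights. Desired outputs are 0 for the
  good-perfusion group (Group I) and 1 for the poor-perfusion group
  (Group IV); Groups II/III are never trained on, only scored.

Decision rule: fuzzy output ≥ threshold (default 0.5) → poor perfusion.
The tie goes to *poor*, failing safe toward flagging a possibly
compromised infant. Outputs are not clamped and can fall slightly outside
[0, 1].

Train/test splitting supports two levels. `subject` (the package default)
keeps all six trials of an infant on one side of the split, which is the
honest generalization setting. `trial` splits individual trials regardless
of subject, reproducing a random 70/30 trial selection; it leaks
within-subject correlation into the test set and scores several points
higher. Both are seeded and stratified (35+35 train, 15+15 test by
default).

## Synthetic cohort generator

The generator exists to exercise the pipeline and reproduce the *reported
statistical structure* of the four clinical groups; it is not a
biophysical microcirculation model.

Per trial it simulates a trapezoidal pressure waveform (0.5 s ramps,
multiplicative amplitude and ±5% timing jitter, additive sensor noise) and
piecewise hemoglobin kinetics driven by the ground-truth cycle boundaries:

* during a press, HbT decays exponentially (τ = 1.5 s) toward
  baseline − drop;
* on release, HbT rises as a reactive-hyperemia ramp at the subject's
  reperfusion rate for 2.6 s, then settles exponentially (τ = 0.8 s) onto
  the recovery plateau;
* StO₂ follows the same piecewise form on its percent scale, with distinct
  first-cycle and repeat-cycle recovery rates (this difference is what
  drives Index VII).

The ramp-then-settle release shape is deliberate: the reported plateau
indexes live on a ~0.03-unit dynamic range around 0.65 while the reported
reperfusion-rate index is ~0.8–1.2 units/s over a 2 s fit window. No
single exponential relaxation toward baseline can produce both, so the
release transient overshoots (as post-occlusive reactive hyperemia does)
at exactly the rate the slope estimator is calibrated to recover.

Δ[HbO₂] and Δ[Hb] are derived by inverting the HbT/StO₂ definitions
(Δ[HbO₂] = HbT·StO₂/100), Gaussian measurement noise is added on the HbT
(σ = 0.003) and StO₂ (σ = 0.15%) trajectories, and the pair is pushed
through the forward Beer–Lambert model to raw dual-wavelength intensities —
so the pipeline under test reads exactly what a device would emit.

**Calibration.** The packaged table holds the reported per-group index
means and SDs (rows marked `reported`); cells the published tables do not
cover — the Group II HbT baseline and rate, the StO₂ baseline/recovery
levels, and the repeat-cycle StO₂ rate (set to 1.8 %/s) — are marked
`assumed` and chosen to preserve the reported group ordering. Presets are
derived so the *pipeline-recovered* statistics match the targets:

* the asymptotic press drop is inflated by 1/(1 − α), where α is the
  window-mean of the exponential decay kernel over the press-plateau
  window, correcting for finite settling;
* per-trial press-drop and recovery-deficit components carry SDs
  √max(sd²_II − sd²_I, 0) etc., so indexes II/III reproduce their reported
  SDs without being deterministic functions of index I;
* reported variance is split 70% between subjects and 30% within trials
  (configurable); per-cycle rate draws are inflated by √3 so the
  cycle-averaged Index VI keeps the full within-trial share.

Measured against each trial's own ground truth, pipeline bias on indexes I
and VI is below 10⁻⁴. Cohort means at the clinical sizes (24 and 13
subjects) still carry sampling error — the standard error of the Group IV
mean reperfusion rate is ≈ 0.11 units/s, about 9% of its 1.2393 target —
so single-seed cohort means scatter accordingly.

**What passing tests show.** That the algorithms are implemented correctly
and that, *if* real data had the reported group means, SDs and timing, the
pipeline would recover them and the classifier would separate the extreme
groups (replicated 70/30 trial splits average ≈ 85% held-out accuracy,
close to the reported 83.3%, and the mean network output rises from
Group I to Group IV). They do not validate the clinical claims: the
generator assumes Gaussian, independent-across-index-component variation,
first-order kinetics, and contains no motion artifacts, ambient-light
drift, contact-pressure variation or between-trial physiological trends.
The reported clinical accuracies themselves are not reproducible without
the original recordings. Under subject-level splitting — unseen infants at
test time — mean accuracy drops several points (~76% across seeds), a gap
worth remembering when reading trial-level results.

## Numerical details and degenerate inputs

* Missing samples (non-positive detected intensity, vanishing StO₂
  denominator) propagate as NaN; window means skip them and error only on
  fully-missing windows; slope fits require ≥ 3 valid samples.
* Index V/VII are NaN when fewer than two cycles exist; feature assembly
  drops such trials with a log entry.
* The k-means brute-force optimum property is exercised on n ≤ 8, k ≤ 3
  instances; multi-restart makes the match robust, though Lloyd's algorithm
  carries no general global-optimality guarantee.
* Flat pressure traces, too-few detected cycles, ill-conditioned extinction
  tables and non-binary NLMS targets all raise typed errors naming the
  offending input.
* All randomness (generator, k-means, NLMS shuffling, splits) flows through
  one `numpy.random.Generator`; identical (config, seed) reproduce output
  byte-for-byte.

## Known limitations

* Two wavelengths only; no scattering model and no absolute (non-Δ)
  quantification. The HbT index scale is left in "signal units" — the
  published values carry no units, and absolute calibration is open.
* Timing-only protocol conformance; no motion-artifact rejection.
* The acceptance thresholds for classifier behavior are meaningful only
  under the generator's study conditions; they substitute for, and cannot
  stand in as, clinical validation.
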