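# Methods

## Signal model and pipeline

One subject contributes a single short walk recorded by eight insole
force-sensitive resistors (S0–S3 right foot, S4–S7 left; S0/S4 heel, S1/S2
and S5/S6 metatarsal, S3/S7 toe) sampled at 20 Hz. The analysis treats each
sensor's stance-phase waveform as

    signal = habitual pressure profile ("trend") + fluctuation,

and takes the position that diagnostic information lives in the fluctuation,
not the profile: a person may have an odd but perfectly stable gait. The
pipeline is

1. **Contact detection.** Channels are min–max normalized per sensor; a foot
   is in the air wherever the maximum of its four normalized channels stays
   below `air_threshold` (default 0.05 — the threshold itself is a free
   parameter; results are insensitive over 0.02–0.10 because swing-phase
   output is near the sensor noise floor). Contact runs shorter than
   `min_segment_samples` (default 3, i.e. 150 ms at 20 Hz) are rejected as
   spikes rather than steps.
2. **Framing.** The first and last stance interval per foot are discarded:
   gait initiation and termination lack steady-state dynamics. Normalization
   is then recomputed over the framed stance samples (framing before
   normalization; the alternative order is available via
   `interpolate_steps(..., renormalize=False)` after an external scaling).
3. **Interpolation.** Each stance segment of length L is refined 20-fold to
   `20·(L−1)+1` samples with shape-preserving piecewise-cubic Hermite
   (PCHIP) interpolation. PCHIP passes exactly through the original samples
   and cannot overshoot the local data range, so normalized steps stay in
   [0, 1]. The refinement exists purely to populate entropy histograms: a
   13-sample stance at 20 Hz cannot fill 25 bins.
4. **Stepwise detrending.** `T_1 = F_1`; for later steps the previous trend
   is time-scaled to the current step length by nearest-neighbour lookup
   (index `round_half_up(j·(Lp−1)/(Lc−1))`; ties are vanishingly rare and
   round up) and blended: `T_i = αF_i + (1−α)Ť_{i−1}`. Since
   `mean|T_i − F_i| = (1−α)·mean|Ť − F_i|` is linear in α, the smallest α
   reaching the convergence threshold (10⁻⁶) is available in closed form,
   capped at `alpha_max = 0.23`; an iterative α search would terminate at
   the same value, so none is performed (verified against a fine grid
   search in the tests). The cap balances trend adaptivity against
   absorbing the very fluctuation being measured. The convergence error is
   interpreted as a mean *absolute* deviation: a signed mean would be
   near-zero for any α and could not serve as a convergence criterion.
5. **Entropy features.** Per sensor, residual samples where the sensor's own
   normalized value is below `activity_threshold` (default shared with
   `air_threshold`) are dropped — a toe sensor is uninformative during heel
   strike even though the foot is on the ground. Absolute residuals are
   histogrammed with equal-width bins over [0, max]; the bin count is 25,
   reduced to `max(2, n/4)` when fewer than 100 samples remain so that bins
   stay populated. The first step is excluded from all entropy statistics:
   its residual is structurally zero and would inflate the zero bin.
   Features per sensor:
   * **entire-gait TE** — Tsallis entropy (q = 0.82) of the pooled masked
     residuals;
   * **σE′** — per-step TE values `e_k` are computed, the change series
     `Δ_k = e_{k+1} − e_k` is formed, and σE′ is the population standard
     deviation of `{Δ_k} ∪ {−Δ_k}`, algebraically the RMS of `Δ_k` (both
     forms are implemented and cross-checked). The statistic measures
     deviation from the steady-walker ideal `Δ_k ≡ 0`. Applying the
     expansion to the raw `e_k` instead is available as
     `stepwise_mode="raw"`; the default "diff" reading is the one under
     which the zero-ideal argument is coherent. The largest |Δ_k| is kept
     as a diagnostic (`stepwise_max`), not a classification feature.
6. **Classification.** The 16-feature rows are median-imputed and
   standardized using training-fold statistics only, then evaluated by
   stratified 10-fold cross-validation (a stratified 75/25 holdout — 45
   train / 15 test at n = 60 — is available as `scheme="holdout"`; the
   k-fold scheme is the default because single splits are high-variance at
   this sample size). KNN uses cosine distance with 10 neighbours; the SVM a
   Gaussian kernel; "neural net (wide)" is a single 100-unit hidden layer;
   naive Bayes uses per-feature Gaussian KDE class densities; the quadratic
   discriminant uses Ledoit–Wolf shrinkage since per-class counts (~27 in a
   training fold) barely exceed the 16 features. Sensitivity, F1 and MCC
   take *diseased* as positive. Standardization matters: cosine KNN and
   RBF kernels are scale-sensitive and TE features are an order of
   magnitude larger than σE′ features.

## Histogram range policy and its consequences

Binning each sample over its own [0, max] range makes TE exactly invariant
to a uniform rescaling of the residuals. Two consequences are worth
understanding:

* A *scale-only* class difference (diseased fluctuation simply larger) is
  invisible to entire-gait TE, and a lognormal per-step scale mixture
  actually *lowers* pooled TE slightly (the widest step stretches the range,
  concentrating the bulk in low bins). Class separation therefore requires
  a *shape* difference in the residual distribution, which is exactly what
  smooth postural-sway deviations produce (see the generator below).
* Per-step TE under own-range bins is amplitude-blind, so step-to-step
  amplitude jitter moves σE′ only through shape effects. A
  `bin_mode="shared"` option bins every step over the walk-wide range
  instead, making per-step TE amplitude-sensitive; under shared edges
  amplitude jitter demonstrably increases σE′ (property-tested). The
  default remains per-step binning.

## The synthetic cohort generator

Real recordings of this kind are clinical data; `gaitent.synth` generates
cohorts with the structure the analysis assumes, so the defaults define the
package's reference test conditions:

* **Geometry/timing**: 20 Hz, 12 s walks; stance 0.55–0.75 s, swing
  0.35–0.50 s, drawn per step; left foot half a cycle out of phase.
* **Habit profile**: per sensor a Gaussian bump in normalized stance time —
  heel peaks early (0.22), metatarsals mid (0.45/0.58), toe late (0.78) —
  jittered once per subject (the fixed habit) and identical for every step.
* **Fluctuation**: within-stance AR(1) noise (coefficient 0.8) with
  stationary scale 0.02 (healthy) / 0.06 (diseased) in normalized units,
  multiplied per step by a lognormal factor whose log-sd is 0.25 for healthy
  and 0.25 × `step_jitter_diseased` (default 2.0) for diseased.
* **Postural sway**: a per-step sinusoid (0.6–1.3 Hz, random phase),
  amplitude 0.005 (healthy) / 0.22 (diseased). This is the feature that
  actually separates the classes in entropy terms: |smooth low-frequency
  deviations| spread broadly over the histogram range, flattening the
  distribution and raising TE, whereas peaked AR noise concentrates near
  zero. It also varies per-step residual shape (random phase), driving σE′.
  The amplitude was fixed once so that the diseased-minus-healthy TE
  contrast is positive on every non-heel sensor and the best classifier
  reaches the 90%+ regime across seeds at n = 30 + 30.
* **Heel attenuation**: every class difference on S0/S4 is multiplied by
  0.3 — even an unsteady walker loads the heel stereotypically — so heel
  sensors carry the weakest class signal.
* **Swing floor**: small positive noise (≈0.002–0.01) rather than exact
  zeros, so contact detection is non-trivial.

What the generator does *not* emulate: biomechanical coupling between
sensors, asymmetric or disease-subtype-specific gait patterns, sensor
nonlinearity/hysteresis and drift, missed steps, or inter-subject diversity
beyond profile jitter. Passing tests therefore demonstrate that the pipeline
recovers a class difference *of the assumed kind* at realistic sample sizes
— not clinical performance on real recordings.

The force/voltage calibration `w = exp((vo + 0.2245)/0.9265)` of the
FSR-plus-1 kΩ divider front end is included for working in physical units;
the synthetic channels are generated directly in normalized units.

## Numerical and degenerate-input choices

* Tsallis entropy at q = 1 dispatches to the Shannon form; zero-probability
  bins contribute nothing for any q. The pseudo-additivity identity
  `TE(X×Y) = TE(X) + TE(Y) + (1−q)TE(X)TE(Y)` is used as a correctness
  oracle (holds to <10⁻¹⁰ on random product distributions).
* All-zero residuals yield a single-bin histogram with p = 1 and TE = 0.
* Constant sensor channels raise a degenerate-input error at normalization;
  sensors inactive for a whole walk yield flagged missing features, which
  are median-imputed from the training fold at classification time.
* Problem sizes in the test and acceptance runs — 30 + 30 subjects, 12 s
  walks, 20 permutation repeats — are the package's reference conditions;
  the full suite plus acceptance run completes in well under a minute on
  one CPU.

## Known limitations

* The α-cap 0.23 and q = 0.82 are adopted as fixed defaults; the statistical
  procedures that originally selected them require clinical data, though
  `GaitEntropyModel.q_sweep` reproduces the q-selection procedure on any
  cohort.
* The 10-fold CV and 45/15 holdout descriptions of the reference evaluation
  are not mutually consistent; both schemes are implemented and k-fold is
  the default.
* With 60 subjects, fold-level metrics are quantized in steps of 1/6; small
  accuracy differences between classifiers are not meaningful.
* The cosine-KNN neighbour count (10) and the wide-net hidden width (100)
  follow common learner-tool presets; exact third-party presets are
  proprietary and approximated here.
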