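# Methods

## Signal model and scope

The package treats one cardiac cycle of wrist PPG, s(n) for n = 0..M−1 at
sampling rate fs = 256 Hz, as a sum of five Gaussian component waves
G(n|Θ) = Σᵢ αᵢ·exp(−(n−βᵢ)²/(2γᵢ²)), with per-component amplitude αᵢ
(normalized units), position βᵢ and width γᵢ (samples). Physiologically
G1–G3 absorb the forward ejection wave and its systolic reflections and
G4–G5 the diastolic reflection; their sums define the forward, systolic
and diastolic waves and the stiffness index SI = n_pd − n_ps. The ECG
channel contributes only two landmarks per beat, the R and T peaks; the
pulse-arrival time PAT = −n_R is the span from R to the PPG valley of the
same beat (the cycle-relative R position n_R is negative by convention).

Estimation runs per measurement: cycle features are reduced to a
measurement-level vector (median over cycles within a sequence, mean of
sequence medians within a measurement), merged with anthropometrics, and
mapped to brachial-ankle PWV (cm/s) by one of the fitted models.

## Preprocessing choices

**Baseline removal.** Discrete wavelet decomposition (sym8) with the
level chosen so the approximation band lies below 0.5 Hz — level 9 at
256 Hz, approximation band [0, 0.25] Hz; the approximation coefficients
are zeroed and the signal reconstructed. Periodized boundaries with an
orthogonal wavelet make the operation an exact orthogonal projection:
applying it twice is a no-op to ~1e−13 on block-aligned lengths (other
lengths are reflect-padded to the 512-sample block and cropped, which
perturbs only edge neighborhoods). Measured response: ≥ 97% power
removal for drift at 0.1 Hz; unity gain at and above 0.5 Hz. The start
and end of a finite record carry an envelope step whose spectrum reaches
below 0.5 Hz; its removal is correct behavior but means the first/last
few seconds of a record differ from the ideal infinite train — tests
evaluate pass-through distortion away from those transients.

**Notch.** Second-order IIR at 60 Hz, quality factor 30, applied
forward–backward (zero phase, so fiducial timing is untouched). The
quality factor is a package default for a narrow notch that leaves the
pulse band untouched.

**Normalization.** One affine map of the whole preprocessed segment onto
[−1, +1]; per-cycle renormalization would destroy amplitude relations
between beats.

**R peaks.** Energy detector (5–30 Hz bandpass → derivative → squaring →
150 ms integration → adaptive threshold), candidates refined to the local
ECG maximum within ±100 ms, then an amplitude screen (≥ 50% of the median
top-candidate amplitude) rejects T-wave bumps, and a 200 ms refractory is
enforced. This is a standard energy-based QRS design; nothing about the
estimation method depends on the particular detector.

**PPG valleys.** The diastolic tail ahead of the pulse foot is nearly
flat, so a per-beat argmin is noise-fragile. The detector instead (i)
finds maximal-upstroke positions on a 12 Hz low-passed copy, (ii) builds
an ensemble beat template by averaging beats, (iii) takes the template's
minimum (after Savitzky–Golay smoothing, which unlike a moving average
does not bias a quadratic minimum) as the upstroke-to-valley anchor, and
(iv) aligns each beat to the template by cross-correlation (a whole-beat
matched filter). Measured: exact on noiseless records, ≥ 98% of beats
within ±2 samples at SNR 20 dB. Single-beat records fall back to a plain
minimum search.

**Cycle SQI.** Records whose ECG or PPG cycle-length skewness exceeds 1.0
in magnitude or whose coefficient of variation (SD with the N−1
denominator over the mean) exceeds 0.2 have all cycles excluded; cycles
without an R peak in the 1.0 s before their onset are excluded
individually. The numeric thresholds are package defaults (configurable),
not clinically validated constants. Skewness is treated as 0 when
the cycle-length SD is ≤ 1.5 samples: at that level the variation is
sampling quantization and the normalized third moment is meaningless.
The R-pairing window default of 1.0 s (rather than a fraction of a
typical cycle) accommodates pulse-arrival times up to ~0.9 s.

## Fiducials

Landmarks are located on 3-sample moving-average smoothed copies (to
suppress quantization plateaus) with strict-inequality extrema and
earliest-index tie-breaks; reported amplitudes are read from the
unsmoothed arrays. The systolic region for the SDPPG a–d scan is
[0, n_notch], or [0, 0.4·M] when the notch is missing; e is the largest
SDPPG maximum within ±10% of M around the notch estimate and f the first
minimum after e. Absent landmarks are reported by name in `missing`
rather than raising — wrist pulses genuinely lack many of them — and a
cycle without resolvable a and b is marked unusable for SDPPG features.

## Weighted pulse decomposition

The objective is the weighted mean of squared residuals
(1/M)·Σ w(n)·[s(n) − G(n|Θ)]², with w(n) = ω inside [n_a, n_f] and 1
outside; ω defaults to 80. When a or f is unavailable the window falls
back to the whole cycle and the result is flagged. Because a sum of
positive Gaussians is non-negative while normalized cycles dip below
zero, the cycle is shifted so its minimum is zero before fitting; the
offset is kept on the result. Solved with a trust-region-reflective
bounded least-squares routine (an interior-type method), tolerances
1e−10, at most 500 iterations, no stochastic restarts — fits are
deterministic given the configuration.

Box bounds (defaults, configurable, echoed in output): α ∈ [0,
1.5·max s], βᵢ in overlapping fifths of [0, M) (fifth i widened by M/10
on each side), γ ∈ [1, M/4] samples. Initialization: β at fifth
midpoints, α = 0.6·s(β_init) clamped into bounds, γ = M/12. The ordering
β₁ ≤ … ≤ β₅ is induced by the staggered boxes rather than explicit
inequality constraints; the fitted components are sorted by position
before further use. These bounds are the package's own self-consistent
choices, so recovery
tests plant parameters inside these boxes.

The WPD-SQI gate uses the *unweighted* MSE between the shifted cycle and
its reconstruction: fits strictly above 2×10⁻³ are discarded; a fit at
exactly the threshold passes. Measured recovery: with initialization
within 10% of truth, ≥ 99 of 100 random in-bounds noiseless pulses reach
MSE ≤ 1e−6 with median parameter error ≈ 0; with additive noise of
SD 0.01 the weighting keeps SI within ±3 samples of its noiseless value.

## Features

Time features are stored in samples with the sampling interval carried
alongside (all interval features are index differences; seconds are a
view, position × Ts). Ratio combination forms u/v for ordered feature
pairs — all pairs by default at the vector level, a curated list in the
pipeline (the full cross product of a measurement-level matrix is
supported but rarely useful) — skipping denominators below 1e−9.
Missingness propagates: a feature computed from an absent landmark is
absent, and aggregation ignores missing cycle values rather than
imputing. One deliberate exception implements the wrist-specific
fallback: when the raw diastolic peak is missing but the decomposition
produced a diastolic wave, n_dia/A_dia are filled from n_pd with
provenance "WPD-derived", so downstream consumers can distinguish
measured from model-derived values. No statistical imputation is
performed. Conventional numeric ids for the pinned features are kept in
`CANONICAL_IDS` (P2O = 1, SDPPG c/d/e amplitudes = 18/19/20, age = 23,
SI = 51, age² = 63); everything else lives in the open registry, which
users extend with their own definitions.

## Models

The hierarchical model partitions PWV at τ = 1600 cm/s. The global
random-forest classifier learns the binary label PWV < τ; the low
regressor trains on PWV ≤ τ + W/2 and the high on PWV ≥ τ − W/2, W ∈
{0, 200, 400, 600} cm/s — with W = 400, edges 1800 and 1400. Routing is
by hard majority vote; probability-weighted blending exists behind a
non-default flag. Two default hyperparameter profiles are shipped
(male: forest 100 trees / depth 20, low-submodel boosted trees depth 5;
female: forest 250 / depth 9, depth 3), with min_samples_split = 3,
min_samples_leaf = 1, 200 boosted estimators, column subsample 0.7,
loss-reduction floor 0 and learning rate 0.1 (exposed in the validation
grid).

Oversampling duplicates rows (fixed seed) until every non-empty
100 cm/s bin matches the largest; duplicates carry a flag so validation
folds never share duplicated rows with training. Splits are
participant-disjoint, asserted on every fit/evaluation path.
Leave-one-participant-out validation removes *all* of a participant's
measurements per fold, picks the grid point with minimal pooled RMSE,
and breaks ties toward fewer trees, then shallower depth.

## Synthetic data: what it emulates, what it does not

Records are concatenations of five-Gaussian pulses (template fractions
of the cycle length: amplitudes 1.0/0.55/0.30/0.30/0.18, positions
0.12/0.22/0.36/0.58/0.74, widths 0.038/0.058/0.078/0.075/0.15) rendered
with overlapping tails, so the signal is smooth; the annotated valley of
each beat is the computed minimum of the clean signal and the R spike
sits exactly one PAT before it, making the PAT ground truth exact. An
unannotated warm-up beat precedes the first annotated one so every
annotated valley follows a genuine diastolic decay. Optional baseline
wander (sinusoid, default 0.15 Hz), 60 Hz interference, white noise,
per-beat parameter jitter and cycle-length variability are layered on
top. The template was designed for realistic wrist morphology — crisp
systolic takeoff, weak diastolic features, a stable diastolic-wave peak —
and for well-posedness of the recovery tests (components inside the
default WPD boxes).

Cohorts draw a per-participant latent stiffness that jointly raises age,
shortens PAT (150 → 80 samples), shifts the diastolic components earlier
(shorter SI) and sets the true PWV — by an affine map onto the PWV range,
or by a user-supplied pwv_function(age, PAT, SI proxy) for planted-slope
recovery tests. The tabular cohort generator plants piecewise structure:
one globally informative predictor, one informative only below the
1600 cm/s boundary, one only above, plus pure-noise columns — the regime
structure a classify-then-regress model exists for.

None of this is a physiologically validated hemodynamic simulation: there
are no arrhythmias, no motion artifacts beyond additive noise, no
sensor-specific distortions, and the feature→PWV mapping is a planted
convenience, not vascular physics. Passing tests therefore demonstrate
that the pipeline recovers known structure through every processing
stage at realistic noise levels — not clinical accuracy on real wrist
recordings.

## Numerical conventions and degenerate inputs

Error = measured − estimated everywhere, so positive mean error is
underestimation; SD uses N−1; Bland–Altman differences follow the same
sign and limits are bias ± 1.96·SD. Correlation is Pearson (two-sided p
from the t transform, N−2 df); Spearman behind a flag. Constant signals
are rejected by normalization and correlation; flat cycles by landmark
search; all-zero pulses by the decomposition; fewer than 3 cycles by the
SQI (skewness undefined); fewer than 2 pairs by the metrics (SD
undefined); sub-5-measurement submodel ranges by the hierarchical fit.
Extremum ties break earliest; solver determinism is part of the test
contract (identical seeds ⇒ bit-identical records, fits, models and
predictions).

## Problem sizes

Default experiment sizes were chosen so every check runs comfortably on
a laptop core: 100 pulses for recovery, 60-beat records for detection
rates, 150-measurement cohorts over 20 seeds for the model comparison,
and 8–12-participant signal-level cohorts for end-to-end runs. All are
configuration parameters, not limits of the implementation.

## Known limitations

- Only the individually named features are pinned to canonical ids; the
  rest of the catalog is an open registry that users extend.
- Record-level SQI excludes all cycles of a failing record; a per-cycle
  variant would be less conservative.
- EDF output is not provided (no writer in the supported dependency
  set); record I/O is CSV plus a JSON annotation sidecar.
- The baseline-removal projection is exact only on block-aligned
  lengths; elsewhere edges deviate slightly.
- Sex-specific modelling is a configuration profile, not a learned
  component; no claim is made about which profile suits which data.
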