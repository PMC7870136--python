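# Methods

This note documents the models, the numerical choices and the limits of
what the synthetic-data tests demonstrate.

## TCSPC forward model

A photon emitted by component *i* arrives at t = t₀ + ε + δ, where ε ~
N(0, σ²) is the instrument response (IRF) jitter and δ ~ Exp(τᵢ) the decay
delay. Under periodic excitation with period T (12.5 ns at 80 MHz) only
t mod T is observed, so the arrival density on [0, T) is the wrapped
exGaussian mixture. The expected count in a bin is evaluated in closed
form: the exGaussian CDF

    F(t) = Φ(z) − ½ e^(−z²/2) erfcx((σ/τ − z)/√2),   z = (t − t₀)/σ

is differenced across bin edges for pulse offsets k ∈ {−1, 0, 1} (k = −1
catches the Gaussian left tail that wraps to the end of the previous
period), and all earlier pulses (k ≥ 2) are summed as a geometric series
in e^(−T/τ) with the erfc saturated at 2 — exact to double precision for
any σ ≤ 1 ns when T = 12.5 ns. The erfcx form is numerically stable for
every σ/τ in the fit bounds; for arguments below −25 the term is
rewritten with a combined exponent to avoid overflow. σ = 0 degenerates to
the plain exponential CDF. Amplitudes are parametrized as per-component
*photon totals*, so the expectation over one full period sums exactly to
a₁ + a₂.

The sampler in `synth` draws (component, ε, δ) directly and wraps mod T —
exact inverse-CDF sampling of each factor of the same generative model, so
the generator and the fitted model agree by construction and the
histograms are pure functions of (parameters, seed).

## Fitting and tau8

Histograms are fitted by bounded trust-region least squares on counts
(τ ∈ [0.05, 10] ns, σ ∈ [0.01, 1] ns, amplitudes ≥ 0), the objective the
unweighted sum of squares; a Poisson-deviance objective is available and
gives slightly smaller variance at low counts. Start values come from the
histogram shape (t₀ and σ from the 10–90 % rising edge, lifetimes from
log-linear slopes of the early and late thirds of the tail, amplitudes
from the photon total); time-series fits warm-start from the previous
frame. Lifetimes are reported with τ₁ ≤ τ₂ enforced after the fit. Fits
below 10³ photons are refused rather than silently returned.

tau8 — the photon-weighted mean arrival time of the deconvolved decay
restricted to [0, W], W = 8 ns — is computed from the fitted parameters,
not from the raw histogram, so the IRF and the wrap do not bias it. The
window interprets the "8" of the statistic and matches the usable span of
a 12.5 ns period after a ~2 ns IRF offset; it is configurable. Because of
the truncation, tau8 of a single exponential is slightly below τ
(0.9973 ns for τ = 1 ns), and tau8 of a mixture is the
photons-in-window-weighted mean of the component tau8 values — the
identity that makes the lifetime bleedthrough correction exact. Simulated
lifetime waveforms are therefore programmed in tau8 units and realized by
numerically inverting the single-exponential tau8 mapping.

## Bleedthrough

The 2×2 intensity mixing (6.0 % green→red, 4.4 % red→green by default) is
inverted jointly — exact for any fractions with product < 1, and reducing
to the historical one-pass subtraction (kept behind a flag) when the
reverse fraction is small. Negative unmixed intensities are clipped to
zero and flagged rather than propagated. The lifetime correction removes
the contaminant species (tau8 0.675 ns) per frame by default; whether such
a correction should be applied per frame or only to baseline levels is an
open choice in practice, so both modes exist — per-frame is the default
because it is exact under the forward model at every time point.

## Transient quantification

Stimulus onset defines t = 0; all windows are half-open [start, end).
Defaults, all configurable: baseline mean over the 60 s before the
stimulus; peak search 90 s post-stimulus for slow metabolic transients,
10 s for Ca2+ spikes, 4 s for the NAD(P)H oxidation dip (negative
polarity); dip and overshoot windows mirrored for FAD+. Display rebinning
averages 20 consecutive frames except for fast channels within 10 s after
a stimulus, where single frames are kept; a trailing partial window is
averaged as-is. Inclusion thresholds are inclusive (≥), matching the
printed criteria (≥ 0.05 ns lifetime response, ≥ 1 % peak amplitude).
Recovery time is the first post-peak return into a band of 10 % of |Δ|
around baseline, flagged as undefined when the trace never returns. AUC
integrates the ΔF/F trace by the trapezoidal rule directly on the
(possibly irregular) timestamps over a 2 min span, boundary points
linearly interpolated; no resampling. Baseline-step exclusion flags a
jump ≥ 0.1 ns between consecutive rebinned points that never returns
below half the step height within 60 s (or to the end of the trace) —
"sudden and irreversible" made operational.

## Synthetic acquisitions

Transients are difference-of-exponentials (alpha-like) curves normalized
to unit peak; the NAD(P)H dip is a brief truncated Gaussian preceding the
overshoot, FAD+ its sign-mirrored counterpart. These shapes are a modeling
choice — the in-vivo shapes are described only qualitatively — so tests
recover *programmed* amplitudes and timings, which validates the
quantification chain, not the biology. Default study conditions: stimulus
trains of 25–200 pulses at 50 Hz (100 default); 2p frames every 0.5 s;
widefield cadence 1 frame / 2 s with a 6 Hz burst for 10 s starting 2 s
pre-stimulus (exactly 60 burst frames); O2 sampled at 1 Hz with an affine
electrode map, optional linear drift and a two-point calibration pair.
Peredox transients use rise/decay constants of 15/60 s on a 1.55 ns
baseline; RCaMP spikes 1/10 s on 1.10 ns — fast relative to the metabolic
transient while sampled adequately at the 0.5 s frame interval. Photon
counts per ROI-frame are not published; the default of 3×10⁴ (configurable
10³–10⁵) makes per-frame two-component fits stable while keeping the
end-to-end simulation inexpensive. Widefield noise is additive Gaussian on
the ΔF/F scale; shot noise is deliberately not modeled.

What the synthetic data does *not* emulate: focus drift, movement,
photobleaching, astrocytic contamination, scanner artifacts or pixel-level
images. Passing tests show the estimators are correct on data obeying the
stated models, with noise of the stated family.

## Chelation

Apparent constants follow the classic calculator scheme: reference log K
and pK values at 20 °C / 0.1 M (EGTA: pK 9.47, 8.85; log K Ca 10.97, Mg
5.21), van't Hoff temperature adjustment with tabulated ΔH (−5.6, −5.7,
−8.1, +5.5 kcal/mol), Davies-equation ionic-strength adjustment (charge
model Ca²⁺/Mg²⁺ + EGTA⁴⁻), and pH read as hydrogen-ion activity converted
to concentration with the Davies single-ion coefficient. Only the two
amine protonations enter the correction; the carboxylate pKs (~2.7, 2.0)
are irrelevant above pH 5. The coupled equilibria are solved by Brent
root-finding on the free-ligand conservation function, which is monotone
on [0, L_total]; conservation at the solution is verified to < 10⁻⁹ mM.
Published EGTA constants spread by roughly ±0.1 log unit between
compilations, so `sensitivity()` reports the induced range; the saturated
Ca estimate is insensitive, the weakly bound Mg estimate moves by
~0.05 mM per 0.1 log unit.

## Oxygen

The electrode is assumed linear; calibration is the affine map through
the anoxic (0 µM) and high standards. The high standard's concentration is
never hard-coded: it defaults to Henry's-law solubility at the bath
temperature for a 20 % O2 gas fraction at 1 atm (~220 µM at 34 °C),
carried explicitly on the calibration pair. Baseline shifts are percent
changes of window means and are invariant to any recalibration sharing
the same zero.

## Statistics

Normality is tested per group with the Lilliefors-corrected
Kolmogorov-Smirnov test at α = 0.05 (the gate's α is a convention, and it
is recorded in the run log). The parametric branch uses paired/unpaired t
(Welch when the SDs differ by more than 1.5×), one-way or
repeated-measures ANOVA; the non-parametric branch Wilcoxon matched pairs,
Mann-Whitney, Kruskal-Wallis, or Friedman with a hand-implemented Dunn
post-test (rank-sum z statistics, Bonferroni-adjusted). After a
significant RM-ANOVA the post hoc is pairwise paired t with Holm
adjustment — a Student-Newman-Keuls routine is not available in the
dependency set, and Holm is the conservative replacement; the report names
the test actually run. Box summaries use linear-interpolation percentiles.
No multiple-testing correction is applied beyond the named post-tests.

## Problem sizes

The test suite simulates cohorts of 2–5 cells with 20–340 frames per
channel and 2–10×10⁴ photons per frame, and 100 + 90 replicate histograms
for the bias and error-scaling checks — sizes chosen so the full suite
runs in a few minutes while every statistical assertion retains comfortable
margins. All seeds are fixed; every simulation is reproducible bit for bit.
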