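# Methods

## Rheological models

Tissue is a homogeneous, isotropic, linearly viscoelastic solid of density
ρ (default 1000 kg/m³, the soft-tissue convention; configurable — density
is not measured by either instrument). Three lumped models of the complex
shear modulus are implemented:

* Kelvin–Voigt (the working model): G\* = μ + iωη.
* Maxwell: G\* = iωημ/(μ + iωη); fluid-like at DC, used only for model
  comparison.
* Zener (standard linear solid), parameterized as a spring μ in parallel
  with a Maxwell arm (μ₂ in series with η): G\* = μ + iωημ₂/(μ₂ + iωη).
  Other Zener parameterizations exist; this one degenerates cleanly to
  Voigt as μ₂ → ∞, which the tests exercise.

Phase velocity follows from the modulus as
c = sqrt(2(G′²+G″²)/(ρ(G′+sqrt(G′²+G″²)))); for Voigt moduli this is
algebraically identical to the familiar dispersion relation in μ, η, and
the identity is enforced to 1e-12 in the tests. The complex wavenumber
k\* = ω·sqrt(ρ/G\*) supplies the simulator's phase (Re k\*) and attenuation
(α = −Im k\*). All public interfaces take frequency in Hz; the single
ω = 2πf conversion happens inside `complex_modulus`.

### Dispersion-curve fitting

Bounded nonlinear least squares (μ ∈ (0, 100 kPa], η ∈ [0, 100 Pa·s]) from
a deterministic 3×3 multi-start grid over the (μ, η) decades
{0.1, 1, 10 kPa} × {0.1, 1, 10 Pa·s}; lowest residual sum of squares wins,
ties broken toward smaller η. Because low-frequency elastic data make the
objective flat in η to machine precision, a boundary polish accepts η = 0
when it fits no worse. R² is reported as NaN when the data have zero total
variance. Weighting is unweighted by default (per-stage analyses fit mean
curves); inverse-variance weighting by the per-point SD is available.

A conditioning caveat that shapes several tests: in the 160–380 Hz band of
a liver-like medium ωη > μ, so the response is viscosity-dominated and μ is
weakly identified from that band alone — a ~2% curve error maps to a
10–20% μ̂ error. The combined 1–380 Hz fit restores conditioning because
the low band pins the elastic plateau.

## Wavefield simulator

The simulator replaces the acoustic-radiation-force push and beamforming
with their end product: a plane shear wavefront entering at the first
lateral column, uniform in depth, propagating in +x with the medium's
k\*(f). The source is a differentiated-Gaussian velocity pulse
(A(f) ∝ f² exp(−2π²σ_t²f²), σ_t = 0.3 ms, spectral peak ≈ 750 Hz, exactly
zero at DC, pulse centre t₀ = 1.5 ms). Two constraints force this shape:

* the pulse must fit inside the 5 ms observation window (50 frames at
  10 kHz) at every analyzed lateral position, or windowed Fourier phases
  are truncation-biased — this rules out narrowband sources centred on the
  analysis band, whose pulses are longer than the window;
* the spectrum must roll off smoothly to zero at both ends — any spectral
  cliff rings for longer than the window.

Physically this mimics the impulsive (sub-millisecond) radiation-force
push, whose spectrum is broad and vanishes at DC. Synthesis is a direct
sum over a 10 Hz frequency grid out to where the magnitude falls below
1e-4 of peak (an error is raised if that reaches Nyquist). An optional
reflected wave is the forward wave mirrored at the far lateral boundary
(path 2L − x), and additive white Gaussian velocity noise defaults to 5%
of the peak amplitude. Every stochastic call takes an explicit seed.

The IQ model phase-modulates a carrier by the round-trip path change:
iq = exp(i·4π·f_c·d/c_sound) with d the cumulative (trapezoidal) integral
of v — precisely the model the pipeline's lag-one autocorrelator inverts.

Reflections from the far boundary are *invisible* under liver-like
parameters: the return path exceeds 13 ms of travel against a 5 ms window,
and attenuation over 2L is ~e⁻¹⁰. Directional-filter efficacy is therefore
demonstrated in a low-loss scenario (μ = 500 Pa, η = 0.005 Pa·s, 250
frames, σ_t = 0.5 ms, cubic DC rolloff) where the reflected wave genuinely
overlaps the acquisition and the two propagation directions are spectrally
resolvable.

## SWE processing chain

Stages, in order: (1) lag-one temporal autocorrelation of IQ with a 3×3
spatial average, scaled by c·PRF/(4π f_c); (2) 3×3 median filter per frame
then a 10-pixel axial boxcar, then cubic-spline temporal interpolation ×5
(original samples preserved); (3) removal of the leading reverberation
frames (default 2 original frames = 10 interpolated samples; the count is
not instrument-documented and is configurable) and a zero-phase 4th-order
Butterworth low-pass at 1 kHz; (4) directional filtering and per-frequency
Fourier phase regression over the lateral axis; (5) Voigt inversion.

### Spectral readout

The temporal transform is evaluated directly at the readout frequencies
(160–380 Hz in 20 Hz steps — the step is a stability choice, configurable),
equivalent to densely zero-padded FFT bins: with a 5 ms record the natural
bin spacing is ~200 Hz, so nearest-bin readout at 20 Hz spacing would
collapse all points onto one or two bins.

Window truncation is the dominant error source at this record length.
Each lateral column is therefore time-gated with a flat-top window over its
detected pulse support (depth-averaged envelope above 10% of its peak,
raised-cosine tails of 0.4 ms): an identity on complete pulses that zeroes
out-of-pulse filter transients. Columns whose support touches a window
edge (the pulse never fully passed) are excluded; if fewer than three
columns have a complete pulse — continuous-wave-like fields — the gate and
the completeness requirement are dropped. Per frequency, the largest
contiguous run of columns above 10% of the spectral-amplitude maximum is
regressed: phase of the coherent depth average, unwrapped along x,
amplitude²-weighted least squares; c(f) = −2πf/slope; the per-point SD
propagates the spread of per-depth slopes. Frequencies with non-negative
slope or total phase span under π/4 are dropped; fewer than three
surviving points is an error.

Under these defaults the noiseless end-to-end dispersion error at
healthy-stage parameters is ≤1.6% across the band (≤3% over the wider
stage parameter range), and the fitted (μ, η) land within 10% of truth.
With the default 5% tracking noise a single movie recovers μ with ~16%
median error over 20 seeds (band conditioning, above); the study design
averages ten acquisitions per subject for exactly this reason.

### Directional filter

A hard quadrant mask in the (lateral frequency ξ, temporal frequency f)
plane is the textbook reflection remover, but in a strongly attenuating
medium it damages the wave it is meant to keep: at 270 Hz liver-like
attenuation gives α/k ≈ 0.5, so the forward wave's spatial spectrum is a
Lorentzian of half-width α/2π whose tail crosses ξ = 0, and clipping the
whole wrong-sign half-plane removes ~17% of the forward amplitude mass
(>20% velocity bias measured). The implemented mask is adaptive per
temporal frequency: the dominant spatial ridge of the depth-pooled,
4×-zero-padded power spectrum is located, its contiguous extent above 10%
of peak power (measured above the noise floor) sets a guard band of twice
that half-width (floor of one resolution bin), and wrong-sign components
are attenuated only beyond the guard, with a one-bin raised-cosine edge.
Where attenuation smears the spectrum across both signs the guard widens
and the filter approaches identity — counter-propagating energy that close
in ξ is unresolvable in principle at this aperture. Measured behaviour:
≤2% velocity change on forward-only liver fields; on the resolvable
low-loss scenario, forward correlation 0.997, reflected-only energy
reduced to ~1%, and superposition recovery correlation 0.992.

## DMA

Shape factor SF = width·length/thickness (0.01875 m for the standard
5 × 15 × 4 mm specimen). G′ = (F\*/X\*)cos δ/SF and G″ = (F\*/X\*)sin δ/SF —
the loss modulus takes sin δ (the imaginary part of (σ₀/ε₀)e^{iδ}); a
repeated cos here would violate G′²+G″² = ((F\*/X\*)/SF)², which a test
enforces. The synthetic instrument inverts these relations from a model's
G\*(ω) with multiplicative noise on the stiffness ratio and additive noise
on δ. Strain amplitude (1%), pre-compression and the 38.1 °C bath are
instrument metadata, not model inputs. Both entry points exist: raw
(F\*/X\*, δ) sweeps and direct (G′, G″) sweeps.

## Combined fit

DMA (1–41 Hz) and SWE (160–380 Hz) curves are concatenated — overlapping
frequencies are an error, as no averaging rule is defined, and the
41–160 Hz gap is left empty — and fitted with one Voigt model. Per-stage
analyses fit stage-mean curves (unweighted); per-subject combined values
(for box plots and ROC) are fitted per subject. With Table-calibrated
conflicting bands the combined elasticity exceeds both band-wise values
(~1.43 kPa for healthy stage from 1.12/0.86 kPa inputs): the nearly flat
high-band plateau pins μ near ρc², while the low band anchors the elastic
toe. The same pattern appears in real paired SWE/DMA liver data (combined
elasticities above both band-wise group means), so it is asserted, not
treated as a defect.

## Synthetic cohort

Five stages with counts 17/14/19/12/7 (n = 69). Stage-wise means ± SD per
method and parameter default to the emulated study's group values. Per
animal, the
four latent parameters (μ_SWE, μ_DMA, η_SWE, η_DMA) are drawn from a
Gaussian copula: elasticities correlated across methods at 0.628,
viscosities at 0 (paired in-vivo/bench viscosities are essentially
uncorrelated, r ≈ −0.01), other cross-pairs
independent. Marginals are Gaussians clipped from below at 10% of their
mean; for these mild truncations the copula correlation tracks the
realized Pearson correlation within a few hundredths (calibration test:
mean sample r over replicate cohorts within ±0.1 of target). Replicates
(10 SWE, 3 DMA) multiply the latent truth by 1 + N(0, cv), cv = 0.10 —
chosen so the per-animal standard error is small against the ~25–30%
between-animal spreads. Fat fractions are uniform within each stage's
histologic interval (0–4, 5–25, 26–50, 51–75, 76–100%); staging maps
(75, 100] to S4, closing the gap in the literal ">76%" definition.

What the generator does *not* emulate: spatial heterogeneity, anisotropy,
blood-flow and breathing artifacts, operator variability, instrument drift,
or any feeding-duration → stage dynamics. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
statistical model, not field performance on real livers.

`cohort_to_curves` has two modes: `fast` evaluates the dispersion relation
analytically at measurement-level parameters; `full_physics` runs the wave
simulator + SWE chain and the rheometer simulator + DMA chain per
replicate. The modes agree within 10% on noiseless input; full-physics is
used on single animals in tests (seconds per movie).

## Statistics

* IQR fence: quartiles by linear interpolation of order statistics
  (stated because the exclusion set depends on the convention); exclude
  outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; fewer than 4 values pass through
  with a warning.
* Pearson r with the two-sided t-transform p (t = r√(n−2)/√(1−r²), n−2 df).
* One-way ANOVA (scipy); identical groups report F = 0.
* Tukey–Kramer: |Δmean| vs q(α, k, df)·sqrt(MSW/2·(1/nᵢ+1/nⱼ)) with q from
  the studentized-range distribution; an independent Gauss–Legendre
  integration of the studentized-range CDF cross-checks the quantile in
  the tests.
* ROC: Mann–Whitney AUROC with half credit for ties (verified against
  brute-force pair counting and scikit-learn); Youden-optimal cutoff with
  ties resolved toward the lower cutoff, classifying score ≥ cutoff as
  positive; 95% CI by Hanley–McNeil SE with a normal approximation clipped
  to [0, 1] — the CI method is a documented choice (reported AUROC
  confidence intervals in the literature rarely state theirs).
* Between-method comparisons per stage use Welch's t-test (variance
  equality is not assumed).

`study_report` assembles: per-stage mean ± SD per method/parameter after
IQR filtering, ANOVA + Tukey across stages, cross-method Pearson on
per-animal means, and ROC of the combined-fit elasticity for S0 vs S1–S4
and S0–S1 vs S2–S4. Everything is deterministic given the cohort seed.

## Problem sizes and numerical choices

Default grids: 100 × 150 × 50 movie samples (5 × 15 mm at 50/100 µm pitch,
5 ms at 10 kHz), 12-point SWE band, 9-point DMA sweep, 69-animal cohorts;
Monte-Carlo checks use 20–50 seeds for recovery and 50–200 replicate
cohorts for calibration — sizes at which the estimators' behaviour is
stable and a full test run completes in about a minute and a half.
Known limitations: no speckle or beamforming physics, no 3-D wavefields,
no fractional-derivative rheology, single-ROI scalar outputs, and the
band-conditioning limit on single-acquisition μ̂ noted above.
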