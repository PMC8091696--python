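# hepavisc

Liver shear viscoelasticity from dispersion data: shear-wave elastography
(SWE), dynamic mechanical analysis (DMA), and a combined Kelvin–Voigt fit,
with a fully synthetic replication of a five-stage hepatic-steatosis rat
study.

## Who this is for

Quantitative-ultrasound and tissue-biomechanics researchers who want a
tested, end-to-end reference implementation of shear-wave dispersion
inversion — from a particle-velocity movie to (μ, η) — together with the
bench-rheometry counterpart and the group-level statistics used to stage
fatty liver, all runnable without any proprietary acquisition hardware or
animal data.

## The model

Liver tissue is modelled as a Kelvin–Voigt solid: a spring μ (shear
elasticity, Pa) in parallel with a dashpot η (shear viscosity, Pa·s), so
G\*(ω) = μ + iωη. A plane shear wave then propagates with phase velocity

```
c(ω) = sqrt( 2 (μ² + ω²η²) / (ρ (μ + sqrt(μ² + ω²η²))) )
```

with ρ the mass density (1000 kg/m³ by default). Dispersion — the rise of
c with frequency — encodes η; the low-frequency plateau encodes μ. The two
measurement routes probe different bands:

* **SWE (160–380 Hz)**: a synthetic ultrafast acquisition (10 kHz frame
  rate, 50 frames, 5 × 15 mm region) tracks a simulated planar shear pulse;
  the processing chain is autocorrelation velocity estimation, despeckling,
  temporal spline interpolation, reverberation-frame removal, zero-phase
  low-pass filtering, directional filtering, per-frequency Fourier phase
  regression along the lateral axis, and a nonlinear Voigt fit.
* **DMA (1–41 Hz, 5 Hz steps)**: oscillatory shear on a 5 × 15 × 4 mm
  specimen gives stiffness ratio and phase lag per frequency; with the
  shape factor width·length/thickness these become storage and loss moduli
  G′ = (F\*/X\*)cos δ / SF, G″ = (F\*/X\*)sin δ / SF, hence phase
  velocities, hence another Voigt fit.
* **Combined (1–380 Hz)**: both curves merged and fitted with one Voigt
  model — the best-constrained elasticity estimate, used for ROC staging.

The synthetic cohort draws 69 animals in stages S0–S4 (counts 17/14/19/12/7,
graded by macrovesicular fat fraction) with stage-dependent bivariate
(SWE, DMA) parameters, a tunable cross-method elasticity correlation
(default 0.628), replicate measurement noise, and full seed determinism.
Statistics follow the standard study pattern: 1.5×IQR outlier exclusion,
one-way ANOVA with Tukey–Kramer post-hoc tests, Pearson correlation, and
nonparametric AUROC with Youden-index cutoffs.

## Worked example

```python
import numpy as np
from hepavisc.rheology import (RheoParams, RheoModel, DispersionCurve,
                               voigt_phase_velocity)
from hepavisc.wavefield_sim import simulate_planar_wave
from hepavisc.swe_dispersion import swe_estimate
from hepavisc.dma import simulate_dma_sweep, dma_estimate, DEFAULT_DMA_FREQS
from hepavisc.combined_fit import combined_estimate

# healthy-stage liver as SWE sees it: mu = 0.86 kPa, eta = 0.77 Pa*s
liver = RheoParams(RheoModel.VOIGT, mu=860.0, eta=0.77)
movie = simulate_planar_wave(liver, noise_sd=0.0, seed=0)
fit = swe_estimate(movie)
print(f"SWE: mu = {fit.params.mu:.1f} Pa, eta = {fit.params.eta:.3f} Pa*s")
# -> SWE: mu = 935.2 Pa, eta = 0.748 Pa*s

# the same liver on the bench (DMA band): mu = 1.12 kPa, eta = 5.40 Pa*s
bench = RheoParams(RheoModel.VOIGT, mu=1120.0, eta=5.40)
dfit = dma_estimate(simulate_dma_sweep(bench, noise_rel=0.01, seed=0))
print(f"DMA: mu = {dfit.params.mu:.1f} Pa, eta = {dfit.params.eta:.3f} Pa*s")
# -> DMA: mu = 1120.5 Pa, eta = 5.401 Pa*s

# one Voigt model across both bands (1-380 Hz)
f_dma, f_swe = DEFAULT_DMA_FREQS, np.arange(160., 381., 20.)
dc = DispersionCurve(f_dma, voigt_phase_velocity(1120., 5.40, 1000., f_dma), band="dma")
sc = DispersionCurve(f_swe, voigt_phase_velocity(860., 0.77, 1000., f_swe), band="swe")
cfit = combined_estimate(dc, sc)
print(f"combined: mu = {cfit.params.mu/1e3:.2f} kPa, eta = {cfit.params.eta:.3f} Pa*s")
# -> combined: mu = 1.43 kPa, eta = 0.685 Pa*s
```

The SWE estimate lands within ~9% of the simulated truth (band-limited
elasticity information; the 160–380 Hz response is viscosity-dominated),
the rheometer round trip is essentially exact, and the combined elasticity
sits above both band-wise values because the flat high-band plateau pins μ
near ρ·c². A full study replication — cohort table, per-rat fits, stage
summaries, ANOVA/Tukey, correlation and ROC — runs from the shell:

```
hepavisc run --seed 1 --out-dir results/study
hepavisc config --dump     # all defaults as YAML
```

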