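"""Dynamic mechanical analysis: oscillatory-shear sweeps to Voigt parameters.

A parallel-plate shear rheometer applies a sinusoidal strain and reports, per
frequency, the complex stiffness ratio F*/X* (N/m) and the stress--strain
phase lag delta. With the specimen shape factor SF = width*length/thickness
the storage and loss moduli follow as

    G'  = (F*/X*) cos(delta) / SF
    G'' = (F*/X*) sin(delta) / SF

(note: sin in the loss modulus — the imaginary part of the complex modulus
``(sigma0/eps0)(cos delta + i sin delta)``; a printed source of these
formulas carries a copy-paste error repeating cos, which would violate
G'^2 + G''^2 = (F*/X* / SF)^2). Phase velocity then follows from the
complex modulus, and a Voigt fit of the resulting 1-41 Hz dispersion curve
yields (mu, eta).

The standard sweep covers 1-41 Hz in 5 Hz steps (9 points) at 1% strain;
strain amplitude, pre-compression and bath temperature affect the instrument
but not the math and are carried as metadata only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .rheology import (
    DEFAULT_RHO,
    ComplexModulusSweep,
    DispersionCurve,
    FitResult,
    RheoModel,
    RheoParams,
    complex_modulus,
    fit_dispersion,
    phase_velocity_from_modulus,
)

__all__ = [
    "SpecimenGeometry",
    "DMARawSweep",
    "DEFAULT_DMA_FREQS",
    "shape_factor",
    "moduli_from_raw",
    "dma_dispersion",
    "simulate_dma_sweep",
    "dma_estimate",
]

#: 1-41 Hz in 5 Hz steps: the standard frequency-sweep grid (9 points).
DEFAULT_DMA_FREQS = np.arange(1.0, 42.0, 5.0)


@dataclass(frozen=True)
class SpecimenGeometry:
    """Rectangular specimen dimensions, metres (default 5 x 15 x 4 mm)."""

    width: float = 0.005
    length: float = 0.015
    thickness: float = 0.004

    def __post_init__(self) -> None:
        if min(self.width, self.length, self.thickness) <= 0:
            raise ValueError("specimen dimensions must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"width_m": self.width, "length_m": self.length, "thickness_m": self.thickness},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SpecimenGeometry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["width_m"], d["length_m"], d["thickness_m"])


@dataclass
class DMARawSweep:
    """Per-frequency stiffness ratio and phase lag from the instrument.

    stiffness_ratio is F*/X* in N/m (positive); delta is the stress-strain
    phase lag in radians, within [0, pi/2).
    """

    freqs: np.ndarray
    stiffness_ratio: np.ndarray
    delta: np.ndarray
    geometry: SpecimenGeometry = field(default_factory=SpecimenGeometry)
    strain_amplitude: float = 0.01  # metadata: 1% strain
    temperature_c: float = 38.1  # metadata: saline bath temperature

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.stiffness_ratio = np.asarray(self.stiffness_ratio, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if not (self.freqs.shape == self.stiffness_ratio.shape == self.delta.shape):
            raise ValueError("freqs, stiffness_ratio, delta must have equal length")
        if np.any(self.stiffness_ratio <= 0):
            raise ValueError("stiffness ratio must be positive")
        if np.any((self.delta < 0) | (self.delta >= np.pi / 2)):
            raise ValueError("phase lag must lie in [0, pi/2)")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "freq_hz": self.freqs,
                "stiffness_n_per_m": self.stiffness_ratio,
                "delta_rad": self.delta,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, geometry: SpecimenGeometry | None = None) -> "DMARawSweep":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["freq_hz"].to_numpy(),
            df["stiffness_n_per_m"].to_numpy(),
            df["delta_rad"].to_numpy(),
            geometry or SpecimenGeometry(),
        )


def shape_factor(geometry: SpecimenGeometry) -> float:
    """Geometry correction (width*length)/thickness, metres."""
    return geometry.width * geometry.length / geometry.thickness


def moduli_from_raw(sweep: DMARawSweep) -> ComplexModulusSweep:
    """Storage and loss moduli from a raw stiffness-and-phase sweep."""
    sf = shape_factor(sweep.geometry)
    g_storage = sweep.stiffness_ratio * np.cos(sweep.delta) / sf
    g_loss = sweep.stiffness_ratio * np.sin(sweep.delta) / sf
    return ComplexModulusSweep(sweep.freqs, g_storage, g_loss)


def dma_dispersion(moduli: ComplexModulusSweep, rho: float = DEFAULT_RHO) -> DispersionCurve:
    """Phase-velocity dispersion curve from a modulus sweep (band tag ``dma``)."""
    c = phase_velocity_from_modulus(moduli.g_storage, moduli.g_loss, rho)
    return DispersionCurve(moduli.freqs, np.asarray(c), band="dma")


def simulate_dma_sweep(
    params: RheoParams,
    geometry: SpecimenGeometry | None = None,
    noise_rel: float = 0.0,
    seed: int = 0,
    freqs: np.ndarray | None = None,
) -> DMARawSweep:
    """Synthetic instrument: invert moduli_from_raw for a model's G*(omega).

    Multiplicative Gaussian noise (relative SD ``noise_rel``) perturbs the
    stiffness ratio and additive Gaussian noise of the same scale (radians x
    noise_rel) perturbs the phase lag.
    """
    geometry = geometry or SpecimenGeometry()
    freqs = DEFAULT_DMA_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    gp, gpp = complex_modulus(params, freqs)
    sf = shape_factor(geometry)
    ratio = np.hypot(gp, gpp) * sf
    delta = np.arctan2(gpp, gp)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio * (1.0 + rng.normal(0.0, noise_rel, size=ratio.shape))
        delta = delta + rng.normal(0.0, noise_rel, size=delta.shape)
    ratio = np.maximum(ratio, 1e-12)
    delta = np.clip(delta, 0.0, np.pi / 2 - 1e-9)
    return DMARawSweep(freqs, ratio, delta, geometry)


def dma_estimate(
    sweep: DMARawSweep,
    rho: float = DEFAULT_RHO,
    model: RheoModel | str = RheoModel.VOIGT,
) -> FitResult:
    """Full chain: raw sweep -> moduli -> dispersion -> model fit."""
    curve = dma_dispersion(moduli_from_raw(sweep), rho)
    return fit_dispersion(curve, model, rho=rho)
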