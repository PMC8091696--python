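"""Rheological models of soft tissue and dispersion-curve fitting.

Three lumped-parameter models of the complex shear modulus G*(omega) are
provided:

* Kelvin--Voigt: spring mu in parallel with dashpot eta, ``G* = mu + i*omega*eta``.
  The standard model for liver shear-wave work; its phase-velocity dispersion
  relation is

      c(omega) = sqrt( 2 (mu^2 + omega^2 eta^2)
                       / (rho (mu + sqrt(mu^2 + omega^2 eta^2))) )

* Maxwell: spring and dashpot in series, ``G* = i*omega*eta*mu / (mu + i*omega*eta)``.
  Fluid-like at low frequency (G* -> 0 as omega -> 0).

* Zener (standard linear solid): spring mu in parallel with a Maxwell arm
  (mu2, eta), ``G* = mu + i*omega*eta*mu2 / (mu2 + i*omega*eta)``.
  Solid-like at both frequency extremes (G' -> mu at DC, mu + mu2 at infinity).

Phase velocity follows from the modulus through

    c = sqrt( 2 (G'^2 + G''^2) / (rho (G' + sqrt(G'^2 + G''^2))) )

which for a Voigt medium reduces exactly to the dispersion relation above.

All public interfaces take frequency in Hz; the omega = 2*pi*f conversion
happens exactly once, inside :func:`complex_modulus`.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RheoModel",
    "MediumProperties",
    "RheoParams",
    "DispersionCurve",
    "ComplexModulusSweep",
    "FitResult",
    "complex_modulus",
    "phase_velocity_from_modulus",
    "voigt_phase_velocity",
    "complex_wavenumber",
    "fit_dispersion",
    "DEFAULT_RHO",
]

#: Soft-tissue mass density convention, kg/m^3.
DEFAULT_RHO = 1000.0

# Fit bounds: mu in (0, 100 kPa], eta in [0, 100 Pa s].
_MU_LO, _MU_HI = 1e-6, 1.0e5
_ETA_LO, _ETA_HI = 0.0, 100.0


class RheoModel(str, enum.Enum):
    """Identity of the rheological model."""

    VOIGT = "voigt"
    MAXWELL = "maxwell"
    ZENER = "zener"


@dataclass(frozen=True)
class MediumProperties:
    """Bulk properties of the propagation medium.

    Parameters
    ----------
    rho : float
        Mass density in kg/m^3. Must be positive.
    """

    rho: float = DEFAULT_RHO

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")


@dataclass(frozen=True)
class RheoParams:
    """Parameters of a rheological model.

    Parameters
    ----------
    model : RheoModel
        Which lumped-parameter model the numbers belong to.
    mu : float
        Shear elasticity in Pa (the spring constant; for Zener, the
        parallel spring).
    eta : float
        Shear viscosity in Pa*s (the dashpot).
    mu2 : float, optional
        Second spring constant in Pa; required by (and only by) Zener,
        where it sits in series with the dashpot.
    """

    model: RheoModel
    mu: float
    eta: float
    mu2: float | None = None

    def __post_init__(self) -> None:
        model = RheoModel(self.model)
        object.__setattr__(self, "model", model)
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.eta < 0:
            raise ValueError(f"eta must be non-negative, got {self.eta}")
        if model is RheoModel.ZENER:
            if self.mu2 is None or self.mu2 <= 0:
                raise ValueError("zener requires mu2 > 0")
        elif self.mu2 is not None:
            raise ValueError(f"mu2 is only meaningful for zener, not {model.value}")


@dataclass
class DispersionCurve:
    """Phase velocity as a function of frequency.

    The central exchange object between the elastography pipeline, the
    bench-rheometry pipeline and the model fitters.

    Parameters
    ----------
    freqs : array
        Strictly increasing frequencies, Hz.
    c : array
        Phase velocity at each frequency, m/s, all positive.
    c_sd : array, optional
        Per-point standard deviation of c, m/s.
    band : str
        Which acquisition band the curve came from: ``"dma"``, ``"swe"``
        or ``"combined"``.
    """

    freqs: np.ndarray
    c: np.ndarray
    c_sd: np.ndarray | None = None
    band: str = "swe"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.c_sd is not None:
            self.c_sd = np.asarray(self.c_sd, dtype=float)
            if self.c_sd.shape != self.freqs.shape:
                raise ValueError("c_sd length must match freqs")
        if self.band not in ("dma", "swe", "combined"):
            raise ValueError(f"unknown band {self.band!r}")
        if self.freqs.ndim != 1 or self.freqs.size == 0:
            raise ValueError("freqs must be a non-empty 1-D array")
        if self.c.shape != self.freqs.shape:
            raise ValueError("c length must match freqs")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.c <= 0):
            raise ValueError("phase velocities must be positive")

    def __len__(self) -> int:
        return self.freqs.size

    def to_csv(self, path) -> None:
        """Write the curve as CSV with columns freq_hz, c_mps[, c_sd_mps]."""
        import pandas as pd

        cols = {"freq_hz": self.freqs, "c_mps": self.c}
        if self.c_sd is not None:
            cols["c_sd_mps"] = self.c_sd
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, band: str = "swe") -> "DispersionCurve":
        import pandas as pd

        df = pd.read_csv(path)
        sd = df["c_sd_mps"].to_numpy() if "c_sd_mps" in df.columns else None
        return cls(df["freq_hz"].to_numpy(), df["c_mps"].to_numpy(), sd, band)


@dataclass
class ComplexModulusSweep:
    """Storage and loss modulus versus frequency.

    g_storage is G' (elastic response, Pa, positive); g_loss is G''
    (dissipative response, Pa, non-negative).
    """

    freqs: np.ndarray
    g_storage: np.ndarray
    g_loss: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.g_storage = np.asarray(self.g_storage, dtype=float)
        self.g_loss = np.asarray(self.g_loss, dtype=float)
        if not (self.freqs.shape == self.g_storage.shape == self.g_loss.shape):
            raise ValueError("freqs, g_storage, g_loss must have equal length")
        if np.any(self.g_storage <= 0):
            raise ValueError("storage modulus must be positive")
        if np.any(self.g_loss < 0):
            raise ValueError("loss modulus must be non-negative")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"freq_hz": self.freqs, "g_storage_pa": self.g_storage, "g_loss_pa": self.g_loss}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ComplexModulusSweep":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["freq_hz"].to_numpy(),
            df["g_storage_pa"].to_numpy(),
            df["g_loss_pa"].to_numpy(),
        )


@dataclass
class FitResult:
    """Outcome of a dispersion-curve fit.

    r2 is the coefficient of determination computed on the fitted points;
    it is NaN when the data have zero total variance (r2 undefined).
    rss is the residual sum of squares in (m/s)^2.
    """

    params: RheoParams
    r2: float
    rss: float
    converged: bool
    n_points: int
    residuals: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.params.model.value,
            "mu_pa": self.params.mu,
            "eta_pas": self.params.eta,
            "r2": None if math.isnan(self.r2) else self.r2,
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
        }
        if self.params.mu2 is not None:
            payload["mu2_pa"] = self.params.mu2
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ----------------------------------------------------------------------------
# forward models


def complex_modulus(params: RheoParams, freq) -> tuple[np.ndarray, np.ndarray]:
    """Storage and loss modulus (G', G'') of a model at frequency ``freq`` (Hz).

    Accepts scalar or array frequency; freq must be >= 0.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    omega = 2.0 * np.pi * f
    model = RheoModel(params.model)
    if model is RheoModel.VOIGT:
        g = params.mu + 1j * omega * params.eta
    elif model is RheoModel.MAXWELL:
        # series spring+dashpot; relaxes fully at DC
        num = 1j * omega * params.eta * params.mu
        den = params.mu + 1j * omega * params.eta
        g = np.where(den == 0, 0.0, num / np.where(den == 0, 1.0, den))
    elif model is RheoModel.ZENER:
        num = 1j * omega * params.eta * params.mu2
        den = params.mu2 + 1j * omega * params.eta
        g = params.mu + num / den
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown model {params.model!r}")
    return np.real(g), np.imag(g)


def phase_velocity_from_modulus(g_storage, g_loss, rho: float = DEFAULT_RHO):
    """Shear phase velocity from the complex modulus.

    ``c = sqrt( 2 (G'^2+G''^2) / (rho (G' + sqrt(G'^2+G''^2))) )``.

    G' must be positive (the expression is undefined in the lossless-fluid
    limit G' = 0), G'' non-negative.
    """
    gp = np.asarray(g_storage, dtype=float)
    gpp = np.asarray(g_loss, dtype=float)
    if np.any(gp <= 0):
        raise ValueError("storage modulus must be positive")
    if np.any(gpp < 0):
        raise ValueError("loss modulus must be non-negative")
    if rho <= 0:
        raise ValueError("rho must be positive")
    mag = np.hypot(gp, gpp)
    c = np.sqrt(2.0 * mag**2 / (rho * (gp + mag)))
    return c if c.ndim else float(c)


def voigt_phase_velocity(mu: float, eta: float, rho: float = DEFAULT_RHO, freq=None):
    """Voigt phase velocity c(f) at frequency ``freq`` in Hz.

    Implements the Voigt dispersion relation directly; identical (to machine
    precision) to ``phase_velocity_from_modulus(mu, 2*pi*f*eta, rho)``.
    """
    if freq is None:
        raise TypeError("freq is required")
    if mu <= 0 and eta <= 0:
        raise ValueError("mu and eta cannot both be zero")
    if rho <= 0:
        raise ValueError("rho must be positive")
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    mag = np.sqrt(mu**2 + omega**2 * eta**2)
    c = np.sqrt(2.0 * mag**2 / (rho * (mu + mag)))
    return c if c.ndim else float(c)


def complex_wavenumber(params: RheoParams, rho: float = DEFAULT_RHO, freq=None):
    """Complex wavenumber k* = omega*sqrt(rho/G*) of a plane shear wave.

    Returns ``(k_re, alpha)`` with k_re = Re k* in rad/m and attenuation
    alpha = -Im k* in Np/m (alpha >= 0 for a passive medium).
    ``omega / k_re`` equals the phase velocity.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    gp, gpp = complex_modulus(params, f)
    gstar = gp + 1j * gpp
    if np.any(gstar == 0):
        raise ValueError("G* = 0: wavenumber undefined")
    omega = 2.0 * np.pi * f
    k = omega * np.sqrt(rho / gstar)
    k_re = np.real(k)
    alpha = -np.imag(k)
    if k_re.ndim:
        return k_re, alpha
    return float(k_re), float(alpha)


def model_phase_velocity(params: RheoParams, rho: float, freq):
    """Phase velocity of any model at frequency freq (Hz)."""
    gp, gpp = complex_modulus(params, freq)
    return phase_velocity_from_modulus(gp, gpp, rho)


# ----------------------------------------------------------------------------
# fitting


def _make_params(model: RheoModel, theta: np.ndarray) -> RheoParams:
    if model is RheoModel.ZENER:
        return RheoParams(model, mu=theta[0], eta=theta[1], mu2=theta[2])
    return RheoParams(model, mu=theta[0], eta=theta[1])


def _initial_grid(model: RheoModel) -> list[np.ndarray]:
    """Deterministic multi-start grid spanning (mu, eta) decades."""
    mus = [1e2, 1e3, 1e4]
    etas = [0.1, 1.0, 10.0]
    starts = []
    for m in mus:
        for e in etas:
            if model is RheoModel.ZENER:
                starts.append(np.array([m, e, m]))
            else:
                starts.append(np.array([m, e]))
    return starts


def fit_dispersion(
    curve: DispersionCurve,
    model: RheoModel | str = RheoModel.VOIGT,
    rho: float = DEFAULT_RHO,
    weights: str = "none",
) -> FitResult:
    """Nonlinear least-squares fit of a rheological model to a dispersion curve.

    Minimizes ``sum_i w_i (c_i - c_model(f_i; theta))^2`` over bounded
    parameters (mu in (0, 100 kPa], eta in [0, 100 Pa*s]) from a
    deterministic 3x3 multi-start grid over (mu, eta) decades; the start with
    the lowest residual sum of squares wins, ties broken by smaller eta.

    Parameters
    ----------
    weights : {"none", "inverse_variance"}
        ``inverse_variance`` uses 1/c_sd^2 (requires curve.c_sd); the
        default fits the mean curve unweighted.
    """
    model = RheoModel(model)
    n_min = 4 if model is RheoModel.ZENER else 3
    if len(curve) < n_min:
        raise ValueError(f"{model.value} fit needs at least {n_min} points, got {len(curve)}")
    if weights not in ("none", "inverse_variance"):
        raise ValueError(f"unknown weights {weights!r}")
    f = curve.freqs
    c = curve.c
    if weights == "inverse_variance":
        if curve.c_sd is None:
            raise ValueError("inverse_variance weighting requires c_sd")
        if np.any(curve.c_sd <= 0):
            raise ValueError("c_sd must be positive for inverse_variance weighting")
        sqrt_w = 1.0 / curve.c_sd
    else:
        sqrt_w = np.ones_like(c)

    def resid(theta: np.ndarray) -> np.ndarray:
        p = _make_params(model, theta)
        return sqrt_w * (c - model_phase_velocity(p, rho, f))

    if model is RheoModel.ZENER:
        lo = [_MU_LO, _ETA_LO, _MU_LO]
        hi = [_MU_HI, _ETA_HI, _MU_HI]
    else:
        lo = [_MU_LO, _ETA_LO]
        hi = [_MU_HI, _ETA_HI]

    best = None
    for x0 in _initial_grid(model):
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
        rss = float(np.sum(sol.fun**2))
        key = (rss, sol.x[1])  # tie-break on smaller eta
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    x_best = sol.x.copy()
    if model is RheoModel.VOIGT and x_best[1] > 0:
        # the objective is flat to machine precision in eta near 0 for
        # low-frequency data; prefer the purely elastic boundary when it
        # fits no worse
        x_zero = x_best.copy()
        x_zero[1] = 0.0
        rss_best = float(np.sum(resid(x_best) ** 2))
        signal = float(np.sum((sqrt_w * c) ** 2))
        if float(np.sum(resid(x_zero) ** 2)) <= rss_best + 1e-15 * signal:
            x_best = x_zero
    params = _make_params(model, x_best)
    res = sqrt_w * (c - model_phase_velocity(params, rho, f))
    rss = float(np.sum(res**2))
    cbar = np.average(c, weights=sqrt_w**2)
    tss = float(np.sum((sqrt_w * (c - cbar)) ** 2))
    r2 = float("nan") if tss == 0.0 else 1.0 - rss / tss
    return FitResult(
        params=params,
        r2=r2,
        rss=rss,
        converged=bool(sol.success),
        n_points=len(curve),
        residuals=res,
    )
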