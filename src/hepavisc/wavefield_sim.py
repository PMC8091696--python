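"""Synthetic planar shear-wave movies in a viscoelastic medium.

A stand-in for the ultrafast ultrasound acquisition: instead of modelling the
acoustic-radiation-force push and beamforming, the wave enters the field of
view as a plane front at the first lateral column (x = 0), uniform along
depth, and propagates in +x with the dispersion and attenuation dictated by
the medium's complex wavenumber k*(f) = 2*pi*f*sqrt(rho/G*(f)).

The source is a band-limited pulse: a Gaussian magnitude spectrum (zero phase
at x = 0, t = t0) sampled on a fine frequency grid, so the particle-velocity
trace at each position is a short transient that enters and leaves the
observation window -- the same situation the spectral phase analysis of the
processing pipeline assumes.

An optional single reflected wave (mirrored at the far lateral boundary)
exercises the pipeline's directional filter, and additive white Gaussian
noise models tracking jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .rheology import RheoParams, RheoModel, complex_wavenumber, DEFAULT_RHO

__all__ = [
    "AcquisitionConfig",
    "SourceSpectrum",
    "WavefieldMovie",
    "simulate_planar_wave",
    "velocity_to_iq",
    "save_movie",
    "load_movie",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Ultrafast-tracking acquisition geometry and timing.

    Defaults: 10 kHz pulse repetition frequency, 50 tracked frames at
    6.25 MHz carrier, region of interest 5 mm axially by 15 mm laterally.
    """

    prf: float = 10_000.0  # Hz
    n_frames: int = 50
    roi_axial: float = 0.005  # m
    roi_lateral: float = 0.015  # m
    pitch_axial: float = 5e-5  # m
    pitch_lateral: float = 1e-4  # m
    carrier_freq: float = 6.25e6  # Hz
    sound_speed: float = 1540.0  # m/s

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError("prf must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if min(self.pitch_axial, self.pitch_lateral) <= 0:
            raise ValueError("pitches must be positive")
        if min(self.roi_axial, self.roi_lateral) <= 0:
            raise ValueError("ROI dimensions must be positive")

    @property
    def n_z(self) -> int:
        return int(round(self.roi_axial / self.pitch_axial))

    @property
    def n_x(self) -> int:
        return int(round(self.roi_lateral / self.pitch_lateral))

    @property
    def x(self) -> np.ndarray:
        """Lateral coordinates of the grid columns, m."""
        return np.arange(self.n_x) * self.pitch_lateral

    @property
    def t(self) -> np.ndarray:
        """Frame times, s."""
        return np.arange(self.n_frames) / self.prf


@dataclass(frozen=True)
class SourceSpectrum:
    """Magnitude spectrum of the injected shear pulse.

    The source mimics an impulsive radiation-force push: a differentiated-
    Gaussian velocity pulse whose magnitude spectrum is

        A(f) = (f / f_peak)^dc_order * exp(dc_order/2 - 2 pi^2 sigma_t^2 f^2)

    (normalized to 1 at the spectral peak ``f_peak =
    sqrt(dc_order)/(2 pi sigma_t)``). It is exactly zero at DC, rolls off
    smoothly at both ends, and its time-domain support is a few
    ``pulse_width`` -- short enough to enter and leave the millisecond-scale
    observation window, which the spectral phase analysis downstream
    requires. The defaults (pulse_width 0.3 ms, dc_order 2, peak near
    750 Hz) cover the 160-380 Hz analysis band with substantial amplitude.
    """

    pulse_width: float = 3.0e-4  # Gaussian time constant sigma_t, s
    dc_order: int = 2  # order of the zero at f = 0

    def __post_init__(self) -> None:
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if self.dc_order < 1:
            raise ValueError("dc_order must be >= 1")

    @property
    def peak_freq(self) -> float:
        """Frequency of the spectral magnitude peak, Hz."""
        return math.sqrt(self.dc_order) / (2.0 * np.pi * self.pulse_width)

    def amplitude(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        n = self.dc_order
        return (f / self.peak_freq) ** n * np.exp(
            n / 2.0 - 2.0 * np.pi**2 * self.pulse_width**2 * f**2
        )


@dataclass
class WavefieldMovie:
    """Particle-velocity (and optionally IQ) movie on a (z, x, t) grid."""

    v: np.ndarray  # m/s, shape (n_z, n_x, n_t)
    config: AcquisitionConfig
    iq: np.ndarray | None = None  # complex, same shape
    truth: RheoParams | None = None
    prf: float | None = None  # effective frame rate; differs from config after interpolation

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 3:
            raise ValueError("v must be (n_z, n_x, n_t)")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("non-finite values in v")
        if self.prf is None:
            self.prf = self.config.prf

    @property
    def n_t(self) -> int:
        return self.v.shape[2]

    def copy_with(self, v: np.ndarray | None = None, **kw) -> "WavefieldMovie":
        return WavefieldMovie(
            v=self.v if v is None else v,
            config=self.config,
            iq=kw.get("iq", self.iq),
            truth=self.truth,
            prf=kw.get("prf", self.prf),
        )


def _frequency_grid(source: SourceSpectrum, prf: float, df: float = 10.0) -> np.ndarray:
    """Synthesis frequencies: df-spaced, up to where the spectrum is negligible.

    The grid extends to the frequency where the magnitude has fallen to 1e-4
    of peak; that frequency must stay below Nyquist (prf/2).
    """
    f = np.arange(df, prf / 2.0, df)
    a = source.amplitude(f)
    keep = a >= 1e-4
    if keep[-1]:
        raise ValueError("source band reaches Nyquist; shorten the pulse or raise prf")
    return f[: int(np.max(np.nonzero(keep)[0])) + 1]


def simulate_planar_wave(
    params: RheoParams,
    rho: float = DEFAULT_RHO,
    config: AcquisitionConfig | None = None,
    source: SourceSpectrum | None = None,
    noise_sd: float | None = None,
    reflect_coeff: float = 0.0,
    seed: int = 0,
    t0: float = 1.5e-3,
    amplitude: float = 1.0e-3,
) -> WavefieldMovie:
    """Simulate a planar shear-wave particle-velocity movie.

    The field is a superposition over the source band:

        v(z, x, t) = sum_f A(f) exp(-alpha(f) x) cos(2 pi f (t - t0) - k(f) x)
                     + reflect_coeff * (mirrored term propagating in -x)
                     + white Gaussian noise

    uniform along z (plane front). The reflected term is the forward wave
    mirrored at the far lateral boundary, i.e. it has travelled to
    x = L and back, with the corresponding extra attenuation.

    Parameters
    ----------
    noise_sd : float, optional
        Standard deviation of additive velocity noise, m/s. Default is 5% of
        the peak noiseless |v|; pass 0 for a clean movie.
    reflect_coeff : float
        Amplitude reflection coefficient in [0, 1] at the far boundary.
    t0 : float
        Pulse center time at x = 0, s.
    amplitude : float
        Peak spectral amplitude scale, m/s per frequency component.
    """
    config = config or AcquisitionConfig()
    source = source or SourceSpectrum()
    if not 0.0 <= reflect_coeff <= 1.0:
        raise ValueError("reflect_coeff must be in [0, 1]")
    freqs = _frequency_grid(source, config.prf)
    amps = amplitude * source.amplitude(freqs)
    k_re, alpha = complex_wavenumber(params, rho, freqs)
    x = config.x  # (n_x,)
    t = config.t  # (n_t,)
    L = config.roi_lateral

    # phase(f, x, t) = 2 pi f (t - t0) - k x ; broadcast (n_f, n_x, n_t)
    wt = 2.0 * np.pi * freqs[:, None] * (t[None, :] - t0)  # (n_f, n_t)
    decay = np.exp(-alpha[:, None] * x[None, :])  # (n_f, n_x)
    kx = k_re[:, None] * x[None, :]  # (n_f, n_x)
    field2d = np.einsum(
        "fx,fxt->xt", amps[:, None] * decay, np.cos(wt[:, None, :] - kx[:, :, None])
    )
    if reflect_coeff > 0.0:
        # mirrored at x = L: total path L + (L - x), propagating in -x
        path = 2.0 * L - x
        decay_r = np.exp(-alpha[:, None] * path[None, :])
        kx_r = k_re[:, None] * path[None, :]
        field2d = field2d + reflect_coeff * np.einsum(
            "fx,fxt->xt", amps[:, None] * decay_r, np.cos(wt[:, None, :] - kx_r[:, :, None])
        )

    v = np.broadcast_to(field2d[None, :, :], (config.n_z,) + field2d.shape).copy()
    if noise_sd is None:
        noise_sd = 0.05 * np.max(np.abs(field2d))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v += rng.normal(0.0, noise_sd, size=v.shape)
    return WavefieldMovie(v=v, config=config, truth=params)


def velocity_to_iq(movie: WavefieldMovie, a0: float = 1.0) -> WavefieldMovie:
    """Synthesize complex baseband (IQ) samples from the velocity movie.

    The scatterer displacement is the cumulative time-integral of v; the IQ
    sample is phase-modulated by the round-trip path change,
    ``iq = a0 * exp(i * 4 pi f_c d / c_sound)``. The pipeline's lag-one
    autocorrelator inverts this relation for sub-wavelength displacements.
    """
    cfg = movie.config
    dt = 1.0 / movie.prf
    # trapezoidal cumulative integral, d(t=0) = 0
    d = np.concatenate(
        [
            np.zeros(movie.v.shape[:2] + (1,)),
            np.cumsum(0.5 * (movie.v[..., 1:] + movie.v[..., :-1]) * dt, axis=-1),
        ],
        axis=-1,
    )
    iq = a0 * np.exp(1j * 4.0 * np.pi * cfg.carrier_freq * d / cfg.sound_speed)
    return movie.copy_with(iq=iq)


def save_movie(movie: WavefieldMovie, path) -> None:
    """Store a movie as HDF5 (/v, optional /iq, config and truth as attrs)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("v", data=movie.v)
        if movie.iq is not None:
            fh.create_dataset("iq", data=movie.iq)
        for key, val in asdict(movie.config).items():
            fh.attrs[f"config_{key}"] = val
        fh.attrs["prf_effective"] = movie.prf
        if movie.truth is not None:
            fh.attrs["truth_model"] = movie.truth.model.value
            fh.attrs["truth_mu"] = movie.truth.mu
            fh.attrs["truth_eta"] = movie.truth.eta
            if movie.truth.mu2 is not None:
                fh.attrs["truth_mu2"] = movie.truth.mu2


def load_movie(path) -> WavefieldMovie:
    import h5py

    with h5py.File(path, "r") as fh:
        v = fh["v"][...]
        iq = fh["iq"][...] if "iq" in fh else None
        cfg_kw = {
            key[len("config_"):]: val.item() if hasattr(val, "item") else val
            for key, val in fh.attrs.items()
            if key.startswith("config_")
        }
        cfg_kw["n_frames"] = int(cfg_kw["n_frames"])
        config = AcquisitionConfig(**cfg_kw)
        truth = None
        if "truth_model" in fh.attrs:
            truth = RheoParams(
                RheoModel(str(fh.attrs["truth_model"])),
                mu=float(fh.attrs["truth_mu"]),
                eta=float(fh.attrs["truth_eta"]),
                mu2=float(fh.attrs["truth_mu2"]) if "truth_mu2" in fh.attrs else None,
            )
        prf = float(fh.attrs.get("prf_effective", config.prf))
    return WavefieldMovie(v=v, config=config, iq=iq, truth=truth, prf=prf)
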