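"""Combined low- and high-frequency Voigt analysis.

Bench rheometry (1-41 Hz) and shear-wave elastography (160-380 Hz) probe
non-overlapping frequency bands; fitting one Kelvin--Voigt model across the
merged 1-380 Hz dispersion data constrains (mu, eta) far better than either
band alone, because the elastic plateau dominates the low band and the
viscous rise dominates the high band. The 41-160 Hz gap is left empty -- no
pseudo-data are interpolated into it.
"""

from __future__ import annotations

import warnings

import numpy as np

from .rheology import (
    DEFAULT_RHO,
    DispersionCurve,
    FitResult,
    RheoModel,
    fit_dispersion,
)

__all__ = ["merge_curves", "combined_estimate"]


def merge_curves(dma_curve: DispersionCurve, swe_curve: DispersionCurve) -> DispersionCurve:
    """Concatenate a DMA-band and an SWE-band curve into one combined curve.

    Frequencies must not overlap between the bands (no averaging rule is
    defined for duplicate frequencies). Per-point standard deviations are
    carried through where both curves have them.
    """
    if dma_curve.band != "dma":
        raise ValueError(f"first curve must have band 'dma', got {dma_curve.band!r}")
    if swe_curve.band != "swe":
        raise ValueError(f"second curve must have band 'swe', got {swe_curve.band!r}")
    if np.intersect1d(dma_curve.freqs, swe_curve.freqs).size:
        raise ValueError("bands overlap in frequency; no merge rule defined")
    freqs = np.concatenate([dma_curve.freqs, swe_curve.freqs])
    c = np.concatenate([dma_curve.c, swe_curve.c])
    order = np.argsort(freqs)
    if dma_curve.c_sd is not None and swe_curve.c_sd is not None:
        sd = np.concatenate([dma_curve.c_sd, swe_curve.c_sd])[order]
    else:
        sd = None
    return DispersionCurve(freqs[order], c[order], sd, band="combined")


def combined_estimate(
    dma_curve: DispersionCurve | None,
    swe_curve: DispersionCurve | None,
    rho: float = DEFAULT_RHO,
    weights: str = "none",
) -> FitResult:
    """Voigt fit over the merged 1-380 Hz dispersion data.

    With only one band supplied the fit degenerates to that band alone (a
    warning is raised). Weighting defaults to unweighted -- per-stage fits
    operate on mean curves; pass ``"inverse_variance"`` to use per-point
    standard deviations.
    """
    if dma_curve is None and swe_curve is None:
        raise ValueError("at least one band is required")
    if dma_curve is None or swe_curve is None:
        warnings.warn("single-band input: combined fit degenerates to a plain band fit")
        curve = dma_curve if dma_curve is not None else swe_curve
    else:
        curve = merge_curves(dma_curve, swe_curve)
    return fit_dispersion(curve, RheoModel.VOIGT, rho=rho, weights=weights)


def band_residuals(
    result: FitResult, curve: DispersionCurve, rho: float = DEFAULT_RHO
) -> dict[str, float]:
    """Residual sum of squares split by band for a combined-curve fit."""
    from .rheology import model_phase_velocity

    res = curve.c - model_phase_velocity(result.params, rho, curve.freqs)
    low = curve.freqs <= 41.0
    return {
        "rss_dma": float(np.sum(res[low] ** 2)),
        "rss_swe": float(np.sum(res[~low] ** 2)),
    }
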