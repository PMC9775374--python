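"""Spectral conditioning: baseline, smoothing, normalization, SD-IR.

The conditioning chain mirrors standard FTIR practice for serum spectra:
linear two-anchor baseline correction, Savitzky-Golay smoothing, vector (or
min-max) normalization, and the Savitzky-Golay second derivative (SD-IR), in
which absorption band maxima appear as local minima.  A wet-minus-dry
differential removes the residual liquid-water background before analysis.

All filters delegate to :func:`scipy.signal.savgol_filter`; the second
derivative is taken with respect to wavenumber (units a.u. * cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectrum import Spectrum


@dataclass
class PreprocessConfig:
    """Defaults for the conditioning chain.

    The study names the algorithms but not their parameters.  The window
    defaults are deliberately short (smoothing +/-6 cm^-1, derivative
    +/-8 cm^-1 at 2 cm^-1 spacing): longer windows act as a wide convolution
    kernel that lets neighboring bands ~25 cm^-1 apart pull each other's
    SD-IR minima by several tenths of a cm^-1, which would swamp the 1.8-3
    cm^-1 group shifts of interest.  All parameters are config and logged.
    """

    smooth_window: int = 7
    smooth_order: int = 3
    deriv_window: int = 9
    deriv_order: int = 3
    normalization: str = "vector"  # or "minmax"
    baseline_anchor_fraction: float = 0.02
    range_cm: tuple = (900.0, 3500.0)  # working range after conditioning

    def __post_init__(self) -> None:
        for w, o in ((self.smooth_window, self.smooth_order), (self.deriv_window, self.deriv_order)):
            if w % 2 == 0:
                raise ValueError("Savitzky-Golay window must be odd")
            if w <= o:
                raise ValueError("Savitzky-Golay window must exceed polynomial order")
        if self.deriv_order < 2:
            raise ValueError("second derivative needs polynomial order >= 2")
        if not 0 < self.baseline_anchor_fraction <= 0.5:
            raise ValueError("baseline_anchor_fraction must lie in (0, 0.5]")


def baseline_correct(spectrum: Spectrum, anchor_fraction: float = 0.02) -> Spectrum:
    """Subtract the line through the minima of the first/last anchor windows.

    The anchor windows are the leading and trailing ``anchor_fraction`` of the
    grid (at least 2 points each).  A pure line maps to zero; re-application
    is idempotent because the anchor minima of a corrected spectrum are the
    anchor points themselves.
    """
    n = spectrum.wavenumbers.size
    k = max(2, int(round(anchor_fraction * n)))
    if 2 * k > n:
        raise ValueError("anchor windows overlap; reduce anchor_fraction")
    i_lo = int(np.argmin(spectrum.absorbance[:k]))
    i_hi = n - k + int(np.argmin(spectrum.absorbance[-k:]))
    x0, y0 = spectrum.wavenumbers[i_lo], spectrum.absorbance[i_lo]
    x1, y1 = spectrum.wavenumbers[i_hi], spectrum.absorbance[i_hi]
    slope = (y1 - y0) / (x1 - x0)
    line = y0 + slope * (spectrum.wavenumbers - x0)
    return spectrum.with_absorbance(spectrum.absorbance - line)


def smooth(spectrum: Spectrum, window: int = 11, order: int = 3) -> Spectrum:
    """Savitzky-Golay 0th-derivative smoothing (exact on degree <= order)."""
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and exceed the polynomial order")
    if window > spectrum.wavenumbers.size:
        raise ValueError("window exceeds grid length")
    return spectrum.with_absorbance(savgol_filter(spectrum.absorbance, window, order))


def normalize(spectrum: Spectrum, mode: str = "vector") -> Spectrum:
    """Unit-Euclidean-norm ("vector") or [0, 1] ("minmax") normalization."""
    a = spectrum.absorbance
    if mode == "vector":
        nrm = float(np.linalg.norm(a))
        if nrm == 0.0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return spectrum.with_absorbance(a / nrm)
    if mode == "minmax":
        rng = float(a.max() - a.min())
        if rng == 0.0:
            raise ValueError("cannot min-max normalize a constant spectrum")
        return spectrum.with_absorbance((a - a.min()) / rng)
    raise ValueError(f"unknown normalization mode {mode!r}")


def second_derivative(spectrum: Spectrum, window: int = 13, order: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative w.r.t. wavenumber.

    Absorption maxima appear as local minima of the output.  The half-window
    at each grid edge is polynomial extrapolation; band search downstream
    stays clear of the edges.
    """
    if window % 2 == 0 or window <= order or order < 2:
        raise ValueError("window must be odd, window > order >= 2")
    if window > spectrum.wavenumbers.size:
        raise ValueError("window exceeds grid length")
    d2 = savgol_filter(spectrum.absorbance, window, order, deriv=2, delta=spectrum.step)
    return spectrum.with_absorbance(d2)


def differential_spectrum(wet: Spectrum, dry: Spectrum) -> Spectrum:
    """Pointwise wet - dry on identical grids (recovers the water background)."""
    if wet.wavenumbers.size != dry.wavenumbers.size or not np.allclose(
        wet.wavenumbers, dry.wavenumbers, rtol=0, atol=1e-9
    ):
        raise ValueError("wet and dry spectra must share an identical grid")
    out = wet.with_absorbance(wet.absorbance - dry.absorbance)
    out.meta["state"] = "differential"
    return out


def conditioned(spectrum: Spectrum, config: PreprocessConfig | None = None) -> dict:
    """Full chain for one spectrum.

    Returns ``{"raw": baseline-corrected/smoothed/clipped spectrum,
    "norm": its vector-normalized form, "sd": SD-IR of the normalized form}``.
    Band amplitudes for Table-1-style relative absorbance are read from
    ``"raw"``; classification features are read from ``"norm"``/``"sd"``.
    """
    config = config or PreprocessConfig()
    s = baseline_correct(spectrum, config.baseline_anchor_fraction)
    s = smooth(s, config.smooth_window, config.smooth_order)
    s = s.clip(*config.range_cm)
    norm = normalize(s, config.normalization)
    sd = second_derivative(norm, config.deriv_window, config.deriv_order)
    return {"raw": s, "norm": norm, "sd": sd}
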