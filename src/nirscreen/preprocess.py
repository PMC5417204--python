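"""Spectral preprocessing: replicate averaging, absorbance conversion,
Savitzky–Golay smoothing / second derivative, and baseline subtraction.

Two fixed pipelines mirror the two analysis branches:

* qualitative (library matching): average → absorbance → Savitzky–Golay
  second derivative;
* quantitative (regression): average → absorbance → Savitzky–Golay
  smoothing → linear-endpoint baseline subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumState

__all__ = [
    "PreprocessConfig",
    "average_replicates",
    "to_absorbance",
    "savitzky_golay",
    "second_derivative",
    "subtract_baseline",
    "preprocess_qualitative",
    "preprocess_quantitative",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter and baseline settings shared by both pipelines."""

    window: int = 11
    polyorder: int = 3
    baseline: str = "linear_endpoints"  # or "none"

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError(f"window must be odd, got {self.window}")
        if self.window <= self.polyorder:
            raise ValueError("window must exceed polyorder")
        if self.baseline not in ("linear_endpoints", "none"):
            raise ValueError("baseline must be 'linear_endpoints' or 'none'")


def average_replicates(scans) -> Spectrum:
    """Pointwise mean of replicate scans sharing one grid and state."""
    scans = list(scans)
    if not scans:
        raise ValueError("need at least one scan to average")
    first = scans[0]
    for s in scans[1:]:
        if s.state is not first.state:
            raise ValueError(f"mixed states: {first.state.value} vs {s.state.value}")
        if not s.same_grid(first):
            raise ValueError("replicate scans are on different grids")
    mean = np.mean([s.values for s in scans], axis=0)
    out = first.copy_with(mean, first.state, n_replicates=len(scans))
    out.meta.pop("replicate", None)
    return out


def to_absorbance(spectrum: Spectrum) -> Spectrum:
    """A(λ) = -log10 R(λ)."""
    if spectrum.state is not SpectrumState.REFLECTANCE:
        raise ValueError(f"expected reflectance spectrum, got {spectrum.state.value}")
    if np.any(spectrum.values <= 0):
        bad = spectrum.wavelengths[np.argmax(spectrum.values <= 0)]
        raise ValueError(f"non-positive reflectance at {bad:g} nm")
    return spectrum.copy_with(-np.log10(spectrum.values), SpectrumState.ABSORBANCE)


def _uniform_spacing(wavelengths: np.ndarray) -> float:
    d = np.diff(wavelengths)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError("Savitzky–Golay filtering requires a uniform wavelength grid")
    return float(d[0])


def savitzky_golay(spectrum: Spectrum, window: int, polyorder: int, deriv: int = 0) -> Spectrum:
    """Sliding least-squares polynomial fit, optionally differentiated.

    Output units are input units per nm**deriv (the derivative is scaled by
    the grid spacing). Edges are handled by evaluating the terminal-window
    polynomial fits, so the output grid equals the input grid.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if deriv > polyorder:
        raise ValueError("deriv must not exceed polyorder")
    if len(spectrum) < window:
        raise ValueError(f"spectrum length {len(spectrum)} shorter than window {window}")
    delta = _uniform_spacing(spectrum.wavelengths)
    values = savgol_filter(
        spectrum.values, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=delta, mode="interp",
    )
    state = SpectrumState.SECOND_DERIVATIVE if deriv == 2 else SpectrumState.SMOOTHED
    return spectrum.copy_with(values, state)


def second_derivative(spectrum: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky–Golay second derivative (absorbance per nm²)."""
    return savitzky_golay(spectrum, window, polyorder, deriv=2)


def subtract_baseline(spectrum: Spectrum, mode: str = "linear_endpoints") -> Spectrum:
    """Remove the straight line through the means of the first and last
    5 points; ``mode='none'`` is the identity."""
    if mode == "none":
        return spectrum.copy_with(spectrum.values, spectrum.state)
    if mode != "linear_endpoints":
        raise ValueError(f"unknown baseline mode {mode!r}")
    if spectrum.state not in (SpectrumState.ABSORBANCE, SpectrumState.SMOOTHED):
        raise ValueError(
            f"baseline subtraction expects absorbance or smoothed state, got {spectrum.state.value}"
        )
    if len(spectrum) < 10:
        raise ValueError("need >= 10 points for linear_endpoints baseline")
    w, v = spectrum.wavelengths, spectrum.values
    x0, y0 = w[:5].mean(), v[:5].mean()
    x1, y1 = w[-5:].mean(), v[-5:].mean()
    slope = (y1 - y0) / (x1 - x0)
    line = y0 + slope * (w - x0)
    return spectrum.copy_with(v - line, spectrum.state)


def preprocess_qualitative(scans, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """average → absorbance → second derivative (library-matching input)."""
    avg = average_replicates(scans)
    absb = to_absorbance(avg)
    return savitzky_golay(absb, config.window, config.polyorder, deriv=2)


def preprocess_quantitative(scans, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """average → absorbance → smooth → baseline subtraction (regression input)."""
    avg = average_replicates(scans)
    absb = to_absorbance(avg)
    smoothed = savitzky_golay(absb, config.window, config.polyorder, deriv=0)
    return subtract_baseline(smoothed, config.baseline)
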