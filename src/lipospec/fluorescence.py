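"""Fluorescence analytics: anisotropy, calcein release, Beer-Lambert dye
quantification and emission-peak location.

Formulas:

* G factor:       G = I_HV / I_HH
* anisotropy:     r = (I_VV - G I_VH) / (I_VV + 2 G I_VH)
* calcein release (percent of encapsulated dye escaped before detergent
  lysis):  CR = (I_t/I_max,t - I_0/I_max,0) * I_max,t / (I_max,t - I_0) * 100
* Beer-Lambert:   c = A / (epsilon * l)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PolarizedIntensities:
    """One polarized quadruple; first subscript = excitation polarizer,
    second = emission polarizer (V vertical, H horizontal)."""

    I_VV: float
    I_VH: float
    I_HV: float
    I_HH: float

    def __post_init__(self):
        vals = (self.I_VV, self.I_VH, self.I_HV, self.I_HH)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("all polarized intensities must be positive and finite")


@dataclass(frozen=True)
class ReleaseTimepoint:
    """Fluorescence readings at incubation time t, before (I) and after
    (I_max) Triton X-100 lysis; the 0-subscript pair is the reference
    measured immediately after dilution."""

    t: float
    I_0: float
    I_max0: float
    I_t: float
    I_maxt: float

    def __post_init__(self):
        if not (self.I_max0 > self.I_0 >= 0):
            raise ValueError("require I_max0 > I_0 >= 0")
        if self.I_maxt <= 0:
            raise ValueError("I_maxt must be positive")
        if self.I_maxt < self.I_t:
            raise ValueError("lysis intensity I_maxt cannot be below I_t")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Emission intensity on an ascending wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensity", it)
        if wl.size != it.size or wl.size < 2:
            raise ValueError("wavelengths and intensity must be equal-length arrays (>= 2 points)")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(it))):
            raise ValueError("emission spectrum contains non-finite values")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")


def g_factor(i_hv: float, i_hh: float) -> float:
    """Instrument polarization correction G = I_HV / I_HH."""
    if i_hh == 0:
        raise ZeroDivisionError("I_HH must be non-zero")
    return i_hv / i_hh


def anisotropy(p: PolarizedIntensities) -> float:
    """Fluorescence anisotropy r from a polarized quadruple.

    r ranges from 0 (freely rotating fluorophore) to 0.4 (immobile limit for
    one-photon excitation); values outside [0, 0.4] are returned unchanged
    with a warning, since noisy triplicates may straddle the bounds.
    """
    g = g_factor(p.I_HV, p.I_HH)
    denom = p.I_VV + 2.0 * g * p.I_VH
    if denom == 0:
        raise ZeroDivisionError("anisotropy denominator I_VV + 2 G I_VH is zero")
    r = (p.I_VV - g * p.I_VH) / denom
    if not 0.0 <= r <= 0.4:
        warnings.warn(f"anisotropy {r:.4f} outside the physical range [0, 0.4]", stacklevel=2)
    return r


def calcein_release(tp: ReleaseTimepoint) -> float:
    """Percent of calcein released at time t, from dequenching before/after
    detergent lysis.  Returned unclipped: noise can push CR slightly below 0
    or above 100, and clipping would bias triplicate means."""
    if tp.I_maxt == tp.I_0:
        raise ZeroDivisionError("I_maxt equals I_0; release fraction undefined")
    cr = (tp.I_t / tp.I_maxt - tp.I_0 / tp.I_max0) * tp.I_maxt / (tp.I_maxt - tp.I_0) * 100.0
    if not -5.0 <= cr <= 105.0:
        warnings.warn(f"calcein release {cr:.1f}% far outside [0, 100]", stacklevel=2)
    return cr


def release_curve(timepoints: list[ReleaseTimepoint]) -> np.ndarray:
    """CR (%) for each timepoint, in input order."""
    return np.array([calcein_release(tp) for tp in timepoints])


def dye_concentration(absorbance: float, epsilon: float = 74_000.0, path: float = 1.0) -> float:
    """Molar dye concentration by Beer-Lambert, c = A / (epsilon * l).

    Defaults fit calcein quantification at 504 nm (epsilon 74,000 M^-1 cm^-1,
    1 cm cuvette).
    """
    if epsilon <= 0:
        raise ValueError("molar absorptivity must be positive")
    if path <= 0:
        raise ValueError("path length must be positive")
    return absorbance / (epsilon * path)


def emission_peak(
    s: EmissionSpectrum, window_low: float, window_high: float
) -> tuple[float, float]:
    """Wavelength and intensity of the emission maximum within a window.

    Reported at grid resolution; ties and monotone edges resolve to the
    lowest wavelength, with a warning when the maximum sits on a window
    boundary or the window is flat.
    """
    mask = (s.wavelengths >= window_low) & (s.wavelengths <= window_high)
    if not mask.any():
        raise ValueError(f"window [{window_low}, {window_high}] contains no grid points")
    wl, it = s.wavelengths[mask], s.intensity[mask]
    idx = int(np.argmax(it))  # argmax takes the first (lowest-wavelength) tie
    if np.all(it == it[0]):
        warnings.warn("flat emission spectrum in window; returning first grid point", stacklevel=2)
    elif idx in (0, it.size - 1):
        warnings.warn("emission maximum on window boundary", stacklevel=2)
    return float(wl[idx]), float(it[idx])


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and SD (ddof=1) of replicate measurements, e.g. triplicate CR."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two replicates")
    return float(arr.mean()), float(arr.std(ddof=1))
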