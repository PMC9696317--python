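"""Ground-truth-labelled synthetic data: spectra, polarized intensities,
dye-leakage traces.

These generators stand in for the spectrometer and fluorimeter so that every
analysis stage can be tested against known truth.  At zero noise each
generator is the exact inverse of the corresponding analysis operation:
``anisotropy(gen_polarized(r, g)) == r``, the calcein-release formula applied
to a noiseless trace returns the underlying released fraction, and band
centers/areas of a generated spectrum match the requested components.

All randomness is funnelled through ``numpy.random.default_rng(seed)``;
identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluorescence import PolarizedIntensities, ReleaseTimepoint
from .types import BandComponent, Spectrum


@dataclass(frozen=True)
class GroundTruthSpectrumSpec:
    """True parameters of a synthetic absorbance spectrum.

    The spectrum is a sum of pseudo-Voigt bands on a straight baseline with
    iid Gaussian noise on absorbance (the white-noise model that
    Savitzky-Golay smoothing presumes).
    """

    components: tuple[BandComponent, ...]
    grid_start: float = 900.0
    grid_end: float = 3000.0
    grid_step: float = 1.0
    baseline_slope: float = 0.0   # absorbance per cm^-1
    baseline_offset: float = 0.0  # absorbance
    noise_sd: float = 0.0         # absorbance a.u.
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise ValueError("at least one band component is required")
        if not self.grid_start < self.grid_end:
            raise ValueError("grid_start must be below grid_end")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        params = [self.grid_start, self.grid_end, self.grid_step,
                  self.baseline_slope, self.baseline_offset, self.noise_sd]
        if not np.isfinite(params).all():
            raise ValueError("spectrum spec parameters must be finite")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_end - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def gen_spectrum(spec: GroundTruthSpectrumSpec) -> Spectrum:
    """Evaluate ``sum(bands) + baseline + noise`` on the regular grid."""
    x = spec.grid
    y = spec.baseline_offset + spec.baseline_slope * (x - x[0])
    for comp in spec.components:
        y = y + comp(x)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, x.size)
    return Spectrum(x, y)


def gen_polarized(
    r_true: float,
    g_true: float,
    total_intensity: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PolarizedIntensities:
    """Polarized intensity quadruple with known anisotropy and G factor.

    Inverts the anisotropy formula r = (I_VV - G I_VH)/(I_VV + 2 G I_VH) with
    G = I_HV/I_HH: setting S = I_VV + 2 G I_VH = ``total_intensity`` gives
    I_VV = S(1+2r)/3 and I_VH = S(1-r)/(3G).  At zero noise the round trip
    through the analysis formulas is exact.
    """
    if not -0.5 < r_true < 1.0:
        raise ValueError("r_true must lie in (-0.5, 1)")
    if g_true <= 0:
        raise ValueError("g_true must be positive")
    if total_intensity <= 0:
        raise ValueError("total_intensity must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    s = float(total_intensity)
    i_vv = s * (1.0 + 2.0 * r_true) / 3.0
    i_vh = s * (1.0 - r_true) / (3.0 * g_true)
    i_hh = s / 4.0
    i_hv = g_true * i_hh
    vals = np.array([i_vv, i_vh, i_hv, i_hh])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, 4)
        vals = np.maximum(vals, 1e-12)  # intensities stay physical
    return PolarizedIntensities(*vals)


@dataclass(frozen=True)
class GroundTruthReleaseSpec:
    """First-order dye-leakage kinetics with a known rate.

    The underlying released fraction follows
    ``f(t) = 1 - (1 - I0_fraction) * exp(-leak_rate * t)``.  Fluorescence is
    modelled with a residual self-quenching yield ``quench_residual``:
    encapsulated dye emits that fraction of its dequenched intensity, so the
    detergent-lysed reading I_max is constant while I_t grows with release.
    Noise is multiplicative (photometric noise scales with signal).
    """

    leak_rate: float            # fraction released per minute
    duration: float = 60.0      # minutes
    sampling: float = 5.0       # minutes between readings
    I0_fraction: float = 0.0    # fraction already released at t = 0
    noise_sd: float = 0.0       # relative (multiplicative) noise
    seed: int = 0
    quench_residual: float = 0.1
    max_intensity: float = 1000.0

    def __post_init__(self):
        if self.leak_rate < 0:
            raise ValueError("leak_rate must be non-negative")
        if not 0.0 <= self.I0_fraction < 1.0:
            raise ValueError("I0_fraction must lie in [0, 1)")
        if self.duration <= 0 or self.sampling <= 0:
            raise ValueError("duration and sampling must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.quench_residual < 1.0:
            raise ValueError("quench_residual must lie in [0, 1)")

    def released_fraction(self, t: np.ndarray | float) -> np.ndarray | float:
        return 1.0 - (1.0 - self.I0_fraction) * np.exp(-self.leak_rate * np.asarray(t, dtype=float))

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.sampling + 1e-9))
        return self.sampling * np.arange(n + 1)


def gen_release_trace(spec: GroundTruthReleaseSpec) -> list[ReleaseTimepoint]:
    """Kinetic timepoint tuples (t, I_0, I_max0, I_t, I_maxt).

    At zero noise the calcein-release formula applied to each timepoint
    recovers ``(f(t) - f(0)) / (1 - f(0)) * 100`` — the released fraction
    re-referenced to the post-dilution state.
    """
    t = spec.times
    f = np.asarray(spec.released_fraction(t), dtype=float)
    q = spec.quench_residual
    m = spec.max_intensity
    intensity = m * (f + q * (1.0 - f))
    i0, imax0 = float(intensity[0]), m
    i_t = intensity.copy()
    i_max_t = np.full_like(i_t, m)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        factor = lambda n: 1.0 + rng.normal(0.0, spec.noise_sd, n)  # noqa: E731
        i0 = i0 * float(factor(1)[0])
        imax0 = imax0 * float(factor(1)[0])
        i_t = i_t * factor(i_t.size)
        i_max_t = i_max_t * factor(i_t.size)
        i_max_t = np.maximum(i_max_t, i_t + 1e-9)  # lysis never dims the signal
    return [
        ReleaseTimepoint(t=float(ti), I_0=i0, I_max0=imax0, I_t=float(it), I_maxt=float(imt))
        for ti, it, imt in zip(t, i_t, i_max_t)
    ]


def amide_components(
    alpha: float,
    beta_sheet: float,
    random_coil: float,
    fwhm: float = 20.0,
    total_area: float = 100.0,
) -> tuple[BandComponent, ...]:
    """Three-Gaussian Amide I truth with areas proportional to the given
    percentages, centered at the canonical helix/sheet/coil positions
    (1655, 1633, 1645 cm^-1)."""
    from .types import GAUSS_AREA_FACTOR

    fractions = np.array([alpha, beta_sheet, random_coil], dtype=float)
    if np.any(fractions < 0) or fractions.sum() <= 0:
        raise ValueError("percentages must be non-negative and not all zero")
    areas = total_area * fractions / fractions.sum()
    centers = (1655.0, 1633.0, 1645.0)
    return tuple(
        BandComponent(center=c, fwhm=fwhm, amplitude=a / (fwhm * GAUSS_AREA_FACTOR))
        for c, a in zip(centers, areas)
    )
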