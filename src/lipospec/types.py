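"""Core data carriers shared across the FTIR and fluorescence pipelines.

The universal container is :class:`Spectrum` — a pair of equal-length arrays
(wavenumber in cm^-1, strictly increasing; absorbance in a.u.).  Fitted bands
are :class:`BandComponent` pseudo-Voigt profiles; a fitted region is a
:class:`BandFitResult`.  Protein secondary-structure composition estimated
from the Amide I band is a :class:`SecondaryStructure`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: closed-form Gaussian area factor: area = amplitude * fwhm * sqrt(pi/ln 16)
GAUSS_AREA_FACTOR = math.sqrt(math.pi / math.log(16.0))
#: Lorentzian area factor: area = amplitude * fwhm * pi/2
LORENTZ_AREA_FACTOR = math.pi / 2.0


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavenumber axis."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.ndim != 1 or ab.ndim != 1 or wn.size != ab.size:
            raise ValueError("wavenumbers and absorbance must be 1-D arrays of equal length")
        if wn.size < 3:
            raise ValueError("spectrum needs at least 3 points")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise ValueError("spectrum contains non-finite values")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def slice(self, low: float, high: float) -> "Spectrum":
        """Return the sub-spectrum with ``low <= wavenumber <= high``."""
        mask = (self.wavenumbers >= low) & (self.wavenumbers <= high)
        if mask.sum() < 3:
            raise ValueError(f"region [{low}, {high}] covers fewer than 3 grid points")
        return Spectrum(self.wavenumbers[mask], self.absorbance[mask])

    @property
    def step(self) -> float:
        """Median grid spacing (cm^-1)."""
        return float(np.median(np.diff(self.wavenumbers)))


@dataclass(frozen=True)
class BandRegion:
    """A named wavenumber interval, e.g. the Amide I or phosphate band."""

    low: float
    high: float
    name: str = ""

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"region bounds must satisfy low < high, got [{self.low}, {self.high}]")

    def contains(self, wn: float) -> bool:
        return self.low <= wn <= self.high


#: Default analysis regions.  Phosphate and carbonyl bounds follow the lipid
#: band definitions used throughout the FTIR analysis; the Amide I window is
#: widened to 1618-1696 cm^-1 so that intermolecular beta-sheet (aggregate)
#: wings are included in the fit.
REGIONS: dict[str, BandRegion] = {
    "amide_i": BandRegion(1618.0, 1696.0, "amide_i"),
    "phosphate_asym": BandRegion(1220.0, 1260.0, "phosphate_asym"),
    "carbonyl": BandRegion(1700.0, 1760.0, "carbonyl"),
    "ch2_asym": BandRegion(2880.0, 2950.0, "ch2_asym"),
    "ch2_sym": BandRegion(2830.0, 2880.0, "ch2_sym"),
    "choline": BandRegion(950.0, 990.0, "choline"),
}


@dataclass(frozen=True)
class BandComponent:
    """One pseudo-Voigt spectral band.

    ``lorentz_fraction`` mixes a Gaussian (0) and a Lorentzian (1) of equal
    center, FWHM and amplitude.  ``area`` is the closed-form integral.
    """

    center: float
    fwhm: float
    amplitude: float
    lorentz_fraction: float = 0.0

    def __post_init__(self):
        if not np.isfinite([self.center, self.fwhm, self.amplitude, self.lorentz_fraction]).all():
            raise ValueError("band parameters must be finite")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.lorentz_fraction <= 1.0:
            raise ValueError("lorentz_fraction must lie in [0, 1]")

    @property
    def area(self) -> float:
        g = (1.0 - self.lorentz_fraction) * GAUSS_AREA_FACTOR
        lz = self.lorentz_fraction * LORENTZ_AREA_FACTOR
        return self.amplitude * self.fwhm * (g + lz)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the profile on wavenumber array ``x``."""
        x = np.asarray(x, dtype=float)
        u = (x - self.center) / self.fwhm
        gauss = np.exp(-4.0 * np.log(2.0) * u * u)
        lorentz = 1.0 / (1.0 + 4.0 * u * u)
        f = self.lorentz_fraction
        return self.amplitude * ((1.0 - f) * gauss + f * lorentz)


@dataclass(frozen=True)
class BandFitResult:
    """Outcome of a multi-component band fit over one region."""

    region: BandRegion
    components: tuple[BandComponent, ...]
    baseline_slope: float
    baseline_offset: float
    residual_rms: float
    converged: bool
    noise_estimate: float = float("nan")

    def __post_init__(self):
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")
        comps = tuple(sorted(self.components, key=lambda c: c.center))
        object.__setattr__(self, "components", comps)

    @property
    def total_area(self) -> float:
        return sum(c.area for c in self.components)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Fitted model (components + residual baseline) on ``x``."""
        x = np.asarray(x, dtype=float)
        y = self.baseline_slope * (x - x.mean()) + self.baseline_offset
        for c in self.components:
            y = y + c(x)
        return y


# -- Amide I assignment ------------------------------------------------------

#: Canonical anchor position (cm^-1) used when a structural element needs a
#: seeded component and the second derivative shows no resolvable minimum.
ELEMENT_ANCHORS: dict[str, float] = {
    "beta_sheet": 1633.0,
    "random_coil": 1645.0,
    "alpha_helix": 1655.0,
    "beta_turn": 1672.0,
    "aggregates": 1624.0,
    "aggregates_high": 1692.0,
}

AGGREGATE_LABEL = "aggregates"


@dataclass(frozen=True)
class AssignmentTable:
    """Mapping from Amide I component position to secondary-structure element.

    Ranges are half-open ``[low, high)``.  A center falling in none of the
    ranges is assigned to the nearest range; distance ties go to the
    lower-wavenumber range.
    """

    ranges: tuple[tuple[str, float, float], ...] = (
        ("aggregates", 1618.0, 1626.0),
        ("beta_sheet", 1628.0, 1639.0),
        ("random_coil", 1640.0, 1649.0),
        ("alpha_helix", 1650.0, 1660.0),
        ("beta_turn", 1664.0, 1687.0),
        ("aggregates", 1688.0, 1696.0),
    )

    def __post_init__(self):
        rs = sorted(self.ranges, key=lambda r: r[1])
        for (_, lo, hi) in rs:
            if not lo < hi:
                raise ValueError("assignment ranges need low < high")
        for (_, _, hi_a), (_, lo_b, _) in zip(rs, rs[1:]):
            if lo_b < hi_a:
                raise ValueError("assignment ranges must not overlap")
        object.__setattr__(self, "ranges", tuple(rs))

    def assign(self, center: float) -> str:
        for label, lo, hi in self.ranges:
            if lo <= center < hi:
                return label
        # nearest range; ties broken toward the lower-wavenumber range
        best_label, best_dist = None, np.inf
        for label, lo, hi in self.ranges:
            dist = lo - center if center < lo else center - hi
            if dist < best_dist:  # strict: earlier (lower) range wins ties
                best_label, best_dist = label, dist
        return best_label


@dataclass(frozen=True)
class SecondaryStructure:
    """Secondary-structure composition in percent.

    The four conformational classes are normalized to 100% over the
    non-aggregate area; the intermolecular beta-sheet (aggregate) fraction is
    reported separately against the total fitted area.
    """

    alpha_helix: float
    beta_sheet: float
    beta_turn: float
    random_coil: float
    aggregates: float = 0.0

    def __post_init__(self):
        total = self.alpha_helix + self.beta_sheet + self.beta_turn + self.random_coil
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"non-aggregate percentages must sum to 100 +- 0.1, got {total:.3f}")

    @property
    def beta_total(self) -> float:
        """Beta-sheet plus beta-turn, the jointly reported beta fraction."""
        return self.beta_sheet + self.beta_turn

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha_helix": self.alpha_helix,
            "beta_sheet": self.beta_sheet,
            "beta_turn": self.beta_turn,
            "random_coil": self.random_coil,
            "beta_total": self.beta_total,
            "aggregates": self.aggregates,
        }


@dataclass(frozen=True)
class ShiftResult:
    """Band position change between two spectra (after - before, cm^-1)."""

    position_before: float
    position_after: float
    se: float = float("nan")

    @property
    def shift(self) -> float:
        return self.position_after - self.position_before
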