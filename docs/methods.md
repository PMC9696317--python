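# Methods

This note documents the models, numerical choices and limitations behind
lipospec's analyses, in the order data flows through the package.

## Spectral model

A spectrum is absorbance on a strictly increasing wavenumber grid
(default 900–3000 cm⁻¹ at 1 cm⁻¹; ATR-FTIR instruments typically digitize at
2–4 cm⁻¹, so a 1 cm⁻¹ synthetic grid makes interpolation artifacts
negligible).  Bands are pseudo-Voigt profiles parameterized by center *c*,
full width at half maximum *w*, amplitude *A* and Lorentz fraction
*f* ∈ [0, 1]:

    V(ν) = A · [(1−f) · exp(−4 ln2 ((ν−c)/w)²) + f / (1 + 4((ν−c)/w)²)]

with closed-form area `A·w·[(1−f)·√(π/ln16) + f·π/2]`.  The synthetic
generator evaluates a sum of such bands on a straight baseline and adds iid
Gaussian noise on absorbance — the white-noise model that Savitzky–Golay
smoothing presumes.  Fluorescence-kinetics noise is multiplicative instead,
since photometric noise scales with signal.

What the generator does *not* emulate: water-vapour and CO₂ interference
lines, ATR penetration-depth wavelength dependence, Mie scattering baselines,
detector 1/f drift, and band-shape changes with temperature.  Passing
recovery tests therefore demonstrates that the *analysis* is correct and
well-conditioned under the stated noise model, not that every instrument
artifact is handled.

## Preprocessing

`preprocess` slices a named region, subtracts the straight line through two
edge anchors (each the mean absorbance over a 5 cm⁻¹ margin), and applies
Savitzky–Golay smoothing (window 9, order 3 by default — appropriate for a
~1 cm⁻¹ grid; pass `sg_window=None` to skip).  The anchor construction
assumes the region edges are locally band-free; if a band's tails reach the
margins the subtraction removes a small amount of real signal, so regions
should be chosen wider than the bands they contain.

`second_derivative` is the Savitzky–Golay second derivative (window 9,
order 3, `mode="interp"` for one-sided edge fits).  `pick_peaks` returns
local minima of the second derivative filtered by prominence relative to the
deepest minimum (default fraction 0.05).  Prominence, not raw depth, is used
because minima riding on the broad negative lobe of a strong band are
otherwise inflated.

## Band fitting

`fit_bands` is a bounded trust-region least-squares solve
(Levenberg–Marquardt class) over the component parameters plus a residual
baseline (offset + slope by default; offset-only via `baseline_degree=0`).
Tolerances: `xtol = ftol = 1e-12`, 5000 function evaluations.  Centers are
constrained to ±5 cm⁻¹ of their initial guesses by default.  Convergence is
reported as a flag, never an exception; fits with more parameters than
points are rejected up front.

Two mechanisms deal with model inadequacy:

* **Component addition** (`add_components=True`): while the residual RMS
  exceeds 1.5× the estimated noise floor, a component is seeded at the
  largest-|residual| grid point, up to 8 components.  The noise floor is
  estimated as `sd(diff(residual))/√2` — differencing removes smooth
  structured misfit and leaves the white-noise level.
* **Lorentz release** (`shape_policy="gauss_lorentz"`): the Lorentz fraction
  starts at zero and is freed only if the pure-Gaussian fit misses the same
  noise-consistency tolerance, i.e. Lorentz admixture only "if unavoidable".

## Amide I secondary structure

The decomposition window is 1618–1696 cm⁻¹ — wider than the commonly quoted
1620–1680 cm⁻¹ core so that the intermolecular β-sheet (aggregate) wings at
~1624 and ~1692 cm⁻¹ fall inside the fit.  Assignment ranges (half-open
[low, high)): aggregates 1618–1626 and 1688–1696, β-sheet 1628–1639, random
coil 1640–1649, α-helix 1650–1660, β-turn 1664–1687.  Centers falling in a
gap go to the nearest range, ties to the lower-wavenumber range.  The four
conformational classes are renormalized to 100 % over non-aggregate area;
the aggregate percentage is reported against total area, because published
composition tables sum to ~100 without aggregates.

**Conditioning, and why centers are pinned.**  Albumin's helix (1655), coil
(1645) and sheet (1633) components are separated by 10–12 cm⁻¹ but are
~20 cm⁻¹ wide.  Two consequences, both verified numerically:

1. the second derivative of the three-band sum has only *two* minima even
   without noise — the coil shoulder is mathematically unresolvable by
   curvature;
2. with all nine Gaussian parameters free, the fit is nearly collinear: at a
   signal-to-noise ratio of 100 the α-helix area fraction scatters by ±13
   percentage points across noise realizations, and a two-component fit
   reproduces the data to ~10× *below* the noise floor, so no residual
   criterion can detect the missing band.

`amide_i_analysis` therefore always seeds the three core elements at their
canonical anchor positions (1633 / 1645 / 1655 cm⁻¹), refines centers only
within ±0.1 cm⁻¹, and shares a single bandwidth across components.  This
reduces the decomposition to a well-conditioned area-apportionment problem
(α-helix scatter ±0.5 points under the same conditions) and mirrors the
classical fixed-position protocol for Amide I work, where positions come
from second-derivative analysis and literature assignments rather than from
the area fit itself.  β-turn and aggregate components are added only when
the second derivative shows a minimum in their ranges, so absent elements do
not siphon area from present ones.  For the derivative step inside this
pipeline a wider smoothing window (21 points) and a higher prominence
threshold (0.10) are used than the `pick_peaks` defaults: at SNR 100 the
default settings admit noise minima that would seed phantom components.

The anchor positions and every threshold are exposed on `AmideIConfig`.

## Lipid-band analyses

`band_position` estimates the dominant band's center to sub-grid precision:
a Gaussian plus constant offset is fitted over the region extended by a
20 cm⁻¹ margin (the flanks inform width and offset), seeded at the grid
argmax, with residual-driven component addition (max 4) to absorb
overlapping neighbours.  The center of the largest-amplitude in-region
component is returned.  The baseline is offset-only because a free slope is
nearly degenerate with band asymmetry over windows comparable to the band
width; baseline tilts are the preprocessing step's job.  Validation on
synthetic bands: error SD ≈ 0.08 cm⁻¹ at SNR 50 for an isolated band, and a
dominant center recovered to < 0.5 cm⁻¹ under a 30 %-amplitude overlapping
neighbour.

`band_shift` is the difference of two such positions (after − before);
positive means a shift to higher wavenumber — the dehydration direction for
the phosphate band and the acyl-chain-disordering direction for the
methylene stretches.  `carbonyl_hydration` classifies fitted 1700–1760 cm⁻¹
components at 1735 cm⁻¹: centers below it (the ~1714 doubly hydrogen-bonded
shoulder, the hydrated sn-2 band at ~1727–1731) count as hydrogen-bonded;
~1738 and ~1742 cm⁻¹ count as free.  The ~1714 shoulder is counted in the
bound numerator since it carries two hydrogen bonds.

## Fluorescence

The anisotropy and calcein-release formulas are implemented exactly as
stated in the README.  Values are returned unclipped: with noisy inputs CR
can fall slightly below 0 or above 100, and clipping would bias triplicate
means; out-of-range anisotropies ([0, 0.4] is the one-photon physical range)
produce warnings, not errors.  `emission_peak` reports at grid resolution
with ties resolved toward lower wavelength — emission analysis here is
intensity-based, so no sub-nm fit is warranted.

The leakage generator models first-order efflux
`f(t) = 1 − (1 − f₀)·exp(−k·t)` with a residual self-quenching yield (10 %
of the dequenched intensity by default): encapsulated dye is almost dark,
lysis dequenches everything.  The CR formula applied to a noiseless trace
recovers `(f(t) − f(0))/(1 − f(0))` — the released fraction re-referenced to
the post-dilution state — independent of the quench-yield parameter.

## Vesicle geometry

Defaults: bilayer thickness 5 nm and area per lipid 0.71 nm² (fluid
phosphatidylcholine), which reproduce the reference count of ~97,700 lipids
for a 110 nm vesicle to 0.1 %; BSA molar mass 66 430 g/mol and a
14 × 4 × 4 nm ellipsoid-of-revolution footprint.  The protein footprint
enters the capacity as the ellipse area π·a·b with the printed axis values —
this convention reproduces both reference capacities (216 side-on, 756
end-on) exactly.  Capacities are floored (a partial molecule does not fit);
lipid counts are rounded.  Back-calculated molecules-per-vesicle values are
sensitive to the molar mass at the few-percent level, so it is exposed as a
parameter.  The model ignores curvature dependence of the area per lipid
and multilayer adsorption.

## Statistics

Mean ± SD (n−1) describes dispersion of kinetic replicates; mean ± SE
describes precision of composition estimates.  Group comparison is the
independent two-sample t-test — pooled-variance Student's t by default
("independent test" read in its classical sense), Welch's variant available
because equal variances are an assumption.  Two-sided p-values, rejection at
α = 0.05, 95 % CI on the mean difference.  No multiple-testing correction is
applied across structural elements; each comparison is reported with its own
p-value.  A Monte-Carlo calibration (10,000 null replications) confirms the
type-I error rate at 0.05 ± 0.01.

## Problem sizes and determinism

Synthetic recovery studies use 10 noise seeds per condition for composition
and shift estimates, and 3 replicates per timepoint in the orchestrated
pipeline run — enough for stable means while keeping the full suite and the
acceptance script in the seconds-to-a-minute range.  All randomness flows
through `numpy.random.default_rng` seeded from a single user-supplied seed;
identical configuration and seed give bit-identical outputs.

## Known limitations

* No Fourier self-deconvolution; overlapped-band resolution relies on the
  second derivative plus constrained fitting.
* The fixed-anchor Amide I decomposition assumes the protein's component
  positions are at (or within ~1 cm⁻¹ of) the canonical albumin values; a
  protein with strongly shifted components needs adjusted anchors in
  `AmideIConfig`.
* No atmospheric compensation, ATR penetration-depth correction, Amide II
  quantification, or O–H region analysis.
* JCAMP-DX support covers AFFN/fixed-point XYDATA tables only; compressed
  ordinate forms are rejected with a clear message.
* The straight-line baseline assumes band-free region edges (see
  Preprocessing).
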