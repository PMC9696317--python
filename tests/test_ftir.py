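"""FTIR pipeline: preprocessing, derivatives, band fitting, Amide I
decomposition and lipid-band shift analysis, each checked against the
synthetic generator's ground truth or a closed form."""

import numpy as np
import pytest

from lipospec import (
    AssignmentTable,
    BandComponent,
    BandRegion,
    GroundTruthSpectrumSpec,
    Spectrum,
    amide_components,
    amide_i_analysis,
    assign_secondary_structure,
    band_position,
    band_shift,
    carbonyl_hydration,
    fit_bands,
    gen_spectrum,
    pick_peaks,
    preprocess,
    second_derivative,
)
from lipospec.ftir import AmideIConfig
from lipospec.types import GAUSS_AREA_FACTOR, BandFitResult

AMIDE = BandRegion(1618.0, 1696.0, "amide_i")


def make_spectrum(components, lo=1580.0, hi=1720.0, **kw):
    return gen_spectrum(GroundTruthSpectrumSpec(
        components=tuple(components), grid_start=lo, grid_end=hi, **kw))


def gauss_band(center, fwhm, area):
    return BandComponent(center, fwhm, area / (fwhm * GAUSS_AREA_FACTOR))


class TestPreprocess:
    def test_pure_ramp_removed(self):
        x = np.arange(1600.0, 1701.0)
        s = Spectrum(x, 0.2 + 1e-3 * (x - x[0]))
        out = preprocess(s, BandRegion(1610, 1690), sg_window=None)
        assert np.max(np.abs(out.absorbance)) < 1e-12

    def test_flat_clean_band_unchanged_without_smoothing(self):
        # band tails vanish at the edge anchors, so nothing is subtracted
        s = make_spectrum([gauss_band(1655.0, 10.0, 50.0)])
        out = preprocess(s, AMIDE, sg_window=None)
        expected = s.slice(AMIDE.low, AMIDE.high).absorbance
        assert np.allclose(out.absorbance, expected, atol=1e-9)

    def test_band_recovered_from_sloped_noisy_spectrum(self):
        truth = gauss_band(1655.0, 20.0, 50.0)
        s = make_spectrum([truth], baseline_slope=1e-4, noise_sd=1e-3, seed=11)
        out = preprocess(s, AMIDE)
        peak = out.wavenumbers[np.argmax(out.absorbance)]
        assert abs(peak - 1655.0) <= 0.5

    def test_region_outside_support_rejected(self):
        s = make_spectrum([gauss_band(1655.0, 20.0, 50.0)])
        with pytest.raises(ValueError):
            preprocess(s, BandRegion(100.0, 200.0))

    def test_oversized_window_rejected(self):
        s = make_spectrum([gauss_band(1655.0, 20.0, 50.0)])
        with pytest.raises(ValueError):
            preprocess(s, BandRegion(1650.0, 1660.0), sg_window=99)


class TestSecondDerivative:
    def test_minimum_at_band_center(self):
        s = make_spectrum([gauss_band(1655.0, 20.0, 50.0)])
        d2 = second_derivative(s)
        assert d2.wavenumbers[np.argmin(d2.absorbance)] == 1655.0

    def test_resolves_two_bands(self):
        s = make_spectrum([gauss_band(1640.0, 12.0, 30.0), gauss_band(1660.0, 12.0, 30.0)],
                          lo=1600.0, hi=1700.0)
        minima = pick_peaks(second_derivative(s))
        assert len(minima) == 2
        assert abs(minima[0] - 1640.0) <= 1.0 and abs(minima[1] - 1660.0) <= 1.0

    def test_straight_line_has_zero_curvature(self):
        x = np.arange(1600.0, 1701.0)
        d2 = second_derivative(Spectrum(x, 0.01 * x + 3.0))
        assert np.max(np.abs(d2.absorbance)) < 1e-10

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            second_derivative(Spectrum(np.arange(5.0), np.zeros(5)))


class TestPickPeaks:
    def test_single_band_single_pick(self):
        s = make_spectrum([gauss_band(1655.0, 20.0, 50.0)])
        assert pick_peaks(second_derivative(s)) == [1655.0]

    def test_three_narrow_components_fall_in_their_ranges(self):
        # FWHM 8 bands at the sheet/coil/helix positions are resolvable
        comps = [gauss_band(1633.0, 8.0, 23.2), gauss_band(1645.0, 8.0, 16.9),
                 gauss_band(1655.0, 8.0, 59.9)]
        picks = pick_peaks(second_derivative(make_spectrum(comps, lo=1600.0, hi=1700.0)))
        assert len(picks) == 3
        table = AssignmentTable()
        assert [table.assign(p) for p in picks] == ["beta_sheet", "random_coil", "alpha_helix"]

    def test_flat_noise_below_prominence_gives_no_band_picks(self):
        rng = np.random.default_rng(0)
        x = np.arange(1600.0, 1701.0)
        d2 = Spectrum(x, np.full(x.size, 1.0) + 0.0 * rng.standard_normal(x.size))
        # strictly positive second derivative: no band-like minima at all
        assert pick_peaks(d2) == []

    def test_prominence_threshold_filters_minor_minima(self):
        s = make_spectrum([gauss_band(1633.0, 10.0, 100.0), gauss_band(1670.0, 10.0, 1.0)],
                          lo=1600.0, hi=1700.0)
        d2 = second_derivative(s)
        assert len(pick_peaks(d2, prominence_fraction=0.5)) == 1
        assert len(pick_peaks(d2, prominence_fraction=0.001)) == 2


class TestFitBands:
    def test_noiseless_single_gaussian_exact(self):
        truth = gauss_band(1230.2, 30.0, 1.0)
        s = make_spectrum([truth], lo=1180.0, hi=1300.0)
        fit = fit_bands(s, BandRegion(1220.0, 1260.0), [1230.0])
        comp = fit.components[0]
        assert fit.converged
        assert comp.center == pytest.approx(1230.2, abs=1e-5)
        assert comp.fwhm == pytest.approx(30.0, rel=1e-6)
        assert comp.area == pytest.approx(truth.area, rel=1e-6)

    def test_matches_closed_form_moment_oracle(self):
        # oracle: center = argmax, area = amplitude*fwhm*sqrt(pi/ln16)
        truth = gauss_band(1655.0, 18.0, 42.0)
        s = make_spectrum([truth])
        fit = fit_bands(s, AMIDE, [1655.0])
        x = s.wavenumbers
        argmax_center = x[np.argmax(s.absorbance)]
        assert abs(fit.components[0].center - argmax_center) <= 0.5
        assert fit.components[0].area == pytest.approx(
            truth.amplitude * truth.fwhm * GAUSS_AREA_FACTOR, rel=1e-6)

    def test_carbonyl_four_component_centers_recovered(self):
        centers = [1714.0, 1731.0, 1738.0, 1742.0]
        comps = [gauss_band(c, 10.0, a) for c, a in zip(centers, [10.0, 40.0, 20.0, 30.0])]
        s = make_spectrum(comps, lo=1680.0, hi=1780.0)
        fit = fit_bands(s, BandRegion(1700.0, 1760.0, "carbonyl"), centers, fwhm_init=12.0)
        assert fit.converged
        fitted = [c.center for c in fit.components]
        assert np.allclose(fitted, centers, atol=1.0)

    def test_residual_consistent_with_noise(self):
        comps = [gauss_band(1655.0, 20.0, 50.0)]
        sd = 1e-3
        s = make_spectrum(comps, noise_sd=sd, seed=3)
        fit = fit_bands(s, AMIDE, [1655.0])
        assert fit.residual_rms <= 1.5 * sd

    def test_ill_posed_fit_rejected(self):
        s = make_spectrum([gauss_band(1655.0, 20.0, 50.0)])
        with pytest.raises(ValueError):
            fit_bands(s, BandRegion(1653.0, 1657.0), [1654.0, 1655.0, 1656.0])

    def test_no_center_in_region_rejected(self):
        s = make_spectrum([gauss_band(1655.0, 20.0, 50.0)])
        with pytest.raises(ValueError):
            fit_bands(s, AMIDE, [1500.0])

    def test_lorentz_released_only_when_needed(self):
        # a pure Lorentzian band defeats the Gaussian model; the
        # gauss_lorentz policy then frees the mixing fraction
        truth = BandComponent(1450.0, 20.0, 1.0, lorentz_fraction=1.0)
        s = gen_spectrum(GroundTruthSpectrumSpec(
            components=(truth,), grid_start=1350.0, grid_end=1550.0))
        region = BandRegion(1380.0, 1520.0)
        gauss_only = fit_bands(s, region, [1450.0], "gauss")
        released = fit_bands(s, region, [1450.0], "gauss_lorentz")
        assert released.components[0].lorentz_fraction > 0.9
        assert released.residual_rms < gauss_only.residual_rms

    def test_component_addition_recovers_missed_band(self):
        comps = [gauss_band(1633.0, 10.0, 50.0), gauss_band(1660.0, 10.0, 30.0)]
        s = make_spectrum(comps, lo=1600.0, hi=1700.0)
        fit = fit_bands(s, BandRegion(1618.0, 1680.0), [1633.0], add_components=True)
        assert len(fit.components) == 2
        assert abs(fit.components[1].center - 1660.0) <= 1.0


class TestAssignment:
    def table(self):
        return AssignmentTable()

    def test_single_helix_component(self):
        fit = BandFitResult(AMIDE, (gauss_band(1655.0, 20.0, 10.0),), 0.0, 0.0, 0.0, True)
        ss = assign_secondary_structure(fit)
        assert ss.alpha_helix == pytest.approx(100.0)

    def test_three_component_composition(self):
        comps = (gauss_band(1633.0, 20.0, 23.2), gauss_band(1645.0, 20.0, 16.9),
                 gauss_band(1655.0, 20.0, 59.9))
        ss = assign_secondary_structure(BandFitResult(AMIDE, comps, 0.0, 0.0, 0.0, True))
        assert ss.beta_sheet == pytest.approx(23.2, abs=1e-9)
        assert ss.random_coil == pytest.approx(16.9, abs=1e-9)
        assert ss.alpha_helix == pytest.approx(59.9, abs=1e-9)

    def test_aggregates_reported_separately_and_core_renormalized(self):
        comps = (gauss_band(1624.0, 20.0, 10.0), gauss_band(1633.0, 20.0, 30.0),
                 gauss_band(1655.0, 20.0, 60.0))
        ss = assign_secondary_structure(BandFitResult(AMIDE, comps, 0.0, 0.0, 0.0, True))
        assert ss.aggregates == pytest.approx(10.0)
        assert ss.alpha_helix == pytest.approx(100.0 * 60.0 / 90.0)
        assert ss.alpha_helix + ss.beta_sheet + ss.beta_turn + ss.random_coil == pytest.approx(100.0)

    def test_permutation_invariance(self):
        comps = [gauss_band(1633.0, 20.0, 23.2), gauss_band(1645.0, 20.0, 16.9),
                 gauss_band(1655.0, 20.0, 59.9)]
        a = assign_secondary_structure(BandFitResult(AMIDE, tuple(comps), 0.0, 0.0, 0.0, True))
        b = assign_secondary_structure(BandFitResult(AMIDE, tuple(comps[::-1]), 0.0, 0.0, 0.0, True))
        assert a.as_dict() == b.as_dict()

    def test_gap_centers_resolve_to_nearest_range(self):
        table = self.table()
        assert table.assign(1639.4) == "beta_sheet"     # [1639, 1640) gap, nearer sheet edge
        assert table.assign(1661.0) == "alpha_helix"    # [1660, 1664) gap
        assert table.assign(1663.0) == "beta_turn"
        assert table.assign(1627.0) == "aggregates"     # tie at 1627 goes to the lower range

    def test_empty_fit_rejected(self):
        fit = BandFitResult(AMIDE, (gauss_band(1655.0, 20.0, 1.0),), 0.0, 0.0, 0.0, True)
        object.__setattr__(fit, "components", ())
        with pytest.raises(ValueError):
            assign_secondary_structure(fit)

    def test_component_outside_amide_window_rejected(self):
        fit = BandFitResult(AMIDE, (gauss_band(1550.0, 20.0, 1.0),), 0.0, 0.0, 0.0, True)
        with pytest.raises(ValueError):
            assign_secondary_structure(fit)


class TestAmideIAnalysis:
    def synth(self, composition, seed):
        comps = amide_components(*composition, fwhm=20.0, total_area=100.0)
        grid = np.arange(1580.0, 1720.5, 1.0)
        peak = sum(c(grid) for c in comps).max()
        return make_spectrum(comps, noise_sd=peak / 100.0, seed=seed)

    def test_free_albumin_composition_recovered(self):
        truth = (59.9, 23.2, 16.9)
        alphas, sheets, coils = [], [], []
        for seed in range(1, 4):
            ss = amide_i_analysis(self.synth(truth, seed))
            alphas.append(ss.alpha_helix)
            sheets.append(ss.beta_sheet)
            coils.append(ss.random_coil)
        assert abs(np.mean(alphas) - truth[0]) <= 1.5
        assert abs(np.mean(sheets) - truth[1]) <= 1.5
        assert abs(np.mean(coils) - truth[2]) <= 1.5

    def test_composition_sums_to_hundred(self):
        ss = amide_i_analysis(self.synth((52.8, 19.1, 28.0), seed=2))
        total = ss.alpha_helix + ss.beta_sheet + ss.beta_turn + ss.random_coil
        assert total == pytest.approx(100.0, abs=0.1)

    def test_spectrum_not_covering_window_rejected(self):
        s = make_spectrum([gauss_band(1655.0, 20.0, 50.0)], lo=1640.0, hi=1720.0)
        with pytest.raises(ValueError):
            amide_i_analysis(s)


class TestBandPosition:
    def test_noiseless_subgrid_position(self):
        s = make_spectrum([gauss_band(1230.2, 30.0, 1.0)], lo=1180.0, hi=1300.0)
        pos = band_position(s, BandRegion(1220.0, 1260.0))
        assert pos == pytest.approx(1230.2, abs=0.01)

    def test_noisy_methylene_band_within_tolerance(self):
        amp = 1.0 / (25.0 * GAUSS_AREA_FACTOR)
        errors = []
        for seed in range(1, 6):
            s = make_spectrum([BandComponent(2924.0, 25.0, amp)], lo=2850.0, hi=3000.0,
                              noise_sd=amp / 50.0, seed=seed)
            errors.append(band_position(s, BandRegion(2880.0, 2950.0)) - 2924.0)
        assert np.max(np.abs(errors)) <= 0.2

    def test_dominant_band_among_overlap(self):
        comps = [gauss_band(1231.6, 30.0, 1.0), gauss_band(1255.0, 25.0, 0.3)]
        s = make_spectrum(comps, lo=1180.0, hi=1320.0)
        pos = band_position(s, BandRegion(1220.0, 1260.0))
        assert abs(pos - 1231.6) <= 0.5

    def test_no_maximum_rejected(self):
        x = np.arange(1200.0, 1301.0)
        s = Spectrum(x, np.linspace(1.0, 0.0, x.size))
        with pytest.raises(ValueError):
            band_position(s, BandRegion(1240.0, 1260.0))

    def test_recovery_error_grows_with_noise(self):
        # median center error over seeds is non-decreasing along a noise ladder
        amp = 1.0 / (30.0 * GAUSS_AREA_FACTOR)
        medians = []
        for rel_sd in (0.0, 1e-4, 1e-3, 1e-2):
            errs = []
            for seed in range(1, 8):
                s = make_spectrum([BandComponent(1230.2, 30.0, amp)], lo=1180.0, hi=1300.0,
                                  noise_sd=amp * rel_sd, seed=seed)
                errs.append(abs(band_position(s, BandRegion(1220.0, 1260.0)) - 1230.2))
            medians.append(np.median(errs))
        assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))


class TestBandShift:
    def test_identical_spectra_zero_shift(self):
        s = make_spectrum([gauss_band(1230.2, 30.0, 1.0)], lo=1180.0, hi=1300.0)
        assert band_shift(s, s, BandRegion(1220.0, 1260.0)).shift == 0.0

    def test_antisymmetry(self):
        a = make_spectrum([gauss_band(1230.2, 30.0, 1.0)], lo=1180.0, hi=1300.0)
        b = make_spectrum([gauss_band(1233.6, 30.0, 1.0)], lo=1180.0, hi=1300.0)
        region = BandRegion(1220.0, 1260.0)
        assert band_shift(a, b, region).shift == pytest.approx(
            -band_shift(b, a, region).shift, abs=1e-9)

    def test_phosphate_dehydration_shift(self):
        a = make_spectrum([gauss_band(1230.2, 30.0, 1.0)], lo=1180.0, hi=1300.0)
        b = make_spectrum([gauss_band(1233.6, 30.0, 1.0)], lo=1180.0, hi=1300.0)
        shift = band_shift(a, b, BandRegion(1220.0, 1260.0)).shift
        assert shift == pytest.approx(3.4, abs=0.05)


class TestCarbonylHydration:
    def fit_of(self, pairs):
        comps = tuple(gauss_band(c, 10.0, a) for c, a in pairs)
        return BandFitResult(BandRegion(1700.0, 1760.0), comps, 0.0, 0.0, 0.0, True)

    def test_even_split(self):
        assert carbonyl_hydration(self.fit_of([(1731.0, 50.0), (1742.0, 50.0)])) == pytest.approx(50.0)

    def test_four_component_classification(self):
        fit = self.fit_of([(1714.0, 10.0), (1731.0, 40.0), (1738.0, 20.0), (1742.0, 30.0)])
        assert carbonyl_hydration(fit) == pytest.approx(50.0)

    def test_all_free_carbonyls(self):
        assert carbonyl_hydration(self.fit_of([(1742.0, 80.0)])) == pytest.approx(0.0)
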