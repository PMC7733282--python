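import numpy as np
import pytest

import plaquefir as pf
from plaquefir.amide_analysis import (
    NormalizationError,
    second_derivative,
    spline_resample,
)
from plaquefir.spectra_core import channel_slice


def _gauss(axis, center, sigma, amp):
    return amp * np.exp(-0.5 * ((axis.values - center) / sigma) ** 2)


class TestLinearBaseline:
    def test_linear_input_maps_to_zero(self, axis):
        spec = pf.Spectrum(axis, 0.3 + 0.001 * axis.values)
        out = pf.subtract_linear_baseline(spec, 1480.0, 1800.0)
        assert np.abs(out.absorbance).max() < 1e-12

    def test_constant_input_maps_to_zero(self, axis):
        spec = pf.Spectrum(axis, np.full(axis.n_channels, 0.7))
        out = pf.subtract_linear_baseline(spec, 1480.0, 1800.0)
        assert np.abs(out.absorbance).max() == 0.0

    def test_gaussian_on_ramp_recovered(self, axis):
        g = _gauss(axis, 1640.0, 8.0, 0.5)
        spec = pf.Spectrum(axis, g + 0.2 + 0.0005 * axis.values)
        out = pf.subtract_linear_baseline(spec, 1480.0, 1800.0)
        sl = channel_slice(out.axis, 1500.0, 1780.0)  # away from endpoints
        expected = _gauss(out.axis, 1640.0, 8.0, 0.5)
        assert np.abs(out.absorbance[sl] - expected[sl]).max() < 1e-10


class TestAreaNormalize:
    def test_unit_integral(self, axis):
        spec = pf.Spectrum(axis, _gauss(axis, 1650.0, 20.0, 0.8) + 0.01)
        out = pf.area_normalize(spec)
        sl = channel_slice(out.axis, 1610.0, 1690.0)
        integral = np.abs(out.absorbance[sl]).sum() * out.axis.step_cm1
        assert integral == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, axis):
        spec = pf.Spectrum(axis, _gauss(axis, 1650.0, 20.0, 0.8))
        a = pf.area_normalize(spec)
        b = pf.area_normalize(pf.Spectrum(axis, 7.0 * spec.absorbance))
        assert np.allclose(a.absorbance, b.absorbance)

    def test_idempotent(self, axis):
        spec = pf.Spectrum(axis, _gauss(axis, 1650.0, 20.0, 0.8))
        once = pf.area_normalize(spec)
        twice = pf.area_normalize(once)
        assert np.allclose(once.absorbance, twice.absorbance, atol=1e-12)

    def test_zero_segment_rejected(self, axis):
        with pytest.raises(NormalizationError):
            pf.area_normalize(pf.Spectrum(axis, np.zeros(axis.n_channels)))


class TestDifferenceSpectrum:
    def test_identical_inputs_zero(self, axis):
        spec = pf.Spectrum(axis, _gauss(axis, 1650.0, 20.0, 0.8) + 0.05)
        d = pf.difference_spectrum(spec, spec, mode="amide")
        assert np.abs(d.absorbance).max() < 1e-12

    def test_antisymmetry(self, axis):
        a = pf.Spectrum(axis, _gauss(axis, 1650.0, 20.0, 0.8))
        b = pf.Spectrum(axis, _gauss(axis, 1630.0, 10.0, 0.5) + _gauss(axis, 1655.0, 15.0, 0.3))
        d1 = pf.difference_spectrum(a, b, mode="beta")
        d2 = pf.difference_spectrum(b, a, mode="beta")
        assert np.allclose(d1.absorbance, -d2.absorbance, atol=1e-12)

    def test_beta_mode_difference_integrates_to_zero(self, axis):
        # bands centered on the window midpoint stay non-negative after
        # the endpoint baseline, so both normalized integrals are
        # exactly 1 and the difference integrates to zero
        a = pf.Spectrum(axis, _gauss(axis, 1650.0, 20.0, 0.8) + 0.02)
        b = pf.Spectrum(
            axis,
            _gauss(axis, 1650.0, 12.0, 0.5) + _gauss(axis, 1650.0, 25.0, 0.2) + 0.02,
        )
        d = pf.difference_spectrum(a, b, mode="beta")
        integral = d.absorbance.sum() * d.axis.step_cm1
        assert abs(integral) < 1e-6

    def test_beta_mode_difference_near_zero_on_tissue_spectra(self, cored_analysis):
        # realistic spectra can dip marginally below the endpoint
        # baseline, so the cancellation is only near-exact
        _, _, _, art = cored_analysis
        gs = art["rois"][0]["group_spectra"]
        d = pf.difference_spectrum(
            gs.plaque_spectrum, gs.surrounding_spectrum, mode="beta"
        )
        integral = d.absorbance.sum() * d.axis.step_cm1
        assert abs(integral) < 5e-3

    def test_core_minus_surround_difference_features(self, cored_analysis):
        """Beta-mode difference of a fibrillar core vs its surround shows
        the positive turn feature below 1690 and the negative
        antiparallel feature just above it (amide-window variant)."""
        _, _, _, art = cored_analysis
        gs = art["rois"][0]["group_spectra"]
        ca = pf.subtract_linear_baseline(gs.core_spectrum, 1480.0, 1800.0)
        sa = pf.subtract_linear_baseline(gs.surrounding_spectrum, 1480.0, 1800.0)
        can, san = pf.area_normalize(ca), pf.area_normalize(sa)
        d = pf.Spectrum(can.axis, can.absorbance - san.absorbance)
        wn = d.axis.values
        pos_window = (wn >= 1675.0) & (wn <= 1690.0)
        neg_window = (wn > 1690.0) & (wn <= 1700.0)
        assert d.absorbance[pos_window].max() > 0
        assert d.absorbance[neg_window].min() < 0

    def test_axis_mismatch_rejected(self, axis):
        a = pf.Spectrum(axis, np.ones(axis.n_channels))
        short = pf.WavenumberAxis(axis.values[:100])
        b = pf.Spectrum(short, np.ones(100))
        with pytest.raises(pf.InputError):
            pf.difference_spectrum(a, b)


class TestSecondDerivative:
    def test_exact_on_quadratic(self, axis):
        k = np.arange(axis.n_channels, dtype=float)
        spec = pf.Spectrum(axis, k**2)
        d2 = second_derivative(spec)
        interior = d2.absorbance[2:-2]
        assert np.allclose(interior, 2.0 / axis.step_cm1**2, rtol=1e-10)

    def test_linear_input_gives_zero(self, axis):
        spec = pf.Spectrum(axis, 5.0 - 0.01 * axis.values)
        d2 = second_derivative(spec)
        assert np.abs(d2.absorbance[2:-2]).max() < 1e-12

    def test_edges_marked_invalid(self, axis):
        spec = pf.Spectrum(axis, np.ones(axis.n_channels))
        d2 = second_derivative(spec)
        assert np.isnan(d2.absorbance[:2]).all()
        assert np.isnan(d2.absorbance[-2:]).all()

    def test_gaussian_minimum_at_band_center(self, axis):
        spec = pf.Spectrum(axis, _gauss(axis, 1630.0, 8.0, 1.0))
        d2 = second_derivative(spec)
        pick = pf.pick_band(d2, 1630.0, 5.0, sense="min")
        assert pick.resolved
        assert pick.position_cm1 == pytest.approx(1630.0, abs=0.2)

    def test_too_short_segment_rejected(self):
        ax = pf.WavenumberAxis(np.array([4.0, 3.0, 2.0, 1.0]))
        with pytest.raises(pf.InputError):
            second_derivative(pf.Spectrum(ax, np.ones(4)))


class TestPickBand:
    def test_single_gaussian_position(self, axis):
        spec = pf.Spectrum(axis, _gauss(axis, 1630.0, 8.0, 0.5))
        pick = pf.pick_band(spec, 1630.0, 5.0, sense="max")
        assert pick.resolved
        assert pick.position_cm1 == pytest.approx(1630.0, abs=0.2)
        # height is read at the nearest grid channel (unrefined)
        assert pick.height == pytest.approx(0.5, abs=5e-3)

    def test_flat_segment_unresolved(self, axis):
        spec = pf.Spectrum(axis, np.full(axis.n_channels, 0.3))
        pick = pf.pick_band(spec, 1630.0, 5.0, sense="max")
        assert not pick.resolved

    def test_overlap_pulls_apparent_position_down(self, axis):
        """1628 + 1655 mixture: the apparent beta extremum sits below
        1630 (oracle: dense-grid evaluation of the analytic mixture)."""
        mix = _gauss(axis, 1628.0, 9.0, 1.0) + _gauss(axis, 1655.0, 13.0, 0.6)
        spec = pf.Spectrum(axis, mix)
        pick = pf.pick_band(spec, 1630.0, 5.0, sense="max")
        dense = np.linspace(1620.0, 1640.0, 20001)
        mix_d = 1.0 * np.exp(-0.5 * ((dense - 1628.0) / 9.0) ** 2) + 0.6 * np.exp(
            -0.5 * ((dense - 1655.0) / 13.0) ** 2
        )
        oracle = dense[np.argmax(mix_d)]
        assert oracle < 1630.0
        assert pick.position_cm1 == pytest.approx(oracle, abs=0.3)
        assert pick.position_cm1 < 1630.0


class TestComputeRatios:
    def test_direct_quotients_on_constructed_spectrum(self, axis):
        y = np.zeros(axis.n_channels)
        y += _gauss(axis, 1545.0, 4.0, 0.30)
        y += _gauss(axis, 1630.0, 4.0, 0.20)
        y += _gauss(axis, 1655.0, 4.0, 0.40)
        sl_ch = channel_slice(axis, 2800.0, 3000.0)
        y[sl_ch] = 0.60
        ratios = pf.compute_ratios(pf.Spectrum(axis, y))
        assert ratios.protein_ratio == pytest.approx(0.5, abs=1e-2)
        assert ratios.beta_ratio == pytest.approx(0.5, abs=1e-2)

    def test_gray_matter_below_core_beta_ratio(self, cored_analysis):
        _, _, _, art = cored_analysis
        gs = art["rois"][0]["group_spectra"]
        gray = pf.compute_ratios(gs.surrounding_spectrum)
        core = pf.compute_ratios(gs.core_spectrum)
        assert gray.beta_ratio < core.beta_ratio

    def test_ratios_scale_invariant(self, axis):
        gray = pf.synthetic_scene.GRAY_MATTER_BANDS.evaluate(axis)
        r1 = pf.compute_ratios(pf.Spectrum(axis, gray))
        r2 = pf.compute_ratios(pf.Spectrum(axis, 3.7 * gray))
        assert r1.protein_ratio == pytest.approx(r2.protein_ratio, rel=1e-9)
        assert r1.beta_ratio == pytest.approx(r2.beta_ratio, rel=1e-9)
        # the d2 height difference is deliberately not scale-free
        assert r2.d2_height_diff == pytest.approx(3.7 * r1.d2_height_diff, rel=1e-6)

    def test_beta_position_decreases_with_fibril_fraction(self, axis):
        """Noise-free mixtures: picked beta position is strictly
        decreasing as the fibril fraction goes 0 -> 1."""
        from plaquefir.synthetic_scene import (
            FIBRIL_BANDS,
            GRAY_MATTER_BANDS,
            OLIGOMER_BANDS,
        )

        gray = GRAY_MATTER_BANDS.evaluate(axis)
        olig = OLIGOMER_BANDS.evaluate(axis)
        fib = FIBRIL_BANDS.evaluate(axis)
        positions, d2_diffs = [], []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = pf.Spectrum(axis, gray + 1.5 * ((1 - f) * olig + f * fib))
            r = pf.compute_ratios(spec)
            positions.append(r.beta_position_cm1)
            d2_diffs.append(r.d2_height_diff)
        assert all(a > b for a, b in zip(positions, positions[1:]))
        # increasing 1628 dominance: the height difference trends more
        # negative (tolerance absorbs pick-window boundary jitter)
        assert all(b <= a + 1e-4 for a, b in zip(d2_diffs, d2_diffs[1:]))
        assert d2_diffs[-1] < d2_diffs[0] - 1e-3


class TestRatioMaps:
    def test_constant_cube_gives_constant_maps(self, axis):
        gray = pf.synthetic_scene.GRAY_MATTER_BANDS.evaluate(axis).astype(np.float32)
        cube = pf.HyperCube(np.broadcast_to(gray, (5, 5, axis.n_channels)).copy(), axis)
        protein, beta = pf.ratio_maps(cube)
        assert np.allclose(protein, protein[0, 0])
        assert np.allclose(beta, beta[0, 0])

    def test_invalid_pixels_are_nan(self, cored_analysis):
        _, _, _, art = cored_analysis
        qc = art["qc"]
        protein, beta = pf.ratio_maps(art["corrected"], qc)
        assert np.isnan(protein[~qc.valid]).all()
        assert np.isfinite(protein[qc.valid]).all()

    def test_cored_scene_compartment_ordering(self, cored_analysis):
        """Mean per-pixel beta ratio: core > corona > surround."""
        _, _, _, art = cored_analysis
        truth = art["truth"]
        qc = art["qc"]
        _, beta = pf.ratio_maps(art["corrected"], qc)
        core = truth.core_masks[0]
        corona = truth.plaque_masks[0] & ~core
        surround = ~truth.plaque_masks[0]
        vals = [np.nanmean(beta[m]) for m in (core, corona, surround)]
        assert vals[0] > vals[1] > vals[2]


def test_spline_resample_preserves_values_at_nodes(axis):
    spec = pf.Spectrum(axis, np.sin(axis.values / 50.0))
    dense = spline_resample(spec, factor=3)
    assert dense.axis.n_channels == (axis.n_channels - 1) * 3 + 1
    assert dense.absorbance[0] == pytest.approx(spec.absorbance[0])
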