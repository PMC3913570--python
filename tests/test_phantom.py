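"""Phantom generator: bolus model, residue kernel, signal model, population build."""

import numpy as np
import pytest
from scipy.integrate import quad

from dscaif import (
    AcquisitionParams,
    AifModelParams,
    SampledCurve,
    TissueClassParams,
    build_phantom,
    calibrate_signal_constant,
    concentration_to_signal,
    gamma_variate,
    make_grid,
    pseudo_aif_grid,
    recirculation_component,
    recirculation_scale,
    residue_function,
    signal_to_concentration,
    tissue_concentration,
    true_aif_curve,
)
from dscaif.phantom import DEFAULT_COMPOSITION, _draw_mtt

from .conftest import brute_force_convolution


class TestGammaVariate:
    @pytest.mark.parametrize(
        "offset, expected",
        [
            (5.0, 125 * np.exp(-10 / 3)),  # sampled maximum on the 1 s grid: 4.4592 to 4 dp
            (4.5, 91.125 * np.exp(-3.0)),  # continuous maximum at alpha*beta: 4.5368 to 4 dp
        ],
    )
    def test_known_values(self, aif_params, offset, expected):
        assert gamma_variate(aif_params.t0 + offset, aif_params) == pytest.approx(expected, rel=1e-12)

    def test_sampled_maximum_prints_table_value(self, aif_params):
        assert round(gamma_variate(aif_params.t0 + 5.0, aif_params), 4) == 4.4592

    def test_vanishes_at_and_before_arrival(self, aif_params):
        t = np.array([0.0, 10.0, aif_params.t0])
        assert np.all(gamma_variate(t, aif_params) == 0.0)

    def test_nonnegative_and_continuous(self, aif_params):
        t = np.linspace(0, 90, 9001)
        v = gamma_variate(t, aif_params)
        assert np.all(v >= 0)
        assert np.max(np.abs(np.diff(v))) < 0.05  # no jumps on a 0.01 s grid

    def test_rejects_non_finite_time(self, aif_params):
        with pytest.raises(ValueError):
            gamma_variate(np.array([1.0, np.nan]), aif_params)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            AifModelParams(alpha=-1.0)
        with pytest.raises(ValueError):
            AifModelParams(beta=0.0)
        with pytest.raises(ValueError):
            AifModelParams(td=-2.0)


class TestRecirculation:
    def test_peak_is_one_third_of_main(self, aif_params):
        for dt in (1.0, 0.05, 0.01):
            grid = make_grid(90.0, dt)
            rec = recirculation_component(grid, aif_params)
            main_peak = np.max(gamma_variate(grid, aif_params))
            assert np.max(rec.values) == pytest.approx(main_peak / 3.0, rel=1e-9)

    def test_zero_until_delayed_arrival(self, aif_params, fine_grid):
        rec = recirculation_component(fine_grid, aif_params)
        cutoff = aif_params.t0 + aif_params.td
        assert np.all(rec.values[fine_grid <= cutoff] == 0.0)

    def test_scale_matches_dense_numerical_solve(self, aif_params):
        # independent oracle: dense convolution + peak-ratio solve on a 0.01 s grid
        grid = make_grid(90.0, 0.01)
        dt = 0.01
        delayed = gamma_variate(grid - aif_params.td, aif_params)
        kernel = np.exp(-grid / aif_params.tau)
        conv = np.convolve(delayed, kernel)[: grid.size] * dt
        expected = (np.max(gamma_variate(grid, aif_params)) / 3.0) / np.max(conv)
        assert recirculation_scale(grid, aif_params) == pytest.approx(expected, rel=1e-12)

    def test_empty_grid_rejected(self, aif_params):
        with pytest.raises(ValueError):
            recirculation_component(np.array([]), aif_params)


class TestTrueAif:
    def test_sampled_maximum_matches_table_anchor(self, true_aif):
        assert np.max(true_aif.values) == pytest.approx(4.4592, abs=5e-5)

    def test_zero_before_arrival(self, true_aif, aif_params):
        assert np.all(true_aif.values[true_aif.times < aif_params.t0] == 0.0)

    def test_is_sum_of_components(self, coarse_grid, aif_params):
        total = true_aif_curve(coarse_grid, aif_params)
        main = gamma_variate(coarse_grid, aif_params)
        rec = recirculation_component(coarse_grid, aif_params)
        np.testing.assert_allclose(total.values, main + rec.values, rtol=1e-12)

    def test_single_global_maximum(self, fine_grid, aif_params):
        v = true_aif_curve(fine_grid, aif_params).values
        peak = np.max(v)
        assert np.sum(v > 0.999 * peak) < 30  # one narrow lobe at the top


class TestResidueFunction:
    def test_integral_equals_mtt(self, coarse_grid):
        for mtt in (0.5, 4.0, 10.0):
            r = residue_function(coarse_grid, mtt)
            assert r.integral() == pytest.approx(mtt, rel=1e-6)

    def test_vanishes_at_origin_and_nonnegative(self, coarse_grid):
        r = residue_function(coarse_grid, 4.0)
        assert r.values[0] == 0.0
        assert np.all(r.values >= 0)

    def test_doubling_mtt_doubles_integral(self, coarse_grid):
        r1 = residue_function(coarse_grid, 3.0)
        r2 = residue_function(coarse_grid, 6.0)
        assert r2.integral() / r1.integral() == pytest.approx(2.0, rel=1e-9)

    def test_rejects_nonpositive_mtt(self, coarse_grid):
        with pytest.raises(ValueError):
            residue_function(coarse_grid, 0.0)


class TestTissueConcentration:
    gm = TissueClassParams("gm_normal", cbv=4.0, mtt_mean=4.0, mtt_sd=0.33, count=0)

    def test_zero_aif_gives_zero_tissue(self, coarse_grid, acq):
        aif = SampledCurve(coarse_grid, np.zeros_like(coarse_grid))
        out = tissue_concentration(aif, self.gm, acq, 4.0)
        assert np.all(out.values == 0.0)

    def test_linear_in_aif_amplitude(self, true_aif, acq):
        doubled = true_aif.with_values(2.0 * true_aif.values)
        c1 = tissue_concentration(true_aif, self.gm, acq, 4.0)
        c2 = tissue_concentration(doubled, self.gm, acq, 4.0)
        np.testing.assert_allclose(c2.values, 2.0 * c1.values, rtol=1e-12)

    def test_matches_brute_force_convolution(self, aif_params, acq):
        # O(n^2) double-loop oracle on a short grid
        grid = make_grid(64.0, 1.0)
        aif = true_aif_curve(grid, aif_params)
        r = residue_function(grid, 4.0)
        expected = (acq.rho / acq.k_h) * (4.0 / 100.0 / 4.0) * brute_force_convolution(
            aif.values, r.values, 1.0
        )
        got = tissue_concentration(aif, self.gm, acq, 4.0)
        np.testing.assert_allclose(got.values, expected, rtol=1e-9, atol=1e-15)


class TestSignalModel:
    def test_calibration_closed_form(self, coarse_grid, acq):
        conc = SampledCurve(coarse_grid, np.where(coarse_grid == 30.0, 1.0, 0.0))
        k = calibrate_signal_constant(conc, acq)
        assert k == pytest.approx(-np.log(0.6) / 0.03, rel=1e-12)  # = 17.0275 to 4 dp

    def test_calibration_gives_forty_percent_drop(self, true_aif, acq):
        gm = TissueClassParams("gm_normal", cbv=4.0, mtt_mean=4.0, mtt_sd=0.33, count=0)
        conc = tissue_concentration(true_aif, gm, acq, 4.0)
        acq_cal = AcquisitionParams(k_signal=calibrate_signal_constant(conc, acq))
        signal = concentration_to_signal(conc, acq_cal)
        assert np.min(signal.values) / acq_cal.s0 == pytest.approx(0.60, abs=1e-12)

    def test_calibration_inverse_proportional_to_peak(self, coarse_grid, acq):
        base = SampledCurve(coarse_grid, np.where(coarse_grid == 30.0, 1.0, 0.0))
        k1 = calibrate_signal_constant(base, acq)
        k2 = calibrate_signal_constant(base.with_values(2.0 * base.values), acq)
        assert k1 / k2 == pytest.approx(2.0, rel=1e-12)

    def test_calibration_rejects_zero_curve(self, coarse_grid, acq):
        with pytest.raises(ValueError):
            calibrate_signal_constant(SampledCurve(coarse_grid, np.zeros_like(coarse_grid)), acq)

    def test_signal_at_zero_concentration_is_baseline(self, coarse_grid):
        acq = AcquisitionParams(k_signal=10.0)
        conc = SampledCurve(coarse_grid, np.zeros_like(coarse_grid))
        assert np.all(concentration_to_signal(conc, acq).values == 100.0)

    def test_closed_form_drop_inversion(self, coarse_grid):
        acq = AcquisitionParams(k_signal=10.0)
        c_star = np.log(10.0 / 6.0) / (acq.k_signal * acq.te)
        conc = SampledCurve(coarse_grid, np.full_like(coarse_grid, c_star))
        np.testing.assert_allclose(concentration_to_signal(conc, acq).values, 60.0, rtol=1e-12)

    def test_round_trip_with_inversion(self, true_aif):
        acq = AcquisitionParams(k_signal=2.0)
        signal = concentration_to_signal(true_aif, acq)
        back = signal_to_concentration(signal, acq.s0, acq)
        np.testing.assert_allclose(back.values, true_aif.values, atol=1e-9)

    def test_requires_calibrated_constant(self, true_aif, acq):
        with pytest.raises(ValueError):
            concentration_to_signal(true_aif, acq)


class TestPseudoAifGrid:
    def test_sixteen_distinct_delay_pairs(self, aif_params):
        grid = pseudo_aif_grid(aif_params)
        assert len(grid) == 16
        pairs = {(p.t0, p.td) for p in grid}
        assert len(pairs) == 16
        assert pairs == {(t0, td) for t0 in (27, 28, 29, 30) for td in (9, 10, 11, 12)}

    def test_first_element_and_copied_fields(self, aif_params):
        first = pseudo_aif_grid(aif_params)[0]
        assert (first.t0, first.td) == (27.0, 9.0)
        assert (first.alpha, first.beta, first.tau) == (
            aif_params.alpha,
            aif_params.beta,
            aif_params.tau,
        )


class TestBuildPhantom:
    def test_default_composition_counts(self, default_phantom):
        assert default_phantom.n_voxels == 1902
        assert default_phantom.label_counts() == dict(DEFAULT_COMPOSITION)

    def test_seeded_determinism(self, default_phantom):
        again = build_phantom(seed=default_phantom.seed)
        np.testing.assert_array_equal(again.curves, default_phantom.curves)
        np.testing.assert_array_equal(again.labels, default_phantom.labels)

    def test_signals_strictly_positive(self, default_phantom):
        assert np.all(default_phantom.curves > 0)

    def test_pre_arrival_samples_at_baseline(self, default_phantom):
        pre = default_phantom.times < default_phantom.aif_params.t0
        np.testing.assert_allclose(default_phantom.curves[:, pre], 100.0, atol=1e-9)

    def test_pve_curves_bounded_by_mixture_parents(self, default_phantom):
        # convex signal mixtures stay within the envelope of arterial and tissue signals
        arterial = default_phantom.curves[0]
        pve = default_phantom.curves[default_phantom.labels == "pve"]
        lo = np.minimum(arterial, default_phantom.curves.min(axis=0))
        assert np.all(pve >= lo - 1e-9)
        assert np.all(pve <= 100.0 + 1e-9)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            build_phantom(seed=0, composition={"true_arterial": -1})
        with pytest.raises(ValueError):
            build_phantom(seed=0, composition={"nonsense": 3})

    def test_mtt_draw_mean_within_three_standard_errors(self):
        rng = np.random.default_rng(1234)
        draws = _draw_mtt(rng, mean=4.0, sd=0.33, size=10_000)
        se = 0.33 / np.sqrt(10_000)
        assert abs(draws.mean() - 4.0) < 3 * se
        assert np.all(draws >= 0.1)
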