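"""The five SIF760 retrievals: exactness regimes, degeneracies, aggregation."""

import math
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluosif import (
    SimConfig,
    aggregate_halfhour,
    filter_sif,
    find_band,
    ifld,
    instrument_model,
    make_irradiance,
    make_sif,
    make_reflectance,
    compose_radiance,
    retrieve_all,
    sfld,
    sfm_linear,
    sfm_nonlinear,
    threefld,
)
from fluosif.retrieval import METHODS, BandSelection
from fluosif.solar import CST
from fluosif.spectra import PairedObservation

from conftest import build_scene


class TestFindBand:
    def test_locates_simulator_dip(self, hr_grid, config):
        band = find_band(make_irradiance(hr_grid, config))
        assert abs(band.lambda_in - config.absorption_center) <= config.step_hr

    def test_flat_spectrum_rejected(self, hr_grid):
        e = make_irradiance(hr_grid, SimConfig(absorption_depth=0.0))
        with pytest.raises(ValueError, match="absorption"):
            find_band(e)

    def test_scale_invariant(self, hr_grid, config):
        e = make_irradiance(hr_grid, config)
        b1 = find_band(e)
        b2 = find_band(e.with_values(e.values * 37.0))
        assert (b1.lambda_in, b1.lambda_left, b1.lambda_right) == (
            b2.lambda_in, b2.lambda_left, b2.lambda_right
        )


class TestExactnessLadder:
    """Each retrieval is exact precisely in its own model regime."""

    def test_sfld_exact_flat_r_constant_sif(self, hr_grid):
        e, _, _, l = build_scene(hr_grid, sif_kind="constant", magnitude=1.5)
        assert sfld(e, l, find_band(e)).sif760 == pytest.approx(1.5, abs=1e-9)

    def test_sfld_zero_sif(self, hr_grid):
        e, _, _, l = build_scene(hr_grid, sif_kind="constant", magnitude=0.0)
        assert sfld(e, l, find_band(e)).sif760 == pytest.approx(0.0, abs=1e-9)

    def test_sfld_biased_under_sloped_reflectance(self, hr_grid):
        e, _, _, l = build_scene(
            hr_grid, r_kind="linear", r_params={"a": 0.002, "b": -1.1},
            sif_kind="constant", magnitude=1.5,
        )
        band = find_band(e)
        res = sfld(e, l, band)
        assert abs(res.sif760 - 1.5) > 1e-3
        # brute-force evaluation of the two-band formula reproduces the bias
        e_in, e_out = e.value_at(band.lambda_in), e.value_at(band.lambda_right)
        l_in, l_out = l.value_at(band.lambda_in), l.value_at(band.lambda_right)
        oracle = (e_out * l_in - e_in * l_out) / (e_out - e_in)
        assert res.sif760 == pytest.approx(oracle, rel=1e-12)

    def test_threefld_exact_flat_continuum_linear_r_linear_sif(self, hr_grid):
        cfg = SimConfig(continuum_coeffs=(1000.0,))
        e, _, s, l = build_scene(
            hr_grid, config=cfg,
            r_kind="linear", r_params={"a": 0.001, "b": -0.36},
            sif_kind="linear", sif_params={"slope": 0.01},
        )
        band = find_band(e)
        truth_at_band = float(s.interp(band.lambda_in))
        assert threefld(e, l, band).sif760 == pytest.approx(truth_at_band, abs=1e-9)

    def test_threefld_equals_sfld_when_flat(self, hr_grid):
        e, _, _, l = build_scene(hr_grid, sif_kind="constant", magnitude=1.5)
        band = find_band(e)
        assert threefld(e, l, band).sif760 == pytest.approx(
            sfld(e, l, band).sif760, abs=1e-9
        )

    def test_threefld_weights_sum_to_one(self, hr_grid, config):
        e, _, _, l = build_scene(hr_grid)
        res = threefld(e, l, find_band(e))
        assert res.params["w_left"] + res.params["w_right"] == pytest.approx(1.0)

    def test_sfm_linear_exact_in_model_family(self, hr_grid):
        e, _, s, l = build_scene(
            hr_grid, r_kind="linear", r_params={"a": 0.001, "b": -0.36},
            sif_kind="linear", sif_params={"slope": 0.01},
        )
        res = sfm_linear(e, l, find_band(e))
        assert res.sif760 == pytest.approx(1.5, abs=1e-6)
        assert res.params["a"] == pytest.approx(0.001, abs=1e-8)
        assert res.params["c"] == pytest.approx(0.01, abs=1e-8)

    def test_sfm_linear_nested_zero_sif(self, hr_grid):
        e, _, _, l = build_scene(
            hr_grid, r_kind="linear", r_params={"a": 0.001, "b": -0.36},
            sif_kind="constant", magnitude=0.0,
        )
        assert sfm_linear(e, l, find_band(e)).sif760 == pytest.approx(0.0, abs=1e-6)

    def test_sfm_linear_degenerate_without_dip(self, hr_grid, config):
        cfg0 = SimConfig(absorption_depth=0.0)
        e, _, _, l = build_scene(hr_grid, config=cfg0)
        band = find_band(make_irradiance(hr_grid, config))  # band from a dipped E
        with pytest.raises(ValueError, match="degenerate"):
            sfm_linear(e, l, band)

    def test_sfm_nonlinear_self_consistent(self, hr_grid):
        e, _, _, l = build_scene(
            hr_grid,
            r_kind="smooth-spline",
            r_params={"knots": [730, 745, 760, 775, 780],
                      "values": [0.38, 0.40, 0.42, 0.45, 0.46]},
            sif_kind="gaussian", magnitude=1.5,
        )
        res = sfm_nonlinear(e, l, find_band(e))
        assert res.ok
        assert res.sif760 == pytest.approx(1.5, abs=1e-3)

    def test_sfm_nonlinear_zero_sif(self, hr_grid):
        e, _, _, l = build_scene(hr_grid, sif_kind="constant", magnitude=0.0)
        res = sfm_nonlinear(e, l, find_band(e))
        assert res.sif760 == pytest.approx(0.0, abs=1e-3)


class TestIFLD:
    def test_unit_alphas_reduce_to_sfld(self, hr_grid):
        """With alpha_R = alpha_F = 1 the iFLD formula is algebraically sFLD;
        single-pixel reads make the identity exact."""
        e, _, _, l = build_scene(hr_grid)
        base = find_band(e)
        band = BandSelection(
            base.lambda_in, base.lambda_left, base.lambda_right,
            base.shoulder_left, base.shoulder_right, base.fit_window,
            shoulder_half_width=0.0, ifld_half_width=0.0,
        )
        e_in, e_out = e.value_at(band.lambda_in), e.value_at(band.lambda_right)
        l_in, l_out = l.value_at(band.lambda_in), l.value_at(band.lambda_right)
        reduced = (1.0 * e_out * l_in - e_in * l_out) / (1.0 * e_out - 1.0 * e_in)
        assert reduced == pytest.approx(sfld(e, l, band).sif760, abs=1e-12)

    def test_flat_scene_recovery_within_2pct(self, hr_grid):
        e, _, _, l = build_scene(hr_grid, sif_kind="constant", magnitude=1.5)
        assert ifld(e, l, find_band(e)).sif760 == pytest.approx(1.5, rel=0.02)

    def test_continuum_interpolation_accuracy(self, hr_grid):
        """The interpolated irradiance at lambda_in approximates the
        no-absorption continuum within 1% for a linear continuum."""
        cfg = SimConfig(continuum_coeffs=(1150.0, -1.0))
        e = make_irradiance(hr_grid, cfg)
        band = find_band(e)
        from fluosif.retrieval import _shoulder_interpolant

        e_tilde = float(_shoulder_interpolant(e, band)(band.lambda_in))
        cont = make_irradiance(hr_grid, SimConfig(continuum_coeffs=(1150.0, -1.0),
                                                  absorption_depth=0.0))
        assert e_tilde == pytest.approx(float(cont.interp(band.lambda_in)), rel=0.01)


class TestRobustnessProperties:
    def test_monotone_in_injected_magnitude(self, truth_grid, hr_grid, config):
        e_t = make_irradiance(truth_grid, config)
        r_t = make_reflectance(truth_grid, "constant", {"value": 0.42})
        e = instrument_model(e_t, config.fwhm_hr, hr_grid, 0.0, 0.0)
        band = find_band(e)
        retrieved = {m: [] for m in METHODS}
        for mag in np.linspace(0.0, 5.0, 6):
            s_t = make_sif(truth_grid, "gaussian", mag, {"peak": 740, "width": 20})
            l = instrument_model(
                compose_radiance(e_t, r_t, s_t), config.fwhm_hr, hr_grid, 0.0, 0.0
            )
            retrieved["sFLD"].append(sfld(e, l, band).sif760)
            retrieved["3FLD"].append(threefld(e, l, band).sif760)
            retrieved["iFLD"].append(ifld(e, l, band).sif760)
            retrieved["SFM_nonlinear"].append(sfm_nonlinear(e, l, band).sif760)
            retrieved["SFM_linear"].append(sfm_linear(e, l, band).sif760)
        for method, vals in retrieved.items():
            assert np.all(np.diff(vals) > 0), method

    def test_all_methods_within_5pct_on_clean_scene(self, truth_grid, hr_grid, config):
        e_t, r_t, s_t, l_t = build_scene(truth_grid, config)
        e = instrument_model(e_t, config.fwhm_hr, hr_grid, 0.0, 0.0)
        l = instrument_model(l_t, config.fwhm_hr, hr_grid, 0.0, 0.0)
        band = find_band(e)
        for fn in (sfld, threefld, ifld, sfm_nonlinear, sfm_linear):
            assert fn(e, l, band).sif760 == pytest.approx(1.5, rel=0.05)

    def test_threefld_noise_error_not_worse_than_sfld(self, truth_grid, hr_grid, config):
        """Median |error| of 3FLD <= sFLD at 1% multiplicative noise."""
        e_t, r_t, s_t, l_t = build_scene(truth_grid, config)
        rng = np.random.default_rng(17)
        err_s, err_3 = [], []
        for _ in range(200):
            e = instrument_model(e_t, config.fwhm_hr, hr_grid, 0.01, 0.0, rng)
            l = instrument_model(l_t, config.fwhm_hr, hr_grid, 0.01, 0.0, rng)
            band = find_band(e)
            err_s.append(abs(sfld(e, l, band).sif760 - 1.5))
            err_3.append(abs(threefld(e, l, band).sif760 - 1.5))
        assert np.median(err_3) <= np.median(err_s)

    def test_sfm_linear_most_shift_sensitive(self, truth_grid, hr_grid, config):
        """A radiance-only wavelength shift perturbs the linear spectral fit
        far more than any line-depth method (the in-band reads sit at the
        dip minimum where the first-order shift effect vanishes)."""
        e_t, r_t, s_t, l_t = build_scene(truth_grid, config)
        e = instrument_model(e_t, config.fwhm_hr, hr_grid, 0.0, 0.0)
        l0 = instrument_model(l_t, config.fwhm_hr, hr_grid, 0.0, 0.0)
        ls = instrument_model(l_t, config.fwhm_hr, hr_grid, 0.0, 0.02)
        band = find_band(e)
        deltas = {
            fn.__name__: abs(fn(e, ls, band).sif760 - fn(e, l0, band).sif760)
            for fn in (sfld, threefld, ifld, sfm_linear)
        }
        assert deltas["sfm_linear"] > max(
            deltas["sfld"], deltas["threefld"], deltas["ifld"]
        )


class TestRetrieveAll:
    def test_isolation_and_completeness(self, observed_scene):
        e, l = observed_scene
        obs = PairedObservation(datetime(2019, 7, 1, 12, tzinfo=CST), e_hr=e, l_hr=l)
        results = retrieve_all(obs)
        assert set(results) == set(METHODS)
        assert all(r.ok for r in results.values())

    def test_band_failure_flags_all_methods(self, hr_grid):
        e = make_irradiance(hr_grid, SimConfig(absorption_depth=0.0))
        obs = PairedObservation(datetime(2019, 7, 1, 12, tzinfo=CST), e_hr=e, l_hr=e)
        results = retrieve_all(obs)
        assert all(not r.ok and math.isnan(r.sif760) for r in results.values())

    def test_reproducible(self, observed_scene):
        e, l = observed_scene
        obs = PairedObservation(datetime(2019, 7, 1, 12, tzinfo=CST), e_hr=e, l_hr=l)
        a = {m: r.sif760 for m, r in retrieve_all(obs).items()}
        b = {m: r.sif760 for m, r in retrieve_all(obs).items()}
        assert a == b


class TestFilterAndAggregate:
    def test_filter_reference_case(self):
        out = filter_sif([-0.1, 0.0, 2.3, 5.0, 5.2])
        np.testing.assert_array_equal(out, [0.0, 2.3, 5.0])

    def test_filter_keeps_valid_and_empty(self):
        np.testing.assert_array_equal(filter_sif([1.0, 2.0]), [1.0, 2.0])
        assert filter_sif([]).size == 0

    @given(
        st.lists(st.floats(allow_nan=False, allow_infinity=False,
                           min_value=-50, max_value=50), max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_filter_bounds_property(self, values):
        out = filter_sif(values)
        assert np.all((out >= 0.0) & (out <= 5.0))
        assert out.size == sum(0.0 <= v <= 5.0 for v in values)

    @staticmethod
    def _series(values, start="2019-07-01 10:00"):
        idx = pd.date_range(start, periods=len(values), freq="5min")
        return pd.Series(values, index=idx, dtype=float)

    def test_four_points_is_missing(self):
        s = self._series([1.0, 1.0, 1.0, 1.0, np.nan, np.nan])
        out = aggregate_halfhour(s)
        assert out["n"].iloc[0] == 4 and math.isnan(out["mean"].iloc[0])

    def test_six_identical_values(self):
        s = self._series([2.0] * 6)
        out = aggregate_halfhour(s)
        assert out["mean"].iloc[0] == 2.0 and out["stderror"].iloc[0] == 0.0

    def test_stderror_matches_hand_computation(self):
        vals = [1.0, 2.0, 2.5, 3.0, 4.0]
        s = self._series(vals + [np.nan])
        out = aggregate_halfhour(s)
        assert out["stderror"].iloc[0] == pytest.approx(
            np.std(vals, ddof=1) / math.sqrt(5)
        )

    def test_bin_edges(self):
        idx = [pd.Timestamp("2019-07-01 10:25"), pd.Timestamp("2019-07-01 10:30")]
        s = pd.Series([1.0, 2.0], index=pd.DatetimeIndex(idx))
        out = aggregate_halfhour(s, min_count=1)
        assert list(out.index) == [
            pd.Timestamp("2019-07-01 10:00"), pd.Timestamp("2019-07-01 10:30")
        ]
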