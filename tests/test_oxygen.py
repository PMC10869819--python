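"""Schmidt scaling, source apportionment, forward integration and daily R2."""

import numpy as np
import pandas as pd
import pytest

from rivermetab import SyntheticConfig, simulate_site
from rivermetab.model.oxygen import (
    apportion_sources,
    daily_r2,
    forward_simulate,
    k600_to_kgas,
    schmidt_number,
    split_metabolic_days,
)
from rivermetab.synthetic import truth_frame


class TestSchmidt:
    @pytest.mark.parametrize("t, expected", [(0.0, 1568.0), (10.0, 900.2), (20.0, 531.2)])
    def test_polynomial_values(self, t, expected):
        assert schmidt_number(t) == pytest.approx(expected, abs=1e-6)

    def test_positive_over_range(self):
        assert (schmidt_number(np.linspace(0, 40, 100)) > 0).all()

    def test_domain(self):
        with pytest.raises(ValueError):
            schmidt_number(45.0)


class TestK600Conversion:
    def test_normalization_point(self):
        # find T where Sc = 600 and check K2 == K600 there
        from scipy.optimize import brentq

        t600 = brentq(lambda t: schmidt_number(t) - 600.0, 0, 40)
        assert k600_to_kgas(5.0, t600) == pytest.approx(5.0, rel=1e-9)

    def test_evaluation_at_20C(self):
        assert k600_to_kgas(10.0, 20.0) == pytest.approx(10.628, abs=1e-3)

    def test_zero_maps_to_zero(self):
        assert k600_to_kgas(0.0, 15.0) == 0.0


class TestApportionment:
    def test_uniform_light_gives_constant_rate(self):
        p, r = apportion_sources(4.0, -2.0, 2.0, np.ones(96))
        np.testing.assert_allclose(p, 4.0 / 2.0)
        np.testing.assert_allclose(r, -1.0)

    def test_dark_intervals_carry_no_production(self):
        light = np.zeros(96)
        light[40:56] = 500.0
        p, _ = apportion_sources(4.0, -2.0, 2.0, light)
        assert (p[:40] == 0).all() and (p[56:] == 0).all()

    def test_interval_share_follows_light_share(self):
        light = np.zeros(96)
        light[40:48] = 1.0
        light[50] = 8.0  # half of the day's light in one interval
        p, _ = apportion_sources(4.0, 0.0, 2.0, light)
        dt = 1.0 / 96.0
        assert p[50] * dt == pytest.approx(0.5 * 4.0 / 2.0)

    def test_integral_conservation(self):
        rng = np.random.default_rng(7)
        light = rng.uniform(0, 1000, 96)
        gpp, er, h = 5.3, -6.1, 1.7
        p, r = apportion_sources(gpp, er, h, light)
        dt = 1.0 / 96.0
        assert p.sum() * dt == pytest.approx(gpp / h)
        assert r.sum() * dt == pytest.approx(er / h)

    def test_all_dark_with_gpp_is_degenerate(self):
        with pytest.raises(ValueError, match="light"):
            apportion_sources(4.0, -2.0, 2.0, np.zeros(96))


def _flat_forcing(n_days=1, temp=20.0, do=None):
    idx = pd.date_range("2020-06-01 04:00", periods=96 * n_days, freq="15min")
    from rivermetab.prep import ForcingSeries, do_saturation, light_ppfd

    frame = pd.DataFrame(
        {
            "DO.obs": do_saturation(temp) if do is None else do,
            "DO.sat": do_saturation(temp),
            "depth": 2.0,
            "temp.water": temp,
            "light": light_ppfd(idx, 41.3),
            "discharge": 50.0,
            "gage.height": 1.2,
            "salinity": 0.0,
            "pressure": 1013.25,
            "usable": True,
        },
        index=idx,
    )
    return ForcingSeries(frame, latitude=41.3, longitude=-88.7)


class TestForwardSimulate:
    def test_equilibrium_fixed_point(self):
        forcing = _flat_forcing()
        params = pd.DataFrame(
            {"GPP": [0.0], "ER": [0.0], "K600": [3.0]}, index=[pd.Timestamp("2020-06-01")]
        )
        from rivermetab.prep import do_saturation

        out = forward_simulate(params, forcing, o2_init=do_saturation(20.0))
        np.testing.assert_allclose(out.to_numpy(), do_saturation(20.0), rtol=1e-12)

    def test_large_k600_tracks_saturation(self):
        forcing = _flat_forcing()
        date = pd.Timestamp("2020-06-01")
        devs = []
        for k in (2.0, 10.0, 40.0):
            params = pd.DataFrame({"GPP": [5.0], "ER": [-5.0], "K600": [k]}, index=[date])
            out = forward_simulate(params, forcing, o2_init=9.0)
            devs.append(np.max(np.abs(out.to_numpy() - forcing.frame["DO.sat"].to_numpy())))
        assert devs[0] > devs[1] > devs[2]

    def test_deterministic_without_process_noise(self):
        forcing = _flat_forcing()
        params = pd.DataFrame(
            {"GPP": [5.0], "ER": [-5.0], "K600": [3.0]}, index=[pd.Timestamp("2020-06-01")]
        )
        a = forward_simulate(params, forcing, o2_init=9.0)
        b = forward_simulate(params, forcing, o2_init=9.0)
        pd.testing.assert_series_equal(a, b)

    def test_euler_matches_one_second_reference(self):
        """15-minute Euler within 0.01 mg/L of a 1-second-step integration."""
        forcing = _flat_forcing()
        day = split_metabolic_days(forcing)[0]
        gpp, er, k600, o0 = 5.0, -5.0, 3.0, 9.0
        k2 = k600 * day.sc_fac
        p = (gpp / day.depth) * day.frac_rate
        r = er / day.depth
        dt = day.dt_days

        coarse = np.empty(day.n_obs)
        state = o0
        for i in range(day.n_obs):
            coarse[i] = state
            state += dt * (p[i] + r + k2[i] * (day.do_sat[i] - state))

        nsub = 900  # 1-second substeps per 15-minute interval
        fine = np.empty(day.n_obs)
        state = o0
        for i in range(day.n_obs):
            fine[i] = state
            for _ in range(nsub):
                state += (dt / nsub) * (p[i] + r + k2[i] * (day.do_sat[i] - state))

        assert np.max(np.abs(coarse - fine)) < 0.01

    def test_daytime_do_exceeds_night_only_simulation(self, noise_free_site):
        _, forcing, truth = noise_free_site
        tf = truth_frame(truth)
        date = tf.index[0]
        params_gpp = pd.DataFrame(
            {"GPP": [4.0], "ER": [0.0], "K600": [tf["K600_true"].iloc[0]]}, index=[date]
        )
        params_dark = params_gpp.assign(GPP=0.0)
        day = split_metabolic_days(forcing)[0]
        sub = forcing.frame.loc[day.index]
        from rivermetab.prep import ForcingSeries

        f1 = ForcingSeries(sub, forcing.latitude, forcing.longitude)
        lit = forward_simulate(params_gpp, f1, o2_init=8.0)
        dark = forward_simulate(params_dark, f1, o2_init=8.0)
        daylight = day.frac_rate > 0
        # production accumulates: strictly higher DO after the first lit step
        lag = np.roll(daylight, 1)
        lag[0] = False
        assert (lit.to_numpy()[lag] > dark.to_numpy()[lag]).all()


class TestDailyR2:
    def test_perfect_model(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert daily_r2(obs, obs) == pytest.approx(1.0)

    def test_mean_model_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert daily_r2(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert daily_r2(obs, obs[::-1]) < 0

    def test_degenerate_cases_are_nan(self):
        assert np.isnan(daily_r2([1.0, 1.0, 1.0], [1.0, 1.1, 0.9]))
        assert np.isnan(daily_r2([1.0, 2.0], [1.0, 2.0]))
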