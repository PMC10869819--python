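"""Series preparation: regridding, gap filling, unit conversion, solubility,
salinity, solar time and clear-sky light."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rivermetab import prep
from rivermetab.prep import (
    RawSeries,
    assemble_input,
    do_saturation,
    light_ppfd,
    regrid_and_fill,
    salinity_from_conductance,
    utc_to_solar,
)


def _raw(times, values, kind="do", units="mg/L"):
    return RawSeries(pd.DatetimeIndex(times), np.asarray(values, float), kind, units)


class TestRegridAndFill:
    def test_short_gap_linearly_interpolated(self):
        raw = _raw(["2020-01-01 00:00", "2020-01-01 02:00"], [2.0, 4.0])
        out = regrid_and_fill(raw)
        assert out.loc["2020-01-01 00:15+00:00"] == pytest.approx(2.25)
        assert out.loc["2020-01-01 01:00+00:00"] == pytest.approx(3.0)
        assert not out.isna().any()

    def test_long_gap_left_missing(self):
        raw = _raw(["2020-01-01 00:00", "2020-01-01 04:00"], [2.0, 4.0])
        out = regrid_and_fill(raw)
        assert out.loc["2020-01-01 02:00+00:00":"2020-01-01 03:45+00:00"].isna().all()
        assert out.iloc[0] == 2.0 and out.iloc[-1] == 4.0

    def test_gap_of_exactly_three_hours_not_filled(self):
        raw = _raw(["2020-01-01 00:00", "2020-01-01 03:00"], [1.0, 2.0])
        out = regrid_and_fill(raw)
        assert out.iloc[1:-1].isna().all()

    def test_cubic_feet_converted_to_cubic_meters(self):
        raw = _raw(
            ["2020-01-01 00:00", "2020-01-01 00:15"], [100.0, 100.0],
            kind="discharge", units="ft3/s",
        )
        out = regrid_and_fill(raw)
        assert out.iloc[0] == pytest.approx(2.8317, abs=1e-4)

    def test_idempotent_on_gridded_series(self):
        idx = pd.date_range("2020-01-01", periods=20, freq="15min", tz="UTC")
        vals = np.sin(np.arange(20.0))
        raw = _raw(idx, vals)
        out = regrid_and_fill(raw)
        assert (out.index == idx).all()
        np.testing.assert_allclose(out.to_numpy(), vals)

    def test_duplicates_averaged_with_warning(self):
        raw = _raw(
            ["2020-01-01 00:00", "2020-01-01 00:00", "2020-01-01 00:15"],
            [1.0, 3.0, 5.0],
        )
        with pytest.warns(UserWarning, match="duplicate"):
            out = regrid_and_fill(raw)
        assert out.iloc[0] == pytest.approx(2.0)

    def test_all_missing_returns_empty_not_crash(self):
        raw = _raw(["2020-01-01 00:00", "2020-01-01 01:00"], [np.nan, np.nan])
        assert len(regrid_and_fill(raw)) == 0

    def test_rejects_wrong_units(self):
        with pytest.raises(ValueError, match="units"):
            _raw(["2020-01-01"], [1.0], kind="do", units="ft")


class TestSalinity:
    def test_zero_conductance_is_fresh(self):
        assert salinity_from_conductance(0.0) == 0.0

    def test_standard_seawater_reference(self):
        assert salinity_from_conductance(53087.0) == pytest.approx(35.0, abs=0.05)

    def test_typical_river_range(self):
        assert 0.1 < salinity_from_conductance(500.0) < 0.4

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            salinity_from_conductance(-1.0)

    @given(st.floats(0, 60000), st.floats(0, 1000))
    def test_monotone_nondecreasing(self, spc, delta):
        assert salinity_from_conductance(spc + delta) >= salinity_from_conductance(spc)


class TestSolarTime:
    @pytest.mark.parametrize(
        "longitude, hours",
        [(-90.0, -6.0), (0.0, 0.0), (-88.25, -5.8833), (180.0, 12.0)],
    )
    def test_longitude_offset(self, longitude, hours):
        t = pd.Timestamp("2020-06-01 12:00")
        out = utc_to_solar(t, longitude)
        assert (out - t) / pd.Timedelta(hours=1) == pytest.approx(hours, abs=1e-3)

    def test_day_length_exactly_24h(self):
        idx = pd.date_range("2020-06-01", periods=3, freq="24h")
        out = utc_to_solar(idx, -88.0)
        assert ((out[1:] - out[:-1]) == pd.Timedelta(hours=24)).all()

    def test_invalid_longitude(self):
        with pytest.raises(ValueError):
            utc_to_solar(pd.Timestamp("2020-01-01"), -200.0)


class TestDOSaturation:
    def test_freshwater_20C_reference_value(self):
        # published freshwater solubility table: ~9.08-9.09 mg/L at 20 degC, 1 atm
        assert do_saturation(20.0, 1013.25, 0.0) == pytest.approx(9.08, abs=0.03)

    def test_approximately_proportional_to_pressure(self):
        ratio = do_saturation(20.0, 2026.5, 0.0) / do_saturation(20.0, 1013.25, 0.0)
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_salting_out(self):
        assert do_saturation(20.0, 1013.25, 35.0) < do_saturation(20.0, 1013.25, 0.0)

    def test_decreasing_in_temperature(self):
        temps = np.linspace(0.0, 40.0, 30)
        sat = do_saturation(temps)
        assert (np.diff(sat) < 0).all()

    def test_out_of_range_temperature(self):
        with pytest.raises(ValueError):
            do_saturation(50.0)


class TestLight:
    def test_zero_at_solar_midnight(self):
        t = pd.DatetimeIndex(["2020-06-21 00:00"])
        assert light_ppfd(t, 41.1)[0] == 0.0

    def test_peak_at_solar_noon_and_symmetric(self):
        idx = pd.date_range("2020-06-21", periods=96, freq="15min")
        ppfd = light_ppfd(idx, 41.1)
        assert np.argmax(ppfd) == 48  # 12:00
        np.testing.assert_allclose(ppfd[1:48], ppfd[49:][::-1], rtol=1e-8)

    def test_june_daylight_duration_at_41N(self):
        idx = pd.date_range("2020-06-21", periods=1440, freq="1min")
        ppfd = light_ppfd(idx, 41.1)
        daylight_h = (ppfd > 0).sum() / 60.0
        assert daylight_h == pytest.approx(15.0, abs=0.5)

    def test_pure_function(self):
        idx = pd.date_range("2020-03-20", periods=10, freq="15min")
        np.testing.assert_array_equal(light_ppfd(idx, 10.0), light_ppfd(idx, 10.0))


class TestAssembleInput:
    @staticmethod
    def _components(n=192):
        idx = pd.date_range("2020-06-01", periods=n, freq="15min", tz="UTC")
        return idx, {
            "do": pd.Series(8.0, index=idx),
            "temp": pd.Series(20.0, index=idx),
            "discharge": pd.Series(50.0, index=idx),
            "gage_height": pd.Series(1.2, index=idx),
        }

    def test_row_count_preserved(self):
        idx, comps = self._components()
        forcing = assemble_input(comps, 41.3, -88.7, depth=pd.Series(2.0, index=idx))
        assert len(forcing.frame) == len(idx)
        assert forcing.frame["usable"].all()

    def test_missing_temperature_flags_row(self):
        idx, comps = self._components()
        comps["temp"].iloc[5] = np.nan
        forcing = assemble_input(comps, 41.3, -88.7, depth=pd.Series(2.0, index=idx))
        assert not forcing.frame["usable"].iloc[5]
        assert forcing.frame["usable"].drop(forcing.frame.index[5]).all()
        assert np.isnan(forcing.frame["DO.sat"].iloc[5])

    def test_inputs_pass_through_unchanged(self):
        idx, comps = self._components()
        forcing = assemble_input(comps, 41.3, -88.7, depth=pd.Series(2.0, index=idx))
        np.testing.assert_array_equal(forcing.frame["DO.obs"], comps["do"].to_numpy())
        np.testing.assert_array_equal(
            forcing.frame["discharge"], comps["discharge"].to_numpy()
        )

    def test_solar_shift_applied(self):
        idx, comps = self._components()
        forcing = assemble_input(comps, 41.3, -90.0, depth=pd.Series(2.0, index=idx))
        expected = idx.tz_localize(None) - pd.Timedelta(hours=6)
        assert (forcing.frame.index == expected).all()

    def test_requires_do_and_temp(self):
        idx, comps = self._components()
        del comps["temp"]
        with pytest.raises(ValueError, match="temperature"):
            assemble_input(comps, 41.3, -88.7, depth=pd.Series(2.0, index=idx))
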