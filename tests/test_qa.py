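"""Daily flags, censoring, the five-criterion confidence rubric, summaries
and the basin rollup."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rivermetab.model.bayes import DailyMetabolism, FitDiagnostics
from rivermetab.qa import (
    ConfidenceAssessment,
    apply_flags,
    assess_confidence,
    basin_rollup,
    censor,
    combine_ratings,
    reach_length,
    site_summary,
)


def _day(gpp=3.0, er=-5.0, k600=4.0, r2=0.9, date=0):
    return DailyMetabolism(
        date=date, GPP=gpp, ER=er, K600=k600,
        gpp_sd=0.1, er_sd=0.1, k600_sd=0.1, r2_det=r2, n_obs=96,
    )


def _diag(rhat=1.05, er_k600_r2=0.1):
    return FitDiagnostics(
        rhat_sigma_obs=rhat, rhat_sigma_proc=rhat, rhat_sigma_k600=rhat,
        er_k600_r2=er_k600_r2, n_chains=4, n_warmup=1000,
    )


class TestReachLength:
    def test_turnover_distance(self):
        assert reach_length(10_000.0, 2.0) == pytest.approx(8047.2, abs=0.5)

    def test_zero_velocity(self):
        assert reach_length(0.0, 2.0) == 0.0

    def test_linear_in_velocity(self):
        assert reach_length(2000.0, 1.3) == pytest.approx(2 * reach_length(1000.0, 1.3))

    def test_nonpositive_k_is_nan(self):
        assert np.isnan(reach_length(1000.0, 0.0))


class TestFlags:
    def test_gpp_threshold_boundary(self):
        days = [_day(gpp=-0.6, date=0), _day(gpp=-0.4, date=1)] + [
            _day(date=i) for i in range(2, 10)
        ]
        flags = apply_flags(days)
        assert flags[0].flag2_gpp and not flags[1].flag2_gpp

    def test_er_threshold_boundary(self):
        days = [_day(er=0.6, date=0), _day(er=0.5, date=1), _day(er=0.4, date=2)]
        flags = apply_flags(days)
        assert [f.flag3_er for f in flags] == [True, False, False]

    def test_k600_threshold_boundary(self):
        days = [_day(k600=25.0, date=0), _day(k600=20.0, date=1)]
        flags = apply_flags(days)
        assert flags[0].flag4_k600 and not flags[1].flag4_k600

    def test_flag1_inactive_when_percentile_positive(self):
        # 15th percentile of r2 is positive -> no day flagged however low its r2
        r2s = [0.2, 0.3, 0.5, 0.6, 0.9, 0.95, 0.99, 0.4, 0.7, 0.8]
        flags = apply_flags([_day(r2=r, date=i) for i, r in enumerate(r2s)])
        assert not any(f.flag1_low_snr for f in flags)

    def test_flag1_active_when_percentile_negative(self):
        r2s = [-0.9, -0.5, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        flags = apply_flags([_day(r2=r, date=i) for i, r in enumerate(r2s)])
        thresh = np.percentile(r2s, 15)
        assert thresh < 0
        expect = [r < thresh for r in r2s]
        assert [f.flag1_low_snr for f in flags] == expect

    def test_any_flag_is_or_of_four(self):
        days = [_day(gpp=-1.0, k600=30.0, date=0), _day(date=1)]
        flags = apply_flags(days)
        assert flags[0].any_flag and not flags[1].any_flag


class TestCensor:
    def test_no_flags_identity(self):
        days = [_day(date=i) for i in range(5)]
        assert censor(days, apply_flags(days)) == days

    def test_all_flagged_empty_not_error(self):
        days = [_day(gpp=-2.0, date=i) for i in range(3)]
        assert censor(days, apply_flags(days)) == []

    def test_order_preserved(self):
        days = [_day(gpp=(-2.0 if i in (1, 4, 7) else 3.0), date=i) for i in range(10)]
        kept = censor(days, apply_flags(days))
        assert [d.date for d in kept] == [0, 2, 3, 5, 6, 8, 9]


class TestConfidence:
    @pytest.mark.parametrize("pct_bad, expected", [(10, "HIGH"), (30, "MEDIUM"), (60, "LOW")])
    def test_c1_bins(self, pct_bad, expected):
        n = 10
        n_bad = pct_bad * n // 100
        days = [_day(gpp=-1.0, date=i) for i in range(n_bad)] + [
            _day(date=i) for i in range(n_bad, n)
        ]
        conf = assess_confidence(days, apply_flags(days), _diag(),
                                 reach_lengths=[1.0] * n,
                                 upstream_structure_distance_m=1e6)
        assert conf.c1_gpp_rating == expected

    @pytest.mark.parametrize("pct_bad, expected", [(20, "HIGH"), (40, "MEDIUM"), (50, "LOW")])
    def test_c2_bins(self, pct_bad, expected):
        n = 10
        n_bad = pct_bad * n // 100
        days = [_day(er=1.0, date=i) for i in range(n_bad)] + [
            _day(date=i) for i in range(n_bad, n)
        ]
        conf = assess_confidence(days, apply_flags(days), _diag(),
                                 reach_lengths=[1.0] * n,
                                 upstream_structure_distance_m=1e6)
        assert conf.c2_er_rating == expected

    @pytest.mark.parametrize(
        "spread, expected", [(10.0, "HIGH"), (30.0, "MEDIUM"), (50.0, "MEDIUM"), (60.0, "LOW")]
    )
    def test_c3_k600_spread_bins(self, spread, expected):
        # construct K600 values whose 90th-10th percentile equals `spread`
        k = np.concatenate([np.full(10, 1.0), np.full(10, 1.0 + spread)])
        days = [_day(k600=float(v), date=i) for i, v in enumerate(k)]
        conf = assess_confidence(days, apply_flags(days), _diag(),
                                 reach_lengths=[1.0] * len(k),
                                 upstream_structure_distance_m=1e6)
        assert conf.c3_k600_range_rating == expected

    @pytest.mark.parametrize("rhat, expected", [(1.15, "HIGH"), (1.25, "LOW"), (1.2, "LOW")])
    def test_c4_convergence_binary(self, rhat, expected):
        days = [_day(date=i) for i in range(4)]
        diag = FitDiagnostics(
            rhat_sigma_obs=1.0, rhat_sigma_proc=1.0, rhat_sigma_k600=rhat,
            er_k600_r2=0.1, n_chains=4, n_warmup=1000,
        )
        conf = assess_confidence(days, apply_flags(days), diag,
                                 reach_lengths=[1.0] * 4,
                                 upstream_structure_distance_m=1e6)
        assert conf.c4_convergence_rating == expected

    @pytest.mark.parametrize(
        "frac_beyond, expected", [(0.9, "HIGH"), (0.7, "MEDIUM"), (0.4, "LOW")]
    )
    def test_c5_reach_bins(self, frac_beyond, expected):
        n = 10
        n_beyond = int(frac_beyond * n)
        # distance 1000 m; reach shorter than distance on n_beyond days
        reach = [500.0] * n_beyond + [5000.0] * (n - n_beyond)
        days = [_day(date=i) for i in range(n)]
        conf = assess_confidence(days, apply_flags(days), _diag(),
                                 reach_lengths=reach,
                                 upstream_structure_distance_m=1000.0)
        assert conf.c5_reach_rating == expected

    def test_missing_upstream_distance_caps_at_medium(self):
        days = [_day(date=i) for i in range(4)]
        with pytest.warns(UserWarning, match="upstream"):
            conf = assess_confidence(days, apply_flags(days), _diag())
        assert conf.c5_reach_rating == "MISSING"
        assert conf.overall == "MEDIUM"

    @pytest.mark.parametrize(
        "ratings, expected",
        [
            (["HIGH"] * 5, "HIGH"),
            (["HIGH", "MEDIUM", "HIGH", "HIGH", "HIGH"], "MEDIUM"),
            (["HIGH", "HIGH", "HIGH", "LOW", "HIGH"], "LOW"),
            (["MEDIUM"] * 5, "MEDIUM"),
        ],
    )
    def test_combination_rule(self, ratings, expected):
        assert combine_ratings(ratings) == expected

    @given(st.lists(st.sampled_from(["HIGH", "MEDIUM", "LOW"]), min_size=5, max_size=5),
           st.integers(0, 4))
    def test_combination_monotone_under_upgrade(self, ratings, i):
        order = {"LOW": 0, "MEDIUM": 1, "HIGH": 2}
        upgraded = list(ratings)
        upgraded[i] = {"LOW": "MEDIUM", "MEDIUM": "HIGH", "HIGH": "HIGH"}[ratings[i]]
        assert order[combine_ratings(upgraded)] >= order[combine_ratings(ratings)]


class TestSiteSummary:
    def test_half_autotrophic(self):
        days = [_day(gpp=4.0, er=-3.0, date=0), _day(gpp=2.0, er=-3.0, date=1)]
        s = site_summary(days, apply_flags(days))
        assert s.pct_autotrophic == 50.0

    def test_all_heterotrophic(self):
        days = [_day(gpp=1.0, er=-3.0, date=i) for i in range(4)]
        s = site_summary(days, apply_flags(days))
        assert s.pct_autotrophic == 0.0

    def test_means_use_unflagged_days_only(self):
        days = [_day(gpp=3.0, date=0), _day(gpp=-2.0, date=1)]  # second flagged
        s = site_summary(days, apply_flags(days))
        assert s.n_days_unflagged == 1
        assert s.mean_gpp == pytest.approx(3.0)

    def test_empty_after_censoring_gives_missing_values(self):
        days = [_day(gpp=-2.0, date=i) for i in range(3)]
        s = site_summary(days, apply_flags(days))
        assert s.n_days_unflagged == 0
        assert np.isnan(s.mean_gpp)

    def test_censor_then_summarize_consistency(self):
        days = [_day(gpp=(-2.0 if i % 3 == 0 else 3.0 + i), date=i) for i in range(9)]
        flags = apply_flags(days)
        s1 = site_summary(days, flags)
        kept = censor(days, flags)
        from rivermetab.qa import FlagSet

        clean_flags = [
            FlagSet(date=d.date, flag1_low_snr=False, flag2_gpp=False,
                    flag3_er=False, flag4_k600=False)
            for d in kept
        ]
        s2 = site_summary(kept, clean_flags)
        assert s1.mean_gpp == pytest.approx(s2.mean_gpp)
        assert s1.mean_nep == pytest.approx(s2.mean_nep)


class TestBasinRollup:
    def test_published_table_aggregates(self):
        from rivermetab.io import load_published_site_summaries

        summaries, confidences = load_published_site_summaries()
        roll = basin_rollup(summaries, confidences)
        assert roll["n_sites"] == 17
        assert roll["mean_gpp"] == pytest.approx(2.77, abs=0.01)
        assert roll["mean_er"] == pytest.approx(-6.05, abs=0.005)
        assert roll["mean_nep"] == pytest.approx(-3.28, abs=0.005)
        assert roll["mean_pct_days_flagged"] == 29
        assert roll["pct_autotrophic_by_group"]["illinois"] == 33
        assert roll["pct_autotrophic_by_group"]["fox"] == 43
        assert roll["pct_autotrophic_by_group"]["kankakee"] == 1
        assert roll["pct_high_or_medium_confidence"] == 76

    def test_fox_group_mean_gpp(self):
        from rivermetab.io import load_published_site_summaries

        summaries, _ = load_published_site_summaries()
        fox = [s.mean_gpp for s in summaries if s.group == "fox"]
        assert np.mean(fox) == pytest.approx(7.13, abs=0.005)

    def test_single_site_rollup_equals_site(self):
        days = [_day(gpp=3.0, er=-2.0, date=i) for i in range(4)]
        s = site_summary(days, apply_flags(days), site_id="x", group="g")
        roll = basin_rollup([s], ["HIGH"])
        assert roll["mean_gpp"] == pytest.approx(s.mean_gpp)
        assert roll["mean_nep"] == pytest.approx(s.mean_nep)
        assert roll["pct_high_or_medium_confidence"] == 100


class TestNEPIdentity:
    def test_nep_is_exactly_gpp_plus_er(self):
        d = _day(gpp=3.123456, er=-2.654321)
        assert d.NEP == d.GPP + d.ER
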