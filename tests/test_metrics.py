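"""Session-RPE load metrics, quantile binning and cohort assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acwr_bayes import metrics
from acwr_bayes.metrics import (
    QuantileBinning,
    SessionRecord,
    acute_load,
    acwr,
    acwrr,
    build_observation_table,
    chronic_load,
    cumulative_load,
    fit_quantile_binning,
    monotony,
    session_load,
)


class TestSessionLoad:
    @pytest.mark.parametrize(
        "duration,rpe,expected",
        [(60, 4, 240), (0, 7, 0), (90, 7, 630)],
    )
    def test_examples(self, duration, rpe, expected):
        assert session_load(duration, rpe) == expected

    @pytest.mark.parametrize("duration,rpe", [(-1, 5), (60, -0.5), (60, 10.5)])
    def test_invalid_inputs(self, duration, rpe):
        with pytest.raises(ValueError):
            session_load(duration, rpe)

    @given(
        duration=st.floats(0.1, 300),
        rpe=st.floats(0.1, 5),
    )
    def test_bilinear(self, duration, rpe):
        base = session_load(duration, rpe)
        assert session_load(2 * duration, rpe) == pytest.approx(2 * base)
        assert session_load(duration, 2 * rpe) == pytest.approx(2 * base)


class TestWeeklyAggregates:
    def test_acute_load_sums_sessions(self):
        recs = [
            SessionRecord("A", 1, 1, 60, 4),   # 240
            SessionRecord("A", 1, 2, 60, 5),   # 300
            SessionRecord("A", 1, 3, 92, 5),   # 460
        ]
        assert acute_load(recs) == 1000

    def test_acute_load_empty_week_is_zero(self):
        assert acute_load([]) == 0.0

    def test_acute_load_seven_identical_sessions(self):
        recs = [SessionRecord("A", 1, d, 60, 5) for d in range(1, 8)]
        assert acute_load(recs) == 2100

    def test_acute_load_rejects_mixed_weeks(self):
        recs = [SessionRecord("A", 1, 1, 60, 4), SessionRecord("A", 2, 1, 60, 4)]
        with pytest.raises(ValueError):
            acute_load(recs)

    @pytest.mark.parametrize(
        "seq,k,expected",
        [([1000, 1200], 2, 2200), ([500], 1, 500), ([400] * 4, 4, 1600)],
    )
    def test_cumulative_load(self, seq, k, expected):
        assert cumulative_load(seq, k) == expected

    def test_cumulative_load_needs_enough_weeks(self):
        with pytest.raises(ValueError):
            cumulative_load([100, 200], 3)

    def test_cumulative_1w_equals_acute(self):
        seq = [800.0, 950.0, 1100.0]
        assert cumulative_load(seq, 1) == seq[-1]

    @pytest.mark.parametrize(
        "seq,expected",
        [([1000] * 4, 1000), ([800, 1200, 1600, 2000], 1400)],
    )
    def test_chronic_load(self, seq, expected):
        assert chronic_load(seq) == expected

    @given(c=st.floats(1, 1e4), n=st.integers(4, 10))
    def test_chronic_of_constant_series_is_identity(self, c, n):
        assert chronic_load([c] * n) == pytest.approx(c)

    def test_chronic_times_four_is_cumulative_four(self):
        seq = [700.0, 1500.0, 900.0, 2100.0, 1300.0]
        assert 4 * chronic_load(seq) == pytest.approx(cumulative_load(seq, 4))


class TestACWR:
    def test_ratio(self):
        assert acwr(2000, 1600) == pytest.approx(1.25)

    def test_constant_series_gives_one(self):
        seq = [1500.0] * 6
        assert acwr(seq[-1], chronic_load(seq)) == pytest.approx(1.0)

    def test_squad_scale_ratio(self):
        # squad medians: acute 1800 AU over chronic 1900 AU sits near 1
        assert acwr(1800, 1900) == pytest.approx(0.947, abs=1e-3)

    def test_nonpositive_chronic_rejected(self):
        with pytest.raises(ValueError):
            acwr(1000, 0.0)


class TestACWRr:
    def test_zero_acute_is_zero(self, rng):
        assert acwrr(0.0, rng=rng) == 0.0

    def test_equality_case(self, rng):
        # gamma == acute gives exactly 1
        class FixedGamma:
            def normal(self, mean, sd):
                return 1900.0

        assert acwrr(1900.0, rng=FixedGamma()) == 1.0

    def test_sd_to_zero_limit(self, rng):
        vals = [acwrr(1800.0, denominator_sd=1e-6, rng=rng) for _ in range(50)]
        assert np.allclose(vals, 1800.0 / 1900.0)

    def test_median_and_spread(self, rng):
        draws = np.array([acwrr(1800.0, rng=rng) for _ in range(20_000)])
        assert np.median(draws) == pytest.approx(1800.0 / 1900.0, rel=0.05)
        # destroying the denominator inflates spread relative to a real ACWR
        assert np.percentile(draws, 75) - np.percentile(draws, 25) > 0.3

    def test_rejection_floor_keeps_ratio_positive(self, rng):
        draws = [acwrr(1000.0, denominator_mean=100.0, denominator_sd=500.0, rng=rng) for _ in range(500)]
        assert all(d > 0 for d in draws)

    def test_invalid_sd(self, rng):
        with pytest.raises(ValueError):
            acwrr(1000.0, denominator_sd=0.0, rng=rng)

    def test_requires_rng(self):
        with pytest.raises(ValueError):
            acwrr(1000.0)


class TestMonotony:
    def test_two_day_week(self):
        # mean 200, sample SD sqrt(20000) = 141.42...
        assert monotony([100, 300]) == pytest.approx(200 / 141.4213562, rel=1e-6)

    @pytest.mark.parametrize("loads", [[250] * 7, [0.0] * 5])
    def test_constant_week_undefined(self, loads):
        with pytest.raises(ValueError):
            monotony(loads)


class TestQuantileBinning:
    def test_one_to_eight(self):
        binning = fit_quantile_binning(range(1, 9))
        assert binning.cut_points == pytest.approx((2.75, 4.5, 6.25))
        labels = binning.assign(np.arange(1, 9))
        assert [int((labels == b).sum()) for b in (1, 2, 3, 4)] == [2, 2, 2, 2]

    def test_tie_free_data_balances_bins(self, rng):
        v = rng.uniform(0, 1, 815)
        labels = fit_quantile_binning(v).assign(v)
        counts = np.bincount(labels, minlength=5)[1:]
        assert counts.max() - counts.min() <= 1

    @given(n=st.integers(40, 400))
    def test_self_application_balance(self, n):
        v = np.linspace(0.0, 1.0, n) ** 2
        counts = np.bincount(fit_quantile_binning(v).assign(v), minlength=5)[1:]
        assert counts.max() - counts.min() <= 1

    def test_upper_inclusive_assignment(self):
        binning = QuantileBinning((1.0, 2.0, 3.0))
        assert list(binning.assign([1.0, 2.0, 3.0, 3.1])) == [1, 2, 3, 4]

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            fit_quantile_binning([1.0, 1.0, 1.0, 2.0])


class TestObservationTable:
    def test_toy_player_five_weeks(self, toy_sessions):
        injuries = pd.DataFrame(
            {"player_id": ["A"], "onset_week": [5], "days_lost": [10]}
        )
        obs = build_observation_table(toy_sessions, injuries, seed=0)
        assert len(obs) == 2
        assert sorted(obs["week"]) == [4, 5]
        assert bool(obs.loc[obs["week"] == 4, "injured"].iloc[0]) is True
        assert bool(obs.loc[obs["week"] == 5, "injured"].iloc[0]) is False
        # constant 300 AU load: chronic equals acute, ACWR exactly 1
        assert obs["acute_load"].tolist() == [300.0, 300.0]
        assert obs["acwr"].tolist() == pytest.approx([1.0, 1.0])

    def test_no_injuries_all_flags_false(self, toy_sessions):
        obs = build_observation_table(toy_sessions, None, seed=0)
        assert not obs["injured"].any()

    def test_absence_weeks_excluded(self, toy_sessions):
        extra = toy_sessions.copy()
        extra["week"] += 5  # weeks 6..10
        sessions = pd.concat([toy_sessions, extra], ignore_index=True)
        injuries = pd.DataFrame({"player_id": ["A"], "onset_week": [6], "days_lost": [14]})
        obs = build_observation_table(sessions, injuries, seed=0)
        # weeks 7 and 8 are absence weeks and must not appear
        assert not set(obs["week"]) & {7, 8}
        assert bool(obs.loc[obs["week"] == 5, "injured"].iloc[0]) is True

    def test_unknown_player_rejected(self, toy_sessions):
        injuries = pd.DataFrame({"player_id": ["Z"], "onset_week": [3], "days_lost": [7]})
        with pytest.raises(ValueError):
            build_observation_table(toy_sessions, injuries)

    def test_uncoupled_chronic_excludes_current_week(self, toy_sessions):
        sessions = toy_sessions.copy()
        sessions.loc[sessions["week"] == 5, "duration_min"] = 120.0  # week 5: 600 AU
        obs = build_observation_table(sessions, None, coupled=False, seed=0)
        assert len(obs) == 1
        row = obs.iloc[0]
        assert row["week"] == 5
        assert row["chronic_load"] == pytest.approx(300.0)  # weeks 1-4 only
        assert row["acwr"] == pytest.approx(2.0)

    def test_quantile_labels_cover_all_rows(self, observations):
        for col in ("acwr_quantile", "acwrr_quantile", "acute_quantile"):
            assert set(observations[col].dropna().astype(int)) <= {1, 2, 3, 4}
            assert observations[col].notna().all()

    def test_acwr_definition_holds_rowwise(self, observations):
        ratio = observations["acute_load"] / observations["chronic_load"]
        assert np.allclose(ratio, observations["acwr"])

    def test_acwrr_wider_than_acwr(self, observations):
        iqr = lambda v: np.subtract(*np.percentile(v, [75, 25]))
        assert iqr(observations["acwrr"]) > iqr(observations["acwr"])

    def test_csv_roundtrip(self, toy_sessions, tmp_path):
        p = tmp_path / "sessions.csv"
        toy_sessions.to_csv(p, index=False)
        assert metrics.read_sessions(p).equals(toy_sessions)
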