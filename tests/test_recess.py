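"""Recess classification, bout extraction, daily metrics and exposure tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestsurv import recess
from conftest import day_times

NEST = (1000.0, 2000.0)


class TestClassifyFix:
    @pytest.mark.parametrize(
        "offset, expected",
        [
            ((27.5, 0.0), "nest"),  # boundary is on-nest (<= 27.5 m)
            ((0.0, 0.0), "nest"),
            ((27.51, 0.0), "recess"),  # strictly beyond the buffer
            ((0.0, -27.6), "recess"),
            ((19.5, 19.5), "recess"),  # 27.58 m diagonal
        ],
    )
    def test_buffer_rule(self, offset, expected):
        fix = (NEST[0] + offset[0], NEST[1] + offset[1])
        assert recess.classify_fix(fix, NEST) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            recess.classify_fix((np.nan, 0.0), NEST)


def _track(pattern, step=100.0):
    """Coordinates from a N/R pattern: N at nest, R 100 m east."""
    return np.array([[NEST[0] + (step if c == "R" else 0.0), NEST[1]] for c in pattern])


class TestExtractBouts:
    @pytest.mark.parametrize(
        "pattern, sizes",
        [
            ("NNRRNRN", [2, 1]),
            ("NNNNNNN", []),
            ("R" * 17, [17]),
            ("RNR", [1, 1]),
            ("NRRRN", [3]),
        ],
    )
    def test_maximal_runs(self, pattern, sizes):
        xy = _track(pattern)
        bouts = recess.extract_bouts(day_times(n=len(pattern)), xy, NEST)
        assert [b.n_fixes for b in bouts] == sizes

    def test_empty_input(self):
        assert recess.extract_bouts([], np.empty((0, 2)), NEST) == []

    def test_bout_fields(self):
        bouts = recess.extract_bouts(day_times(n=5), _track("NRRNN"), NEST)
        (b,) = bouts
        assert b.max_displacement_m == pytest.approx(100.0)
        assert b.start.hour == 6 and b.end.hour == 7


class TestDailyMetrics:
    def test_all_on_nest_identical(self):
        xy = np.tile(NEST, (17, 1))
        assert recess.daily_metrics(day_times(), xy, NEST) == (0.0, 0.0, 0)

    def test_out_and_back(self):
        # nest, 100 m east, nest: 200 m path, 1 off-nest hour, 1 recess
        xy = _track("NRN")
        dist, dur, nrec = recess.daily_metrics(day_times(n=3), xy, NEST)
        assert dist == pytest.approx(200.0)
        assert dur == 1.0
        assert nrec == 1

    def test_night_fix_weight(self):
        pattern = "N" * 16 + "R"
        xy = _track(pattern)
        _, dur_full, _ = recess.daily_metrics(day_times(), xy, NEST)
        _, dur_half, _ = recess.daily_metrics(day_times(), xy, NEST, night_fix_weight=0.5)
        assert dur_full == 1.0 and dur_half == 0.5

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 400.0), min_size=2, max_size=17), st.data())
    def test_buffer_monotonicity(self, radii, data):
        """Enlarging the buffer never increases off-nest duration, and the
        bout count never exceeds the off-nest fix count.  (The bout count
        itself is not monotone: a larger buffer can split one run in two.)"""
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        angles = rng.uniform(0, 2 * np.pi, len(radii))
        xy = np.column_stack([
            NEST[0] + np.array(radii) * np.cos(angles),
            NEST[1] + np.array(radii) * np.sin(angles),
        ])
        t = day_times(n=len(radii))
        prev_dur = None
        for buf in (10.0, 27.5, 50.0, 200.0):
            _, dur, nrec = recess.daily_metrics(t, xy, NEST, buffer_m=buf)
            bouts = recess.extract_bouts(t, xy, NEST, buffer_m=buf)
            assert sum(b.n_fixes for b in bouts) == dur  # conservation
            assert nrec <= dur or dur == 0
            if prev_dur is not None:
                assert dur <= prev_dur
            prev_dur = dur


class TestDetectOnset:
    def test_sitting_bird_onset_at_first_fix(self):
        t = pd.date_range("2016-04-01 05:00", periods=48, freq="h")
        xy = np.tile(NEST, (48, 1)) + np.random.default_rng(0).normal(0, 3, (48, 2))
        assert recess.detect_onset(t, xy) == t[0]

    def test_ranging_bird_no_onset(self):
        t = pd.date_range("2016-04-01 05:00", periods=48, freq="h")
        xy = np.cumsum(np.full((48, 2), 120.0), axis=0)  # 170 m steps
        assert recess.detect_onset(t, xy) is None

    def test_transition_found_within_one_interval(self):
        rng = np.random.default_rng(5)
        t = pd.date_range("2016-04-01 05:00", periods=96, freq="h")
        ranging = np.cumsum(rng.normal(0, 150, (40, 2)), axis=0)
        sitting = ranging[-1] + rng.normal(0, 2, (56, 2))
        xy = np.vstack([ranging, sitting])
        onset = recess.detect_onset(t, xy)
        assert onset is not None
        assert abs((onset - t[40]).total_seconds()) <= 3600

    def test_too_short_stream_rejected(self):
        t = pd.date_range("2016-04-01", periods=5, freq="h")
        with pytest.raises(ValueError):
            recess.detect_onset(t, np.tile(NEST, (5, 1)))


def _nest_row(**kw):
    base = dict(
        nest_id="N1", bird_id="B1", site="S1", year=2016, attempt=1,
        onset="2016-04-01", termination="2016-04-30", nest_fate="hatched",
        female_fate="alive", nest_x=NEST[0], nest_y=NEST[1], concealment_cm=90.0,
    )
    base.update(kw)
    return base


def _fixes_for(nest, onset, n_days, rng=None):
    rng = rng or np.random.default_rng(1)
    rows = []
    for d in range(n_days):
        t = day_times(pd.Timestamp(onset) + pd.Timedelta(days=d))
        for ts in t:
            rows.append(("B1", ts, nest[0] + rng.normal(0, 3), nest[1] + rng.normal(0, 3)))
    return pd.DataFrame(rows, columns=["bird_id", "timestamp", "x", "y"])


class TestBuildExposureTable:
    def test_hatched_30_day_nest(self):
        nests = pd.DataFrame([_nest_row()])
        fixes = _fixes_for(NEST, "2016-04-01", 30)
        cov, period = recess.build_exposure_table(nests, fixes)
        assert len(cov) == 30 and len(period) == 30
        assert (cov.nest_alive == 1).all() and (cov.female_alive == 1).all()
        assert list(cov.day) == list(range(1, 31))
        # first and last day carry the across-day mean covariates
        interior = cov.iloc[1:-1]
        assert cov.iloc[0].distance == pytest.approx(interior.distance.mean())
        assert cov.iloc[-1].distance == pytest.approx(interior.distance.mean())

    def test_day2_depredation_censored_from_covariates(self):
        nests = pd.DataFrame([
            _nest_row(termination="2016-04-02", nest_fate="depredated")
        ])
        fixes = _fixes_for(NEST, "2016-04-01", 2)
        cov, period = recess.build_exposure_table(nests, fixes)
        assert len(cov) == 0
        assert len(period) == 2
        assert list(period.nest_alive) == [1, 0]

    def test_female_death_coded_on_last_day_only(self):
        nests = pd.DataFrame([
            _nest_row(termination="2016-04-10", nest_fate="depredated", female_fate="dead")
        ])
        fixes = _fixes_for(NEST, "2016-04-01", 10)
        cov, _ = recess.build_exposure_table(nests, fixes)
        assert list(cov.female_alive) == [1] * 9 + [0]
        assert list(cov.nest_alive) == [1] * 9 + [0]

    def test_nest_without_fixes_excluded(self, caplog):
        nests = pd.DataFrame([_nest_row(), _nest_row(nest_id="N2", bird_id="B9")])
        fixes = _fixes_for(NEST, "2016-04-01", 30)
        with caplog.at_level("WARNING"):
            cov, _ = recess.build_exposure_table(nests, fixes)
        assert set(cov.nest_id) == {"N1"}
        assert "N2" in caplog.text

    def test_period_rows_match_observed_days(self, small_dataset):
        """Period dataset accounting: one row per nest per incubated day."""
        cov, period = recess.build_exposure_table(small_dataset.nests, small_dataset.fixes)
        expected = small_dataset.truth_nests.incubated_days.sum()
        assert len(period) == expected
        short = small_dataset.truth_nests.query("incubated_days < 3").nest_id
        assert not set(short) & set(cov.nest_id)
        assert set(short) <= set(period.nest_id)


class TestCollinearityScreen:
    def test_identical_columns_dropped(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        res = recess.screen_collinearity(df, ["a", "b", "c"])
        assert res.dropped == [("b", "a", pytest.approx(1.0))]
        assert res.kept == ["a", "c"]

    def test_independent_columns_survive(self, rng):
        df = pd.DataFrame(rng.normal(size=(1000, 3)), columns=list("abc"))
        res = recess.screen_collinearity(df, list("abc"))
        assert res.dropped == []
        assert np.allclose(np.diag(res.corr), 1.0)
        assert np.allclose(res.corr, res.corr.T)

    def test_range_size_dropped_against_distance(self, rng):
        # range size generated with r = 0.74 against distance
        n = 4000
        z = rng.normal(size=n)
        distance = z
        range_size = 0.74 * z + np.sqrt(1 - 0.74**2) * rng.normal(size=n)
        df = pd.DataFrame({"distance": distance, "range_size": range_size})
        res = recess.screen_collinearity(
            df, ["distance", "range_size"], priority=["distance", "range_size"]
        )
        assert [d[0] for d in res.dropped] == ["range_size"]
        assert res.dropped[0][2] == pytest.approx(0.74, abs=0.05)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"flat": np.ones(50), "ok": np.arange(50.0)})
        with pytest.raises(ValueError, match="flat"):
            recess.screen_collinearity(df, ["flat", "ok"])
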