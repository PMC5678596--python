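import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenodiel import (
    Frame,
    Modality,
    PRASeries,
    build_session,
    daily_rer,
    detect_dawn_dips,
    diel_rer,
    rer,
)
from phenodiel.growth import daily_rer_block_means, sliding_median


def _session(schedule, n_days=3, start_hour=8):
    start = dt.datetime(2024, 3, 1, start_hour, 0)
    frames = []
    for k in range(n_days * 72):
        ts = start + dt.timedelta(minutes=20 * k)
        if schedule.is_light(ts):
            frames.append(Frame(np.zeros((4, 4, 3), np.uint8), ts, Modality.VIS))
        else:
            frames.append(Frame(np.zeros((4, 4), np.uint8), ts, Modality.NIR))
    return build_session(frames, schedule)


def _series(values, pid=1):
    n = len(values)
    return PRASeries(pid, np.arange(n) * 20 / 1440.0, np.asarray(values, float),
                     frame_index=np.arange(n))


class TestPointRER:
    def test_no_change_is_zero(self):
        assert rer(100.0, 100.0, 0.0, 1.0) == 0.0

    def test_exponential_growth_recovered(self):
        assert rer(100.0, 100.0 * math.exp(0.2), 0.0, 1.0) == pytest.approx(
            0.2, abs=1e-12
        )

    def test_halving_over_two_days(self):
        assert rer(200.0, 100.0, 0.0, 2.0) == pytest.approx(
            -math.log(2) / 2, abs=1e-12
        )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            rer(0.0, 100.0, 0.0, 1.0)

    def test_equal_times_rejected(self):
        with pytest.raises(ValueError):
            rer(100.0, 120.0, 1.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(1.0, 1e6), b=st.floats(1.0, 1e6),
        t1=st.floats(0.0, 10.0), dt_=st.floats(0.01, 10.0),
        shift=st.floats(-50.0, 50.0), scale=st.floats(0.01, 100.0),
    )
    def test_invariances(self, a, b, t1, dt_, shift, scale):
        t2 = t1 + dt_
        base = rer(a, b, t1, t2)
        # antisymmetry in the area order
        assert rer(b, a, t1, t2) == pytest.approx(-base, rel=1e-9, abs=1e-12)
        # time-shift invariance
        assert rer(a, b, t1 + shift, t2 + shift) == pytest.approx(
            base, rel=1e-9, abs=1e-9
        )
        # unit/scale invariance (px vs mm2)
        assert rer(a * scale, b * scale, t1, t2) == pytest.approx(
            base, rel=1e-9, abs=1e-9
        )


class TestDailyRER:
    def test_noiseless_exponential_exact(self, schedule_12_12):
        session = _session(schedule_12_12)
        t = np.arange(len(session.frames)) * 20 / 1440.0
        series = PRASeries(1, t, 100 * np.exp(0.15 * t),
                           frame_index=np.arange(len(t)))
        values = [v for _, v in daily_rer(series, session)]
        assert len(values) == 3
        np.testing.assert_allclose(values, 0.15, atol=1e-9)

    def test_constant_series_is_zero(self, schedule_12_12):
        session = _session(schedule_12_12)
        series = _series([500.0] * len(session.frames))
        values = [v for _, v in daily_rer(series, session)]
        np.testing.assert_allclose(values, 0.0, atol=1e-12)

    def test_noisy_estimate_unbiased_within_3_sigma(self, schedule_12_12):
        """2% endpoint noise propagates to sigma = sqrt(2)*0.02/dt per day;
        the 3-day mean must sit within 3 sigma of the true rate."""
        session = _session(schedule_12_12)
        t = np.arange(len(session.frames)) * 20 / 1440.0
        dt_days = 35 * 20 / 1440.0  # first-to-last frame span of a light period
        sigma_mean = math.sqrt(2) * 0.02 / dt_days / math.sqrt(3)
        rng = np.random.default_rng(42)
        for pid in range(4):
            noisy = 100 * np.exp(0.15 * t) * rng.normal(1.0, 0.02, t.size)
            series = PRASeries(pid + 1, t, noisy, frame_index=np.arange(t.size))
            mean = np.mean([v for _, v in daily_rer(series, session)])
            assert abs(mean - 0.15) < 3 * sigma_mean

    def test_incomplete_trailing_period_skipped(self, schedule_12_12):
        # 3 full days plus 2 h of the fourth morning
        session = _session(schedule_12_12)
        start = session.frames[-1].timestamp + dt.timedelta(minutes=20)
        extra = [
            Frame(np.zeros((4, 4, 3), np.uint8),
                  start + dt.timedelta(minutes=20 * k), Modality.VIS)
            for k in range(6)
        ]
        session2 = build_session(list(session.frames) + extra, schedule_12_12)
        t = np.arange(len(session2.frames)) * 20 / 1440.0
        series = PRASeries(1, t, 100 * np.exp(0.15 * t),
                           frame_index=np.arange(t.size))
        with pytest.warns(UserWarning, match="incomplete"):
            values = daily_rer(series, session2)
        assert len(values) == 3

    def test_no_complete_period_errors(self, schedule_12_12):
        session = _session(schedule_12_12)
        t = np.arange(4) * 20 / 1440.0
        series = PRASeries(1, t, np.full(4, 100.0), frame_index=np.arange(4))
        with pytest.raises(ValueError, match="no complete light period"):
            with pytest.warns(UserWarning):
                daily_rer(series, session)

    def test_block_means(self):
        daily = [(i, v) for i, v in enumerate([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])]
        assert daily_rer_block_means(daily, 3) == [
            pytest.approx(0.2), pytest.approx(0.5)
        ]


class TestDielRER:
    def test_default_window_is_ten_frames(self):
        t = np.arange(100) * 20 / 1440.0
        series = PRASeries(1, t, 100 * np.exp(0.2 * t))
        assert diel_rer(series).window_frames == 10

    def test_noiseless_exponential_preserved_by_median(self):
        t = np.arange(144) * 20 / 1440.0
        series = PRASeries(1, t, 100 * np.exp(0.25 * t))
        out = diel_rer(series)
        np.testing.assert_allclose(out.rer_values, 0.25, atol=1e-9)

    def test_constant_series_is_zero(self):
        series = _series([321.0] * 50)
        np.testing.assert_allclose(diel_rer(series).rer_values, 0.0, atol=1e-12)

    def test_median_rejects_spikes(self):
        """A one-frame 3x segmentation blow-up shifts the smoothed level by
        at most one sample step (local RER wiggle ~ r), whereas the raw
        difference would spike by ln(3)/dt ~ 79 day^-1."""
        t = np.arange(72) * 20 / 1440.0
        vals = 100 * np.exp(0.2 * t)
        vals[30] *= 3.0
        smoothed = diel_rer(PRASeries(1, t, vals))
        raw = diel_rer(PRASeries(1, t, vals), window_frames=1)
        assert np.abs(raw.rer_values - 0.2).max() > 30.0
        assert np.abs(smoothed.rer_values - 0.2).max() <= 0.21

    def test_short_series_rejected(self):
        series = _series([100.0] * 5)
        with pytest.raises(ValueError, match="shorter"):
            diel_rer(series, window_frames=10)

    def test_short_gap_interpolated_long_gap_split(self):
        t = np.arange(80) * 20 / 1440.0
        vals = 100 * np.exp(0.2 * t)
        missing = np.zeros(80, bool)
        missing[20:22] = True    # 2-frame gap: interpolated
        series = PRASeries(1, t, vals, missing=missing)
        out = diel_rer(series)
        assert out.times.size == 80 - 10  # single segment, edge frames lost
        missing[50:55] = True    # 5-frame gap: split
        series2 = PRASeries(1, t, vals, missing=missing)
        out2 = diel_rer(series2)
        assert out2.times.size < out.times.size
        # linear interpolation of an exponential leaves a tiny curvature error
        np.testing.assert_allclose(out2.rer_values, 0.2, atol=1e-3)

    def test_sliding_median_centres(self):
        idx, med = sliding_median(np.arange(10.0), 4)
        np.testing.assert_array_equal(idx, [2, 3, 4, 5, 6, 7, 8])
        np.testing.assert_allclose(med, np.arange(1.5, 8.5))


class TestDawnDip:
    def _dipped_session_series(self, schedule, amp):
        session = _session(schedule, n_days=2)
        t = np.arange(len(session.frames)) * 20 / 1440.0
        vals = 100 * np.exp(0.2 * t)
        # superimpose a 2-h half-sine dip after the second dawn (t = 1 day)
        dawn = 1.0
        dur = 2.0 / 24.0
        in_dip = (t >= dawn) & (t < dawn + dur)
        vals[in_dip] *= 1 - amp * np.sin(np.pi * (t[in_dip] - dawn) / dur)
        return session, PRASeries(1, t, vals, frame_index=np.arange(t.size))

    def test_dip_detected(self, schedule_12_12):
        session, series = self._dipped_session_series(schedule_12_12, 0.10)
        dips = detect_dawn_dips(series, session)
        assert len(dips) == 1  # only the second dawn follows a dark period
        assert dips[0]["dipped"] and dips[0]["depth"] > 0.02

    def test_no_dip_without_modulation(self, schedule_12_12):
        session, series = self._dipped_session_series(schedule_12_12, 0.0)
        dips = detect_dawn_dips(series, session)
        assert len(dips) == 1
        assert not dips[0]["dipped"]
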