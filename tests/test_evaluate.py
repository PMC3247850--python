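"""Performance analysis: binarization, cross-covariance, events, Monte Carlo."""

import numpy as np
import pytest

from bcifes.evaluate import (
    BinaryTimeline,
    binarize_goniometer,
    count_events,
    cross_covariance_report,
    default_online_cues,
    monte_carlo_chance,
    resample_binary,
)
from bcifes.exceptions import DataError
from bcifes.online import DecoderState, decoder_step
from bcifes.selection import Thresholds


def brute_force_rho(x, y, max_lag):
    """Double-loop oracle for the normalized cross-covariance."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    lags = range(-max_lag, max_lag + 1)
    rho = []
    for m in lags:
        s = 0.0
        for i in range(n):
            j = i - m  # x index aligned so positive m means y lags x
            if 0 <= j < n:
                s += xc[j] * yc[i]
        rho.append(s / denom)
    return np.array(list(lags)), np.array(rho)


class TestBinarizeGoniometer:
    def test_constant_traces(self):
        assert (binarize_goniometer(np.full(500, 10.0), 256.0, 5.0).values == 1).all()
        assert (binarize_goniometer(np.full(500, 1.0), 256.0, 5.0).values == 0).all()

    def test_square_pulse_edges_within_smoothing_width(self):
        fs = 256.0
        trace = np.zeros(int(4 * fs))
        a, b = int(1.0 * fs), int(3.0 * fs)
        trace[a:b] = 20.0
        tl = binarize_goniometer(trace, fs, 5.0, smooth_ms=100.0)
        half_width = int(0.05 * fs) + 1
        on = np.flatnonzero(tl.values)
        assert abs(on[0] - a) <= half_width and abs(on[-1] - (b - 1)) <= half_width

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            binarize_goniometer(np.array([1.0, np.nan, 2.0] * 50), 256.0, 5.0)


class TestCrossCovariance:
    def test_self_agreement(self):
        x = BinaryTimeline(np.tile([1] * 10 + [0] * 10, 8), 2.0)
        _, m_star, rho_star = cross_covariance_report(x, x)
        assert m_star == 0 and rho_star == pytest.approx(1.0)

    def test_complement_anticorrelated_at_zero_lag(self):
        v = np.tile([1, 0], 50)
        x = BinaryTimeline(v, 2.0)
        y = BinaryTimeline(1 - v, 2.0)
        rho, _, _ = cross_covariance_report(x, y)
        mid = (rho.size - 1) // 2
        assert rho[mid] == pytest.approx(-1.0)

    def test_recovers_injected_delay(self):
        v = np.tile([1] * 20 + [0] * 20, 6)
        y = np.concatenate([np.zeros(12, dtype=int), v[:-12]])
        _, m_star, _ = cross_covariance_report(BinaryTimeline(v, 8.0), BinaryTimeline(y, 8.0))
        assert m_star == 12

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for n in (50, 333, 2000):
            v = (rng.random(n) < 0.4).astype(int)
            w = (rng.random(n) < 0.6).astype(int)
            max_lag_s = 4.0
            rho, m_star, rho_star = cross_covariance_report(
                BinaryTimeline(v, 2.0), BinaryTimeline(w, 2.0), max_lag=max_lag_s
            )
            lags, oracle = brute_force_rho(v, w, int(max_lag_s * 2.0))
            np.testing.assert_allclose(rho, oracle, atol=1e-12)
            assert rho_star == pytest.approx(oracle.max())

    def test_rho_bounded_by_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = (rng.random(100) < rng.uniform(0.2, 0.8)).astype(int)
            w = (rng.random(100) < rng.uniform(0.2, 0.8)).astype(int)
            if v.var() == 0 or w.var() == 0:
                continue
            rho, _, _ = cross_covariance_report(BinaryTimeline(v, 2.0), BinaryTimeline(w, 2.0))
            assert (np.abs(rho) <= 1.0 + 1e-12).all()

    def test_swapping_series_negates_the_lag(self):
        v = np.tile([1] * 15 + [0] * 15, 5)
        y = np.concatenate([np.zeros(7, dtype=int), v[:-7]])
        tx, ty = BinaryTimeline(v, 2.0), BinaryTimeline(y, 2.0)
        _, m_xy, _ = cross_covariance_report(tx, ty)
        _, m_yx, _ = cross_covariance_report(ty, tx)
        assert m_xy == -m_yx

    def test_constant_series_rejected(self):
        with pytest.raises(DataError, match="y"):
            cross_covariance_report(
                BinaryTimeline(np.tile([0, 1], 20), 2.0),
                BinaryTimeline(np.r_[np.ones(39), 1].astype(int), 2.0),
            )


class TestCountEvents:
    cues = default_online_cues(n_pairs=3)  # I/D alternating, 10 s each

    def _timeline(self, starts_s, fs=2.0, dur=0.5, total=60.0):
        v = np.zeros(int(total * fs), dtype=int)
        for s in starts_s:
            v[int(s * fs) : int((s + dur) * fs)] = 1
        return BinaryTimeline(v, fs)

    def test_delayed_tracking_is_clean(self):
        x = self._timeline([10.0, 30.0, 50.0], dur=10.0)
        y = self._timeline([12.0, 32.0, 52.0], dur=8.0)
        assert count_events(x, y, self.cues) == (0, 0)

    def test_silent_response_counts_all_omissions(self):
        x = self._timeline([10.0, 30.0, 50.0], dur=10.0)
        y = BinaryTimeline(np.r_[np.zeros(119, dtype=int), 1], 2.0)  # one late blip
        om, fa = count_events(x, y, self.cues)
        assert om == 2  # blip lands in the last movement epoch

    def test_initiation_in_idle_is_a_false_alarm(self):
        x = self._timeline([10.0, 30.0, 50.0], dur=10.0)
        y = self._timeline([12.0, 25.0, 32.0, 52.0], dur=3.0)
        assert count_events(x, y, self.cues) == (0, 1)

    def test_invariant_to_response_duration(self):
        x = self._timeline([10.0, 30.0, 50.0], dur=10.0)
        short = self._timeline([12.0, 32.0, 52.0], dur=1.0)
        long = self._timeline([12.0, 32.0, 52.0], dur=6.0)
        assert count_events(x, short, self.cues) == count_events(x, long, self.cues)

    def test_overlapping_cues_rejected(self):
        x = self._timeline([10.0], dur=10.0)
        with pytest.raises(DataError):
            count_events(x, x, [(0.0, 10.0, "I"), (5.0, 15.0, "D")])


class TestMonteCarloChance:
    def test_reproducible(self):
        a = monte_carlo_chance(n_trials=200, seed=4)
        b = monte_carlo_chance(n_trials=200, seed=4)
        assert a.max_rho == b.max_rho
        np.testing.assert_array_equal(a.rho, b.rho)

    def test_constant_response_trials_get_zero(self):
        # impossible thresholds freeze the machine in idle -> rho* = 0
        null = monte_carlo_chance(thresholds=Thresholds(T1=1.0, T2=0.0), n_trials=5, seed=0)
        assert (null.rho == 0).all()

    def test_vectorized_fsm_matches_decoder_step(self):
        from bcifes.evaluate import _chance_fsm

        rng = np.random.default_rng(7)
        p = (rng.random((4, 60)) < 0.5).astype(float)
        thr = Thresholds(T1=0.5, T2=0.5)
        y_fast = _chance_fsm(p, thr.T1, thr.T2, 3)
        for row in range(4):
            st = DecoderState(buffer_len=3)
            ref = []
            for val in p[row]:
                st, _ = decoder_step(st, float(val), thr)
                ref.append(1 if st.state == "D" else 0)
            np.testing.assert_array_equal(y_fast[row], ref)

    def test_decision_clock_equals_resampled_clock(self):
        # rho is piecewise linear in the lag with knots on the 0.5-s grid, so
        # computing at 2 Hz equals computing on a 256 Hz resampled pair
        from bcifes.evaluate import _chance_fsm

        rng = np.random.default_rng(8)
        cues = default_online_cues()
        n_steps = 400
        t = np.arange(n_steps) / 2.0
        x = np.zeros(n_steps, dtype=int)
        for s, e, lab in cues:
            if lab == "D":
                x[(t >= s) & (t < e)] = 1
        p = (rng.random((1, n_steps)) < 0.5).astype(float)
        y = _chance_fsm(p, 0.5, 0.5, 3)[0]
        coarse = cross_covariance_report(
            BinaryTimeline(x, 2.0), BinaryTimeline(y, 2.0), max_lag=5.0
        )
        fine = cross_covariance_report(
            resample_binary(BinaryTimeline(x, 2.0), 256.0),
            resample_binary(BinaryTimeline(y, 2.0), 256.0),
            max_lag=5.0,
        )
        assert coarse[2] == pytest.approx(fine[2], abs=1e-9)
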