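"""Metabolic rates (Brockway), transient removal, and point-mass work."""

import numpy as np
import pandas as pd
import pytest

from splitbelt.energetics import (brockway_rate, com_velocity_3d,
                                  leg_power_and_work, net_relative_rate,
                                  percent_vo2peak, remove_onset_transient)
from splitbelt.preprocess import Stride


class TestBrockway:
    def test_zero_inputs(self):
        assert brockway_rate(0.0, 0.0) == (0.0, 0.0)

    def test_reference_value(self):
        e, w = brockway_rate(300.0, 240.0)
        assert e == pytest.approx(16.58 * 300 + 4.51 * 240)  # 6056.4 J/min
        assert w == pytest.approx(100.94)

    def test_linearity(self):
        e1, w1 = brockway_rate(250.0, 200.0)
        e2, w2 = brockway_rate(500.0, 400.0)
        assert e2 == pytest.approx(2 * e1) and w2 == pytest.approx(2 * w1)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            brockway_rate(-1.0, 0.0)


class TestNetRelativeRate:
    def test_reference_subtraction_and_normalization(self):
        w_net, w_kg, base = net_relative_rate(np.array([300.0]),
                                              np.array([100.0, 100.0]), 80.0)
        assert w_net[0] == pytest.approx(200.0)
        assert w_kg[0] == pytest.approx(2.5)
        assert base == pytest.approx(100.0)

    def test_walking_equal_standing_gives_zero(self):
        w_net, _, _ = net_relative_rate(np.array([120.0]), np.array([120.0]), 70.0)
        assert w_net[0] == pytest.approx(0.0)


class TestTransientRemoval:
    def test_constructed_peak_removed(self):
        """Series rising to a peak at 90 s: every pre-peak breath is removed,
        and the cut lands within one smoothing window of the peak (the
        trailing average tops out after the rise has finished)."""
        t = np.arange(0.0, 600.0, 4.0)
        w = np.where(t < 90, t / 90.0, np.exp(-(t - 90) / 300.0))
        t2, w2 = remove_onset_transient(t, w)
        assert 90.0 <= t2[0] <= 120.0
        np.testing.assert_array_equal(t2, t[t >= t2[0]])

    def test_monotone_decay_untouched(self):
        t = np.arange(0.0, 600.0, 4.0)
        w = np.exp(-t / 200.0)
        t2, w2 = remove_onset_transient(t, w)
        assert t2[0] == t[0]
        assert len(t2) == len(t)

    def test_constant_series_flagged_and_untouched(self):
        t = np.arange(0.0, 400.0, 4.0)
        w = np.full_like(t, 2.0)
        with pytest.warns(UserWarning, match="constant"):
            t2, w2 = remove_onset_transient(t, w)
        assert len(t2) == len(t)

    def test_short_series_warns(self):
        t = np.arange(0.0, 100.0, 4.0)
        with pytest.warns(UserWarning, match="shorter"):
            remove_onset_transient(t, np.exp(-t / 50.0))


class TestPercentVo2peak:
    def test_reference_values(self):
        assert percent_vo2peak(12.0, 40.0) == pytest.approx(30.0)
        assert percent_vo2peak(40.0, 40.0) == pytest.approx(100.0)

    def test_invalid_peak(self):
        with pytest.raises(ValueError):
            percent_vo2peak(10.0, 0.0)


def one_stride(duration=1.0, rate=1000.0):
    n = int(duration * rate)
    t = np.arange(n) / rate
    return t, [Stride(start=0.0, end=duration, ipsi_off=0.7 * duration,
                      contra_strike=0.5 * duration, contra_off=0.2 * duration)]


class TestComVelocity:
    def test_gravity_balanced_force_gives_zero_velocity(self):
        t, strides = one_stride()
        grf = np.zeros((len(t), 3))
        grf[:, 2] = 72.0 * 9.81
        v = com_velocity_3d(t, grf, 72.0, strides)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_sinusoidal_force_amplitude_recovered(self):
        """F_z = mg + B sin(2 pi t): velocity amplitude B/(2 pi m) within 2%."""
        t, strides = one_stride()
        B = 100.0
        grf = np.zeros((len(t), 3))
        grf[:, 2] = 72.0 * 9.81 + B * np.sin(2 * np.pi * t)
        v = com_velocity_3d(t, grf, 72.0, strides)
        expected = B / (2 * np.pi * 72.0)
        assert (v[:, 2].max() - v[:, 2].min()) / 2 == pytest.approx(expected, rel=0.02)

    def test_per_stride_mean_velocity_is_zero(self, rng):
        t, strides = one_stride()
        grf = rng.normal(0, 50, (len(t), 3))
        grf[:, 2] += 72.0 * 9.81
        v = com_velocity_3d(t, grf, 72.0, strides)
        np.testing.assert_allclose(v.mean(axis=0), 0.0, atol=1e-12)

    def test_force_dropout_rejected(self):
        t, strides = one_stride()
        grf = np.zeros((len(t), 3))
        grf[5, 2] = np.nan
        with pytest.raises(ValueError, match="dropout"):
            com_velocity_3d(t, grf, 72.0, strides)


class TestLegPower:
    def test_vertical_force_orthogonal_to_horizontal_motion(self):
        t, strides = one_stride()
        grf = np.tile([0.0, 0.0, 700.0], (len(t), 1))
        v = np.zeros_like(grf)
        work = leg_power_and_work(t, grf, grf * 0, v, (1.5, 0.5), strides)
        assert work["w_pos_fast"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_treadmill_term_dot_product(self):
        # belt (-1.5, 0, 0) against force-on-belt (-10, 0, -700): 15 W
        t, strides = one_stride()
        grf = np.tile([10.0, 0.0, 700.0], (len(t), 1))
        v = np.zeros_like(grf)
        work = leg_power_and_work(t, grf, grf * 0, v, (1.5, 0.5), strides)
        # trapezoid over the discrete stride slice: boundary sample excluded
        assert work["w_pos_fast"].iloc[0] == pytest.approx(15.0, rel=2e-3)

    def test_body_term_dot_product(self):
        # v_com (0.1, 0, -0.05) . (10, 0, 700) = 1 - 35 = -34 W; belt term +15
        t, strides = one_stride()
        grf = np.tile([10.0, 0.0, 700.0], (len(t), 1))
        v = np.tile([0.1, 0.0, -0.05], (len(t), 1))
        work = leg_power_and_work(t, grf, grf * 0, v, (1.5, 0.5), strides)
        assert work["w_neg_fast"].iloc[0] == pytest.approx(-34.0 + 15.0, rel=2e-3)

    def test_rectification_identity(self, rng):
        """W+ + W- equals the signed power integral to 1e-9 of its scale."""
        from scipy.integrate import trapezoid
        t, strides = one_stride()
        grf_f = rng.normal(0, 200, (len(t), 3))
        grf_s = rng.normal(0, 200, (len(t), 3))
        v = rng.normal(0, 0.2, (len(t), 3))
        work = leg_power_and_work(t, grf_f, grf_s, v, (1.5, 0.5), strides)
        p_f = (v * grf_f).sum(axis=1) + (-grf_f) @ np.array([-1.5, 0, 0])
        net_f = trapezoid(p_f, t) / 1.0
        got = work["w_pos_fast"].iloc[0] + work["w_neg_fast"].iloc[0]
        assert abs(got - net_f) < 1e-9 * max(abs(net_f), 1.0)

    def test_time_reversal_swaps_rectified_work(self, rng):
        """Reversing a stride (positions mirrored, velocities negated) turns
        every positive power excursion into a negative one: W+ <-> -W-."""
        t, strides = one_stride()
        grf_f = rng.normal(0, 200, (len(t), 3))
        v = rng.normal(0, 0.2, (len(t), 3))
        fwd = leg_power_and_work(t, grf_f, grf_f * 0, v, (0.0, 0.0), strides)
        rev = leg_power_and_work(t, grf_f[::-1], grf_f[::-1] * 0, -v[::-1],
                                 (0.0, 0.0), strides)
        assert rev["w_pos_fast"].iloc[0] == pytest.approx(
            -fwd["w_neg_fast"].iloc[0], rel=1e-9)

    def test_mismatched_streams_rejected(self):
        t, strides = one_stride()
        with pytest.raises(ValueError, match="mismatched"):
            leg_power_and_work(t, np.zeros((10, 3)), np.zeros((10, 3)),
                               np.zeros((11, 3)), (1.5, 0.5), strides)

    def test_invariants_on_signal_trial(self, processed_trial):
        """W+ >= 0 >= W- per stride, and the net rate tracks the generator's
        scheduled net-work curve (correlation > 0.9)."""
        trial, res = processed_trial
        st_df = res["strides"].dropna(subset=["w_net"])
        for leg in ("fast", "slow"):
            assert (st_df[f"w_pos_{leg}"] >= 0).all()
            assert (st_df[f"w_neg_{leg}"] <= 0).all()
        gt = trial.truth
        i = np.abs(st_df["t"].to_numpy()[:, None]
                   - gt["fast_strikes"][None, :]).argmin(axis=1)
        sched = gt["work_net_w_per_kg"][i] * trial.subject.mass
        assert np.corrcoef(st_df["w_net"], sched)[0, 1] > 0.9
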