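"""Centre of pressure, force-integrated CoM, extrapolated CoM, and ML MoS."""

import numpy as np
import pytest

from splitbelt.preprocess import EventTable
from splitbelt.stability import (com_ml_absolute, combined_cop_ml, mos_per_stride,
                                 xcom)


class TestCombinedCop:
    def test_single_plate_moment_lever(self):
        n = 100
        fz = np.full((n, 1), 700.0)
        mx = np.full((n, 1), 35.0)  # lever 0.05 m
        cop = combined_cop_ml(fz, mx, (0.0,), rate=1000.0)
        np.testing.assert_allclose(cop, 0.05)

    def test_load_weighted_combination(self):
        n = 100
        fz = np.tile([600.0, 200.0], (n, 1))
        mx = np.tile([60.0, -20.0], (n, 1))  # plate CoPs +0.10 and -0.10
        cop = combined_cop_ml(fz, mx, (0.0, 0.0), rate=1000.0)
        np.testing.assert_allclose(cop, (0.10 * 600 - 0.10 * 200) / 800.0)

    def test_equal_loads_opposite_cops_cancel(self):
        n = 50
        fz = np.tile([500.0, 500.0], (n, 1))
        mx = np.tile([25.0, -25.0], (n, 1))
        np.testing.assert_allclose(combined_cop_ml(fz, mx, (0.0, 0.0), 1000.0), 0.0)

    def test_prolonged_unloading_rejected(self):
        fz = np.full((200, 2), 700.0)
        fz[50:150] = 0.0  # 100 ms gap at 1 kHz
        mx = np.zeros_like(fz)
        with pytest.raises(ValueError, match="unloaded"):
            combined_cop_ml(fz, mx, (0.0, 0.0), rate=1000.0)


class TestComIntegration:
    def test_zero_force_constant_cop(self):
        n = 20000
        com, vcom = com_ml_absolute(np.zeros(n), 70.0, np.full(n, 0.02), 1000.0)
        np.testing.assert_allclose(com, 0.02, atol=1e-9)
        np.testing.assert_allclose(vcom, 0.0, atol=1e-9)

    def test_sway_amplitude_and_phase_recovered(self):
        """Closed-form oracle: x = A sin(w t); feeding F = m x'' and the
        consistent CoP recovers amplitude within 5% and phase within 5 deg."""
        rate, A, f = 1000.0, 0.02, 0.9
        t = np.arange(0, 60, 1 / rate)
        om = 2 * np.pi * f
        x = A * np.sin(om * t)
        F = 72.0 * (-A * om**2 * np.sin(om * t))
        com, _ = com_ml_absolute(F, 72.0, x, rate)
        mid = slice(10000, 50000)
        amp = (com[mid].max() - com[mid].min()) / 2
        assert amp == pytest.approx(A, rel=0.05)
        z = np.vdot(np.exp(1j * om * t[mid]), com[mid] - com[mid].mean())
        phase_err = np.angle(z) + np.pi / 2  # sin lags the analytic exp by 90 deg
        assert abs(np.degrees(phase_err)) < 5.0

    def test_white_noise_force_has_no_secular_drift(self, rng):
        """Double integration of noise is drift-controlled: output variance in
        the last minute is no larger than a few times the first minute's."""
        rate = 200.0
        n = int(1200 * rate)
        F = rng.normal(0, 20.0, n)
        com, _ = com_ml_absolute(F, 72.0, np.zeros(n), rate)
        first = com[int(60 * rate):int(120 * rate)].var()
        last = com[-int(60 * rate):].var()
        assert last < 10.0 * first + 1e-8

    def test_mass_validated(self):
        with pytest.raises(ValueError, match="mass"):
            com_ml_absolute(np.zeros(10), 0.0, np.zeros(10), 100.0)


class TestXcom:
    def test_zero_velocity_is_identity(self):
        assert xcom(0.03, 0.0, 0.9) == pytest.approx(0.03)

    def test_pendulum_eigenfrequency(self):
        # omega0 = sqrt(9.81 / 0.9) = 3.3015
        assert np.sqrt(9.81 / 0.9) == pytest.approx(3.3015, abs=1e-4)
        assert xcom(0.0, 0.1, 0.9) == pytest.approx(0.1 / 3.3015, abs=1e-5)

    def test_invalid_leg_length(self):
        with pytest.raises(ValueError, match="leg_length"):
            xcom(0.0, 0.1, -1.0)


def event_table(fast_offs, slow_offs):
    fo = np.asarray(fast_offs, float)
    so = np.asarray(slow_offs, float)
    return EventTable(fast_strikes=fo - 0.7, fast_offs=fo,
                      slow_strikes=so - 0.7, slow_offs=so)


class TestMos:
    def test_medial_xcom_positive_margin(self):
        t = np.linspace(0, 2, 2001)
        xc = np.full_like(t, 0.05)
        bos_fast = np.full_like(t, 0.10)
        ev = event_table([1.2], [1.0])
        mos = mos_per_stride(t, xc, bos_fast, -bos_fast, ev, fast_side="left")
        assert mos["mos_fast"].iloc[0] == pytest.approx(5.0)  # cm

    def test_lateral_xcom_negative_margin(self):
        t = np.linspace(0, 2, 2001)
        xc = np.full_like(t, 0.12)
        bos_fast = np.full_like(t, 0.10)
        ev = event_table([1.2], [1.0])
        mos = mos_per_stride(t, xc, bos_fast, -bos_fast, ev, fast_side="left")
        assert mos["mos_fast"].iloc[0] == pytest.approx(-2.0)

    def test_mirror_negates_xcom_and_preserves_margins(self):
        t = np.linspace(0, 4, 4001)
        xc = 0.03 * np.sin(2 * np.pi * t)
        bos_f = 0.10 + 0.01 * np.cos(2 * np.pi * t)
        bos_s = -0.09 + 0.01 * np.sin(2 * np.pi * t)
        ev = event_table([1.2, 2.3], [1.0, 2.1])
        mos = mos_per_stride(t, xc, bos_f, bos_s, ev, fast_side="left")
        mirrored = mos_per_stride(t, -xc, -bos_f, -bos_s, ev, fast_side="right")
        np.testing.assert_allclose(mirrored["mos_fast"], mos["mos_fast"], atol=1e-12)
        np.testing.assert_allclose(mirrored["mos_slow"], mos["mos_slow"], atol=1e-12)

    def test_event_outside_stream_rejected(self):
        t = np.linspace(0, 1, 101)
        ev = event_table([2.0], [0.5])
        with pytest.raises(ValueError, match="outside stream range"):
            mos_per_stride(t, t, t, t, ev)

    def test_signal_tier_reproduces_mos_schedule(self, processed_trial):
        """Pipeline MoS tracks the generator's exponential schedule
        (correlation > 0.95)."""
        trial, res = processed_trial
        st_df = res["strides"]
        gt = trial.truth
        for col, tkey, vkey in (("mos_fast", "slow_offs", "mos_fast_cm"),
                                ("mos_slow", "fast_offs", "mos_slow_cm")):
            v = st_df[col].to_numpy()
            ok = ~np.isnan(v)
            sched = np.interp(st_df["t"], gt[tkey], gt[vkey])
            assert np.corrcoef(v[ok], sched[ok])[0, 1] > 0.95
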