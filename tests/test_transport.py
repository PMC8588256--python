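"""Drift linearization, fits, analytic D_eff models, selectivity."""

import numpy as np
import pytest

from helknot.channel import HelicalChannelSpec
from helknot.transport import (
    DriftSeries,
    analyze_transport,
    d_eff_active_chiral,
    d_eff_tortuosity,
    fit_drift_speed,
    fit_msd_ballistic,
    linearize_drift,
    msd_from_linearized,
    selectivity_ratio,
)
from helknot.units import DEFAULT_UNITS


def _series(times, xs, signs):
    return DriftSeries(np.asarray(times, float), np.asarray(xs, float),
                       np.asarray(signs, float))


class TestLinearize:
    def test_sign_rule_example(self):
        s = _series([0, 1, 2, 3, 4], [0, 1, 2, 1, 0], [1, 1, -1, -1, -1])
        assert linearize_drift(s).tolist() == [0, 1, 2, 3, 4]

    def test_constant_sign_is_displacement(self):
        x = [0.0, 2.0, 3.5, 7.0]
        s = _series([0, 1, 2, 3], x, [1, 1, 1, 1])
        assert np.allclose(linearize_drift(s), np.array(x) - x[0])

    def test_sawtooth_linearizes_to_constant_slope(self):
        # sawtooth +-v exactly: up 10 steps, down 10 steps; the recorded
        # sign matches the force direction during each step
        x = np.concatenate([np.arange(11.0), np.arange(9.0, -1.0, -1)])
        signs = np.concatenate([np.ones(10), -np.ones(11)])
        t = np.arange(21.0)
        lin = linearize_drift(_series(t, x, signs))
        assert np.allclose(np.diff(lin), 1.0)

    def test_frame_gap_rejected(self):
        s = _series([0, 1], [0.0, 500.0], [1, 1])
        with pytest.raises(ValueError, match="jump"):
            linearize_drift(s, max_jump_nm=300.0)


class TestDriftFit:
    def test_exact_line(self):
        t = np.linspace(0, 10, 50)
        v, se, r2 = fit_drift_speed(t, 2.0e3 * t)   # 2 um/s in nm
        assert v == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            fit_drift_speed(np.arange(5.0), np.arange(5.0))


class TestMSDFit:
    def test_noiseless_inversion(self):
        d_true = 10.0   # um^2/s
        t = np.linspace(0.001, 0.05, 40)
        msd = (0.05 * d_true * t / 0.003) ** 2 + 2 * d_true * t
        d_fit, _ = fit_msd_ballistic(t, msd, f_ext=0.05, units=DEFAULT_UNITS)
        assert d_fit == pytest.approx(d_true, rel=1e-6)

    def test_zero_force_reduces_to_pure_diffusion(self):
        d_true = 4.0
        t = np.linspace(0.001, 0.05, 40)
        d_fit, _ = fit_msd_ballistic(t, 2 * d_true * t, f_ext=0.0)
        assert d_fit == pytest.approx(d_true, rel=1e-9)

    def test_windows_restart_at_flips(self):
        # a flip in the middle: lags never span the flip boundary
        t = np.arange(40.0)
        x = np.concatenate([np.arange(20.0), 19.0 - np.arange(20.0)]) * 10
        signs = np.concatenate([np.ones(20), -np.ones(20)])
        dx = linearize_drift(_series(t, x, signs))
        lags, msd = msd_from_linearized(t, dx, signs, n_lags=10)
        assert len(lags) >= 3
        assert np.all(np.isfinite(msd))


class TestParameterRecovery:
    def test_biased_random_walk_recovery(self):
        """Linearize -> fits recover (v, D) of a synthetic biased walk
        within 2 combined SEs at 5000 frames."""
        rng = np.random.default_rng(2021)
        n = 5000
        dt = 1e-5                     # s
        v_true = 300.0                # um/s
        d_true = 15.0                 # um^2/s
        steps = v_true * dt + np.sqrt(2 * d_true * dt) * rng.normal(size=n)
        x_um = np.concatenate([[0.0], np.cumsum(steps)])
        t = np.arange(n + 1) * dt
        # fold into a sawtooth with flips every 1000 frames
        signs = np.ones(n + 1)
        x_folded = x_um.copy()
        for k0 in range(1000, n + 1, 2000):
            k1 = min(k0 + 1000, n + 1)
            signs[k0:k1] = -1
        inc = np.diff(x_um)
        x = np.concatenate([[0.0], np.cumsum(signs[:-1] * inc)])
        series = _series(t, x * 1e3, signs)     # position in nm
        # linearization inverts the folding exactly
        assert np.allclose(linearize_drift(series) * 1e-3, x_um - x_um[0])
        res = analyze_transport([series], f_ext=0.05)
        # the walk's own realized slope fluctuates with
        # sigma_v = sqrt(2 D / T_total) ~ 24 um/s; allow 3 sigma
        sigma_v = np.sqrt(2 * d_true / t[-1])
        assert res.v_drift == pytest.approx(v_true, abs=3 * sigma_v)
        assert res.D == pytest.approx(d_true, rel=0.30)


class TestAnalyticModels:
    def test_tortuosity_limits(self):
        straight = HelicalChannelSpec(r_ch=3, r_h=0.0, pitch_k=1.5, n_turns=1)
        assert d_eff_tortuosity(5.0, straight) == 5.0
        default = HelicalChannelSpec(r_ch=3, r_h=1.5, pitch_k=1.5, n_turns=1)
        assert d_eff_tortuosity(5.0, default) == pytest.approx(5.0 / np.sqrt(2))

    def test_d_eff_monotone_in_helix_radius(self):
        vals = [d_eff_tortuosity(5.0, HelicalChannelSpec(
            r_ch=1.0, r_h=r, pitch_k=1.5, n_turns=1))
            for r in (0.0, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_active_chiral_limits_and_value(self):
        spec = HelicalChannelSpec(r_ch=0.2, r_h=1.0, pitch_k=1 / (2 * np.pi),
                                  n_turns=1)
        # v0 = 0 -> D_eff = D
        assert d_eff_active_chiral(2.0, 0.0, spec) == 2.0
        # D = 1, v0 = 1, R_H = 1, k = 1/(2 pi): D_theta = 0.75, Omega = 1
        # -> D_eff = 1 + 0.75/(2 (0.5625 + 1)) = 1.24
        assert d_eff_active_chiral(1.0, 1.0, spec) == pytest.approx(1.24)
        # k -> 0 (Omega -> inf) -> D_eff -> D
        tiny_k = HelicalChannelSpec(r_ch=1e-6, r_h=1.0, pitch_k=1e-6,
                                    n_turns=1)
        assert d_eff_active_chiral(1.0, 1.0, tiny_k) == pytest.approx(
            1.0, abs=1e-6)

    def test_active_chiral_requires_helix(self):
        spec = HelicalChannelSpec(r_ch=3, r_h=0.0, pitch_k=1.5, n_turns=1)
        with pytest.raises(ValueError):
            d_eff_active_chiral(1.0, 1.0, spec)


class TestSelectivity:
    def test_equal_inputs_no_selectivity(self):
        assert selectivity_ratio(3.0, 3.0) == 1.0

    def test_confined_trefoil_reference_values(self):
        # ratio of the reference confined diffusivities
        assert selectivity_ratio(10.29, 3.94) == pytest.approx(2.61, abs=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            selectivity_ratio(0.0, 1.0)
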