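"""Circuit dynamics: input equation, fixed points, calibration, integration."""

import dataclasses

import numpy as np
import pytest

import microcirc as mc
from microcirc.presets import FI_PARAMS, POPULATIONS, W_GENERIC

from conftest import LOW, HIGH, VIP_STEP, draw_stable_wd


def decoupled_circuit():
    return mc.Circuit(
        populations=POPULATIONS,
        fi=tuple(FI_PARAMS[p] for p in POPULATIONS),
        W=np.zeros((4, 4)),
    )


class TestNetInput:
    def test_zero_activity_returns_leak_potential(self):
        c = decoupled_circuit()
        V = mc.net_input(c, np.zeros(4), 0.0)
        np.testing.assert_array_equal(V, np.full(4, -70.0))

    def test_recurrent_term_hand_dot_product(self, low_circuit):
        # E row of the generic matrix at rates (1, 10, 3, 2) Hz:
        # 2.42*1 - 0.33*10 - 0.80*3 + 0 = -3.28 pA
        c = low_circuit.with_background(np.zeros(4))
        V = mc.net_input(c, LOW, 0.0)
        assert V[0] == pytest.approx(-70.0 + (-3.28) / 6.25, rel=1e-12)

    def test_external_current_is_additive(self, low_circuit):
        V0 = mc.net_input(low_circuit, LOW, 0.0)
        V1 = mc.net_input(low_circuit, LOW, VIP_STEP)
        np.testing.assert_allclose(V1 - V0, [0, 0, 0, 10.0 / 5.0], atol=1e-12)

    def test_dimension_mismatch_rejected(self, low_circuit):
        with pytest.raises(ValueError):
            mc.net_input(low_circuit, np.zeros(3), 0.0)


class TestSteadyStateAndCalibration:
    def test_decoupled_targets_recovered_exactly(self):
        c = decoupled_circuit()
        targets = np.array([3.0, 7.0, 2.0, 11.0])
        i_bkg = mc.calibrate_background(c, targets)
        # no recurrence: I_bkg = g_l (f^-1(r) - V_l)
        for k, p in enumerate(c.fi):
            assert i_bkg[k] == pytest.approx(p.g_l * (p.inverse(targets[k]) + 70.0), rel=1e-12)
        r = mc.steady_state(c.with_background(i_bkg), 0.0, r0=targets)
        np.testing.assert_allclose(r, targets, atol=1e-8)

    def test_low_baseline_reproduces_published_currents(self, low_circuit):
        # (114.7, 233.6, 94.3, 89.9) pA within 2%
        np.testing.assert_allclose(
            low_circuit.i_bkg, [114.7, 233.6, 94.3, 89.9], rtol=0.02
        )

    def test_low_baseline_fixed_point(self, low_circuit, low_fp):
        np.testing.assert_allclose(low_fp, LOW, atol=1e-6)

    def test_unprinted_targets_round_trip(self):
        base = mc.generic_circuit(baseline=None)
        targets = np.array([30.0, 50.0, 30.0, 20.0])
        c = mc.calibrated(base, targets)
        r = mc.steady_state(c, 0.0, r0=targets)
        np.testing.assert_allclose(r, targets, atol=1e-6)

    def test_vip_step_suppresses_sst_at_low_baseline(self, low_circuit, low_fp):
        r = mc.steady_state(low_circuit, VIP_STEP, r0=low_fp)
        assert r[2] < 3.0  # SST suppressed: disinhibition
        assert r[0] > 1.0 and r[1] > 10.0 and r[3] > 2.0

    def test_calibration_round_trip_random_circuits(self):
        rng = np.random.default_rng(7)
        n_ok = 0
        while n_ok < 50:
            W, _ = draw_stable_wd(rng)
            base = mc.generic_circuit(baseline=None).with_connectivity(W)
            targets = rng.uniform(0.5, 40.0, 4)
            try:
                c = mc.calibrated(base, targets)
                r = mc.steady_state(c, 0.0, r0=targets)
            except mc.ConvergenceError:
                continue  # calibrated point exists but solver may leave basin
            np.testing.assert_allclose(r, targets, atol=1e-6)
            n_ok += 1

    def test_nonpositive_targets_rejected(self, low_circuit):
        with pytest.raises(ValueError):
            mc.calibrate_background(low_circuit, [1.0, -1.0, 3.0, 2.0])


class TestSimulate:
    def test_equilibrium_stays_put(self, low_circuit, low_fp):
        traj = mc.simulate(
            low_circuit, mc.InputSchedule.zero(4), r0=low_fp, T=0.05, dt=1e-4
        )
        assert np.max(np.abs(traj.rates - low_fp)) < 1e-6

    def test_converges_to_steady_state(self, low_circuit, low_fp):
        traj = mc.simulate(
            low_circuit, mc.InputSchedule.constant(VIP_STEP), r0=low_fp, T=1.0, dt=1e-4
        )
        r_inf = mc.steady_state(low_circuit, VIP_STEP, r0=low_fp)
        np.testing.assert_allclose(traj.rates[-1], r_inf, atol=1e-4)

    def test_dt_halving_changes_endpoint_below_tolerance(self, low_circuit, low_fp):
        kw = dict(schedule=mc.InputSchedule.constant(VIP_STEP), r0=low_fp, T=0.3)
        end1 = mc.simulate(low_circuit, dt=1e-4, **kw).rates[-1]
        end2 = mc.simulate(low_circuit, dt=5e-5, **kw).rates[-1]
        assert np.max(np.abs(end1 - end2)) < 1e-4

    def test_rk4_agrees_with_euler(self, low_circuit, low_fp):
        kw = dict(schedule=mc.InputSchedule.constant(VIP_STEP), r0=low_fp, T=0.2)
        eu = mc.simulate(low_circuit, dt=5e-5, method="euler", **kw).rates[-1]
        rk = mc.simulate(low_circuit, dt=5e-5, method="rk4", **kw).rates[-1]
        np.testing.assert_allclose(eu, rk, atol=1e-4)

    def test_low_baseline_transients_match_regime(self, low_circuit, low_fp):
        traj = mc.simulate(
            low_circuit, mc.InputSchedule.constant(VIP_STEP), r0=low_fp, T=0.5, dt=1e-4
        )
        final = traj.rates[-1]
        assert final[2] < low_fp[2]  # SST settles below baseline
        assert np.all(np.diff(traj.rates[:, 2]) <= 1e-9)  # monotone decay
        assert np.all(final[[0, 1, 3]] > low_fp[[0, 1, 3]])

    def test_high_baseline_sst_dips_then_reverses(self, high_circuit, high_fp):
        traj = mc.simulate(
            high_circuit, mc.InputSchedule.constant(VIP_STEP), r0=high_fp, T=0.5, dt=1e-4
        )
        s = traj.rates[:, 2]
        assert s.min() < high_fp[2] - 1e-3
        assert s[-1] > high_fp[2] + 1e-3

    def test_coarse_dt_rejected(self, low_circuit, low_fp):
        with pytest.raises(ValueError):
            mc.simulate(low_circuit, mc.InputSchedule.zero(4), r0=low_fp, T=0.1, dt=1e-3)

    def test_linearity_of_small_responses(self, low_circuit, low_fp):
        # response to +/- eps pA on VIP is antisymmetric to O(eps^2): the
        # residual asymmetry must shrink quadratically when eps is halved
        def asym(eps):
            up = mc.steady_state(low_circuit, [0, 0, 0, eps], r0=low_fp)
            dn = mc.steady_state(low_circuit, [0, 0, 0, -eps], r0=low_fp)
            return np.max(np.abs((up - low_fp) + (dn - low_fp)))

        a1, a2 = asym(0.02), asym(0.01)
        assert a1 < 1e-4  # already tiny on the response scale
        assert 2.5 < a1 / a2 < 6.0  # quadratic scaling in eps


class TestStability:
    def test_decoupled_eigenvalues_are_leak_rate(self):
        c = decoupled_circuit().with_background(
            mc.calibrate_background(decoupled_circuit(), [1.0, 1.0, 1.0, 1.0])
        )
        r = mc.steady_state(c, 0.0, r0=np.ones(4))
        rep = mc.jacobian_stability(c, r)
        np.testing.assert_allclose(rep.eigenvalues.real, -1.0 / 0.002, rtol=1e-9)
        assert rep.is_stable

    @pytest.mark.parametrize("baseline", ["low", "high"])
    def test_both_baselines_stable(self, baseline):
        c = mc.generic_circuit(baseline)
        targets = LOW if baseline == "low" else HIGH
        r = mc.steady_state(c, 0.0, r0=targets)
        rep = mc.jacobian_stability(c, r)
        assert rep.is_stable
        # stability implies det(D - W) > 0 at the operating point
        rm = mc.response_matrix_numeric(c, r)
        assert rm.C > 0

    def test_non_fixed_point_rejected(self, low_circuit):
        with pytest.raises(ValueError):
            mc.jacobian_stability(low_circuit, LOW + 1.0)


class TestValidation:
    def test_sign_structure_enforced(self):
        W = W_GENERIC.copy()
        W[0, 1] = +0.33  # PV source column must stay non-positive
        with pytest.raises(ValueError):
            mc.Circuit(
                populations=POPULATIONS,
                fi=tuple(FI_PARAMS[p] for p in POPULATIONS),
                W=W,
            )

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError):
            mc.InputSchedule(((0.0, 1.0, np.zeros(4)), (0.5, 2.0, np.ones(4))))

    def test_schedule_lookup(self):
        s = mc.InputSchedule.step(VIP_STEP, t_on=0.1, t_off=0.2)
        assert np.all(s.current(0.05, 4) == 0)
        np.testing.assert_array_equal(s.current(0.15, 4), VIP_STEP)
        assert np.all(s.current(0.25, 4) == 0)
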