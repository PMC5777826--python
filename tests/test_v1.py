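"""Mouse-V1 battery: stimulus currents, condition patterns, robustness."""

import numpy as np
import pytest

import microcirc as mc
from microcirc.v1 import pattern_check, stimulus_current

from conftest import LOW


class TestStimulusCurrents:
    def test_darkness_is_zero(self):
        np.testing.assert_array_equal(stimulus_current("darkness"), np.zeros(4))

    def test_gray_screen_targets_e_only(self):
        np.testing.assert_array_equal(stimulus_current("gray"), [50.0, 0, 0, 0])

    def test_grating_sigmoid_values(self):
        # weak stimulus, 6 deg: E channel 100/(1+e^-3)+5, S channel 20/(1+e^-1)+5
        I = stimulus_current("grating", 6.0)
        assert I[0] == pytest.approx(100 / (1 + np.exp(-3.0)) + 5, rel=1e-12)
        assert I[2] == pytest.approx(20 / (1 + np.exp(-1.0)) + 5, rel=1e-12)
        assert I[0] == pytest.approx(100.26, abs=0.01)
        assert I[2] == pytest.approx(19.62, abs=0.01)
        assert I[1] == 0 and I[3] == 0

    def test_grating_midpoint_and_saturation(self):
        assert stimulus_current("grating", 0.0)[0] == pytest.approx(55.0)
        I_inf = stimulus_current("grating", 1e4)
        assert I_inf[0] == pytest.approx(105.0)
        assert I_inf[2] == pytest.approx(25.0)

    def test_monotone_in_diameter(self):
        thetas = np.linspace(0, 80, 40)
        I = np.array([stimulus_current("grating", t) for t in thetas])
        assert np.all(np.diff(I[:, 0]) >= 0) and np.all(np.diff(I[:, 2]) >= 0)

    def test_input_saturation_scales(self):
        # center input ~saturated by 20 deg, surround only by ~60 deg
        I20 = stimulus_current("grating", 20.0)
        I60 = stimulus_current("grating", 60.0)
        assert I20[0] > 0.99 * 105.0
        assert I20[2] < 0.98 * 25.0
        assert I60[2] > 0.99 * 25.0

    def test_pv_variant_currents(self):
        assert stimulus_current("darkness", targets=("E", "S", "P"))[1] == 0.0
        assert stimulus_current("gray", targets=("E", "S", "P"))[1] == 10.0
        I = stimulus_current("grating", 1e4, targets=("E", "S", "P"))
        assert I[1] == pytest.approx(25.0)  # a_P + 5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stimulus_current("grating", -1.0)
        with pytest.raises(ValueError):
            stimulus_current("grating")
        with pytest.raises(ValueError):
            stimulus_current("flicker")


RATE_COLS = [f"r_{l}" for l in "EPSV"]


def locomotion_delta(battery, condition):
    g = battery[battery.condition == condition].set_index("state")
    return g.loc["locomotion", RATE_COLS] - g.loc["immobility", RATE_COLS]


@pytest.fixture(scope="module")
def battery(v1_low):
    return mc.run_condition_battery(v1_low)


class TestBattery:
    def test_all_conditions_stable(self, battery):
        assert battery["stable"].all()

    def test_darkness_locomotion_suppresses_sst(self, battery):
        delta = locomotion_delta(battery, "darkness")
        assert delta["r_S"] < -1e-2
        assert all(delta[f"r_{l}"] > 1e-2 for l in "EPV")

    @pytest.mark.parametrize("cond", ["gray", "grating(25)"])
    def test_visual_stimulation_locomotion_raises_all(self, battery, cond):
        delta = locomotion_delta(battery, cond)
        assert all(delta[f"r_{l}"] > 1e-2 for l in "EPSV")

    def test_pattern_check_summary(self, battery):
        checks = pattern_check(battery)
        assert checks["all"]

    def test_weak_stimulus_sst_ordering_reverses(self, v1_low):
        # pre-stimulus SST is higher for immobility; during a weak (6 deg)
        # grating the order flips and locomotion gives the higher SST rate
        df = mc.run_condition_battery(v1_low, grating_deg=6.0)
        dark = df[df.condition == "darkness"].set_index("state")
        grat = df[df.condition == "grating(6)"].set_index("state")
        assert dark.loc["immobility", "r_S"] > dark.loc["locomotion", "r_S"]
        assert grat.loc["locomotion", "r_S"] > grat.loc["immobility", "r_S"]

    def test_battery_deterministic(self, v1_low, battery):
        again = mc.run_condition_battery(v1_low)
        for col in ("r_E", "r_P", "r_S", "r_V"):
            np.testing.assert_array_equal(battery[col].values, again[col].values)

    def test_regime_diagnostic_consistent_with_simulated_sign_flip(self, v1_low):
        # cross-module coherence between the local M_SV diagnostic and the
        # simulated finite (10 pA) SST locomotion response.  In darkness both
        # endpoints sit in the disinhibition regime and SST drops; under a
        # gray screen both sit in the reversal regime and SST rises; the
        # grating condition starts marginally below the reversal boundary and
        # crosses it en route, so the destination regime carries the sign.
        loco = np.array([0, 0, 0, 10.0])
        signs = {}
        for kind, theta in (("darkness", None), ("gray", None), ("grating", 25.0)):
            I = stimulus_current(kind, theta)
            r = mc.steady_state(v1_low, I, r0=np.ones(4))
            r_loc = mc.steady_state(v1_low, I + loco, r0=r)
            m_imm = mc.classify_regime(v1_low, r, i_ext=I).m_sv
            m_loc = mc.classify_regime(v1_low, r_loc, i_ext=I + loco).m_sv
            signs[kind] = (m_imm, m_loc, r_loc[2] - r[2])
        m_imm, m_loc, dS = signs["darkness"]
        assert m_imm < 0 and m_loc < 0 and dS < 0
        m_imm, m_loc, dS = signs["gray"]
        assert m_imm > 0 and m_loc > 0 and dS > 0
        m_imm, m_loc, dS = signs["grating"]
        assert m_loc > 0 and dS > 0  # reversal at the destination


class TestSizeTuning:
    def test_e_rate_nonmonotone_in_diameter(self, v1_low):
        df = mc.size_tuning(v1_low, [2, 6, 10, 20, 40, 60])
        assert df.attrs["e_nonmonotone"]
        e = df["r_E"].to_numpy()
        assert e.max() > e[0] + 1e-2 and e.max() > e[-1] + 1e-2

    def test_sst_rate_increases_with_diameter(self, v1_low):
        df = mc.size_tuning(v1_low, [2, 6, 10, 20, 40, 60])
        s = df["r_S"].to_numpy()
        assert np.all(np.diff(s) > 0)

    def test_grid_must_increase(self, v1_low):
        with pytest.raises(ValueError):
            mc.size_tuning(v1_low, [10, 5, 20])


class TestRobustness:
    def test_zero_fraction_preserves_everything(self, v1_low):
        rep = mc.perturb_connectivity(v1_low, LOW, fraction=0.0, n_draws=3, seed=0)
        assert rep.n_stable == 3 and rep.n_preserved == 3
        assert rep.preservation_rate == 1.0

    def test_perturbed_entries_within_band_and_sign_preserved(self, v1_low):
        rng = np.random.default_rng(0)
        factors = rng.uniform(0.9, 1.1, size=v1_low.W.shape)
        W = v1_low.W * np.where(v1_low.W != 0, factors, 1.0)
        nz = v1_low.W != 0
        ratio = W[nz] / v1_low.W[nz]
        assert np.all((ratio >= 0.9) & (ratio <= 1.1))
        assert np.array_equal(np.sign(W), np.sign(v1_low.W))

    def test_majority_of_stable_draws_preserve_pattern(self, v1_low):
        rep = mc.perturb_connectivity(v1_low, LOW, fraction=0.10, n_draws=30, seed=3)
        assert rep.n_stable > 0
        assert rep.n_preserved > rep.n_stable / 2
        assert rep.ci_low <= rep.preservation_rate <= rep.ci_high


class TestVariants:
    def test_zero_extra_weight_is_regression_neutral(self, v1_low):
        base = mc.run_condition_battery(v1_low)
        var = mc.variant_battery(v1_low, "pv_to_vip", extra_weight=0.0)
        for col in ("r_E", "r_P", "r_S", "r_V"):
            np.testing.assert_allclose(base[col].values, var[col].values, atol=1e-12)

    @pytest.mark.parametrize("variant", ["pv_to_vip", "pv_to_sst"])
    def test_extra_projection_battery_runs_and_pattern_holds(self, v1_low, variant):
        df = mc.variant_battery(v1_low, variant, extra_weight=0.1, baseline_targets=LOW)
        assert df["stable"].all()
        assert pattern_check(df)["all"]

    def test_thalamic_to_pv_battery(self, v1_low):
        df = mc.variant_battery(v1_low, "thalamic_to_pv")
        assert df["stable"].all()
        # PV now receives stimulus current; darkness must be unchanged
        base = mc.run_condition_battery(v1_low)
        dark_v = df[df.condition == "darkness"]
        dark_b = base[base.condition == "darkness"]
        for col in ("r_E", "r_P", "r_S", "r_V"):
            np.testing.assert_allclose(dark_v[col].values, dark_b[col].values, atol=1e-9)

    def test_unknown_variant_rejected(self, v1_low):
        with pytest.raises(ValueError):
            mc.variant_battery(v1_low, "thalamic_to_sst")
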