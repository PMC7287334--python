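"""Clamp-model oracles: DC circuit, limiting cases, leak handling, engines."""

import numpy as np
import pytest

import vclamp
from vclamp.cells import ModelCellTypeI, ModelCellTypeII
from vclamp.clamp import (
    ArtefactResidual,
    ArtefactTrue,
    MachineSettings,
    Recording,
    compensated_settings,
    estimate_leak,
    full_clamp_rhs,
    simplified_clamp_rhs,
    simulate,
    subtract_leak,
)
from vclamp.protocol import Protocol, Segment, sample

from conftest import dc_circuit_solution


def hold(v, duration=400.0, dt=2.0, holding=0.0):
    return Protocol((Segment(duration, v, v),), dt=dt, holding=holding)


class TestDCKirchhoff:
    """Full-model steady states against the independent DC circuit solver.

    This is the principal oracle for the transcription of the full
    experiment model: every resistive pathway, offset and compensation
    term must balance at DC.
    """

    @pytest.mark.parametrize("R_s", [0.01, 0.03])
    @pytest.mark.parametrize("R_m", [0.2, 0.5])
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.8])
    @pytest.mark.parametrize("V_off", [0.0, 5.0])
    @pytest.mark.parametrize("cell_type", ["I", "II"])
    def test_steady_state_grid(self, R_s, R_m, alpha, V_off, cell_type):
        cell = (ModelCellTypeI(R_m=R_m) if cell_type == "I"
                else ModelCellTypeII(R_m=R_m, R_k=0.1, C_k=1000.0))
        art = ArtefactTrue(V_off=V_off, C_p=4.7, C_m=22.0, R_s=R_s,
                           g_leak=0.2, E_leak=-10.0)
        mach = compensated_settings(art, alpha=alpha) if alpha > 0 \
            else MachineSettings()
        v_cmd = 80.0
        rec = simulate(hold(v_cmd, duration=3000.0), "full", cell,
                       artefact=art, machine=mach)
        V_m_expect, I_expect = dc_circuit_solution(
            v_cmd, R_m=R_m, R_s=R_s, alpha=mach.alpha,
            R_s_star=mach.R_s_star, V_off=V_off, V_off_star=mach.V_off_star,
            g_leak=art.g_leak, E_leak=art.E_leak)
        assert rec.v_m[-1] == pytest.approx(V_m_expect, rel=1e-6)
        assert rec.i_out[-1] == pytest.approx(I_expect, rel=1e-6)

    def test_reference_uncompensated_divider(self):
        """The canonical voltage-divider numbers: 30 MOhm + 500 MOhm."""
        cell = ModelCellTypeI(R_m=0.5)
        art = ArtefactTrue(V_off=0.0, C_p=4.7, C_m=22.0, R_s=0.03)
        rec = simulate(hold(100.0, duration=1000.0), "full", cell,
                       artefact=art, machine=MachineSettings())
        assert rec.i_out[-1] == pytest.approx(100.0 / 0.53, rel=1e-6)
        assert rec.v_m[-1] == pytest.approx(100.0 * 0.5 / 0.53, rel=1e-6)


class TestIdealClamp:
    def test_type1_exact_ohms_law(self, staircase):
        rec = vclamp.ideal_clamp(staircase, ModelCellTypeI(R_m=0.5))
        assert np.allclose(rec.i_out, rec.v_cmd / 0.5)
        assert np.allclose(rec.v_m, rec.v_cmd)

    def test_ikr_held_at_reversal_is_silent(self, ikr_default):
        p = hold(ikr_default.E_K, duration=2000.0, holding=ikr_default.E_K)
        rec = vclamp.ideal_clamp(p, ikr_default)
        assert np.max(np.abs(rec.i_out)) < 1e-9


class TestLimitingCases:
    def test_simplified_equals_ideal_under_perfect_compensation(
            self, staircase, ikr_default):
        """alpha = 1 with accurate R_s* and zero residuals is an ideal clamp."""
        art = ArtefactTrue(C_m=10.0, R_s=0.01)
        mach = MachineSettings(alpha=1.0, R_s_star=0.01, C_m_star=10.0)
        r_simp = simulate(staircase, "simplified", ikr_default, artefact=art,
                          machine=mach, residual=ArtefactResidual())
        r_ideal = vclamp.ideal_clamp(staircase, ikr_default)
        rel = (np.linalg.norm(r_simp.i_post - r_ideal.i_out)
               / np.linalg.norm(r_ideal.i_out))
        assert rel < 1e-8
        assert np.allclose(r_simp.v_m, r_ideal.v_m)

    def test_simplified_equals_ideal_model_cell(self, staircase):
        cell = ModelCellTypeII()
        art = ArtefactTrue(C_m=22.0, R_s=0.03)
        mach = MachineSettings(alpha=1.0, R_s_star=0.03, C_m_star=22.0)
        r_simp = simulate(staircase, "simplified", cell, artefact=art,
                          machine=mach, residual=ArtefactResidual())
        r_ideal = vclamp.ideal_clamp(staircase, cell)
        rel = (np.linalg.norm(r_simp.i_out - r_ideal.i_out)
               / np.linalg.norm(r_ideal.i_out))
        assert rel < 1e-8

    def test_full_matches_simplified_on_staircase(self, staircase):
        """The fast-amplifier reduction holds to <1% on slow timescales."""
        cell = ModelCellTypeI(R_m=0.5)
        art = ArtefactTrue(C_p=4.7, C_m=22.0, R_s=0.03)
        mach = compensated_settings(art, alpha=0.8)
        r_full = simulate(staircase, "full", cell, artefact=art, machine=mach)
        r_simp = simulate(staircase, "simplified", cell, artefact=art,
                          machine=mach, residual=ArtefactResidual())
        rel = (np.linalg.norm(r_full.i_out - r_simp.i_out)
               / np.linalg.norm(r_full.i_out))
        assert rel < 0.01

    def test_vanishing_artefacts_recover_ideal_readout(self):
        """Tiny R_s, no C_p/V_off/leak: I_out tracks I_ion after ~tau_z."""
        cell = ModelCellTypeI(R_m=0.5)
        art = ArtefactTrue(V_off=0.0, C_p=0.0, C_m=1.0, R_s=1e-5)
        rec = simulate(hold(100.0, duration=50.0, dt=0.5), "full", cell,
                       artefact=art, machine=MachineSettings())
        I_ion = 100.0 / 0.5
        assert rec.i_out[-1] == pytest.approx(I_ion, rel=1e-3)

    def test_capacitive_spike_charge_conservation(self):
        """Uncompensated C_p: the step-transient integral carries C_p * dV.

        C-slow is enabled (C_m*, R_s* accurate, alpha = 0) so the membrane
        charging current is cancelled and the spike isolates C_p.
        """
        cell = ModelCellTypeI(R_m=100.0)  # huge R_m: resistive current tiny
        art = ArtefactTrue(C_p=4.7, C_m=1.0, R_s=0.002)
        p = Protocol((Segment(20.0, 0.0, 0.0), Segment(30.0, 40.0, 40.0)),
                     dt=0.002, holding=0.0)
        rec = simulate(p, "full", cell, artefact=art,
                       machine=MachineSettings(C_m_star=1.0, R_s_star=0.002))
        after = rec.t > 20.0
        baseline = rec.i_out[-1]
        charge = np.trapezoid(rec.i_out[after] - baseline, rec.t[after])
        assert charge == pytest.approx(4.7 * 40.0, rel=0.05)

    def test_rs_artefact_proportional_to_current(self):
        """|V_m - V_cmd| scales linearly with the current magnitude."""
        cell = ModelCellTypeI(R_m=0.5)
        art = ArtefactTrue(C_m=22.0, R_s=0.03)
        mach = compensated_settings(art, alpha=0.5)
        ratios = []
        for v in (40.0, 80.0, 120.0):
            rec = simulate(hold(v, duration=1000.0), "full", cell,
                           artefact=art, machine=mach)
            err = abs(rec.v_m[-1] - rec.v_cmd[-1])
            ratios.append(err / abs(rec.i_out[-1]))
        assert np.allclose(ratios, ratios[0], rtol=1e-6)

    def test_compensation_shrinks_voltage_error_fivefold(self):
        """At alpha = 0.8 the per-pA voltage error drops by 1/(1-alpha)."""
        cell = ModelCellTypeI(R_m=0.5)
        art = ArtefactTrue(C_p=4.7, C_m=22.0, R_s=0.03)
        r0 = simulate(hold(100.0, duration=1000.0), "full", cell,
                      artefact=art, machine=MachineSettings())
        r1 = simulate(hold(100.0, duration=1000.0), "full", cell,
                      artefact=art, machine=compensated_settings(art, 0.8))
        err0 = abs(r0.v_m[-1] - 100.0) / abs(r0.i_out[-1])
        err1 = abs(r1.v_m[-1] - 100.0) / abs(r1.i_out[-1])
        assert err0 / err1 >= 5.0 - 1e-6


class TestSimulateContracts:
    def test_noiseless_determinism(self, staircase, ikr_default):
        art = ArtefactTrue(C_m=12.0, R_s=0.012)
        mach = MachineSettings(alpha=0.8, R_s_star=0.012, C_m_star=12.0)
        res = ArtefactResidual(V_off_dagger=1.0, g_leak_dagger=0.2)
        a = simulate(staircase, "simplified", ikr_default, artefact=art,
                     machine=mach, residual=res)
        b = simulate(staircase, "simplified", ikr_default, artefact=art,
                     machine=mach, residual=res)
        assert np.array_equal(a.i_post, b.i_post)

    def test_noise_seeding(self, ikr_default):
        p = hold(-20.0, duration=200.0, holding=-80.0)
        kw = dict(noise_sd=5.0)
        a = vclamp.ideal_clamp(p, ikr_default, seed=11, **kw)
        b = vclamp.ideal_clamp(p, ikr_default, seed=11, **kw)
        c = vclamp.ideal_clamp(p, ikr_default, seed=12, **kw)
        assert np.array_equal(a.i_out, b.i_out)
        assert not np.array_equal(a.i_out, c.i_out)

    def test_solver_tolerance_convergence(self, staircase):
        """Halving the stiff-solver tolerances barely moves the trace."""
        trunc = Protocol(staircase.segments[:8], dt=1.0, holding=-80.0)
        cell = ModelCellTypeII()
        art = ArtefactTrue(C_p=4.7, C_m=22.0, R_s=0.03)
        r1 = simulate(trunc, "full", cell, artefact=art,
                      machine=MachineSettings(),
                      solver_opts={"engine": "scipy", "rtol": 1e-6,
                                   "atol": 1e-8})
        r2 = simulate(trunc, "full", cell, artefact=art,
                      machine=MachineSettings(),
                      solver_opts={"engine": "scipy", "rtol": 5e-7,
                                   "atol": 5e-9})
        rms = (np.sqrt(np.mean((r1.i_out - r2.i_out) ** 2))
               / np.sqrt(np.mean(r2.i_out ** 2)))
        assert rms < 1e-3

    def test_engines_agree_linear_cell(self):
        """Exact LTI propagation vs stiff integration of the same RHS."""
        p = Protocol((Segment(50.0, 0.0, 0.0), Segment(100.0, 40.0, 40.0),
                      Segment(100.0, -40.0, 0.0)), dt=0.5, holding=0.0)
        cell = ModelCellTypeII()
        art = ArtefactTrue(C_p=4.7, C_m=22.0, R_s=0.03)
        mach = compensated_settings(art, alpha=0.8)
        a = simulate(p, "full", cell, artefact=art, machine=mach)
        b = simulate(p, "full", cell, artefact=art, machine=mach,
                     solver_opts={"engine": "scipy", "method": "BDF"})
        rel = np.linalg.norm(a.i_out - b.i_out) / np.linalg.norm(a.i_out)
        assert rel < 1e-6

    def test_engines_agree_ikr(self, fixture_protocols, ikr_default):
        """Exponential-splitting kernel vs reference stiff integration."""
        ap = fixture_protocols["ap_like"]
        art = ArtefactTrue(C_m=12.0, R_s=0.012)
        mach = MachineSettings(alpha=0.8, R_s_star=0.012, C_m_star=12.0)
        res = ArtefactResidual(V_off_dagger=2.0, g_leak_dagger=0.3)
        a = simulate(ap, "simplified", ikr_default, artefact=art,
                     machine=mach, residual=res)
        b = simulate(ap, "simplified", ikr_default, artefact=art,
                     machine=mach, residual=res,
                     solver_opts={"engine": "scipy", "rtol": 1e-9,
                                  "atol": 1e-11})
        rel = np.linalg.norm(a.i_post - b.i_post) / np.linalg.norm(b.i_post)
        assert rel < 1e-3


class TestRhsAPI:
    def test_full_rhs_shape_and_observables(self, ikr_default):
        art = ArtefactTrue()
        mach = MachineSettings()
        state = np.array([-80.0, -80.0, -80.0, 0.0, -80.0, 0.1, 0.9])
        d, obs = full_clamp_rhs(state, 0.0, -80.0, ikr_default, art, mach)
        assert d.shape == state.shape
        assert set(obs) == {"I_out", "V_m", "V_p"}

    def test_full_rhs_rejects_nonfinite_state(self):
        from vclamp.clamp import SimulationError

        art, mach = ArtefactTrue(), MachineSettings()
        state = np.array([np.nan, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(SimulationError):
            full_clamp_rhs(state, 0.0, 0.0, ModelCellTypeI(), art, mach)

    def test_simplified_rhs_dc_offset_only(self):
        """With no current flowing, V_m settles at V_cmd + V_off^†."""
        res = ArtefactResidual(V_off_dagger=3.0)
        mach = MachineSettings(alpha=0.8, R_s_star=0.01)
        cell = ModelCellTypeI(R_m=1e12)  # effectively no ionic current
        v_eq = -50.0 + 3.0
        d, obs = simplified_clamp_rhs(np.array([v_eq]), 0.0, -50.0, cell,
                                      res, mach, C_m=10.0, R_s=0.01)
        assert d[0] == pytest.approx(0.0, abs=1e-9)
        assert obs["V_m"] == pytest.approx(v_eq)

    def test_over_compensation_rejected(self):
        res = ArtefactResidual()
        mach = MachineSettings(alpha=1.0, R_s_star=0.02)
        with pytest.raises(ValueError):
            simplified_clamp_rhs(np.array([0.0]), 0.0, 0.0,
                                 ModelCellTypeI(), res, mach,
                                 C_m=10.0, R_s=0.01)


class TestLeak:
    def make_leak_recording(self, g, E, noise_sd=0.0, seed=0):
        p = vclamp.fixtures()["leak_ramp"]
        t, v = sample(p)
        i = g * (v - E)
        if noise_sd > 0:
            i = i + np.random.default_rng(seed).normal(0, noise_sd, len(i))
        return Recording(t=t, v_cmd=v, i_out=i), p

    def test_exact_recovery(self):
        rec, _ = self.make_leak_recording(0.5, -20.0)
        est = estimate_leak(rec, (100.0, 500.0), holding=-80.0)
        assert est["g_leak_star"] == pytest.approx(0.5, abs=1e-9)
        assert est["E_leak_star"] == pytest.approx(-20.0, abs=1e-9)
        assert not est["degenerate"]

    def test_degenerate_zero_current(self):
        rec, _ = self.make_leak_recording(0.0, 0.0)
        est = estimate_leak(rec, (100.0, 500.0), holding=-80.0)
        assert est["g_leak_star"] == 0.0
        assert est["E_leak_star"] == -80.0
        assert est["degenerate"]

    def test_constant_window_rejected(self):
        rec, _ = self.make_leak_recording(0.5, -20.0)
        with pytest.raises(ValueError):
            estimate_leak(rec, (505.0, 690.0), holding=-80.0)

    def test_noisy_recovery_within_regression_error_bars(self):
        """The slope estimate follows ordinary-least-squares theory."""
        g, E, sd = 0.5, -20.0, 5.0
        rec, p = self.make_leak_recording(g, E, noise_sd=sd, seed=4)
        w = (rec.t >= 100.0) & (rec.t <= 500.0)
        V = rec.v_cmd[w]
        sd_g = sd / np.sqrt(np.sum((V - V.mean()) ** 2))
        n_hold = int(np.sum((~w) & (np.abs(rec.v_cmd + 80.0) < 1e-6)))
        sd_E = sd / (np.sqrt(n_hold) * g)  # holding-current pathway
        est = estimate_leak(rec, (100.0, 500.0), holding=-80.0)
        assert abs(est["g_leak_star"] - g) < 3 * sd_g
        # E = holding - I_hold / g_hat propagates both error sources:
        # dE ~ (holding - E) dg/g - dI_hold/g
        assert abs(est["E_leak_star"] - E) < 3 * (sd_E + abs(-80.0 - E) * sd_g / g)

    def test_subtract_identity_and_perfect(self):
        rec, _ = self.make_leak_recording(0.5, -20.0)
        same = subtract_leak(rec, 0.0, 0.0)
        assert np.array_equal(same.i_post, rec.i_out)
        clean = subtract_leak(rec, 0.5, -20.0)
        assert np.max(np.abs(clean.i_post)) < 1e-9
        assert np.array_equal(clean.i_out, rec.i_out)  # raw trace retained

    def test_leak_at_vm_subtracted_at_vcmd_leaves_residual(self):
        """Series resistance makes V_m lag V_cmd, so subtraction at V_cmd
        leaves a residual proportional to V_m - V_cmd: the imperfection the
        simplified model's residual leak conductance absorbs."""
        g_leak, E_leak = 1.0, -10.0
        cell = ModelCellTypeI(R_m=0.5)
        art = ArtefactTrue(C_m=22.0, R_s=0.05, g_leak=g_leak, E_leak=E_leak)
        p = hold(100.0, duration=1500.0)
        rec = simulate(p, "full", cell, artefact=art,
                       machine=MachineSettings())
        v_m = rec.v_m[-1]
        # remove the cell's own current, keeping the measured leak pathway
        leak_measured = rec.i_out[-1] - v_m / 0.5
        residual = leak_measured - g_leak * (100.0 - E_leak)
        assert residual == pytest.approx(g_leak * (v_m - 100.0), rel=1e-6)

    def test_missing_trace_errors(self):
        rec = Recording(t=np.arange(3.0), v_cmd=np.zeros(3))
        with pytest.raises(ValueError):
            subtract_leak(rec, 0.1, 0.0)


class TestRecordingIO:
    def test_roundtrip(self, tmp_path, ikr_default):
        p = hold(-20.0, duration=100.0, holding=-80.0)
        rec = vclamp.ideal_clamp(p, ikr_default, noise_sd=2.0, seed=3)
        rec.i_post = rec.i_out.copy()
        path = tmp_path / "rec.csv"
        rec.to_file(path)
        back = Recording.from_file(path)
        assert np.allclose(back.t, rec.t)
        assert np.allclose(back.i_out, rec.i_out)
        assert np.allclose(back.i_post, rec.i_post)
        assert back.meta["mode"] == "ideal"

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            Recording(t=np.arange(5.0), v_cmd=np.zeros(4))
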