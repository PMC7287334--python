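"""Transforms, objective, optimizer behaviour and fit contracts.

Heavy recovery fits live in the acceptance suite; here the fits use short
protocols and small budgets to exercise the machinery.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vclamp
from vclamp.clamp import ArtefactResidual, ArtefactTrue, MachineSettings
from vclamp.inference import (
    CMAES,
    FitResult,
    ParameterTransform,
    _cma_minimise,
    default_transform,
    dof_count,
    fit_cell,
    fit_shared,
    objective_sse,
)
from vclamp.protocol import Protocol, Segment
from vclamp.synthetic import (
    PopulationHyperparameters,
    _row_models,
    draw_population,
    generate_dataset,
)


@pytest.fixture(scope="module")
def mini_protocol():
    """A compressed staircase: enough structure to constrain g and offsets."""
    segs = (
        Segment(100.0, -80.0, -80.0),
        Segment(100.0, -120.0, -120.0),
        Segment(200.0, -120.0, -80.0),
        Segment(400.0, 0.0, 0.0),
        Segment(400.0, 40.0, 40.0),
        Segment(300.0, -40.0, -40.0),
        Segment(200.0, -120.0, -120.0),
        Segment(200.0, -80.0, -80.0),
    )
    return Protocol(segs, dt=2.0, holding=-80.0)


@pytest.fixture(scope="module")
def one_cell(mini_protocol):
    truth = draw_population(PopulationHyperparameters(N=1, noise_sd=0.0), 3)
    recs = generate_dataset(truth, mini_protocol, seed=3, noise_sd=0.0)
    row = truth.iloc[0]
    _, _, art, mach = _row_models(row, truth.attrs["theta"],
                                  truth.attrs["E_K"])
    return truth, recs[0], art, mach


class TestTransforms:
    @pytest.mark.parametrize("mode", ["kinetics_only", "kinetics_artefacts",
                                      "conductance_artefacts", "model_cell"])
    def test_roundtrip_exact(self, mode):
        tr = default_transform(mode)
        rng = np.random.default_rng(0)
        u = rng.uniform(0.05, 0.95, tr.n)
        x = tr.from_unit(u)
        assert np.allclose(tr.to_unit(x), u, atol=1e-12)
        assert np.allclose(tr.inverse(tr.transform(x)), x, rtol=1e-12)

    def test_bounds_respected(self):
        tr = default_transform("conductance_artefacts")
        assert np.allclose(tr.from_unit(np.zeros(tr.n)), tr.lower, rtol=1e-12)
        assert np.allclose(tr.from_unit(np.ones(tr.n)), tr.upper, rtol=1e-12)
        # out-of-box requests are clipped, never extrapolated
        assert np.allclose(tr.from_unit(np.full(tr.n, 2.0)), tr.upper,
                           rtol=1e-12)

    def test_invalid_transforms_rejected(self):
        with pytest.raises(ValueError):
            ParameterTransform(("a",), ("log",), np.array([-1.0]),
                               np.array([1.0]))
        with pytest.raises(ValueError):
            ParameterTransform(("a",), ("weird",), np.array([0.1]),
                               np.array([1.0]))


class TestObjective:
    def test_zero_at_truth_on_noiseless_data(self, mini_protocol, one_cell):
        truth, rec, art, mach = one_cell
        row = truth.iloc[0]
        from vclamp.inference import _make_predictor

        predict = _make_predictor("conductance_artefacts", mini_protocol,
                                  rec, mach, art,
                                  theta=truth.attrs["theta"],
                                  E_K=truth.attrs["E_K"])
        x_true = (row["g_Kr"], row["V_off_dagger"], row["g_leak_dagger"])
        assert objective_sse(rec, predict, x_true) == pytest.approx(0.0, abs=1e-12)
        # any perturbation must cost something (local identifiability)
        for bump in ([1.05, 1.0, 1.0], [1.0, 1.2, 1.0], [1.0, 1.0, 3.0]):
            x = np.array(x_true) * bump
            assert objective_sse(rec, predict, x) > 1e-4

    def test_zero_model_costs_sum_of_squares(self, one_cell):
        _, rec, _, _ = one_cell
        obj = objective_sse(rec, lambda x: np.zeros_like(rec.i_post), None)
        assert obj == pytest.approx(np.sum(rec.i_post ** 2))

    def test_simulation_failure_maps_to_inf(self, one_cell):
        _, rec, _, _ = one_cell

        def broken(x):
            raise vclamp.clamp.SimulationError("boom")

        assert objective_sse(rec, broken, None) == float("inf")


class TestCMAES:
    def test_minimises_shifted_sphere(self):
        rng = np.random.default_rng(1)
        target = np.array([0.3, 0.7, 0.55])
        x, f, _ = _cma_minimise(lambda u: float(np.sum((u - target) ** 2)),
                                np.full(3, 0.5), 0.3, 8, 200, rng)
        assert f < 1e-10
        assert np.allclose(x, target, atol=1e-4)

    def test_deterministic_given_rng_seed(self):
        def f(u):
            return float(np.sum((u - 0.25) ** 2))

        a = _cma_minimise(f, np.full(2, 0.5), 0.3, 6, 50,
                          np.random.default_rng(9))
        b = _cma_minimise(f, np.full(2, 0.5), 0.3, 6, 50,
                          np.random.default_rng(9))
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_never_returns_out_of_bounds(self):
        rng = np.random.default_rng(2)
        # optimum outside the box: solution must sit on the boundary
        x, f, _ = _cma_minimise(lambda u: float(np.sum((u - 1.5) ** 2)),
                                np.full(2, 0.5), 0.3, 6, 100, rng)
        assert np.all(x <= 1.0) and np.all(x >= 0.0)
        assert np.allclose(x, 1.0, atol=1e-6)


class TestFitCell:
    def test_inner_mode_recovers_truth(self, mini_protocol, one_cell):
        truth, rec, art, mach = one_cell
        row = truth.iloc[0]
        fr = fit_cell(rec, "conductance+artefacts_given_theta", mini_protocol,
                      machine=mach, artefact=art,
                      theta=truth.attrs["theta"], E_K=truth.attrs["E_K"],
                      seed=5, optimizer_opts={"maxiter": 60, "restarts": 1})
        assert fr.parameters["g_Kr"] == pytest.approx(row["g_Kr"], rel=1e-3)
        assert fr.parameters["V_off_dagger"] == pytest.approx(
            row["V_off_dagger"], abs=0.05)
        assert fr.objective < 1e-6
        assert fr.converged

    def test_seeded_determinism(self, mini_protocol, one_cell):
        truth, rec, art, mach = one_cell
        kw = dict(machine=mach, artefact=art, theta=truth.attrs["theta"],
                  E_K=truth.attrs["E_K"], seed=5,
                  optimizer_opts={"maxiter": 20, "restarts": 1,
                                  "polish": False})
        a = fit_cell(rec, "conductance_artefacts", mini_protocol, **kw)
        b = fit_cell(rec, "conductance_artefacts", mini_protocol, **kw)
        assert a.parameters == b.parameters
        assert a.objective == b.objective

    def test_bound_hit_flagged_when_bound_excludes_truth(self, mini_protocol):
        """A lower bound on R_s above the true value must be flagged.

        Regression guard for the known failure signature where series
        resistance estimates pile up at an imposed bound.
        """
        from vclamp.cells import ModelCellTypeII
        from vclamp.inference import ParameterTransform

        cell = ModelCellTypeII()
        art = ArtefactTrue(V_off=0.0, C_p=4.7, C_m=22.0, R_s=0.03)
        rec = vclamp.simulate(mini_protocol, "full", cell, artefact=art,
                              machine=MachineSettings())
        # R_s is boxed to [0.05, 0.5] GOhm: truth (0.03) is excluded; the
        # remaining components are boxed tightly around their true values so
        # they cannot absorb the misfit
        tight = lambda v: (0.999 * v, 1.001 * v)
        tr = ParameterTransform(
            ("R_m", "R_k", "C_k", "C_m", "R_s", "C_p", "V_off"),
            ("log", "log", "log", "log", "log", "log", "identity"),
            np.array([tight(0.5)[0], tight(0.1)[0], tight(1000.0)[0],
                      tight(22.0)[0], 0.05, tight(4.7)[0], -0.01]),
            np.array([tight(0.5)[1], tight(0.1)[1], tight(1000.0)[1],
                      tight(22.0)[1], 0.5, tight(4.7)[1], 0.01]))
        fr = fit_cell(rec, "model_cell", mini_protocol, transform=tr, seed=2,
                      optimizer_opts={"maxiter": 60, "restarts": 1})
        assert fr.bound_hit["R_s"]
        assert fr.parameters["R_s"] == pytest.approx(0.05, rel=1e-2)

    def test_unknown_mode_rejected(self, mini_protocol, one_cell):
        _, rec, _, _ = one_cell
        with pytest.raises(KeyError):
            fit_cell(rec, "nonsense", mini_protocol)


class TestFitShared:
    def test_single_cell_agrees_with_fit_cell(self, mini_protocol, one_cell):
        """N = 1 degenerates to an 11-parameter single-cell fit."""
        truth, rec, art, mach = one_cell
        row = truth.iloc[0]
        res = fit_shared([rec], mini_protocol, machines=[mach],
                         artefacts=[art], E_K=truth.attrs["E_K"], seed=8,
                         optimizer_opts={"maxiter": 25})
        # recovers the generating cell parameters (same optimum fit_cell
        # targets), up to optimizer tolerance
        pc = res.per_cell.iloc[0]
        assert pc["g_Kr"] == pytest.approx(row["g_Kr"], rel=0.02)
        assert res.total_objective < 1e-2
        trace = np.array(res.outer_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_empty_input_rejected(self, mini_protocol):
        with pytest.raises(ValueError):
            fit_shared([], mini_protocol)


class TestDofCount:
    @pytest.mark.parametrize("hyp, N, expected", [
        ("H1", 124, 1116),
        ("H2", 124, 380),
        ("H3", 124, 1364),
        ("H1", 5, 45),
        ("H2", 5, 23),
        ("H1", 1, 9),
        ("H2", 1, 11),
    ])
    def test_ledger(self, hyp, N, expected):
        assert dof_count(hyp, N) == expected

    def test_h1_minus_h2_difference(self):
        assert dof_count("H1", 124) - dof_count("H2", 124) == 736

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dof_count("H4", 5)
        with pytest.raises(ValueError):
            dof_count("H1", 0)
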