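"""Parameter estimation for clamp + cell models.

The objective is the sum of squared differences between the simulated and
recorded current (its negation is the log-likelihood up to a constant for
iid Gaussian noise).  Fits run a covariance-matrix-adaptation evolution
strategy (CMA-ES) in a transformed, box-bounded search space — strictly
positive parameters (conductances, base rates, resistances, capacitances,
residual leak) are log-transformed, voltage sensitivities and offsets are
searched on the identity scale with positivity/box bounds — optionally
followed by a bounded least-squares polish.

Two schemes are provided:

* :func:`fit_cell` — single-recording fits: kinetics-only (ideal-clamp
  hypothesis), kinetics + artefacts (simplified clamp), conductance +
  artefacts at fixed kinetics (the inner problem of the shared fit), and
  full-model electrical-model-cell component fits.
* :func:`fit_shared` — N recordings share one kinetic parameter vector θ
  while every cell keeps its own conductance and artefact residuals.  A
  nested ("Gibbs-style") scheme alternates one outer CMA-ES generation on
  θ — where each θ candidate is scored by optimising every cell's
  {g, V_off†, g_leak†} to convergence — with warm-started inner
  refinement; a θ update is kept only if the total objective improves, so
  the outer trace is monotone non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cells import IKrParameters, ModelCellTypeII
from .clamp import (
    ArtefactResidual,
    ArtefactTrue,
    MachineSettings,
    Recording,
    SimulationError,
    simulate,
)
from .protocol import Protocol

__all__ = [
    "ParameterTransform",
    "FitResult",
    "SharedFitResult",
    "objective_sse",
    "fit_cell",
    "fit_shared",
    "dof_count",
    "CMAES",
]

# I_Kr transition rates are kept inside this window (ms^-1) over the
# physiological voltage range; parameter sets that leave it are rejected
# with an infinite objective (they imply unresolvably fast or frozen gates).
_RATE_MIN, _RATE_MAX = 1.67e-5, 1e3
_V_LO, _V_HI = -120.0, 60.0


# ---------------------------------------------------------------------------
# Parameter transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterTransform:
    """Per-parameter log/identity maps with bounds.

    ``kinds`` is a sequence of ``"log"`` or ``"identity"``; bounds are in
    natural (untransformed) units.  The transform is bijective on the
    feasible box and ``inverse(transform(x)) == x``.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.kinds) == n == len(self.lower) == len(self.upper)):
            raise ValueError("transform component lengths disagree")
        for k, lo, hi in zip(self.kinds, self.lower, self.upper):
            if k not in ("log", "identity"):
                raise ValueError(f"unknown transform kind {k!r}")
            if k == "log" and lo <= 0:
                raise ValueError("log-transformed parameters need positive bounds")
            if not lo < hi:
                raise ValueError("need lower < upper")

    @property
    def n(self) -> int:
        return len(self.names)

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = x.copy()
        for i, k in enumerate(self.kinds):
            if k == "log":
                y[i] = math.log(x[i])
        return y

    def inverse(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        x = y.copy()
        for i, k in enumerate(self.kinds):
            if k == "log":
                x[i] = math.exp(y[i])
        return x

    @property
    def t_lower(self) -> np.ndarray:
        return self.transform(self.lower)

    @property
    def t_upper(self) -> np.ndarray:
        return self.transform(self.upper)

    def to_unit(self, x) -> np.ndarray:
        """Natural parameters -> the optimizer's [0, 1]^n box."""
        return (self.transform(x) - self.t_lower) / (self.t_upper - self.t_lower)

    def from_unit(self, u) -> np.ndarray:
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        return self.inverse(self.t_lower + u * (self.t_upper - self.t_lower))


def _kinetic_bounds() -> tuple[list, list, list]:
    kinds, lo, hi = [], [], []
    for i in range(8):
        if i % 2 == 0:  # p1, p3, p5, p7: base rates, ms^-1
            kinds.append("log")
            lo.append(1e-7)
            hi.append(1.0)
        else:  # p2, p4, p6, p8: voltage sensitivities, mV^-1
            kinds.append("identity")
            lo.append(1e-7)
            hi.append(0.2)
    return kinds, lo, hi


def default_transform(mode: str) -> ParameterTransform:
    """Search-space definition for each fit mode."""
    kk, klo, khi = _kinetic_bounds()
    pnames = tuple(f"p{i + 1}" for i in range(8))
    if mode == "kinetics_only":
        return ParameterTransform(
            ("g_Kr",) + pnames, ("log",) + tuple(kk),
            np.array([0.1] + klo), np.array([3000.0] + khi))
    if mode == "kinetics_artefacts":
        return ParameterTransform(
            ("g_Kr",) + pnames + ("V_off_dagger", "g_leak_dagger"),
            ("log",) + tuple(kk) + ("identity", "log"),
            np.array([0.1] + klo + [-30.0, 1e-6]),
            np.array([3000.0] + khi + [30.0, 10.0]))
    if mode == "conductance_artefacts":
        return ParameterTransform(
            ("g_Kr", "V_off_dagger", "g_leak_dagger"),
            ("log", "identity", "log"),
            np.array([0.1, -30.0, 1e-6]),
            np.array([3000.0, 30.0, 10.0]))
    if mode == "model_cell":
        return ParameterTransform(
            ("R_m", "R_k", "C_k", "C_m", "R_s", "C_p", "V_off"),
            ("log", "log", "log", "log", "log", "log", "identity"),
            np.array([0.01, 0.001, 10.0, 1.0, 0.001, 0.1, -30.0]),
            np.array([10.0, 10.0, 1e4, 200.0, 1.0, 50.0, 30.0]))
    raise ValueError(f"unknown fit mode {mode!r}")


_MODE_ALIASES = {
    "kinetics_only": "kinetics_only",
    "kinetics+artefacts": "kinetics_artefacts",
    "kinetics_artefacts": "kinetics_artefacts",
    "conductance+artefacts_given_theta": "conductance_artefacts",
    "conductance_artefacts": "conductance_artefacts",
    "model_cell": "model_cell",
}


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def objective_sse(rec: Recording, predict, params,
                  target: str = "auto") -> float:
    """Sum of squared model-data current differences.

    ``predict(params) -> model current trace`` on the recording's grid; a
    simulation failure yields ``+inf`` so optimisers can continue.  The
    negated value is the Gaussian log-likelihood up to a constant.
    """
    data = _target_trace(rec, target)
    model = _safe_predict(predict, params)
    if model is None:
        return float("inf")
    return float(np.sum((model - data) ** 2))


def _target_trace(rec: Recording, target: str) -> np.ndarray:
    if target == "auto":
        tr = rec.i_post if rec.i_post is not None else rec.i_out
    elif target == "i_post":
        tr = rec.i_post
    else:
        tr = rec.i_out
    if tr is None:
        raise ValueError(f"recording lacks the target trace {target!r}")
    return tr


def _safe_predict(predict, params):
    try:
        model = predict(params)
    except (SimulationError, FloatingPointError, OverflowError, ValueError):
        return None
    if model is None or not np.all(np.isfinite(model)):
        return None
    return model


def _rates_admissible(theta) -> bool:
    """Each rate, at the voltage where it is largest, stays in the window."""
    p = np.asarray(theta)
    for base, sens, sign in ((p[0], p[1], +1), (p[2], p[3], -1),
                             (p[4], p[5], +1), (p[6], p[7], -1)):
        V = _V_HI if sign > 0 else _V_LO
        k_max = base * math.exp(sign * sens * V)
        if not (_RATE_MIN <= k_max <= _RATE_MAX):
            return False
    return True


def _make_predictor(mode: str, protocol: Protocol, rec: Recording,
                    machine: MachineSettings | None,
                    artefact: ArtefactTrue | None,
                    theta=None, E_K: float = -85.2,
                    solver_opts: dict | None = None):
    """Map a natural parameter vector to a model current trace."""
    solver_opts = solver_opts or {}

    if mode == "kinetics_only":
        def predict(x):
            g, th = x[0], x[1:9]
            if not _rates_admissible(th):
                return None
            cell = IKrParameters(g, *th, E_K=E_K)
            r = simulate(protocol, "ideal", cell, solver_opts=solver_opts)
            return r.i_out
        return predict

    if mode == "kinetics_artefacts":
        def predict(x):
            g, th = x[0], x[1:9]
            voff, gleak = x[9], x[10]
            if not _rates_admissible(th):
                return None
            cell = IKrParameters(g, *th, E_K=E_K)
            res = ArtefactResidual(V_off_dagger=voff, g_leak_dagger=gleak,
                                   E_leak_dagger=protocol.holding)
            r = simulate(protocol, "simplified", cell, artefact=artefact,
                         machine=machine, residual=res,
                         solver_opts=solver_opts)
            return r.i_post
        return predict

    if mode == "conductance_artefacts":
        th = np.asarray(theta, dtype=float)
        if not _rates_admissible(th):
            raise ValueError("fixed theta violates the rate bounds")

        def predict(x):
            g, voff, gleak = x
            cell = IKrParameters(g, *th, E_K=E_K)
            res = ArtefactResidual(V_off_dagger=voff, g_leak_dagger=gleak,
                                   E_leak_dagger=protocol.holding)
            r = simulate(protocol, "simplified", cell, artefact=artefact,
                         machine=machine, residual=res,
                         solver_opts=solver_opts)
            return r.i_post
        return predict

    if mode == "model_cell":
        mach = machine or MachineSettings()

        def predict(x):
            R_m, R_k, C_k, C_m, R_s, C_p, V_off = x
            cell = ModelCellTypeII(R_m=R_m, R_k=R_k, C_k=C_k)
            art = ArtefactTrue(V_off=V_off, C_p=C_p, C_m=C_m, R_s=R_s)
            r = simulate(protocol, "full", cell, artefact=art, machine=mach,
                         solver_opts=solver_opts)
            return r.i_out
        return predict

    raise ValueError(f"unknown fit mode {mode!r}")


# ---------------------------------------------------------------------------
# CMA-ES (minimal, with box repair + penalty)
# ---------------------------------------------------------------------------


class CMAES:
    """Covariance-matrix-adaptation evolution strategy on [0, 1]^n.

    Standard (mu/mu_w, lambda) formulation with cumulative step-size
    adaptation and rank-one/rank-mu covariance updates.  Out-of-box
    candidates are repaired by clipping; the evaluated objective receives a
    quadratic penalty on the repair distance, so the optimizer never
    *returns* an out-of-bounds point.
    """

    def __init__(self, x0, sigma0: float, popsize: int,
                 rng: np.random.Generator):
        self.n = len(x0)
        self.m = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        self.lam = int(popsize)
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.w = w / w.sum()
        self.mueff = 1.0 / np.sum(self.w ** 2)
        n, mueff = self.n, self.mueff
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.ds = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (n + 1)) - 1) + self.cs
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(1 - self.c1,
                       2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
        self.chiN = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))
        self.ps = np.zeros(n)
        self.pc = np.zeros(n)
        self.C = np.eye(n)
        self.rng = rng
        self.t = 0
        self._decompose()

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2
        d, B = np.linalg.eigh(self.C)
        d = np.maximum(d, 1e-20)
        self.B = B
        self.D = np.sqrt(d)

    def ask(self) -> np.ndarray:
        z = self.rng.standard_normal((self.lam, self.n))
        y = (self.B * self.D) @ z.T
        self._y = y.T
        return self.m + self.sigma * self._y

    def tell(self, xs: np.ndarray, fs: np.ndarray) -> None:
        order = np.argsort(fs)
        ysel = self._y[order[: self.mu]]
        yw = self.w @ ysel
        self.m = self.m + self.sigma * yw
        Cinvsqrt_yw = self.B @ ((self.B.T @ yw) / self.D)
        self.ps = (1 - self.cs) * self.ps + math.sqrt(
            self.cs * (2 - self.cs) * self.mueff) * Cinvsqrt_yw
        self.t += 1
        hsig = (np.linalg.norm(self.ps)
                / math.sqrt(1 - (1 - self.cs) ** (2 * self.t)) / self.chiN
                < 1.4 + 2 / (self.n + 1))
        self.pc = (1 - self.cc) * self.pc + hsig * math.sqrt(
            self.cc * (2 - self.cc) * self.mueff) * yw
        rank1 = np.outer(self.pc, self.pc)
        if not hsig:
            rank1 = rank1 + self.cc * (2 - self.cc) * self.C
        rankmu = (ysel.T * self.w) @ ysel
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * rank1 + self.cmu * rankmu)
        self.sigma *= math.exp(
            (self.cs / self.ds) * (np.linalg.norm(self.ps) / self.chiN - 1))
        self.sigma = min(self.sigma, 1.0)
        self._decompose()


def _cma_minimise(f, x0, sigma0, popsize, maxiter, rng, ftol=1e-12,
                  trace=None):
    """Minimise f on [0,1]^n; returns (best_x, best_f, n_iter)."""
    es = CMAES(x0, sigma0, popsize, rng)
    best_x = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    best_f = f(best_x)
    stall = 0
    for it in range(maxiter):
        xs = es.ask()
        fs = np.empty(len(xs))
        for i, x in enumerate(xs):
            xr = np.clip(x, 0.0, 1.0)
            pen = np.sum((x - xr) ** 2)
            fi = f(xr)
            fs[i] = fi + 1e4 * (1.0 + abs(fi)) * pen if np.isfinite(fi) \
                else 1e30 + 1e4 * pen
        es.tell(xs, fs)
        i_best = int(np.argmin(fs))
        if fs[i_best] < best_f:
            gain = best_f - fs[i_best]
            best_f = float(fs[i_best])
            best_x = np.clip(xs[i_best], 0.0, 1.0)
            stall = 0 if gain > ftol * max(1.0, abs(best_f)) else stall + 1
        else:
            stall += 1
        if trace is not None:
            trace.append(best_f)
        if stall >= 40 or es.sigma < 1e-12:
            return best_x, best_f, it + 1
    return best_x, best_f, maxiter


def _polish(f_resid, x0, max_nfev=None):
    """Bounded least-squares refinement on [0,1]^n (trf, 2-point Jacobian)."""
    try:
        sol = least_squares(f_resid, np.clip(x0, 1e-12, 1 - 1e-12),
                            bounds=(0.0, 1.0), method="trf",
                            diff_step=1e-6, max_nfev=max_nfev)
        return sol.x, float(np.sum(sol.fun ** 2))
    except Exception:
        return x0, float("inf")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Optimised parameters with diagnostics.

    ``bound_hit`` flags parameters whose optimum lies at (within tolerance
    of) a search bound — a warning sign that the bound, not the data, set
    the value, as happens when series resistance is pushed to its lower
    bound by model discrepancy.
    """

    parameters: dict[str, float]
    objective: float
    iterations: int
    converged: bool
    seed: int | None
    bound_hit: dict[str, bool]
    trace: list = field(default_factory=list)
    mode: str = ""

    @property
    def x(self) -> np.ndarray:
        return np.array(list(self.parameters.values()))


@dataclass
class SharedFitResult:
    """Result of the shared-kinetics (identical kinetics) fit."""

    theta: np.ndarray
    per_cell: pd.DataFrame  # columns: cell, g_Kr, V_off_dagger, g_leak_dagger, objective
    total_objective: float
    outer_trace: list
    seed: int | None

    def cell_parameters(self, i: int) -> dict[str, float]:
        row = self.per_cell.loc[self.per_cell["cell"] == i].iloc[0]
        return {k: float(row[k]) for k in
                ("g_Kr", "V_off_dagger", "g_leak_dagger")}


_DEFAULT_OPT = {
    "popsize": None,      # default 4 + floor(3 ln n)
    "maxiter": 300,
    "restarts": 2,
    "sigma0": 0.3,
    "polish": True,
    "ftol": 1e-12,
}


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2 ** 31))


def fit_cell(rec: Recording, mode: str, protocol: Protocol,
             machine: MachineSettings | None = None,
             artefact: ArtefactTrue | None = None,
             theta=None, E_K: float = -85.2,
             transform: ParameterTransform | None = None,
             optimizer_opts: dict | None = None,
             solver_opts: dict | None = None,
             target: str = "auto",
             seed: int | None = None) -> FitResult:
    """Fit one recording with a CMA-ES global search plus polish.

    ``mode`` selects the free-parameter vector (see module docstring);
    results are deterministic given ``seed``.  Restarts launch from
    perturbed unit-box midpoints; the best restart is returned.
    """
    mode = _MODE_ALIASES[mode]
    tr = transform or default_transform(mode)
    opts = dict(_DEFAULT_OPT)
    if optimizer_opts:
        opts.update(optimizer_opts)
    popsize = opts["popsize"] or (4 + int(3 * math.log(tr.n)))
    predict = _make_predictor(mode, protocol, rec, machine, artefact,
                              theta=theta, E_K=E_K, solver_opts=solver_opts)
    data = _target_trace(rec, target)

    def f_unit(u):
        model = _safe_predict(predict, tr.from_unit(u))
        if model is None:
            return float("inf")
        return float(np.sum((model - data) ** 2))

    def resid_unit(u):
        model = _safe_predict(predict, tr.from_unit(u))
        if model is None:
            return np.full(len(data), 1e6)
        return model - data

    master = np.random.SeedSequence(seed if seed is not None else 0)
    best = (None, float("inf"), 0)
    trace: list = []
    n_restarts = max(1, int(opts["restarts"]))
    for r, child in enumerate(master.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        x0 = np.full(tr.n, 0.5)
        if r > 0:
            x0 = np.clip(0.5 + 0.25 * rng.standard_normal(tr.n), 0.05, 0.95)
        rtrace: list = []
        x, fval, iters = _cma_minimise(f_unit, x0, opts["sigma0"], popsize,
                                       opts["maxiter"], rng,
                                       ftol=opts["ftol"], trace=rtrace)
        if opts["polish"] and np.isfinite(fval):
            xp, fp = _polish(resid_unit, x)
            if fp < fval:
                x, fval = xp, fp
        if fval < best[1]:
            best = (x, fval, iters)
            trace = rtrace
    x, fval, iters = best
    if x is None:
        raise RuntimeError("all optimisation restarts failed")
    params = tr.from_unit(x)
    tol = 1e-3
    bound_hit = {name: bool(xi <= tol or xi >= 1 - tol)
                 for name, xi in zip(tr.names, x)}
    return FitResult(
        parameters={name: float(v) for name, v in zip(tr.names, params)},
        objective=float(fval), iterations=iters,
        converged=bool(np.isfinite(fval)), seed=seed,
        bound_hit=bound_hit, trace=trace, mode=mode)


# ---------------------------------------------------------------------------
# Shared-kinetics (nested) fit
# ---------------------------------------------------------------------------


def _inner_fit(rec, protocol, machine, artefact, theta, E_K, tr_inner,
               warm_u, solver_opts, rng, budget: str):
    """Optimise {g, V_off†, g_leak†} for one cell at fixed theta."""
    predict = _make_predictor("conductance_artefacts", protocol, rec,
                              machine, artefact, theta=theta, E_K=E_K,
                              solver_opts=solver_opts)
    data = _target_trace(rec, "auto")

    def resid(u):
        model = _safe_predict(predict, tr_inner.from_unit(u))
        if model is None:
            return np.full(len(data), 1e6)
        return model - data

    def f(u):
        r = resid(u)
        return float(np.sum(r ** 2))

    starts = []
    if warm_u is not None:
        starts.append(np.asarray(warm_u))
    if budget == "full" or warm_u is None:
        x0, f0, _ = _cma_minimise(
            f, np.full(tr_inner.n, 0.5), 0.3,
            4 + int(3 * math.log(tr_inner.n)), 40, rng)
        starts.append(x0)
    best_u, best_f = None, float("inf")
    max_nfev = None if budget == "full" else 15
    for s in starts:
        xu, fu = _polish(resid, s, max_nfev=max_nfev)
        if fu < best_f:
            best_u, best_f = xu, fu
    return best_u, best_f


def fit_shared(recs: list[Recording], protocol: Protocol,
               machines: list[MachineSettings] | None = None,
               artefacts: list[ArtefactTrue] | None = None,
               theta_init=None, E_K: float = -85.2,
               transform: ParameterTransform | None = None,
               optimizer_opts: dict | None = None,
               solver_opts: dict | None = None,
               seed: int | None = None) -> SharedFitResult:
    """Shared-kinetics fit: one θ for all cells, per-cell {g, V_off†, g_leak†}.

    Outer loop: one CMA-ES generation over θ per iteration, each candidate
    scored by warm-started inner per-cell optimisations; the running best
    (θ, per-cell parameters) is only ever replaced by a better total
    objective, so the outer objective trace is non-increasing.  Cells whose
    inner problem fails are excluded with a warning and reported.
    """
    if len(recs) == 0:
        raise ValueError("need at least one recording")
    opts = dict(_DEFAULT_OPT)
    opts.update({"maxiter": 15, "stall": 8, "rel_tol": 1e-6,
                 "popsize": 6, "joint_polish": True})
    if optimizer_opts:
        opts.update(optimizer_opts)
    machines = machines or [MachineSettings()] * len(recs)
    artefacts = artefacts or [ArtefactTrue()] * len(recs)
    kk, klo, khi = _kinetic_bounds()
    tr_theta = transform or ParameterTransform(
        tuple(f"p{i + 1}" for i in range(8)), tuple(kk),
        np.array(klo), np.array(khi))
    tr_inner = default_transform("conductance_artefacts")

    master = np.random.SeedSequence(seed if seed is not None else 0)
    ss_outer, ss_inner = master.spawn(2)
    rng_outer = np.random.default_rng(ss_outer)
    rng_inner = np.random.default_rng(ss_inner)

    warm: list = [None] * len(recs)
    failed: set[int] = set()

    def eval_theta(u_theta, budget="warm", update_warm=False):
        theta = tr_theta.from_unit(u_theta)
        if not _rates_admissible(theta):
            return float("inf"), None
        total = 0.0
        inner_us = []
        for i, rec in enumerate(recs):
            if i in failed:
                inner_us.append(None)
                continue
            try:
                u, fval = _inner_fit(rec, protocol, machines[i], artefacts[i],
                                     theta, E_K, tr_inner, warm[i],
                                     solver_opts, rng_inner, budget)
            except Exception:
                import warnings

                warnings.warn(f"cell {i} failed during the inner fit; excluded")
                failed.add(i)
                inner_us.append(None)
                continue
            total += fval
            inner_us.append(u)
        if update_warm:
            for i, u in enumerate(inner_us):
                if u is not None:
                    warm[i] = u
        return total, inner_us

    if theta_init is not None:
        u_best = tr_theta.to_unit(np.asarray(theta_init, dtype=float))
    else:
        u_best = np.full(tr_theta.n, 0.5)
    f_best, inner_best = eval_theta(u_best, budget="full", update_warm=True)

    popsize = opts["popsize"] or (4 + int(3 * math.log(tr_theta.n)))
    es = CMAES(u_best, opts["sigma0"], popsize, rng_outer)
    outer_trace = [f_best]
    stall = 0
    for it in range(opts["maxiter"]):
        xs = es.ask()
        fs = np.empty(len(xs))
        cand = []
        for i, x in enumerate(xs):
            xr = np.clip(x, 0.0, 1.0)
            pen = float(np.sum((x - xr) ** 2))
            fi, inner_us = eval_theta(xr)
            cand.append((xr, fi, inner_us))
            fs[i] = fi + 1e4 * (1.0 + abs(fi)) * pen if np.isfinite(fi) \
                else 1e30 + 1e4 * pen
        es.tell(xs, fs)
        i_best = int(np.argmin(fs))
        xr, fi, inner_us = cand[i_best]
        if np.isfinite(fi) and fi < f_best:  # accept only if better
            rel_gain = (f_best - fi) / max(abs(f_best), 1e-300)
            u_best, f_best, inner_best = xr, fi, inner_us
            for i, u in enumerate(inner_us):
                if u is not None:
                    warm[i] = u
            stall = 0 if rel_gain > opts["rel_tol"] else stall + 1
        else:
            stall += 1
        outer_trace.append(f_best)
        if stall >= opts["stall"]:
            break

    if inner_best is None:
        raise RuntimeError(
            "shared fit found no admissible kinetics: widen the bounds or "
            "increase the outer iteration budget")
    # joint refinement of theta and all per-cell parameters at once
    # (accept-if-better, so the trace stays monotone)
    active = [i for i in range(len(recs)) if i not in failed
              and inner_best[i] is not None]
    if opts["joint_polish"] and active:
        datas = {i: _target_trace(recs[i], "auto") for i in active}

        def resid_joint(ufull):
            theta_c = tr_theta.from_unit(ufull[: tr_theta.n])
            if not _rates_admissible(theta_c):
                return np.full(sum(len(datas[i]) for i in active), 1e6)
            parts = []
            for j, i in enumerate(active):
                u_i = ufull[tr_theta.n + 3 * j: tr_theta.n + 3 * (j + 1)]
                g, voff, gleak = tr_inner.from_unit(u_i)
                predict = _make_predictor(
                    "conductance_artefacts", protocol, recs[i], machines[i],
                    artefacts[i], theta=theta_c, E_K=E_K,
                    solver_opts=solver_opts)
                model = _safe_predict(predict, (g, voff, gleak))
                parts.append(np.full(len(datas[i]), 1e6) if model is None
                             else model - datas[i])
            return np.concatenate(parts)

        x0_joint = np.concatenate(
            [u_best] + [np.asarray(inner_best[i]) for i in active])
        xj, fj = _polish(resid_joint, x0_joint)
        if np.isfinite(fj) and fj < f_best:
            f_best = fj
            u_best = xj[: tr_theta.n]
            for j, i in enumerate(active):
                inner_best[i] = xj[tr_theta.n + 3 * j: tr_theta.n + 3 * (j + 1)]
    else:
        f_final, inner_final = eval_theta(u_best, budget="full",
                                          update_warm=True)
        if np.isfinite(f_final) and f_final < f_best:
            f_best, inner_best = f_final, inner_final
    outer_trace.append(f_best)

    theta = tr_theta.from_unit(u_best)
    rows = []
    for i, rec in enumerate(recs):
        if i in failed or inner_best[i] is None:
            continue
        g, voff, gleak = tr_inner.from_unit(inner_best[i])
        predict = _make_predictor("conductance_artefacts", protocol, rec,
                                  machines[i], artefacts[i], theta=theta,
                                  E_K=E_K, solver_opts=solver_opts)
        obj = objective_sse(rec, predict, (g, voff, gleak))
        rows.append(dict(cell=i, g_Kr=g, V_off_dagger=voff,
                         g_leak_dagger=gleak, objective=obj))
    per_cell = pd.DataFrame(rows)
    total = float(per_cell["objective"].sum())
    return SharedFitResult(theta=theta, per_cell=per_cell,
                           total_objective=total, outer_trace=outer_trace,
                           seed=seed)


# ---------------------------------------------------------------------------
# Degrees-of-freedom ledger
# ---------------------------------------------------------------------------


def dof_count(hypothesis: str, N: int, n_kinetic: int = 8,
              n_conductance: int = 1, n_artefact: int = 2) -> int:
    """Total number of fitted parameters under each variability hypothesis.

    H1 (cell-specific kinetics, no artefacts): N * (n_kinetic + n_conductance).
    H2 (identical kinetics, cell-specific artefacts):
        n_kinetic + N * (n_conductance + n_artefact).
    H3 (everything cell-specific):
        N * (n_kinetic + n_conductance + n_artefact).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    h = hypothesis.upper()
    if h == "H1":
        return N * (n_kinetic + n_conductance)
    if h == "H2":
        return n_kinetic + N * (n_conductance + n_artefact)
    if h == "H3":
        return N * (n_kinetic + n_conductance + n_artefact)
    raise ValueError(f"unknown hypothesis {hypothesis!r}")
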