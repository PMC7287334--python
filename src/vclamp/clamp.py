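"""Voltage-clamp experiment models: ideal, full and simplified.

Three levels of realism are provided, all wrapping an arbitrary cell model
(I_Kr or an electrical model cell):

ideal
    The textbook assumption: V_m == V_cmd and I_out == I_ion.  Only the
    cell states are integrated.

full
    The whole experiment: membrane charging through the series resistance
    R_s, pipette/parasitic capacitance C_p, voltage offset V_off, seal leak
    g_leak, plus the amplifier's compensation circuitry — offset correction
    V_off*, C-fast (C_p*) and C-slow (C_m*) capacitance-current injection,
    fractional series-resistance compensation alpha with supercharging, a
    summing-amplifier lag tau_sum, the clamp time constant tau_clamp and
    the transconductor (measurement) time constant tau_z = R_f * C_f.
    State vector: [V_m, V_p, V_clamp, I_out, V_est] + cell states, where
    V_est is the C-slow circuit's internal estimate of the membrane
    voltage.  Equations (outward membrane current positive; V_off enters
    as a pipette-side offset added to the applied potential)::

        I_Rs      = (V_p + V_off - V_m) / R_s
        C_m dV_m  = I_Rs - I_cell(V_m, ...) - g_leak (V_m - E_leak)
        dV_p      = (V_clamp - V_p) / tau_clamp
        I_cs      = (V_clamp - V_est) / R_s*          (C-slow injection)
        dV_est    = I_cs / C_m*
        dV_clamp  = (V_cmd - V_off* + alpha R_s* (I_out + I_cs)
                     - V_clamp) / tau_sum
        I_in      = (C_p - C_p*) dV_p + I_Rs - I_cs
        dI_out    = (I_in - I_out) / tau_z

    The R_s compensation is driven by the total estimated access current
    (measured current plus the C-slow injection), i.e. supercharging is
    included; this is what makes the model reduce exactly to the
    simplified model in the fast-amplifier limit.

simplified
    For slow currents the amplifier time constants (tau_clamp, tau_z,
    tau_sum) are taken as instantaneous, capacitance artefacts in the
    observed current as fully compensated (C_p* ~ C_p, C_m* ~ C_m) and the
    machine estimates R_s*, C_m* as accurate.  The state reduces to V_m
    plus the cell states::

        R_eff     = R_s - alpha R_s*
        I_Rs      = (V_cmd + V_off^† - V_m) / R_eff
        C_m dV_m  = I_Rs - I_cell - g_leak^† (V_m - E_leak^†)
        I_out     = I_cell + g_leak^† (V_m - E_leak^†)

    The model operates downstream of the primary leak subtraction, so its
    residual-leak observable I_post coincides with I_out.  At alpha = 1
    with R_s* = R_s the effective access resistance vanishes and
    V_m == V_cmd + V_off^† exactly (handled analytically).

The steady-state voltage error obeys V_cmd + V_off^† - V_m = R_eff * I_Rs:
the series-resistance artefact is proportional to the current size.

Numerical engines
-----------------
* ``expm`` — exact piecewise propagation of the linear time-invariant
  circuit (model cells in any mode) using the augmented matrix
  exponential per protocol segment.  Machine-precision, fast.
* ``split`` — fixed-substep exponential integrator for I_Kr under the
  ideal/simplified clamps: Rush–Larsen updates for the gates and an exact
  exponential step for the (conditionally linear) V_m equation.
  Unconditionally stable, so the sub-ms access time constant does not
  limit the step.  numba-compiled.
* ``scipy`` — reference stiff integration (``solve_ivp`` LSODA/BDF) of the
  exact right-hand sides, segment by segment with re-initialisation at
  step discontinuities.  Default rtol 1e-8, atol 1e-10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .cells import (
    IKrParameters,
    ModelCellTypeI,
    ModelCellTypeII,
)
from .protocol import Protocol, sample

__all__ = [
    "ArtefactTrue",
    "MachineSettings",
    "ArtefactResidual",
    "Recording",
    "SimulationError",
    "ideal_clamp",
    "full_clamp_rhs",
    "simplified_clamp_rhs",
    "simulate",
    "estimate_leak",
    "subtract_leak",
    "compensated_settings",
    "FULL_STATE_NAMES",
]

_PERFECT_EPS = 1e-9  # GOhm; below this the effective access resistance is
                     # treated as zero (perfect-compensation branch)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ArtefactTrue:
    """True (physical) artefact parameter values.

    V_off mV; C_p, C_m pF; R_s GOhm; seal leak conductance g_leak nS
    (g_leak ~ 1/R_seal) with reversal E_leak mV.
    """

    V_off: float = 0.0
    C_p: float = 4.7
    C_m: float = 22.0
    R_s: float = 0.03
    g_leak: float = 0.0
    E_leak: float = 0.0

    def __post_init__(self) -> None:
        if self.C_p < 0 or self.C_m <= 0 or self.R_s <= 0 or self.g_leak < 0:
            raise ValueError("require C_p >= 0, C_m > 0, R_s > 0, g_leak >= 0")

    @property
    def tau_access(self) -> float:
        """Membrane access time constant R_s * C_m in ms (50-2000 us typical).

        Distinct from the activation-gate time constant tau_act, despite
        the shared traditional symbol.
        """
        return self.R_s * self.C_m


@dataclass(frozen=True)
class MachineSettings:
    """Amplifier settings: compensation estimates and internal constants.

    alpha is the requested fraction of series-resistance compensation
    (typically 0.7-0.85); starred quantities are the machine's estimates of
    the corresponding artefact parameters.  R_f/C_f form the transconductor
    time constant tau_z = R_f * C_f (7.5 us with the default 25 MOhm /
    0.3 pF); tau_clamp is the clamp time constant (0.8 us) and tau_sum the
    summing-amplifier response (5-70 us; default 20 us).
    """

    V_off_star: float = 0.0
    C_p_star: float = 0.0
    C_m_star: float = 0.0
    R_s_star: float = 0.0
    alpha: float = 0.0
    R_f: float = 0.025
    C_f: float = 0.3
    tau_sum: float = 0.02
    tau_clamp: float = 8e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if min(self.tau_sum, self.tau_clamp, self.R_f, self.C_f) <= 0:
            raise ValueError("amplifier time constants must be positive")

    @property
    def tau_z(self) -> float:
        """Transconductor time constant R_f * C_f in ms."""
        return self.R_f * self.C_f


@dataclass(frozen=True)
class ArtefactResidual:
    """Residual (uncompensated) artefacts of the simplified model.

    V_off^† is the residual voltage offset (expected O(10) mV at most,
    typically within ±5 mV); g_leak^† the residual leak conductance after
    the primary leak subtraction, with effective reversal E_leak^† fixed at
    the holding potential (−80 mV) because the primary subtraction zeroed
    the current there.
    """

    V_off_dagger: float = 0.0
    g_leak_dagger: float = 0.0
    E_leak_dagger: float = -80.0

    def __post_init__(self) -> None:
        if self.g_leak_dagger < 0:
            raise ValueError("g_leak_dagger must be >= 0")


def compensated_settings(artefact: ArtefactTrue, alpha: float = 0.8,
                         **overrides) -> MachineSettings:
    """Machine settings with accurate estimates of the given artefacts."""
    kw = dict(
        V_off_star=artefact.V_off,
        C_p_star=artefact.C_p,
        C_m_star=artefact.C_m,
        R_s_star=artefact.R_s,
        alpha=alpha,
    )
    kw.update(overrides)
    return MachineSettings(**kw)


# ---------------------------------------------------------------------------
# Recording container + I/O
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Aligned traces of a (real or simulated) voltage-clamp measurement.

    All traces share the time grid ``t`` (ms).  ``i_out`` is the raw
    current readout (pA), ``i_post`` the leak-subtracted current, ``v_m``
    the membrane voltage (mV) where available.  ``meta`` carries units,
    amplifier settings, seeds and provenance.
    """

    t: np.ndarray
    v_cmd: np.ndarray
    i_out: np.ndarray | None = None
    i_post: np.ndarray | None = None
    v_m: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("v_cmd", "i_out", "i_post", "v_m"):
            tr = getattr(self, name)
            if tr is not None and len(tr) != n:
                raise ValueError(f"trace {name} length {len(tr)} != grid length {n}")
        self.meta.setdefault("units", "t:ms v:mV i:pA")

    def to_file(self, path) -> None:
        cols = [("t_ms", self.t), ("v_cmd_mV", self.v_cmd)]
        if self.i_out is not None:
            cols.append(("i_out_pA", self.i_out))
        if self.i_post is not None:
            cols.append(("i_post_pA", self.i_post))
        if self.v_m is not None:
            cols.append(("v_m_mV", self.v_m))
        header = ",".join(name for name, _ in cols)
        np.savetxt(path, np.column_stack([c for _, c in cols]),
                   delimiter=",", header=header, comments="")
        with open(f"{path}.meta", "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"{k} {v}\n")

    @classmethod
    def from_file(cls, path) -> "Recording":
        with open(path) as fh:
            names = fh.readline().strip().split(",")
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        col = {name: arr[:, i] for i, name in enumerate(names)}
        meta = {}
        try:
            with open(f"{path}.meta") as fh:
                for line in fh:
                    if line.strip():
                        k, _, v = line.partition(" ")
                        meta[k.strip()] = v.strip()
        except FileNotFoundError:
            pass
        return cls(
            t=col["t_ms"], v_cmd=col["v_cmd_mV"],
            i_out=col.get("i_out_pA"), i_post=col.get("i_post_pA"),
            v_m=col.get("v_m_mV"), meta=meta,
        )


# ---------------------------------------------------------------------------
# Right-hand sides (exact model definitions)
# ---------------------------------------------------------------------------

FULL_STATE_NAMES = ("V_m", "V_p", "V_clamp", "I_out", "V_est")


def _cell_current_and_rhs(cell, V_m: float, cell_state: np.ndarray,
                          ikr: IKrParameters | None = None):
    """(I_cell, d(cell_state)/dt) for any supported cell model."""
    if isinstance(cell, ModelCellTypeI):
        return V_m / cell.R_m, np.empty(0)
    if isinstance(cell, ModelCellTypeII):
        V_k = cell_state[0]
        I_k = (V_m - V_k) / cell.R_k
        return V_m / cell.R_m + I_k, np.array([I_k / cell.C_k])
    if isinstance(cell, IKrParameters):
        a, r = cell_state
        p = cell
        k1 = p.p1 * math.exp(p.p2 * V_m)
        k2 = p.p3 * math.exp(-p.p4 * V_m)
        k3 = p.p5 * math.exp(p.p6 * V_m)
        k4 = p.p7 * math.exp(-p.p8 * V_m)
        da = k1 * (1.0 - a) - k2 * a
        dr = k4 * (1.0 - r) - k3 * r
        I = p.g_Kr * a * r * (V_m - p.E_K)
        return I, np.array([da, dr])
    raise TypeError(f"unsupported cell model: {type(cell)!r}")


def _n_cell_states(cell) -> int:
    if isinstance(cell, ModelCellTypeI):
        return 0
    if isinstance(cell, ModelCellTypeII):
        return 1
    if isinstance(cell, IKrParameters):
        return 2
    raise TypeError(f"unsupported cell model: {type(cell)!r}")


def full_clamp_rhs(state: np.ndarray, t: float, protocol_or_vcmd, cell,
                   artefact: ArtefactTrue, machine: MachineSettings
                   ) -> tuple[np.ndarray, dict]:
    """Derivative of the full-experiment state and its observables.

    ``state`` is ``[V_m, V_p, V_clamp, I_out, V_est, *cell_states]``;
    ``protocol_or_vcmd`` may be a :class:`~vclamp.protocol.Protocol` or a
    callable/number giving V_cmd(t) in mV.  Returns ``(dstate, obs)`` with
    ``obs = {"I_out", "V_m", "V_p"}`` (``V_out = I_out * R_f`` is derived).
    """
    if not np.all(np.isfinite(state)):
        raise SimulationError(f"non-finite state at t={t}: {state}")
    v_cmd = _eval_vcmd(protocol_or_vcmd, t)
    a, m = artefact, machine
    V_m, V_p, V_clamp, I_out, V_est = state[:5]
    cell_state = state[5:]

    I_Rs = (V_p + a.V_off - V_m) / a.R_s
    I_cell, dcell = _cell_current_and_rhs(cell, V_m, cell_state)
    dV_m = (I_Rs - I_cell - a.g_leak * (V_m - a.E_leak)) / a.C_m
    dV_p = (V_clamp - V_p) / m.tau_clamp
    if m.C_m_star > 0 and m.R_s_star > 0:
        I_cs = (V_clamp - V_est) / m.R_s_star
        dV_est = I_cs / m.C_m_star
    else:
        # C-slow disabled: no injection; keep the idle estimator state
        # relaxing to V_clamp so the state dimension stays fixed
        I_cs, dV_est = 0.0, V_clamp - V_est
    target = v_cmd - m.V_off_star + m.alpha * m.R_s_star * (I_out + I_cs)
    dV_clamp = (target - V_clamp) / m.tau_sum
    I_in = (a.C_p - m.C_p_star) * dV_p + I_Rs - I_cs
    dI_out = (I_in - I_out) / m.tau_z

    dstate = np.concatenate([[dV_m, dV_p, dV_clamp, dI_out, dV_est], dcell])
    return dstate, {"I_out": I_out, "V_m": V_m, "V_p": V_p}


def simplified_clamp_rhs(state: np.ndarray, t: float, protocol_or_vcmd, cell,
                         residual: ArtefactResidual, machine: MachineSettings,
                         C_m: float, R_s: float) -> tuple[np.ndarray, dict]:
    """Derivative of the simplified-experiment state and its observables.

    ``state`` is ``[V_m, *cell_states]``.  The amplifier is algebraic; the
    effective access resistance is R_eff = R_s - alpha * R_s*.  Observables
    are ``I_out`` (residual-leak-inclusive model current), ``I_post``
    (coinciding with I_out: the model lives downstream of the primary leak
    subtraction) and ``V_m``.
    """
    if not np.all(np.isfinite(state)):
        raise SimulationError(f"non-finite state at t={t}: {state}")
    v_cmd = _eval_vcmd(protocol_or_vcmd, t)
    r = residual
    R_eff = R_s - machine.alpha * machine.R_s_star
    if R_eff < -_PERFECT_EPS:
        raise ValueError("alpha * R_s_star exceeds R_s: over-compensated (unstable)")
    V_m = state[0]
    cell_state = state[1:]
    if R_eff <= _PERFECT_EPS:
        # perfect compensation: V_m is slaved to the command algebraically
        V_m = v_cmd + r.V_off_dagger
        I_cell, dcell = _cell_current_and_rhs(cell, V_m, cell_state)
        dV_m = 0.0  # carried algebraically by the engines
    else:
        I_Rs = (v_cmd + r.V_off_dagger - V_m) / R_eff
        I_cell, dcell = _cell_current_and_rhs(cell, V_m, cell_state)
        I_leak = r.g_leak_dagger * (V_m - r.E_leak_dagger)
        dV_m = (I_Rs - I_cell - I_leak) / C_m
    I_obs = I_cell + r.g_leak_dagger * (V_m - r.E_leak_dagger)
    dstate = np.concatenate([[dV_m], dcell])
    return dstate, {"I_out": I_obs, "I_post": I_obs, "V_m": V_m}


def _eval_vcmd(protocol_or_vcmd, t: float) -> float:
    from .protocol import voltage_at

    if isinstance(protocol_or_vcmd, Protocol):
        return voltage_at(protocol_or_vcmd, t)
    if callable(protocol_or_vcmd):
        return float(protocol_or_vcmd(t))
    return float(protocol_or_vcmd)


# ---------------------------------------------------------------------------
# Exact LTI engine (linear model cells, any clamp mode)
# ---------------------------------------------------------------------------


def _lti_matrices(mode: str, cell, artefact, machine, residual):
    """(A, B) with dx/dt = A x + B [v_cmd, 1], plus output rows.

    Returns (A, B, out) where out maps observable name -> (row_x, row_u)
    such that obs = row_x @ x + row_u @ [v_cmd, 1].
    """
    type2 = isinstance(cell, ModelCellTypeII)
    if not (type2 or isinstance(cell, ModelCellTypeI)):
        raise TypeError("LTI engine supports model cells only")
    g_m = 1.0 / cell.R_m

    if mode == "full":
        a, m = artefact, machine
        n = 5 + (1 if type2 else 0)
        A = np.zeros((n, n))
        B = np.zeros((n, 2))
        iVm, iVp, iVc, iIo, iVe = range(5)
        # membrane
        A[iVm, iVm] = -(1.0 / a.R_s + g_m + a.g_leak) / a.C_m
        A[iVm, iVp] = 1.0 / (a.R_s * a.C_m)
        B[iVm, 1] = (a.V_off / a.R_s + a.g_leak * a.E_leak) / a.C_m
        if type2:
            iVk = 5
            A[iVm, iVm] += -1.0 / (cell.R_k * a.C_m)
            A[iVm, iVk] = 1.0 / (cell.R_k * a.C_m)
            A[iVk, iVm] = 1.0 / (cell.R_k * cell.C_k)
            A[iVk, iVk] = -1.0 / (cell.R_k * cell.C_k)
        # pipette
        A[iVp, iVp] = -1.0 / m.tau_clamp
        A[iVp, iVc] = 1.0 / m.tau_clamp
        # C-slow estimate
        cslow = m.C_m_star > 0 and m.R_s_star > 0
        if cslow:
            A[iVe, iVc] = 1.0 / (m.R_s_star * m.C_m_star)
            A[iVe, iVe] = -1.0 / (m.R_s_star * m.C_m_star)
        else:
            # idle estimator state relaxes to V_clamp (feeds no output)
            A[iVe, iVc] = 1.0
            A[iVe, iVe] = -1.0
        # summing amp: I_cs = (V_clamp - V_est)/R_s*
        A[iVc, iVc] = -1.0 / m.tau_sum
        A[iVc, iIo] = m.alpha * m.R_s_star / m.tau_sum
        if cslow:
            A[iVc, iVc] += m.alpha / m.tau_sum
            A[iVc, iVe] += -m.alpha / m.tau_sum
        B[iVc, 0] = 1.0 / m.tau_sum
        B[iVc, 1] = -m.V_off_star / m.tau_sum
        # measured current: I_in = (C_p - C_p*) dV_p + I_Rs - I_cs
        dCp = a.C_p - m.C_p_star
        A[iIo, iVp] += dCp * (-1.0 / m.tau_clamp) / m.tau_z
        A[iIo, iVc] += dCp * (1.0 / m.tau_clamp) / m.tau_z
        A[iIo, iVp] += (1.0 / a.R_s) / m.tau_z
        A[iIo, iVm] += (-1.0 / a.R_s) / m.tau_z
        B[iIo, 1] += (a.V_off / a.R_s) / m.tau_z
        if cslow:
            A[iIo, iVc] += (-1.0 / m.R_s_star) / m.tau_z
            A[iIo, iVe] += (1.0 / m.R_s_star) / m.tau_z
        A[iIo, iIo] += -1.0 / m.tau_z
        out = {
            "I_out": (np.eye(n)[iIo], np.zeros(2)),
            "V_m": (np.eye(n)[iVm], np.zeros(2)),
            "V_p": (np.eye(n)[iVp], np.zeros(2)),
        }
        return A, B, out

    if mode == "simplified":
        r = residual
        C_m, R_s = artefact.C_m, artefact.R_s
        R_eff = R_s - machine.alpha * machine.R_s_star
        if R_eff < -_PERFECT_EPS:
            raise ValueError("over-compensated: alpha * R_s_star exceeds R_s")
        g_dag = r.g_leak_dagger
        if R_eff <= _PERFECT_EPS:
            # V_m = v_cmd + V_off_dagger algebraically; states = cell only
            if type2:
                A = np.array([[-1.0 / (cell.R_k * cell.C_k)]])
                B = np.array([[1.0 / (cell.R_k * cell.C_k),
                               r.V_off_dagger / (cell.R_k * cell.C_k)]])
                # I_out = g_m V_m + (V_m - V_k)/R_k + g_dag (V_m - E_dag)
                row_x = np.array([-1.0 / cell.R_k])
                row_u = np.array([g_m + 1.0 / cell.R_k + g_dag,
                                  (g_m + 1.0 / cell.R_k + g_dag) * r.V_off_dagger
                                  - g_dag * r.E_leak_dagger])
                vm_x = np.zeros(1)
            else:
                A = np.zeros((0, 0))
                B = np.zeros((0, 2))
                row_x = np.zeros(0)
                row_u = np.array([g_m + g_dag,
                                  (g_m + g_dag) * r.V_off_dagger
                                  - g_dag * r.E_leak_dagger])
                vm_x = np.zeros(0)
            out = {
                "I_out": (row_x, row_u),
                "I_post": (row_x, row_u),
                "V_m": (vm_x, np.array([1.0, r.V_off_dagger])),
            }
            return A, B, out
        n = 1 + (1 if type2 else 0)
        A = np.zeros((n, n))
        B = np.zeros((n, 2))
        A[0, 0] = -(1.0 / R_eff + g_m + g_dag) / C_m
        B[0, 0] = 1.0 / (R_eff * C_m)
        B[0, 1] = (r.V_off_dagger / R_eff + g_dag * r.E_leak_dagger) / C_m
        if type2:
            A[0, 0] += -1.0 / (cell.R_k * C_m)
            A[0, 1] = 1.0 / (cell.R_k * C_m)
            A[1, 0] = 1.0 / (cell.R_k * cell.C_k)
            A[1, 1] = -1.0 / (cell.R_k * cell.C_k)
            row_x = np.array([g_m + 1.0 / cell.R_k + g_dag, -1.0 / cell.R_k])
        else:
            row_x = np.array([g_m + g_dag])
        row_u = np.array([0.0, -g_dag * r.E_leak_dagger])
        out = {
            "I_out": (row_x, row_u),
            "I_post": (row_x, row_u),
            "V_m": (np.eye(n)[0], np.zeros(2)),
        }
        return A, B, out

    if mode == "ideal":
        # V_m = v_cmd; only Type II has a state
        if type2:
            A = np.array([[-1.0 / (cell.R_k * cell.C_k)]])
            B = np.array([[1.0 / (cell.R_k * cell.C_k), 0.0]])
            row_x = np.array([-1.0 / cell.R_k])
            row_u = np.array([g_m + 1.0 / cell.R_k, 0.0])
            vm_x = np.zeros(1)
        else:
            A = np.zeros((0, 0))
            B = np.zeros((0, 2))
            row_x = np.zeros(0)
            row_u = np.array([g_m, 0.0])
            vm_x = np.zeros(0)
        out = {
            "I_out": (row_x, row_u),
            "V_m": (vm_x, np.array([1.0, 0.0])),
        }
        return A, B, out

    raise ValueError(f"unknown mode {mode!r}")


def _lti_steady_state(A, B, v_cmd: float) -> np.ndarray:
    if A.shape[0] == 0:
        return np.zeros(0)
    u = np.array([v_cmd, 1.0])
    return np.linalg.solve(A, -B @ u)


def _lti_simulate(protocol: Protocol, A, B, x0):
    """Exact sampled trajectory of dx/dt = A x + B [v_cmd(t), 1]."""
    t_out, v_out = sample(protocol)
    n = A.shape[0]
    xs = np.empty((len(t_out), n))
    if n == 0:
        return t_out, v_out, xs
    x = np.asarray(x0, dtype=float).copy()
    xs[0] = x
    edges = protocol.boundaries
    k = 1  # next output index
    for i, seg in enumerate(protocol.segments):
        t0, t1 = edges[i], edges[i + 1]
        slope = (seg.v_end - seg.v_start) / seg.duration
        # augmented system z = [x, v, 1]
        Aa = np.zeros((n + 2, n + 2))
        Aa[:n, :n] = A
        Aa[:n, n] = B[:, 0]
        Aa[:n, n + 1] = B[:, 1]
        Aa[n, n + 1] = slope
        cache: dict[float, np.ndarray] = {}

        def prop(z, h):
            key = round(h, 12)
            if key not in cache:
                cache[key] = expm(Aa * h)
            return cache[key] @ z

        z = np.concatenate([x, [seg.v_start, 1.0]])
        t_cur = t0
        # output times inside this segment
        k_end = k
        while k_end < len(t_out) and t_out[k_end] <= t1 + 1e-9:
            k_end += 1
        ts = t_out[k:k_end]
        if len(ts) > 0:
            # align to the first output time, then propagate the regular
            # grid in one shot via the eigendecomposition of the one-step map
            h0 = ts[0] - t_cur
            if h0 > 0:
                z = prop(z, h0)
            xs[k] = z[:n]
            if len(ts) > 1:
                dt_grid = ts[1] - ts[0]
                regular = np.allclose(np.diff(ts), dt_grid, rtol=0, atol=1e-9)
                M = None
                if regular and len(ts) > 3:
                    M = expm(Aa * dt_grid)
                    try:
                        w, V = np.linalg.eig(M)
                        Vinv = np.linalg.inv(V)
                        if np.linalg.cond(V) < 1e10:
                            ks = np.arange(1, len(ts))
                            coeff = Vinv @ z
                            zs = (V @ (coeff[:, None]
                                       * w[:, None] ** ks[None, :])).real
                            xs[k + 1:k_end] = zs[:n].T
                            z = zs[:, -1].copy()
                        else:
                            raise np.linalg.LinAlgError
                    except np.linalg.LinAlgError:
                        for j in range(k + 1, k_end):
                            z = M @ z
                            xs[j] = z[:n]
                else:
                    for j in range(k + 1, k_end):
                        z = prop(z, t_out[j] - t_out[j - 1])
                        xs[j] = z[:n]
            t_cur = ts[-1]
            k = k_end
        if t1 - t_cur > 1e-9:
            z = prop(z, t1 - t_cur)
        x = z[:n].real if np.iscomplexobj(z) else z[:n]
    return t_out, v_out, xs


# ---------------------------------------------------------------------------
# scipy reference engine (any cell, any mode)
# ---------------------------------------------------------------------------


def _scipy_simulate(protocol, mode, cell, artefact, machine, residual,
                    rtol, atol, method):
    from .protocol import voltage_at

    t_out, v_out = sample(protocol)
    n_cell = _n_cell_states(cell)
    x0 = _initial_state(protocol, mode, cell, artefact, machine, residual)

    def rhs_factory(seg):
        t0 = seg[0]
        v0, slope = seg[1], seg[2]

        def vc(t):
            return v0 + slope * (t - t0)

        if mode == "full":
            def rhs(t, x):
                d, _ = full_clamp_rhs(x, t, vc, cell, artefact, machine)
                return d
        elif mode == "simplified":
            def rhs(t, x):
                d, _ = simplified_clamp_rhs(x, t, vc, cell, residual, machine,
                                            artefact.C_m, artefact.R_s)
                return d
        else:  # ideal
            def rhs(t, x):
                _, dcell = _cell_current_and_rhs(cell, vc(t), x)
                return dcell
        return rhs

    edges = protocol.boundaries
    xs = np.empty((len(t_out), len(x0)))
    xs[0] = x0
    x = np.asarray(x0, dtype=float)
    k = 1
    for i, seg in enumerate(protocol.segments):
        t0, t1 = edges[i], edges[i + 1]
        slope = (seg.v_end - seg.v_start) / seg.duration
        rhs = rhs_factory((t0, seg.v_start, slope))
        t_eval = t_out[(t_out > t0 + 1e-9) & (t_out <= t1 + 1e-9)]
        if len(x) == 0:
            k += len(t_eval)
            continue
        # always land exactly on the segment edge for the next segment's init
        n_out = len(t_eval)
        if n_out == 0 or abs(t_eval[-1] - t1) > 1e-9:
            t_eval_full = np.append(t_eval, t1)
        else:
            t_eval_full = t_eval
        sol = solve_ivp(rhs, (t0, t1), x, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval_full, dense_output=False)
        if not sol.success:
            raise SimulationError(f"solver failed in segment {i}: {sol.message}")
        for j in range(n_out):
            xs[k] = sol.y[:, j]
            k += 1
        x = sol.y[:, -1]
    return t_out, v_out, xs


def _initial_state(protocol, mode, cell, artefact, machine, residual):
    """Steady state at the holding potential (pre-protocol conditions)."""
    v_hold = protocol.holding
    if isinstance(cell, (ModelCellTypeI, ModelCellTypeII)):
        A, B, _ = _lti_matrices(mode, cell, artefact, machine, residual)
        return _lti_steady_state(A, B, v_hold)
    # I_Kr: find the DC membrane voltage, then gate steady states
    p: IKrParameters = cell
    if mode == "ideal":
        V_m = v_hold
    elif mode == "simplified":
        r = residual
        R_eff = artefact.R_s - machine.alpha * machine.R_s_star
        V_m = v_hold + r.V_off_dagger
        if R_eff > _PERFECT_EPS:
            for _ in range(200):  # fixed-point iteration on the DC balance
                k1 = p.p1 * math.exp(p.p2 * V_m)
                k2 = p.p3 * math.exp(-p.p4 * V_m)
                k3 = p.p5 * math.exp(p.p6 * V_m)
                k4 = p.p7 * math.exp(-p.p8 * V_m)
                G = p.g_Kr * (k1 / (k1 + k2)) * (k4 / (k3 + k4))
                num = (v_hold + r.V_off_dagger) / R_eff + G * p.E_K \
                    + r.g_leak_dagger * r.E_leak_dagger
                den = 1.0 / R_eff + G + r.g_leak_dagger
                V_new = num / den
                if abs(V_new - V_m) < 1e-12:
                    V_m = V_new
                    break
                V_m = 0.5 * (V_m + V_new)
    else:  # full
        a, m = artefact, machine
        # DC: V_p = V_clamp = V_est; I_out = I_Rs; nonlinear in V_m via gates
        V_m = v_hold
        for _ in range(400):
            k1 = p.p1 * math.exp(p.p2 * V_m)
            k2 = p.p3 * math.exp(-p.p4 * V_m)
            k3 = p.p5 * math.exp(p.p6 * V_m)
            k4 = p.p7 * math.exp(-p.p8 * V_m)
            G = p.g_Kr * (k1 / (k1 + k2)) * (k4 / (k3 + k4))
            gtot = G + a.g_leak
            ecomb = (G * p.E_K + a.g_leak * a.E_leak) / gtot if gtot > 0 else 0.0
            # membrane: (Vc + V_off - V_m)/R_s = gtot (V_m - ecomb) = I
            # command: Vc = v_hold - V_off* + alpha R_s* I
            denom = a.R_s - m.alpha * m.R_s_star
            # I = (v_hold - V_off* + V_off - V_m)/denom
            I = (v_hold - m.V_off_star + a.V_off - V_m) / denom
            V_new = ecomb + I / gtot if gtot > 0 else v_hold - m.V_off_star + a.V_off
            if abs(V_new - V_m) < 1e-12:
                V_m = V_new
                break
            V_m = 0.5 * (V_m + V_new)

    k1 = p.p1 * math.exp(p.p2 * V_m)
    k2 = p.p3 * math.exp(-p.p4 * V_m)
    k3 = p.p5 * math.exp(p.p6 * V_m)
    k4 = p.p7 * math.exp(-p.p8 * V_m)
    a_inf = k1 / (k1 + k2)
    r_inf = k4 / (k3 + k4)
    if mode == "ideal":
        return np.array([a_inf, r_inf])
    if mode == "simplified":
        return np.array([V_m, a_inf, r_inf])
    # full: [V_m, V_p, V_clamp, I_out, V_est, a, r]
    gtot = p.g_Kr * a_inf * r_inf + artefact.g_leak
    I = p.g_Kr * a_inf * r_inf * (V_m - p.E_K) \
        + artefact.g_leak * (V_m - artefact.E_leak)
    V_c = V_m - artefact.V_off + I * artefact.R_s
    return np.array([V_m, V_c, V_c, I, V_c, a_inf, r_inf])


# ---------------------------------------------------------------------------
# Fast numba engine for I_Kr (ideal / simplified)
# ---------------------------------------------------------------------------

_plan_cache: dict = {}


def _substep_plan(protocol: Protocol, dt_int: float):
    """Precomputed substep sizes, midpoint commands and output markers.

    Substeps never straddle a segment edge or an output time, so the
    piecewise-linear command is smooth within each substep.
    """
    key = (id(protocol), protocol.duration, protocol.dt, dt_int,
           tuple((s.duration, s.v_start, s.v_end) for s in protocol.segments))
    if key in _plan_cache:
        return _plan_cache[key]
    t_out, v_out = sample(protocol)
    edges = protocol.boundaries
    cut = np.unique(np.concatenate([t_out, edges]))
    from .protocol import voltages_at

    hs_list, tmid_list, rec_list = [], [], []
    out_idx = 1
    for a, b in zip(cut[:-1], cut[1:]):
        nsub = max(1, int(math.ceil((b - a) / dt_int - 1e-9)))
        h = (b - a) / nsub
        hs_list.append(np.full(nsub, h))
        tmid_list.append(a + (np.arange(nsub) + 0.5) * h)
        r = np.full(nsub, -1, dtype=np.int64)
        if out_idx < len(t_out) and abs(b - t_out[out_idx]) < 1e-9:
            r[-1] = out_idx
            out_idx += 1
        rec_list.append(r)
    hs = np.concatenate(hs_list)
    vmid = voltages_at(protocol, np.concatenate(tmid_list))
    rec = np.concatenate(rec_list)
    plan = (hs, vmid, rec, t_out, v_out)
    if len(_plan_cache) > 32:
        _plan_cache.clear()
    _plan_cache[key] = plan
    return plan


try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _ikr_split_kernel(hs, vmid, rec, pars, voff, gdag, edag, Reff, Cm,
                      perfect, x0, out):  # pragma: no cover - jitted
    g = pars[0]
    p1, p2, p3, p4, p5, p6, p7, p8 = (pars[1], pars[2], pars[3], pars[4],
                                      pars[5], pars[6], pars[7], pars[8])
    E_K = pars[9]
    Vm = x0[0]
    a = x0[1]
    r = x0[2]
    for i in range(hs.shape[0]):
        h = hs[i]
        v = vmid[i]
        if perfect:
            Vm = v + voff
        # Rush-Larsen gate update at current V_m
        k1 = p1 * math.exp(p2 * Vm)
        k2 = p3 * math.exp(-p4 * Vm)
        k3 = p5 * math.exp(p6 * Vm)
        k4 = p7 * math.exp(-p8 * Vm)
        ainf = k1 / (k1 + k2)
        rinf = k4 / (k3 + k4)
        a = ainf + (a - ainf) * math.exp(-h * (k1 + k2))
        r = rinf + (r - rinf) * math.exp(-h * (k3 + k4))
        if not perfect:
            # exact exponential step of the conditionally linear V_m ODE
            G = g * a * r
            Acoef = -(1.0 / Reff + G + gdag) / Cm
            Bcoef = ((v + voff) / Reff + G * E_K + gdag * edag) / Cm
            Vinf = -Bcoef / Acoef
            Vm = Vinf + (Vm - Vinf) * math.exp(Acoef * h)
        j = rec[i]
        if j >= 0:
            out[j, 0] = Vm
            out[j, 1] = a
            out[j, 2] = r
    return 0


def _ikr_fast_simulate(protocol, mode, cell: IKrParameters, artefact, machine,
                       residual, dt_int):
    hs, vmid, rec, t_out, v_out = _substep_plan(protocol, dt_int)
    if mode == "ideal":
        voff, gdag, edag = 0.0, 0.0, -80.0
        Reff, Cm, perfect = 1.0, 1.0, True
        residual_eff = ArtefactResidual()
    else:
        r = residual
        voff, gdag, edag = r.V_off_dagger, r.g_leak_dagger, r.E_leak_dagger
        Reff = artefact.R_s - machine.alpha * machine.R_s_star
        Cm = artefact.C_m
        perfect = Reff <= _PERFECT_EPS
        residual_eff = r
    x0_full = _initial_state(protocol, mode, cell, artefact, machine,
                             residual_eff)
    if mode == "ideal":
        x0 = np.array([protocol.holding, x0_full[0], x0_full[1]])
    else:
        x0 = x0_full
    pars = np.array([cell.g_Kr, cell.p1, cell.p2, cell.p3, cell.p4,
                     cell.p5, cell.p6, cell.p7, cell.p8, cell.E_K])
    out = np.empty((len(t_out), 3))
    out[0] = x0 if not perfect else np.array([v_out[0] + voff, x0[1], x0[2]])
    _ikr_split_kernel(hs, vmid, rec, pars, voff, gdag, edag,
                      max(Reff, _PERFECT_EPS), Cm, perfect, x0, out)
    V_m = out[:, 0]
    a, r_ = out[:, 1], out[:, 2]
    if perfect:
        V_m = v_out + voff
    I_ion = cell.g_Kr * a * r_ * (V_m - cell.E_K)
    I_obs = I_ion + gdag * (V_m - edag)
    return t_out, v_out, V_m, I_obs


# ---------------------------------------------------------------------------
# Top-level simulation front-end
# ---------------------------------------------------------------------------

_DEFAULT_SOLVER = {
    "engine": "auto",       # auto | expm | split | scipy
    "rtol": 1e-8,
    "atol": 1e-10,
    "method": "LSODA",      # scipy engine method (LSODA or BDF)
    "dt_int": 0.05,         # split-engine substep, ms
}


def ideal_clamp(protocol: Protocol, cell, solver_opts=None,
                noise_sd: float = 0.0, seed=None) -> Recording:
    """Perfect-clamp simulation: V_m == V_cmd, I_out == I_ion."""
    return simulate(protocol, "ideal", cell, solver_opts=solver_opts,
                    noise_sd=noise_sd, seed=seed)


def simulate(protocol: Protocol, mode: str, cell,
             artefact: ArtefactTrue | None = None,
             machine: MachineSettings | None = None,
             residual: ArtefactResidual | None = None,
             solver_opts: dict | None = None,
             noise_sd: float = 0.0, seed=None) -> Recording:
    """Simulate a voltage-clamp recording.

    Integrates segment by segment (re-initialising at step
    discontinuities), evaluates the mode's observables on the protocol's
    sampling grid, and optionally appends iid Gaussian current noise of
    standard deviation ``noise_sd`` pA using the given seed.

    ``mode`` is ``"ideal"``, ``"full"`` (requires ``artefact`` and
    ``machine``) or ``"simplified"`` (requires ``residual``, ``machine``
    and — for the true C_m, R_s values — ``artefact``).
    """
    if mode not in ("ideal", "full", "simplified"):
        raise ValueError(f"unknown mode {mode!r}")
    opts = dict(_DEFAULT_SOLVER)
    if solver_opts:
        opts.update(solver_opts)
    machine = machine or MachineSettings()
    artefact = artefact or ArtefactTrue()
    residual = residual or ArtefactResidual()
    engine = opts["engine"]
    linear = isinstance(cell, (ModelCellTypeI, ModelCellTypeII))
    if engine == "auto":
        if linear:
            engine = "expm"
        elif mode in ("ideal", "simplified"):
            engine = "split"
        else:
            engine = "scipy"

    v_m_trace = None
    i_post = None
    if engine == "expm":
        if not linear:
            raise ValueError("expm engine requires a linear model cell")
        A, B, outmap = _lti_matrices(mode, cell, artefact, machine, residual)
        x0 = _lti_steady_state(A, B, protocol.holding)
        t, v, xs = _lti_simulate(protocol, A, B, x0)
        u = np.column_stack([v, np.ones_like(v)])

        def read(name):
            rx, ru = outmap[name]
            return xs @ rx + u @ ru

        i_out = read("I_out")
        v_m_trace = read("V_m")
        if "I_post" in outmap:
            i_post = read("I_post")
    elif engine == "split":
        if not isinstance(cell, IKrParameters) or mode == "full":
            raise ValueError("split engine supports I_Kr under ideal/simplified clamps")
        t, v, v_m_trace, i_out = _ikr_fast_simulate(
            protocol, mode, cell, artefact, machine, residual, opts["dt_int"])
        if mode == "simplified":
            i_post = i_out.copy()
    elif engine == "scipy":
        t, v, xs = _scipy_simulate(protocol, mode, cell, artefact, machine,
                                   residual, opts["rtol"], opts["atol"],
                                   opts["method"])
        i_out, i_post, v_m_trace = _observables_from_states(
            mode, cell, artefact, machine, residual, t, v, xs)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    i_out = np.asarray(i_out, dtype=float).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i_out = i_out + rng.normal(0.0, noise_sd, size=i_out.shape)
        if i_post is not None:
            i_post = i_out.copy()
    meta = {
        "mode": mode,
        "engine": engine,
        "noise_sd_pA": noise_sd,
        "seed": seed,
        "holding_mV": protocol.holding,
        "alpha": machine.alpha,
        "R_s_star_GOhm": machine.R_s_star,
        "C_m_star_pF": machine.C_m_star,
        "C_p_star_pF": machine.C_p_star,
        "V_off_star_mV": machine.V_off_star,
    }
    return Recording(t=t, v_cmd=v, i_out=i_out, i_post=i_post,
                     v_m=None if v_m_trace is None else np.asarray(v_m_trace),
                     meta=meta)


def _observables_from_states(mode, cell, artefact, machine, residual, t, v, xs):
    n = len(t)
    i_out = np.empty(n)
    v_m = np.empty(n)
    i_post = None
    if mode == "full":
        for i in range(n):
            i_out[i] = xs[i, 3]
            v_m[i] = xs[i, 0]
    elif mode == "simplified":
        i_post = np.empty(n)
        R_eff = artefact.R_s - machine.alpha * machine.R_s_star
        perfect = R_eff <= _PERFECT_EPS
        for i in range(n):
            Vm = v[i] + residual.V_off_dagger if perfect else xs[i, 0]
            cs = xs[i, 1:] if not perfect else xs[i, 1:]
            I_cell, _ = _cell_current_and_rhs(cell, Vm, cs)
            i_out[i] = I_cell + residual.g_leak_dagger * (Vm - residual.E_leak_dagger)
            v_m[i] = Vm
        i_post = i_out.copy()
    else:  # ideal
        for i in range(n):
            I_cell, _ = _cell_current_and_rhs(cell, v[i], xs[i])
            i_out[i] = I_cell
            v_m[i] = v[i]
    return i_out, i_post, v_m


# ---------------------------------------------------------------------------
# Leak estimation and subtraction
# ---------------------------------------------------------------------------


def estimate_leak(rec: Recording, ramp_window: tuple[float, float],
                  holding: float = -80.0) -> dict:
    """Estimate linear leak parameters from a voltage-ramp window.

    Fits I = g (V_cmd − E) by least squares over samples with
    ``ramp_window[0] <= t <= ramp_window[1]`` (which must span a
    non-constant command voltage), then re-solves E from the measured mean
    holding current so that g (holding − E) reproduces it — the "zero
    current at holding potential" convention.  For data that are exactly
    linear leak the adjustment returns the fitted E unchanged.

    Returns ``{"g_leak_star": nS, "E_leak_star": mV, "degenerate": bool}``.
    """
    if rec.i_out is None:
        raise ValueError("recording has no i_out trace")
    t0, t1 = ramp_window
    w = (rec.t >= t0) & (rec.t <= t1)
    V = rec.v_cmd[w]
    I = rec.i_out[w]
    if len(V) < 2 or np.ptp(V) < 1e-9:
        raise ValueError("ramp window holds a constant voltage: singular leak fit")
    X = np.column_stack([V, np.ones_like(V)])
    (g, c), *_ = np.linalg.lstsq(X, I, rcond=None)
    if abs(g) < 1e-12:
        return {"g_leak_star": 0.0, "E_leak_star": float(holding),
                "degenerate": True}
    E = -c / g
    hold_mask = (~w) & (np.abs(rec.v_cmd - holding) < 1e-6)
    if np.any(hold_mask):
        I_hold = float(np.mean(rec.i_out[hold_mask]))
        E = holding - I_hold / g
    return {"g_leak_star": float(g), "E_leak_star": float(E),
            "degenerate": False}


def subtract_leak(rec: Recording, g_leak_star: float,
                  E_leak_star: float) -> Recording:
    """I_post = I_out − g* (V_cmd − E*); the raw I_out is retained."""
    if rec.i_out is None:
        raise ValueError("recording has no i_out trace to leak-subtract")
    i_post = rec.i_out - g_leak_star * (rec.v_cmd - E_leak_star)
    meta = dict(rec.meta)
    meta["g_leak_star_nS"] = g_leak_star
    meta["E_leak_star_mV"] = E_leak_star
    return Recording(t=rec.t, v_cmd=rec.v_cmd, i_out=rec.i_out,
                     i_post=i_post, v_m=rec.v_m, meta=meta)
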