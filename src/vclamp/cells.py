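"""Plug-in membrane-current models.

Three cell models are provided:

* a Hodgkin–Huxley I_Kr (hERG) model with an activation gate ``a`` and a
  recovery-from-inactivation gate ``r``,
* the Type I electrical model cell (a pure membrane resistor; the membrane
  capacitor lives in the clamp circuit), and
* the Type II electrical model cell, which adds an R_k–C_k branch in
  parallel to give the circuit simple current kinetics with time constant
  tau_k = R_k * C_k, of the same order as I_Kr gating (~100 ms).

Unit system (fixed package-wide): ms, mV, GOhm, pF, pA, nS.  With these,
R*C is in ms, V/R in pA and nS*mV = pA.  Kinetic rate parameters p1,p3,p5,p7
are in ms^-1 and p2,p4,p6,p8 in mV^-1; conversion from per-second/per-volt
conventions happens only at the file I/O boundary.

The traditional symbol tau_a is ambiguous between the activation-gate time
constant and the access time constant R_s*C_m; here they are named
``tau_act`` and (in the clamp module) ``tau_access``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IKrParameters",
    "IKrState",
    "ModelCellTypeI",
    "ModelCellTypeII",
    "ikr_rates",
    "ikr_instantaneous",
    "ikr_rhs",
    "ikr_current",
    "nernst_potential",
    "type1_current",
    "type2_rhs",
    "default_ikr_parameters",
    "read_ikr_parameters",
    "write_ikr_parameters",
]

GAS_CONSTANT = 8.314  # J / (mol K)
FARADAY = 96485.0     # C / mol


def nernst_potential(K_o: float, K_i: float, T: float = 298.15) -> float:
    """Potassium reversal potential E_K in mV from concentrations in mM.

    E_K = (R*T/F) * ln(K_o / K_i), with T in kelvin.
    """
    if K_o <= 0 or K_i <= 0 or T <= 0:
        raise ValueError("concentrations and temperature must be positive")
    return float(1e3 * GAS_CONSTANT * T / FARADAY * np.log(K_o / K_i))


@dataclass(frozen=True)
class IKrParameters:
    """Nine positive parameters of the two-gate I_Kr model plus E_K.

    ``g_Kr`` is the maximal conductance in nS; p1, p3, p5, p7 are base rates
    in ms^-1 and p2, p4, p6, p8 voltage sensitivities in mV^-1.  ``E_K`` may
    be given directly (mV) or computed from concentrations via
    :func:`nernst_potential`.
    """

    g_Kr: float
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float
    E_K: float = -85.2

    def __post_init__(self) -> None:
        for name in ("g_Kr", "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"I_Kr parameter {name} must be strictly positive, got {v}")

    @property
    def theta(self) -> np.ndarray:
        """Kinetic parameter vector (p1..p8)."""
        return np.array([self.p1, self.p2, self.p3, self.p4,
                         self.p5, self.p6, self.p7, self.p8])

    def with_theta(self, theta) -> "IKrParameters":
        p = np.asarray(theta, dtype=float)
        return IKrParameters(self.g_Kr, *p, E_K=self.E_K)


@dataclass
class IKrState:
    """Gating state: activation ``a`` and recovery ``r``, both in [0, 1]."""

    a: float
    r: float


def default_ikr_parameters() -> IKrParameters:
    """Documented placeholder parameter set.

    Representative room-temperature hERG1a magnitudes: activation relaxes
    over seconds near 0 mV while inactivation recovery is ~10 ms.  Intended
    as a synthetic-data default; fitted values for a particular dataset
    should be loaded from a parameter file instead.
    """
    return IKrParameters(
        g_Kr=30.0,
        p1=2.26e-4, p2=0.0699,
        p3=3.45e-5, p4=0.05462,
        p5=0.0873, p6=8.91e-3,
        p7=5.15e-3, p8=0.03158,
        E_K=nernst_potential(4.0, 110.0, 298.15),
    )


def _check_theta(theta) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if th.shape != (8,) or not np.all(np.isfinite(th)) or np.any(th <= 0):
        raise ValueError("theta must be 8 strictly positive finite rates")
    return th


def ikr_rates(V_m: float, theta) -> dict[str, float]:
    """Transition rates k1..k4 (ms^-1) at membrane voltage V_m (mV).

    k1 = p1 exp(p2 V), k2 = p3 exp(-p4 V), k3 = p5 exp(p6 V),
    k4 = p7 exp(-p8 V); all strictly positive for finite V.
    """
    p1, p2, p3, p4, p5, p6, p7, p8 = _check_theta(theta)
    return {
        "k1": p1 * np.exp(p2 * V_m),
        "k2": p3 * np.exp(-p4 * V_m),
        "k3": p5 * np.exp(p6 * V_m),
        "k4": p7 * np.exp(-p8 * V_m),
    }


def ikr_instantaneous(V_m: float, theta) -> dict[str, float]:
    """Steady states and time constants of the two gates at fixed V_m.

    a_inf = k1/(k1+k2), r_inf = k4/(k3+k4), tau_act = 1/(k1+k2),
    tau_rec = 1/(k3+k4).
    """
    k = ikr_rates(V_m, theta)
    return {
        "a_inf": k["k1"] / (k["k1"] + k["k2"]),
        "r_inf": k["k4"] / (k["k3"] + k["k4"]),
        "tau_act": 1.0 / (k["k1"] + k["k2"]),
        "tau_rec": 1.0 / (k["k3"] + k["k4"]),
    }


def ikr_rhs(state: IKrState, V_m: float, theta) -> tuple[float, float]:
    """(da/dt, dr/dt) — each gate relaxes to its steady state.

    da/dt = (a_inf - a)/tau_act, dr/dt = (r_inf - r)/tau_rec; dynamics keep
    a, r in [0, 1] for initial values in [0, 1].
    """
    inst = ikr_instantaneous(V_m, theta)
    da = (inst["a_inf"] - state.a) / inst["tau_act"]
    dr = (inst["r_inf"] - state.r) / inst["tau_rec"]
    return da, dr


def ikr_current(state: IKrState, V_m: float, g_Kr: float, E_K: float) -> float:
    """Ohmic current I = g_Kr * a * r * (V_m - E_K) in pA (nS * mV)."""
    return g_Kr * state.a * state.r * (V_m - E_K)


@dataclass(frozen=True)
class ModelCellTypeI:
    """Type I electrical model cell: membrane resistor R_m (GOhm) only."""

    R_m: float = 0.5

    def __post_init__(self) -> None:
        if self.R_m <= 0:
            raise ValueError("R_m must be > 0")


@dataclass(frozen=True)
class ModelCellTypeII:
    """Type II electrical model cell: R_m plus an R_k-C_k kinetic branch.

    The branch voltage V_k across C_k is the single circuit state; its time
    constant is tau_k = R_k * C_k (100 ms with the reference component
    values R_k = 0.1 GOhm, C_k = 1000 pF).
    """

    R_m: float = 0.5
    R_k: float = 0.1
    C_k: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.R_m, self.R_k, self.C_k) <= 0:
            raise ValueError("R_m, R_k, C_k must all be > 0")

    @property
    def tau_k(self) -> float:
        return self.R_k * self.C_k


def type1_current(V_m: float, m: ModelCellTypeI) -> float:
    """Ohm's law: I = V_m / R_m (pA); the circuit has no battery."""
    return V_m / m.R_m


def type2_rhs(V_k: float, V_m: float, m: ModelCellTypeII) -> tuple[float, float]:
    """Kinetic-branch dynamics and total cell current.

    Branch current I_k = (V_m - V_k)/R_k charges C_k (dV_k/dt = I_k/C_k);
    the cell current is the resistive path plus the branch,
    I_cell = V_m/R_m + I_k.  The capacitor blocks DC, so at steady state
    I_cell = V_m/R_m, as for the Type I cell.
    """
    I_k = (V_m - V_k) / m.R_k
    dVk = I_k / m.C_k
    return dVk, V_m / m.R_m + I_k


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------
# Flat key-value text.  Keys carry units: g_Kr_nS, p1_per_ms / p1_per_s,
# p2_per_mV / p2_per_V, ..., and either E_K_mV or K_o_mM + K_i_mM + T_K.

_RATE_KEYS = ("p1", "p3", "p5", "p7")
_VOLT_KEYS = ("p2", "p4", "p6", "p8")


def write_ikr_parameters(params: IKrParameters, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"g_Kr_nS {float(params.g_Kr)!r}\n")
        for k in ("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8"):
            unit = "per_ms" if k in _RATE_KEYS else "per_mV"
            fh.write(f"{k}_{unit} {float(getattr(params, k))!r}\n")
        fh.write(f"E_K_mV {float(params.E_K)!r}\n")


def read_ikr_parameters(path) -> IKrParameters:
    kv: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, val = line.split()
                kv[key] = float(val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed key-value line") from exc

    def pick(base: str, ms_unit: str, s_unit: str, factor: float) -> float:
        if f"{base}_{ms_unit}" in kv:
            return kv[f"{base}_{ms_unit}"]
        if f"{base}_{s_unit}" in kv:
            return kv[f"{base}_{s_unit}"] * factor
        raise KeyError(f"missing {base} in {path}")

    vals = {}
    for k in _RATE_KEYS:
        vals[k] = pick(k, "per_ms", "per_s", 1e-3)   # s^-1 -> ms^-1
    for k in _VOLT_KEYS:
        vals[k] = pick(k, "per_mV", "per_V", 1e-3)   # V^-1 -> mV^-1
    if "E_K_mV" in kv:
        E_K = kv["E_K_mV"]
    else:
        E_K = nernst_potential(kv["K_o_mM"], kv["K_i_mM"], kv.get("T_K", 298.15))
    g = kv["g_Kr_nS"] if "g_Kr_nS" in kv else kv["g_Kr_pS"] * 1e-3
    return IKrParameters(g_Kr=g, E_K=E_K, **vals)
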