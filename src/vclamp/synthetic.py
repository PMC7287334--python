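"""Ground-truthed synthetic voltage-clamp datasets.

Emulates multi-well automated patch-clamp experiments in which every cell
expresses the same channel (shared kinetics θ) but has its own maximal
conductance and its own artefact/compensation parameters — the generative
picture behind the identical-kinetics hypothesis — plus electrical
model-cell fixture recordings for amplifier-model validation.

Default hyperparameters follow the typical ranges for CHO cells on a
high-throughput platform: C_m 5–20 pF, R_s 5–20 MOhm, requested series
resistance compensation 70–85%, residual voltage offsets within about
±5 mV and residual leak conductances much smaller than the channel
conductance.  White Gaussian current noise is a declared simplification:
the real instrument's noise spectrum is not modelled.

Reproducibility: each cell draws from its own random stream derived from
(master seed, cell index), so enlarging a population extends it without
reshuffling earlier cells.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import IKrParameters, ModelCellTypeI, ModelCellTypeII, default_ikr_parameters
from .clamp import (
    ArtefactResidual,
    ArtefactTrue,
    MachineSettings,
    Recording,
    compensated_settings,
    simulate,
)
from .protocol import Protocol

__all__ = [
    "PopulationHyperparameters",
    "draw_population",
    "generate_dataset",
    "model_cell_fixture",
    "write_truth",
    "read_truth",
    "write_dataset",
    "read_dataset",
    "MODEL_CELL_COMPONENTS",
]

# Reference hardware component values of the electrical model cells
MODEL_CELL_COMPONENTS = {
    "C_p": 4.7,     # pF
    "R_s": 0.03,    # GOhm (30 MOhm)
    "C_m": 22.0,    # pF
    "R_m": 0.5,     # GOhm (500 MOhm)
    "C_k": 1000.0,  # pF
    "R_k": 0.1,     # GOhm (100 MOhm) -> tau_k = 100 ms
    "V_off": 0.0,   # mV (no battery component)
}


@dataclass(frozen=True)
class PopulationHyperparameters:
    """Distributions for a multi-well population with shared kinetics.

    Conductances are log-normal (median ``g_median`` nS, log-sd
    ``g_log_sd``); residual offsets are normal (``voff_mean`` ±
    ``voff_sd`` mV, the default sd keeping draws within ≈ ±5 mV); residual
    leak conductances are half-normal with scale ``gleak_scale`` nS, much
    smaller than the median conductance.  Machine settings are drawn
    uniformly per cell from the given ranges, with the amplifier estimates
    C_m*, R_s* taken as accurate.
    """

    N: int = 124
    g_median: float = 30.0
    g_log_sd: float = 0.4
    voff_mean: float = 0.0
    voff_sd: float = 2.0
    gleak_scale: float = 0.2
    noise_sd: float = 5.0
    theta: tuple = tuple(default_ikr_parameters().theta)
    E_K: float = default_ikr_parameters().E_K
    alpha_range: tuple[float, float] = (0.7, 0.85)
    C_m_range: tuple[float, float] = (5.0, 20.0)
    R_s_range: tuple[float, float] = (0.005, 0.020)
    C_p_range: tuple[float, float] = (3.0, 5.0)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.g_median <= 0 or self.g_log_sd < 0 or self.voff_sd < 0 \
                or self.gleak_scale < 0 or self.noise_sd < 0:
            raise ValueError("invalid distribution hyperparameters")
        for lo, hi in (self.alpha_range, self.C_m_range, self.R_s_range,
                       self.C_p_range):
            if not (0 <= lo <= hi):
                raise ValueError("ranges must satisfy 0 <= lo <= hi")


def _cell_rng(seed: int, cell: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(cell), stream]))


def draw_population(h: PopulationHyperparameters, seed: int) -> pd.DataFrame:
    """Draw a ground-truth table, one row per cell.

    Deterministic given ``(h, seed)``; each cell uses its own stream so
    populations are extensible.  Columns: cell, g_Kr (nS), V_off_dagger
    (mV), g_leak_dagger (nS), alpha, C_m (pF), R_s (GOhm), C_p (pF), seed.
    """
    rows = []
    for i in range(h.N):
        rng = _cell_rng(seed, i)
        g = h.g_median * np.exp(rng.normal(0.0, h.g_log_sd))
        voff = rng.normal(h.voff_mean, h.voff_sd)
        gleak = abs(rng.normal(0.0, h.gleak_scale)) if h.gleak_scale > 0 else 0.0
        alpha = rng.uniform(*h.alpha_range)
        C_m = rng.uniform(*h.C_m_range)
        R_s = rng.uniform(*h.R_s_range)
        C_p = rng.uniform(*h.C_p_range)
        rows.append(dict(cell=i, g_Kr=g, V_off_dagger=voff,
                         g_leak_dagger=gleak, alpha=alpha, C_m=C_m, R_s=R_s,
                         C_p=C_p, seed=seed))
    df = pd.DataFrame(rows)
    df.attrs["theta"] = tuple(h.theta)
    df.attrs["E_K"] = h.E_K
    df.attrs["noise_sd"] = h.noise_sd
    return df


def _row_models(row, theta, E_K):
    kin = {f"p{i + 1}": theta[i] for i in range(8)}
    cell = IKrParameters(g_Kr=float(row["g_Kr"]), E_K=E_K, **kin)
    residual = ArtefactResidual(V_off_dagger=float(row["V_off_dagger"]),
                                g_leak_dagger=float(row["g_leak_dagger"]))
    artefact = ArtefactTrue(V_off=float(row["V_off_dagger"]),
                            C_p=float(row.get("C_p", 4.0)),
                            C_m=float(row["C_m"]), R_s=float(row["R_s"]),
                            g_leak=float(row["g_leak_dagger"]),
                            E_leak=-80.0)
    machine = MachineSettings(alpha=float(row["alpha"]),
                              R_s_star=float(row["R_s"]),
                              C_m_star=float(row["C_m"]),
                              C_p_star=float(row.get("C_p", 4.0)))
    return cell, residual, artefact, machine


def generate_dataset(truth: pd.DataFrame, protocol: Protocol,
                     mode: str = "simplified", seed: int = 0,
                     noise_sd: float | None = None,
                     theta=None, E_K: float | None = None,
                     solver_opts: dict | None = None) -> list[Recording]:
    """Simulate one recording per truth-table row.

    ``theta``/``E_K`` default to the values attached to the truth table by
    :func:`draw_population`.  Noise streams derive from
    ``(seed, cell index)`` so the dataset regenerates bit-identically.
    """
    theta = tuple(theta) if theta is not None else tuple(truth.attrs["theta"])
    E_K = E_K if E_K is not None else float(truth.attrs.get("E_K", -85.2))
    if noise_sd is None:
        noise_sd = float(truth.attrs.get("noise_sd", 0.0))
    recs = []
    for _, row in truth.iterrows():
        cell, residual, artefact, machine = _row_models(row, theta, E_K)
        noise_seed = int(_cell_rng(seed, int(row["cell"]), 1).integers(2 ** 31))
        try:
            rec = simulate(protocol, mode, cell, artefact=artefact,
                           machine=machine, residual=residual,
                           solver_opts=solver_opts,
                           noise_sd=noise_sd, seed=noise_seed)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for cell {row['cell']}") from exc
        rec.meta["cell"] = int(row["cell"])
        rec.meta["protocol"] = protocol.name
        rec.meta["dataset_seed"] = seed
        recs.append(rec)
    return recs


def model_cell_fixture(cell_type: str, compensated: bool, protocol: Protocol,
                       noise_sd: float = 0.0, seed: int | None = None,
                       solver_opts: dict | None = None) -> Recording:
    """Full-model recording of a Type I or II model cell (I_out and V_m).

    Uses the reference hardware component values; ``compensated`` applies
    accurate amplifier estimates with alpha = 0.8, mirroring the
    dual-amplifier measurement in which both the current readout and the
    membrane voltage are available.
    """
    c = MODEL_CELL_COMPONENTS
    if cell_type == "I":
        cell = ModelCellTypeI(R_m=c["R_m"])
    elif cell_type == "II":
        cell = ModelCellTypeII(R_m=c["R_m"], R_k=c["R_k"], C_k=c["C_k"])
    else:
        raise ValueError("cell_type must be 'I' or 'II'")
    artefact = ArtefactTrue(V_off=c["V_off"], C_p=c["C_p"], C_m=c["C_m"],
                            R_s=c["R_s"], g_leak=0.0)
    if compensated:
        machine = compensated_settings(artefact, alpha=0.8)
    else:
        machine = MachineSettings()
    rec = simulate(protocol, "full", cell, artefact=artefact, machine=machine,
                   solver_opts=solver_opts, noise_sd=noise_sd, seed=seed)
    rec.meta["model_cell"] = cell_type
    rec.meta["compensated"] = compensated
    return rec


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
    with open(f"{path}.meta", "w") as fh:
        fh.write(f"theta {' '.join(repr(float(x)) for x in truth.attrs['theta'])}\n")
        fh.write(f"E_K {float(truth.attrs['E_K'])!r}\n")
        fh.write(f"noise_sd {float(truth.attrs.get('noise_sd', 0.0))!r}\n")


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path)
    try:
        with open(f"{path}.meta") as fh:
            for line in fh:
                key, _, val = line.strip().partition(" ")
                if key == "theta":
                    truth.attrs["theta"] = tuple(float(x) for x in val.split())
                elif key in ("E_K", "noise_sd"):
                    truth.attrs[key] = float(val)
    except FileNotFoundError:
        pass
    return truth


def write_dataset(recs: list[Recording], truth: pd.DataFrame, outdir) -> None:
    """Write recordings, truth table and a manifest to a directory."""
    os.makedirs(outdir, exist_ok=True)
    write_truth(truth, os.path.join(outdir, "truth.csv"))
    names = []
    for rec in recs:
        name = f"cell_{int(rec.meta.get('cell', len(names))):04d}.csv"
        rec.to_file(os.path.join(outdir, name))
        names.append(name)
    with open(os.path.join(outdir, "manifest.txt"), "w") as fh:
        fh.write("truth.csv\n")
        for n in names:
            fh.write(n + "\n")


def read_dataset(outdir) -> tuple[pd.DataFrame, list[Recording]]:
    with open(os.path.join(outdir, "manifest.txt")) as fh:
        names = [line.strip() for line in fh if line.strip()]
    truth = read_truth(os.path.join(outdir, names[0]))
    recs = [Recording.from_file(os.path.join(outdir, n)) for n in names[1:]]
    return truth, recs
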