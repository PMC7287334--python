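"""Quantitative model comparison: RRMSE, summaries and hypothesis tests.

RRMSE normalises the model-data root-mean-square error by the data's RMS
distance from a zero-current trace, making scores comparable across cells
whose current magnitudes differ by conductance alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cells import IKrParameters
from .clamp import ArtefactResidual, simulate
from .inference import FitResult, SharedFitResult, dof_count
from .protocol import Protocol
from .synthetic import _row_models, generate_dataset

__all__ = [
    "rrmse",
    "summarize",
    "comparison_table",
    "hypothesis_comparison",
]


def rrmse(model, data) -> float:
    """sqrt(sum (model-data)^2) / sqrt(sum data^2).

    0 for a perfect fit; 1 for a model that predicts zero current.
    Undefined (error) for identically-zero data.
    """
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if model.shape != data.shape:
        raise ValueError("model and data traces must have equal length")
    denom = float(np.sum(data ** 2))
    if denom == 0.0:
        raise ValueError("RRMSE undefined: data trace is identically zero")
    return float(np.sqrt(np.sum((model - data) ** 2) / denom))


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Best / median / 90th-percentile RRMSE per protocol and hypothesis.

    ``rows`` needs columns ``protocol``, ``hypothesis``, ``rrmse`` (and
    optionally ``cell``).  Median uses the mean-of-middle-two convention
    and the percentile linear interpolation between order statistics.
    Empty groups are skipped with a warning.
    """
    required = {"protocol", "hypothesis", "rrmse"}
    if not required.issubset(rows.columns):
        raise ValueError(f"rows must have columns {sorted(required)}")
    out = []
    for (proto, hyp), grp in rows.groupby(["protocol", "hypothesis"],
                                          sort=True):
        vals = grp["rrmse"].to_numpy(dtype=float)
        if len(vals) == 0:
            import warnings

            warnings.warn(f"empty group {proto}/{hyp}: skipped")
            continue
        out.append(dict(
            protocol=proto, hypothesis=hyp, n=len(vals),
            best=float(np.min(vals)),
            median=float(np.percentile(vals, 50)),
            p90=float(np.percentile(vals, 90)),
        ))
    return pd.DataFrame(out)


def comparison_table(entries: list[dict]) -> pd.DataFrame:
    """Assemble ComparisonRow records into a tidy table.

    Each entry: cell, protocol, hypothesis, rrmse, kind ("fit" or
    "prediction"); a ``dof`` column is attached per hypothesis at the
    population size implied by the distinct cells.
    """
    df = pd.DataFrame(entries)
    if (df["rrmse"] < 0).any():
        raise ValueError("RRMSE must be non-negative")
    N = df["cell"].nunique()
    df["dof"] = [dof_count(h, N) for h in df["hypothesis"]]
    return df


def hypothesis_comparison(truth: pd.DataFrame,
                          calibration: Protocol,
                          validation: Protocol,
                          h1_fits: list[FitResult],
                          h2_fit: SharedFitResult,
                          E_K: float) -> pd.DataFrame:
    """Score per-cell and shared-kinetics fits on fit + prediction data.

    For every cell, noiseless data are regenerated from the truth table
    under both protocols; each hypothesis' model trace is simulated from
    its *calibration-protocol* parameters and scored with RRMSE.  Returns
    a comparison table (see :func:`comparison_table`).
    """
    theta_true = tuple(truth.attrs["theta"])
    entries = []
    for proto, kind in ((calibration, "fit"), (validation, "prediction")):
        data = generate_dataset(truth, proto, mode="simplified", seed=0,
                                noise_sd=0.0)
        for j, (_, row) in enumerate(truth.iterrows()):
            i = int(row["cell"])
            d = data[j].i_post
            # Hypothesis 1: per-cell kinetics, ideal clamp
            fr = h1_fits[j]
            x = fr.parameters
            cell1 = IKrParameters(x["g_Kr"], *[x[f"p{k}"] for k in
                                               range(1, 9)], E_K=E_K)
            m1 = simulate(proto, "ideal", cell1).i_out
            entries.append(dict(cell=i, protocol=proto.name, hypothesis="H1",
                                rrmse=rrmse(m1, d), kind=kind))
            # Hypothesis 2: shared kinetics + cell-specific artefacts
            pc = h2_fit.cell_parameters(i)
            cell2 = IKrParameters(pc["g_Kr"], *h2_fit.theta, E_K=E_K)
            _, _, artefact, machine = _row_models(row, theta_true, E_K)
            res = ArtefactResidual(V_off_dagger=pc["V_off_dagger"],
                                   g_leak_dagger=pc["g_leak_dagger"],
                                   E_leak_dagger=proto.holding)
            m2 = simulate(proto, "simplified", cell2, artefact=artefact,
                          machine=machine, residual=res).i_post
            entries.append(dict(cell=i, protocol=proto.name, hypothesis="H2",
                                rrmse=rrmse(m2, d), kind=kind))
    return comparison_table(entries)
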