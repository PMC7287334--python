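"""Piecewise-linear voltage-command protocols.

A protocol is an ordered list of segments, each either a constant step
(``v_start == v_end``) or a linear ramp, tiling ``[0, T]`` with no gaps.
Units are fixed package-wide: time in ms, voltage in mV.

Segments are left-closed, right-open: at an exact boundary between two
segments the *later* segment's start value applies.  This convention makes
re-initialisation of the ODE solver at step discontinuities deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Segment",
    "Protocol",
    "voltage_at",
    "voltages_at",
    "sample",
    "fixtures",
    "model_cell_calibration",
    "read_segments",
    "write_segments",
    "read_trace",
    "write_trace",
]


class ProtocolError(ValueError):
    """Raised for malformed protocols or out-of-range queries."""


@dataclass(frozen=True)
class Segment:
    """One step or ramp of a voltage-command protocol.

    Parameters
    ----------
    duration : float
        Segment length in ms, strictly positive.
    v_start, v_end : float
        Command voltage (mV) at the start and end of the segment.  Equal
        values encode a step; unequal values a linear ramp.
    """

    duration: float
    v_start: float
    v_end: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ProtocolError(f"segment duration must be > 0, got {self.duration}")
        if not (np.isfinite(self.v_start) and np.isfinite(self.v_end)):
            raise ProtocolError("segment voltages must be finite")

    @property
    def is_ramp(self) -> bool:
        return self.v_start != self.v_end


@dataclass(frozen=True)
class Protocol:
    """An ordered list of segments plus a sampling grid and holding level.

    ``dt`` is the sampling interval (ms) used by :func:`sample`; ``holding``
    is the potential (mV) maintained before and after the protocol.
    """

    segments: tuple[Segment, ...]
    dt: float = 1.0
    holding: float = -80.0
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if len(self.segments) == 0:
            raise ProtocolError("protocol needs at least one segment")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ProtocolError(f"dt must be > 0, got {self.dt}")
        edges = np.concatenate(
            [[0.0], np.cumsum([s.duration for s in self.segments])])
        object.__setattr__(self, "_edges", edges)
        object.__setattr__(self, "_v0", np.array([s.v_start for s in self.segments]))
        object.__setattr__(self, "_v1", np.array([s.v_end for s in self.segments]))
        object.__setattr__(self, "_dur", np.array([s.duration for s in self.segments]))

    @property
    def duration(self) -> float:
        """Total duration in ms (sum of segment durations)."""
        return float(self._edges[-1])

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment edges ``[0, t1, ..., T]``."""
        return self._edges

    def voltage_range(self) -> tuple[float, float]:
        v = [x for s in self.segments for x in (s.v_start, s.v_end)]
        return (min(v), max(v))

    def with_dt(self, dt: float) -> "Protocol":
        return replace(self, dt=dt)


def _locate(p: Protocol, t: float) -> int:
    """Index of the segment containing time t (left-closed, right-open)."""
    edges = p.boundaries
    T = edges[-1]
    if not (0.0 <= t <= T):
        raise ProtocolError(f"t={t} outside protocol range [0, {T}]")
    if t >= T:  # final instant belongs to the last segment
        return len(p.segments) - 1
    return int(np.searchsorted(edges, t, side="right") - 1)


def voltage_at(p: Protocol, t: float) -> float:
    """Command voltage (mV) at time ``t`` (ms).

    Piecewise-linear interpolation within the containing segment; at an
    exact internal boundary the later segment's start value is returned.
    """
    i = _locate(p, t)
    seg = p.segments[i]
    t0 = p.boundaries[i]
    frac = (t - t0) / seg.duration
    return float(seg.v_start + frac * (seg.v_end - seg.v_start))


def voltages_at(p: Protocol, ts: np.ndarray) -> np.ndarray:
    """Vectorised :func:`voltage_at` for an array of times."""
    ts = np.asarray(ts, dtype=float)
    T = p.duration
    if np.any(ts < 0.0) or np.any(ts > T + 1e-9):
        raise ProtocolError("times outside protocol range")
    idx = np.searchsorted(p._edges, ts, side="right") - 1
    idx = np.clip(idx, 0, len(p.segments) - 1)
    frac = (ts - p._edges[idx]) / p._dur[idx]
    return p._v0[idx] + frac * (p._v1[idx] - p._v0[idx])


def sample(p: Protocol, dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample the protocol on its grid ``t = 0, dt, ..., <= T``.

    Returns ``(t, v_cmd)`` arrays of length ``floor(T/dt) + 1``.
    """
    dt = p.dt if dt is None else dt
    if dt <= 0:
        raise ProtocolError(f"dt must be > 0, got {dt}")
    T = p.duration
    n = int(np.floor(T / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    t[-1] = min(t[-1], T)
    v = voltages_at(p, t)
    return t, v


# ---------------------------------------------------------------------------
# Fixture protocols
# ---------------------------------------------------------------------------
#
# The exact staircase and action-potential-series protocols used with the
# high-throughput hERG dataset are published as segment tables elsewhere;
# the fixtures below are approximate stand-ins with the same envelope:
# a staircase-like sweep spanning -120..+60 mV over ~15.5 s with a leading
# -120 to -80 mV leak ramp, and an AP-like series of depolarisation/
# repolarisation spikes built from steps and fast ramps.  Users can load an
# exact published protocol from a segment file via read_segments().


def _staircase_like(dt: float = 1.0) -> Protocol:
    segs: list[Segment] = []

    def step(d, v):
        segs.append(Segment(d, v, v))

    def ramp(d, v0, v1):
        segs.append(Segment(d, v0, v1))

    step(250.0, -80.0)
    step(250.0, -120.0)
    ramp(500.0, -120.0, -80.0)  # leak-calibration ramp
    step(400.0, -80.0)
    # ascending staircase -120 -> +60 in 20 mV steps
    for k in range(10):
        step(500.0, -120.0 + 20.0 * k)
    # descending staircase +60 -> -120
    for k in range(10):
        step(500.0, 60.0 - 20.0 * k)
    # deactivation probe: depolarise then ramp down
    step(500.0, 40.0)
    ramp(500.0, 40.0, -70.0)
    step(500.0, -120.0)
    ramp(500.0, -120.0, -80.0)
    step(1100.0, -80.0)
    return Protocol(tuple(segs), dt=dt, holding=-80.0, name="staircase_like")


def _leak_ramp(dt: float = 1.0) -> Protocol:
    segs = (
        Segment(100.0, -120.0, -120.0),
        Segment(400.0, -120.0, -80.0),
        Segment(200.0, -80.0, -80.0),
    )
    return Protocol(segs, dt=dt, holding=-80.0, name="leak_ramp")


def _ap_like(dt: float = 1.0) -> Protocol:
    """Step/ramp approximation of action-potential-like spikes."""
    segs: list[Segment] = [Segment(200.0, -80.0, -80.0)]
    for pause, apd in ((600.0, 250.0), (400.0, 220.0), (250.0, 180.0), (150.0, 150.0)):
        segs.append(Segment(10.0, -80.0, 40.0))     # fast upstroke ramp
        segs.append(Segment(apd, 40.0, -55.0))      # repolarisation ramp
        segs.append(Segment(20.0, -55.0, -80.0))    # late repolarisation
        segs.append(Segment(pause, -80.0, -80.0))   # diastole
    segs.append(Segment(300.0, -80.0, -80.0))
    return Protocol(tuple(segs), dt=dt, holding=-80.0, name="ap_like")


def fixtures(dt: float = 1.0) -> dict[str, Protocol]:
    """Named fixture protocols: ``staircase_like``, ``leak_ramp``, ``ap_like``."""
    return {
        "staircase_like": _staircase_like(dt),
        "leak_ramp": _leak_ramp(dt),
        "ap_like": _ap_like(dt),
    }


def model_cell_calibration(dt: float = 0.2) -> Protocol:
    """Step protocol with fast (2 ms) ramp edges for model-cell fitting.

    Electrical model cells are characterised by their step responses; the
    capacitances only show up in the fast transients.  Finite-slope edges
    make the parasitic capacitance draw a sustained, sampleable current
    (C_p dV/dt ~ 100 pA at 50 mV/ms), so all circuit components are
    identifiable at ordinary sampling rates.  Holding 0 mV, matching the
    model-cell measurement convention.
    """
    segs = [Segment(200.0, 0.0, 0.0)]
    for v in (-120.0, -80.0, 40.0, -40.0, 60.0, -120.0, 0.0):
        prev = segs[-1].v_end
        segs.append(Segment(2.0, prev, v))
        segs.append(Segment(398.0, v, v))
    return Protocol(tuple(segs), dt=dt, holding=0.0,
                    name="model_cell_calibration")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------
# Segment-list format: one segment per line, "duration_ms v_start_mV v_end_mV",
# '#' starts a comment.  Sampled traces: delimited text "t_ms,v_cmd_mV".


def write_segments(p: Protocol, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# protocol {p.name or 'unnamed'}; dt_ms={p.dt!r}; holding_mV={p.holding!r}\n")
        for s in p.segments:
            fh.write(f"{s.duration!r} {s.v_start!r} {s.v_end!r}\n")


def read_segments(path, dt: float = 1.0, holding: float = -80.0, name: str = "") -> Protocol:
    segs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ProtocolError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            d, v0, v1 = (float(x) for x in parts)
            segs.append(Segment(d, v0, v1))
    return Protocol(tuple(segs), dt=dt, holding=holding, name=name)


def write_trace(path, t: np.ndarray, v: np.ndarray) -> None:
    arr = np.column_stack([t, v])
    header = "t_ms,v_cmd_mV"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")


def read_trace(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return arr[:, 0], arr[:, 1]
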