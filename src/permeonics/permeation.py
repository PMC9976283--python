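"""Permeation-event detection and single-channel conductance.

An ion crossing a membrane channel is counted with a three-state
hysteresis detector: the ion must pass fully through the channel span
(below → inside → above for an outward event, the reverse for inward).
Re-entries that retreat to the same side emit nothing, so boundary jitter
is never double-counted. Event counts convert to current
I = n·q·e/t and conductance g = I/V.

Periodic z-wrapping is removed per ion by minimum-image unwrapping of the
frame-to-frame displacement before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .constants import E_CHARGE
from .core.types import Trajectory

BELOW, INSIDE, ABOVE = -1, 0, 1


class Direction(str, Enum):
    OUTWARD = "outward"   # +z, intracellular -> extracellular
    INWARD = "inward"     # -z


@dataclass
class ChannelSpan:
    """The z-interval an ion must fully traverse to count as permeating.

    ``lateral_radius`` optionally gates events on the distance from the
    pore (z) axis while the ion is inside the span.
    """

    z_lower: float
    z_upper: float
    lateral_radius: float | None = None
    axis_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValueError("z_lower must be < z_upper")
        if self.lateral_radius is not None and self.lateral_radius <= 0:
            raise ValueError("lateral_radius must be positive")


@dataclass
class PermeationEvent:
    ion_id: int
    completion_frame: int
    direction: Direction


@dataclass
class ConductanceEstimate:
    """Event counts converted to current (A) and conductance (pS)."""

    n_events: int
    sim_time: float          # ns
    voltage: float           # V
    ion_charge: float        # e
    current: float           # A
    conductance: float       # pS
    per_replica: list[float] = field(default_factory=list)
    mean: float | None = None
    sd: float | None = None


def unwrap_z(z: np.ndarray, box_z: np.ndarray | float) -> np.ndarray:
    """Remove periodic jumps from a per-frame z series (minimum image).

    Assumes physical displacements below box_z/2 per frame; a warning is
    emitted if any |unwrapped step| still exceeds box_z/2 (undersampled
    trajectory).
    """
    z = np.asarray(z, float)
    bz = np.broadcast_to(np.asarray(box_z, float), z.shape)
    dz = np.diff(z)
    shift = -np.round(dz / bz[1:]) * bz[1:]
    out = z.copy()
    out[1:] = z[0] + np.cumsum(dz + shift)
    steps = np.abs(np.diff(out))
    if np.any(steps > bz[1:] / 2):
        warnings.warn("unwrapped displacement exceeds box_z/2 between frames; "
                      "the trajectory may be too coarsely sampled", stacklevel=2)
    return out


def _classify(z: float, span: ChannelSpan) -> int:
    if z < span.z_lower:
        return BELOW
    if z > span.z_upper:
        return ABOVE
    return INSIDE


def detect_events(traj: Trajectory, span: ChannelSpan,
                  ion_selection="ion") -> list[PermeationEvent]:
    """Count full channel crossings with the three-state hysteresis detector.

    An outward event completes at the first frame where an ion that entered
    the span from below exits above; inward events are the mirror image.
    Lateral gating (if configured) requires the ion to stay within the
    cylinder while inside the span.
    """
    per_ion = traj.positions_by_atom(ion_selection)
    if not per_ion:
        raise ValueError("ion selection matched no atoms")
    boxes = traj.boxes()
    box_z = boxes[:, 2]
    if span.z_upper - span.z_lower >= box_z.min():
        raise ValueError("channel span wider than the box along z")
    events: list[PermeationEvent] = []
    for ion_id, pos in per_ion.items():
        z = unwrap_z(pos[:, 2], box_z)
        # the span is periodic: compare against the image nearest each frame
        offset = np.round((z - 0.5 * (span.z_lower + span.z_upper)) / box_z) * box_z
        zz = z - offset
        state = _classify(zz[0], span)
        came_from = state if state != INSIDE else None
        for f in range(1, len(zz)):
            s = _classify(zz[f], span)
            if abs(zz[f] - zz[f - 1]) > box_z[f] / 2:
                # jump between periodic images of the span (reservoir
                # recycling), not a physical displacement: reset, no event
                state = s
                came_from = s if s != INSIDE else None
                continue
            if span.lateral_radius is not None and s == INSIDE:
                r = np.hypot(pos[f, 0] - span.axis_xy[0], pos[f, 1] - span.axis_xy[1])
                if r > span.lateral_radius:
                    came_from = None
                    state = s
                    continue
            if s == state:
                continue
            if s == INSIDE:
                if state != INSIDE:
                    came_from = state
            else:
                if came_from is not None and came_from != s:
                    events.append(PermeationEvent(
                        ion_id=ion_id, completion_frame=f,
                        direction=Direction.OUTWARD if s == ABOVE else Direction.INWARD))
                came_from = s
            state = s
    events.sort(key=lambda e: (e.completion_frame, e.ion_id))
    return events


def net_outward(events: list[PermeationEvent]) -> int:
    up = sum(1 for e in events if e.direction == Direction.OUTWARD)
    return 2 * up - len(events)


def conductance(events: list[PermeationEvent] | int, sim_time: float,
                voltage: float, ion_charge: float = 2.0,
                counting: str = "net") -> ConductanceEstimate:
    """Convert permeation events to current and conductance.

    ``events`` may be a detector output (counted per ``counting``: "net" =
    outward − inward, "outward" = outward only) or a plain signed count.
    sim_time in ns, voltage in V, ion_charge in units of e. Conductance is
    returned in pS.
    """
    if sim_time <= 0:
        raise ValueError("sim_time must be positive")
    if voltage == 0:
        raise ValueError("conductance is undefined at zero voltage")
    if isinstance(events, (int, np.integer)):
        n = int(events)
    elif counting == "net":
        n = net_outward(events)
    elif counting == "outward":
        n = sum(1 for e in events if e.direction == Direction.OUTWARD)
    else:
        raise ValueError("counting must be 'net' or 'outward'")
    current = n * ion_charge * E_CHARGE / (sim_time * 1e-9)  # A
    cond_ps = current / voltage * 1e12
    return ConductanceEstimate(n_events=n, sim_time=sim_time, voltage=voltage,
                               ion_charge=ion_charge, current=current,
                               conductance=cond_ps)


def replicate_stats(per_replica: list[float]) -> tuple[float, float | None]:
    """Mean and sample standard deviation (n−1) over replica conductances."""
    if len(per_replica) == 0:
        raise ValueError("no replicas")
    arr = np.asarray(per_replica, float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else None
    return mean, sd


def summarize_replicas(per_replica: list[float], voltage: float,
                       ion_charge: float = 2.0) -> ConductanceEstimate:
    mean, sd = replicate_stats(per_replica)
    est = ConductanceEstimate(n_events=0, sim_time=float("nan"), voltage=voltage,
                              ion_charge=ion_charge, current=float("nan"),
                              conductance=mean, per_replica=list(per_replica),
                              mean=mean, sd=sd)
    return est


def trace_table(traj: Trajectory, span: ChannelSpan, ion_selection="ion",
                window: float = 15.0) -> pd.DataFrame:
    """Per-ion unwrapped z(t) restricted to a window around the span.

    Returns a tidy table (ion_id, time, z) suitable for plotting permeation
    traces; ``window`` (Å) extends the kept interval beyond the span edges.
    """
    per_ion = traj.positions_by_atom(ion_selection)
    times = traj.times()
    box_z = traj.boxes()[:, 2]
    rows = []
    lo, hi = span.z_lower - window, span.z_upper + window
    for ion_id, pos in per_ion.items():
        z = unwrap_z(pos[:, 2], box_z)
        offset = np.round((z - 0.5 * (span.z_lower + span.z_upper)) / box_z) * box_z
        zz = z - offset
        keep = (zz >= lo) & (zz <= hi)
        for t, zv in zip(times[keep], zz[keep]):
            rows.append((ion_id, t, zv))
    return pd.DataFrame(rows, columns=["ion_id", "time", "z"])
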