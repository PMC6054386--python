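"""Streamline-based global perfusion P_s.

A streamline is traced through the flux field with FACT (fiber assignment
by continuous tracking, borrowed from tractography): within each grid cell
the flow vector is taken constant (the cell-average of the face fluxes),
the trace advances along a straight segment to the exit face, then adopts
the next cell's vector.  For a complete arterial-to-venous streamline the
global perfusion is

    P_s = 1 / integral_0^l du / |q(s(u))|,

the reciprocal transit-time integral of the squared flow-tube radius
r(u)^2 = 1/|q|.  P_s is constant along a streamline and, unlike voxel
inflow based definitions, independent of the discretization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .darcy import FluxField
from .phantom import ML_MIN_100ML, PhantomSpec

__all__ = [
    "Streamline",
    "PerfusionMap",
    "trace_fact",
    "global_perfusion_ps",
    "transit_time",
    "ps_map",
]

#: traces stop when cell speed falls below this fraction of the field max
STAGNATION_FRACTION = 1e-6
#: traces stop beyond this many domain lengths of arc
MAX_LENGTH_FACTOR = 50.0


@dataclass(frozen=True)
class Streamline:
    """Polyline trace of the flux field.

    ``points`` has shape (n+1, 2) in physical (x, y) mm coordinates
    (x rightward, y downward from the top-left corner); ``seg_len`` and
    ``seg_speed`` give arc length [mm] and |q| [mm/s] of the n segments.
    ``terminated_start``/``terminated_end`` record why the backward and
    forward halves stopped: one of ``source``, ``sink``, ``boundary``,
    ``stagnation``, ``max_length`` (or ``seed`` for a one-sided trace).
    """

    points: np.ndarray
    seg_len: np.ndarray
    seg_speed: np.ndarray
    terminated_start: str
    terminated_end: str

    @property
    def length(self) -> float:
        """Total arc length l [mm]."""
        return float(self.seg_len.sum())

    @property
    def complete(self) -> bool:
        """True for a full arterial-to-venous trace."""
        return self.terminated_start == "source" and self.terminated_end == "sink"


@dataclass(frozen=True)
class PerfusionMap:
    """Scalar per-cell (or per-block) perfusion field with units tag.

    ``definition`` is one of ``Ps``, ``Pv``, ``bSVD``, ``MS``; cells where
    the quantity could not be computed are NaN and flagged in ``valid``.
    """

    values: np.ndarray
    units: str
    definition: str

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def mean(self) -> float:
        """Mean over valid cells."""
        return float(np.nanmean(self.values))

    def in_units(self, units: str) -> "PerfusionMap":
        from .phantom import unit_convert
        return PerfusionMap(values=unit_convert(self.values, self.units, units),
                            units=units, definition=self.definition)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        nx, ny = self.values.shape
        ii, jj = np.meshgrid(np.arange(1, nx + 1), np.arange(1, ny + 1),
                             indexing="ij")
        pd.DataFrame({
            "i": ii.ravel(), "j": jj.ravel(), "value": self.values.ravel(),
            "units": self.units, "definition": self.definition,
        }).to_csv(path, index=False)


def _trace_one_way(spec: PhantomSpec, q: FluxField, vx: np.ndarray,
                   vy: np.ndarray, x: float, y: float, sign: float,
                   speed_floor: float, max_len: float):
    """March one direction; returns (points, seg_len, seg_speed, reason)."""
    hx, hy = spec.hx, spec.hy
    nx, ny = spec.nx, spec.ny
    source = spec.source_rc0
    sink = spec.sink_rc0
    i = min(int(y / hy), nx - 1)
    j = min(int(x / hx), ny - 1)
    pts = [(x, y)]
    lens: list[float] = []
    speeds: list[float] = []
    total = 0.0
    reason = "max_length"
    zero_steps = 0
    max_steps = 4 * (nx + ny) * int(MAX_LENGTH_FACTOR)
    for _ in range(max_steps):
        if (i, j) == source:
            reason = "source"
            break
        if (i, j) == sink:
            reason = "sink"
            break
        ux = sign * vx[i, j]
        uy = sign * vy[i, j]
        # a no-flow outer wall is itself a streamline, so in wall cells the
        # outward normal component (an artifact of the cell-center average)
        # is projected out and the trace slides; walls whose boundary face
        # genuinely carries flux are left crossable.
        if ((j == 0 and ux < 0 and abs(q.qx[i, 0]) <= speed_floor)
                or (j == ny - 1 and ux > 0
                    and abs(q.qx[i, ny]) <= speed_floor)):
            ux = 0.0
        if ((i == 0 and uy < 0 and abs(q.qy[0, j]) <= speed_floor)
                or (i == nx - 1 and uy > 0
                    and abs(q.qy[nx, j]) <= speed_floor)):
            uy = 0.0
        speed = np.hypot(ux, uy)
        if speed <= speed_floor:
            reason = "stagnation"
            break
        # time-of-flight to the cell's exit faces along the straight segment
        tx = ((j + 1) * hx - x) / ux if ux > 0 else (
            (j * hx - x) / ux if ux < 0 else np.inf)
        ty = ((i + 1) * hy - y) / uy if uy > 0 else (
            (i * hy - y) / uy if uy < 0 else np.inf)
        t = min(tx, ty)
        x += ux * t
        y += uy * t
        seg = speed * t
        if seg > 0:
            pts.append((x, y))
            lens.append(seg)
            speeds.append(speed)
            total += seg
            zero_steps = 0
        else:
            # bouncing between faces of near-stagnant cells
            zero_steps += 1
            if zero_steps >= 2:
                reason = "stagnation"
                break
        if total > max_len:
            reason = "max_length"
            break
        if tx <= ty:
            j += 1 if ux > 0 else -1
        if ty <= tx:
            i += 1 if uy > 0 else -1
        if not (0 <= i < nx and 0 <= j < ny):
            reason = "boundary"
            break
    return pts, lens, speeds, reason


def trace_fact(spec: PhantomSpec, q: FluxField, seed: tuple[float, float],
               direction: str = "both",
               stagnation_fraction: float = STAGNATION_FRACTION,
               max_length_factor: float = MAX_LENGTH_FACTOR) -> Streamline:
    """FACT-trace a streamline from a physical seed point (x, y) [mm].

    ``direction`` is ``forward`` (with the flow, toward the sink),
    ``backward`` (against it, toward the source) or ``both`` (the two
    half-traces concatenated into one arterial-to-venous polyline).
    """
    x0, y0 = float(seed[0]), float(seed[1])
    if not (0 <= x0 <= spec.L and 0 <= y0 <= spec.L):
        raise ValueError(f"seed {seed} outside the {spec.L} mm domain")
    if direction not in ("forward", "backward", "both"):
        raise ValueError("direction must be forward, backward or both")
    vx, vy = q.cell_center_vectors()
    speed_floor = stagnation_fraction * float(np.hypot(vx, vy).max())
    max_len = max_length_factor * spec.L

    def run(sign):
        return _trace_one_way(spec, q, vx, vy, x0, y0, sign, speed_floor,
                              max_len)

    if direction == "forward":
        pts, lens, speeds, reason = run(+1.0)
        return Streamline(np.asarray(pts), np.asarray(lens), np.asarray(speeds),
                          terminated_start="seed", terminated_end=reason)
    if direction == "backward":
        pts, lens, speeds, reason = run(-1.0)
        # store the polyline in flow order: upstream terminus -> seed
        return Streamline(np.asarray(pts[::-1]), np.asarray(lens[::-1]),
                          np.asarray(speeds[::-1]),
                          terminated_start=reason, terminated_end="seed")

    fpts, flens, fspeeds, freason = run(+1.0)
    bpts, blens, bspeeds, breason = run(-1.0)
    # stitch: reversed backward polyline + forward polyline (seed once)
    pts = bpts[::-1] + fpts[1:]
    lens = blens[::-1] + flens
    speeds = bspeeds[::-1] + fspeeds
    return Streamline(np.asarray(pts), np.asarray(lens), np.asarray(speeds),
                      terminated_start=breason, terminated_end=freason)


def global_perfusion_ps(sl: Streamline) -> float:
    """Global perfusion of a complete streamline [s^-1].

    Discretizes ``P_s = (integral r(u)^2 du)^-1`` with ``r^2 = 1/|q|`` as
    the reciprocal of ``sum(seg_len / seg_speed)``.

    Raises ``ValueError`` for an incomplete trace (no arterial-to-venous
    connection): such values must not enter averages.
    """
    if not sl.complete:
        raise ValueError(
            f"incomplete streamline (start={sl.terminated_start}, "
            f"end={sl.terminated_end}); P_s is defined source-to-sink")
    denom = float(np.sum(sl.seg_len / sl.seg_speed))
    if denom <= 0:
        raise ValueError("degenerate streamline with zero transit integral")
    return 1.0 / denom


def transit_time(sl: Streamline, phi: float) -> float:
    """Advective transit time T = sum(seg_len * phi / seg_speed) [s].

    Pore velocity is q/phi, so for uniform porosity T = phi / P_s (the
    central volume theorem specialized to one flow tube).
    """
    if not sl.complete:
        raise ValueError("transit time requires a complete streamline")
    return float(np.sum(sl.seg_len * phi / sl.seg_speed))


def ps_map(spec: PhantomSpec, q: FluxField,
           stagnation_fraction: float = STAGNATION_FRACTION) -> PerfusionMap:
    """Seed one streamline per cell center and map P_s over the grid.

    Cells whose trace does not connect source to sink (stagnant corners)
    are NaN.  Source and sink cells themselves are seeded like any other;
    their traces terminate immediately and are flagged.
    """
    nx, ny = spec.nx, spec.ny
    values = np.full((nx, ny), np.nan)
    for i in range(nx):
        y = (i + 0.5) * spec.hy
        for j in range(ny):
            if (i, j) in (spec.source_rc0, spec.sink_rc0):
                continue
            x = (j + 0.5) * spec.hx
            sl = trace_fact(spec, q, (x, y), "both",
                            stagnation_fraction=stagnation_fraction)
            if sl.complete:
                values[i, j] = global_perfusion_ps(sl)
    return PerfusionMap(values=values, units="s^-1", definition="Ps")
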