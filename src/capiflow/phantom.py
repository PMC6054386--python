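"""Synthetic capillary-domain specification.

The phantom is a square 2D slab of homogeneous porous tissue: a single
arterial source voxel in the upper-left corner injects blood (and tracer)
which percolates through the capillary continuum and drains through a
venous sink voxel in the lower-right corner.  All physical parameters are
held in :class:`PhantomSpec`; the bolus entering the source follows a
gamma-variate arterial input function (:class:`AIFParams`).

Index convention: cell indices are 1-based ``(row, column)`` with row 1 at
the top, so "upper left" is ``(1, 1)`` and "lower right" is ``(nx, ny)``.
Internally arrays have shape ``(nx, ny)`` = (rows, columns); axis 0 points
downward (+y), axis 1 rightward (+x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "PhantomSpec",
    "AIFParams",
    "SourceField",
    "TimeGrid",
    "build_default_phantom",
    "build_source_field",
    "aif_value",
    "unit_convert",
    "load_config",
    "resolved_config",
]

log = logging.getLogger(__name__)

#: 1 ml/min/100ml expressed in s^-1 (1/60 of a minute, per 100 ml = 100 cm^3).
ML_MIN_100ML = 1.0 / 6000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of the synthetic capillary domain.

    Parameters
    ----------
    nx, ny
        Number of grid cells along rows (vertical) and columns (horizontal).
    L
        Physical side length of the square domain [mm].
    thickness
        Out-of-plane slab thickness [mm]; defaults to ``L`` so that
        volume-normalized perfusion keeps its clinical meaning.
    k
        Scalar isotropic permeability [mm^2].
    mu
        Dynamic viscosity [kPa s].
    phi
        Porosity (fractional blood volume), scalar or per-cell array
        [mm^3/mm^3].
    P_bar
        Target mean perfusion of the whole domain [s^-1]. The source
        strength is derived from it: ``F0 = P_bar * L**2 * thickness``.
    source_index, sink_index
        1-based (row, column) cell coordinates of the arterial source and
        venous sink.
    """

    nx: int = 64
    ny: int = 64
    L: float = 3.0
    thickness: float | None = None
    k: float = 5e-6
    mu: float = 5e-6
    phi: float | np.ndarray = 0.05
    P_bar: float = 50.0 * ML_MIN_100ML
    source_index: tuple[int, int] = (1, 1)
    sink_index: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.thickness is None:
            object.__setattr__(self, "thickness", float(self.L))
        if self.sink_index is None:
            object.__setattr__(self, "sink_index", (self.nx, self.ny))
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2x2")
        if self.L <= 0 or self.thickness <= 0:
            raise ValueError("L and thickness must be positive")
        if self.k <= 0 or self.mu <= 0:
            raise ValueError("permeability and viscosity must be positive")
        phi = np.asarray(self.phi, dtype=float)
        if np.any(phi <= 0) or np.any(phi > 1):
            raise ValueError("porosity must satisfy 0 < phi <= 1")
        if phi.ndim not in (0, 2):
            raise ValueError("phi must be scalar or a (nx, ny) field")
        if phi.ndim == 2 and phi.shape != (self.nx, self.ny):
            raise ValueError(f"phi field must have shape {(self.nx, self.ny)}")
        for name in ("source_index", "sink_index"):
            i, j = getattr(self, name)
            if not (1 <= i <= self.nx and 1 <= j <= self.ny):
                raise ValueError(f"{name} {(i, j)} outside the grid")
        if tuple(self.source_index) == tuple(self.sink_index):
            raise ValueError("source and sink must be distinct cells")
        if self.F0 <= 0:
            raise ValueError("target mean perfusion must be positive")

    # --- derived geometry -------------------------------------------------
    @property
    def hx(self) -> float:
        """Cell width along columns [mm]."""
        return self.L / self.ny

    @property
    def hy(self) -> float:
        """Cell height along rows [mm]."""
        return self.L / self.nx

    @property
    def cell_volume(self) -> float:
        """Volume of one grid cell [mm^3]."""
        return self.hx * self.hy * self.thickness

    @property
    def domain_volume(self) -> float:
        """Total domain volume [mm^3]."""
        return self.L * self.L * self.thickness

    @property
    def F0(self) -> float:
        """Total arterial inflow [mm^3/s], ``P_bar * domain volume``."""
        return self.P_bar * self.domain_volume

    @property
    def phi_field(self) -> np.ndarray:
        """Porosity as a full (nx, ny) array."""
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim == 0:
            return np.full((self.nx, self.ny), float(phi))
        return phi

    @property
    def source_rc0(self) -> tuple[int, int]:
        """0-based (row, col) of the source cell."""
        return (self.source_index[0] - 1, self.source_index[1] - 1)

    @property
    def sink_rc0(self) -> tuple[int, int]:
        """0-based (row, col) of the sink cell."""
        return (self.sink_index[0] - 1, self.sink_index[1] - 1)

    def with_(self, **kwargs) -> "PhantomSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AIFParams:
    """Gamma-variate arterial input function ``c_a(t) = D0 (t-t0)^a e^-(t-t0)/b``.

    Defaults: ``alpha=3``, ``D0=1`` mmol/l/s^alpha, ``beta=1.5`` s, ``t0=0`` s —
    a standard bolus shape peaking at ``t0 + alpha*beta`` = 4.5 s.
    """

    D0: float = 1.0
    alpha: float = 3.0
    beta: float = 1.5
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.D0 < 0:
            raise ValueError("require alpha > 0, beta > 0, D0 >= 0")

    def __call__(self, t):
        return aif_value(self, t)


def aif_value(p: AIFParams, t):
    """Evaluate the gamma-variate AIF at time(s) ``t`` [s] -> [mmol/l].

    Zero for ``t <= t0``; smooth unimodal bolus afterwards.
    """
    t = np.asarray(t, dtype=float)
    tau = t - p.t0
    with np.errstate(invalid="ignore"):
        out = np.where(tau > 0, p.D0 * np.maximum(tau, 0.0) ** p.alpha
                       * np.exp(-np.maximum(tau, 0.0) / p.beta), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SourceField:
    """Per-cell volumetric source density ``Q = Q_so + Q_si`` [mm^3/s/mm^3].

    ``Q_so >= 0`` is nonzero only at the source cell, ``Q_si <= 0`` only at
    the sink; the field integrates to zero over the domain (incompressible
    net balance).
    """

    Q_so: np.ndarray
    Q_si: np.ndarray

    @property
    def Q(self) -> np.ndarray:
        return self.Q_so + self.Q_si

    def net_volume_rate(self, cell_volume: float) -> float:
        """Net volumetric injection [mm^3/s]; zero for a balanced field."""
        return float(np.sum(self.Q) * cell_volume)


def build_source_field(spec: PhantomSpec) -> SourceField:
    """Source/sink density realizing total inflow ``F0`` at the corner cells."""
    Q_so = np.zeros((spec.nx, spec.ny))
    Q_si = np.zeros((spec.nx, spec.ny))
    Q_so[spec.source_rc0] = spec.F0 / spec.cell_volume
    Q_si[spec.sink_rc0] = -spec.F0 / spec.cell_volume
    return SourceField(Q_so=Q_so, Q_si=Q_si)


@dataclass(frozen=True)
class TimeGrid:
    """Simulation time axis: total duration, solver step, output step [s].

    ``dt_sim=None`` lets the transport solver pick a CFL-stable step that
    divides ``dt_out`` exactly.  The default horizon of 90 s lets the bolus
    wash out completely (residual tracer < 0.5% of injected).
    """

    t_end: float = 90.0
    dt_out: float = 0.1
    dt_sim: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.dt_out <= self.t_end):
            raise ValueError("require 0 < dt_out <= t_end")
        if self.dt_sim is not None and not (0 < self.dt_sim <= self.dt_out):
            raise ValueError("require 0 < dt_sim <= dt_out")

    @property
    def output_times(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt_out))
        return np.arange(n + 1) * self.dt_out


# --- units ----------------------------------------------------------------

#: multiplicative factor taking each recognized perfusion unit to s^-1
_TO_PER_SECOND: Mapping[str, float] = {
    "s^-1": 1.0,
    "1/s": 1.0,
    "mm^3 s^-1 mm^-3": 1.0,
    "ml/min/100ml": ML_MIN_100ML,
}


def unit_convert(value, from_unit: str, to_unit: str):
    """Convert perfusion values between s^-1 and ml/min/100ml (exact)."""
    try:
        a = _TO_PER_SECOND[from_unit]
        b = _TO_PER_SECOND[to_unit]
    except KeyError as e:
        raise ValueError(f"unknown perfusion unit {e.args[0]!r}; "
                         f"known: {sorted(_TO_PER_SECOND)}") from None
    return np.asarray(value) * (a / b) if np.ndim(value) else value * (a / b)


def build_default_phantom(**overrides) -> PhantomSpec:
    """The default study configuration.

    64x64 grid on a 3 mm x 3 mm field of view with 3 mm slab thickness,
    arterial source in the upper-left cell, venous sink in the lower-right
    cell, permeability 5e-6 mm^2, viscosity 5e-6 kPa s, uniform porosity
    0.05 and mean perfusion 50 ml/min/100ml.  Any field can be overridden.
    """
    return PhantomSpec(**overrides)


# --- configuration I/O ----------------------------------------------------

_AIF_KEYS = {"D0", "alpha", "beta", "t0"}
_TIME_KEYS = {"t_end", "dt_out", "dt_sim"}


def load_config(path: str | Path) -> tuple[PhantomSpec, AIFParams, TimeGrid]:
    """Read a YAML config whose keys mirror the dataclass field names.

    Top-level sections ``phantom``, ``aif`` and ``time`` are each optional;
    a flat file with bare field names is also accepted.  Unknown keys raise.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    sections = {"phantom": dict(raw.get("phantom", {})),
                "aif": dict(raw.get("aif", {})),
                "time": dict(raw.get("time", {}))}
    for key, val in raw.items():
        if key in ("phantom", "aif", "time"):
            continue
        if key in _AIF_KEYS:
            sections["aif"][key] = val
        elif key in _TIME_KEYS:
            sections["time"][key] = val
        else:
            sections["phantom"][key] = val
    ph = sections["phantom"]
    for name in ("source_index", "sink_index"):
        if name in ph and ph[name] is not None:
            ph[name] = tuple(int(v) for v in ph[name])
    spec = PhantomSpec(**ph)
    aif = AIFParams(**sections["aif"])
    tg = TimeGrid(**sections["time"])
    return spec, aif, tg


def resolved_config(spec: PhantomSpec, aif: AIFParams, tg: TimeGrid) -> dict:
    """Fully resolved configuration (including derived F0) as plain types."""
    phi = np.asarray(spec.phi)
    cfg = {
        "phantom": {
            "nx": spec.nx, "ny": spec.ny, "L": spec.L,
            "thickness": spec.thickness, "k": spec.k, "mu": spec.mu,
            "phi": float(phi) if phi.ndim == 0 else "field",
            "P_bar": spec.P_bar,
            "P_bar_ml_min_100ml": spec.P_bar / ML_MIN_100ML,
            "source_index": list(spec.source_index),
            "sink_index": list(spec.sink_index),
            "F0_mm3_per_s": spec.F0,
        },
        "aif": {"D0": aif.D0, "alpha": aif.alpha, "beta": aif.beta,
                "t0": aif.t0},
        "time": {"t_end": tg.t_end, "dt_out": tg.dt_out,
                 "dt_sim": tg.dt_sim},
    }
    return cfg


def log_config(spec: PhantomSpec, aif: AIFParams, tg: TimeGrid) -> None:
    """Log the fully resolved run configuration."""
    log.info("resolved configuration: %s", resolved_config(spec, aif, tg))
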