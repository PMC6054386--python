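"""Steady incompressible Darcy flow on the phantom grid.

Solves the elliptic pressure equation ``div(-(k/mu) grad p) = Q`` with
no-flow outer boundaries using the standard two-point flux approximation
(TPFA) of porous-media simulation, then recovers the face-centered surface
flux ``q = -(k/mu) grad p`` [mm^3 s^-1 mm^-2].

Flux storage is staggered: ``qx`` lives on vertical faces with positive
sign meaning flow in +x (left to right), ``qy`` on horizontal faces with
positive sign meaning flow in +y (top to bottom).  All domain-boundary
faces carry flux exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import PhantomSpec, SourceField, build_source_field

__all__ = [
    "PressureField",
    "FluxField",
    "solve_pressure",
    "compute_flux",
    "divergence",
    "solve_flow",
]

#: relative residual demanded of the pressure solve
SOLVER_RTOL = 1e-10


@dataclass(frozen=True)
class PressureField:
    """Cell-centered pressure [kPa], defined up to the pinned gauge cell."""

    p: np.ndarray                   # (nx, ny)
    gauge_index: tuple[int, int]    # 1-based (row, col) where p = 0


@dataclass(frozen=True)
class FluxField:
    """Face-centered surface flux [mm^3 s^-1 mm^-2] on a staggered grid.

    ``qx`` has shape (nx, ny+1) — vertical faces, positive rightward;
    ``qy`` has shape (nx+1, ny) — horizontal faces, positive downward.
    """

    qx: np.ndarray
    qy: np.ndarray

    def cell_center_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Average face fluxes to one (vx, vy) vector per cell."""
        vx = 0.5 * (self.qx[:, :-1] + self.qx[:, 1:])
        vy = 0.5 * (self.qy[:-1, :] + self.qy[1:, :])
        return vx, vy

    def speed(self) -> np.ndarray:
        """Cell-centered |q| from the averaged vectors."""
        vx, vy = self.cell_center_vectors()
        return np.hypot(vx, vy)


def _check_spec(spec: PhantomSpec) -> None:
    if spec.k <= 0 or spec.mu <= 0:
        raise ValueError("permeability and viscosity must be positive")


def solve_pressure(spec: PhantomSpec, src: SourceField,
                   rtol: float = SOLVER_RTOL) -> PressureField:
    """TPFA solve of the no-flow-boundary pressure equation.

    The source field must be balanced (net volume rate zero), otherwise the
    homogeneous-Neumann problem has no solution.  The gauge is fixed by
    pinning the sink cell to p = 0; fluxes are gauge-invariant.
    """
    _check_spec(spec)
    nx, ny = spec.nx, spec.ny
    V = spec.cell_volume
    b = src.Q.ravel() * V                       # mm^3/s per cell
    scale = np.abs(b).sum()
    if scale == 0:
        # Q == 0: pressure is constant; return the gauge value everywhere.
        return PressureField(p=np.zeros((nx, ny)), gauge_index=spec.sink_index)
    if abs(b.sum()) > 1e-9 * scale:
        raise ValueError(
            "unbalanced source field: net injection "
            f"{b.sum():.3e} mm^3/s; no-flow boundaries admit no solution")

    lam = spec.k / spec.mu                      # mobility, uniform
    # harmonic mean of the (uniform) mobility across a face is lam itself
    tx = lam * (spec.hy * spec.thickness) / spec.hx   # vertical faces
    ty = lam * (spec.hx * spec.thickness) / spec.hy   # horizontal faces

    n = nx * ny
    idx = np.arange(n).reshape(nx, ny)
    # interior vertical faces pair (i,j)-(i,j+1); horizontal pair (i,j)-(i+1,j)
    pairs = [(idx[:, :-1].ravel(), idx[:, 1:].ravel(), tx),
             (idx[:-1, :].ravel(), idx[1:, :].ravel(), ty)]
    rows, cols, vals = [], [], []
    for i0, i1, t in pairs:
        tv = np.full(i0.size, t)
        rows.append(np.concatenate([i0, i1, i0, i1]))
        cols.append(np.concatenate([i0, i1, i1, i0]))
        vals.append(np.concatenate([tv, tv, -tv, -tv]))
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))

    # pin the gauge cell (sink) to zero: replace its row by identity
    g = idx[spec.sink_rc0]
    A_pinned = A.tolil()
    A_pinned.rows[g] = [g]
    A_pinned.data[g] = [1.0]
    b_pinned = b.copy()
    b_pinned[g] = 0.0
    p = spla.spsolve(A_pinned.tocsr(), b_pinned)

    residual = np.linalg.norm(A @ p - b) / np.linalg.norm(b)
    if residual > rtol:
        raise RuntimeError(f"pressure solve residual {residual:.2e} > {rtol}")
    return PressureField(p=p.reshape(nx, ny), gauge_index=spec.sink_index)


def compute_flux(spec: PhantomSpec, pf: PressureField) -> FluxField:
    """Darcy face fluxes from the cell pressures (two-point differences)."""
    _check_spec(spec)
    p = pf.p
    if p.shape != (spec.nx, spec.ny):
        raise ValueError(f"pressure shape {p.shape} does not match grid "
                         f"{(spec.nx, spec.ny)}")
    lam = spec.k / spec.mu
    qx = np.zeros((spec.nx, spec.ny + 1))
    qy = np.zeros((spec.nx + 1, spec.ny))
    qx[:, 1:-1] = -lam * (p[:, 1:] - p[:, :-1]) / spec.hx
    qy[1:-1, :] = -lam * (p[1:, :] - p[:-1, :]) / spec.hy
    return FluxField(qx=qx, qy=qy)


def divergence(spec: PhantomSpec, q: FluxField) -> np.ndarray:
    """Discrete divergence: net outgoing face flow per cell volume [s^-1]."""
    ax = spec.hy * spec.thickness
    ay = spec.hx * spec.thickness
    net_out = ((q.qx[:, 1:] - q.qx[:, :-1]) * ax
               + (q.qy[1:, :] - q.qy[:-1, :]) * ay)
    return net_out / spec.cell_volume


def solve_flow(spec: PhantomSpec,
               src: SourceField | None = None
               ) -> tuple[PressureField, FluxField, SourceField]:
    """Convenience wrapper: build the source field, solve, differentiate."""
    if src is None:
        src = build_source_field(spec)
    pf = solve_pressure(spec, src)
    return pf, compute_flux(spec, pf), src
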