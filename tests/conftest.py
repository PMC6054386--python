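"""Shared fixtures.

The default-phantom pipeline (flow solve, transport simulation, streamline
map, full discretization study) is expensive, so it is computed once per
session and shared; tests must treat these objects as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import capiflow as cf

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec() -> cf.PhantomSpec:
    return cf.build_default_phantom()


@pytest.fixture(scope="session")
def flow(default_spec):
    """(pressure, flux, source) of the default phantom."""
    return cf.solve_flow(default_spec)


@pytest.fixture(scope="session")
def experiment_result() -> cf.ExperimentResult:
    """The full discretization study on the default phantom."""
    return cf.run_discretization_experiment()


@pytest.fixture(scope="session")
def movie(experiment_result) -> cf.ConcentrationMovie:
    return experiment_result.movie


@pytest.fixture(scope="session")
def ps_result(experiment_result) -> cf.PerfusionMap:
    return experiment_result.ps


def make_channel(nx: int = 2, ny: int = 16, q0: float = 0.02,
                 phi: float = 0.05, L: float = 3.0):
    """Uniform rightward channel flow: inject at the left column, extract
    at the right, constant interior flux q0 [mm/s].  Returns
    (spec, flux, source)."""
    spec = cf.PhantomSpec(nx=nx, ny=ny, L=L, phi=phi,
                          source_index=(1, 1), sink_index=(nx, ny))
    qx = np.zeros((nx, ny + 1))
    qx[:, 1:-1] = q0
    qy = np.zeros((nx + 1, ny))
    q = cf.FluxField(qx=qx, qy=qy)
    V = spec.cell_volume
    area = spec.hy * spec.thickness
    Q_so = np.zeros((nx, ny))
    Q_si = np.zeros((nx, ny))
    Q_so[:, 0] = q0 * area / V
    Q_si[:, -1] = -q0 * area / V
    src = cf.SourceField(Q_so=Q_so, Q_si=Q_si)
    return spec, q, src
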