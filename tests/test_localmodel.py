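"""Local perfusion P_v, local AIF, and the recursive compartment view."""

import numpy as np
import pytest

import capiflow as cf
from capiflow.localmodel import (VoxelFlowDecomposition, decompose_flow,
                                 exponential_kernel_convolve, local_aif,
                                 local_convolution_curve,
                                 recursive_impulse_response)
from conftest import make_channel


@pytest.fixture(scope="module")
def decomp(default_spec, flow):
    _, q, src = flow
    return decompose_flow(default_spec, q, src)


class TestLocalPerfusion:
    def test_channel_cells_inflow_over_spacing(self):
        q0 = 0.02
        spec, q, src = make_channel(nx=2, ny=16, q0=q0)
        pv = cf.local_perfusion_pv(spec, q, src)
        # one inflow face of area A per cell and volume A*hx
        assert np.allclose(pv.values, q0 / spec.hx, rtol=1e-12)

    def test_whole_domain_recovers_target_mean(self, default_spec, flow):
        _, q, src = flow
        pv = cf.local_perfusion_pv(default_spec, q, src, block=64)
        assert pv.values.shape == (1, 1)
        assert pv.values[0, 0] == pytest.approx(default_spec.P_bar, rel=1e-12)

    def test_halving_the_control_volume_doubles_pv(self):
        # serially fed sub-volumes: the same flow is counted in both halves,
        # so P at block b equals exactly twice P at block 2b
        q0 = 0.02
        spec, q, src = make_channel(nx=2, ny=4, q0=q0)
        fine = cf.local_perfusion_pv(spec, q, src, block=1)
        merged = cf.local_perfusion_pv(spec, q, src, block=2)
        assert np.allclose(fine.values, 2.0 * merged.values[0, 0], rtol=1e-12)

    def test_map_mean_exceeds_target_on_default_phantom(self, default_spec,
                                                        flow):
        _, q, src = flow
        pv = cf.local_perfusion_pv(default_spec, q, src)
        assert pv.mean() > default_spec.P_bar

    def test_worked_value_at_cell_32_35(self, default_spec, flow):
        _, q, src = flow
        pv = cf.local_perfusion_pv(default_spec, q, src)
        value = cf.unit_convert(pv.values[31, 34], "s^-1", "ml/min/100ml")
        assert value == pytest.approx(5328.0, rel=0.02)

    def test_invalid_block_factor_rejected(self, default_spec, flow):
        _, q, src = flow
        with pytest.raises(ValueError):
            cf.local_perfusion_pv(default_spec, q, src, block=3)


class TestDecomposition:
    def test_total_inflow_matches_pv_map(self, default_spec, flow, decomp):
        _, q, src = flow
        pv = cf.local_perfusion_pv(default_spec, q, src)
        assert np.allclose(decomp.P, pv.values, rtol=1e-12)

    def test_inflow_equals_outflow_off_source_sink(self, default_spec, flow,
                                                   decomp):
        _, q, src = flow
        from capiflow.transport import _outflow_rate
        out = _outflow_rate(default_spec, q, src)
        interior = np.ones_like(out, dtype=bool)
        interior[default_spec.source_rc0] = False
        interior[default_spec.sink_rc0] = False
        assert np.allclose(decomp.total_inflow[interior], out[interior],
                           rtol=1e-9)

    def test_source_cell_is_purely_arterial(self, decomp):
        assert decomp.P0[0, 0] == pytest.approx(decomp.P[0, 0])
        assert decomp.upstream_neighbors((0, 0)) == []


class TestLocalAif:
    def test_uniform_concentration_passes_through(self, movie, decomp):
        # weights sum to one, so a spatially uniform field is unchanged
        fake = movie.c[:, 32, 32].copy()
        uniform = type(movie)(
            times=movie.times, c=np.broadcast_to(
                fake[:, None, None], movie.c.shape).copy(),
            phi=movie.phi, ca=fake, injected=movie.injected,
            extracted=movie.extracted, cell_volume=movie.cell_volume,
            dt_sim=movie.dt_sim)
        cin = local_aif(uniform, decomp, (30, 30))
        assert np.allclose(cin, fake, rtol=1e-12)

    def test_source_cell_sees_global_aif(self, movie, decomp):
        cin = local_aif(movie, decomp, (1, 1))
        assert np.allclose(cin, movie.ca)


class TestLocalConvolution:
    def test_zero_input_zero_output(self, decomp, movie):
        out = local_convolution_curve(decomp, 0.05,
                                      np.zeros_like(movie.times), (32, 35),
                                      movie.times)
        assert np.all(out == 0)

    def test_step_response_saturates_at_phi_c0(self, decomp, movie):
        c0 = 2.0
        out = local_convolution_curve(decomp, 0.05,
                                      np.full(movie.times.size, c0),
                                      (40, 40), movie.times)
        assert out[-1] == pytest.approx(0.05 * c0, rel=1e-6)
        assert np.all(np.diff(out) >= -1e-15)

    def test_matches_pde_curve_at_interior_cell(self, movie, decomp):
        # the continuous model restricted to one voxel is a one-compartment
        # system driven by its upstream neighbours
        cin = local_aif(movie, decomp, (32, 35))
        conv = local_convolution_curve(decomp, 0.05, cin, (32, 35),
                                       movie.times)
        pde = cf.voxel_tissue_curve(movie, (32, 35))
        assert np.max(np.abs(conv - pde)) / pde.max() < 0.02

    def test_exponential_convolver_against_quadrature(self):
        # J * g for a smooth g, checked against direct numerical convolution
        kappa, dt = 0.8, 0.01
        t = np.arange(0, 20, dt)
        g = np.sin(0.3 * t) ** 2
        J = kappa * np.exp(-kappa * t)
        brute = np.convolve(J, g)[:t.size] * dt
        fast = exponential_kernel_convolve(kappa, g, dt)
        assert np.max(np.abs(fast - brute)) < 5e-3 * brute.max()


class TestRecursiveImpulseResponse:
    def test_source_cell_base_case(self, decomp, movie):
        # purely arterial cell: I = phi J, so I(0) = phi kappa = P_v
        I = recursive_impulse_response(decomp, 0.05, (1, 1), movie.times)
        assert I[0] == pytest.approx(decomp.P[0, 0], rel=1e-12)

    def test_unit_area_property(self, decomp, movie):
        # areas multiply under convolution and each kernel has unit area,
        # so the tissue impulse response integrates to phi
        I = recursive_impulse_response(decomp, 0.05, (1, 20), movie.times)
        assert np.trapezoid(I, movie.times) == pytest.approx(0.05, rel=0.01)

    def test_matches_exact_deconvolution(self, decomp, movie):
        # noise-free deconvolution of the simulated curve with the global
        # AIF recovers the recursive upstream impulse response
        I = recursive_impulse_response(decomp, 0.05, (1, 20), movie.times)
        pde = cf.voxel_tissue_curve(movie, (1, 20))
        ir = cf.bsvd_deconvolve(pde, movie.ca, movie.dt_out,
                                cf.DeconvolutionSettings(svd_threshold=0.0))
        n = movie.times.size
        assert np.max(np.abs(I - ir.I[:n])) / I.max() < 0.05

    def test_forward_convolution_reproduces_pde_curve(self, decomp, movie):
        I = recursive_impulse_response(decomp, 0.05, (1, 20), movie.times)
        conv = np.convolve(I, movie.ca)[:movie.times.size] * movie.dt_out
        pde = cf.voxel_tissue_curve(movie, (1, 20))
        assert np.max(np.abs(conv - pde)) / pde.max() < 0.01

    def test_cycle_detected(self):
        # two cells feeding each other is unphysical for potential flow
        # and must be refused
        in_flux = {d: np.zeros((1, 2)) for d in ("left", "right", "top",
                                                 "bottom")}
        in_flux["right"][0, 0] = 1.0   # cell (0,0) fed by (0,1)
        in_flux["left"][0, 1] = 1.0    # cell (0,1) fed by (0,0)
        decomp = VoxelFlowDecomposition(in_flux=in_flux,
                                        arterial=np.zeros((1, 2)),
                                        cell_volume=1.0)
        with pytest.raises(RuntimeError, match="cycle"):
            recursive_impulse_response(decomp, 0.05, (1, 1),
                                       np.arange(0, 1, 0.1))
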