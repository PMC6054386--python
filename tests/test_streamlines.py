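"""FACT tracing and streamline (global) perfusion P_s."""

import numpy as np
import pytest

import capiflow as cf
from capiflow.streamlines import Streamline


def uniform_flux(spec, q0):
    qx = np.full((spec.nx, spec.ny + 1), q0)
    qy = np.zeros((spec.nx + 1, spec.ny))
    return cf.FluxField(qx=qx, qy=qy)


def synthetic_streamline(lengths, speeds, start="source", end="sink"):
    pts = np.zeros((len(lengths) + 1, 2))
    pts[1:, 0] = np.cumsum(lengths)
    return Streamline(points=pts, seg_len=np.asarray(lengths, float),
                      seg_speed=np.asarray(speeds, float),
                      terminated_start=start, terminated_end=end)


class TestTraceFact:
    def test_uniform_field_gives_straight_horizontal_line(self):
        spec = cf.PhantomSpec(nx=8, ny=8)
        q = uniform_flux(spec, 0.01)
        sl = cf.trace_fact(spec, q, (0.2, 1.3), "forward")
        assert np.allclose(sl.points[:, 1], 1.3)
        assert np.all(np.diff(sl.points[:, 0]) > 0)
        assert sl.terminated_end == "boundary"

    def test_sign_reversal_swaps_directions(self):
        spec = cf.PhantomSpec(nx=8, ny=8)
        q = uniform_flux(spec, 0.01)
        rq = cf.FluxField(qx=-q.qx, qy=-q.qy)
        fwd = cf.trace_fact(spec, q, (1.5, 0.7), "forward")
        back = cf.trace_fact(spec, rq, (1.5, 0.7), "backward")
        assert np.allclose(fwd.points, back.points[::-1])
        assert np.allclose(fwd.seg_len, back.seg_len[::-1])

    def test_seed_outside_domain_rejected(self, default_spec, flow):
        _, q, _ = flow
        with pytest.raises(ValueError):
            cf.trace_fact(default_spec, q, (-0.1, 1.0))
        with pytest.raises(ValueError):
            cf.trace_fact(default_spec, q, (1.0, 5.0), "forward")

    def test_diagonal_seed_connects_source_to_sink(self, default_spec, flow):
        _, q, _ = flow
        sl = cf.trace_fact(default_spec, q, (1.5, 1.45), "both")
        assert sl.terminated_start == "source"
        assert sl.terminated_end == "sink"
        assert sl.complete
        assert sl.length == pytest.approx(sl.seg_len.sum())

    def test_traces_never_run_against_the_flux(self, default_spec, flow):
        # each polyline segment must point along the local flow direction
        _, q, _ = flow
        sl = cf.trace_fact(default_spec, q, (0.8, 2.0), "both")
        vx, vy = q.cell_center_vectors()
        steps = np.diff(sl.points, axis=0)
        mids = 0.5 * (sl.points[:-1] + sl.points[1:])
        i = np.clip((mids[:, 1] / default_spec.hy).astype(int), 0, 63)
        j = np.clip((mids[:, 0] / default_spec.hx).astype(int), 0, 63)
        dots = steps[:, 0] * vx[i, j] + steps[:, 1] * vy[i, j]
        assert np.all(dots > -1e-15)


class TestGlobalPerfusion:
    def test_straight_channel_closed_form(self):
        # uniform speed q0 along length l: P_s = (l / q0)^-1 = q0 / l
        q0, l = 0.04, 2.0
        sl = synthetic_streamline([l / 4] * 4, [q0] * 4)
        assert cf.global_perfusion_ps(sl) == pytest.approx(q0 / l)

    def test_central_volume_identity_uniform_channel(self):
        q0, l, phi = 0.04, 2.0, 0.05
        sl = synthetic_streamline([l / 4] * 4, [q0] * 4)
        T = cf.transit_time(sl, phi)
        assert T == pytest.approx(l * phi / q0)
        assert cf.global_perfusion_ps(sl) * T == pytest.approx(phi)

    def test_incomplete_streamline_rejected(self):
        sl = synthetic_streamline([1.0], [0.1], end="boundary")
        with pytest.raises(ValueError, match="incomplete"):
            cf.global_perfusion_ps(sl)
        with pytest.raises(ValueError):
            cf.transit_time(sl, 0.05)

    def test_central_volume_identity_on_traced_lines(self, default_spec,
                                                     flow):
        _, q, _ = flow
        phi = 0.05
        for seed in [(0.9, 1.1), (2.0, 2.3), (0.4, 2.6)]:
            sl = cf.trace_fact(default_spec, q, seed, "both")
            assert sl.complete
            prod = cf.global_perfusion_ps(sl) * cf.transit_time(sl, phi)
            assert prod == pytest.approx(phi, rel=1e-9)

    def test_value_constant_along_a_streamline(self, default_spec, flow):
        _, q, _ = flow
        sl = cf.trace_fact(default_spec, q, (1.2, 0.9), "both")
        ps_ref = cf.global_perfusion_ps(sl)
        # re-seed from three interior vertices of the same polyline
        for k in (len(sl.points) // 4, len(sl.points) // 2,
                  3 * len(sl.points) // 4):
            x, y = sl.points[k]
            x = min(max(x, 1e-9), default_spec.L - 1e-9)
            y = min(max(y, 1e-9), default_spec.L - 1e-9)
            sl2 = cf.trace_fact(default_spec, q, (x, y), "both")
            assert cf.global_perfusion_ps(sl2) == pytest.approx(ps_ref,
                                                                rel=0.01)

    def test_flow_weighted_transit_time_matches_central_volume(
            self, default_spec, flow):
        # MTT = CBV / CBF = phi V / F0 = 0.05 * 27 / 0.225 = 6 s
        _, q, _ = flow
        spec = default_spec
        h, eps, nsub = spec.hx, 1e-9, 8
        times = []
        for m in range(nsub):
            frac = (m + 0.5) / nsub
            for seed in [((h + eps), frac * h), (frac * h, h + eps)]:
                sl = cf.trace_fact(spec, q, seed, "both")
                if sl.complete:
                    times.append(cf.transit_time(sl, 0.05))
        assert np.mean(times) == pytest.approx(6.0, rel=0.05)


class TestPsMap:
    def test_all_traced_values_positive(self, ps_result):
        vals = ps_result.values[ps_result.valid]
        assert vals.size >= 4094
        assert np.all(vals > 0)

    def test_mean_near_target_perfusion(self, ps_result):
        mean = cf.unit_convert(ps_result.mean(), "s^-1", "ml/min/100ml")
        assert mean == pytest.approx(50.0, rel=0.05)

    def test_block_averaging_preserves_the_mean(self, ps_result):
        fine_mean = np.nanmean(ps_result.values)
        for b in (2, 4, 8, 16, 32, 64):
            coarse = cf.nanblock_average(ps_result.values, b)
            assert np.nanmean(coarse) == pytest.approx(fine_mean, rel=0.01)

    def test_units_conversion_and_csv_export(self, tmp_path, ps_result):
        clin = ps_result.in_units("ml/min/100ml")
        assert clin.mean() == pytest.approx(ps_result.mean() * 6000)
        out = tmp_path / "ps.csv"
        clin.to_csv(out)
        import pandas as pd
        df = pd.read_csv(out)
        assert len(df) == 64 * 64
        assert set(df.columns) >= {"i", "j", "value", "units", "definition"}
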