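"""Dynamic-acquisition adapter: resampling, smoothing, ROI comparison."""

import numpy as np
import pytest

import capiflow as cf
from capiflow.realdata import (DynamicAcquisition, compare_roi_vs_voxelwise,
                               gaussian_smooth, resample_uniform)


def make_acq(nt=40, uniform=True, nx=4, ny=4, nz=3, seed=3):
    rng = np.random.default_rng(seed)
    if uniform:
        times = np.arange(nt) * 1.0
    else:
        times = np.sort(rng.uniform(0, 60, nt))
    data = rng.random((nx, ny, nz, nt))
    aif = rng.random(nt)
    mask = np.ones((nx, ny, nz), dtype=bool)
    return DynamicAcquisition(data=data, times=times, aif=aif, mask=mask)


class TestValidation:
    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            DynamicAcquisition(data=np.zeros((2, 2, 2, 3)),
                               times=np.array([0.0, 2.0, 1.0]),
                               aif=np.zeros(3), mask=np.ones((2, 2, 2), bool))

    def test_shape_mismatches_rejected(self):
        with pytest.raises(ValueError):
            DynamicAcquisition(data=np.zeros((2, 2, 2, 3)),
                               times=np.arange(3.0), aif=np.zeros(4),
                               mask=np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            DynamicAcquisition(data=np.zeros((2, 2, 2, 3)),
                               times=np.arange(3.0), aif=np.zeros(3),
                               mask=np.ones((2, 2), bool))


class TestResample:
    def test_identity_on_already_uniform(self):
        acq = make_acq()
        out = resample_uniform(acq, 1.0)
        assert np.allclose(out.data, acq.data)
        assert np.allclose(out.aif, acq.aif)

    def test_linear_curves_reproduced_exactly(self):
        times = np.array([0.0, 1.0, 3.0, 7.0, 10.0])
        data = np.tile(2.0 * times + 1.0, (2, 2, 2, 1))
        acq = DynamicAcquisition(data=data, times=times, aif=3.0 * times,
                                 mask=np.ones((2, 2, 2), bool))
        out = resample_uniform(acq, 0.5)
        assert np.allclose(out.data[0, 0, 0], 2.0 * out.times + 1.0)
        assert np.allclose(out.aif, 3.0 * out.times)

    def test_down_then_upsample_error_bounded(self):
        # piecewise-linear interpolation error <= h^2/8 * max|f''|
        t = np.arange(0, 30, 0.1)
        f = np.sin(0.5 * t)
        acq = DynamicAcquisition(
            data=np.tile(f, (1, 1, 1, 1)), times=t, aif=f,
            mask=np.ones((1, 1, 1), bool))
        coarse = resample_uniform(acq, 1.0)
        fine = resample_uniform(coarse, 0.1)
        n = fine.times.size
        bound = (1.0 ** 2 / 8) * 0.25 + 1e-12
        assert np.max(np.abs(fine.aif - np.sin(0.5 * fine.times[:n]))) <= bound

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            resample_uniform(make_acq(), -1.0)


class TestSmoothing:
    def test_sigma_zero_is_identity(self):
        acq = make_acq()
        assert gaussian_smooth(acq, 0.0) is acq

    def test_constant_volume_preserved(self):
        acq = make_acq(nx=6, ny=6, nz=6)
        const = DynamicAcquisition(data=np.full_like(acq.data, 2.5),
                                   times=acq.times, aif=acq.aif,
                                   mask=acq.mask)
        out = gaussian_smooth(const, 1.0, 5)
        assert np.allclose(out.data, 2.5)

    def test_centered_blob_intensity_preserved(self):
        data = np.zeros((11, 11, 11, 1))
        data[4:7, 4:7, 4:7, 0] = 1.0
        acq = DynamicAcquisition(data=data, times=np.array([0.0]),
                                 aif=np.array([1.0]),
                                 mask=np.ones((11, 11, 11), bool))
        out = gaussian_smooth(acq, 1.0, 5)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(make_acq(), 1.0, 4)


@pytest.fixture(scope="module")
def phantom_acq(movie):
    # the synthetic phantom movie recast as a single-slice acquisition,
    # spatially coarsened and time-decimated to keep deconvolution cheap
    C = cf.block_average(movie.C, 4)[::2]
    data = C.transpose(1, 2, 0)[:, :, None, :]
    return DynamicAcquisition(data=data, times=movie.times[::2],
                              aif=movie.ca[::2],
                              mask=np.ones(data.shape[:3], bool))


class TestRoiComparison:
    def test_voxelwise_mean_exceeds_whole_roi(self, phantom_acq):
        out = compare_roi_vs_voxelwise(phantom_acq)
        assert out["voxelwise_mean"] > out["whole_roi"]
        assert out["overestimation_re_percent"] > 0

    def test_whole_roi_near_true_mean_perfusion(self, phantom_acq):
        out = compare_roi_vs_voxelwise(phantom_acq)
        assert out["whole_roi"] == pytest.approx(50.0 / 6000.0, rel=0.10)

    def test_single_voxel_mask_degenerates(self, phantom_acq):
        mask = np.zeros(phantom_acq.data.shape[:3], bool)
        mask[10, 10, 0] = True
        single = DynamicAcquisition(data=phantom_acq.data,
                                    times=phantom_acq.times,
                                    aif=phantom_acq.aif, mask=mask)
        out = compare_roi_vs_voxelwise(single)
        assert out["voxelwise_mean"] == pytest.approx(out["whole_roi"])
        assert out["n_voxels"] == 1

    def test_empty_mask_rejected(self, phantom_acq):
        empty = DynamicAcquisition(data=phantom_acq.data,
                                   times=phantom_acq.times,
                                   aif=phantom_acq.aif,
                                   mask=np.zeros(phantom_acq.data.shape[:3],
                                                 bool))
        with pytest.raises(ValueError, match="mask"):
            compare_roi_vs_voxelwise(empty)

    def test_nonuniform_sampling_rejected(self):
        acq = make_acq(uniform=False)
        with pytest.raises(ValueError, match="uniform"):
            compare_roi_vs_voxelwise(acq)
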