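import math

import numpy as np
import pytest

from casemap.normative import NormativeCohort
from casemap.single_case_stats import crawford_howell_t
from casemap.synthetic import SimulationConfig, simulate_gm_images, sphere_mask
from casemap.voxelwise import (
    FWHM_TO_SIGMA,
    compute_analysis_mask,
    gaussian_smooth,
    threshold_binarize,
    voxelwise_single_case,
)

from conftest import make_image


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self, rng):
        img = make_image(rng.random((12, 12, 12)))
        out = gaussian_smooth(img, 0.0)
        assert np.array_equal(out.data, img.data)

    def test_fwhm_sigma_conversion_constant(self):
        # 8 mm FWHM on 2 mm voxels -> sigma = 8 / 2.3548 / 2 voxels
        assert FWHM_TO_SIGMA == pytest.approx(2.3548200450309493)
        assert 8.0 / FWHM_TO_SIGMA / 2.0 == pytest.approx(1.69864, abs=1e-5)

    def test_mass_conserved(self, rng):
        img = make_image(rng.random((16, 16, 16)))
        out = gaussian_smooth(img, 6.0)
        assert out.data.sum() == pytest.approx(img.data.sum(), rel=1e-6)

    def test_delta_matches_closed_form_gaussian(self):
        size = 33
        data = np.zeros((size, size, size))
        data[16, 16, 16] = 1.0
        img = make_image(data, voxel_size=(2.0, 2.0, 2.0))
        fwhm = 6.0
        out = gaussian_smooth(img, fwhm)
        sigma = fwhm / FWHM_TO_SIGMA / 2.0  # in voxels
        coords = np.arange(size) - 16.0
        g = np.exp(-(coords**2) / (2 * sigma**2))
        g /= g.sum()
        expected = g[:, None, None] * g[None, :, None] * g[None, None, :]
        assert np.max(np.abs(out.data - expected)) < 1e-6

    def test_anisotropic_voxels_get_anisotropic_kernels(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        out = gaussian_smooth(make_image(data, voxel_size=(1.0, 2.0, 4.0)), 8.0)
        # spread (in voxels) is larger along the fine axis: at 4 voxels from the
        # peak the fine-axis profile is higher than the coarse-axis profile
        assert out.data[14, 10, 10] > out.data[10, 10, 14]

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            gaussian_smooth(make_image(rng.random((4, 4, 4))), -1.0)


class TestAnalysisMask:
    def test_zero_corner_excluded(self, rng):
        imgs = []
        for _ in range(4):
            data = rng.uniform(0.3, 0.8, (8, 8, 8))
            data[:2, :2, :2] = 0.0
            imgs.append(make_image(data))
        mask = compute_analysis_mask(imgs)
        assert mask.data[:2, :2, :2].sum() == 0
        assert mask.data[4:, 4:, 4:].all()

    def test_constant_voxel_excluded_by_sd_floor(self, rng):
        imgs = [make_image(rng.uniform(0.3, 0.8, (6, 6, 6))) for _ in range(4)]
        for img in imgs:
            img.data[3, 3, 3] = 0.5  # identical nonzero across controls
        mask = compute_analysis_mask(imgs)
        assert mask.data[3, 3, 3] == 0

    def test_floors_zero_keeps_varying_voxels(self, rng):
        imgs = [make_image(rng.random((6, 6, 6))) for _ in range(3)]
        mask = compute_analysis_mask(imgs, gm_floor=0.0, sd_floor=0.0)
        stack = np.stack([i.data for i in imgs])
        assert np.array_equal(mask.data.astype(bool), stack.std(0, ddof=1) >= 0.0)

    def test_grid_mismatch_rejected(self, rng):
        a = make_image(rng.random((6, 6, 6)))
        b = make_image(rng.random((7, 6, 6)))
        with pytest.raises(ValueError, match="grid"):
            compute_analysis_mask([a, b])


class TestVoxelwiseSingleCase:
    def _stack(self, rng, n=8, shape=(10, 10, 10)):
        base = rng.uniform(0.4, 0.8, shape)
        controls = [make_image(base + rng.normal(0, 0.05, shape)) for _ in range(n)]
        return base, controls

    def test_subject_equal_to_mean_gives_zero_t(self, rng):
        _, controls = self._stack(rng)
        mean = np.mean([c.data for c in controls], axis=0)
        stat = voxelwise_single_case(make_image(mean), controls, tails="less", fwhm_mm=0)
        inside = stat.mask.data.astype(bool)
        assert np.allclose(stat.t.data[inside], 0.0)
        assert np.allclose(stat.p.data[inside], 0.5)
        stat2 = voxelwise_single_case(make_image(mean), controls, tails="two", fwhm_mm=0)
        assert np.allclose(stat2.p.data[inside], 1.0)

    def test_matches_scalar_operation_per_voxel(self, rng):
        _, controls = self._stack(rng)
        subject = make_image(rng.uniform(0.3, 0.9, (10, 10, 10)))
        for tails in ("less", "two"):
            stat = voxelwise_single_case(subject, controls, tails=tails, fwhm_mm=0)
            inside = np.argwhere(stat.mask.data)
            pick = inside[rng.choice(len(inside), 25, replace=False)]
            for i, j, k in pick:
                cohort = NormativeCohort(
                    biomarker_key=("voxel", "volume_mm3"),
                    values=[c.data[i, j, k] for c in controls],
                    control_ids=[str(m) for m in range(len(controls))],
                    age_window=(0, 100),
                )
                t_ref, df_ref, p_ref = crawford_howell_t(
                    subject.data[i, j, k], cohort, tails=tails
                )
                assert stat.df == df_ref
                assert stat.t.data[i, j, k] == pytest.approx(t_ref, abs=1e-10)
                assert stat.p.data[i, j, k] == pytest.approx(p_ref, abs=1e-10)

    def test_nan_outside_mask(self, rng):
        _, controls = self._stack(rng)
        for c in controls:
            c.data[0, 0, 0] = 0.0
        subject = make_image(rng.uniform(0.3, 0.9, (10, 10, 10)))
        stat = voxelwise_single_case(subject, controls, fwhm_mm=0)
        assert math.isnan(stat.t.data[0, 0, 0])
        assert math.isnan(stat.p.data[0, 0, 0])

    def test_implanted_sphere_minimum_inside(self):
        config = SimulationConfig(
            seed=42, n_controls=20, n_patients=1,
            grid_shape=(24, 24, 24), image_noise_sd=0.05,
            implants_voxel=[("pat000", (12, 12, 12), 4.0, 4.0)],
        )
        images = simulate_gm_images(config)
        controls = [images[f"ctrl{i:03d}"] for i in range(20)]
        stat = voxelwise_single_case(images["pat000"], controls, tails="less", fwhm_mm=4.0)
        idx = np.unravel_index(np.nanargmin(stat.t.data), stat.t.data.shape)
        assert sphere_mask((24, 24, 24), (12, 12, 12), 4.0)[idx]


class TestThresholdBinarize:
    def _stat(self, rng, p_values):
        _, controls = TestVoxelwiseSingleCase()._stack(rng, shape=p_values.shape)
        subject = make_image(rng.uniform(0.3, 0.9, p_values.shape))
        stat = voxelwise_single_case(subject, controls, tails="less", fwhm_mm=0)
        stat.p.data[stat.mask.data.astype(bool)] = p_values[stat.mask.data.astype(bool)]
        return stat

    def test_all_half_p_gives_empty_map(self, rng):
        stat = self._stat(rng, np.full((6, 6, 6), 0.5))
        assert threshold_binarize(stat, 0.005).count == 0

    def test_strict_threshold_boundary(self, rng):
        p = np.full((6, 6, 6), 0.5)
        p[2, 2, 2] = 0.004
        p[3, 3, 3] = 0.005  # exactly at threshold: excluded
        stat = self._stat(rng, p)
        binary = threshold_binarize(stat, 0.005)
        assert binary.count == 1
        assert binary.data.data[2, 2, 2] == 1
        assert binary.data.data[3, 3, 3] == 0

    def test_values_exactly_binary_and_within_mask(self, rng):
        stat = self._stat(rng, np.full((6, 6, 6), 0.001))
        binary = threshold_binarize(stat, 0.005)
        assert set(np.unique(binary.data.data)) <= {0, 1}
        assert binary.count <= int(stat.mask.data.sum())

    def test_invalid_threshold(self, rng):
        stat = self._stat(rng, np.full((6, 6, 6), 0.5))
        with pytest.raises(ValueError):
            threshold_binarize(stat, 0.0)
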