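"""3D IF quantification: filtering, segmentation, shell, ratios, statistics."""

import numpy as np
import pytest

from fibermod.image_quant import (compare_groups, measure_cell,
                                  median_filter_3d, quantify_stack,
                                  segment_chromosomes, shell_mask,
                                  simulate_cells)


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        vol = np.full((8, 16, 16), 7.0)
        np.testing.assert_array_equal(median_filter_3d(vol), vol)

    def test_impulse_rejected(self):
        vol = np.zeros((8, 16, 16))
        vol[4, 8, 8] = 100.0
        assert median_filter_3d(vol).max() == 0.0

    def test_matches_nested_loop_oracle(self, rng):
        vol = rng.random((11, 11, 7))
        got = median_filter_3d(vol, kernel_yxz=(3, 3, 3))
        kz = ky = kx = 3
        # edge-value-repeating reflection, matching the filter's padding
        pad = np.pad(vol, 1, mode="symmetric")
        expected = np.empty_like(vol)
        for z in range(vol.shape[0]):
            for y in range(vol.shape[1]):
                for x in range(vol.shape[2]):
                    expected[z, y, x] = np.median(
                        pad[z:z + kz, y:y + ky, x:x + kx])
        np.testing.assert_allclose(got, expected)

    def test_even_or_oversized_kernel_rejected(self):
        vol = np.zeros((4, 8, 8))
        with pytest.raises(ValueError, match="odd"):
            median_filter_3d(vol, kernel_yxz=(4, 7, 3))
        with pytest.raises(ValueError, match="larger"):
            median_filter_3d(vol, kernel_yxz=(7, 7, 5))


def ellipsoid(shape, center, radii):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return (((zz - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2
            + ((xx - center[2]) / radii[2]) ** 2) <= 1.0


class TestSegmentation:
    def test_single_ellipsoid_recovered(self, rng):
        shape = (24, 64, 64)
        truth = ellipsoid(shape, (12, 32, 32), (7, 18, 18))
        dapi = np.where(truth, 1000.0, 100.0) + rng.normal(0, 50, shape)
        labels = segment_chromosomes(median_filter_3d(dapi), min_size=50)
        assert labels.max() == 1
        overlap = ((labels > 0) & truth).sum() / truth.sum()
        assert overlap >= 0.95

    def test_two_separated_objects(self, rng):
        shape = (16, 64, 64)
        truth = (ellipsoid(shape, (8, 16, 16), (5, 10, 10))
                 | ellipsoid(shape, (8, 48, 48), (5, 10, 10)))
        dapi = np.where(truth, 1000.0, 100.0) + rng.normal(0, 50, shape)
        labels = segment_chromosomes(median_filter_3d(dapi), min_size=50)
        assert labels.max() == 2

    def test_min_size_filters_everything(self, rng, caplog):
        shape = (16, 32, 32)
        truth = ellipsoid(shape, (8, 16, 16), (4, 8, 8))
        dapi = np.where(truth, 1000.0, 100.0)
        labels = segment_chromosomes(median_filter_3d(dapi), min_size=10 ** 6)
        assert labels.max() == 0


class TestShellMask:
    def test_single_voxel_shell_is_ball_minus_center(self):
        from skimage.morphology import ball

        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        shell = shell_mask(mask, radius=2)
        expected = np.zeros_like(mask)
        expected[2:7, 2:7, 2:7] = ball(2).astype(bool)
        expected[4, 4, 4] = False
        np.testing.assert_array_equal(shell, expected)

    def test_border_clipping_keeps_disjointness(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[0:2, 0:2, 0:2] = True
        shell = shell_mask(mask, radius=2)
        assert not (shell & mask).any()
        assert shell.any()

    def test_cube_shell_volume_near_surface_times_radius(self):
        mask = np.zeros((60, 60, 60), bool)
        mask[10:50, 10:50, 10:50] = True
        shell = shell_mask(mask, radius=2)
        surface = 6 * 40 * 40
        assert abs(shell.sum() - 2 * surface) < 0.15 * 2 * surface

    def test_empty_or_full_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shell_mask(np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError, match="shell"):
            shell_mask(np.ones((4, 4, 4), bool))


class TestMeasureCell:
    def _masks(self):
        mask = np.zeros((10, 20, 20), bool)
        mask[3:7, 5:15, 5:15] = True
        return mask, shell_mask(mask, 2)

    def test_constant_intensities_give_exact_ratio(self):
        mask, shell = self._masks()
        sig = np.where(mask, 10.0, 5.0)
        m = measure_cell(sig, mask, shell)
        assert m.ratio == pytest.approx(2.0)
        m1 = measure_cell(np.full(mask.shape, 3.0), mask, shell)
        assert m1.ratio == pytest.approx(1.0)

    def test_ratio_invariant_to_positive_scaling(self, rng):
        mask, shell = self._masks()
        sig = rng.random(mask.shape) + 0.5
        r1 = measure_cell(sig, mask, shell).ratio
        r2 = measure_cell(37.5 * sig, mask, shell).ratio
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_zero_shell_mean_rejected(self):
        mask, shell = self._masks()
        with pytest.raises(ZeroDivisionError):
            measure_cell(np.where(mask, 1.0, 0.0), mask, shell)


class TestCompareGroups:
    @staticmethod
    def _cohort(rng, spec):
        from fibermod.image_quant import CellMeasurement

        out = []
        for group, mean, sd, n in spec:
            for i in range(n):
                r = float(rng.normal(mean, sd))
                out.append(CellMeasurement(f"{group}{i}", group, r, 1.0, r,
                                           100, 100))
        return out

    def test_identical_groups_null(self, rng):
        vals = rng.normal(2.0, 0.1, 10)
        meas = self._cohort(rng, [])
        from fibermod.image_quant import CellMeasurement

        for g in ("a", "ref"):
            meas += [CellMeasurement(f"{g}{i}", g, v, 1.0, v, 100, 100)
                     for i, v in enumerate(vals)]
        df = compare_groups(meas, "ref").set_index("group")
        assert df.loc["a", "t"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc["a", "p"] == pytest.approx(1.0)

    def test_group_swap_negates_t_preserves_p(self, rng):
        meas = self._cohort(rng, [("a", 3.0, 0.1, 10), ("b", 1.0, 0.1, 10)])
        d1 = compare_groups(meas, "b").set_index("group")
        d2 = compare_groups(meas, "a").set_index("group")
        assert d1.loc["a", "t"] == pytest.approx(-d2.loc["b", "t"])
        assert d1.loc["a", "p"] == pytest.approx(d2.loc["b", "p"])

    def test_separated_groups_extreme_p(self, rng):
        meas = self._cohort(rng, [("hi", 3.0, 0.1, 10), ("ref", 1.0, 0.1, 10)])
        df = compare_groups(meas, "ref").set_index("group")
        assert df.loc["hi", "p"] < 1e-10

    def test_missing_reference_rejected(self, rng):
        meas = self._cohort(rng, [("a", 1.0, 0.1, 5)])
        with pytest.raises(ValueError):
            compare_groups(meas, "ref")


class TestSimulateCells:
    def test_noiseless_phantom_recovered_exactly(self):
        cells, truth = simulate_cells(
            [dict(group="g", true_ratio=2.5, cytoplasm_level=100.0,
                  noise_sd=0.0, n_cells=2)], seed=1)
        for c in cells:
            m = quantify_stack(c["dapi"], c["signal"], c["cell_id"],
                               c["group"])
            assert m.ratio == pytest.approx(2.5, rel=1e-6)

    def test_unit_ratio_group_centered_on_one(self):
        cells, _ = simulate_cells(
            [dict(group="null", true_ratio=1.0, cytoplasm_level=150.0,
                  noise_sd=0.1, n_cells=5)], seed=2)
        ratios = [quantify_stack(c["dapi"], c["signal"]).ratio for c in cells]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)

    def test_cohort_ranked_by_true_ratio(self):
        spec = [dict(group=f"g{r}", true_ratio=r, cytoplasm_level=200.0,
                     noise_sd=0.1, n_cells=3)
                for r in (3.0, 2.0, 1.2, 1.0)]
        cells, _ = simulate_cells(spec, seed=3)
        means = {}
        for c in cells:
            means.setdefault(c["group"], []).append(
                quantify_stack(c["dapi"], c["signal"]).ratio)
        ordered = sorted(means, key=lambda g: -np.mean(means[g]))
        assert ordered == ["g3.0", "g2.0", "g1.2", "g1.0"]
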