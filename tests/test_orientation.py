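import numpy as np
import pytest

from fbrseg.orientation import (
    NOT_ORIENTED,
    OrientationKernelBank,
    OrientationMap,
    build_kernel_bank,
    circular_moving_average,
    collagen_orientation,
    elliptical_footprint,
    filter_orientation_clusters,
    mask_exclusion,
    orientation_histogram,
    orientation_map,
    relative_orientation,
    scaffold_mask_postprocess,
    variance_filter,
)
from fbrseg.synthetic import make_oriented_fibers, make_scaffold_grid


def circ_err(a, b):
    return min((a - b) % 180, (b - a) % 180)


class TestKernelBank:
    def test_bank_shape_and_angles(self, bank):
        assert bank.kernels.shape == (360, 33, 33)

    def test_positive_and_negative_normalization(self, bank):
        for k in bank.kernels:
            assert k[k > 0].sum() == pytest.approx(1.0, abs=1e-9)
            assert k[k < 0].sum() == pytest.approx(-1.0, abs=1e-9)
            assert abs(k.sum()) < 1e-9

    def test_polarity_antisymmetry(self, bank):
        assert np.allclose(bank.kernels[:180], -bank.kernels[180:], atol=1e-12)

    def test_zero_outside_radius(self, bank):
        r, c = np.mgrid[0:33, 0:33]
        outside = (r - 16) ** 2 + (c - 16) ** 2 > 15**2
        assert np.all(bank.kernels[:, outside] == 0.0)

    def test_center_line_coefficients_are_zero(self, bank):
        # for the horizontal kernel the central row lies exactly on the line
        assert np.all(bank.kernels[0][16, :] == 0.0)

    def test_quarter_turn_rotates_kernel_exactly(self, bank):
        for theta in (0, 30, 45, 77):
            assert np.allclose(bank.kernels[theta + 90], np.rot90(bank.kernels[theta]), atol=1e-12)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            build_kernel_bank(size=32)

    def test_save_load_roundtrip(self, bank, tmp_path):
        bank.save(tmp_path / "bank")
        again = OrientationKernelBank.load(tmp_path / "bank")
        assert np.array_equal(again.kernels, bank.kernels)
        assert (again.size, again.radius, again.n_angles) == (33, 15, 360)


class TestOrientationMap:
    def test_blank_image_all_not_oriented(self, bank):
        om = orientation_map(np.zeros((64, 64)), bank, 0.5)
        assert not om.oriented.any()

    def test_response_bounded_by_one_on_binary_image(self, bank, rng):
        img = (rng.random((64, 64)) > 0.5).astype(float)
        om = orientation_map(img, bank, 0.06)
        assert om.magnitude.max() <= 1.0 + 1e-6

    def test_stripe_interior_edges_recover_planted_angle(self, bank):
        img, _ = make_oriented_fibers(size=128, angle=30.0)
        om = orientation_map(img, bank, 0.5)
        angles = om.angle[om.oriented]
        frac_close = np.mean([circ_err(a, 30) <= 1 for a in angles])
        assert frac_close > 0.9

    def test_border_forced_not_oriented(self, bank):
        img, _ = make_oriented_fibers(size=64, angle=0.0)
        om = orientation_map(img, bank, 0.06, border=4)
        assert not om.oriented[:4, :].any()
        assert not om.oriented[-4:, :].any()
        assert not om.oriented[:, :4].any()
        assert not om.oriented[:, -4:].any()


class TestFilters:
    def _map(self, angle, shape=(32, 32)):
        a = np.full(shape, angle, dtype=np.int16)
        return OrientationMap(a, np.ones(shape))

    def test_variance_filter_discards_flat_response_pixels(self, bank):
        shape = (8, 8)
        stack = np.full((180, *shape), 0.3, dtype=np.float32)
        stack[:, 0, 0] = 0.0
        stack[17, 0, 0] = 0.9      # one dominant kernel: high variance, kept
        om = OrientationMap(np.full(shape, 17, dtype=np.int16), np.ones(shape), stack)
        out = variance_filter(om)
        assert out.angle[0, 0] == 17
        assert np.all(out.angle[0, 1:] == NOT_ORIENTED)  # equal responses: var 0

    def test_variance_threshold_monotonicity(self, bank):
        img, _ = make_oriented_fibers(size=96, angle=40.0)
        om = orientation_map(img, bank, 0.06)
        counts = [
            variance_filter(om, var_threshold=t).oriented.sum() for t in (1e-5, 3.5e-4, 1e-2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_mask_exclusion_directions(self):
        om = self._map(25)
        scaffold = np.zeros((32, 32), dtype=bool)
        assert mask_exclusion(om, scaffold).oriented.all()     # empty mask: unchanged
        scaffold[:] = True
        assert not mask_exclusion(om, scaffold).oriented.any()  # full mask: all removed
        half = np.zeros((32, 32), dtype=bool)
        half[:, :16] = True
        out = mask_exclusion(om, half)
        assert not out.oriented[:, :16].any() and out.oriented[:, 16:].all()

    def test_mask_exclusion_literal_switch(self):
        om = self._map(25)
        half = np.zeros((32, 32), dtype=bool)
        half[:, :16] = True
        out = mask_exclusion(om, half, keep_outside=False)
        assert out.oriented[:, :16].all() and not out.oriented[:, 16:].any()

    def test_cluster_filter_area_rule(self):
        angle = np.full((32, 32), NOT_ORIENTED, dtype=np.int16)
        angle[2:4, 2:7] = 10     # 10 px cluster: removed
        angle[10:14, 10:15] = 20  # 20 px cluster: kept
        om = OrientationMap(angle, np.ones((32, 32)))
        out = filter_orientation_clusters(om, min_area=15)
        assert not (out.angle == 10).any()
        assert (out.angle == 20).sum() == 20

    def test_cluster_filter_trivial_cases(self):
        empty = OrientationMap(np.full((8, 8), NOT_ORIENTED, dtype=np.int16), np.zeros((8, 8)))
        assert not filter_orientation_clusters(empty).oriented.any()
        full = self._map(5, (8, 8))
        assert filter_orientation_clusters(full).oriented.all()

    def test_pipeline_only_removes_pixels(self, bank):
        img, _ = make_oriented_fibers(size=96, angle=70.0)
        om = orientation_map(img, bank, 0.06)
        n0 = om.oriented.sum()
        om1 = variance_filter(om)
        om2 = mask_exclusion(om1, np.zeros_like(img, dtype=bool))
        om3 = filter_orientation_clusters(om2)
        ns = [o.oriented.sum() for o in (om1, om2, om3)]
        assert all(n <= n0 for n in ns) and ns[2] <= ns[1] <= ns[0]


class TestHistogram:
    def test_uniform_unchanged_by_smoothing(self):
        h = circular_moving_average(np.full(180, 4.0))
        assert np.allclose(h, 4.0)

    def test_delta_spreads_over_seven_wraparound_bins(self):
        counts = np.zeros(180)
        counts[0] = 14.0
        sm = circular_moving_average(counts)
        hit = [177, 178, 179, 0, 1, 2, 3]
        assert np.allclose(sm[hit], 2.0)
        assert sm.sum() == pytest.approx(14.0)

    def test_total_count_conserved(self, rng):
        counts = rng.integers(0, 50, 180).astype(float)
        assert circular_moving_average(counts).sum() == pytest.approx(counts.sum())

    def test_preferential_is_raw_mode_ties_to_smallest(self):
        angle = np.full((10, 10), NOT_ORIENTED, dtype=np.int16)
        angle[0, :5] = 40
        angle[1, :5] = 90
        om = OrientationMap(angle, np.ones((10, 10)))
        assert orientation_histogram(om).preferential == 40

    def test_empty_map_has_no_preferential(self):
        om = OrientationMap(np.full((8, 8), NOT_ORIENTED, dtype=np.int16), np.zeros((8, 8)))
        assert orientation_histogram(om).preferential is None


class TestRelative:
    def _hist_at(self, angle):
        a = np.full((20, 20), angle, dtype=np.int16)
        return orientation_histogram(OrientationMap(a, np.ones((20, 20))))

    def test_parallel_peaks_at_zero(self):
        rel = relative_orientation(self._hist_at(37), 37)
        assert rel.preferential == 0

    def test_perpendicular_peaks_at_ninety(self):
        rel = relative_orientation(self._hist_at(127), 37)
        assert rel.preferential == 90

    def test_common_shift_invariance(self):
        rel_a = relative_orientation(self._hist_at(60), 20)
        rel_b = relative_orientation(self._hist_at(100), 60)
        assert np.array_equal(rel_a.counts, rel_b.counts)

    def test_missing_scaffold_reference_raises(self):
        with pytest.raises(ValueError):
            relative_orientation(self._hist_at(10), None)


class TestRecovery:
    @pytest.mark.parametrize("angle", [0, 13, 30, 45, 66, 90, 120, 135, 161])
    def test_planted_angle_recovered(self, bank, angle):
        img, _ = make_oriented_fibers(size=256, angle=float(angle))
        om = orientation_map(img, bank, 0.5, keep_stack=False)
        om = filter_orientation_clusters(om)
        h = orientation_histogram(om)
        assert circ_err(h.preferential, angle) <= 1

    def test_quarter_rotation_equivariance(self, bank):
        img, _ = make_oriented_fibers(size=192, angle=25.0)
        om = orientation_map(img, bank, 0.5, keep_stack=False)
        h = orientation_histogram(filter_orientation_clusters(om))
        om_r = orientation_map(np.rot90(img), bank, 0.5, keep_stack=False)
        h_r = orientation_histogram(filter_orientation_clusters(om_r))
        assert circ_err(h_r.preferential, (h.preferential + 90) % 180) <= 1

    def test_collagen_pipeline_on_crossed_fibers(self, bank):
        img, truth = make_oriented_fibers(size=192, mode="crossed", angles=(20.0, 110.0))
        _, hist = collagen_orientation(img, bank, magnitude_threshold=0.5)
        # both families present: mass near both planted angles
        near20 = sum(hist.counts[(20 + d) % 180] for d in range(-2, 3))
        near110 = sum(hist.counts[(110 + d) % 180] for d in range(-2, 3))
        assert near20 > 0.2 * hist.counts.sum()
        assert near110 > 0.2 * hist.counts.sum()


class TestScaffoldPostprocess:
    def test_empty_in_empty_out(self):
        skel, dil = scaffold_mask_postprocess(np.zeros((64, 64), dtype=bool))
        assert not skel.any() and not dil.any()

    def test_small_blob_removed_by_opening(self):
        m = np.zeros((128, 128), dtype=bool)
        m[10:15, 10:15] = True  # 5x5: smaller than the 20x20 opening element
        skel, dil = scaffold_mask_postprocess(m)
        assert not skel.any() and not dil.any()

    def test_bar_skeleton_is_central_line(self):
        m = np.zeros((160, 160), dtype=bool)
        m[70:95, 10:150] = True  # thick horizontal bar, center row 82
        skel, dil = scaffold_mask_postprocess(m)
        assert dil.sum() > m.sum()  # dilation fattens the opened bar
        rows = np.nonzero(skel.any(axis=1))[0]
        assert len(rows) > 0
        assert rows.min() >= 75 and rows.max() <= 90  # thin band near the centerline

    def test_elliptical_footprints_degenerate_to_squares(self):
        assert elliptical_footprint(2, 2).all()
        assert elliptical_footprint(3, 3).all()
        e = elliptical_footprint(20, 20)
        assert e[10, 10] and not e[0, 0]  # corners excluded at larger sizes
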