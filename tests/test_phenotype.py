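import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from trenchroot import (CumulativeProfile, FrameSpec, RootMask, Skeleton,
                        cumulative_profile, fold_half, phenotype_image,
                        quantile_distance, root_length_cm, skeletonize_mask)
from trenchroot.synth import truncated_exponential_median


class TestFoldHalf:
    def test_single_left_pixel_maps_to_distance_column(self):
        m = np.zeros((8, 32), np.uint8)
        m[3, 16 - 10] = 1
        folded = fold_half(m, hill_column=16)
        assert folded[3, 10] == 1 and folded.sum() == 1

    def test_symmetric_mask_folds_onto_one_half(self, rng):
        half = (rng.random((8, 16)) > 0.7).astype(np.uint8)
        m = np.concatenate([half[:, ::-1], half[:, 1:]], axis=1)  # mirror about col 15
        folded = fold_half(m, hill_column=15)
        assert np.array_equal(folded[:, :16], half)

    def test_overlap_is_or_not_sum(self):
        m = np.zeros((4, 32), np.uint8)
        m[1, 16 - 10] = 1
        m[1, 16 + 10] = 1
        folded = fold_half(m, hill_column=16)
        assert folded[1, 10] == 1 and folded.sum() == 1

    def test_fold_mirror_expand_fold_idempotent(self, rng):
        m = (rng.random((16, 33)) > 0.8).astype(np.uint8)
        folded = fold_half(m, hill_column=16)
        expanded = np.concatenate([folded[:, ::-1], folded[:, 1:]], axis=1)
        refolded = fold_half(expanded, hill_column=folded.shape[1] - 1)
        assert np.array_equal(refolded, folded)

    def test_hill_outside_raster_rejected(self):
        with pytest.raises(ValueError, match="hill"):
            fold_half(np.zeros((4, 8), np.uint8), hill_column=99)


class TestSkeletonize:
    def test_wide_bar_thins_to_centerline(self):
        # oracle run: a 4-px-wide, 20-px-long bar thins to 17 px; end
        # pixels erode, interior is a single collinear run
        short = np.zeros((10, 30), np.uint8)
        short[3:7, 5:25] = 1
        assert skeletonize_mask(short).n_pixels == 17
        bar = np.zeros((20, 300), np.uint8)
        bar[8:12, 20:276] = 1
        sk = skeletonize_mask(bar)
        assert abs(sk.n_pixels - 256) <= 4
        rows = np.nonzero(sk.pixels)[0]
        assert rows.max() - rows.min() <= 1  # collinear up to the 1-px medial shift

    def test_empty_mask(self):
        assert skeletonize_mask(np.zeros((8, 8), np.uint8)).n_pixels == 0

    def test_idempotent_on_thin_curve(self):
        m = np.zeros((16, 16), np.uint8)
        rr = np.arange(2, 14)
        m[rr, rr] = 1
        sk = skeletonize_mask(m)
        assert np.array_equal(sk.pixels, m.astype(bool))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            skeletonize_mask(np.full((4, 4), 3, np.uint8))


class TestRootLength:
    def test_256_pixels_span_10_cm(self, full_frame):
        sk = Skeleton(np.zeros((1536, 1536), bool), full_frame)
        sk.pixels[5, :256] = True
        assert root_length_cm(sk) == pytest.approx(10.0)

    def test_single_pixel_is_0p39_mm(self, full_frame):
        sk = Skeleton(np.zeros((10, 10), bool), full_frame)
        sk.pixels[0, 0] = True
        assert root_length_cm(sk) == pytest.approx(0.0390625)

    def test_empty_skeleton(self, full_frame):
        assert root_length_cm(Skeleton(np.zeros((4, 4), bool), full_frame)) == 0.0


class TestCumulativeProfile:
    def test_all_mass_in_first_row(self, toy_frame):
        sk = Skeleton(np.zeros((64, 64), bool), toy_frame)
        sk.pixels[0, :10] = True
        prof = cumulative_profile(sk, "depth")
        assert prof.cumulative[0] == 1.0

    def test_uniform_rows_give_linear_profile(self, toy_frame):
        sk = Skeleton(np.ones((64, 64), bool), toy_frame)
        prof = cumulative_profile(sk, "depth")
        assert prof.cumulative[31] == pytest.approx(0.5)
        assert np.allclose(np.diff(prof.cumulative), 1 / 64)

    def test_two_cluster_step(self, full_frame):
        sk = Skeleton(np.zeros((1536, 1536), bool), full_frame)
        sk.pixels[256, :100] = True
        sk.pixels[1280, :100] = True
        prof = cumulative_profile(sk, "depth")
        assert prof.cumulative[255] == 0.0
        assert prof.cumulative[256] == pytest.approx(0.5)

    def test_empty_skeleton_rejected(self, toy_frame):
        with pytest.raises(ValueError, match="no roots"):
            cumulative_profile(Skeleton(np.zeros((4, 4), bool), toy_frame), "depth")


class TestQuantileDistance:
    def test_uniform_median_is_half_depth(self, full_frame):
        sk = Skeleton(np.ones((1536, 1536), bool), full_frame)
        assert quantile_distance(cumulative_profile(sk, "depth"), 0.5) == pytest.approx(30.0)

    def test_point_mass_at_10cm(self, full_frame):
        sk = Skeleton(np.zeros((1536, 1536), bool), full_frame)
        sk.pixels[256, :500] = True
        d = quantile_distance(cumulative_profile(sk, "depth"), 0.5)
        assert d == pytest.approx(10.0, abs=0.039)

    def test_truncated_exponential_median_recovered(self, full_frame):
        # 20000 pixels sampled from the truncated-exponential depth law
        # (rate 0.1/cm, truncation 60 cm); closed-form median oracle
        rate, depth = 0.1, 60.0
        rng = np.random.default_rng(42)
        u = rng.random(20000)
        d_cm = -np.log(1.0 - u * (1.0 - np.exp(-rate * depth))) / rate
        rows = np.minimum((d_cm * 25.6).astype(int), 1535)
        counts = np.bincount(rows, minlength=1536)
        sk = Skeleton(np.zeros((1536, 1536), bool), full_frame)
        for r in np.nonzero(counts)[0]:
            sk.pixels[r, :counts[r]] = True
        d50 = quantile_distance(cumulative_profile(sk, "depth"), 0.5)
        assert d50 == pytest.approx(truncated_exponential_median(rate, depth), abs=0.2)

    def test_q_out_of_range_rejected(self, toy_frame):
        sk = Skeleton(np.ones((4, 4), bool), toy_frame)
        prof = cumulative_profile(sk, "depth")
        with pytest.raises(ValueError):
            quantile_distance(prof, 1.5)


class TestPhenotypeImage:
    def test_vertical_root_under_hill(self, full_frame):
        m = np.zeros((1536, 1536), np.uint8)
        m[:512, 768] = 1  # straight down to 20 cm
        p = phenotype_image(m, frame=full_frame, hill_column=768)
        assert p.depth50_cm == pytest.approx(10.0, abs=0.1)
        assert p.width50_cm < 0.2
        assert p.total_root_length_cm == pytest.approx(20.0, abs=0.2)

    def test_horizontal_root_at_5cm(self, full_frame):
        m = np.zeros((1536, 1536), np.uint8)
        m[128, 768:768 + 512] = 1  # depth 5 cm, spanning 0-20 cm from hill
        p = phenotype_image(m, frame=full_frame, hill_column=768)
        assert p.depth50_cm == pytest.approx(5.0, abs=0.1)
        assert p.width50_cm == pytest.approx(10.0, abs=0.1)

    def test_empty_mask_rejected(self, full_frame):
        with pytest.raises(ValueError, match="no roots"):
            phenotype_image(np.zeros((1536, 1536), np.uint8), frame=full_frame)

    def test_dilation_invariance_on_sparse_roots(self, full_frame):
        """Pencil-width labels (<= 4 px) do not move Depth50/Width50 for
        non-touching roots: thinning removes the label width."""
        m = np.zeros((1536, 1536), np.uint8)
        m[:512, 768] = 1
        m[:300, 600] = 1
        m[100:400, 1000] = 1
        base = phenotype_image(m, frame=full_frame, hill_column=768)
        fat = binary_dilation(m.astype(bool), np.ones((4, 4))).astype(np.uint8)
        dil = phenotype_image(fat, frame=full_frame, hill_column=768)
        assert dil.depth50_cm == pytest.approx(base.depth50_cm, abs=0.3)
        assert dil.width50_cm == pytest.approx(base.width50_cm, abs=0.3)

    def test_depth50_monotone_under_deepening(self, toy_frame):
        m = np.zeros((64, 64), np.uint8)
        m[10, 40] = m[20, 30] = m[30, 20] = 1
        before = phenotype_image(m, frame=toy_frame, hill_column=32, skeletonized=True)
        m[10, 40] = 0
        m[55, 40] = 1  # move one pixel deeper
        after = phenotype_image(m, frame=toy_frame, hill_column=32, skeletonized=True)
        assert after.depth50_cm >= before.depth50_cm

    def test_depth50_invariant_to_row_count_doubling(self, toy_frame):
        m = np.zeros((64, 64), np.uint8)
        m[5, :4] = 1
        m[40, :8] = 1
        single = phenotype_image(m, frame=toy_frame, hill_column=0, skeletonized=True)
        m2 = np.zeros((64, 64), np.uint8)
        m2[5, :8] = 1
        m2[40, :16] = 1
        double = phenotype_image(m2, frame=toy_frame, hill_column=0, skeletonized=True)
        assert double.depth50_cm == pytest.approx(single.depth50_cm)
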