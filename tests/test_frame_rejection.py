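"""Empty-frame rejection: grayscale mapping, Otsu, morphology, components,
auto-threshold, filtering, diagnostics — all against independent oracles."""

import numpy as np
import pytest

from conftest import brute_force_otsu, flood_fill_largest
from gliomgmt.framereject import (Gray8Frame, RejectionThreshold,
                                  auto_threshold, filter_frames, frame_stats,
                                  foreground_mask, largest_component_area,
                                  otsu_threshold, rejection_diagnostics,
                                  stack_to_gray8, to_gray8)


class TestToGray8:
    def test_constant_frame_maps_to_zeros(self):
        assert to_gray8(np.full((4, 4), 3.7)).pixels.max() == 0

    def test_three_point_frame_rounds_half_away_from_zero(self):
        frame = to_gray8(np.array([[0.0, 0.5], [1.0, 0.5]]))
        np.testing.assert_array_equal(frame.pixels,
                                      [[0, 128], [255, 128]])

    def test_output_range_contract(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = to_gray8(rng.normal(scale=100, size=(6, 6))).pixels
            assert g.min() >= 0 and g.max() <= 255

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            to_gray8(np.array([[np.nan, 1.0]]))


class TestOtsu:
    def test_two_valued_frame_splits_the_populations(self):
        px = np.zeros((8, 8), dtype=np.uint8)
        px[:, 4:] = 255
        t = otsu_threshold(Gray8Frame(px))
        assert 0 <= t < 255
        assert ((px > t) == (px == 255)).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_exhaustive_search_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        assert otsu_threshold(Gray8Frame(px)) == brute_force_otsu(px)

    def test_photometric_inversion_symmetry(self):
        # dense histograms keep the argmax plateau narrow; inversion maps
        # the (<= t | > t) split to (<= 254 - t | > 254 - t)
        rng = np.random.default_rng(99)
        for _ in range(10):
            px = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
            t = otsu_threshold(Gray8Frame(px))
            t_inv = otsu_threshold(Gray8Frame(255 - px))
            assert abs(t_inv - (255 - t)) <= 2

    def test_single_valued_frame_returns_that_value(self):
        assert otsu_threshold(Gray8Frame(np.full((4, 4), 77, dtype=np.uint8))) == 77


def _disk_frame(radius=10, size=24, bright=True):
    # the disk is the majority structure of the frame, so the polarity
    # choice tracks the disk rather than the background
    ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    disk = (ii - size // 2) ** 2 + (jj - size // 2) ** 2 <= radius ** 2
    px = np.where(disk, 230, 20).astype(np.uint8)
    return (px if bright else 255 - px), disk


class TestForegroundMask:
    def test_bright_disk_selected_with_bright_polarity(self):
        px, disk = _disk_frame()
        mask, polarity = foreground_mask(Gray8Frame(px))
        assert polarity == "bright_on_dark"
        # morphology may shave the disk rim by at most one 3x3 erosion
        assert abs(int(mask.sum()) - int(disk.sum())) <= 2 * np.pi * 10 * 2

    def test_inverted_disk_keeps_component_area_flips_polarity(self):
        px, _ = _disk_frame()
        inv, _ = _disk_frame(bright=False)
        area = foreground_mask(Gray8Frame(px))[0].sum()
        mask_inv, polarity = foreground_mask(Gray8Frame(inv))
        assert polarity == "dark_on_bright"
        assert mask_inv.sum() == area

    def test_opening_removes_isolated_noise_pixels(self):
        """Single-pixel speckle vanishes, matching a brute-force 3x3
        erosion-then-dilation oracle."""
        px, disk = _disk_frame()
        noise_at = [(1, 1), (1, 22), (22, 1), (22, 22)]
        for i, j in noise_at:
            px[i, j] = 230
        mask, polarity = foreground_mask(Gray8Frame(px))
        assert polarity == "bright_on_dark"
        for i, j in noise_at:
            assert not mask[i, j]
        # oracle: erosion of the binary image kills isolated pixels
        binary = px > otsu_threshold(Gray8Frame(px))
        eroded = np.zeros_like(binary)
        for i in range(1, 23):
            for j in range(1, 23):
                eroded[i, j] = binary[i - 1:i + 2, j - 1:j + 2].all()
        for i, j in noise_at:
            assert not eroded[i, j]


class TestFrameStats:
    def test_empty_foreground_scores_zero(self):
        st = frame_stats(Gray8Frame(np.zeros((6, 6), dtype=np.uint8)))
        assert (st.largest_component_area, st.area_ratio) == (0, 0.0)

    def test_full_foreground_scores_one(self):
        px = np.zeros((6, 8), dtype=np.uint8)
        px[1:, :] = 255  # bright majority fills the frame after closing
        st = frame_stats(Gray8Frame(px))
        assert st.area_ratio == st.largest_component_area / 48

    def test_two_components_pick_the_larger_by_8_connectivity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:3, 0:4] = True          # 12 px
        mask[5:10, 2:8] = True         # 30 px
        assert largest_component_area(mask) == 30
        assert flood_fill_largest(mask) == 30

    @pytest.mark.parametrize("seed", range(30))
    def test_largest_component_matches_flood_fill_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((9, 9)) < 0.45
        assert largest_component_area(mask) == flood_fill_largest(mask)

    def test_adding_pixels_never_decreases_area(self):
        rng = np.random.default_rng(3)
        mask = rng.random((12, 12)) < 0.3
        before = largest_component_area(mask)
        grown = mask.copy()
        grown[rng.random((12, 12)) < 0.2] = True
        assert largest_component_area(grown) >= before


class TestAutoThreshold:
    def test_two_well_separated_clusters_yield_midpoint(self):
        rng = np.random.default_rng(0)
        ratios = np.concatenate([rng.normal(0.02, 0.005, 200).clip(0, 1),
                                 rng.normal(0.80, 0.02, 200).clip(0, 1)])
        thr = auto_threshold(ratios, seed=0)
        assert thr.method == "bimodal"
        assert thr.value == pytest.approx(0.41, abs=0.03)

    def test_degenerate_identical_ratios_fall_back_to_quantile(self):
        thr = auto_threshold([0.3] * 50)
        assert thr.method == "quantile_fallback"
        assert thr.value == pytest.approx(0.3)

    def test_tiny_minority_cluster_triggers_fallback(self):
        rng = np.random.default_rng(1)
        ratios = np.concatenate([rng.normal(0.1, 0.01, 500).clip(0, 1),
                                 [0.9] * 3])
        thr = auto_threshold(ratios, seed=0)
        assert thr.method == "quantile_fallback"
        assert thr.quantile_used == 0.05

    def test_cohort_shaped_mixture_separates_the_two_modes(self):
        """Dense low-ratio mass vs a high-ratio mass: the returned
        threshold cleanly separates the two modes."""
        rng = np.random.default_rng(2)
        low = rng.uniform(0.0, 0.25, 900)
        high = rng.uniform(0.75, 1.0, 100)
        thr = auto_threshold(np.concatenate([low, high]), seed=0)
        assert thr.method == "bimodal"
        assert low.max() < thr.value < high.min()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            auto_threshold([])


class TestFilterFrames:
    @staticmethod
    def _stats(ratios):
        from types import SimpleNamespace
        return [SimpleNamespace(area_ratio=float(r)) for r in ratios]

    def test_zero_threshold_rejects_nothing(self):
        frames = list("abcd")
        stats = self._stats([0.0, 0.1, 0.5, 1.0])
        kept, rejected = filter_frames(frames, stats,
                                       RejectionThreshold(0.0, "fixed"))
        assert kept == frames and rejected == []

    def test_strict_rule_at_published_threshold(self):
        frames = list("abcd")
        stats = self._stats([0.00, 0.05, 0.15, 0.30])
        kept, rejected = filter_frames(frames, stats,
                                       RejectionThreshold(0.1000, "fixed"))
        assert rejected == ["a", "b"] and kept == ["c", "d"]

    @pytest.mark.parametrize("seed", range(10))
    def test_raising_threshold_never_keeps_more(self, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.random(30)
        stats = self._stats(ratios)
        frames = list(range(30))
        counts = []
        for t in np.linspace(0, 1, 11):
            kept, rej = filter_frames(frames, stats, RejectionThreshold(t, "fixed"))
            assert sorted(kept + rej) == frames
            counts.append(len(kept))
        assert counts == sorted(counts, reverse=True)


class TestDiagnostics:
    def test_single_ratio_cdf_is_one_at_that_ratio(self):
        d = rejection_diagnostics([0.5], RejectionThreshold(0.5, "fixed"))
        assert d.cdf[-1] == 1.0
        assert d.threshold_cdf == 1.0

    def test_uniform_sample_cdf_near_identity(self):
        rng = np.random.default_rng(4)
        ratios = rng.random(10_000)
        d = rejection_diagnostics(ratios, RejectionThreshold(0.25, "fixed"))
        k = np.searchsorted(d.sorted_ratios, 0.25)
        assert d.cdf[k] == pytest.approx(0.25, abs=0.02)

    def test_histogram_density_integrates_to_one(self):
        rng = np.random.default_rng(5)
        d = rejection_diagnostics(rng.random(500), RejectionThreshold(0.1, "fixed"))
        widths = np.diff(d.bin_edges)
        assert (d.density * widths).sum() == pytest.approx(1.0, abs=1e-6)


def test_phantom_air_slices_rejected_brain_slices_kept(cohort_dir):
    """End-to-end on a phantom case: slices outside the brain (noise only)
    score near-zero ratios and are rejected; tumor-bearing slices are kept."""
    from gliomgmt.pipeline import read_study

    out, table = cohort_dir
    study = read_study(out / table.BraTS21ID.iloc[0])
    ratios = {}
    for k in range(study.n_slices):
        gray = to_gray8(study.volumes["flair"][:, :, k])
        ratios[k] = frame_stats(gray).area_ratio
    air = [k for k in ratios if not (2.5 <= k <= 28.5)]   # outside brain z-extent
    tumor = [k for k in range(study.n_slices) if study.mask[:, :, k].any()]
    thr = RejectionThreshold(0.1, "fixed")
    for k in air:
        assert ratios[k] < thr.value
    for k in tumor:
        assert ratios[k] >= thr.value
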