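import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from skimage.draw import disk

from spheroscreen.imaging import (
    ImageStack,
    MIPImage,
    SpheroidSegmenter,
    kinetic_area_trace,
    max_intensity_projection,
    segment_spheroid,
    total_mip_area,
)
from spheroscreen.simulate import gen_spheroid_stack


def stack_of(*slices, px=1.0):
    return ImageStack(voxels=np.array(slices, dtype=float), pixel_size_um=px)


class TestMIP:
    def test_single_slice_identity(self):
        s = np.arange(12.0).reshape(3, 4)
        mip = max_intensity_projection(stack_of(s))
        assert np.array_equal(mip.pixels, s)

    def test_pointwise_maximum(self):
        mip = max_intensity_projection(stack_of([[1.0, 5.0]], [[3.0, 2.0]]))
        assert np.array_equal(mip.pixels, [[3.0, 5.0]])

    def test_idempotent(self):
        mip = max_intensity_projection(stack_of([[1, 5]], [[3, 2]]))
        again = max_intensity_projection(ImageStack(mip.pixels[None], mip.pixel_size_um))
        assert np.array_equal(again.pixels, mip.pixels)

    @settings(derandomize=True, max_examples=25)
    @given(
        arrays(
            float,
            st.tuples(st.integers(1, 6), st.integers(1, 8), st.integers(1, 8)),
            elements=st.floats(0, 1e4, allow_nan=False),
        )
    )
    def test_dominates_slices_and_permutation_invariant(self, vox):
        stack = ImageStack(vox, pixel_size_um=1.0)
        mip = max_intensity_projection(stack)
        assert np.all(mip.pixels[None] >= stack.voxels)
        perm = np.random.default_rng(0).permutation(vox.shape[0])
        mip_p = max_intensity_projection(ImageStack(vox[perm], 1.0))
        assert np.array_equal(mip.pixels, mip_p.pixels)

    def test_pixel_size_propagates(self):
        assert max_intensity_projection(stack_of([[0.0]], px=1.3)).pixel_size_um == 1.3


class TestSegmentation:
    def test_pure_background_segments_to_nothing(self):
        rng = np.random.default_rng(0)
        mip = MIPImage(rng.normal(10, 1, (64, 64)).clip(0), 1.0)
        seg = segment_spheroid(mip, min_object_px=20)
        assert seg.total_area_um2 == 0.0 and seg.n_objects == 0

    def test_disk_area_matches_pixel_count_oracle(self):
        """A noise-free radius-20 disk at 1.3 um/px covers ~pi*26^2 um^2."""
        img = np.zeros((100, 100))
        rr, cc = disk((50, 50), 20.0)
        img[rr, cc] = 100.0
        seg = segment_spheroid(MIPImage(img, 1.3), threshold=50.0, min_object_px=0)
        oracle = img[img > 50].size * 1.3**2
        assert seg.total_area_um2 == pytest.approx(oracle)
        assert seg.total_area_um2 == pytest.approx(np.pi * (20 * 1.3) ** 2, rel=0.05)
        assert seg.largest_radius_um == pytest.approx(20 * 1.3, rel=0.05)

    def test_speck_removal_keeps_real_objects(self):
        img = np.zeros((80, 80))
        rr, cc = disk((20, 20), 6.0)
        img[rr, cc] = 100.0  # ~113 px
        rr, cc = disk((60, 60), 6.0)
        img[rr, cc] = 100.0
        img[5, 70] = img[5, 71] = img[6, 70] = 100.0  # 3-px speck
        seg = segment_spheroid(MIPImage(img, 1.0), threshold=50.0, min_object_px=10)
        assert seg.n_objects == 2
        oracle = (img > 50).sum() - 3  # all lit pixels minus the speck
        assert seg.total_area_um2 == pytest.approx(oracle)

    def test_flat_image_under_otsu_flags_not_raises(self):
        seg = segment_spheroid(MIPImage(np.full((32, 32), 9.0), 1.0))
        assert seg.warning == "flat_image"
        assert seg.n_objects == 0 and seg.total_area_um2 == 0.0

    def test_total_area_sums_all_segments(self):
        img = np.zeros((60, 180))
        for k in range(3):
            rr, cc = disk((30, 30 + 60 * k), 8.0)
            img[rr, cc] = 100.0
        seg = segment_spheroid(MIPImage(img, 1.0), threshold=10.0, min_object_px=5)
        assert seg.n_objects == 3
        assert total_mip_area(seg) == pytest.approx(sum(seg.segment_areas_um2))
        assert total_mip_area(seg) == pytest.approx(img[img > 0].size)

    def test_area_monotone_in_mask(self):
        img = np.zeros((40, 40))
        img[10:20, 10:20] = 100.0
        small = segment_spheroid(MIPImage(img, 1.0), threshold=10.0, min_object_px=0)
        img[10:25, 10:25] = 100.0
        big = segment_spheroid(MIPImage(img, 1.0), threshold=10.0, min_object_px=0)
        assert big.total_area_um2 > small.total_area_um2


class TestRoundTrip:
    @pytest.mark.parametrize("background_sd", [0.0, 60.0])
    def test_generated_stacks_recover_true_area(self, background_sd):
        for area in np.linspace(4000, 28000, 4):
            st = gen_spheroid_stack(area, background_sd=background_sd, seed=int(area))
            seg = segment_spheroid(max_intensity_projection(st))
            assert abs(seg.total_area_um2 - area) / area < 0.05


class TestKineticTrace:
    def frame(self, r):
        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), r)
        img[rr, cc] = 100.0
        return MIPImage(img, 1.0)

    def test_identical_frames_trace_of_ones(self):
        frames = [self.frame(10)] * 5
        out = kinetic_area_trace(frames, [0, 12, 24, 36, 48], threshold=50.0)
        assert np.allclose(out["norm_area"], 1.0)

    def test_doubling_area_reaches_two(self):
        a0 = self.frame(10)
        seg_area = lambda f: segment_spheroid(f, threshold=50.0).total_area_um2
        # pick a radius whose pixelated area is ~2x the first frame's
        r2 = 10 * np.sqrt(2)
        out = kinetic_area_trace([a0, self.frame(r2)], [0, 12], threshold=50.0)
        assert out["norm_area"].iloc[0] == 1.0
        assert out["norm_area"].iloc[1] == pytest.approx(2.0, rel=0.05)

    def test_twelve_hour_sampling_spans_five_days(self):
        times = list(range(0, 121, 12))
        frames = [self.frame(10)] * len(times)
        out = kinetic_area_trace(frames, times, threshold=50.0)
        assert len(out) == 11
        assert out["time_h"].iloc[-1] - out["time_h"].iloc[0] == 120

    def test_zero_initial_area_raises(self):
        empty = MIPImage(np.zeros((16, 16)), 1.0)
        with pytest.raises(ValueError, match="normalise"):
            kinetic_area_trace([empty, self.frame(5)], [0, 12], threshold=50.0)

    def test_validates_times(self):
        with pytest.raises(ValueError):
            kinetic_area_trace([self.frame(5), self.frame(5)], [12, 0], threshold=50.0)
        with pytest.raises(ValueError):
            kinetic_area_trace([self.frame(5)], [0], threshold=50.0)


class TestStackValidation:
    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError):
            ImageStack(-np.ones((2, 4, 4)), 1.0)

    def test_rejects_bad_pixel_size(self):
        with pytest.raises(ValueError):
            ImageStack(np.ones((2, 4, 4)), 0.0)

    def test_tiff_round_trip(self, tmp_path):
        st = gen_spheroid_stack(2000.0, pixel_size_um=1.3, n_slices=8, background_sd=3.0, seed=2)
        path = tmp_path / "stack.tif"
        st.to_tiff(path)
        back = ImageStack.from_tiff(path)
        assert np.allclose(back.voxels, st.voxels, atol=1e-4)
        assert back.pixel_size_um == pytest.approx(1.3)


def test_segmenter_transform_tabulates_wells():
    stacks = [gen_spheroid_stack(a, seed=int(a)) for a in (5000.0, 12000.0)]
    out = SpheroidSegmenter().fit().transform(stacks)
    assert list(out["index"]) == [0, 1]
    assert np.all(np.abs(out["area_um2"].to_numpy() - [5000, 12000]) / [5000, 12000] < 0.05)
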