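"""Zero-lag Pearson machinery: time courses, SPC maps, correlation matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesoconn import (
    CoordinateSystem,
    ImageStack,
    SeedRoI,
    correlation_matrix,
    pearson_r,
    roi_timecourse,
    spc_map,
)


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_half_correlation_case(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_series_signaled(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_pairwise_deletion_of_undefined_frames(self):
        a = [1.0, 2.0, np.nan, 3.0, 4.0]
        b = [2.0, 4.0, 5.0, 6.0, 8.0]
        assert pearson_r(a, b) == pytest.approx(1.0)

    def test_too_few_complete_frames_rejected(self):
        with pytest.raises(ValueError, match="pairwise-complete"):
            pearson_r([1.0, np.nan, 2.0], [1.0, 2.0, np.nan])

    @given(
        alpha=st.floats(0.1, 10), beta=st.floats(-5, 5), sign=st.sampled_from([-1, 1])
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, alpha, beta, sign):
        rng = np.random.default_rng(99)
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        r0 = pearson_r(a, b)
        r1 = pearson_r(sign * alpha * a + beta, b)
        assert r1 == pytest.approx(sign * r0, abs=1e-9)


class TestRoiTimecourse:
    def test_single_pixel_identity(self, small_stack):
        tc = roi_timecourse(small_stack, {(2, 3)})
        np.testing.assert_array_equal(tc, small_stack.data[:, 3, 2])

    def test_opposite_pixels_cancel(self, rng):
        s = rng.standard_normal(20)
        data = np.zeros((20, 1, 2))
        data[:, 0, 0] = s
        data[:, 0, 1] = -s
        tc = roi_timecourse(ImageStack(data, 30.0), {(0, 0), (1, 0)})
        np.testing.assert_allclose(tc, 0.0, atol=1e-15)

    def test_block_matches_loop_mean(self, small_stack):
        pixels = {(x, y) for x in (2, 3, 4) for y in (2, 3, 4)}
        tc = roi_timecourse(small_stack, pixels)
        for t in range(small_stack.n_frames):
            expected = np.mean([small_stack.data[t, y, x] for x, y in pixels])
            assert tc[t] == pytest.approx(expected)

    def test_fully_masked_roi_rejected(self, small_stack):
        small_stack.data[:, 5, 5] = np.nan
        with pytest.raises(ValueError, match="masked"):
            roi_timecourse(small_stack, {(5, 5)})


class TestSpcMap:
    def test_seed_value_is_one_and_negation_is_minus_one(self, rng):
        s = rng.standard_normal(100)
        data = np.zeros((100, 2, 2))
        data[:, 0, 0] = s
        data[:, 0, 1] = -s
        data[:, 1, 0] = rng.standard_normal(100)
        data[:, 1, 1] = 2.0 * s + 1.0
        m = spc_map(ImageStack(data, 30.0), (0, 0))
        assert m.values[0, 0] == 1.0
        assert m.values[0, 1] == pytest.approx(-1.0)
        assert m.values[1, 1] == pytest.approx(1.0)  # affine copy of the seed

    def test_reciprocity(self, two_region_stack):
        stack, _ = two_region_stack
        a, b = (10, 10), (30, 30)
        m_a = spc_map(stack, a)
        m_b = spc_map(stack, b)
        assert m_a.values[b[1], b[0]] == pytest.approx(m_b.values[a[1], a[0]], abs=1e-12)

    def test_masked_pixels_are_undefined_in_map(self, two_region_stack):
        stack, _ = two_region_stack
        stack = stack.copy()
        stack.data[:, 0, :] = np.nan
        m = spc_map(stack, (10, 10))
        assert np.isnan(m.values[0]).all()
        assert np.isfinite(m.values[10, 10])

    def test_seed_in_masked_region_rejected(self, two_region_stack):
        stack, _ = two_region_stack
        stack = stack.copy()
        stack.data[:, 10, 10] = np.nan
        with pytest.raises(ValueError, match="masked"):
            spc_map(stack, (10, 10))

    def test_shared_source_and_independent_region(self):
        """Noise-free regions sharing one source correlate at exactly 1."""
        from mesoconn import Region, SynthConfig, dff, generate_stack

        cfg = SynthConfig(
            height=32,
            width=32,
            n_frames=300,
            regions=[Region((8, 8), 4, 0), Region((24, 24), 4, 0)],
            noise_sigma=0.0,
            heartbeat_amplitude=0.0,
            global_amplitude=0.0,
            seed=11,
        )
        stack, _ = generate_stack(cfg)
        m = spc_map(dff(stack), (8, 8))
        assert m.values[24, 24] == pytest.approx(1.0, abs=1e-9)


class TestCorrelationMatrix:
    CS = CoordinateSystem(origin=(20.0, 20.0), um_per_px=41.0)

    def _rois(self):
        return [SeedRoI("a", -410.0, 410.0), SeedRoI("b", 410.0, -410.0)]

    def test_single_stack_std_is_zero(self, two_region_stack):
        stack, _ = two_region_stack
        res = correlation_matrix([stack], self._rois(), self.CS)
        np.testing.assert_array_equal(res.std_r, 0.0)
        assert res.mean_r[0, 0] == 1.0
        assert res.n_stacks == 1

    def test_two_stack_mean_and_std(self, rng):
        """Planted pair r-values 1 and 0 give mean 0.5, std 1/sqrt(2)."""
        n = 60
        s = rng.standard_normal(n)
        other = rng.standard_normal(n)
        # stack 1: both RoIs follow s (r = 1); stack 2: independent (r ~ 0)
        d1 = np.zeros((n, 40, 40))
        d1[:, :, :] = s[:, None, None]
        d2 = np.zeros((n, 40, 40))
        d2[:, :20, :] = s[:, None, None]
        d2[:, 20:, :] = other[:, None, None]
        r2 = pearson_r(s, other)
        stacks = [ImageStack(d1, 30.0), ImageStack(d2, 30.0)]
        cs = CoordinateSystem(origin=(20.0, 20.0), um_per_px=41.0)
        rois = [SeedRoI("top", 0.0, 410.0), SeedRoI("bottom", 0.0, -410.0)]
        res = correlation_matrix(stacks, rois, cs)
        assert res.mean_r[0, 1] == pytest.approx((1.0 + r2) / 2)
        assert res.std_r[0, 1] == pytest.approx(abs(1.0 - r2) / np.sqrt(2))

    def test_fourteen_roi_structure(self, two_region_stack):
        """A full bilateral seed set yields a symmetric unit-diagonal matrix."""
        from mesoconn import cortical_rois

        stack, _ = two_region_stack
        cs = CoordinateSystem(origin=(20.0, 20.0), um_per_px=250.0)
        res = correlation_matrix([stack], cortical_rois(), cs)
        assert res.mean_r.shape == (14, 14)
        np.testing.assert_allclose(res.mean_r, res.mean_r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(res.mean_r), 1.0)
        assert res.roi_names[0] == "L-V1"

    def test_masked_roi_names_stack_and_roi(self, two_region_stack):
        stack, _ = two_region_stack
        stack = stack.copy()
        stack.data[:, 30, 30] = np.nan  # kill RoI "b" (maps to pixel 30,30)
        rois = [SeedRoI("a", -2500.0, 2500.0), SeedRoI("b", 2500.0, -2500.0)]
        cs = CoordinateSystem(origin=(20.0, 20.0), um_per_px=250.0)
        with pytest.raises(ValueError, match="'b'.*stack 0"):
            correlation_matrix([stack], rois, cs)

    def test_fewer_than_two_rois_rejected(self, two_region_stack):
        stack, _ = two_region_stack
        with pytest.raises(ValueError, match="two RoIs"):
            correlation_matrix([stack], [SeedRoI("a", 0.0, 0.0)], self.CS)
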