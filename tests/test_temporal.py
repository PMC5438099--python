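"""Temporal operations: trimming, bandpass, ΔF/F0, GSR, concatenation, maps."""

import numpy as np
import pytest

from mesoconn import (
    FilterSpec,
    ImageStack,
    cheby_bandpass,
    concat_stacks,
    dff,
    divide_stacks,
    evoked_average,
    global_signal,
    gsr,
    stdev_map,
    trim_frames,
)


def _stack_from_series(*series, fps=30.0):
    """Stack with one pixel per given time series (1×k frame)."""
    arr = np.stack([np.asarray(s, dtype=float) for s in series], axis=1)[:, None, :]
    return ImageStack(arr, fps)


class TestTrim:
    def test_front_trim_drops_exactly(self, rng):
        stack = ImageStack(rng.standard_normal((100, 4, 4)), 30.0)
        out = trim_frames(stack, n_front=20)
        assert out.n_frames == 80
        np.testing.assert_array_equal(out.data[0], stack.data[20])

    def test_zero_trim_is_identity(self, small_stack):
        out = trim_frames(small_stack, 0, 0)
        np.testing.assert_array_equal(out.data, small_stack.data)

    def test_over_trim_rejected(self, rng):
        stack = ImageStack(rng.standard_normal((100, 2, 2)), 30.0)
        with pytest.raises(ValueError, match="cannot trim"):
            trim_frames(stack, 60, 60)


class TestBandpass:
    SPEC = FilterSpec(low_hz=0.3, high_hz=3.0, order=4, ripple_db=0.1)

    def _sinusoid(self, freq, fps=30.0, n=900):
        t = np.arange(n) / fps
        return np.sin(2 * np.pi * freq * t)

    def test_dc_fully_rejected(self):
        stack = ImageStack(np.full((600, 3, 3), 100.0), 30.0)
        out = cheby_bandpass(stack, self.SPEC)
        assert np.nanmax(np.abs(out.data)) < 1e-6 * 100.0

    def test_passband_and_stopband_gains_on_sinusoids(self):
        for freq, lo, hi in [(1.0, 0.95, 1.05), (10.0, 0.0, 0.05)]:
            stack = _stack_from_series(self._sinusoid(freq))
            out = cheby_bandpass(stack, self.SPEC)
            mid = slice(300, 600)  # away from edge transients
            ratio = np.abs(out.data[mid, 0, 0]).max()
            assert lo <= ratio <= hi, f"{freq} Hz gain {ratio}"

    def test_gains_match_designed_frequency_response(self):
        """Measured sinusoid gain agrees with |H(f)|^2 of the design."""
        for freq in [0.5, 1.0, 2.0]:
            expected = float(self.SPEC.gain(freq, fps=30.0)[0])
            stack = _stack_from_series(self._sinusoid(freq, n=3000))
            out = cheby_bandpass(stack, self.SPEC)
            measured = np.abs(out.data[1000:2000, 0, 0]).max()
            assert measured == pytest.approx(expected, rel=0.02)

    def test_linearity(self, rng):
        x = rng.standard_normal(600)
        y = rng.standard_normal(600)
        fx = cheby_bandpass(_stack_from_series(x), self.SPEC).data[:, 0, 0]
        fy = cheby_bandpass(_stack_from_series(y), self.SPEC).data[:, 0, 0]
        fxy = cheby_bandpass(_stack_from_series(2 * x + 3 * y), self.SPEC).data[:, 0, 0]
        np.testing.assert_allclose(fxy, 2 * fx + 3 * fy, rtol=1e-9, atol=1e-9)

    def test_zero_phase_no_lag_in_passband(self):
        x = self._sinusoid(1.0, n=1500)
        out = cheby_bandpass(_stack_from_series(x), self.SPEC).data[:, 0, 0]
        # cross-correlation peak of input vs output at lag 0
        mid = slice(300, 1200)
        lags = range(-10, 11)
        cc = [np.dot(x[mid], np.roll(out, lag)[mid]) for lag in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_undefined_pixels_stay_undefined(self, rng):
        data = rng.standard_normal((600, 2, 2))
        data[:, 0, 0] = np.nan
        out = cheby_bandpass(ImageStack(data, 30.0), self.SPEC)
        assert np.isnan(out.data[:, 0, 0]).all()
        assert np.isfinite(out.data[:, 1, 1]).all()

    def test_band_outside_nyquist_rejected(self):
        stack = ImageStack(np.random.default_rng(0).standard_normal((600, 2, 2)), 5.0)
        with pytest.raises(ValueError, match="Nyquist"):
            cheby_bandpass(stack, self.SPEC)

    def test_too_short_stack_rejected(self):
        stack = ImageStack(np.zeros((10, 2, 2)), 30.0)
        with pytest.raises(ValueError, match="too short"):
            cheby_bandpass(stack, self.SPEC)


class TestDff:
    def test_constant_pixel_becomes_zero(self):
        out = dff(_stack_from_series([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(out.data, 0.0)

    def test_two_point_series(self):
        out = dff(_stack_from_series([8.0, 12.0]))
        np.testing.assert_allclose(out.data[:, 0, 0], [-0.2, 0.2])

    def test_zero_baseline_marked_undefined(self):
        out = dff(_stack_from_series([0.0, 0.0]))
        assert np.isnan(out.data).all()

    def test_temporal_mean_is_zero_at_defined_pixels(self, small_stack):
        out = dff(small_stack)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12


class TestGlobalSignal:
    def test_symmetric_pair_averages_flat(self):
        g = global_signal(_stack_from_series([0.0, 2.0], [2.0, 0.0]))
        np.testing.assert_allclose(g.series, [1.0, 1.0])

    def test_identical_pixels_reproduce_series(self, rng):
        s = rng.standard_normal(50)
        stack = ImageStack(np.tile(s[:, None, None], (1, 3, 3)), 30.0)
        np.testing.assert_allclose(global_signal(stack).series, s)

    def test_matches_double_loop(self, small_stack):
        g = global_signal(small_stack).series
        expected = [
            np.mean([small_stack.data[t, i, j] for i in range(8) for j in range(8)])
            for t in range(small_stack.n_frames)
        ]
        np.testing.assert_allclose(g, expected)

    def test_skips_masked_pixels(self, small_stack):
        masked = small_stack.copy()
        masked.data[:, 0, :] = np.nan
        g = global_signal(masked).series
        expected = np.nanmean(masked.data.reshape(masked.n_frames, -1), axis=1)
        np.testing.assert_allclose(g, expected)


class TestGsr:
    def test_perfect_fit_gives_zero_residuals(self, rng):
        g = rng.standard_normal(60)
        alphas = rng.uniform(-1, 1, size=(4, 4))
        betas = rng.uniform(0.5, 2.0, size=(4, 4))
        data = alphas[None] + betas[None] * g[:, None, None]
        out = gsr(ImageStack(data, 30.0))
        assert np.abs(out.data).max() < 1e-10

    def test_residuals_orthogonal_to_global_signal(self, small_stack):
        g = global_signal(small_stack).series
        out = gsr(small_stack)
        flat = out.data.reshape(out.n_frames, -1)
        gc = g - g.mean()
        scale = np.abs(flat).max() * np.abs(gc).max() * len(gc)
        assert np.abs(flat.T @ gc).max() < 1e-8 * scale

    def test_spatial_mean_residual_is_zero(self, small_stack):
        out = gsr(small_stack)
        assert np.abs(out.data.mean(axis=(1, 2))).max() < 1e-10

    def test_recovers_local_source_under_global_confound(self, rng):
        """Noise-free: one pixel carries local + 0.8*g, the rest only 0.8*g;
        the residual at that pixel follows the local source almost exactly."""
        n = 400
        local = rng.standard_normal(n)
        g = rng.standard_normal(n)
        data = np.tile((0.8 * g)[:, None, None], (1, 10, 10))
        data[:, 0, 0] += local
        out = gsr(ImageStack(data, 30.0))
        r = np.corrcoef(out.data[:, 0, 0], local)[0, 1]
        assert r > 0.99

    def test_constant_global_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gsr(ImageStack(np.ones((10, 2, 2)), 30.0))


class TestConcat:
    def test_single_stack_identity(self, small_stack):
        out = concat_stacks([small_stack])
        np.testing.assert_array_equal(out.data, small_stack.data)

    def test_boundary_frame_indexing(self, rng):
        a = ImageStack(rng.standard_normal((30, 4, 4)), 30.0)
        b = ImageStack(rng.standard_normal((70, 4, 4)), 30.0)
        out = concat_stacks([a, b])
        assert out.n_frames == 100
        np.testing.assert_array_equal(out.data[30], b.data[0])

    def test_thirty_one_trials_frame_count(self, rng):
        stacks = [ImageStack(rng.standard_normal((900, 2, 2)), 30.0) for _ in range(31)]
        assert concat_stacks(stacks).n_frames == 27_900

    def test_associativity_bit_exact(self, rng):
        a, b, c = (ImageStack(rng.standard_normal((10, 3, 3)), 30.0) for _ in range(3))
        left = concat_stacks([concat_stacks([a, b]), c])
        flat = concat_stacks([a, b, c])
        np.testing.assert_array_equal(left.data, flat.data)

    def test_shape_mismatch_rejected(self, rng):
        a = ImageStack(rng.standard_normal((10, 3, 3)), 30.0)
        b = ImageStack(rng.standard_normal((10, 4, 4)), 30.0)
        with pytest.raises(ValueError, match="shape"):
            concat_stacks([a, b])

    def test_fps_mismatch_rejected(self, rng):
        a = ImageStack(rng.standard_normal((10, 3, 3)), 30.0)
        b = ImageStack(rng.standard_normal((10, 3, 3)), 15.0)
        with pytest.raises(ValueError, match="fps"):
            concat_stacks([a, b])


class TestDivide:
    def test_self_division_is_one(self, small_stack):
        out = divide_stacks(small_stack, small_stack)
        np.testing.assert_allclose(out.data, 1.0)

    def test_zero_denominator_undefined_only_there(self, rng):
        num = ImageStack(rng.standard_normal((5, 3, 3)) + 10, 30.0)
        den_data = rng.standard_normal((5, 3, 3)) + 10
        den_data[2, 1, 1] = 0.0
        out = divide_stacks(num, ImageStack(den_data, 30.0))
        assert np.isnan(out.data[2, 1, 1])
        out.data[2, 1, 1] = 0.0
        assert np.isfinite(out.data).all()

    def test_matches_loop_ratios(self, rng):
        a = rng.standard_normal((4, 2, 2)) + 5
        b = rng.standard_normal((4, 2, 2)) + 5
        out = divide_stacks(ImageStack(a, 30.0), ImageStack(b, 30.0))
        for t in range(4):
            for i in range(2):
                for j in range(2):
                    assert out.data[t, i, j] == a[t, i, j] / b[t, i, j]


class TestEvokedAverage:
    def test_identical_trials_average_to_one_trial(self, small_stack):
        out = evoked_average([small_stack, small_stack.copy()])
        np.testing.assert_allclose(out.data, small_stack.data)

    def test_two_constant_trials(self):
        a = ImageStack(np.full((5, 2, 2), 1.0), 30.0)
        b = ImageStack(np.full((5, 2, 2), 3.0), 30.0)
        np.testing.assert_allclose(evoked_average([a, b]).data, 2.0)

    def test_noise_shrinks_like_sqrt_n(self, rng):
        n_trials, n = 16, 200
        response = np.sin(np.linspace(0, 4 * np.pi, n))[:, None, None]
        trials = [
            ImageStack(response + rng.standard_normal((n, 4, 4)), 30.0)
            for _ in range(n_trials)
        ]
        avg = evoked_average(trials)
        residual = avg.data - response
        assert residual.std() == pytest.approx(1.0 / np.sqrt(n_trials), rel=0.2)

    def test_length_mismatch_needs_flag(self, rng):
        a = ImageStack(rng.standard_normal((10, 2, 2)), 30.0)
        b = ImageStack(rng.standard_normal((12, 2, 2)), 30.0)
        with pytest.raises(ValueError, match="truncate"):
            evoked_average([a, b])
        out = evoked_average([a, b], truncate_to_shortest=True)
        assert out.n_frames == 10


class TestStdevMap:
    def test_constant_stack_gives_zero_map(self):
        out = stdev_map(ImageStack(np.full((10, 3, 3), 2.0), 30.0))
        np.testing.assert_allclose(out, 0.0)

    def test_two_point_series_population_std(self):
        out = stdev_map(_stack_from_series([0.0, 2.0]))
        assert out[0, 0] == pytest.approx(1.0)

    def test_matches_loop_oracle(self, small_stack):
        out = stdev_map(small_stack)
        for i in range(3):
            for j in range(3):
                series = small_stack.data[:, i, j]
                assert out[i, j] == pytest.approx(
                    np.sqrt(((series - series.mean()) ** 2).mean())
                )

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            stdev_map(ImageStack(np.zeros((1, 2, 2)), 30.0))
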