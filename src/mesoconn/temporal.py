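"""Per-stack temporal operations.

These are the per-pixel time-series stages of the widefield preprocessing
pipeline: frame trimming, zero-phase Chebyshev bandpass, ΔF/F0 against the
all-frame mean, global signal regression (GSR), trial concatenation,
stack division (hemodynamic correction), evoked averaging across trials and
temporal standard-deviation maps.

Undefined pixels (NaN) propagate: a pixel undefined at any frame is treated
as undefined for whole-series operations (filtering, regression), and the
global signal is computed over defined pixels only so masked regions never
contaminate it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .stack import UNDEFINED, ImageStack

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """Type-I Chebyshev bandpass design.

    ``low_hz``/``high_hz`` are the passband edges, ``order`` the filter
    order, ``ripple_db`` the maximum passband ripple in dB. The defaults are
    the band recommended for slow calcium indicators sampled at 30 Hz:
    0.3–3 Hz, order 4, 0.1 dB ripple.
    """

    low_hz: float = 0.3
    high_hz: float = 3.0
    order: int = 4
    ripple_db: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if not (self.ripple_db > 0):
            raise ValueError(f"ripple_db must be positive, got {self.ripple_db}")

    def validate_for_fps(self, fps: float) -> None:
        if self.high_hz >= fps / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz is at or above Nyquist ({fps / 2} Hz)"
            )

    def sos(self, fps: float) -> np.ndarray:
        """Second-order-sections representation of the designed filter."""
        self.validate_for_fps(fps)
        return signal.cheby1(
            self.order,
            self.ripple_db,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=fps,
            output="sos",
        )

    def gain(self, freq_hz: float | np.ndarray, fps: float, zero_phase: bool = True) -> np.ndarray:
        """Magnitude response at ``freq_hz``; squared for forward–backward use."""
        w, h = signal.sosfreqz(self.sos(fps), worN=np.atleast_1d(freq_hz), fs=fps)
        mag = np.abs(h)
        return mag**2 if zero_phase else mag


@dataclass
class GlobalSignal:
    """Frame-wise spatial mean over defined pixels."""

    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64).ravel()


# ---------------------------------------------------------------------------


def trim_frames(stack: ImageStack, n_front: int = 20, n_back: int = 0) -> ImageStack:
    """Drop frames from the front and back of a stack.

    The leading frames of a recording can contain motion from mechanical
    settling of the head fixation; trimming them is a precaution taken
    before alignment.
    """
    if n_front < 0 or n_back < 0:
        raise ValueError("trim counts must be non-negative")
    if n_front + n_back >= stack.n_frames:
        raise ValueError(
            f"cannot trim {n_front}+{n_back} frames from a "
            f"{stack.n_frames}-frame stack"
        )
    return stack.with_data(stack.data[n_front : stack.n_frames - n_back].copy())


def _defined_columns(data: np.ndarray) -> np.ndarray:
    """Pixels (flattened) defined at every frame."""
    return np.isfinite(data).all(axis=0)


def cheby_bandpass(stack: ImageStack, spec: FilterSpec | None = None) -> ImageStack:
    """Zero-phase type-I Chebyshev bandpass of every pixel's time series.

    The designed filter is applied forward–backward (``sosfiltfilt`` with
    its odd-reflection padding), so the result has zero phase lag — the
    zero-lag Pearson correlations computed downstream are not biased by a
    filter delay. Undefined pixels stay undefined.
    """
    spec = spec or FilterSpec()
    sos = spec.sos(stack.fps)
    # warm-up: forward-backward needs a few filter lengths of data
    ntaps = 2 * spec.order + 1
    if stack.n_frames < 3 * ntaps:
        raise ValueError(
            f"stack of {stack.n_frames} frames is too short for an order-"
            f"{spec.order} bandpass (need >= {3 * ntaps})"
        )
    flat = stack.data.reshape(stack.n_frames, -1)
    defined = _defined_columns(flat)
    out = np.full_like(flat, UNDEFINED)
    if defined.any():
        out[:, defined] = signal.sosfiltfilt(sos, flat[:, defined], axis=0)
    return stack.with_data(out.reshape(stack.data.shape))


def dff(stack: ImageStack) -> ImageStack:
    """ΔF/F0 against the all-frame mean.

    Per pixel, the baseline F0 is the temporal mean of F and the output is
    ``(F − F0) / F0``. Pixels with a zero baseline become undefined (a count
    is logged); undefined inputs propagate through the mean.
    """
    f0 = stack.data.mean(axis=0)
    zero = f0 == 0
    n_zero = int(np.count_nonzero(zero))
    if n_zero:
        logger.info("dff: %d pixel(s) with zero baseline marked undefined", n_zero)
        f0 = f0.copy()
        f0[zero] = UNDEFINED
    return stack.with_data((stack.data - f0[None]) / f0[None])


def global_signal(stack: ImageStack) -> GlobalSignal:
    """Frame-wise mean over all defined pixels."""
    defined = _defined_columns(stack.data.reshape(stack.n_frames, -1))
    if not defined.any():
        raise ValueError("global signal undefined: no pixel is defined at all frames")
    series = stack.data.reshape(stack.n_frames, -1)[:, defined].mean(axis=1)
    return GlobalSignal(series)


def gsr(stack: ImageStack) -> ImageStack:
    """Global signal regression: per-pixel removal of the global signal.

    Each defined pixel's series is regressed (ordinary least squares, with
    intercept) on the global signal — the frame-wise mean over defined
    pixels — and replaced by its residuals. This suppresses brain-wide
    fluctuations and heightens local structure in later correlation
    analysis. Undefined pixels propagate.
    """
    if stack.n_frames < 3:
        raise ValueError("gsr needs at least 3 frames")
    g = global_signal(stack).series
    if np.ptp(g) == 0:
        raise ValueError("gsr undefined: global signal is constant")
    flat = stack.data.reshape(stack.n_frames, -1)
    defined = _defined_columns(flat)
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, flat[:, defined], rcond=None)
    out = np.full_like(flat, UNDEFINED)
    out[:, defined] = flat[:, defined] - X @ beta
    return stack.with_data(out.reshape(stack.data.shape))


def concat_stacks(stacks: Sequence[ImageStack]) -> ImageStack:
    """Concatenate trials along time, in list order.

    All stacks must share frame shape and frame rate. Pooling every trial
    into one long series is how seed-pixel correlation maps use as much
    spontaneous activity as possible.
    """
    if len(stacks) == 0:
        raise ValueError("nothing to concatenate")
    first = stacks[0]
    for i, s in enumerate(stacks[1:], start=1):
        if s.frame_shape != first.frame_shape:
            raise ValueError(
                f"stack {i} shape {s.frame_shape} != stack 0 shape {first.frame_shape}"
            )
        if s.fps != first.fps:
            raise ValueError(f"stack {i} fps {s.fps} != stack 0 fps {first.fps}")
    return ImageStack(np.concatenate([s.data for s in stacks], axis=0), first.fps)


def divide_stacks(numerator: ImageStack, denominator: ImageStack) -> ImageStack:
    """Elementwise ratio of two stacks; zero denominators become undefined.

    Dividing fluorescence ΔF/F0 by reflectance ΔF/F0 is a simple hemodynamic
    correction.
    """
    if numerator.data.shape != denominator.data.shape:
        raise ValueError(
            f"shape mismatch: {numerator.data.shape} vs {denominator.data.shape}"
        )
    den = denominator.data
    with np.errstate(divide="ignore", invalid="ignore"):
        out = numerator.data / den
    out[den == 0] = UNDEFINED
    return numerator.with_data(out)


def evoked_average(
    stacks: Sequence[ImageStack], truncate_to_shortest: bool = False
) -> ImageStack:
    """Frame-by-frame mean across trials.

    All trials must share shape and length unless ``truncate_to_shortest``
    is set, in which case every trial is cut to the shortest one first.
    """
    if len(stacks) == 0:
        raise ValueError("nothing to average")
    first = stacks[0]
    for i, s in enumerate(stacks[1:], start=1):
        if s.frame_shape != first.frame_shape:
            raise ValueError(f"trial {i} frame shape differs from trial 0")
    lengths = {s.n_frames for s in stacks}
    if len(lengths) > 1:
        if not truncate_to_shortest:
            raise ValueError(
                f"trial lengths differ ({sorted(lengths)}); "
                "pass truncate_to_shortest=True to truncate"
            )
        n = min(lengths)
        arrays = [s.data[:n] for s in stacks]
    else:
        arrays = [s.data for s in stacks]
    return ImageStack(np.mean(arrays, axis=0), first.fps)


def stdev_map(stack: ImageStack) -> np.ndarray:
    """Per-pixel temporal standard deviation (population, divisor n)."""
    if stack.n_frames < 2:
        raise ValueError("stdev map needs at least 2 frames")
    return stack.data.std(axis=0, ddof=0)
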