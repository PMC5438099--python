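"""Zero-lag Pearson connectivity machinery.

Functional connectivity between cortical locations is measured as the
zero-lag Pearson correlation of their fluorescence time series. Two views
are produced:

* a seed-pixel correlation (SPC) map — the correlation of one seed pixel's
  series with every other pixel's, rendered over the frame; and
* RoI×RoI correlation matrices — per trial, the correlation between every
  pair of RoI time courses, then summarised across trials by the mean and
  the sample standard deviation of each pair's r-value.

Frames where either series is undefined are dropped pairwise before the
correlation is computed; the effective sample size is tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .coords import CoordinateSystem, SeedRoI, seed_pixels
from .stack import UNDEFINED, ImageStack

#: Minimum pairwise-complete frames for a correlation to be defined.
_MIN_FRAMES = 3


@dataclass
class SPCMap:
    """Seed-pixel correlation map.

    ``values`` is a height×width array of Pearson r in [−1, 1], NaN where a
    pixel is masked or has zero variance; ``seed`` is the (x, y) pixel the
    map is seeded at; ``provenance`` carries the manipulation history of the
    source stack when known.
    """

    values: np.ndarray
    seed: tuple[int, int]
    provenance: list = field(default_factory=list)


@dataclass
class CorrelationMatrices:
    """Cross-trial summary of RoI×RoI correlations."""

    roi_names: list[str]
    mean_r: np.ndarray
    std_r: np.ndarray
    n_stacks: int


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag Pearson correlation with pairwise deletion of undefined frames.

    Raises if fewer than three pairwise-complete frames remain or either
    series is constant over them (the correlation is then undefined).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"series lengths differ: {a.size} vs {b.size}")
    valid = np.isfinite(a) & np.isfinite(b)
    n = int(valid.sum())
    if n < _MIN_FRAMES:
        raise ValueError(f"need >= {_MIN_FRAMES} pairwise-complete frames, have {n}")
    av, bv = a[valid], b[valid]
    av = av - av.mean()
    bv = bv - bv.mean()
    na, nb = np.sqrt(av @ av), np.sqrt(bv @ bv)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined: constant series")
    return float((av @ bv) / (na * nb))


def roi_timecourse(
    stack: ImageStack, pixels: Iterable[tuple[int, int]]
) -> np.ndarray:
    """Frame-wise mean over a set of (x, y) pixels, skipping undefined values.

    Raises if the set contains no pixel that is ever defined.
    """
    pix = list(pixels)
    if not pix:
        raise ValueError("empty pixel set")
    xs = np.array([p[0] for p in pix])
    ys = np.array([p[1] for p in pix])
    block = stack.data[:, ys, xs]  # n_frames × n_pixels
    finite = np.isfinite(block)
    if not finite.any():
        raise ValueError("RoI is fully masked: no defined pixel")
    counts = finite.sum(axis=1)
    sums = np.where(finite, block, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        series = sums / counts
    series[counts == 0] = UNDEFINED
    return series


def _corr_with_seed(
    flat: np.ndarray, seed_series: np.ndarray, chunk: int = 8192
) -> np.ndarray:
    """Pearson r of every column of ``flat`` against ``seed_series``.

    Pairwise deletion per column; columns with < _MIN_FRAMES complete frames
    or zero variance come back NaN. Chunked so memory stays bounded for
    long concatenated recordings.
    """
    n = flat.shape[0]
    s = seed_series
    s_ok = np.isfinite(s)
    r = np.full(flat.shape[1], UNDEFINED)
    for start in range(0, flat.shape[1], chunk):
        cols = flat[:, start : start + chunk]
        ok = np.isfinite(cols) & s_ok[:, None]
        cnt = ok.sum(axis=0).astype(np.float64)
        x = np.where(ok, cols, 0.0)
        sv = np.where(ok, s[:, None], 0.0)
        sx = x.sum(axis=0)
        ss = sv.sum(axis=0)
        sxx = (x * x).sum(axis=0)
        sss = (sv * sv).sum(axis=0)
        sxs = (x * sv).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxs - sx * ss / cnt
            vx = sxx - sx * sx / cnt
            vs = sss - ss * ss / cnt
            rr = cov / np.sqrt(vx * vs)
        bad = (cnt < _MIN_FRAMES) | (vx <= 0) | (vs <= 0)
        rr[bad] = UNDEFINED
        r[start : start + chunk] = rr
    return r


def spc_map(
    stack: ImageStack,
    seed: tuple[int, int],
    provenance: Sequence | None = None,
) -> SPCMap:
    """Correlate one seed pixel's series with every pixel in the stack.

    ``seed`` is an (x, y) pixel coordinate. The value at the seed itself is
    exactly 1; masked or zero-variance pixels are NaN.
    """
    x, y = int(seed[0]), int(seed[1])
    if not (0 <= x < stack.width and 0 <= y < stack.height):
        raise ValueError(f"seed ({x}, {y}) outside {stack.height}×{stack.width} frame")
    s = stack.data[:, y, x]
    if int(np.isfinite(s).sum()) < _MIN_FRAMES:
        raise ValueError(f"seed ({x}, {y}) lies in a masked region")
    if np.nanstd(s) == 0:
        raise ValueError(f"seed ({x}, {y}) series is constant")
    flat = stack.data.reshape(stack.n_frames, -1)
    r = _corr_with_seed(flat, s).reshape(stack.frame_shape)
    r[y, x] = 1.0
    return SPCMap(values=r, seed=(x, y), provenance=list(provenance or []))


def correlation_matrix(
    stacks: Sequence[ImageStack],
    rois: Sequence[SeedRoI],
    cs: CoordinateSystem,
) -> CorrelationMatrices:
    """RoI×RoI correlation matrices averaged across trials.

    For every stack, each RoI is resolved to its pixel block and reduced to
    a time course; the zero-lag Pearson r is computed for every RoI pair.
    ``mean_r`` is the arithmetic mean across stacks, ``std_r`` the sample
    (n−1) standard deviation — zero when there is a single stack.
    """
    if len(stacks) < 1:
        raise ValueError("need at least one stack")
    if len(rois) < 2:
        raise ValueError("need at least two RoIs")
    k = len(rois)
    mats = np.empty((len(stacks), k, k))
    for si, stack in enumerate(stacks):
        tcs = []
        for roi in rois:
            pix = seed_pixels(roi, cs, stack.frame_shape)
            try:
                tcs.append(roi_timecourse(stack, pix))
            except ValueError as exc:
                raise ValueError(
                    f"RoI {roi.name!r} unusable in stack {si}: {exc}"
                ) from exc
        m = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                try:
                    rij = pearson_r(tcs[i], tcs[j])
                except ValueError as exc:
                    raise ValueError(
                        f"correlation of {rois[i].name!r} and {rois[j].name!r} "
                        f"undefined in stack {si}: {exc}"
                    ) from exc
                m[i, j] = m[j, i] = rij
        mats[si] = m
    mean_r = mats.mean(axis=0)
    std_r = mats.std(axis=0, ddof=1) if len(stacks) > 1 else np.zeros((k, k))
    np.fill_diagonal(mean_r, 1.0)
    np.fill_diagonal(std_r, 0.0)
    return CorrelationMatrices(
        roi_names=[r.name for r in rois],
        mean_r=mean_r,
        std_r=std_r,
        n_stacks=len(stacks),
    )
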