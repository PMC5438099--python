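"""Ground-truth synthetic widefield stacks and on-disk project fixtures.

The generator emulates what the processing pipeline sees in practice:
256×256-pixel stacks at 30 Hz in which a handful of cortical regions (disks)
each follow a latent band-limited source signal, every pixel additionally
carries a shared slow "global" component, a fast heartbeat-band sinusoid and
per-pixel white noise, and whole stacks may be rigidly misaligned. The
latent sources are drawn with an exactly controllable pairwise correlation
structure, so seed-pixel correlation maps and correlation matrices computed
downstream can be checked against planted ground truth.

Pixel model, per region pixel::

    F(t) = baseline * (1 + a_src * source(t) + a_glob * global(t)
                         + a_heart * sin(2π f_heart t) + σ * ε(t))

with ``source``/``global`` standardized (zero mean, unit variance)
moving-average-smoothed Gaussian series and ε white Gaussian noise. Pixels
outside every region omit the source term.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .register import RigidTransform, apply_transform
from .stack import ImageStack


@dataclass
class Region:
    """Disk-shaped source region: center (x, y) px, radius px, source index."""

    center: tuple[float, float]
    radius: float
    source_id: int


@dataclass
class SynthConfig:
    """Study conditions for one synthetic stack.

    Defaults emulate the recordings the pipeline was designed around:
    256×256 pixels at 30 Hz, 900-frame (30 s) epochs, two lateral regions
    per hemisphere, a heartbeat confound near 10 Hz, and a few-percent
    fluorescence fluctuation on a flat baseline.
    """

    height: int = 256
    width: int = 256
    n_frames: int = 900
    fps: float = 30.0
    regions: Sequence[Region] = field(default_factory=list)
    source_correlations: np.ndarray | None = None
    source_amplitude: float = 0.05
    global_amplitude: float = 0.0
    heartbeat_hz: float = 10.0
    heartbeat_amplitude: float = 0.02
    noise_sigma: float = 0.01
    baseline: float = 100.0
    smooth_window: int = 3
    rigid_motion: RigidTransform | None = None
    seed: int = 0
    #: Seed of the static vessel anatomy multiplying the baseline. Stacks
    #: recorded from one animal share it (the fixture generator keeps it
    #: fixed across trials), giving registration stable structure to lock
    #: onto. None disables anatomy (flat baseline).
    anatomy_seed: int | None = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (self.baseline > 0):
            raise ValueError("baseline must be positive")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")

    @property
    def n_sources(self) -> int:
        return 1 + max((r.source_id for r in self.regions), default=-1)


def default_regions(height: int = 256, width: int = 256) -> list[Region]:
    """Four disk regions, two per hemisphere, each with its own source."""
    h, w = height, width
    r = min(h, w) / 10.0
    return [
        Region(center=(w * 0.30, h * 0.30), radius=r, source_id=0),
        Region(center=(w * 0.70, h * 0.30), radius=r, source_id=1),
        Region(center=(w * 0.30, h * 0.70), radius=r, source_id=2),
        Region(center=(w * 0.70, h * 0.70), radius=r, source_id=3),
    ]


def _correlation_root(corr: np.ndarray) -> np.ndarray:
    """Matrix square root L with L Lᵀ = corr; validates the matrix."""
    corr = np.asarray(corr, dtype=np.float64)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("source_correlations must be square")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("source_correlations must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("source_correlations must have unit diagonal")
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-10:
        raise ValueError(
            f"source_correlations is not positive semidefinite "
            f"(min eigenvalue {vals.min():.3g})"
        )
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def _smoothed_standardized(
    rng: np.random.Generator, n_series: int, n_frames: int, window: int
) -> np.ndarray:
    """n_frames × n_series band-limited standardized Gaussian series."""
    z = rng.standard_normal((n_frames + window - 1, n_series))
    if window > 1:
        z = ndimage.uniform_filter1d(z, size=window, axis=0, mode="nearest")
    z = z[:n_frames]
    z = z - z.mean(axis=0)
    sd = z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return z / sd


def generate_sources(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent region sources with the requested correlation structure.

    Independent smoothed series are mixed through a matrix square root of
    ``source_correlations``; the planted pairwise correlations hold exactly
    in expectation and converge with the number of frames.
    """
    k = cfg.n_sources
    if k == 0:
        return np.zeros((cfg.n_frames, 0))
    corr = cfg.source_correlations
    if corr is None:
        corr = np.eye(k)
    L = _correlation_root(corr)
    if L.shape[0] != k:
        raise ValueError(
            f"source_correlations is {L.shape[0]}×{L.shape[0]} but regions "
            f"reference {k} sources"
        )
    z = _smoothed_standardized(rng, k, cfg.n_frames, cfg.smooth_window)
    return z @ L.T


def region_masks(cfg: SynthConfig) -> np.ndarray:
    """n_sources × height × width boolean masks (overlaps sum sources)."""
    masks = np.zeros((cfg.n_sources, cfg.height, cfg.width), dtype=bool)
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    for reg in cfg.regions:
        d2 = (xx - reg.center[0]) ** 2 + (yy - reg.center[1]) ** 2
        masks[reg.source_id] |= d2 <= reg.radius**2
    return masks


def generate_stack(cfg: SynthConfig) -> tuple[ImageStack, dict]:
    """Generate one synthetic stack plus its ground-truth record.

    Fully reproducible from ``cfg.seed``. The ground truth carries the
    source series, the global series, region definitions and any applied
    rigid motion.
    """
    rng = np.random.default_rng(cfg.seed)
    sources = generate_sources(cfg, rng)
    glob = _smoothed_standardized(rng, 1, cfg.n_frames, cfg.smooth_window)[:, 0]
    t = np.arange(cfg.n_frames) / cfg.fps
    heart = np.sin(2.0 * np.pi * cfg.heartbeat_hz * t)

    frames = np.ones((cfg.n_frames, cfg.height, cfg.width))
    if cfg.n_sources:
        masks = region_masks(cfg)
        for sid in range(cfg.n_sources):
            frames[:, masks[sid]] += (
                cfg.source_amplitude * sources[:, sid]
            )[:, None]
    frames += (cfg.global_amplitude * glob + cfg.heartbeat_amplitude * heart)[
        :, None, None
    ]
    if cfg.noise_sigma > 0:
        frames += cfg.noise_sigma * rng.standard_normal(frames.shape)
    if cfg.anatomy_seed is None:
        baseline_img = np.full((cfg.height, cfg.width), cfg.baseline)
    else:
        scene = make_vessel_scene((cfg.height, cfg.width), seed=cfg.anatomy_seed)
        baseline_img = cfg.baseline * scene / scene.mean()
    stack = ImageStack(baseline_img[None] * frames, cfg.fps)
    if cfg.rigid_motion is not None:
        stack = apply_transform(stack, cfg.rigid_motion)

    truth = {
        "seed": cfg.seed,
        "anatomy_seed": cfg.anatomy_seed,
        "sources": sources,
        "global": glob,
        "regions": [
            {"center": list(r.center), "radius": r.radius, "source_id": r.source_id}
            for r in cfg.regions
        ],
        "rigid_motion": (
            None
            if cfg.rigid_motion is None
            else {
                "dx": cfg.rigid_motion.dx,
                "dy": cfg.rigid_motion.dy,
                "theta": cfg.rigid_motion.theta,
                "scale": cfg.rigid_motion.scale,
            }
        ),
    }
    return stack, truth


def make_vessel_scene(
    shape: tuple[int, int], n_vessels: int = 24, seed: int = 0
) -> np.ndarray:
    """Vessel-like test frame: dark meandering curves on a smooth background.

    Emulates the blood-vessel pattern that anchors rigid registration of
    widefield frames — oriented, sharp, spatially sparse structure over a
    slowly varying illumination profile.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.zeros(shape)
    for _ in range(n_vessels):
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(2 * max(h, w)):
            ang += rng.normal(0, 0.15)
            x += np.cos(ang)
            y += np.sin(ang)
            ix, iy = int(round(x)), int(round(y))
            if 0 <= ix < w and 0 <= iy < h:
                img[iy, ix] = 1.0
    img = ndimage.gaussian_filter(img, 1.2)
    bg = ndimage.gaussian_filter(rng.standard_normal(shape), 6)
    return 100.0 * (1.0 + 0.3 * bg) - 30.0 * img


def misaligned_views(
    size: int, motion: RigidTransform, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """A reference view and a rigidly moved view of one vessel scene.

    Both views are ``size × size`` center crops of a twice-larger scene, so
    the moved view is full-field (no exposed border) exactly as a moved
    camera would see it. The returned pair satisfies
    ``apply_transform(moving, motion) ≈ reference`` away from the borders.
    """
    big = make_vessel_scene((2 * size, 2 * size), seed=seed)
    c0 = size // 2
    ref = big[c0 : c0 + size, c0 : c0 + size].copy()
    inv = motion.inverse()
    # build the inverse motion about the crop center, in scene coordinates
    cx = cy = c0 + (size - 1) / 2.0
    th = np.deg2rad(inv.theta)
    c, s = np.cos(th), np.sin(th)
    rs = inv.scale * np.array([[c, -s], [s, c]])
    m = np.eye(3)
    m[:2, :2] = rs
    m[:2, 2] = [
        cx + inv.dx - rs[0, 0] * cx - rs[0, 1] * cy,
        cy + inv.dy - rs[1, 0] * cx - rs[1, 1] * cy,
    ]
    from skimage.transform import warp

    moved = warp(
        big, inverse_map=np.linalg.inv(m), order=1, mode="edge", preserve_range=True
    )
    return ref, moved[c0 : c0 + size, c0 : c0 + size].copy()


def generate_project_fixture(
    cfg: SynthConfig,
    n_stacks: int,
    project_dir: str | os.PathLike,
    motions: Sequence[RigidTransform | None] | None = None,
):
    """Write an on-disk project of RAW stacks plus manifest and ground truth.

    Every stack shares the region layout and source correlation structure;
    source series and noise are redrawn per stack (seeds derived from
    ``cfg.seed``), so trials are exchangeable but independent. RAW files are
    float64 single-channel; each is imported into the project (NPY
    conversion, an ``import`` manipulation) exactly as a recorded file would
    be. Ground truth is saved as JSON beside the stacks.
    """
    from dataclasses import replace

    from . import project as prj
    from .stackio import RawSpec, write_raw_stack

    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    manifest = prj.create_project(project_dir)
    truths = {}
    for i in range(n_stacks):
        motion = motions[i] if motions is not None else cfg.rigid_motion
        stack_cfg = replace(cfg, seed=cfg.seed + 1000 * (i + 1), rigid_motion=motion)
        stack, truth = generate_stack(stack_cfg)
        name = f"stack_{i:03d}"
        raw_path = os.path.join(manifest.project_dir, name + ".raw")
        write_raw_stack(stack, raw_path, dtype="float64")
        spec = RawSpec(width=cfg.width, height=cfg.height, n_channels=1, dtype="float64")
        prj.import_raw(manifest, raw_path, spec, fps=cfg.fps, name=name)
        truths[name] = {
            "seed": truth["seed"],
            "regions": truth["regions"],
            "rigid_motion": truth["rigid_motion"],
        }
    with open(os.path.join(manifest.project_dir, "ground_truth.json"), "w") as fh:
        json.dump(truths, fh, indent=1)
    return manifest
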