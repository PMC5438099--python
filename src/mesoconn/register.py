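"""FFT-based rigid alignment of image stacks to a vessel-emphasizing reference.

Widefield recordings collected across sessions are brought into one frame of
reference in three steps: every frame of a chosen template stack is
sharpened with an unsharp filter so the blood-vessel pattern stands out, a
band of its frames is averaged into the reference frame, and each stack is
then rigidly aligned to that reference. The rigid motion (translation,
rotation, scale) is estimated once per stack from a single frame — head
movement *within* a stack is assumed negligible — and applied to all of its
frames.

Rotation and scale are estimated first, from the phase correlation of
log-polar resampled magnitude spectra of Hann-windowed frames (the spectrum
magnitude is translation-invariant; rotation and log-scale become shifts in
log-polar coordinates). The residual translation is then recovered by plain
phase correlation with subpixel peak interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import warp, warp_polar

from .stack import UNDEFINED, ImageStack


@dataclass
class RigidTransform:
    """Rigid-body motion: translation (pixels), rotation (degrees, CCW about
    the frame center), isotropic scale about the frame center.

    Applying the transform maps a *moving* frame into the reference frame:
    scale and rotation about the center first, then translation by
    ``(dx, dy)`` (x = columns rightward, y = rows downward).
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")

    def matrix(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """3×3 forward matrix in homogeneous (x, y) pixel coordinates."""
        h, w = frame_shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        t = np.deg2rad(self.theta)
        c, s = np.cos(t), np.sin(t)
        rs = self.scale * np.array([[c, -s], [s, c]])
        m = np.eye(3)
        m[:2, :2] = rs
        m[:2, 2] = [
            cx + self.dx - rs[0, 0] * cx - rs[0, 1] * cy,
            cy + self.dy - rs[1, 0] * cx - rs[1, 1] * cy,
        ]
        return m

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one (exact in parameters; resampling twice
        still costs interpolation error)."""
        t = np.deg2rad(self.theta)
        c, s = np.cos(t), np.sin(t)
        inv_s = 1.0 / self.scale
        # rotate the translation back into the moving frame's axes
        dx = -(c * self.dx + s * self.dy) * inv_s
        dy = -(-s * self.dx + c * self.dy) * inv_s
        return RigidTransform(dx=dx, dy=dy, theta=-self.theta, scale=inv_s)


def unsharp_filter(stack: ImageStack, kernel_size: int = 8) -> ImageStack:
    """Sharpen every frame: ``frame + (frame − blur(frame))``.

    The blur is Gaussian with standard deviation ``kernel_size / 2`` and
    support radius ``kernel_size // 2``. Emphasizes blood vessels prior to
    building a registration reference. Undefined pixels propagate (and
    spread over the blur support, as any neighborhood filter must).
    """
    if kernel_size < 1:
        raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
    sigma = kernel_size / 2.0
    radius = max(1, kernel_size // 2)
    out = np.empty_like(stack.data)
    for i in range(stack.n_frames):
        blur = ndimage.gaussian_filter(stack.data[i], sigma=sigma, radius=radius)
        out[i] = 2.0 * stack.data[i] - blur
    return stack.with_data(out)


def build_reference(stack: ImageStack, start_frame: int, end_frame: int) -> np.ndarray:
    """Average frames ``[start_frame, end_frame)`` into a reference frame.

    Averaging a band of sharpened frames emphasizes stable anatomy (vessels)
    and suppresses activity transients. A single-frame range returns that
    frame.
    """
    if not (0 <= start_frame < end_frame <= stack.n_frames):
        raise ValueError(
            f"frame range [{start_frame}, {end_frame}) invalid for a "
            f"{stack.n_frames}-frame stack"
        )
    return stack.data[start_frame:end_frame].mean(axis=0)


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def compose_transforms(
    second: RigidTransform, first: RigidTransform, frame_shape: tuple[int, int]
) -> RigidTransform:
    """The single transform equivalent to applying ``first`` then ``second``."""
    m = second.matrix(frame_shape) @ first.matrix(frame_shape)
    a = m[:2, :2]
    scale = float(np.sqrt(np.linalg.det(a)))
    theta = float(np.rad2deg(np.arctan2(a[1, 0], a[0, 0])))
    h, w = frame_shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    d = m[:2, 2] + a @ c - c
    return RigidTransform(dx=float(d[0]), dy=float(d[1]), theta=theta, scale=scale)


def estimate_transform(
    moving: np.ndarray,
    reference: np.ndarray,
    upsample_factor: int = 20,
    bandpass_sigmas: tuple[float, float] | None = None,
    n_iter: int = 4,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    One estimation pass: both frames are band-pass filtered (difference of
    Gaussians, to suppress the flat illumination profile and pixel noise)
    and Hann windowed; rotation and scale are read off as shifts between
    the log-polar resampled low-frequency magnitude spectra — the spectrum
    magnitude is translation invariant, so these are estimated independently
    of any shift — and the remaining translation comes from a second phase
    correlation after undoing the recovered rotation/scale.

    Up to ``n_iter`` passes are run, each re-estimating the residual motion
    of the partially aligned frame and composing it onto the estimate; the
    loop exits early once the residual is negligible. Iteration removes the
    small bias a single pass retains for large combined motions. The
    returned transform satisfies ``apply_transform(moving, t) ≈ reference``.
    """
    t = _estimate_once(moving, reference, upsample_factor, bandpass_sigmas)
    for _ in range(n_iter - 1):
        partial = _warp_frame(moving, t, cval=float(moving.mean()))
        dt = _estimate_once(partial, reference, upsample_factor, bandpass_sigmas)
        t = compose_transforms(dt, t, reference.shape)
        if (
            max(abs(dt.dx), abs(dt.dy)) < 0.02
            and abs(dt.theta) < 0.05
            and abs(dt.scale - 1.0) < 0.002
        ):
            break
    return t


def _estimate_once(
    moving: np.ndarray,
    reference: np.ndarray,
    upsample_factor: int = 20,
    bandpass_sigmas: tuple[float, float] | None = None,
) -> RigidTransform:
    moving = np.asarray(moving, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if moving.shape != reference.shape:
        raise ValueError(f"frame shapes differ: {moving.shape} vs {reference.shape}")
    for name, frame in (("moving", moving), ("reference", reference)):
        if not np.all(np.isfinite(frame)):
            raise ValueError(f"{name} frame contains undefined pixels")
        if np.ptp(frame) == 0:
            raise ValueError(f"{name} frame is constant (degenerate)")

    from skimage.filters import difference_of_gaussians

    if bandpass_sigmas is None:
        # keep vessel-scale detail (a few px) and drop the smooth
        # illumination profile whose spectrum crowds DC and swamps the
        # log-radial axis of the polar warp
        bandpass_sigmas = (1.0, 2.5)
    win = _hann2d(reference.shape)
    spec_ref = np.log1p(np.abs(
        np.fft.fftshift(np.fft.fft2(difference_of_gaussians(reference, *bandpass_sigmas) * win))
    ))
    spec_mov = np.log1p(np.abs(
        np.fft.fftshift(np.fft.fft2(difference_of_gaussians(moving, *bandpass_sigmas) * win))
    ))
    radius = min(spec_ref.shape) // 4
    polar_shape = (360, 256)  # 1 deg / ~1.4% scale per raw bin, refined below
    warped_ref = warp_polar(
        spec_ref, radius=radius, output_shape=polar_shape, scaling="log", order=1
    )
    warped_mov = warp_polar(
        spec_mov, radius=radius, output_shape=polar_shape, scaling="log", order=1
    )
    # upper half only: the magnitude spectrum is point-symmetric
    half = polar_shape[0] // 2
    shifts, _, _ = phase_cross_correlation(
        warped_ref[:half],
        warped_mov[:half],
        upsample_factor=upsample_factor,
        normalization=None,
    )
    dtheta = (360.0 / polar_shape[0]) * shifts[0]
    klog = polar_shape[1] / np.log(radius)
    # a moving frame scaled by s has its spectrum scaled by 1/s
    scale = float(1.0 / np.exp(shifts[1] / klog))
    # wrap the 180-deg ambiguity of the spectrum onto the nearer branch
    if dtheta > 90.0:
        dtheta -= 180.0
    elif dtheta < -90.0:
        dtheta += 180.0
    dtheta = float(dtheta)

    # undo rotation/scale, then recover translation by phase correlation;
    # fill exposed borders with the frame mean to avoid step artifacts
    partial = RigidTransform(dx=0.0, dy=0.0, theta=dtheta, scale=scale)
    compensated = _warp_frame(moving, partial, cval=float(moving.mean()))
    shifts, _, _ = phase_cross_correlation(
        reference,
        compensated,
        upsample_factor=upsample_factor,
        normalization=None,
    )
    return RigidTransform(
        dx=float(shifts[1]), dy=float(shifts[0]), theta=dtheta, scale=scale
    )


def _warp_frame(
    frame: np.ndarray,
    t: RigidTransform,
    cval: float = UNDEFINED,
    mode: str = "constant",
) -> np.ndarray:
    inv = np.linalg.inv(t.matrix(frame.shape))
    return warp(
        frame,
        inverse_map=inv,
        order=1,
        cval=cval,
        mode=mode,
        preserve_range=True,
    )


def apply_transform(stack: ImageStack, t: RigidTransform) -> ImageStack:
    """Resample every frame of a stack under one rigid transform.

    All frames receive the identical transform (negligible within-stack
    motion is assumed). Bilinear interpolation; pixels mapped from outside
    the source frame become undefined rather than zero, so later cropping
    and correlation skip them honestly.
    """
    if (
        t.dx == 0.0
        and t.dy == 0.0
        and t.theta == 0.0
        and t.scale == 1.0
    ):
        return stack.copy()
    out = np.empty_like(stack.data)
    for i in range(stack.n_frames):
        out[i] = _warp_frame(stack.data[i], t)
    return stack.with_data(out)


def align_stacks(
    stacks: list[ImageStack],
    reference_index: int = 0,
    sharpen_kernel: int = 8,
    ref_start: int = 400,
    ref_end: int = 500,
    frame_index: int = 0,
) -> tuple[list[ImageStack], list[RigidTransform]]:
    """Align a set of stacks to a reference built from one of them.

    The reference is the mean of frames ``[ref_start, ref_end)`` of the
    unsharp-filtered stack at ``reference_index`` (the range is clipped to
    the stack length so short stacks still work). Each stack's transform is
    estimated from its ``frame_index``-th frame, sharpened the same way,
    and applied to all of its frames.
    """
    if not stacks:
        raise ValueError("no stacks to align")
    if not (0 <= reference_index < len(stacks)):
        raise ValueError(f"reference_index {reference_index} out of range")
    template = unsharp_filter(stacks[reference_index], sharpen_kernel)
    n = template.n_frames
    start = min(ref_start, n - 1)
    end = min(ref_end, n)
    reference = build_reference(template, start, max(end, start + 1))
    aligned: list[ImageStack] = []
    transforms: list[RigidTransform] = []
    for stack in stacks:
        sharp = ndimage.gaussian_filter(
            stack.data[frame_index], sigma=sharpen_kernel / 2.0,
            radius=max(1, sharpen_kernel // 2),
        )
        frame = 2.0 * stack.data[frame_index] - sharp
        t = estimate_transform(frame, reference)
        transforms.append(t)
        aligned.append(apply_transform(stack, t))
    return aligned, transforms
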