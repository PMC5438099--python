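"""Readers and writers for the stack formats the tool accepts.

Three formats are supported:

* headerless RAW binary with pixel-interleaved channels (the common RGB24
  camera layout: R,G,B,R,G,B…, row-major, frames consecutive), described by a
  :class:`RawSpec`;
* baseline multipage TIFF (grayscale or RGB), pages taken in file order as
  time;
* the native persisted form — a plain NPY file holding the 3-D float64 array
  in C order.

Only a single channel is kept on import and all data are converted to 64-bit
floating point immediately.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile

from .stack import ImageStack

_RAW_DTYPES = {
    "uint8": np.dtype(np.uint8),
    "float32": np.dtype(np.float32),
    "float64": np.dtype(np.float64),
}


@dataclass
class RawSpec:
    """Layout of a headerless RAW stack file.

    ``width``/``height`` are the frame dimensions in pixels, ``n_channels``
    the number of interleaved channels per pixel, ``dtype`` one of
    ``uint8``/``float32``/``float64``, and ``channel_index`` the 0-based
    channel kept on import.
    """

    width: int
    height: int
    n_channels: int = 1
    dtype: str = "uint8"
    channel_index: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.dtype not in _RAW_DTYPES:
            raise ValueError(
                f"unsupported RAW dtype {self.dtype!r}; "
                f"supported: {sorted(_RAW_DTYPES)}"
            )
        if not (0 <= self.channel_index < self.n_channels):
            raise ValueError(
                f"channel_index {self.channel_index} out of range for "
                f"{self.n_channels} channels"
            )

    @property
    def np_dtype(self) -> np.dtype:
        return _RAW_DTYPES[self.dtype]

    @property
    def frame_bytes(self) -> int:
        return self.width * self.height * self.n_channels * self.np_dtype.itemsize


def read_raw_stack(path: str | os.PathLike, spec: RawSpec, fps: float) -> ImageStack:
    """Read one channel of a headerless RAW stack.

    The frame count is inferred from the file size; a size that is not a
    whole number of frames is an error naming the residual bytes.
    """
    size = os.path.getsize(path)
    if size % spec.frame_bytes != 0:
        raise ValueError(
            f"{path}: file size {size} is not a whole number of "
            f"{spec.frame_bytes}-byte frames ({size % spec.frame_bytes} residual bytes)"
        )
    n_frames = size // spec.frame_bytes
    if n_frames == 0:
        raise ValueError(f"{path}: file holds zero frames")
    raw = np.fromfile(path, dtype=spec.np_dtype)
    raw = raw.reshape(n_frames, spec.height, spec.width, spec.n_channels)
    return ImageStack(raw[..., spec.channel_index].astype(np.float64), fps)


def write_raw_stack(
    stack: ImageStack,
    path: str | os.PathLike,
    dtype: str = "float64",
    n_channels: int = 1,
    channel_index: int = 0,
) -> str:
    """Write a stack as headerless RAW (pixel-interleaved channels).

    With ``n_channels > 1`` the stack is placed in ``channel_index`` and the
    remaining channels are zero-filled — useful for building multichannel
    fixtures. Inverse of :func:`read_raw_stack` for matching specs.
    """
    if dtype not in _RAW_DTYPES:
        raise ValueError(f"unsupported RAW dtype {dtype!r}")
    if not (0 <= channel_index < n_channels):
        raise ValueError("channel_index out of range")
    out = np.zeros(stack.data.shape + (n_channels,), dtype=_RAW_DTYPES[dtype])
    out[..., channel_index] = stack.data.astype(_RAW_DTYPES[dtype])
    out.tofile(os.fspath(path))
    return os.fspath(path)


def read_tiff_stack(
    path: str | os.PathLike, channel_index: int | None = None, fps: float = 30.0
) -> ImageStack:
    """Read a multipage TIFF as a stack, optionally extracting one channel.

    Pages are taken in file order as time. For pages carrying several samples
    per pixel (e.g. RGB) a ``channel_index`` must be given.
    """
    try:
        arr = tifffile.imread(os.fspath(path))
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path}: not a readable TIFF file ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:  # pages × rows × cols × samples
        if channel_index is None:
            raise ValueError(
                f"{path}: pages carry {arr.shape[-1]} samples per pixel; "
                "a channel_index is required"
            )
        if not (0 <= channel_index < arr.shape[-1]):
            raise ValueError(
                f"channel_index {channel_index} out of range for "
                f"{arr.shape[-1]} samples per pixel"
            )
        arr = arr[..., channel_index]
    elif arr.ndim != 3:
        raise ValueError(f"{path}: unsupported TIFF layout with shape {arr.shape}")
    elif channel_index not in (None, 0):
        raise ValueError(
            f"channel_index {channel_index} out of range for single-channel TIFF"
        )
    return ImageStack(arr.astype(np.float64), fps)


def persist_stack(stack: ImageStack, path: str | os.PathLike) -> str:
    """Persist a stack to the native NPY form (3-D float64, C order)."""
    path = os.fspath(path)
    try:
        np.save(path, np.ascontiguousarray(stack.data))
    except OSError as exc:
        raise OSError(f"could not write stack to {path}: {exc}") from exc
    return path if path.endswith(".npy") else path + ".npy"


def load_stack(path: str | os.PathLike, fps: float) -> ImageStack:
    """Load a persisted NPY stack.

    NPY holds only the array, so the frame rate is supplied by the caller
    (the project manifest records it per file).
    """
    path = os.fspath(path)
    try:
        data = np.load(path)
    except (OSError, ValueError, EOFError) as exc:
        raise ValueError(f"{path}: not a valid persisted stack ({exc})") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: persisted stack must be 3-D, got shape {data.shape}")
    return ImageStack(data, fps)
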