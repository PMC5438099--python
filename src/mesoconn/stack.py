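"""In-memory container for widefield image stacks.

An image stack is a fluorescence movie: ``n_frames × height × width`` in
64-bit floating point, together with the acquisition frame rate. Pixels that
carry no valid signal — masked by a polygon crop, exposed at the border by a
rigid resampling, or degenerate (zero baseline in ΔF/F0) — are marked with
NaN and every downstream operation either propagates or explicitly skips
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Reserved marker for undefined (masked / out-of-frame / degenerate) pixels.
UNDEFINED = np.nan


@dataclass
class ImageStack:
    """A 3-D fluorescence movie plus its frame rate.

    Parameters
    ----------
    data :
        Array of shape ``(n_frames, height, width)``. Converted to float64 on
        construction; NaN entries mark undefined pixels.
    fps :
        Acquisition frame rate in Hz. Must be positive.
    """

    data: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(
                f"stack data must be 3-D (frames, rows, cols), got shape {data.shape}"
            )
        if data.shape[0] < 1 or data.shape[1] < 1 or data.shape[2] < 1:
            raise ValueError(f"stack dimensions must all be >= 1, got {data.shape}")
        if not (self.fps > 0):
            raise ValueError(f"fps must be positive, got {self.fps}")
        self.data = data
        self.fps = float(self.fps)

    # -- shape accessors ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    # -- undefined-pixel helpers ------------------------------------------
    def defined_mask(self) -> np.ndarray:
        """Boolean array, elementwise: True where the value is defined."""
        return np.isfinite(self.data)

    def pixel_defined(self) -> np.ndarray:
        """2-D boolean mask of pixels defined at *every* frame."""
        return np.isfinite(self.data).all(axis=0)

    def copy(self) -> "ImageStack":
        return ImageStack(self.data.copy(), self.fps)

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """New stack with ``data`` and the same frame rate."""
        return ImageStack(data, self.fps)
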