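"""Rendering of connectivity results to image files.

Correlation maps use a symmetric diverging colormap centered at zero so
positive and negative coupling read symmetrically; the colormap name is
configuration, not contract.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .connectivity import CorrelationMatrices, SPCMap


def render_spc_map(
    m: SPCMap, path: str | os.PathLike, cmap: str = "RdBu_r", title: str | None = None
) -> str:
    """Render a seed-pixel correlation map to a PNG/JPEG; seed marked."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(m.values, cmap=cmap, vmin=-1, vmax=1, interpolation="nearest")
    ax.plot(m.seed[0], m.seed[1], "k+", markersize=8)
    ax.set_title(title or f"seed ({m.seed[0]}, {m.seed[1]})")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(os.fspath(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
    return os.fspath(path)


def render_corr_matrix(
    res: CorrelationMatrices, path: str | os.PathLike, cmap: str = "RdBu_r"
) -> str:
    """Render mean and cross-trial std matrices side by side."""
    k = len(res.roi_names)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.6))
    for ax, mat, label, vmin, vmax in (
        (axes[0], res.mean_r, "mean r", -1, 1),
        (axes[1], res.std_r, "std of r", 0, max(res.std_r.max(), 1e-9)),
    ):
        im = ax.imshow(mat, cmap=cmap if label == "mean r" else "viridis",
                       vmin=vmin, vmax=vmax)
        ax.set_xticks(range(k), res.roi_names, rotation=90, fontsize=7)
        ax.set_yticks(range(k), res.roi_names, fontsize=7)
        ax.set_title(f"{label} (n={res.n_stacks} stacks)")
        fig.colorbar(im, ax=ax)
    fig.savefig(os.fspath(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
    return os.fspath(path)


def plot_timecourses(
    series: dict[str, np.ndarray],
    fps: float,
    path: str | os.PathLike,
    frame_range: tuple[int, int] | None = None,
) -> str:
    """Plot RoI time courses (ΔF/F0 vs time), optionally a frame window."""
    fig, ax = plt.subplots(figsize=(8, 3.2))
    for name, s in series.items():
        s = np.asarray(s)
        lo, hi = frame_range or (0, s.size)
        t = np.arange(lo, hi) / fps
        ax.plot(t, s[lo:hi], lw=0.8, label=name)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ΔF/F0")
    ax.legend(fontsize=7, ncol=min(len(series), 4))
    fig.savefig(os.fspath(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
    return os.fspath(path)
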