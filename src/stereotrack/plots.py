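"""Report figures: MSD curves, depth-error histogram, 3D trajectories, and
red/cyan anaglyph of a stereo pair."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import DepthErrorReport, MsdCurve
from .tracking import Trajectory

__all__ = ["plot_msd", "plot_depth_error_hist", "plot_trajectories_3d", "anaglyph"]


def plot_msd(curves: list[MsdCurve], path: str | Path, labels=None) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, c in enumerate(curves):
        lbl = labels[i] if labels else f"track {i}"
        ax.plot(c.lags_s, c.msd_um2, "o-", ms=3, label=lbl)
    ax.set_xlabel("lag time (s)")
    ax.set_ylabel("MSD (μm²)")
    if len(curves) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_depth_error_hist(report: DepthErrorReport, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(report.errors_um, bins="auto", color="steelblue", edgecolor="k")
    ax.axvline(report.mean_um, color="r", ls="--", label=f"mean {report.mean_um:.2f} μm")
    ax.set_xlabel("|depth error| (μm)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_trajectories_3d(trajectories: list[Trajectory], path: str | Path) -> Path:
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for t in trajectories:
        p = t.positions()
        ax.plot(p[:, 0], p[:, 1], p[:, 2], lw=1)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_zlabel("z (μm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def anaglyph(pair, path: str | Path) -> Path:
    """Red = left view, cyan = right view."""
    def norm(img):
        mx = img.max()
        return img / mx if mx > 0 else img

    rgb = np.zeros(pair.left.shape + (3,))
    rgb[..., 0] = norm(pair.left)
    rgb[..., 1] = norm(pair.right)
    rgb[..., 2] = norm(pair.right)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rgb, origin="upper")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
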