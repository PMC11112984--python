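"""Particle segmentation and feature extraction per view.

Two detector modes share the :class:`Detection2D` output contract:

* ``hough`` — gradient-based circular Hough transform, appropriate for beads
  whose projected disc spans several pixels.
* ``blob`` — local-maximum + centroid detection for PSF-limited spots
  (sub-resolution particles), where a circle fit is ill-posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter, maximum_filter, label, center_of_mass
from skimage.feature import canny
from skimage.transform import hough_circle

__all__ = [
    "Detection2D",
    "segment_adaptive",
    "hough_circles",
    "detect_blobs",
    "extract_features",
    "detect_view",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Detection2D:
    """One detected particle in one view of one frame."""

    view: Literal["left", "right"]
    frame_index: int
    cx_px: float
    cy_px: float
    radius_px: float
    total_intensity: float
    encircled_energy: float


def robust_noise_sd(img: np.ndarray) -> float:
    """MAD-based estimate of the background noise standard deviation."""
    med = np.median(img)
    return 1.4826 * np.median(np.abs(img - med))


def segment_adaptive(img: np.ndarray, block_size_px: int = 31, offset: float = 0.0) -> np.ndarray:
    """Adaptive (local-mean) threshold: foreground iff value > local mean + offset."""
    if block_size_px < 3 or block_size_px % 2 == 0:
        raise ValueError(f"block_size_px must be odd and >= 3, got {block_size_px}")
    img = np.asarray(img, dtype=float)
    local_mean = uniform_filter(img, size=block_size_px, mode="reflect")
    return img > local_mean + offset


def _greedy_nms(
    candidates: list[tuple[float, float, float, float]], min_dist: float
) -> list[tuple[float, float, float]]:
    """Keep highest-score candidates such that no two kept centers are closer
    than ``min_dist``.  Candidates are (score, cx, cy, r); ties broken by
    score desc, then smaller cy, then smaller cx — deterministic ordering."""
    order = sorted(candidates, key=lambda c: (-c[0], c[2], c[1]))
    kept: list[tuple[float, float, float]] = []
    for score, cx, cy, r in order:
        if all((cx - kx) ** 2 + (cy - ky) ** 2 >= min_dist**2 for kx, ky, _ in kept):
            kept.append((cx, cy, r))
    return kept


def hough_circles(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    r_min_px: float = 5,
    r_max_px: float = 15,
    sensitivity: float = 0.35,
) -> list[tuple[float, float, float]]:
    """Detect circular objects via the circular Hough transform.

    Edges come from a Canny detector (optionally restricted to a dilated
    ``mask``); a circle accumulator is evaluated at integer radii in
    ``[r_min, r_max]``; candidates above ``sensitivity`` (fraction of a
    complete circle's edge support) are non-maximum suppressed so no two
    returned centers are closer than ``r_min``.

    Returns a list of ``(cx, cy, r)`` tuples (pixel coordinates).
    """
    if not (0 < r_min_px <= r_max_px):
        raise ValueError(f"invalid radius range [{r_min_px}, {r_max_px}]")
    img = np.asarray(img, dtype=float)
    vmax = img.max()
    if vmax <= 0:
        return []
    norm = img / vmax
    edges = canny(norm, sigma=1.5)
    if mask is not None:
        grow = maximum_filter(mask.astype(bool), size=5)
        edges = edges & grow
    if not edges.any():
        return []
    radii = np.arange(int(np.floor(r_min_px)), int(np.ceil(r_max_px)) + 1)
    accum = hough_circle(edges, radii)  # normalized: 1.0 = full circle support
    candidates: list[tuple[float, float, float, float]] = []
    for acc, r in zip(accum, radii):
        peaks = (acc == maximum_filter(acc, size=3)) & (acc > sensitivity)
        for cy, cx in np.argwhere(peaks):
            candidates.append((float(acc[cy, cx]), float(cx), float(cy), float(r)))
    return _greedy_nms(candidates, float(r_min_px))


def detect_blobs(
    img: np.ndarray,
    mask: np.ndarray,
    r_blob_px: float = 3.0,
    min_area_px: int = 4,
) -> list[tuple[float, float, float]]:
    """Local-maximum detector for PSF-limited spots.

    Connected foreground components of at least ``min_area_px`` pixels yield
    one candidate each at their intensity-weighted center; the reported
    radius is the fixed ``r_blob_px`` (the PSF scale), since sub-resolution
    spots carry no size information.
    """
    lbl, n = label(mask)
    if n == 0:
        return []
    out = []
    background = np.median(img)
    sub = np.clip(img - background, 0.0, None)
    for i in range(1, n + 1):
        region = lbl == i
        if region.sum() < min_area_px:
            continue
        if sub[region].sum() > 0:
            cy, cx = center_of_mass(sub, lbl, i)
        else:  # flat component: geometric centroid
            ys, xs = np.nonzero(region)
            cy, cx = ys.mean(), xs.mean()
        out.append((float(cx), float(cy), float(r_blob_px)))
    out.sort(key=lambda c: (c[1], c[0]))
    return out


def extract_features(
    img: np.ndarray,
    circles: list[tuple[float, float, float]],
    frame_index: int = 0,
    view: Literal["left", "right"] = "left",
) -> list[Detection2D]:
    """Compute the stereo-matching feature vector for each candidate circle.

    The centroid is refined by intensity-weighted center of mass within a
    ``1.5 r`` window; ``total_intensity`` is the background-subtracted sum in
    a ``2 r`` window; ``encircled_energy`` is the fraction of that total
    within ``r`` of the refined centroid.  Background is the frame median
    (robust against sparse bright particles).  Degenerate candidates (window
    outside the frame, or zero net intensity) are dropped with a warning.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    background = np.median(img)
    dets: list[Detection2D] = []
    for cx, cy, r in circles:
        half = 2.0 * r
        y0, y1 = int(np.floor(cy - half)), int(np.ceil(cy + half)) + 1
        x0, x1 = int(np.floor(cx - half)), int(np.ceil(cx + half)) + 1
        if y1 <= 0 or x1 <= 0 or y0 >= h or x0 >= w:
            logger.warning("candidate at (%.1f, %.1f) outside frame; dropped", cx, cy)
            continue
        y0c, y1c, x0c, x1c = max(y0, 0), min(y1, h), max(x0, 0), min(x1, w)
        window = np.clip(img[y0c:y1c, x0c:x1c] - background, 0.0, None)
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]

        # centroid refinement inside 1.5 r
        near = (xx - cx) ** 2 + (yy - cy) ** 2 <= (1.5 * r) ** 2
        wsum = window[near].sum()
        if wsum <= 0:
            logger.warning("zero-intensity candidate at (%.1f, %.1f); dropped", cx, cy)
            continue
        rcx = float((window[near] * xx[near]).sum() / wsum)
        rcy = float((window[near] * yy[near]).sum() / wsum)

        in2r = (xx - rcx) ** 2 + (yy - rcy) ** 2 <= (2.0 * r) ** 2
        total = float(window[in2r].sum())
        if total <= 0:
            logger.warning("zero total intensity at (%.1f, %.1f); dropped", cx, cy)
            continue
        inr = (xx - rcx) ** 2 + (yy - rcy) ** 2 <= r**2
        ee = float(window[inr].sum() / total)
        if not (0.0 <= rcx < w and 0.0 <= rcy < h):
            logger.warning("refined centroid left the frame; dropped")
            continue
        dets.append(
            Detection2D(
                view=view,
                frame_index=frame_index,
                cx_px=rcx,
                cy_px=rcy,
                radius_px=float(r),
                total_intensity=total,
                encircled_energy=min(ee, 1.0),
            )
        )
    return dets


def detect_view(
    img: np.ndarray,
    frame_index: int,
    view: Literal["left", "right"],
    mode: Literal["hough", "blob"] = "hough",
    r_min_px: float = 5,
    r_max_px: float = 15,
    sensitivity: float = 0.35,
    block_size_px: int = 31,
    offset_nsigma: float = 2.0,
    r_blob_px: float = 3.0,
) -> list[Detection2D]:
    """Segment one restored view and return its feature records."""
    # noise-scaled offset with a relative floor so that noiseless images do
    # not segment on numerical fuzz (MAD = 0 there)
    offset = max(offset_nsigma * robust_noise_sd(img), 1e-2 * float(img.max()))
    mask = segment_adaptive(img, block_size_px, offset)
    if mode == "hough":
        circles = hough_circles(img, mask, r_min_px, r_max_px, sensitivity)
    else:
        circles = detect_blobs(img, mask, r_blob_px)
    return extract_features(img, circles, frame_index, view)
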