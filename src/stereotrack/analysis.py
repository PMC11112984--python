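"""Trajectory and reconstruction quality metrics: MSD, localization
precision, depth-error statistics, drift velocity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tracking import Trajectory

__all__ = [
    "MsdCurve",
    "PrecisionReport",
    "DepthErrorReport",
    "compute_msd",
    "localization_precision",
    "depth_error_report",
    "drift_velocity",
]

_DIM_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class MsdCurve:
    """Time-averaged mean squared displacement vs lag time."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    dims: tuple[str, ...]


@dataclass(frozen=True)
class PrecisionReport:
    """Per-axis standard deviation of a nominally stationary particle."""

    sd_x_um: float
    sd_y_um: float
    sd_z_um: float
    n_frames: int


@dataclass
class DepthErrorReport:
    """Absolute depth-error statistics of a reconstruction vs ground truth."""

    errors_um: np.ndarray

    def __post_init__(self) -> None:
        self.errors_um = np.asarray(self.errors_um, dtype=float)
        if np.any(self.errors_um < 0):
            raise ValueError("depth errors must be non-negative")

    @property
    def mean_um(self) -> float:
        return float(self.errors_um.mean()) if self.errors_um.size else float("nan")

    def fraction_below(self, threshold_um: float) -> float:
        """Fraction of particles with |z error| < threshold (a valid CDF)."""
        if self.errors_um.size == 0:
            return float("nan")
        return float(np.mean(self.errors_um < threshold_um))


def _gap_frames(traj: Trajectory) -> set[int]:
    """Frames immediately after a bridged gap; displacement pairs spanning a
    gap are excluded from the MSD average."""
    return {start for _, start in traj.gap_links}


def compute_msd(
    traj: Trajectory,
    dims: Sequence[str] = ("x", "y", "z"),
    max_lag_fraction: float = 0.25,
    volume_rate_hz: float = 30.0,
    overlapping: bool = True,
) -> MsdCurve:
    """Time-averaged MSD of one trajectory over the selected axes.

    Uses all ordered observation pairs at each integer frame lag up to
    ``max_lag_fraction`` of the trajectory duration (overlapping estimator;
    set ``overlapping=False`` for independent, non-overlapping pairs).  Pairs
    whose interval spans a bridged gap are excluded.
    """
    if traj.length < 2:
        raise ValueError("trajectory must have at least 2 points")
    dims = tuple(dims)
    cols = [_DIM_INDEX[d] for d in dims]
    frames = np.array(traj.frames)
    pos = traj.positions()[:, cols]
    span = frames[-1] - frames[0]
    max_lag = max(1, int(np.floor(max_lag_fraction * span)))
    gap_after = _gap_frames(traj)

    lags, msds, counts = [], [], []
    for lag in range(1, max_lag + 1):
        sq = []
        start = 0
        i = 0
        while i < len(frames):
            # find a partner exactly `lag` frames later
            j = np.searchsorted(frames, frames[i] + lag)
            if j < len(frames) and frames[j] == frames[i] + lag:
                # exclude pairs spanning a bridged gap
                if not any(frames[i] < g <= frames[j] for g in gap_after):
                    sq.append(np.sum((pos[j] - pos[i]) ** 2))
                    if not overlapping:
                        i = j
                        continue
            i += 1
        if sq:
            lags.append(lag / volume_rate_hz)
            msds.append(float(np.mean(sq)))
            counts.append(len(sq))
    return MsdCurve(
        lags_s=np.array(lags),
        msd_um2=np.array(msds),
        n_pairs=np.array(counts, dtype=int),
        dims=dims,
    )


def localization_precision(traj: Trajectory, min_frames: int = 10) -> PrecisionReport:
    """Per-axis sample standard deviation of a stationary particle's
    reconstructed coordinates across frames (ddof=1)."""
    if traj.length < min_frames:
        raise ValueError(
            f"need >= {min_frames} frames for a precision estimate, got {traj.length}"
        )
    pos = traj.positions()
    sd = pos.std(axis=0, ddof=1)
    return PrecisionReport(
        sd_x_um=float(sd[0]),
        sd_y_um=float(sd[1]),
        sd_z_um=float(sd[2]),
        n_frames=traj.length,
    )


def depth_error_report(
    estimates: dict[int, float], ground_truth: dict[int, float]
) -> DepthErrorReport:
    """Pair estimated and true depths by particle id; absolute errors.

    Raises if an estimated id has no ground-truth partner.
    """
    missing = set(estimates) - set(ground_truth)
    if missing:
        raise KeyError(f"estimates contain ids without ground truth: {sorted(missing)}")
    errs = np.array(
        [abs(estimates[i] - ground_truth[i]) for i in sorted(estimates)], dtype=float
    )
    return DepthErrorReport(errors_um=errs)


def drift_velocity(
    trajectories: Iterable[Trajectory],
    axis: str = "z",
    volume_rate_hz: float = 30.0,
) -> float:
    """Mean over trajectories of the least-squares slope of coordinate vs time."""
    col = _DIM_INDEX[axis]
    slopes = []
    for traj in trajectories:
        if traj.length < 2:
            continue
        t = traj.times(volume_rate_hz)
        c = traj.positions()[:, col]
        slopes.append(float(np.polyfit(t, c, 1)[0]))
    if not slopes:
        raise ValueError("no trajectory with >= 2 points")
    return float(np.mean(slopes))
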