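"""File formats: multi-page TIFF stereo sequences and tidy CSV tables.

Coordinate conventions in every CSV: micrometers, z relative to the DOF
mid-plane, pixel coordinates 0-based; written as a ``#`` comment header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile

from .detection import Detection2D
from .stereo import Particle3D
from .tracking import Trajectory

__all__ = [
    "write_stereo_sequence",
    "read_stereo_sequence",
    "detections_to_csv",
    "particles_to_csv",
    "particles_from_csv",
    "trajectories_to_csv",
]

COORD_COMMENT = (
    "# coordinates: micrometers; z relative to DOF mid-plane; pixels 0-based\n"
)


def write_stereo_sequence(
    pairs: list,
    out_dir: str | Path,
    dialect: Literal["split", "interleaved"] = "split",
) -> list[Path]:
    """Write a stereo sequence as TIFF.

    ``split``: two stacks ``left.tif`` / ``right.tif``; ``interleaved``: one
    ``stereo.tif`` with even pages = left, odd pages = right.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lefts = np.stack([p.left for p in pairs]).astype(np.float32)
    rights = np.stack([p.right for p in pairs]).astype(np.float32)
    if dialect == "split":
        lp, rp = out_dir / "left.tif", out_dir / "right.tif"
        tifffile.imwrite(lp, lefts, photometric="minisblack")
        tifffile.imwrite(rp, rights, photometric="minisblack")
        return [lp, rp]
    if dialect == "interleaved":
        inter = np.empty(
            (2 * len(pairs),) + lefts.shape[1:], dtype=np.float32
        )
        inter[0::2] = lefts
        inter[1::2] = rights
        sp = out_dir / "stereo.tif"
        tifffile.imwrite(sp, inter, photometric="minisblack")
        return [sp]
    raise ValueError(f"unknown dialect {dialect!r}")


def read_stereo_sequence(
    path, dialect: Literal["split", "interleaved"] = "split"
) -> list:
    """Read a stereo sequence back as a list of StereoPair.

    ``path`` is ``(left_path, right_path)`` (or a directory containing
    ``left.tif``/``right.tif``) for the split dialect, or a single stack path
    for the interleaved dialect.  Pixel data are normalized to float counts.
    """
    from .synth import StereoPair  # local import avoids a cycle

    if dialect == "split":
        if isinstance(path, (str, Path)) and Path(path).is_dir():
            lp, rp = Path(path) / "left.tif", Path(path) / "right.tif"
        else:
            lp, rp = (Path(p) for p in path)
        for p in (lp, rp):
            if not p.exists():
                raise FileNotFoundError(p)
        lefts = _read_stack(lp)
        rights = _read_stack(rp)
        if len(lefts) != len(rights):
            raise ValueError(
                f"page count mismatch: {lp} has {len(lefts)} pages, "
                f"{rp} has {len(rights)}"
            )
        return [
            StereoPair(left=l, right=r, frame_index=i)
            for i, (l, r) in enumerate(zip(lefts, rights))
        ]
    if dialect == "interleaved":
        sp = Path(path)
        if not sp.exists():
            raise FileNotFoundError(sp)
        pages = _read_stack(sp)
        if len(pages) % 2 != 0:
            raise ValueError(
                f"{sp}: interleaved stack must have an even page count, "
                f"got {len(pages)}"
            )
        return [
            StereoPair(left=pages[2 * i], right=pages[2 * i + 1], frame_index=i)
            for i in range(len(pages) // 2)
        ]
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_stack(path: Path) -> list[np.ndarray]:
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - depends on file corruption
        raise ValueError(f"unreadable TIFF {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2D pages, got shape {arr.shape}")
    return [arr[i] for i in range(arr.shape[0])]


def _write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        df.to_csv(fh, index=False)
    return path


def detections_to_csv(dets: list[Detection2D], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            (d.view, d.frame_index, d.cx_px, d.cy_px, d.radius_px,
             d.total_intensity, d.encircled_energy)
            for d in dets
        ],
        columns=["view", "frame", "cx_px", "cy_px", "radius_px",
                 "total_intensity", "encircled_energy"],
    )
    return _write_csv(df, path)


def particles_to_csv(particles: list[Particle3D], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            (p.frame_index, p.x_um, p.y_um, p.z_um, p.disparity_px, p.match_cost)
            for p in particles
        ],
        columns=["frame", "x_um", "y_um", "z_um", "disparity_px", "match_cost"],
    )
    return _write_csv(df, path)


def particles_from_csv(path: str | Path) -> dict[int, list[Particle3D]]:
    """Load a 3D-positions CSV (as written by :func:`particles_to_csv`) into
    the per-frame structure the tracker consumes."""
    df = pd.read_csv(path, comment="#")
    per_frame: dict[int, list[Particle3D]] = {}
    for _, row in df.iterrows():
        p = Particle3D(
            frame_index=int(row["frame"]),
            x_um=float(row["x_um"]),
            y_um=float(row["y_um"]),
            z_um=float(row["z_um"]),
            disparity_px=float(row.get("disparity_px", 0.0)),
            match_cost=float(row.get("match_cost", 0.0)),
            left_id=-1,
            right_id=-1,
        )
        per_frame.setdefault(p.frame_index, []).append(p)
    return per_frame


def trajectories_to_csv(
    trajectories: list[Trajectory], path: str | Path, volume_rate_hz: float = 30.0
) -> Path:
    rows = []
    for t in trajectories:
        gap_starts = {start for _, start in t.gap_links}
        for f, p in t.points:
            rows.append(
                (t.track_id, f, f / volume_rate_hz, p.x_um, p.y_um, p.z_um,
                 int(f in gap_starts))
            )
    df = pd.DataFrame(
        rows,
        columns=["track_id", "frame", "time_s", "x_um", "y_um", "z_um", "gap_flag"],
    )
    return _write_csv(df, path)
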