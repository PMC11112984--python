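"""Imaging geometry: disparity/depth conversions and scattering-medium arithmetic.

All coordinate conversions in the package go through :class:`OpticsConfig` so
that the parallax geometry lives in exactly one place.

Conventions
-----------
* ``parallax_angle_deg`` is the FULL angle between the two view axes; each
  view is tilted by half of it from the optical axis.
* Disparity is ``x_left - x_right`` in pixels; positive disparity maps to
  positive depth.
* Depth ``z`` is measured in micrometers from the axial center of the
  extended focus; the valid reconstruction range is ``[-dof/2, +dof/2]``.
* Image axes: row = y, column = x, origin at the top-left pixel center,
  0-based.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "OpticsConfig",
    "ScatteringMedium",
    "disparity_to_depth",
    "depth_to_disparity",
    "penetration_depths",
    "frames_in_duration",
    "DEFAULT_OPTICS",
]


class OpticsConfig(BaseModel):
    """Stereo acquisition geometry.

    Parameters
    ----------
    parallax_angle_deg:
        Full angle between the two view axes, in degrees; must lie in (0, 90).
    fov_x_um, fov_y_um:
        Lateral field of view in micrometers.
    dof_um:
        Axial extent of the extended focus (depth of field) in micrometers.
    frame_w_px, frame_h_px:
        Frame size in pixels.
    volume_rate_hz:
        Stereo volumes acquired per second.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    parallax_angle_deg: float = 28.1
    fov_x_um: float = 110.0
    fov_y_um: float = 110.0
    dof_um: float = 100.0
    frame_w_px: int = 512
    frame_h_px: int = 512
    volume_rate_hz: float = 30.0

    @model_validator(mode="after")
    def _check(self) -> "OpticsConfig":
        if not (0.0 < self.parallax_angle_deg < 90.0):
            raise ValueError(
                f"parallax_angle_deg must be in (0, 90), got {self.parallax_angle_deg}"
            )
        for name in ("fov_x_um", "fov_y_um", "dof_um", "volume_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.frame_w_px <= 0 or self.frame_h_px <= 0:
            raise ValueError("frame size must be strictly positive")
        return self

    @property
    def pixel_size_um(self) -> float:
        """Lateral pixel pitch, ``fov_x_um / frame_w_px``."""
        return self.fov_x_um / self.frame_w_px

    @property
    def half_angle_rad(self) -> float:
        """Tilt of each view axis from the optical axis, in radians."""
        return math.radians(self.parallax_angle_deg) / 2.0

    @property
    def depth_per_disparity_um(self) -> float:
        """Slope of the depth-vs-disparity line, μm per pixel of disparity."""
        return self.pixel_size_um / (2.0 * math.tan(self.half_angle_rad))


DEFAULT_OPTICS = OpticsConfig()


class ScatteringMedium(BaseModel):
    """Scattering properties of the imaging medium (per millimeter)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    mu_s_per_mm: float
    mu_s_prime_per_mm: float

    @model_validator(mode="after")
    def _check(self) -> "ScatteringMedium":
        if self.mu_s_per_mm <= 0 or self.mu_s_prime_per_mm <= 0:
            raise ValueError("scattering coefficients must be strictly positive")
        if self.mu_s_prime_per_mm > self.mu_s_per_mm:
            raise ValueError(
                "reduced scattering coefficient cannot exceed the scattering coefficient"
            )
        return self


def _as_finite(value, name: str):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr if arr.ndim else float(arr)


def disparity_to_depth(disparity_px, cfg: OpticsConfig = DEFAULT_OPTICS):
    """Convert a signed pixel disparity to depth in μm from the focal mid-plane.

    Under parallel projection along two axes tilted by ±θ/2, a point at depth
    ``z`` appears shifted laterally by ``±z·tan(θ/2)``, so

        z = disparity_px · pixel_size / (2·tan(θ/2)).

    Accepts scalars or arrays; vectorized over ``disparity_px``.
    """
    d = _as_finite(disparity_px, "disparity_px")
    return d * cfg.depth_per_disparity_um


def depth_to_disparity(depth_um, cfg: OpticsConfig = DEFAULT_OPTICS):
    """Exact algebraic inverse of :func:`disparity_to_depth` (μm → pixels)."""
    z = _as_finite(depth_um, "depth_um")
    return z / cfg.depth_per_disparity_um


def penetration_depths(medium: ScatteringMedium) -> tuple[float, float]:
    """Return ``(mfp_mm, tmfp_mm)``: mean free path and transport mean free path.

    ``MFP = 1/μs`` and ``TMFP = 1/μs'``; the useful imaging depth of a
    point-scanning two-photon system lies between the two.
    """
    mfp = 1.0 / medium.mu_s_per_mm
    tmfp = 1.0 / medium.mu_s_prime_per_mm
    return mfp, tmfp


def frames_in_duration(duration_s: float, cfg: OpticsConfig = DEFAULT_OPTICS) -> int:
    """Number of stereo volumes acquired in ``[0, duration_s)`` at the volume rate."""
    if not math.isfinite(duration_s) or duration_s < 0:
        raise ValueError(f"duration_s must be finite and non-negative, got {duration_s}")
    # guard against float fuzz, e.g. 4.0 * 30.0 representing as 119.999...
    return int(math.floor(duration_s * cfg.volume_rate_hz + 1e-9))
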