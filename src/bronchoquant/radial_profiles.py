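"""Radial density-profile casting.

From a lumen centre, 128 equally spaced rays are cast and the slice is
resampled along each by bilinear interpolation, yielding one density profile
per ray.  Ray ``i`` points at angle ``2*pi*i/n_rays`` so ray ``i`` and ray
``i + n_rays/2`` are antiparallel, which later turns outer-border points into
diameter estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import HUImage, sample_points

__all__ = ["RayProfile", "cast_profiles"]


@dataclass
class RayProfile:
    """One radial density profile.

    ``positions`` are distances from the cast centre in mm, starting at 0 with
    uniform step; ``hu`` are the interpolated attenuations.  ``tainted`` is set
    when any sample fell outside the image and was edge-clamped.
    """

    index: int
    angle_rad: float
    step_mm: float
    positions: np.ndarray
    hu: np.ndarray
    tainted: bool = False

    def hu_at(self, pos_mm: float) -> float:
        """Linearly interpolated attenuation at a continuous position."""
        return float(np.interp(pos_mm, self.positions, self.hu))


def cast_profiles(
    image: HUImage,
    center: tuple[float, float],
    n_rays: int = 128,
    step_mm: float = 0.1,
    max_len_mm: float = 15.0,
) -> list[RayProfile]:
    if n_rays < 8 or n_rays % 2:
        raise ValueError("n_rays must be even and >= 8")
    if step_mm <= 0 or step_mm > image.spacing_mm:
        raise ValueError("step_mm must be in (0, spacing_mm]")
    if not image.contains_point(center):
        raise ValueError("center outside image")
    n_steps = int(np.floor(max_len_mm / step_mm + 1e-9)) + 1
    t = np.arange(n_steps) * step_mm
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays
    # sample all rays in one call
    dx = np.cos(angles)[:, None] * t[None, :]
    dy = np.sin(angles)[:, None] * t[None, :]
    pts = np.stack([center[0] + dx, center[1] + dy], axis=-1).reshape(-1, 2)
    values, clamped = sample_points(image, pts)
    values = values.reshape(n_rays, n_steps)
    clamped = clamped.reshape(n_rays, n_steps)
    return [
        RayProfile(
            index=i,
            angle_rad=float(angles[i]),
            step_mm=step_mm,
            positions=t.copy(),
            hu=values[i].copy(),
            tainted=bool(clamped[i].any()),
        )
        for i in range(n_rays)
    ]
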