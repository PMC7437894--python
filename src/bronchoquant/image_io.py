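"""CT slice I/O and basic attenuation measurements.

A slice is held as an :class:`HUImage`: a 2-D raster of Hounsfield units with
isotropic pixel spacing.  All geometry downstream of this module is expressed
in physical millimetres: the pixel at (row ``r``, column ``c``) has its centre
at ``origin + (c * spacing_mm, r * spacing_mm)``, and continuous positions are
defined by bilinear interpolation between pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["HUImage", "read_slice", "write_slice", "roi_mean_hu", "sample_points"]

#: relative tolerance for accepting the two pixel-spacing axes as isotropic
_ANISO_TOL = 0.01


@dataclass
class HUImage:
    """2-D CT slice in Hounsfield units with isotropic spacing.

    Parameters
    ----------
    pixels
        2-D float array of attenuation values (HU), row-major.
    spacing_mm
        Pixel edge length in mm (isotropic, > 0).
    origin
        Physical (x, y) position of the centre of pixel (0, 0), in mm.
    """

    pixels: np.ndarray
    spacing_mm: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not (self.spacing_mm > 0):
            raise ValueError("spacing_mm must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def extent_mm(self) -> tuple[float, float, float, float]:
        """Physical bounding box of pixel centres: (xmin, xmax, ymin, ymax)."""
        nr, nc = self.pixels.shape
        ox, oy = self.origin
        return (ox, ox + (nc - 1) * self.spacing_mm, oy, oy + (nr - 1) * self.spacing_mm)

    def contains_point(self, point_mm: tuple[float, float]) -> bool:
        xmin, xmax, ymin, ymax = self.extent_mm()
        x, y = point_mm
        return xmin <= x <= xmax and ymin <= y <= ymax


def sample_points(image: HUImage, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinearly sample the image at physical points.

    Points outside the pixel-centre bounding box are clamped to the edge value
    and reported in the returned boolean mask so callers can taint dependent
    results.

    Parameters
    ----------
    points_mm
        Array of shape (n, 2) of (x, y) positions in mm.

    Returns
    -------
    values, clamped
        ``values[i]`` is the interpolated HU at ``points_mm[i]``; ``clamped[i]``
        is True where the query fell outside the image.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    nr, nc = image.pixels.shape
    fc = (pts[:, 0] - image.origin[0]) / image.spacing_mm
    fr = (pts[:, 1] - image.origin[1]) / image.spacing_mm
    clamped = (fc < 0) | (fc > nc - 1) | (fr < 0) | (fr > nr - 1)
    coords = np.vstack([np.clip(fr, 0, nr - 1), np.clip(fc, 0, nc - 1)])
    values = map_coordinates(image.pixels, coords, order=1, mode="nearest")
    return values, clamped


def _read_dicom(path: Path) -> HUImage:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-frame 2-D DICOM, got shape {arr.shape}; "
            "extract one slice first"
        )
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    try:
        sp = [float(v) for v in ds.PixelSpacing]
    except AttributeError as exc:
        raise ValueError(f"{path}: PixelSpacing missing") from exc
    if abs(sp[0] - sp[1]) > _ANISO_TOL * max(sp):
        raise ValueError(f"{path}: anisotropic spacing {sp[0]}x{sp[1]} mm not supported")
    return HUImage(arr.astype(float) * slope + intercept, spacing_mm=float(np.mean(sp)))


def _read_nifti(path: Path) -> HUImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(
            f"{path}: expected a 2-D slice, got shape {data.shape}; extract one slice first"
        )
    zooms = img.header.get_zooms()[:2]
    if abs(zooms[0] - zooms[1]) > _ANISO_TOL * max(zooms):
        raise ValueError(
            f"{path}: anisotropic spacing {zooms[0]}x{zooms[1]} mm not supported"
        )
    # stored as (x, y): transpose so axis 0 is the row (y) axis
    return HUImage(data.T, spacing_mm=float(np.mean(zooms)))


def read_slice(path: str | Path, format: str = "auto") -> HUImage:
    """Read a single axial CT slice as true Hounsfield units.

    ``format`` is one of ``dicom``, ``nifti`` or ``auto`` (by extension).
    DICOM stored values are rescaled with RescaleSlope/RescaleIntercept
    (defaulting to 1 and 0).  Anisotropic pixel spacing beyond 1% and 3-D
    volumes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        suffixes = "".join(path.suffixes).lower()
        format = "nifti" if (".nii" in suffixes) else "dicom"
    if format == "dicom":
        return _read_dicom(path)
    if format == "nifti":
        return _read_nifti(path)
    raise ValueError(f"unknown format {format!r}")


def write_slice(image: HUImage, path: str | Path) -> None:
    """Write the slice as NIfTI-1 (float64), spacing recorded in pixdim."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([image.spacing_mm, image.spacing_mm, 1.0, 1.0])
    affine[0, 3], affine[1, 3] = image.origin
    # NIfTI stores (x, y): transpose the row-major raster
    nii = nib.Nifti1Image(image.pixels.T.astype(np.float64), affine)
    nii.header.set_zooms((image.spacing_mm, image.spacing_mm))
    nib.save(nii, str(path))


def roi_mean_hu(
    image: HUImage, center: tuple[float, float], area_cm2: float = 1.0
) -> float:
    """Mean attenuation in a circular region of interest.

    The ROI is a circle of the requested area (default 1 cm**2, radius
    ``sqrt(100/pi)`` mm) around ``center``; membership is by pixel centre.
    Mirrors scanner-console ROI semantics used to read out vessel enhancement.
    """
    if area_cm2 <= 0:
        raise ValueError("area_cm2 must be positive")
    radius = float(np.sqrt(area_cm2 * 100.0 / np.pi))
    cx, cy = float(center[0]), float(center[1])
    xmin, xmax, ymin, ymax = image.extent_mm()
    if cx - radius < xmin or cx + radius > xmax or cy - radius < ymin or cy + radius > ymax:
        raise ValueError("ROI circle exits image bounds")
    nr, nc = image.pixels.shape
    xs = image.origin[0] + np.arange(nc) * image.spacing_mm
    ys = image.origin[1] + np.arange(nr) * image.spacing_mm
    inside = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= radius**2
    if not inside.any():
        raise ValueError("no pixel centres inside ROI; spacing too coarse")
    return float(image.pixels[inside].mean())
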