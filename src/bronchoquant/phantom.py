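"""Synthetic airway phantom rendering with analytic ground truth.

The phantom emulates the in-vivo measurement setting: a circular airway
(air lumen at about -1000 HU inside a soft-tissue wall) embedded in lung
parenchyma (about -850 HU), optionally with an adjacent vessel disc in
contact with the outer wall border.  The vessel attenuation is set per
contrast phase: non-enhanced blood pools around 32 HU, a pulmonary-arterial
bolus peaks around 725 HU, the systemic-arterial phase around 503 HU, and
the equilibrated venous phase around 96 HU.  The continuous scene is
rasterized by supersampling, blurred with an isotropic Gaussian mimicking a
soft reconstruction kernel, and perturbed with white Gaussian noise.
Rendering is a pure function of the spec: same seed, same image.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import HUImage, write_slice

__all__ = [
    "PhantomSpec",
    "AirwayTruth",
    "render_phantom",
    "ground_truth",
    "phase_preset",
    "PHASE_VESSEL_HU",
    "spec_from_yaml",
    "save_phantom",
]

#: maximum vessel attenuation presets per contrast phase (HU)
PHASE_VESSEL_HU: dict[str, float] = {"NE": 32.0, "PA": 725.0, "SA": 503.0, "VE": 96.0}

#: supersampling factor per pixel edge used when rasterizing the scene
SUPERSAMPLE = 8


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic axial slice."""

    lumen_radius_mm: float = 4.75
    wall_thickness_mm: float = 1.0
    airway_center: tuple[float, float] | None = None  # None -> image centre
    hu_lumen: float = -1000.0
    hu_wall: float = 0.0
    hu_parenchyma: float = -850.0
    vessel_radius_mm: float = 0.0
    vessel_hu: float = 32.0
    vessel_gap_mm: float = 0.0
    vessel_angle_deg: float = 0.0
    psf_sigma_mm: float = 0.6
    noise_sd_hu: float = 0.0
    image_size_mm: float = 40.0
    spacing_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.airway_center is None:
            half = self.image_size_mm / 2.0
            self.airway_center = (half, half)
        self.validate()

    def validate(self) -> None:
        if self.lumen_radius_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ValueError("lumen radius and wall thickness must be positive")
        if self.vessel_radius_mm < 0 or self.psf_sigma_mm < 0 or self.noise_sd_hu < 0:
            raise ValueError("vessel radius, psf sigma and noise sd must be >= 0")
        if self.spacing_mm <= 0 or self.image_size_mm <= 0:
            raise ValueError("spacing and image size must be positive")
        outer = self.lumen_radius_mm + self.wall_thickness_mm
        if outer >= self.image_size_mm / 2.0 - 3.0 * self.psf_sigma_mm:
            raise ValueError("airway too large for the image (needs 3 sigma margin)")
        if self.vessel_radius_mm > 0 and self.vessel_gap_mm <= -self.wall_thickness_mm:
            raise ValueError("vessel overlaps the lumen; geometrically meaningless scene")

    @property
    def outer_radius_mm(self) -> float:
        return self.lumen_radius_mm + self.wall_thickness_mm

    def vessel_center(self) -> tuple[float, float] | None:
        """Physical vessel centre, or None when no vessel is present.

        A negative gap pushes the vessel into the wall band; since the wall
        annulus is painted over the vessel, the wall stays intact and the
        vessel wraps it along an extended contact arc, emulating an artery
        pressed against the airway.  Gaps at or below ``-wall_thickness_mm``
        (vessel reaching the lumen) are rejected at validation.
        """
        if self.vessel_radius_mm <= 0:
            return None
        d = self.outer_radius_mm + self.vessel_radius_mm + self.vessel_gap_mm
        th = np.deg2rad(self.vessel_angle_deg)
        cx, cy = self.airway_center
        return (cx + d * np.cos(th), cy + d * np.sin(th))


@dataclass
class AirwayTruth:
    """Closed-form ground-truth morphometry of the phantom airway."""

    TD_mm: float
    LA_mm2: float
    WA_mm2: float
    WT_mm: float


def ground_truth(spec: PhantomSpec) -> AirwayTruth:
    r, wt = spec.lumen_radius_mm, spec.wall_thickness_mm
    return AirwayTruth(
        TD_mm=2.0 * (r + wt),
        LA_mm2=np.pi * r**2,
        WA_mm2=np.pi * ((r + wt) ** 2 - r**2),
        WT_mm=wt,
    )


def phase_preset(phase: str) -> float:
    """Vessel attenuation (HU) for contrast phase NE, PA, SA or VE."""
    try:
        return PHASE_VESSEL_HU[phase]
    except KeyError:
        raise ValueError(f"unknown contrast phase {phase!r}; expected NE/PA/SA/VE") from None


def _scene(spec: PhantomSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate the continuous (pre-blur) scene at physical points."""
    hu = np.full(np.broadcast_shapes(x.shape, y.shape), spec.hu_parenchyma, dtype=float)
    vc = spec.vessel_center()
    if vc is not None:
        hu[(x - vc[0]) ** 2 + (y - vc[1]) ** 2 <= spec.vessel_radius_mm**2] = spec.vessel_hu
    cx, cy = spec.airway_center
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    hu[r2 <= spec.outer_radius_mm**2] = spec.hu_wall
    hu[r2 <= spec.lumen_radius_mm**2] = spec.hu_lumen
    return hu


def render_phantom(spec: PhantomSpec) -> HUImage:
    """Rasterize, blur and noise the phantom scene.

    The continuous scene is rasterized on an 8x8-supersampled grid, convolved
    there with an isotropic Gaussian of SD ``psf_sigma_mm`` (reflective
    padding, truncated at 4 SD), and box-averaged down to the pixel grid;
    blurring at the fine resolution keeps the rendered edge positions faithful
    to the continuous blurred scene instead of aliasing them to the pixel
    grid.  Finally i.i.d. Gaussian noise of SD ``noise_sd_hu`` is added from a
    ``numpy`` generator seeded with ``spec.seed``.
    """
    spec.validate()
    n = int(round(spec.image_size_mm / spec.spacing_mm))
    k = SUPERSAMPLE
    # subpixel centres: pixel c spans [(c-0.5)s, (c+0.5)s] around its centre c*s
    idx = np.arange(n * k)
    fine = ((idx + 0.5) / k - 0.5) * spec.spacing_mm
    hu = _scene(spec, fine[None, :], fine[:, None])
    if spec.psf_sigma_mm > 0:
        hu = gaussian_filter(
            hu,
            sigma=spec.psf_sigma_mm / spec.spacing_mm * k,
            mode="reflect",
            truncate=4.0,
        )
    pixels = hu.reshape(n, k, n, k).mean(axis=(1, 3))
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, spec.noise_sd_hu, pixels.shape)
    return HUImage(pixels, spacing_mm=spec.spacing_mm)


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    """Load a PhantomSpec from a YAML mapping (top level or under ``phantom:``)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "phantom" in doc:
        doc = doc["phantom"]
    return spec_from_mapping(doc)


def spec_from_mapping(doc: dict) -> PhantomSpec:
    allowed = set(PhantomSpec.__dataclass_fields__)
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown phantom keys: {sorted(unknown)}")
    if "airway_center" in doc and doc["airway_center"] is not None:
        doc = dict(doc)
        doc["airway_center"] = tuple(float(v) for v in doc["airway_center"])
    return PhantomSpec(**doc)


def save_phantom(spec: PhantomSpec, image_path: str | Path, truth_path: str | Path | None = None) -> HUImage:
    """Render and write the slice as NIfTI with a JSON ground-truth side-car."""
    img = render_phantom(spec)
    write_slice(img, image_path)
    if truth_path is None:
        truth_path = Path(image_path).with_suffix("").with_suffix("")  # strip .nii(.gz)
        truth_path = Path(str(truth_path) + "_truth.json")
    payload = {"spec": asdict(spec), "truth": asdict(ground_truth(spec))}
    Path(truth_path).write_text(json.dumps(payload, indent=2))
    return img
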