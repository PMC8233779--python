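"""Synthetic OCT B-scan and OCTA en-face angiogram phantoms.

The study conditions this generator emulates are three limbal phenotypes:

* **LSCD** — conjunctivalised, thickened, hyperreflective epithelium over a
  stroma whose apparent reflectivity is reduced by back-shadowing, and a
  dense *superficial* vascular plexus (pannus vessels) that survives
  superficial slab segmentation.
* **non-LSCD mimicker** — normal epithelium over a hyperreflective scarred
  stroma, with predominantly *deep* corneal vessels that are removed by
  superficial slab segmentation.
* **normal** — unremarkable layers (reflectivity ratio near 1) and sparse
  limbal vasculature.

Every phantom carries its ground truth (layer boundaries, vessel masks,
class label) so each downstream stage can be validated without patient data.
All randomness derives from :class:`numpy.random.Generator` seeded from the
spec; identical spec + seed yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .exceptions import PhantomSpecError

__all__ = [
    "ClassLabel",
    "Quadrant",
    "PhantomSpec",
    "GroundTruth",
    "PRESETS",
    "generate_bscan",
    "generate_angiogram",
    "generate_cohort",
]


class ClassLabel(str, Enum):
    LSCD = "LSCD"
    NON_LSCD = "NON_LSCD"
    NORMAL = "NORMAL"


class Quadrant(str, Enum):
    SUP = "SUP"
    INF = "INF"
    NAS = "NAS"
    TEMP = "TEMP"


#: Angular range (degrees, counter-clockwise from +x in pixel coordinates)
#: of each 90-degree limbal sector; boundaries sit on the compass axes.
QUADRANT_SECTORS: dict[Quadrant, tuple[float, float]] = {
    Quadrant.SUP: (0.0, 90.0),
    Quadrant.NAS: (90.0, 180.0),
    Quadrant.INF: (180.0, 270.0),
    Quadrant.TEMP: (270.0, 360.0),
}

# B-scan geometry constants (px). The anterior surface sits well below the
# image top so the pre-corneal background band is visible, as in device
# exports; a gentle sinusoidal sag mimics corneal curvature.
SURFACE_DEPTH_PX = 40
SURFACE_SAG_PX = 6
BACKGROUND_LEVEL = 5.0
ANGIO_BACKGROUND_LEVEL = 25.0
VESSEL_LEVEL = 220.0
# Back-shadowing saturates once thickness x reflectivity reaches this scale
# (a 100 um epithelium at full-scale 255 reflectivity shadows maximally).
SHADOW_SATURATION = 100.0 * 255.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic quadrant.

    Intensities are on the 8-bit [0, 255] scale used by device exports.
    """

    class_label: ClassLabel
    image_height_px: int = 400
    image_width_px: int = 300
    axial_scale_um_per_px: float = 2.0
    epithelial_thickness_um: float = 55.0
    stromal_thickness_um: float = 470.0
    epithelial_reflectivity_mean: float = 130.0
    stromal_reflectivity_mean: float = 140.0
    shadowing_factor: float = 0.0
    noise_sd: float = 4.0
    vessel_count_superficial: int = 2
    vessel_count_deep: int = 1
    vessel_width_px: int = 6
    limbus_center_xy: tuple[float, float] = (150.0, 150.0)
    inner_limbus_radius_px: float = 70.0
    quadrant: Quadrant = Quadrant.SUP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise PhantomSpecError("image dimensions must be positive")
        if not (0.0 <= self.epithelial_reflectivity_mean <= 255.0):
            raise PhantomSpecError("epithelial reflectivity outside [0, 255]")
        if not (0.0 <= self.stromal_reflectivity_mean <= 255.0):
            raise PhantomSpecError("stromal reflectivity outside [0, 255]")
        if self.epithelial_thickness_um <= 0 or self.stromal_thickness_um <= 0:
            raise PhantomSpecError("layer thicknesses must be positive")
        if not (0.0 <= self.shadowing_factor <= 1.0):
            raise PhantomSpecError("shadowing_factor outside [0, 1]")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be non-negative")
        if self.vessel_count_superficial < 0 or self.vessel_count_deep < 0:
            raise PhantomSpecError("vessel counts must be non-negative")
        if self.vessel_width_px <= 0:
            raise PhantomSpecError("vessel width must be positive")
        if self.vessel_width_px >= min(self.image_height_px, self.image_width_px):
            raise PhantomSpecError("vessel width must be smaller than the image")
        if self.inner_limbus_radius_px <= 0:
            raise PhantomSpecError("inner limbus radius must be positive")
        if self.axial_scale_um_per_px <= 0:
            raise PhantomSpecError("axial scale must be positive")
        depth_px = (
            SURFACE_DEPTH_PX
            + SURFACE_SAG_PX
            + (self.epithelial_thickness_um + self.stromal_thickness_um)
            / self.axial_scale_um_per_px
        )
        if depth_px >= self.image_height_px:
            raise PhantomSpecError("layer stack exceeds image depth")

    @property
    def shadow_strength(self) -> float:
        """Fractional stromal attenuation applied under the epithelium.

        Multiplicative model: attenuation = shadowing_factor * s with
        s = clip(thickness_um * reflectivity / (100 um * 255), 0, 1),
        i.e. shadowing grows linearly with the optical load of the
        epithelium and saturates at a 100-um full-scale layer.
        """
        s = (
            self.epithelial_thickness_um
            * self.epithelial_reflectivity_mean
            / SHADOW_SATURATION
        )
        return self.shadowing_factor * min(max(s, 0.0), 1.0)

    @property
    def effective_stromal_reflectivity(self) -> float:
        return self.stromal_reflectivity_mean * (1.0 - self.shadow_strength)


@dataclass
class GroundTruth:
    """Per-phantom truth used as the test oracle for downstream stages."""

    class_label: ClassLabel
    boundary_epithelium_surface: np.ndarray | None = None
    boundary_epi_stroma: np.ndarray | None = None
    boundary_stroma_posterior: np.ndarray | None = None
    vessel_mask_total: np.ndarray | None = None
    vessel_mask_superficial: np.ndarray | None = None

    def validate(self) -> None:
        if self.boundary_epithelium_surface is not None:
            if not (
                np.all(self.boundary_epithelium_surface < self.boundary_epi_stroma)
                and np.all(self.boundary_epi_stroma < self.boundary_stroma_posterior)
            ):
                raise PhantomSpecError("layer boundaries out of order")
        if self.vessel_mask_total is not None and self.vessel_mask_superficial is not None:
            if np.any(self.vessel_mask_superficial & ~self.vessel_mask_total):
                raise PhantomSpecError("superficial vessel mask not nested in total")


#: Class presets: the default study conditions. Reflectivities sit in the
#: ~120-200 range of 8-bit exports; LSCD epithelium is thickened and
#: hyperreflective with back-shadowing and a dense superficial plexus,
#: the non-LSCD mimicker has a scarred hyperreflective stroma and deep
#: vessels, and normals are quiet in both compartments.
PRESETS: dict[ClassLabel, PhantomSpec] = {
    ClassLabel.LSCD: PhantomSpec(
        class_label=ClassLabel.LSCD,
        epithelial_thickness_um=100.0,
        epithelial_reflectivity_mean=200.0,
        stromal_reflectivity_mean=120.0,
        shadowing_factor=0.35,
        vessel_count_superficial=18,
        vessel_count_deep=1,
    ),
    ClassLabel.NON_LSCD: PhantomSpec(
        class_label=ClassLabel.NON_LSCD,
        epithelial_thickness_um=55.0,
        epithelial_reflectivity_mean=130.0,
        stromal_reflectivity_mean=185.0,
        shadowing_factor=0.0,
        vessel_count_superficial=2,
        vessel_count_deep=12,
    ),
    ClassLabel.NORMAL: PhantomSpec(
        class_label=ClassLabel.NORMAL,
        epithelial_thickness_um=53.0,
        epithelial_reflectivity_mean=125.0,
        stromal_reflectivity_mean=140.0,
        shadowing_factor=0.0,
        vessel_count_superficial=2,
        vessel_count_deep=1,
    ),
}


def _validate_presets() -> None:
    lscd = PRESETS[ClassLabel.LSCD]
    assert lscd.epithelial_reflectivity_mean > lscd.stromal_reflectivity_mean
    assert lscd.vessel_count_superficial > 0
    non = PRESETS[ClassLabel.NON_LSCD]
    assert non.stromal_reflectivity_mean > non.epithelial_reflectivity_mean
    assert non.vessel_count_deep >= non.vessel_count_superficial
    norm = PRESETS[ClassLabel.NORMAL]
    ratio = norm.epithelial_reflectivity_mean / norm.stromal_reflectivity_mean
    assert 0.75 <= ratio <= 1.25


_validate_presets()


def _bscan_rng(spec: PhantomSpec) -> np.random.Generator:
    return np.random.default_rng([abs(spec.seed) % (2**31), 11])


def _angio_rng(spec: PhantomSpec) -> np.random.Generator:
    return np.random.default_rng([abs(spec.seed) % (2**31), 13])


def generate_bscan(spec: PhantomSpec):
    """Render a cross-sectional B-scan with known layer boundaries.

    Returns ``(bscan, truth)`` where *bscan* is a
    :class:`limboct.reflectivity.BScan` and *truth* carries the per-column
    boundary rows. Boundary convention: a boundary value is the first row
    of the deeper band, so the epithelium occupies rows
    ``[surface, epi_stroma)`` in each column.
    """
    from .reflectivity import BScan  # local import to avoid a cycle

    h, w = spec.image_height_px, spec.image_width_px
    cols = np.arange(w)
    sag = SURFACE_SAG_PX * np.sin(np.pi * cols / max(w - 1, 1))
    surface = (SURFACE_DEPTH_PX + np.rint(sag)).astype(int)
    epi_px = max(int(round(spec.epithelial_thickness_um / spec.axial_scale_um_per_px)), 1)
    stroma_px = max(int(round(spec.stromal_thickness_um / spec.axial_scale_um_per_px)), 1)
    epi_stroma = surface + epi_px
    posterior = epi_stroma + stroma_px
    if posterior.max() >= h:
        raise PhantomSpecError("layer stack exceeds image depth")

    img = np.full((h, w), BACKGROUND_LEVEL, dtype=float)
    rows = np.arange(h)[:, None]
    img[(rows >= surface) & (rows < epi_stroma)] = spec.epithelial_reflectivity_mean
    img[(rows >= epi_stroma) & (rows < posterior)] = spec.effective_stromal_reflectivity

    if spec.noise_sd > 0:
        img = img + _bscan_rng(spec).normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 255.0)

    truth = GroundTruth(
        class_label=spec.class_label,
        boundary_epithelium_surface=surface,
        boundary_epi_stroma=epi_stroma,
        boundary_stroma_posterior=posterior,
    )
    truth.validate()
    return BScan(intensity=img, axial_scale_um_per_px=spec.axial_scale_um_per_px), truth


def _sector_radians(quadrant: Quadrant) -> tuple[float, float]:
    lo, hi = QUADRANT_SECTORS[quadrant]
    return math.radians(lo), math.radians(hi)


def _draw_vessel(
    mask: np.ndarray,
    rng: np.random.Generator,
    spec: PhantomSpec,
) -> None:
    """Rasterise one radially oriented random-walk vessel into *mask*.

    The polyline starts inside the inner-limbus circle and walks outward
    through the ROI band, with small angular jitter, then is dilated to the
    requested width by the caller.
    """
    lo, hi = _sector_radians(spec.quadrant)
    margin = math.radians(6.0)
    theta = rng.uniform(lo + margin, hi - margin)
    cx, cy = spec.limbus_center_xy
    r0 = max(spec.inner_limbus_radius_px - 25.0, 1.0)
    r1 = spec.inner_limbus_radius_px + 70.0
    n_steps = 14
    radii = np.linspace(r0, r1, n_steps)
    thetas = theta + np.cumsum(rng.normal(0.0, 0.022, size=n_steps))
    xs = cx + radii * np.cos(thetas)
    ys = cy + radii * np.sin(thetas)
    h, w = mask.shape
    for i in range(n_steps - 1):
        rr, cc = draw_line(
            int(round(ys[i])), int(round(xs[i])),
            int(round(ys[i + 1])), int(round(xs[i + 1])),
        )
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True


def generate_angiogram(spec: PhantomSpec):
    """Render the total-depth and superficial en-face slabs of one quadrant.

    Superficial vessels appear in both slabs; deep vessels only in the
    total slab, which is how slab segmentation separates a superficial
    pannus (LSCD) from deep stromal vascularisation (mimickers). Returns
    ``(total, superficial, truth)`` with
    :class:`limboct.density.EnFaceAngiogram` slabs and nested ground-truth
    vessel masks.
    """
    from .density import EnFaceAngiogram, Slab

    rng = _angio_rng(spec)
    size = spec.image_width_px
    shape = (size, size)

    sup_center = np.zeros(shape, dtype=bool)
    for _ in range(spec.vessel_count_superficial):
        _draw_vessel(sup_center, rng, spec)
    deep_center = np.zeros(shape, dtype=bool)
    for _ in range(spec.vessel_count_deep):
        _draw_vessel(deep_center, rng, spec)

    selem = disk(max(spec.vessel_width_px // 2, 1))
    sup_mask = dilation(sup_center, selem)
    deep_mask = dilation(deep_center, selem)
    total_mask = sup_mask | deep_mask

    def render(mask: np.ndarray) -> np.ndarray:
        img = np.where(mask, VESSEL_LEVEL, ANGIO_BACKGROUND_LEVEL)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        return np.clip(img, 0.0, 255.0)

    total_img = render(total_mask)
    sup_img = render(sup_mask)

    truth = GroundTruth(
        class_label=spec.class_label,
        vessel_mask_total=total_mask,
        vessel_mask_superficial=sup_mask,
    )
    truth.validate()
    total = EnFaceAngiogram(intensity=total_img, slab=Slab.TOTAL, quadrant=spec.quadrant)
    sup = EnFaceAngiogram(intensity=sup_img, slab=Slab.SUPERFICIAL, quadrant=spec.quadrant)
    return total, sup, truth


def limbus_contour(spec: PhantomSpec, rng: np.random.Generator, n_points: int = 21) -> np.ndarray:
    """Stand-in for the manual inner-limbus demarcation.

    Samples points along the inner-limbus arc of the quadrant with small
    radial perturbation (the hand tremor of a human annotator), returned as
    an (n, 2) array of 0-based (x, y) pixel coordinates.
    """
    lo, hi = _sector_radians(spec.quadrant)
    margin = math.radians(3.0)
    thetas = np.linspace(lo + margin, hi - margin, n_points)
    radii = spec.inner_limbus_radius_px + rng.normal(0.0, 1.2, size=n_points)
    cx, cy = spec.limbus_center_xy
    return np.column_stack([cx + radii * np.cos(thetas), cy + radii * np.sin(thetas)])


# Within-class variability of the cohort: eye-level offsets are drawn once
# per eye, quadrant-level offsets once per quadrant (both Gaussian unless
# stated). Magnitudes keep every class inside its preset's qualitative regime.
EYE_REFLECTIVITY_SD = 5.0
EYE_THICKNESS_SD = 6.0
QUADRANT_REFLECTIVITY_SD = 2.0
VESSEL_COUNT_JITTER = 1  # uniform integer in [-j, +j], clipped at 0


def _jitter_spec(
    preset: PhantomSpec,
    rng: np.random.Generator,
    eye_refl_offsets: tuple[float, float],
    eye_thick_offset: float,
    quadrant: Quadrant,
    seed: int,
) -> PhantomSpec:
    epi_refl = float(
        np.clip(
            preset.epithelial_reflectivity_mean
            + eye_refl_offsets[0]
            + rng.normal(0.0, QUADRANT_REFLECTIVITY_SD),
            0.0,
            255.0,
        )
    )
    str_refl = float(
        np.clip(
            preset.stromal_reflectivity_mean
            + eye_refl_offsets[1]
            + rng.normal(0.0, QUADRANT_REFLECTIVITY_SD),
            0.0,
            255.0,
        )
    )
    epi_thick = max(preset.epithelial_thickness_um + eye_thick_offset, 20.0)
    jit = rng.integers(-VESSEL_COUNT_JITTER, VESSEL_COUNT_JITTER + 1)
    n_sup = max(int(preset.vessel_count_superficial + jit), 0)
    jit = rng.integers(-VESSEL_COUNT_JITTER, VESSEL_COUNT_JITTER + 1)
    n_deep = max(int(preset.vessel_count_deep + jit), 0)
    if preset.class_label is ClassLabel.LSCD:
        n_sup = max(n_sup, 1)
    return replace(
        preset,
        epithelial_reflectivity_mean=epi_refl,
        stromal_reflectivity_mean=str_refl,
        epithelial_thickness_um=epi_thick,
        vessel_count_superficial=n_sup,
        vessel_count_deep=n_deep,
        quadrant=quadrant,
        seed=seed,
    )


def generate_cohort(
    n_lscd_eyes: int,
    n_nonlscd_eyes: int,
    n_normal_eyes: int,
    seed: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write a synthetic per-quadrant cohort to *out_dir* and return its manifest.

    Every eye contributes its four limbal quadrants; each quadrant record
    has a B-scan PNG, total and superficial angiogram PNGs, an inner-limbus
    contour CSV, and a class label. The manifest (also saved as
    ``manifest.csv``) lists one row per quadrant.
    """
    counts = (n_lscd_eyes, n_nonlscd_eyes, n_normal_eyes)
    if any(c < 0 for c in counts):
        raise ValueError("eye counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("at least one eye is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([abs(seed) % (2**31), 17])

    records = []
    eye_idx = 0
    for label, n_eyes in zip(
        (ClassLabel.LSCD, ClassLabel.NON_LSCD, ClassLabel.NORMAL), counts
    ):
        preset = PRESETS[label]
        for _ in range(n_eyes):
            eye_id = f"eye{eye_idx:03d}"
            eye_refl = (
                rng.normal(0.0, EYE_REFLECTIVITY_SD),
                rng.normal(0.0, EYE_REFLECTIVITY_SD),
            )
            eye_thick = rng.normal(0.0, EYE_THICKNESS_SD)
            for quadrant in Quadrant:
                qseed = int(rng.integers(0, 2**31 - 1))
                spec = _jitter_spec(preset, rng, eye_refl, eye_thick, quadrant, qseed)
                bscan, _ = generate_bscan(spec)
                total, sup, _ = generate_angiogram(spec)
                contour = limbus_contour(spec, rng)

                stem = f"{eye_id}_{quadrant.value}"
                bscan_path = out_dir / f"{stem}_bscan.png"
                total_path = out_dir / f"{stem}_angio_total.png"
                sup_path = out_dir / f"{stem}_angio_superficial.png"
                contour_path = out_dir / f"{stem}_contour.csv"
                iio.imwrite(bscan_path, np.rint(bscan.intensity).astype(np.uint8))
                iio.imwrite(total_path, np.rint(total.intensity).astype(np.uint8))
                iio.imwrite(sup_path, np.rint(sup.intensity).astype(np.uint8))
                pd.DataFrame(contour, columns=["x", "y"]).to_csv(contour_path, index=False)

                records.append(
                    {
                        "eye_id": eye_id,
                        "quadrant": quadrant.value,
                        "class_label": label.value,
                        "bscan_path": str(bscan_path),
                        "angiogram_total_path": str(total_path),
                        "angiogram_superficial_path": str(sup_path),
                        "contour_path": str(contour_path),
                        "axial_scale_um_per_px": spec.axial_scale_um_per_px,
                        "eye_center_x": spec.limbus_center_xy[0],
                        "eye_center_y": spec.limbus_center_xy[1],
                    }
                )
            eye_idx += 1

    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
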