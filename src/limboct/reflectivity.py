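"""Corneal layer reflectivity and thickness features from OCT B-scans.

A B-scan is a depth-by-lateral intensity image; each column is one A-scan.
Three boundaries delimit two bands: the anterior epithelial surface, the
epithelium/stroma interface, and the posterior stromal boundary. From a
segmentation this module measures the thickness of each band, the mean and
mode of its reflectivity (8-bit intensity), and the epithelial:stromal
ratios of both — the discriminating quantities for conjunctivalised
(hyperreflective, thickened) epithelium versus stromal scarring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .exceptions import DegenerateLayerError, SegmentationError

__all__ = ["BScan", "LayerSegmentation", "LayerStats", "segment_layers", "layer_stats"]

#: Fraction of image width used for reflectivity statistics (central window).
DEFAULT_LATERAL_WINDOW = 0.5
#: A column is flagged (no surface) when its strongest axial gradient is
#: below this intensity step.
MIN_SURFACE_STEP = 15.0
#: Minimum row separation enforced between detected boundaries.
MIN_BAND_PX = 4


@dataclass
class BScan:
    """One cross-sectional scan: rows = depth, columns = lateral position."""

    intensity: np.ndarray
    axial_scale_um_per_px: float
    lateral_roi: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("B-scan intensity must be 2-D")
        if self.intensity.min() < 0 or self.intensity.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.axial_scale_um_per_px <= 0:
            raise ValueError("axial scale must be positive")
        if self.lateral_roi is not None:
            lo, hi = self.lateral_roi
            if not (0 <= lo < hi <= self.intensity.shape[1]):
                raise ValueError("lateral ROI outside image width")

    def roi_columns(self) -> np.ndarray:
        """Column indices used for statistics (default: central 50%)."""
        w = self.intensity.shape[1]
        if self.lateral_roi is not None:
            lo, hi = self.lateral_roi
        else:
            half = max(int(round(w * DEFAULT_LATERAL_WINDOW)) // 2, 1)
            mid = w // 2
            lo, hi = mid - half, mid + half
        return np.arange(max(lo, 0), min(hi, w))


@dataclass
class LayerSegmentation:
    """Per-column boundary rows; a boundary is the first row of the deeper band."""

    surface: np.ndarray
    epi_stroma: np.ndarray
    posterior: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.surface = np.asarray(self.surface, dtype=int)
        self.epi_stroma = np.asarray(self.epi_stroma, dtype=int)
        self.posterior = np.asarray(self.posterior, dtype=int)
        if self.valid is None:
            self.valid = np.ones(self.surface.shape, dtype=bool)
        ok = self.valid
        if np.any(self.surface[ok] >= self.epi_stroma[ok]) or np.any(
            self.epi_stroma[ok] >= self.posterior[ok]
        ):
            raise ValueError("boundaries must be strictly ordered per column")


@dataclass
class LayerStats:
    """The B-scan feature set: thicknesses, reflectivities, and their ratios."""

    epithelial_thickness_um: float
    stromal_thickness_um: float
    thickness_ratio: float
    epi_reflectivity_mean: float
    epi_reflectivity_mode: float
    stromal_reflectivity_mean: float
    stromal_reflectivity_mode: float
    reflectivity_ratio_mean: float
    reflectivity_ratio_mode: float
    # literal stromal mean / stromal mode, kept as an optional extra column
    stromal_mean_to_mode_ratio: float


EDGE_HALF_WINDOW = 4


def _edge_response(col: np.ndarray) -> np.ndarray:
    """Matched step-edge filter: mean of the *w* rows at/after index i minus
    the mean of the *w* rows before it. Peaks exactly at the first row of a
    new band while attenuating pixel noise by sqrt(2/w)."""
    w = EDGE_HALF_WINDOW
    n = col.size
    if n < 2 * w + 1:
        return np.zeros(n)
    c = np.cumsum(np.concatenate([[0.0], col]))
    mw = (c[w:] - c[:-w]) / w  # mw[i] = mean(col[i : i + w])
    g = np.zeros(n)
    g[w : n - w + 1] = mw[w : n - w + 1] - mw[: n - 2 * w + 1]
    return g


def _column_boundaries(col: np.ndarray) -> tuple[int, int, int] | None:
    """Locate the three band transitions in one A-scan.

    The surface is the first strong positive edge (background to tissue);
    the interface and posterior boundaries are the two strongest remaining
    transitions (by edge magnitude) below it.
    """
    g = _edge_response(col)
    if g.size == 0 or g.max() < MIN_SURFACE_STEP:
        return None
    strong = np.nonzero(g >= 0.7 * g.max())[0]
    # localize within the first strong run
    run_end = strong[0]
    while run_end + 1 in strong:
        run_end += 1
    first_run = np.arange(strong[0], run_end + 1)
    surface = int(first_run[np.argmax(g[first_run])])

    mag = np.abs(g).copy()
    mag[: surface + MIN_BAND_PX] = 0.0
    # strongest transition below the surface, suppress its neighbourhood,
    # then the next strongest
    first = int(np.argmax(mag))
    if mag[first] <= 0:
        return None
    lo2 = max(first - MIN_BAND_PX, 0)
    mag[lo2 : first + MIN_BAND_PX + 1] = 0.0
    second = int(np.argmax(mag))
    if mag[second] <= 0:
        return None
    b1, b2 = sorted((first, second))
    if b1 - surface < 1 or b2 - b1 < 1:
        return None
    return surface, b1, b2


def segment_layers(bscan: BScan) -> LayerSegmentation:
    """Detect the epithelial surface, epithelium/stroma interface and
    posterior boundary in every A-scan column.

    Columns with no detectable surface (or fewer than two interior
    transitions) are flagged and excluded from statistics; if more than
    half the columns are flagged the scan is rejected. Boundaries are
    median-filtered across columns to suppress isolated errors.
    """
    img = bscan.intensity
    n_cols = img.shape[1]
    surface = np.zeros(n_cols, dtype=float)
    epi = np.zeros(n_cols, dtype=float)
    post = np.zeros(n_cols, dtype=float)
    valid = np.zeros(n_cols, dtype=bool)
    for c in range(n_cols):
        res = _column_boundaries(img[:, c])
        if res is None:
            continue
        surface[c], epi[c], post[c] = res
        valid[c] = True
    if valid.sum() <= n_cols / 2:
        raise SegmentationError(
            f"surface undetectable in {n_cols - int(valid.sum())} of {n_cols} columns"
        )
    # fill flagged columns by nearest valid neighbour before smoothing
    idx = np.arange(n_cols)
    for arr in (surface, epi, post):
        arr[~valid] = np.interp(idx[~valid], idx[valid], arr[valid])
    k = 9 if n_cols >= 9 else (n_cols // 2) * 2 + 1
    surface = median_filter(surface, size=k, mode="nearest")
    epi = median_filter(epi, size=k, mode="nearest")
    post = median_filter(post, size=k, mode="nearest")
    epi = np.maximum(epi, surface + 1)
    post = np.maximum(post, epi + 1)
    return LayerSegmentation(
        surface=np.rint(surface), epi_stroma=np.rint(epi), posterior=np.rint(post),
        valid=valid,
    )


def _band_pixels(img: np.ndarray, top: np.ndarray, bottom: np.ndarray, cols: np.ndarray) -> np.ndarray:
    vals = [img[top[c] : bottom[c], c] for c in cols]
    out = np.concatenate(vals) if vals else np.empty(0)
    if out.size == 0:
        raise DegenerateLayerError("layer region is empty")
    return out


def _mode_8bit(values: np.ndarray) -> float:
    """Most frequent intensity after rounding to the 256 integer bins;
    ties resolve to the smallest intensity."""
    binned = np.clip(np.rint(values), 0, 255).astype(int)
    return float(np.bincount(binned, minlength=256).argmax())


def layer_stats(bscan: BScan, seg: LayerSegmentation) -> LayerStats:
    """Measure thicknesses and reflectivity statistics for both bands.

    Thickness is the mean per-column boundary separation converted to
    micrometres; reflectivity statistics pool the pixels of the band over
    the lateral measurement window (flagged columns excluded).
    """
    img = bscan.intensity
    if seg.surface.shape[0] != img.shape[1]:
        raise ValueError("segmentation does not match B-scan width")
    cols = bscan.roi_columns()
    cols = cols[seg.valid[cols]]
    if cols.size == 0:
        raise DegenerateLayerError("no valid columns in the lateral window")

    epi_px = (seg.epi_stroma - seg.surface)[cols]
    str_px = (seg.posterior - seg.epi_stroma)[cols]
    if np.any(epi_px <= 0) or np.any(str_px <= 0):
        raise DegenerateLayerError("boundaries touch or cross in the window")
    scale = bscan.axial_scale_um_per_px
    epi_um = float(epi_px.mean() * scale)
    str_um = float(str_px.mean() * scale)

    epi_vals = _band_pixels(img, seg.surface, seg.epi_stroma, cols)
    str_vals = _band_pixels(img, seg.epi_stroma, seg.posterior, cols)

    epi_mean = float(epi_vals.mean())
    str_mean = float(str_vals.mean())
    epi_mode = _mode_8bit(epi_vals)
    str_mode = _mode_8bit(str_vals)
    if str_mean == 0 or str_mode == 0:
        raise DegenerateLayerError("stromal reflectivity is zero; ratios undefined")

    return LayerStats(
        epithelial_thickness_um=epi_um,
        stromal_thickness_um=str_um,
        thickness_ratio=epi_um / str_um,
        epi_reflectivity_mean=epi_mean,
        epi_reflectivity_mode=epi_mode,
        stromal_reflectivity_mean=str_mean,
        stromal_reflectivity_mode=str_mode,
        reflectivity_ratio_mean=epi_mean / str_mean,
        reflectivity_ratio_mode=epi_mode / str_mode,
        stromal_mean_to_mode_ratio=str_mean / str_mode,
    )
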