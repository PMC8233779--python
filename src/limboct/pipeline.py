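"""Cohort orchestration: feature extraction, diagnostics, and reporting.

Runs the full workflow over a cohort manifest (one row per limbal
quadrant): B-scan layer segmentation and reflectivity statistics, OCTA
vascular-density quantification, assembly of the per-quadrant feature
matrix, and the diagnostic statistics stack. Emits a feature CSV plus
machine-readable (JSON) and human-readable (Markdown) reports. Quadrants
that fail any stage are logged and skipped; the run is deterministic for a
fixed manifest and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import density as dens
from . import diagnostics as diag
from . import reflectivity as refl
from .density import DensityMetrics, EnFaceAngiogram, LimbusAnnotation, Slab
from .diagnostics import PUBLISHED_THRESHOLDS, PublishedThreshold, ThresholdMetrics
from .exceptions import LimboctError
from .phantom import ClassLabel, Quadrant
from .reflectivity import BScan

__all__ = ["RunConfig", "FEATURE_COLUMNS", "extract_features", "run_cohort", "classify_quadrant"]

logger = logging.getLogger("limboct")

#: Per-quadrant feature columns in the canonical order: thicknesses and
#: their ratio, layer reflectivity means/modes and the epithelial:stromal
#: ratios, then the vascular-density set from the two slabs.
FEATURE_COLUMNS: list[str] = [
    "epithelial_thickness_um",
    "stromal_thickness_um",
    "thickness_ratio",
    "epi_reflectivity_mean",
    "epi_reflectivity_mode",
    "stromal_reflectivity_mean",
    "stromal_reflectivity_mode",
    "reflectivity_ratio_mean",
    "reflectivity_ratio_mode",
    "mean_total_vd",
    "mean_superficial_vd",
    "segmented_to_total_ratio",
    "peak_bin_frequency_total",
    "peak_bin_frequency_superficial",
]

#: Orientation of each headline parameter: whether disease (LSCD) is called
#: at values above ('greater') or at/below ('less_equal') the cutpoint.
KEY_PARAMETERS: dict[str, str] = {
    "epi_reflectivity_mean": "greater",
    "stromal_reflectivity_mean": "less_equal",
    "reflectivity_ratio_mean": "greater",
    "mean_superficial_vd": "greater",
}


@dataclass
class RunConfig:
    """Run-wide knobs, echoed verbatim into every report for provenance."""

    binarization_method: str = "otsu"
    fixed_threshold: float | None = None
    band_inner_px: float = dens.DEFAULT_BAND_INNER_PX
    band_outer_px: float = dens.DEFAULT_BAND_OUTER_PX
    n_radial_bins: int = dens.DEFAULT_N_RADIAL_BINS
    n_angular_bins: int = dens.DEFAULT_N_ANGULAR_BINS
    ci_level: float = 0.95
    stepwise_direction: str = "backward"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.binarization_method not in ("otsu", "fixed"):
            raise ValueError("binarization_method must be 'otsu' or 'fixed'")
        if self.binarization_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required for fixed binarization")
        if self.band_outer_px <= self.band_inner_px:
            raise ValueError("band_outer_px must exceed band_inner_px")
        if self.n_radial_bins < 1 or self.n_angular_bins < 1:
            raise ValueError("bin counts must be >= 1")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")


def _load_gray(path: str | Path) -> np.ndarray:
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img


def _load_contour(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x", "y"]].to_numpy(dtype=float)


def extract_features(record: pd.Series | dict, config: RunConfig) -> dict:
    """Compute the per-quadrant feature vector for one manifest record."""
    rec = dict(record)
    bscan = BScan(
        intensity=_load_gray(rec["bscan_path"]),
        axial_scale_um_per_px=float(rec.get("axial_scale_um_per_px", 1.0)),
    )
    seg = refl.segment_layers(bscan)
    stats = refl.layer_stats(bscan, seg)

    quadrant = Quadrant(rec["quadrant"]) if rec.get("quadrant") else None
    total = EnFaceAngiogram(_load_gray(rec["angiogram_total_path"]), Slab.TOTAL, quadrant)
    sup = EnFaceAngiogram(
        _load_gray(rec["angiogram_superficial_path"]), Slab.SUPERFICIAL, quadrant
    )
    center = None
    if "eye_center_x" in rec and rec["eye_center_x"] is not None:
        center = (float(rec["eye_center_x"]), float(rec["eye_center_y"]))
    ann = LimbusAnnotation(_load_contour(rec["contour_path"]), center)
    dm: DensityMetrics = dens.density_metrics(
        total,
        sup,
        ann,
        band_inner_px=config.band_inner_px,
        band_outer_px=config.band_outer_px,
        n_radial_bins=config.n_radial_bins,
        n_angular_bins=config.n_angular_bins,
        method=config.binarization_method,
        fixed_threshold=config.fixed_threshold,
    )
    row = {
        "eye_id": rec.get("eye_id"),
        "quadrant": rec.get("quadrant"),
        "class_label": rec.get("class_label"),
        **dataclasses.asdict(stats),
        "mean_total_vd": dm.mean_total_vd,
        "mean_superficial_vd": dm.mean_superficial_vd,
        "segmented_to_total_ratio": dm.segmented_to_total_ratio,
        "peak_bin_frequency_total": dm.peak_bin_frequency_total,
        "peak_bin_frequency_superficial": dm.peak_bin_frequency_superficial,
    }
    row.pop("stromal_mean_to_mode_ratio", None)
    return row


def _pct(x: float) -> float:
    return round(100.0 * x, 2)


def _metrics_dict(tm: ThresholdMetrics) -> dict:
    def ci(pair):
        return None if pair is None else [
            None if (isinstance(v, float) and math.isnan(v)) else v for v in pair
        ]

    return {
        "cutpoint": tm.cutpoint,
        "direction": tm.direction,
        "tp": tm.tp,
        "fn": tm.fn,
        "tn": tm.tn,
        "fp": tm.fp,
        "sensitivity_pct": _pct(tm.sensitivity),
        "sensitivity_ci_pct": [_pct(v) for v in tm.sensitivity_ci],
        "specificity_pct": _pct(tm.specificity),
        "specificity_ci_pct": [_pct(v) for v in tm.specificity_ci],
        "youden_j": round(tm.youden_j, 4),
        "lr_positive": None if math.isinf(tm.lr_positive) else round(tm.lr_positive, 3),
        "lr_positive_infinite": math.isinf(tm.lr_positive),
        "lr_positive_ci": ci(tm.lr_positive_ci),
        "lr_negative": None if math.isnan(tm.lr_negative) else round(tm.lr_negative, 3),
        "lr_negative_ci": ci(tm.lr_negative_ci),
        "ppv_pct": _pct(tm.ppv) if not math.isnan(tm.ppv) else None,
        "npv_pct": _pct(tm.npv) if not math.isnan(tm.npv) else None,
    }


def _oriented_youden(scores: np.ndarray, labels: np.ndarray, orientation: str) -> ThresholdMetrics:
    """Youden-optimal cutpoint honouring the parameter's direction
    convention (disease above, or at/below, the cutpoint)."""
    if orientation == "greater":
        return diag.youden_threshold(diag.roc_curve(scores, labels))
    tm_neg = diag.youden_threshold(diag.roc_curve(-scores, labels))
    below = scores[scores < -tm_neg.cutpoint]
    cut = float(below.max()) if below.size else -math.inf
    return diag.threshold_metrics(scores, labels, cut, "less_equal")


def run_cohort(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Extract features for every quadrant in the manifest and run the
    diagnostics stack.

    Returns ``(features, report)``. With fewer than two classes present the
    run degrades to feature-only mode. When *out_dir* is given, writes
    ``features.csv``, ``report.json`` and ``report.md``.
    """
    config = config or RunConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        raise ValueError("empty manifest")

    rows, failures = [], []
    for _, rec in manifest.iterrows():
        try:
            rows.append(extract_features(rec, config))
        except (LimboctError, OSError, FileNotFoundError, ValueError) as exc:
            msg = f"{rec.get('eye_id')}/{rec.get('quadrant')}: {exc}"
            logger.warning("quadrant skipped: %s", msg)
            failures.append(msg)
    if not rows:
        raise LimboctError("all quadrants failed feature extraction")
    features = pd.DataFrame(rows)

    counts = features["class_label"].value_counts().to_dict()
    report: dict = {
        "config": asdict(config),
        "n_quadrants": int(len(features)),
        "n_failed": len(failures),
        "failures": failures,
        "class_counts": {str(k): int(v) for k, v in counts.items()},
    }

    labels = (features["class_label"] == ClassLabel.LSCD.value).astype(int).to_numpy()
    if 0 < labels.sum() < len(labels):
        X = features[FEATURE_COLUMNS]
        try:
            model = diag.stepwise_aic(X, labels, allow_separation=True)
            report["stepwise_model"] = {
                "selected_features": model.selected_features,
                "intercept": float(model.coefficients[0]),
                "coefficients": {
                    f: float(c)
                    for f, c in zip(model.selected_features, model.coefficients[1:])
                },
                "standard_errors": {
                    f: float(s)
                    for f, s in zip(model.selected_features, model.standard_errors[1:])
                },
                "aic": float(model.aic),
                "separated": model.separated,
            }
        except LimboctError as exc:
            report["stepwise_model"] = {"error": str(exc)}

        report["parameters"] = {}
        for name, orientation in KEY_PARAMETERS.items():
            scores = features[name].to_numpy(dtype=float)
            roc = diag.roc_curve(scores if orientation == "greater" else -scores, labels)
            tm = _oriented_youden(scores, labels, orientation)
            report["parameters"][name] = {
                "auc": round(roc.auc, 4),
                "auc_se": round(roc.auc_se, 4),
                "auc_ci95": [round(v, 4) for v in roc.auc_ci95],
                "youden_optimal": _metrics_dict(tm),
            }

        report["published_thresholds"] = {}
        for pt in PUBLISHED_THRESHOLDS:
            if pt.feature not in features.columns:
                continue
            tm = diag.threshold_metrics(
                features[pt.feature].to_numpy(dtype=float),
                labels,
                pt.cutpoint,
                pt.direction,
                config.ci_level,
            )
            report["published_thresholds"][pt.feature] = _metrics_dict(tm)
    else:
        report["diagnostics"] = "skipped: fewer than two classes present"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        features.to_csv(out_dir / "features.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        (out_dir / "report.md").write_text(_markdown_report(report))
    return features, report


def _markdown_report(report: dict) -> str:
    lines = ["# limboct cohort report", ""]
    lines.append(f"Quadrants analysed: {report['n_quadrants']} "
                 f"(failed: {report['n_failed']})")
    lines.append("")
    lines.append("| class | quadrants |")
    lines.append("|---|---|")
    for k, v in sorted(report["class_counts"].items()):
        lines.append(f"| {k} | {v} |")
    lines.append("")
    model = report.get("stepwise_model")
    if model and "selected_features" in model:
        lines.append("## Stepwise-AIC logistic model")
        lines.append("")
        if model["separated"]:
            lines.append(
                "*Complete separation detected: coefficients are not "
                "maximum-likelihood estimates.*"
            )
            lines.append("")
        lines.append("| feature | coefficient | SE |")
        lines.append("|---|---|---|")
        for f in model["selected_features"]:
            lines.append(
                f"| {f} | {model['coefficients'][f]:.4g} "
                f"| {model['standard_errors'][f]:.3g} |"
            )
        lines.append(f"\nAIC: {model['aic']:.2f}")
        lines.append("")
    for section, title in (
        ("parameters", "Youden-optimal cutpoints"),
        ("published_thresholds", "Reference cutpoints"),
    ):
        if section not in report:
            continue
        lines.append(f"## {title}")
        lines.append("")
        lines.append("| parameter | cutpoint | sens % (95% CI) | spec % (95% CI) | LR+ | LR- |")
        lines.append("|---|---|---|---|---|---|")
        for name, entry in report[section].items():
            tm = entry.get("youden_optimal", entry)
            op = ">" if tm["direction"] == "greater" else "<="
            lrp = "inf" if tm["lr_positive_infinite"] else f"{tm['lr_positive']:.2f}"
            lrn = "-" if tm["lr_negative"] is None else f"{tm['lr_negative']:.3f}"
            lines.append(
                f"| {name} | {op}{tm['cutpoint']:.4g} "
                f"| {tm['sensitivity_pct']:.2f} ({tm['sensitivity_ci_pct'][0]:.2f}"
                f"-{tm['sensitivity_ci_pct'][1]:.2f}) "
                f"| {tm['specificity_pct']:.2f} ({tm['specificity_ci_pct'][0]:.2f}"
                f"-{tm['specificity_ci_pct'][1]:.2f}) | {lrp} | {lrn} |"
            )
        lines.append("")
    return "\n".join(lines)


def classify_quadrant(
    features: pd.Series | dict,
    thresholds: tuple[PublishedThreshold, ...] = PUBLISHED_THRESHOLDS,
    combined_rule: str = "reflectivity_ratio_mean",
) -> dict:
    """Apply each reference cutpoint to one quadrant's feature row.

    Returns one boolean call per parameter (None when the feature is
    missing) plus a combined call, which by default is the
    epithelial:stromal reflectivity-ratio rule — the best-performing
    single parameter.
    """
    row = dict(features)
    calls: dict[str, bool | None] = {}
    for pt in thresholds:
        value = row.get(pt.feature)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            calls[pt.feature] = None
            continue
        if pt.direction == "greater":
            calls[pt.feature] = bool(value > pt.cutpoint)
        else:
            calls[pt.feature] = bool(value <= pt.cutpoint)
    calls["combined"] = calls.get(combined_rule)
    return calls
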