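# Methods

## Scope and data model

`limboct` quantifies two imaging signatures of limbal stem cell deficiency
(LSCD) — corneal layer reflectivity on OCT B-scans and slab-resolved limbal
vascular density on OCTA en-face angiograms — and feeds them into a
diagnostic-statistics chain (stepwise-AIC logistic regression, ROC/Youden
cutpoints, exact confidence intervals, likelihood ratios). Because no
patient images are distributed with the package, every stage is exercised
on synthetic phantoms whose ground truth is known by construction.

All images are 8-bit grayscale ([0, 255]); the reference reflectivity
cutpoints (142.9, 151.8) are consistent with that scale, and the phantoms
adopt it throughout. Pixel coordinates are 0-based with x = column and
y = row; angles are counter-clockwise from the +x axis in that frame.

## Phantom generator

The generator renders the three phenotypes the analysis must separate:

| parameter | LSCD | non-LSCD mimicker | normal |
|---|---|---|---|
| epithelial reflectivity (mean) | 200 | 130 | 125 |
| stromal reflectivity (mean) | 120 | 185 | 140 |
| shadowing factor | 0.35 | 0 | 0 |
| epithelial thickness (µm) | 100 | 55 | 53 |
| superficial / deep vessels | 18 / 1 | 2 / 12 | 2 / 1 |

B-scans are 400×300 px at 2 µm axial scale. Layers are flat bands with a
gentle sinusoidal surface sag (6 px); the stroma is 470 µm in all classes.
Back-shadowing is modelled multiplicatively: the stromal band is rendered
at `stromal_mean × (1 − f·s)` with `s = clip(thickness_um ×
epi_reflectivity / (100 µm × 255), 0, 1)` — attenuation grows linearly
with the optical load of the epithelium and saturates at a 100 µm
full-scale layer. The direction (thicker/brighter epithelium ⇒ darker
stroma) is physical; the specific linear-saturating form is a modelling
choice, kept deterministic so band means are exact at zero noise.

Angiograms are 300×300 px per quadrant, eye centre at (150, 150), inner
limbus radius 70 px. Vessels are radially oriented random-walk polylines
crossing the limbus, dilated to the requested width; superficial vessels
are drawn into both slabs, deep vessels into the total slab only, which
guarantees the superficial ground-truth mask is nested in the total mask.
Noise is additive Gaussian (default SD 4) clipped to range — a deliberate
simplification of OCT speckle. Vessel counts (18 superficial for LSCD,
12 deep for mimickers) were chosen so that the LSCD superficial vascular
density sits well above the 0.38 reference cutpoint and the mimickers well
below it after annotation and binarization noise; with ~50 px of a vessel's
length inside the 50 px ROI band at width ~7 px, 18 vessels occupy roughly
half of the ~7500 px quarter-annulus.

Cohorts draw eye-level offsets (reflectivity SD 5, thickness SD 6 µm) and
quadrant-level offsets (reflectivity SD 2, vessel count ±1) around the
presets; each eye contributes four quadrants (SUP/NAS/INF/TEMP, one
90° sector each, boundaries on the compass axes). The manual inner-limbus
demarcation is emulated by 21 contour points with 1.2 px radial jitter.
All randomness flows through `numpy.random.Generator` seeded from the
spec/cohort seed, so identical inputs are bit-identical.

**What the phantoms do not establish.** They are separable by design: flat
layers, constant within-band reflectivity, clean vessel/background
contrast, no projection artefacts, motion, or curvature/refraction
effects. Green end-to-end tests validate the measurement chain
(segmentation, ROI geometry, binning, statistics), not clinical accuracy
on device exports.

## Layer segmentation and reflectivity

Each A-scan column is scanned with a matched step-edge filter (mean of the
4 rows at/after a candidate boundary minus the mean of the 4 rows before
it), which peaks exactly at the first row of a new band and attenuates
pixel noise by √2. The anterior surface is the first strong positive edge
(≥70% of the column maximum, ≥15 intensity units); the epithelium/stroma
interface and posterior boundary are the two strongest remaining
transitions by magnitude, with a 4 px exclusion zone around each pick.
Columns with no detectable surface are flagged and excluded from
statistics; a scan fails if more than half its columns are flagged.
Boundaries are median-filtered across columns (window 9).

Layer statistics pool pixels between boundaries over a lateral measurement
window (default: central 50% of columns; the sampling box is not dictated
by any convention, so it is configurable). Thickness is the mean
per-column boundary separation × axial scale (µm). The reflectivity mode
is computed on the integer-binned [0..255] histogram with ties broken
toward the lower intensity. Both epithelial:stromal ratios (of means and
of modes) are reported; the literal stromal mean÷mode ratio is kept as an
extra column.

## Vascular density

Binarization defaults to Otsu's threshold computed on the ROI-cropped
histogram (whole image if no ROI), calling vessels strictly above the
threshold — which makes the operation idempotent on binary inputs. Otsu
always splits a histogram, so a bimodality guard rejects splits whose
between-class variance is below 75% of the total variance (a unimodal
Gaussian background scores ≈0.64, vessel images ≥0.9); such images are
declared vessel-free rather than half-vessel. A fixed threshold mode is
available for reproducibility studies.

The ROI is an annular band from the inner limbus outward (default 0–50 px;
the band width is a configurable convention). The inner limbus is a
least-squares circle through the manual contour points: when the eye
centre is supplied the radius is fitted about it (the LS radius is the
mean point distance); otherwise a full Kåsa fit supplies centre and
radius. A spline would track non-circular limbi better; quadrant arcs are
short and near-circular, so the circle is an accepted limitation.

Vascular density is the vessel-positive pixel fraction of the ROI (not a
skeletonized length density — both conventions exist in the OCTA
literature). The polar distribution bins ROI pixels by radial offset from
the fitted limbus and by angle about the eye centre (default 5 radial ×
24 angular bins; bin counts are a package convention); empty bins are NaN
and excluded from summaries, and the count-weighted mean over bins equals
the scalar density exactly because the bins partition the ROI. The
segmented-to-total ratio is superficial density ÷ total density, defined
as 0 when both are 0 and an error when only the total is 0; under noise
the measured ratio can slightly exceed 1 even though the ground-truth
masks are nested.

## Diagnostic statistics

Logistic regression is fitted by iteratively reweighted least squares
(tolerance 1e-8 on the log-likelihood, ≤100 iterations), with standard
errors from the observed information and AIC = 2k − 2·loglik. Complete
separation is detected (all margins positive with vanishing deviance) and
raised as an error by default, since the MLE then does not exist.
Backward stepwise elimination starts from the full model and at each step
drops the term whose removal lowers AIC most, stopping when no removal
lowers it; ties break toward the earliest column. The stepwise search may
be run with separation allowed (deviance ≈ 0, AIC ≈ 2k), which mirrors how
standard GLM software behaves, but the selected subset is then an artifact
of the tie-break order — the pipeline flags such models. Separable phantom
cohorts always trigger this flag; support-recovery claims about stepwise
selection are therefore tested on non-separable simulated feature
cohorts (n = 2000). Quadrants are treated as independent observations even
though eyes contribute four correlated quadrants each — a documented
limitation of the reference analysis that the package reproduces rather
than corrects.

ROC curves are empirical over all distinct cutpoints with the convention
"positive when score > cutpoint" (parameters whose low values indicate
disease are analysed on the negated score and reported with a ≤ cutpoint).
AUC is the trapezoid integral, identical to the tie-corrected Mann–Whitney
statistic; its standard error uses the Hanley–McNeil formula and the 95%
CI is the normal approximation clipped to [0, 1]. The Youden-optimal
cutpoint maximises J = Se + Sp − 1 with ties broken toward higher
specificity and equals the exhaustive search over candidate cutpoints.

Sensitivity, specificity and predictive values (at sample prevalence)
carry Clopper–Pearson exact 95% CIs via the beta-quantile relation, the
method that reproduces published exact bounds such as 92.6% for 48/48.
Likelihood-ratio CIs use the log-transform (Simel) method and are reported
as undefined when a zero cell makes the log-variance infinite; LR+ is +∞
at specificity 1 (flagged rather than silently dropped). Wilson intervals
are deliberately not the default: the target convention is the exact
interval.

Reference cutpoints are applied with their stated direction conventions —
strict `>` for 142.9 (epithelial reflectivity), 1.29 (reflectivity ratio)
and 0.38 (superficial vascular density); `≤` for 151.8 (stromal
reflectivity). The reflectivity-ratio rule is the default combined call.

## Problem sizes and numerical conventions

The default synthetic study is 34 eyes (12 LSCD, 12 mimicker, 10 normal;
136 quadrants), matching the structure the analysis is designed for; it
generates and analyses in well under a minute. Simulation-based tests use
n = 2000 observations for coefficient recovery (±3 SE) and stepwise
support recovery, and 100 random instances for the Youden/AUC oracle
equivalences. Band means are exact at zero noise (floating tolerance);
degenerate inputs (constant images, touching boundaries, empty ROIs,
single-class labels) raise typed errors rather than producing numbers.
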