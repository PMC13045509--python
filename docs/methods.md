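# Methods

This note documents the measurement model behind `coroquant`, the
parameter defaults and why they were chosen, what the phantom generator
does and does not emulate, and the numerical choices that matter when
reading its outputs.

## Input model

A cMPR export is treated as, per vessel, an ordered stack of 2D
longitudinal cross-sections in Hounsfield units (default 13 slices of
512×512) with an isotropic in-plane pixel spacing, plus an aligned
integer mask (0 background, 1 lumen, 2 lesion). Slices are analysed
independently in 2D and stacked orthogonally into a pseudo-3D volume
only for pooled voxel counts (calcium) — the pipeline is deliberately
slice-based, matching how the masks are produced. Pixel coordinates are
0-based `(row, col)`; slice 0 is most proximal; the in-plane spacing
defaults to 0.35 mm/px when metadata omits it (a warning is logged).
Stenosis severity is a width ratio and therefore independent of the
assumed spacing; lesion lengths and diameters in mm are not.

## Mask post-processing

Connected components (8-connectivity in-plane, per slice) of the vessel
and lesion labels with **at most 100 pixels** are removed before any
measurement; surviving components have ≥ 101 px. The filter is
idempotent and monotone in its threshold. The same filter, applied to
the plaque label only, precedes plaque-presence calls
(`plaque_min_cluster_px`, default 100).

## Centerline

The vessel region (labels 1∪2) is thinned with the Guo–Hall
two-subiteration topological thinning (`skimage.morphology.thin`),
followed by a simple-point cleanup pass that deletes topologically
redundant pixels from any residual 2×2 junction block, so the skeleton
is strictly one pixel wide and a subset of the vessel. Side branches
are pruned by building the 8-connectivity pixel graph (edge weights 1
axial, √2 diagonal) and keeping the maximum-weight shortest path
between endpoint (degree-1) pixels — the graph diameter restricted to
endpoints. Cycles are logged and handled by the shortest-path search
itself (which always returns a simple path). Ties break on
lexicographic endpoint coordinates; the retained path is oriented
proximal→distal with the endpoint nearer the left image border taken as
proximal (configurable by convention, not exposed as a flag). Arc
length accumulates spacing·1 per axial and spacing·√2 per diagonal
step. A path point is labelled stenotic iff the nearest labelled mask
pixel in its 3×3 neighbourhood has label 2, with ties favouring the
stenotic label (sensitivity-preserving).

## Diameter profile (FWHM)

At each path point the local tangent comes from central differences of
the coordinates after a ±3-point moving-average smoothing; the normal is
the tangent rotated +90°. A symmetric profile is sampled along the
normal with bilinear interpolation at a step of **spacing/4** and a
half-length of **4× the slice's radius estimate** (vessel area divided
by path length, halved), which guarantees background tails on both
sides. By default the profile is taken on the binary vessel mask; an
intensity mode profiles the HU raster instead and exists for masks of
doubtful quality.

FWHM: baseline = mean of the two tail minima (exactly 0 for masks);
half level = baseline + (max − baseline)/2; width = distance between
the two half-level crossings adjacent to the global maximum, each
located by linear interpolation between samples. Points whose profile
never descends to the half level (e.g. normals leaving the frame inside
tissue) are excluded and logged; a slice with > 50 % undefined points is
flagged failed and contributes no lesions.

On a rasterized binary mask each boundary crossing lands midway between
the last inside and first outside pixel center, so single-point widths
carry ±half-pixel noise per edge (zero mean). Because the **minimum**
of a long quantized sequence is biased low, the width sequence is
median-filtered over **5 samples** (~1.7 mm of centerline at default
spacing) before the lesion minimum is read off. This is the one place
the pipeline smooths; the unsmoothed profile is retained for the
reference medians, which are already robust.

## Lesion delineation and quantification

Lesions are maximal contiguous runs of stenotic path points; runs
separated by **fewer than 2** normal points are merged and runs shorter
than **1 mm** of arc length are dropped. Per lesion:

- **MLD** — minimum of the (median-smoothed) width profile inside the run.
- **RVD** — median width over the window of up to **10 mm** immediately
  proximal to the run (lesion points excluded), likewise distal; RVD is
  the mean of the two medians, or the single available one when the
  lesion abuts a path end (interpolated-reference convention
  approximated by the mean). No reference on either side is an error
  for that lesion.
- **Severity** — `(1 − MLD/RVD) × 100`, clamped to [0, 100].
- **Length** — arc length spanned by the run.

The vessel result concatenates lesions across slices with slice
provenance; the per-vessel severity is the maximum lesion severity.

## Grading rules

CAD-RADS 2.0 bands use half-open real intervals anchored at the printed
integer bounds: 0 iff exactly 0 %, (0, 25) → 1, [25, 50) → 2,
[50, 70) → 3, [70, 100) → 4A, exactly 100 % → 5. Patient category is 4B
when the left main exceeds 50 % or at least three vessels are ≥ 70 %
(the 3-vessel clause requires three graded vessels and logs otherwise);
otherwise it is the maximum vessel category. A supplied left-main
severity also contributes its own band category and counts toward the
significant-CAD flag (any severity ≥ 50 %). Obstructive disease is
category 3 and above.

High-risk plaque: low-attenuation plaque strictly < 30 HU, positive
remodeling strictly > 1.1, napkin-ring sign and spotty calcification as
boolean inputs (their pixel-level detection is out of scope);
"vulnerable" requires ≥ 2 positive criteria.

Calcium: a vessel voxel counts as calcified iff HU **strictly exceeds
2,100** (kept as printed for contrast-enhanced cMPR despite the
conventional 130 HU on non-contrast CT; configurable), pooled over all
slices and expressed as a percentage of vessel voxels. The binary
calcified flag defaults to a 1 % cutoff, which is a placeholder — no
published cutoff exists for this score.

## Evaluation statistics

Overlap metrics (DSC, sensitivity, specificity, PPV, NPV) and
confusion-matrix metrics with Wilson 95 % CIs; MAE; Bland–Altman
(bias ± 1.96 × sample SD of differences, n−1 denominator); ICC(2,1)
(two-way random effects, absolute agreement, single rater, McGraw–Wong
F-based confidence bounds — the ICC form is fixed here because sources
rarely state it); unweighted Cohen's kappa. Metrics with empty
denominators are reported as explicit `None`, never silently 0 or 1.

## Phantom generator

The generator emulates what the pipeline consumes, not what a scanner
produces. One vessel = a planar sinusoidal centerline (amplitude 25 px,
one period across the frame; curvature is validated so adjacent normals
cannot cross inside the lumen) with radius

    r(s) = R · (1 − Σᵢ (sevᵢ/100) · gᵢ(s)),

where each stenosis contributes a Hann (cosine-taper) unit bump over
its nominal length. The lesion label covers lumen pixels where the bump
exceeds **0.1** of its peak, which makes the ground-truth lesion length
`2·acos(−0.8)/(2π) ≈ 0.795` of the nominal bump length and unambiguous.
Truth MLD/RVD/severity follow directly from R and sev. HU palette:
lumen 350, wall 50, background −50, calcification 2500, low-attenuation
plaque 20 — chosen to leave wide margins around the 2,100 HU and 30 HU
thresholds, not to reproduce scanner statistics. Gaussian noise
(SD 10 HU) is added to the anatomy first; calcified foci and plaque
disks are painted afterwards at exact HU values, so threshold-based
truths (the calcium fraction in particular) are exact by construction.
All slices of a stack share one geometry (an axisymmetric lumen looks
identical in every rotational cMPR view); only the noise differs.
Everything is deterministic given the seed.

Cohorts sample severity (default uniform [40, 90] %), lesion length
(8–20 mm), base radius (1.8–2.2 mm) and optional calcified foci from a
seeded generator and return a truth table.

What the phantoms do **not** model: blooming and motion artifacts,
partial-volume calcium, eccentric/non-axisymmetric lumina, bifurcations,
intensity inhomogeneity along the vessel, segmentation errors. Passing
the recovery suite therefore demonstrates the correctness of the
measurement chain on clean geometry — not clinical performance on real
scans, where segmentation quality dominates.

## Problem sizes and accuracy

The recovery suite runs 50 phantoms at the default 13×512×512 and
achieves MAE ≈ 1.5 severity points with |bias| < 1 point against truth;
the residual error is dominated by the half-pixel mask rasterization
limit (≈ 0.18 mm on a 4 mm vessel ≈ 4–6 severity points worst case per
single measurement, mostly averaged out by the median smoothing). Unit
tests use 1–3 slice phantoms at 192–320 px for speed; the geometry code
is size-agnostic.

## Known limitations

- Severity is exactly spacing-invariant only up to the mm-denominated
  reference windows selecting slightly different sample sets at
  different spacings (sub-0.5-point effect in tests).
- The proximal/distal orientation heuristic (left image border) is a
  convention; real exports with reversed orientation would swap the
  labels of the two reference windows (RVD itself is unaffected).
- The 2,100 HU calcium threshold and 1 % calcified-flag cutoff are kept
  configurable because neither has an external calibration here.
- Napkin-ring sign and spotty calcification are boolean inputs; no
  image-based detector is provided.
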