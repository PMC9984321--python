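# Methods

## Scope and design

The package reproduces the computational chain of a method-agreement study
of coronary-calcium scoring: Agatston quantification on two CT protocols
(ECG-gated 120 kVp CSCT as reference; non-gated 130 kVp low-dose CT), a
phantom-based adaptation of the detection threshold to tube voltage, risk
categorisation on the ordinal 6-point scale, and the agreement statistics
between scoring arms. Patient scans of such studies are not public, so a
synthetic image model supplies ground-truth-known inputs for every stage;
the published 6×6 confusion matrices are shipped as fixtures and anchor the
statistics exactly.

## Agatston scoring

Scoring is slice-wise on a non-overlapping 3 mm partition, the classic
definition. Pixels ≥ threshold (130 HU by default) form in-plane connected
components (8-connectivity by default, 4 available — vendor implementations
differ and the choice is observable only for diagonally touching pixels,
which is regression-tested). Components below 1 mm² are dropped. The density
weight is 1/2/3/4 for peak HU below 200/300/400/above; lesion score = area ×
weight. Lesion-to-artery attribution takes the majority label of a
co-registered vessel mask (labels 1–4 = LM/LAD/LCx/RCA); unlabeled lesions
count toward the total only. Volume and mass scores are not computed.

Overlapping reconstructions (thickness > increment, e.g. 3 mm slabs every
1.5 mm) are scored on every (thickness/increment)-th slice, phase-locked to
the first slice for determinism. An increment that is not an integer divisor
of the thickness has no non-overlapping partition and is rejected.

For low-dose scans at 130 kVp the detection threshold is rescaled by the
calibration-rod ratio, t = 130 × HU_rod@130 / HU_rod@120 (= 120.33 HU with
the measured rod values 249/269). Only the detection threshold is adapted;
the weight-bin edges stay at 200/300/400 HU, since the adaptation procedure
as published changes nothing else. The threshold is kept unrounded
internally and is overridable everywhere it is consumed.

## Image model

**HU model.** Material HU at 120 kVp is linear in hydroxyapatite density
through (0 mg/cm³ → 35 HU soft tissue) and (200 mg/cm³ → 269 HU), the
standard single-point phantom calibration assumption. Each voxel carries a
separate *calcium-attributable HU* channel (material HU weighted by the
voxel's calcium occupancy). At 130 kVp that channel is multiplied by the
contrast ratio (default 249/269 ≈ 0.926), so a pure rod voxel renders at
exactly 249 HU, a boundary voxel mixes physically, and non-calcium tissue is
exactly kVp-invariant. The ratio is referenced to 0 HU (water), not to the
35 HU soft-tissue baseline: that choice reproduces the measured rod pair
(249, 269) and hence the calibration example exactly, whereas a
soft-tissue-referenced rescale would render the rod at 251.6 HU.

**Partial volume.** Primitives (extruded ellipses and cylinders for the
phantom; spheres for lesions) are rendered at ≥ 4 sub-samples per axis and
box-averaged to the target grid. Doubling the supersampling moves the rod's
ROI mean by well under 1 HU. Overlaps resolve last-listed-wins.

**Acquisition degradation**, in order: (1) calcium-contrast rescale at
130 kVp; (2) isotropic Gaussian blur of sd `motion_sd` mm — the non-gated
protocol's stand-in for cardiac/respiratory motion (no cardiac-phase model
is attempted; nothing in the source material would constrain one); (3) slab
averaging to the protocol slice thickness sampled every increment mm, plus
in-plane box down-sampling (integer factors only); (4) additive Gaussian
noise in HU, seeded. HU are clipped to [−1024, 3071]. The phantom is
physically static, so phantom renderings skip motion blur. No
projection-domain physics, beam hardening or dose model; tube current
enters only through the noise sd.

**Protocol defaults.** Gated: 120 kVp, 3 mm slabs every 1.5 mm
(overlapping), 0.5 mm pixels, noise sd 5 HU, no motion. Low-dose: 130 kVp,
3 mm slabs every 3 mm, 1.0 mm pixels, noise sd 12 HU, motion sd 1.5 mm,
contrast ratio 249/269. The pixel sizes are round approximations of the
protocols' fields of view (228 mm and 500 mm) on a 512 matrix, chosen so
in-plane down-sampling from the 0.25 mm truth grid uses integer factors; the
noise levels are plausible for 80 vs 25 reference mAs. The low-dose
increment defaults to 3.0 mm (the tabulated protocol value; the alternative
1.5 mm appears once in the source text and is available as a parameter).

## Phantom

A thorax section (300 × 200 mm soft-tissue ellipse at 35 HU, two −800 HU
lung ellipses, a 300 HU spine ellipse, and a central 25 mm cylinder of
200 mg/cm³ hydroxyapatite) extruded over 12 mm. Calibration measures the
rod's mean HU in a large circular ROI (80% of the rod diameter, central
slice) in a 120 kVp and a 130 kVp rendering and applies the threshold
formula; on noise-free renderings this recovers 120.33 HU to within 1 HU.

## Cohort generator

Subjects are apportioned to the six risk categories by largest remainder
from the category proportions (default: the reference cohort's 12, 9, 27,
34, 69, 62 of 213 — exact when n = 213). Per subject, spherical lesions
(diameter 3–9 mm; 2.5–5 mm in category 1) with nominal peak HU drawn from
mid-weight-bin values (165–800 HU) are scattered around four vessel anchor
points in a 72 × 72 × 30 mm cardiac patch. The ground truth is the Agatston
result of the noise-free fine rendering (0.25 mm in-plane) slab-averaged to
the same 3 mm partition the scanners use; lesion sets are resized and
re-drawn until the ground truth lands in an inset window of the assigned
category (e.g. 450–950 for category 4) *and* the rendered gated scan scores
inside the category, so assigned categories are exact by construction on
the gated arm. Mid-bin peak HU and the inset windows exist because grids of
different resolution disagree slightly on peak HU and area; placing targets
away from bin and category edges keeps those disagreements from flipping
weights or categories, mimicking the fact that real calcifications are not
adversarially placed at decision boundaries.

Everything is driven by `numpy` `SeedSequence` spawning, so a cohort is
bit-reproducible from its seed, per subject.

What the generator does *not* emulate: realistic coronary anatomy and
curvilinear calcification shapes, streak/beam-hardening artifacts,
respiratory-phase mismatch between the paired scans, patient repositioning,
observer behaviour, or the vendor deep-learning scorer (the "automatic" arm
of the study replica is simply low-dose scoring at the uncorrected 130 HU
threshold; the real algorithm's behaviour enters only through its published
confusion matrix). Passing tests therefore demonstrate the correctness of
the scoring and statistics chain and the qualitative direction of the
degradation effect — not clinical performance on real scans.

## Study replica

`run_study` renders the phantom pair, calibrates, generates the cohort,
scores gated scans at 130 HU (reference) and low-dose scans at both the
calibrated and the uncorrected threshold, applies a reader model (random
±1-category misassignment with probability 0.25 by default) for a "visual"
arm, and reports all agreement statistics per arm. Degenerate tables
(single category in use) report kappa as undefined with an explicit flag
rather than a number.

## Statistics

Weighted kappa uses linear weights `1 − |i−j|/(k−1)` (quadratic available,
not default); the SE is the asymptotic weighted-kappa variance (Fleiss,
Cohen & Everitt form), CI = κ ± 1.96·SE, verified in tests to machine
precision against an independent implementation; a multinomial bootstrap CI
is provided as a cross-check. Paired-score summaries use linear-interpolated
quartiles, the exact binomial order-statistic CI of the median, Spearman
correlation with average ranks, and the Wilcoxon signed-rank test with zero
differences dropped (exact null for n ≤ 25, tie-corrected normal
approximation above); classical Bland–Altman limits (mean ± 1.96 sd) are
emitted alongside the median-based summary. Report output rounds half-up to
the printed precision (2 d.p. for kappa, 1 d.p. for percentages); unrounded
values are always retained in JSON.

## Numerical choices and problem sizes

Ground-truth grids are 0.5 mm (z) × 0.25 mm (in-plane); lesion rasterization
supersamples ×2 on top (effective 0.125 mm). Phantom rasterization defaults
to ×4 supersampling. Simulated-cohort checks run at n = 60 subjects with
fixed seeds, large enough for the directional effects (score loss and
agreement loss under low-dose degradation) to be decisive while keeping the
suite quick. Detection-metric ratios with zero denominators are NaN with the
metric named in an `undefined` field, never silently zero.

## Known limitations

* The motion model is a single isotropic Gaussian; real non-gated scans show
  anisotropic, phase-coherent artifacts that can also *raise* local HU.
* The linear HU–density model is anchored at one measured density; real
  calcium HU is weakly non-linear in density and kernel-dependent.
* Lesions are spheres; Agatston areas of irregular lesions interact with
  connectivity and the 1 mm² filter differently.
* The reader model is a symmetric perturbation and does not reproduce the
  asymmetric (under-calling) behaviour of human readers on noisy scans.
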