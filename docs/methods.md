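# Methods

`sctcalib` replicates, on digital phantoms, the commissioning workflow for
MRI-only prostate radiotherapy planning with a bulk-density synthetic CT
(sCT): quantify CT/sCT HU disagreement, derive a cohort-optimized HU →
relative-electron-density (RED) calibration, and verify that the optimized
calibration removes the systematic dosimetric error the vendor bulk HU values
otherwise introduce.

## The phantom cohort

Each phantom is a pelvis-like elliptical cylinder on a regular grid
(default 96 × 96 × 48 voxels at 2 × 2 × 3 mm — a 2× coarsening of a clinical
~1 × 1 × 1.5 mm acquisition chosen so the full pipeline runs in minutes on
one CPU; clinical-scale grids are a config change). Five tissue classes
partition the grid: air outside the body, a subcutaneous adipose shell
(12 mm), a soft-tissue interior, and bone — an elliptical pelvic ring and two
femoral heads, each with a 3 mm cortical (outer-bone) shell around a
trabecular (inner-bone) core. Soft-tissue organs (PTV, bladder, rectum) are
masks only; they do not change voxel class. The PTV may not intersect bone,
and every organ must lie inside the body (violations raise errors naming the
element).

The CT draws each voxel as `class mean + N(0, class std)` with the class
parameters (HU):

| class | CT mean ± std | sCT bulk | RED |
|---|---|---|---|
| air | −1000 | −1000 | 0.001 |
| adipose | −96 ± 6.1 | −75 | 0.95 |
| soft tissue | 37 ± 3.9 | 0 | 1.04 |
| inner bone | 219 ± 14 | 204 | 1.10 |
| outer bone | 1000 ± 23 | 1170 | 1.70 |

Noise is independent per voxel (no spatial correlation — only per-class
mean ± std is modeled); HU values are not clipped. The sCT is exactly
piecewise constant at the bulk values. Air RED is 0.001 rather than 0 to
keep attenuation logs finite. Cohorts jitter body semi-axes and organ radii
by ±10 % uniform per patient — enough to produce inter-patient MAE spread
without claiming any particular anatomy. Per-patient seeds come from
`SeedSequence(master, spawn_key=(i,))`, so extending a cohort never
reshuffles existing patients.

Three clinically observed CT/sCT discrepancy artifacts can be injected
independently: a rectal gas pocket present on CT only (bowel filling changed
between scans), three small ≥1000 HU fiducial markers in the PTV on CT only
(gold seeds are signal voids on MRI), and a rigid femoral-head displacement
on the sCT only, with vacated voxels filled with the soft-tissue bulk value.

**What the generator does not emulate:** partial-volume voxels, beam
hardening and scatter artifacts, spatially correlated texture, anatomical
variation beyond size jitter, couch/FOV edges, and the MRI/Dixon acquisition
itself. Passing tests therefore demonstrate the *machinery* (segmentation,
calibration algebra, path-length dosimetry, gamma/DVH analysis) and the
*mechanism* of the calibration effect, not clinical performance on real
patients.

## Segmentation

Intensity thresholding with four cut points at the midpoints of adjacent CT
class means: −548, −29.5, 128, 609.5 HU (config-overridable). An optional
per-class morphological opening (default radius 1 voxel) stands in for
manual contour cleanup; voxels removed by the opening are flagged
*unclassified*, never reassigned, and are excluded from class statistics but
included in total MAE. On coarse grids where a structure is one voxel thick
(the cortical shell at 3–4 mm spacing) the opening removes it entirely — use
radius 0 there. Class HU statistics use the population (÷N) standard
deviation.

## Calibration curves

A curve is an ordered list of (HU, RED) anchors. Evaluation is
piecewise-linear between anchors (the standard TPS convention for tabulated
curves), constant below the lowest anchor, and linear continuation of the
last segment above the highest anchor, clamped at a configurable maximum
(default 3.0) so fiducial-level HU cannot produce unphysical densities.
Validity requires strictly increasing HU and non-decreasing RED.

* **Optimized curve** — anchors at the cohort CT class means (air at −1000),
  each paired with its class RED. Cohort aggregation is the unweighted mean
  of per-patient class means (robust to body-size differences; a
  voxel-pooled mode exists). Bone anchors stay at the vendor sCT values
  (204, 1170) by default, since the vendor bone HUs are consistent with
  clinical calibration data; `keep_sct_bone=False` uses cohort bone means.
* **Original (vendor) curve** — anchors at the bulk sCT values
  (−1000, −75, 0, 204, 1170). REDs default to the class REDs; alternatively
  a reference curve supplies them by evaluation at the bulk HUs (see below).

## HU comparison

MAE is the mean absolute voxelwise difference between co-registered volumes,
over all imaging voxels by default (background air inflates agreement, so a
body-mask mode exists and every report records which was used). Per-class
MAE uses CT-derived segmentation masks; total-bone MAE is computed on the
union of inner and outer bone. Difference maps are signed CT − sCT and are
never clipped for computation. The *modified* sCT remaps the sCT's own bulk
palette — adipose −75 → cohort CT adipose mean, soft tissue 0 → cohort soft
mean, bone untouched. A palette remap (rather than a CT-mask override) keeps
sCT-only discrepancies such as a displaced femoral head in place, which is
essential for the bone-mislabel analysis.

## Dose engine

The engine is this package's own simplified stand-in for a clinical
ray-trace algorithm. It deliberately preserves the one mechanism HU
calibration acts through — scaling of each beamlet's effective
(water-equivalent) path length — and nothing else: no scatter, no
heterogeneity-correction kernels, no MLC modeling, no absolute dosimetry.
Per beam, voxel dose is

    D(v) = w · (d_ref / d(v))² · exp(−μ_eff · WED(source → v)) · A(v)

with `d` the source distance, `WED` the radiological path length through the
RED volume, `μ_eff = 0.005 /mm` water-equivalent (a 6-MV-like effective
attenuation), and `A` a Gaussian-edged circular aperture (edge σ = 3 mm)
evaluated at the reference plane. Two path-length routes exist:

* `radiological_path_length` — exact Siddon voxel traversal (the reference);
* `compute_dose` — beam's-eye-view integration: the RED volume is resampled
  on a fan of rays (32 × 32 angular samples across the aperture plus a 12 mm
  margin, 160 depth steps), cumulatively summed into a WED table, and looked
  up trilinearly per voxel. This is O(fan + voxels) per beam instead of
  O(voxels × ray length) and agrees with per-voxel Siddon dose within 2 %
  (tested); both routes are deterministic.

Plans: *arc* — 36 equispaced coplanar gantry angles at SAD 1000 mm aimed at
the PTV centroid; *robotic* — 40 seeded directions on a superior spherical
cap (stratified azimuth, default elevation 15–75°) aimed at jittered points
inside the PTV at SAD 800 mm (non-isocentric). Beam weights are scaled once
so D95(PTV) equals the prescription (default 40 Gy — a config input; no
published value exists for it) on the planning volume, then frozen for every
recomputation. SAD values are conventional, not fitted.

## Plan evaluation

DVHs store raw sorted voxel doses; Dx is the linear-interpolated order
statistic (`quantile(doses, 1 − x/100)`), checked against a sort-based
oracle. The D95 ratio is 100 × D95(sCT dose) / D95(CT dose) on the PTV.

Gamma analysis defaults to 3 %/3 mm with **local** normalization (the dose
criterion divides by the reference voxel's dose; a global mode divides by
prescription). The low-dose cutoff is 10 % of prescription (a common
clinical convention; recorded in every result). The minimum is searched over
a sub-voxel lattice with step DTA/10 within radius 2 × DTA, scanning offsets
in increasing-distance order with early termination once the distance term
alone exceeds every remaining voxel's current best γ — lossless relative to
the exhaustive scan of the same lattice, and validated against an exhaustive
brute-force oracle on 12³ grids. Evaluated-grid lookups outside the volume
clamp to the nearest voxel; voxels where the evaluated dose is zero go
through the same formula with no special-casing.

## Study assembly (the two calibration arms)

Plans are built and normalized on the CT converted with the *clinical
reference curve*: the cohort curve anchored at the CT class means
(`keep_sct_bone=False`), with extrapolation capped at its top-anchor RED —
a tabulated clinical curve ends at its densest commissioned point, and the
vendor bone HUs are consistent with such a curve rather than with an
extrapolated continuation. Dose is then recomputed with frozen plan
parameters on the sCT under two arms:

* **original** — the vendor sCT through the original curve whose REDs come
  from evaluating the clinical reference curve at the bulk HUs. This models
  the pre-commissioning workflow: the sCT's bulk soft-tissue value (0 HU,
  water) reads ~1.015 instead of the true 1.04, adipose −75 reads ~0.964
  instead of 0.95, so every beamlet's effective path length is systematically
  wrong.
* **optimized** — the modified sCT (palette remap to cohort means) through
  the optimized curve. With zero noise this reproduces the CT's effective
  densities exactly, so the recomputed dose is bit-identical; with noise the
  residual is at the noise level.

On the default 10-patient cohort the original arm's |D95 − 100 %| exceeds
the optimized arm's for every patient and both plan styles (~+0.4–0.5 % arc,
~+0.9–1.0 % robotic, versus <0.2 % optimized), and gamma pass rates stay at
100 % for both arms — the phantom geometry is more forgiving than patient
anatomy, so the gamma criterion does not separate the arms at this scale;
the D95 coverage ratio does.

## Numerical and design choices

* One coordinate convention everywhere: 0-based indices,
  `world = origin + index × spacing`, axes (x, y, z) = (right, anterior,
  superior); volumes are co-registered iff shape, spacing, origin are equal.
* Default grids, beam counts and the BEV fan resolution were chosen so a
  full 10-patient, two-style study runs in ~3 minutes on one CPU.
* The elliptical pelvic ring uses a same-angle pseudo-distance to the
  ellipse path — smooth and adequate for a phantom, not an exact Euclidean
  distance.
* Phantom body habitus and organ sizes are illustrative; no published
  distributions exist for them.
* Cohort means skip patients with zero voxels in a class; deriving a curve
  from a cohort with an entirely missing class raises an error naming it.

## Reproducibility

Every stochastic step is seeded: phantom noise and jitter from the master
seed via documented `SeedSequence` spawn keys, robotic beam geometry from a
per-patient plan seed. Rerunning a study with the same config produces
byte-identical reports; every report carries a config hash.
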