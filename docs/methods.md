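# Methods

## Data model and metric conventions

All masks are binary occupancy grids with explicit physical spacing.
NIfTI inputs are reoriented at load to the canonical RAS+ anatomical
frame (grid axes = left–right, anterior–posterior, cranio-caudal), so
octant localization can use grid axes directly. Stored voxel values are
binarized at 0.5, which tolerates fuzzy-edged exports deterministically.

Voxel indices are 0-based; physical positions refer to voxel centers;
every distance is an exact anisotropic Euclidean distance **between
voxel centers** (scipy's exact EDT with per-axis sampling), never a
voxel-count chamfer — margins are reported in millimetres on scans
whose slice thickness (0.5–3.0 mm) can be several times the in-plane
resolution (0.6–1.0 mm), so metric exactness matters more than speed
here. Whether clinical software measures surface-to-surface or
voxel-center distances is not documented; the voxel-center convention
was adopted because it is unambiguous and identical to the alternative
up to one voxel diagonal, and the convergence suite quantifies exactly
that discretization error (see below).

## Margin definitions

**Coverage MAM.** The r-mm safety envelope is the metric dilation of
the tumor, implemented by thresholding the tumor's outside distance map
(so one EDT serves all ten radii). "Completely ablated at r" means the
envelope contains **zero** voxels outside the ablation mask — no
sub-voxel tolerance; the phantom convergence suite exercises the
sensitivity of this choice. A tumor with any voxel outside the ablation
zone is *residual*; margins beyond the 10 mm sweep collapse to 10,
since the definition does not resolve them. For threshold analyses the
residual class carries the sentinel −1 mm, which makes the uniform rule
"positive iff MAM < t" behave identically at t = 0 and t = 1 for
integer margins — matching how coverage-style software, which reports
no absolute value below 0 or above 10 mm, enters such sweeps.

**Surface MAM.** The ablation boundary is the set of ablation voxels
with at least one face-neighbour outside the mask (grid edges count as
outside). Each tumor voxel gets the distance to the nearest boundary
voxel center, signed by its own ablation-mask membership; the minimum
over tumor voxels is rounded to the nearest integer millimetre, half
away from zero. The minimum is taken over the full tumor volume rather
than its surface — identical for positive margins, and for negative
margins it reports the deepest uncovered tumor point, which is the
clinically conservative reading.

**Octants.** The dividing point is the tumor centroid (center of mass
of tumor voxels in physical coordinates); bounding-box centers were the
alternative, but the centroid is robust to mask padding and is the
natural "center" of an irregular lesion. Voxels exactly on a dividing
plane join the positive side (a measure-zero tie-break). Insufficiency
(< 5 mm) is judged on the rounded per-octant minimum, consistent with
integer-mm reporting; empty octants are omitted.

## Rigid registration surrogate

Clinical packages register pre/post scans on image intensities and let
the reader judge alignment on local landmarks (liver vessels). Here the
landmark pairs themselves are the registration currency: the transform
is the closed-form least-squares rigid fit (Kabsch/orthogonal
Procrustes, reflections rejected), which makes the published accuracy
rule computable — registration is insufficient when **more than one**
landmark residual strictly exceeds 3 mm, and such cases are excluded
rather than quantified. Masks are resampled onto the post-ablation grid
(where the ablation zone is defined) with nearest-neighbour
interpolation to preserve binarity. Non-rigid (elastic) registration is
deliberately out of scope; pre-aligned mask pairs are accepted for that
pathway.

## Synthetic phantoms

Phantoms voxelize spheres/ellipsoids by center membership. Two ablation
constructions are supported: an explicit second sphere (closed-form
margin R_a − |offset| − R_t) and the continuous offset of the tumor by
a fixed margin m, whose true minimal margin is m by construction; for
ellipsoids the offset membership test solves the point-to-ellipsoid
projection (Lagrange condition) by vectorized bisection to ~1e-12.
Misalignment is a known rigid transform applied to the pre-scan side,
with consistent landmark pairs (optionally jittered) emitted alongside;
all randomness sits behind one integer seed (default 20240802).

Phantoms emulate geometry only: no CT intensities, no segmentation
error, no deformable motion. Passing the phantom suite therefore
demonstrates correctness of the metric/registration machinery, not
robustness to segmentation variability in real scans.

## Cohort simulator

Per-tumor margins follow a three-category mixture — residual
(sentinel −1), 1–4 mm and 5–10 mm, integer-uniform within category —
with default category probabilities 13/173, 80/173, 80/173, the
frequencies observed in the multicenter cohort the package reconstructs.
Time to LTP is exponential with log-hazard
log h₀ + log(HR_mm)·MAM: the simplest model consistent with a Cox
analysis reporting a per-mm hazard ratio, and sufficient for parameter
recovery. Defaults: HR_mm = 0.5 (the reported per-mm estimates were
0.42–0.51); h₀ = 0.022 /month, chosen so that a mid-category tumor
(2 mm) has ≈16% LTP probability over a median follow-up, matching the
observed mid-category incidence; censoring is lognormal with median 31
months and log-sd 0.62, reproducing the reported 22–47 month IQR. The
second software's margin is the first plus rounded Gaussian noise
(sd 3.0 mm, giving a median absolute inter-software difference near the
reported 2 mm), clipped to the sentinel range [−1, 10]. Covariates
(size, subcapsular/perivascular flags, age, sex, prior chemotherapy,
modality) are drawn independently at the cohort's marginal frequencies;
the simulator does not model covariate–margin correlation, per-patient
clustering, or center effects.

## Printed-counts reconstruction

`reconstruct_published_cohort` encodes the published per-software
category/LTP counts (coverage software 80/80/13 with 0/13/8 LTP;
surface software 79/79/15 with 0/6/15 LTP; 21/173 LTP overall) as an
explicit deterministic record list with one sentinel margin per
category (−1 / 2 / 7 mm). The joint software-by-software table is not
published; it is fixed canonically by maximal overlap — since every
surface-residual tumor progressed but only 8 of 13 coverage-residual
tumors did, the 8 shared LTP cases form the residual-class overlap and
the 5 non-progressing coverage-residual tumors sit in the surface
mid-category. Every statistic the package derives from this cohort
depends only on one software's marginal at a time, which the
construction reproduces exactly. Event and censoring times are
deterministic by index (events spread around the reported 14.7-month
mean; censoring on the follow-up lognormal quantiles) — the published
counts constrain categories and indicators, not individual times.

## Statistical choices

* Threshold sweep: positive iff MAM < t, uniformly including t = 0;
  rates kept as exact fractions, reported to 2 decimals with half-up
  rounding.
* AUC: tie-aware rank formulation (score = −MAM); 95% CI by stratified
  nonparametric bootstrap, 2000 replicates, fixed seed.
* Cox: lifelines partial likelihood with Efron tie handling (the
  original analysis does not state its choice); Wald CIs and p-values;
  tumors treated as independent — no patient-level clustering or center
  stratification, mirroring the per-tumor analysis being emulated. A
  warning (not an error) fires below 5 events per covariate.
* ICC: two-way random-effects, absolute-agreement, single-measurement
  form with F-distribution CI (pingouin), restricted to pairs with both
  margins in [0, 10] mm — outside that range the coverage-style
  software reports no absolute value. Zero between-subject variance is
  flagged as undefined rather than forced.
* No multiplicity correction anywhere (none is applied in the analysis
  being emulated; p < 0.05 nominal).

## Validation problem sizes

Phantom convergence runs at 2, 1 and 0.5 mm isotropic spacing (the
finest grid ≈ 1.5M voxels); brute-force oracle suites use random masks
up to 32³ voxels against O(n²) pairwise distances and rank-sum AUC on
up to 500 records; Cox recovery uses n = 1000 tumors × 100 seeds
(target: HR in [0.4, 0.6] for true 0.5) and 200 null replicates
(Wald CI coverage, nominal 95%, accepted band 93–97%). These sizes give
sub-voxel margin accuracy and ±3% Monte-Carlo precision on recovery
rates while keeping the full suite under a minute of compute for the
deterministic parts.

## Known limitations

* Margins are resolved only to ~1 voxel diagonal; on 3 mm-slice scans
  a reported integer MAM can be off by ±2 mm near category boundaries.
* The rigid surrogate cannot emulate the non-rigid deformation pathway;
  cohorts quantified elastically must arrive pre-registered.
* The simulator's within-category margin distributions are
  configuration, not inference — the study published only category
  frequencies.
* Reconstructed-cohort statistics beyond the category marginals (e.g.
  its AUC of 0.837, ICC, or any per-mm hazard ratio) reflect the
  sentinel construction, not the unpublished per-tumor data, and are
  reported only as internal consistency checks.
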