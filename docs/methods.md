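# Methods

This note documents the models, algorithms and numerical choices behind
`adiposeg`: what each stage assumes, which knobs matter, what the synthetic
data do and do not emulate, and the design decisions taken where several
reasonable implementations existed.

## Imaging model and conventions

Input is a stack of axial T1-weighted slices with fat hyperintense relative
to lean tissue and air dark (the thick-slice 2-D gradient-echo regime, e.g.
22 slices of 10 mm starting at S1-L5 and proceeding proximally). Voxel
arrays are `(n_slices, rows, cols)`; slice 1 is the most caudal slice, and
all user-facing slice numbers are 1-based caudal→cranial so that "slices
4 to 11" means the same thing in configuration files and in print. Physical
geometry (in-plane spacing, slice thickness) is always carried explicitly;
the I/O layer refuses images whose headers omit it rather than assuming a
default.

All morphology is 2-D, per slice, with disk structuring elements. With
10 mm slices, anatomy decorrelates across slices, and 3-D structuring
elements would bridge unrelated structures; per-slice processing also makes
every result exactly equivariant under 90° in-plane rotation, which the
test suite asserts.

## Intensity normalization

Each slice is divided by a Gaussian-smoothed copy of itself that has been
normalized to unit mean, so only the *relative* low-frequency variation
(coil bias) is removed, and is then affinely rescaled so the 1st percentile
maps to 0 and the 99th to 1, clipping outside. The smoothing scale
(`smoothing_scale_vox`, default 48 voxels ≈ one third of the default
matrix) must sit above the anatomical scale and at or below the bias-field
scale; on phantoms with a 30% quadratic bias field this reduces the
within-fat-class coefficient of variation by roughly half.

Division-by-smoothed followed by a percentile stretch is not an analytic
projection, so idempotence is provided structurally: the `ImageStack`
carries a `normalized` provenance flag and normalization of an
already-normalized stack is an exact no-op. A constant slice (zero dynamic
range) is a degenerate-input error naming the slice.

## Torso extraction

Air/tissue separation uses the *lower* cut of a three-class Otsu threshold.
A slice histogram is trimodal (air, lean, fat), and a two-class Otsu on a
trimodal histogram can land in the lean/fat gap when the air class is
large — the three-class variant removes that failure mode while staying
fully histogram-based (hence rotation-invariant). A fixed threshold is
available for controlled inputs.

From the centroid of the bounding box of above-threshold voxels, rays are
cast at 720 equally spaced angles with 0.5-voxel radial steps; a ray stops
at the first run of `ray_stop_run` (default 3) consecutive background
samples, which makes the growth robust to isolated dark voxels inside the
torso while still stopping at genuine air. The accepted region is closed
(disk radius 2), hole-filled, and reduced to its largest connected
component, guaranteeing a simply connected, single-component torso per
slice. If the bounding-box centroid itself falls on background (e.g. a
hollow slice), the centroid of the largest above-threshold component is
used instead and a warning is logged; a slice with no tissue at all is an
error.

## Fat segmentation and the SAT/VAT split

Fat is thresholded within the torso (two-class Otsu on torso voxels, which
are bimodal, or a fixed cut), and components smaller than
`min_component_vox` (default 5) are removed. Raising a fixed threshold can
never grow the mask — monotonicity is property-tested.

The split works per slice:

1. erode fat by `erosion_radius_vox` (default 2) to break the thin bridges
   that connect the subcutaneous ring to visceral fat;
2. label the eroded components; those intersecting the boundary band (the
   `boundary_band_vox`-wide rim, default 3, just inside the torso edge)
   seed SAT, the rest seed VAT;
3. geodesically reconstruct each seed class inside the original fat mask
   (iterated conditional dilation with a disk of `dilation_radius_vox`,
   run to convergence), restoring the eroded voxels;
4. fat voxels reached by both classes — or by neither, when erosion erased
   their whole component — are assigned to the class with the nearer seed
   under the Euclidean distance transform (computed in mm, so anisotropic
   pixels are handled); exact ties go to SAT.

The tie-break to SAT is deliberate: it can only deflate, never inflate, the
headline VAT/SAT ratio, and it is configurable in the sense that the
assignment is symmetric apart from that one comparison. Steps 3–4 make
SAT ∪ VAT an *exact* partition of the fat mask, which the suite asserts on
random masks as well as phantoms. If no component reaches the boundary
band, the slice legitimately has no SAT; that is a logged warning, not an
error. The non-VAT compartment — the dark tissue referenced against the
fat compartments — is the hole-filled interior of the SAT ring minus all
fat, intersected with the torso.

## Scripted manual editing

Interactive mask editing is replaced by an ordered edit script: each entry
names a 1-based slice, a target compartment (SAT or VAT), an action (`add`,
`remove`, `reassign`) and a region, given either as a simple polygon in
voxel coordinates (validated as non-self-intersecting and in-grid) or as an
explicit mask (e.g. one slice of a NIfTI label volume). `add` clips the
region to the torso and removes it from the other compartments first, so
disjointness is preserved by construction; `reassign` moves voxels between
SAT and VAT. Every applied edit is appended to the result's provenance log.
This is how the canonical "remove paraspinal adipose tissue" correction is
expressed and replayed.

## Volumetry

Volumes are voxel counts times `row_spacing × col_spacing × thickness`,
restricted to an inclusive 1-based slice window, default (4, 11) — eight
slices of a 22-slice stack. Both the numerator and denominator of the
VAT/SAT ratio use the same window; a zero SAT volume makes the ratio
undefined (`None`), never a division error. There is no partial-volume
weighting: masks are binary, and a voxel is all-or-nothing. Volume is
exactly additive over adjacent windows and exactly linear in slice
thickness.

## Phantoms

The phantom is deliberately schematic — nested ellipses (torso, SAT
annulus of configurable thickness, abdominal wall, cavity), circular VAT
blobs with a configurable count/size/wall-gap and random contiguous slice
extents, lean "organ" blobs, and an optional posterior spine structure
(dark vertebral body plus a bright paraspinal fat pocket, tracked as its
own truth mask so edit workflows can be validated). The noise-free
composite uses exactly three intensity levels (air 10, lean 40, fat 100 in
arbitrary units), then a per-slice multiplicative quadratic bias field
(amplitude default 0.2) and Rician noise (two Gaussian channels, magnitude;
σ expressed as a fraction of the fat level, default 0.05) are applied.
Truth masks are the exact pre-noise label maps, and stored truth volumes
are exact voxel counts.

The spine structure defaults to off: the automatic stage by design counts
paraspinal fat as VAT (removing it is precisely the manual-edit step), so
phantoms meant to measure *automatic* recovery exclude it, and tests of
the edit pathway enable it explicitly.

What the phantom does **not** emulate: partial-volume fractions at tissue
boundaries (edges are crisp at voxel resolution), chemical-shift artefact,
motion/peristalsis, bowel-content heterogeneity, or anatomically realistic
organ shapes. Recovery numbers on phantoms therefore demonstrate the
correctness of the algorithmic chain (thresholds, morphology, geometry,
bookkeeping), not clinical-grade accuracy on patient data; near-perfect
Dice on phantoms is expected, not suspicious.

One numerical caveat is inherited from voxel-centre rasterization: the
voxel count of an ellipse differs from its analytic area by a lattice
error on the order of the perimeter divided by the pixel size, far more
than one voxel per slice. Tests comparing truth volumes to analytic
annulus volumes therefore use the half-voxel perimeter-band bound, which
the rasterization provably satisfies.

## Synthetic cohorts

Cohorts are drawn from a Gaussian copula. The declared pairwise Spearman
matrix is mapped to the latent Pearson matrix by ρ_P = 2 sin(πρ_S/6)
(exact for the bivariate normal), repaired to the nearest positive
semi-definite correlation matrix by eigenvalue clipping if needed (a
matrix still indefinite after repair is a configuration error), and
sampled; each margin is pushed through its declared inverse CDF (normal,
lognormal, gamma, uniform, bernoulli). Rank-preserving marginal transforms
leave the Spearman structure intact, so realized rank correlations
converge to the target (verified at n = 20 000 within 0.02). The binary
sex margin necessarily coarsens ranks for its own pairs.

The default cohort emulates a midlife obesity imaging sample: age
51.3 ± 6.1 y, ~47% male, BMI 32.3 ± 6.4 kg/m², SAT 2871 ± 1213 cm³, VAT
1138 ± 612 cm³, VAT/SAT ratio ~0.45, fasting glucose 97.8 mg/dL, with
adiposity couplings (BMI–SAT stronger than BMI–VAT, insulin with both) and
an additive male shift of the VAT/SAT ratio applied after the copula step,
mirroring the robust male excess in visceral-to-subcutaneous fat
distribution. The coupling values were chosen jointly so that both the
Spearman target and its latent Pearson counterpart are positive definite
as declared (no silent repair). Where the ratio is itself a declared
copula variable, it is modelled directly rather than derived from the VAT
and SAT columns — the object under test is the correlation machinery, not
algebraic consistency between columns.

## Statistics

**HOMA-IR** is insulin (µU/mL) × glucose (mmol/L) / 22.5, with mg/dL
glucose divided by 18.0182; the unit conversion is exact to 1e-12 by
construction. Printed unit strings for this quantity vary across the
clinical literature; the standard µU/mL–mmol/L convention with divisor
22.5 is used throughout. **BMI** is kg/m² with the obesity predicate
exactly at ≥ 30.

**Partial Spearman correlation** rank-transforms x, y and each covariate
(average ranks on ties), forms the joint correlation matrix of the ranks,
and reads the partial correlation from its inverse:
ρ = −P₀₁/√(P₀₀P₁₁). This is algebraically identical to residualizing the
ranked x and y on the ranked covariates by least squares and correlating
residuals, an identity the suite verifies to 1e-10 against the brute-force
oracle and cross-checks against `pingouin.partial_corr`. The two-sided
p-value uses the t approximation on n−2−k degrees of freedom (the exact
permutation null is out of scope); p-values are clamped to (0, 1].
Missing data are removed listwise per correlation — consistent with
cohorts where different modalities have different coverage — and at least
k+4 complete cases are required.

**Benjamini–Hochberg** is the standard step-up rule with adjusted p-values
min over j ≥ i of m·p₍ⱼ₎/j, capped at 1, input order restored. It is
verified against an exhaustive O(m²) reference (including ties) and
against `statsmodels.multipletests`; rejection sets are monotone in q.
The family is one predictor × its outcome roster. The number of
comparisons per family is whatever the outcome list supplies — the
simulation-based checks use 28 — and a `correct=False` switch supports
outcome families whose regional interdependence (e.g. default-mode-network
SUVRs) violates the independence premise, in which case raw p-values are
compared to q directly.

The normality-gated choice between linear regression and the rank-based
analysis is exposed as an explicit `method` switch (`spearman_partial` |
`linear`) rather than an automatic Shapiro–Wilk branch; an automatic
branch would make the reported statistic silently data-dependent.

## Simulation sizes and calibration checks

The acceptance surface is property- and simulation-based, computed fresh at
run time: 20 seeded default phantoms (128², 22 slices, σ = 0.05, bias 0.2)
for volume/overlap recovery; a 50-seed sweep of small phantoms for the
partition/containment invariants; 1000 null cohorts (n = 32, 28 outcomes,
age and sex covariates) for the family-wise BH rejection rate, expected
near q = 0.05 under the complete null by the Simes identity and bounded at
0.07 with Monte-Carlo slack; 200 replicates at n = 21 for sign recovery of
a planted ρ = 0.55 ratio–outcome correlation and 200 replicates at n = 200
for its dominance among rejections; and byte-identity of full pipeline
reruns. These sizes keep the full validation under a minute on one CPU
while leaving each check's expected margin large relative to its
Monte-Carlo noise.

## Known limitations

- Per-slice 2-D processing cannot exploit through-plane continuity; on
  thin-slice 3-D acquisitions a 3-D variant would be preferable.
- Otsu-based thresholds assume each slice (and each torso) is genuinely
  multimodal; pathological contrast (e.g. a slice that is almost all fat)
  would need fixed thresholds.
- The SAT seed rule assumes subcutaneous fat approaches the torso surface
  within the boundary band everywhere it exists; a subject with a locally
  absent SAT layer yields a (logged) empty-SAT slice rather than an
  inferred one.
- The t-approximate p-value for the partial rank correlation is slightly
  liberal at very small n; the null-calibration simulation quantifies the
  effect at the sample sizes used.
- Phantom realism limits are listed above; no claim about accuracy on
  patient data is made or tested.
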