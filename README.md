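# adiposeg

Semi-automatic segmentation and volumetry of **visceral and subcutaneous
abdominal adipose tissue** (VAT/SAT) from axial T1-weighted abdominal MRI,
together with the cohort-level statistics such measurements feed into:
HOMA-IR, BMI, partial Spearman correlations with covariates, and
Benjamini–Hochberg FDR control.

It is written for body-composition and metabolic-imaging researchers who
need a reproducible, scriptable replacement for interactive fat-segmentation
workflows. On thick-slice (e.g. 10 mm) T1 fl2d acquisitions fat is
hyperintense, so the pipeline is:

1. **Normalization** — each slice is divided by a heavily smoothed copy of
   itself (bias-field flattening) and contrast-stretched so the 1st/99th
   intensity percentiles map to 0/1.
2. **Torso extraction** — radial region growing from the centroid of the
   bounding box of above-air voxels; each ray stops after *k* consecutive
   background voxels; the boundary is closed and hole-filled.
3. **Fat segmentation** — Otsu thresholding of bright voxels within the
   torso (fixed thresholds are also supported), despeckled.
4. **SAT/VAT split** — erosion breaks the thin bridges between the
   subcutaneous ring and visceral fat; eroded components touching a band
   just inside the torso boundary seed SAT, the rest seed VAT; geodesic
   reconstruction inside the original fat mask restores the eroded voxels,
   and contested voxels go to the nearer seed (EDT, ties → SAT). The result
   is an exact partition of the fat mask. The dark tissue enclosed by the
   SAT ring forms the non-VAT compartment.
5. **Scripted manual editing** — the "semi-automatic" corrections (e.g.
   removing paraspinal fat) are replayed from a declarative edit script, so
   every result is reproducible and auditable.
6. **Volumetry** — voxel-count volumes over a slice window (default slices
   4–11 of a 22-slice stack, counted caudal→cranial from S1-L5) and the
   VAT/SAT ratio, a BMI-independent marker of visceral obesity.

Because clinical abdominal MRI is rarely shareable, the package ships a
**phantom generator** (schematic torso: SAT annulus, abdominal wall, cavity
with VAT blobs and organs, optional spine, Rician noise, polynomial bias
field, exact ground-truth masks) and a **cohort generator** (Gaussian copula
with declared marginals and a target Spearman correlation matrix), so every
stage is testable end to end without any data download.

## Statistics

For a cohort table the package computes

- `HOMA-IR = fasting insulin (µU/mL) × fasting glucose (mmol/L) / 22.5`
  (mg/dL glucose converted via 18.0182),
- `BMI = weight (kg) / height (m)²` with the obesity predicate `BMI ≥ 30`,
- partial Spearman correlation: rank-transform x, y and covariates, then
  read the partial correlation off the inverse joint correlation matrix;
  two-sided p from `t = ρ√((n−2−k)/(1−ρ²))` on `n−2−k` df,
- Benjamini–Hochberg step-up FDR control per predictor family,
- OLS summaries `(R², slope, p)`,

and a driver that correlates every predictor against every outcome with
covariates, applies BH within each predictor's family, and optionally
stratifies (e.g. by sex, dropping sex from the covariates).

## Worked example

```python
from adiposeg import (PhantomSpec, generate_phantom, segment_stack,
                      compute_volumes, dice)

stack, truth = generate_phantom(PhantomSpec(seed=1))   # 22 x 10 mm slices
result = segment_stack(stack)                          # normalize→torso→fat→split
report = compute_volumes(result, stack, window=(1, 22))

print(f"SAT {report.sat_cm3:.1f} cm3 (truth {truth.sat_volume_cm3:.1f})")
print(f"VAT {report.vat_cm3:.1f} cm3 (truth {truth.vat_volume_cm3:.1f})")
print(f"VAT/SAT ratio {report.vat_sat_ratio:.3f}")
print(f"Dice SAT {dice(result.sat, truth.sat_mask):.3f}")
```

prints

```
SAT 4055.1 cm3 (truth 4055.0)
VAT 781.2 cm3 (truth 781.2)
VAT/SAT ratio 0.193
Dice SAT 1.000
```

i.e. on a phantom with Rician noise (σ = 5% of the fat level) and a 20%
bias field, the automatic stage recovers both compartment volumes to well
under 1% and overlaps the ground truth almost perfectly.

The same flow is available from the shell:

```bash
adiposeg simulate --config sim.yaml --out sim        # phantoms + cohort
adiposeg segment sim/phantom_001/image.nii --out seg
adiposeg quantify seg --image sim/phantom_001/image.nii --out vol.csv
adiposeg derive sim/cohort.csv --out derived.csv     # + BMI, HOMA-IR, ratio
adiposeg correlate --cohort derived.csv --config stats.yaml --out corr
adiposeg run --config run.yaml                       # full multi-subject pipeline
```

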