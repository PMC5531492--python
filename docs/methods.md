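# Methods

This note records the model, the numerical choices and the known limits of
`lungmech`, in the spirit of a methods appendix.

## Model and conventions

Two inspiratory CT scans of one subject, acquired near total lung capacity
at different times, are compared. The later scan is the **reference**
(Time 1) and the earlier the **floating** image (Time 0); the estimated
warp T(x) = x + u(x) maps reference-grid voxel locations into the floating
image. All geometry is in millimetres: voxel indices are 0-based, the
world position of voxel (i,j,k) is `origin + index·spacing`, grids are
axis-aligned (no direction matrix), and masks must share their image's
grid exactly — a mismatch is an error, never a silent resample.

A voxel is decomposed into air and "tissue" (all non-air material) by
linear interpolation of its calibrated HU between −1000 (air) and +55
(soft tissue), clamped to that range. Calibration is a single global
affine intensity map fitted to two anchors — mean mid-trachea ROI to
−1000 HU and mean aortic ROI to +55 HU. An affine two-point fit (rather
than two independent shifts) was chosen because it is the minimal map that
pins both anchors simultaneously; it is idempotent and order-preserving.

## Registration

**Cost.** The sum of squared tissue volume difference,
E = Σ_Ω (v_tis^r(x) − v_tis^f(T(x)))², summed over the reference
combined mask Ω (union of lung, airway and vessel masks when provided;
lung only otherwise). The floating-side tissue volume is discretized as
`v^r · det(∂T/∂x) · frac(I^f(T(x)))` — interpolated (linear) floating
intensity, clamped to [−1000, 55] *before* the fraction, times the
matched volume of the reference voxel's image under T. This is the
mass-preserving reading: at the true warp of a conserving deformation the
residual is exactly the scan noise.

**Transform.** Cubic B-spline free-form deformation on a lattice with one
knot of margin around the grid. Three pyramid levels (image downsampling
4/2/1 after Gaussian anti-aliasing of σ = factor/2 voxels), control
spacing halved per level, default finest spacing 6 mm. Coefficients
transfer between levels by an exact separable least-squares fit of the
coarser level's field on the finer grid.

**Optimizer.** L-BFGS-B with fully analytic gradients; the
Jacobian-determinant term's gradient uses Jacobi's formula via the
cofactor matrix (no per-voxel inversions). Convergence is declared when
the relative cost decrease stays below `rel_tol` (default 1e-6) for
`patience` (default 5) consecutive accepted steps, capped at `max_iter`
(default 200) per level. Accepted-step cost history is recorded per level
(the data behind convergence plots) and is non-increasing by construction.

**Regularization.** No explicit smoothness term is used. Two implicit
guards substitute for it: (i) each control coefficient is box-bounded to
±0.4 control spacings around its per-level initialization, which prevents
folding for the deformations in scope, and (ii) both images are smoothed
with a small Gaussian (`smoothing_sigma`, default 0.7 voxels) at the
finest level. The smoothing matters: without it the optimizer can drive E
*below* its value at the true warp by fitting scan noise, which shows up
as spurious structure in the Jacobian map. The fraction of lung voxels
with non-positive Jacobian is always computed; above 1% the result is
flagged (but returned).

**Jacobian conventions.** `jacobian_det_map` returns det(∂T/∂x)
(floating volume per reference volume; central differences on the field,
exact for affine warps). The regional mechanics use the reciprocal,
`volume_ratio_map` = J = v^r/v^f, so J > 1 where the lung locally
expanded from Time 0 to Time 1. The analytic lattice Jacobian and the
central-difference map agree to ~1e-3 for smooth fields; both are
exercised against oracles in the tests.

## Regional mechanics

Δ* = J·(V^f/V^r) − 1, with V the geometric lung volume of each image over
its own lung mask. The air and tissue analogues replace J by the matched
compartment ratios; the floating-side compartment volumes use the matched
volume v^f(T(x)) = v^r·det(∂T/∂x), which makes the decomposition identity
(1+Δ*)v^f = (1+Δ_air*)v_air^f + (1+Δ_tissue*)v_tis^f hold to machine
precision. Voxels whose floating-side compartment volume falls below
1e-6·v are excluded from that fractional map and counted, avoiding
division blow-ups. The air-volume normalizer follows the expanded form
(v_air^r/v_air^f)·(V^f/V^r) − 1, mirroring the geometric index's
structure. Summaries report the percent of lung at Δ* thresholds
(default 0.2/0.5/1.0) and tissue analogues; the pair-level hyperinflation
flag compares the 50%-threshold index against lung-volume cutoffs
(default 0.1/0.5/1/2%). An optional interior erosion (default 0)
restricts summaries away from the lung boundary, where large-deformation
artifacts concentrate. Hyper-expanded voxels are additionally classified
by the sign of their air-content change.

## Synthetic phantom

The generator emulates the study inputs at desk scale: a 64³ grid at
2.5 mm spacing (≈160 mm extent — a scaled-down thorax) containing an
ellipsoidal lung (semi-axes 33/36/40% of the extent) of parenchyma at
−860 HU with smooth 40 HU texture (Gaussian field, 2-voxel correlation),
a −1000 HU trachea-like cylinder, +55 HU body and a few bright
vessel-like tubes; i.i.d. Gaussian noise (default 20 HU) is added
independently to each time point. The inter-scan deformation is analytic
and invertible — identity, affine, a random-coefficient B-spline field,
and/or a radial "hyper-expansion" sphere whose core scale is calibrated
(two fixed-point sweeps over the resulting lung masks) to hit a requested
core Δ* exactly, blended to identity over a C¹ monotone-Hermite shell of
width radius/4. Time 1 intensities follow the mass-preserving rule
f₁(x) = f₀(T(x))·det(∂T/∂x) on tissue fractions, with an optional
nodule-like lesion multiplying f₀ (capped at 1) beforehand. Ground truth
(displacement, J, Δ*, Δ_air*, Δ_tissue*) is exact because the deformation
is analytic and the global volumes are the generator's own mask counts.

What the phantom does **not** emulate: airway-tree morphology, scanner
and kernel variability, contrast agent, cardiac/respiratory motion, and —
important for interpretation — the partial-volume boundary of real lungs
is only one voxel thick here, so boundary-driven biases are milder than
in clinical data. Passing the phantom suite demonstrates the pipeline's
internal correctness and its recovery power under the stated noise, not
clinical-grade accuracy.

Two quantitative caveats discovered with the phantom and worth knowing:

- **Tissue lesions bias SSTVD.** Where tissue mass is *not* conserved
  (e.g. a growing nodule: f₁ ≈ m·f₀·det with m > 1), the cost prefers
  det inflated by m, cancelling up to the full expansion signal inside
  the lesion. This is inherent to a mass-preserving metric — the
  conservative behavior is expected for added tissue — so cohort
  phantoms use lesions much smaller than their hyper-expansion regions.
- **Boundary blending breaks global mass bookkeeping for non-local
  warps.** A whole-lung affine shrink maps every reference boundary voxel
  near the floating boundary, where interpolation blends +55 HU body into
  the lung; tissue-mass totals then differ by far more than the interior
  effect. Mass-conservation checks therefore use deformations that are
  identity near the lung boundary.

## Group statistics

Welch's unequal-variance two-sample t test with Welch–Satterthwaite
degrees of freedom and two-sided p values (sidedness is a package choice;
two-sided is the conservative default). Each scan pair is one record;
pairs from the same subject are treated as independent by default, with a
per-subject averaging option for sensitivity analysis. No
multiple-testing correction is applied; raw p values are reported.
Groups with fewer than two records are excluded with a warning.

## Problem sizes and validation configuration

The test suite validates identity recovery and parameter recovery on 64³
phantoms and the synthetic cohort (7 control + 10 case pairs) at 48³,
sizes at which the full suite runs in a few minutes on one core. The
end-to-end validation runs use control spacing 5 mm, `max_iter` 300,
`rel_tol` 1e-8, `patience` 10 and `smoothing_sigma` 0.9 — slightly
stronger smoothing and a longer budget than the library defaults, chosen
on the bias–variance tradeoff visible in the phantom: finer lattices and
less smoothing overfit noise, coarser ones under-resolve the expansion
shell. Recovered Δ50%* indices land within ~2 lung-percent of the oracle
and voxel-wise Δ* correlates with ground truth at r ≈ 0.91 in the lung
interior; the residual underestimate is the smoothing of the synthetic
region's sharp edge.

## Known limitations

- No explicit regularizer or landmark-based accuracy evaluation;
  invertibility is encouraged, not guaranteed (the negative-Jacobian
  fraction is the honesty metric).
- Registration accuracy at the lung boundary is intrinsically weaker; the
  optional interior erosion exists for that reason.
- Contrast-enhanced scans violate the two-component density model; the
  vessel-exclusion option mitigates but does not remove the effect.
- DICOM ingestion and anatomical segmentation are out of scope; inputs
  are NIfTI/MetaImage volumes with precomputed masks.
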