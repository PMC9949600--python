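# Methods

This note documents the models, parameters, and numerical choices
behind `trabecula`, including the calibration of the synthetic
generators and the reasoning behind the statistical test designs.

## 1. Volumes, VOI, and ROI

Volumes are boolean voxel grids with an isotropic physical voxel size;
axis 2 is cranio-caudal, so `mask[:, :, k]` is a transverse slice.
Binarization treats intensity ≥ t as bone (threshold inclusive); Otsu's
method is offered with the returned threshold shifted by one so the
inclusive convention holds.

The analysis VOI follows the centrum-waist protocol:

1. **Waist slice** — the transverse slice minimizing the centrum's
   dorso-ventral extent, then medio-lateral extent; exact ties go to
   the slice nearest the axial midpoint.
2. **Footprint** — the largest axis-aligned square inscribed in the
   waist slice's *trabecular compartment*. The compartment is
   operationalized as every centrum pixel at least as deep (Euclidean
   distance from the centrum boundary) as the shallowest pore in that
   slice: pores can only occur inward of the cortical shell, so this
   reproduces "inside the cortex" without a shell-thickness parameter,
   and it correctly includes trabecular bone. The square is found by
   dynamic programming; among maximal squares, the one whose center is
   nearest the compartment centroid wins, then the smallest
   (row, column).
3. **Axial extension** — the prism grows cranially and caudally for as
   long as every added slice's compartment still contains the
   footprint.
4. **Sphere ROI** — the largest centered inscribed sphere,
   radius = min(footprint side, prism depth) / 2.

## 2. The metric battery

* **BV.TV** — bone voxels / voxels with centers inside the sphere.
  `roi=None` switches to the whole volume; this matters for periodic
  phantoms (section 5).
* **MIL / fabric / DA** — for each direction in a Fibonacci-spiral
  hemisphere set (default 2049 directions, fixed random rotation), a
  parallel grid of test lines (spacing 2 voxels, sampling step 0.5
  voxels) is cast through the sphere. MIL(w) is the mean *complete*
  bone chord length; chords touching the ROI boundary are omitted, and
  directions with no complete chord are dropped with a warning. A
  symmetric second-order tensor is least-squares fit to 1/MIL², and
  the MIL ellipsoid semi-axes are 1/√eigenvalues, sorted descending;
  DA = longest/shortest ≥ 1. Eigenvalues are floored at 1e-8 × the
  largest: a perfect plate stack is a rank-deficient fabric whose
  smallest eigenvalue is numerically ≤ 0, and the relative floor keeps
  DA large-but-finite instead of 1/√ε.
* **SLD** — star length distribution: from seeded random bone points
  (default 2000), intercepts are marched in both senses of each
  direction until leaving bone, capped at the ROI diameter; directional
  means feed the same ellipsoid fit.
* **Tb.Th** — headline value is the local-thickness mean (for each
  bone voxel, the diameter of the largest inscribed sphere containing
  it), computed from the Euclidean distance transform with descending
  half-voxel radius bins. The plate-model value 2·BV/BS (surface
  density from stereological interface crossings, BS/TV = 2·P_L) is
  reported alongside.
* **Tb.N** — direction-averaged complete chords per mm of test line;
  plate-model value (BV/TV)/Tb.Th reported alongside.
* **Connectivity / Conn.D** — Euler characteristic of the cubical
  complex (χ = V − E + F − C) after purification (largest 26-connected
  bone component kept, largest 6-connected background component kept);
  connectivity = 1 − χ, Conn.D = connectivity / ROI volume. Negative
  values are clamped to zero and flagged.
* **QC** — a vertebra passes when connectivity ≥ 40 AND relative
  resolution (Tb.Th / voxel size) ≥ 2.5; both boundaries are inclusive
  and flagged when hit exactly.

## 3. Whole-vertebra morphometry

GC and CSA are restricted to slices satisfying the closed-foramen rule:
the slice background must contain a 4-connected component that does not
touch the image border. Per qualifying slice, bone area is the voxel
count × voxel area and total area is the 2D hole-filled bone area (not
a convex hull). CSA is the mean bone area; GC is the mean of the
per-slice bone/total ratios (mean of ratios, not ratio of means).

## 4. Statistics

* **fit_loglog** — OLS of log10(y) on log10(x); t-based CI and p-value
  with n − 2 df. Strictly positive inputs enforced, offending rows
  named.
* **Allometry call** — "0" iff the isometric exponent lies in the CI;
  otherwise "+"/"−" by the slope's side. The classifier accepts raw
  (slope, ci_low, ci_high) triples so printed table values can be
  re-called verbatim.
* **SMA common slope** — Warton-style likelihood-ratio test: the
  residual axis (y − bx) and fitted axis (y + bx) are uncorrelated
  exactly at a group's own SMA slope; the common slope minimizes
  −Σ nᵢ ln(1 − r²ᵢ(b)) and the minimized statistic is χ² with
  (groups − 1) df.
* **PGLS** — closed-form GLS with Brownian covariance
  C[i, j] = depth of the most recent common ancestor of tips i and j;
  reduces exactly to OLS at C = I. R² is taken about the GLS-weighted
  mean.
* **Blomberg's K** — observed MSE0/MSE about the phylogenetically
  corrected mean, divided by its Brownian expectation
  (tr C − n/(1ᵀC⁻¹1))/(n − 1); significance by tip permutation with
  the (r + 1)/(n + 1) correction. Scale- and shift-invariant.
* **FDA / pFDA** — linear discriminant analysis via optimal scoring
  (verified against scikit-learn's LDA predictions), with a Gaussian
  rule and frequency priors on the discriminant variates. pFDA whitens
  predictors and class indicators by C(λ)^(−1/2), where C(λ) scales
  off-diagonal covariances by Pagel's λ (profile-ML estimate, grid +
  bounded refinement on [0, 1]). At λ = 0 on an ultrametric tree the
  whitening is a scalar, so pFDA reproduces FDA exactly — a structural
  reduction, not a tolerance.

## 5. Synthetic generators

**Rod lattices** — orthogonal cylinders (radius 0.05 mm, spacing
0.5 mm by default) between grid nodes. Ground truth: Tb.Th = strut
diameter; Tb.N = mean 1/spacing; connectivity = cycle rank of the
node-edge graph (E − V + 1, e.g. 5/28/81 for 2³/3³/4³ nodes); BV.TV
from a voxel-counting oracle at half the requested pitch. Note that
rasterized BV.TV carries a voxelization bias of order (voxel/radius)²
— at 20 µm voxels on 50 µm struts it is ≈ 18% — so quantitative BV.TV
claims require pitch ≤ radius/5.

**Plate stacks** — parallel plates of thickness t and gap g
(BV.TV = t/(t + g), Tb.Th = t, plate-model Tb.N = 1/(t + g)). One
plate is centered at mid-extent so centered ROIs sample symmetrically.
A sphere ROI over a periodic structure still has an intrinsic
phase/radius sampling bias of ±5–6% in BV.TV (a 0.7 mm sphere spans
only 1.4 periods of the default 0.5 mm stack — computed analytically,
not tuned); the whole-volume ROI (`roi=None`) over an extent that is an
exact multiple of the period is exact by construction and is what the
phantom recovery test uses. MIL/DA always uses the sphere.

**Synthetic vertebra** — a cortical tube whose outer radius narrows
quadratically to 70% at mid-length (the waist), filled with lattice
trabeculae, plus a concentric arch ring enclosing an annular foramen;
an optional 25° sector cut opens the foramen so slices fail the
closed-foramen rule.

**Clade simulator** — ten species on a fixture tree
((Cingulata,(Folivora,Vermillingua)), ultrametric, root depth 68;
an invented stand-in, not a published calibrated tree), 23 specimens,
six vertebral positions. Per row:

```
log10 IZL    = (1/3) log10(mass) + N(0, 0.04)
log10 metric = intercept + exponent · log10(IZL) + ecology offset
               + Brownian species deviation + iid specimen noise
```

Generating exponents are 0.33 (BV.TV), −0.28 (Tb.N), 0.66 (Tb.Th),
0.14 (GC), 1.84 (CSA), 0.04 (DA), −1.35 (Conn.D); intercepts put
metric magnitudes on realistic scales at IZL = 10 mm. Ecology is a
deterministic function of clade, so ecology and phylogeny are perfectly
confounded by construction — the property that motivates the
phylogenetic variants. Ecology offsets default to **zero**; a demo
preset (`ECOLOGY_EFFECTS_DEMO`) adds separable intercept shifts for
discriminant demonstrations.

**Noise calibration.** Species masses span 85.5 g – 40.6 kg, giving
var(log10 IZL) ≈ 0.086 on the default design. Total residual SDs per
metric (0.160, 0.084, 0.097, 0.051, 0.180, 0.041, 0.260 in the order
above) were derived *a priori* from R² = β²·var(log10 IZL) /
(β²·var(log10 IZL) + σ²), targeting realistic whole-dataset R² values
— they were fixed before any test was run and are not tuned to test
outcomes. `brownian_share` (default 0.5) splits σ² between a
species-level Brownian deviation on the fixture tree and iid specimen
noise.

## 6. Design of the coverage check

The slope-recovery suite checks that the 95% CI from the pooled
log-log OLS covers the generating exponent in ≥ 90% of 100 seeds per
metric. This is run with `brownian_share = 0`: with species-level
Brownian deviations on, pooled-OLS standard errors are provably
anticonservative (errors are clustered by species — effective n is
closer to 10 species than 138 rows), so nominal coverage is *expected*
to fail, and that failure is a property of OLS under phylogenetic
structure, not of this implementation. The phylogenetic side is
validated separately: PGLS reduces exactly to OLS at C = I, its slope
algebra is verified against hand GLS on a three-taxon tree, and
Blomberg's K is calibrated (mean K ≈ 1 over Brownian simulations;
permutation p uniform under the exchangeable-tips null).

## 7. Numerical and reproducibility choices

* All randomness flows from `numpy.random.default_rng` seeds; the
  pipeline derives per-stage seeds from one master seed via a stable
  string hash (< 2³¹), records them in `manifest.json`, and reruns are
  byte-identical.
* Direction sets default to 2049 directions for production use;
  pipeline and tests use 64–256, which is sufficient for the DA
  contrasts exercised (isotropy ≤ 1.15 vs plates > 3).
* Local thickness uses half-voxel radius bins; accuracy is ± 1 voxel,
  matching the tolerance quoted for phantom recovery.
* The MIL line grid uses 2-voxel line spacing and 0.5-voxel sampling
  steps: denser sampling changes plate-phantom MIL by < 1% but scales
  runtime linearly.

## 8. Limitations

* The generators produce idealized geometry (cylinders, plates,
  quadratic waists); they validate the measurement chain, not
  biological realism.
* Rasterized BV.TV at coarse pitch is biased (section 5); tests that
  quantify BV.TV use fine pitch or exact-period whole-volume ROIs.
* The fixture tree and its divergence depths are invented; all
  phylogenetic results on simulated data are demonstrations of the
  machinery, not biological estimates.
* pFDA's λ is estimated from the predictor block only (profile ML),
  and accuracies are resubstitution rates unless leave-one-out is
  requested; with 10 species they are optimistic.
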