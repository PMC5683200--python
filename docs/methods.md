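# Methods

## The radial structure tensor and its intensity-targeted variant

At a voxel `x` of an isotropic volume `I`, the radial structure tensor
(RST) is

    T(x) = Σ_i Σ_j  α_ij · r_i g_ij^T

where `r_i` are unit search directions, `x_ij` is the j-th step along
ray `i`, `g_ij` is the intensity gradient at `x_ij` (central
differences over the six neighbours, H.U./mm), and the opacity

    α_ij = 0                      if |ΔI| <  t_min
         = |ΔI| / |t_max − t_min| if t_min ≤ |ΔI| < t_max   (clamped at 1)
         = 1                      otherwise,   ΔI = I(x) − I(x_ij).

A ray terminates when its accumulated opacity reaches 1 (within
`beta_tolerance`) or its arc length reaches `t_len`.  The eigenvalues
λ0, λ1, λ2 of the symmetrised `T + T^T`, ordered by decreasing
magnitude, describe the surrounding gradient structure: all three
negative and of comparable magnitude means the voxel sits inside a
bright blob, and the blob response is

    f_blob = |λ2|² / |λ0|   if λ0, λ1, λ2 < 0, else 0.

The intensity-targeted RST (ITRST) weights every term additionally by
an indicator γ_ij that is 1 only when **all six neighbours** of `x_ij`
lie inside a target range `[t_dark, t_bright]` (inclusive).  Gradients
formed next to contrast-enhanced vessels (≈150–300 H.U.) or air
(≈−1000 H.U.) are thereby discarded, so a soft-tissue blob touching
such a structure keeps the bright-blob eigenvalue signature instead of
having one eigenvalue swamped by the huge boundary gradient.  With an
unbounded target range γ ≡ 1 and the ITRST reduces exactly to the RST
(this identity is a test).

As a comparison baseline the package also provides a single-scale
Hessian blob filter: Gaussian second derivatives at scale σ (mm),
eigenvalues scored with the same `f_blob`, response multiplied by σ²
for derivative normalisation.  Pure second derivatives are computed as
two first-derivative passes at σ/√2 because a single truncated
order-2 Gaussian kernel does not sum exactly to zero and would leak a
DC term proportional to the local mean.

### Discretisation choices

The printed sources of this construction leave several details open;
the package fixes them as follows.

- **Directions** — vertices of a subdivided icosahedron (antipodally
  symmetric, near-uniform); default `n_directions = 42`.  `n = 6`
  gives the axis-aligned set; non-icosahedral counts fall back to a
  spherical Fibonacci lattice.
- **Steps** — one voxel per step (`step = w_reso` after resampling),
  positions snapped to the nearest voxel so the six-neighbourhood used
  by γ and by the central-difference gradient is always well defined.
  Steps run to `floor(t_len / step)`.
- **Boundaries** — a ray leaving the grid terminates silently; a
  gradient whose stencil leaves the grid contributes nothing; γ is 0 on
  the grid boundary.
- **Opacity middle branch** — the form `|ΔI| / |t_max − t_min|` is
  implemented as printed and clamped at 1 (it would otherwise exceed 1
  just below `t_max`); a continuous variant
  `(|ΔI| − t_min)/(t_max − t_min)` is available via
  `opacity_form="continuous"`.
- **ITRST ray termination** — the accumulated opacity is Σ_j α·γ (the
  same product weighting as the tensor terms).  The alternative
  reading `max(Σ_j α, γ_ij)` is selectable via `beta_mode="literal"`
  for comparison, but taken literally it terminates a ray the moment a
  single in-range sample is seen and is not recommended.
- **Eigenvalue ties** — equal magnitudes order the more negative value
  first (deterministic).
- **t_min / t_max** — no canonical values exist; defaults 10 / 110
  H.U. span the noise floor to soft-tissue/vessel contrast and should
  be tuned per application.
- **Rotation equivariance** — the response commutes exactly with
  axis-aligned 90° rotations only when the direction set is closed
  under the rotation; that holds for `n = 6` (and for the Hessian
  filter), not for the icosahedral sets, whose symmetry group has no
  4-fold axis.  The property test uses `n = 6`.

## Detection pipeline

1. **Preprocess** — order-3 interpolating B-spline resampling to
   isotropic `w_reso` (default 0.625 mm, a typical axial CT pixel),
   then Gaussian smoothing `σ_smooth` (default 1 mm) for gradient
   stability.  Replicate-edge boundaries avoid dark halos in H.U.
   images.
2. **Search region** — air = voxels below `t_air` (default −200 H.U.)
   minus components touching the volume boundary (the air around the
   body); lungs = the largest air component, plus the second largest
   if it is at least 20% of the first (one-component lungs occur when
   both connect through the trachea).  The mediastinum is filled in
   between the lungs by a literal line scan along the right-to-left
   (x) axis: on every (y, z) line with at least two lung runs, a voxel
   x is marked when at least one (but not every) lung-to-background
   transition lies strictly before x and voxel x+1 is background, the
   mark test being evaluated before the transition counter updates.
   Applied literally this leaves the last voxel of each inter-lung gap
   unmarked and marks the final voxel of each lung run after the
   first; an opt-in `fill_complete_gap` mode closes whole gaps
   instead.  The blob filter is evaluated only within the mediastinum
   dilated by `mask_dilation` (default 4 mm) — everything farther away
   cannot produce a surviving candidate, which must touch the
   mediastinum.
3. **Candidates** — a `w_hole`³ median filter (default 3) closes
   isolated zero responses inside blobs; thresholding at
   `t_blob` (default 20; 2000 for the Hessian filter whose response
   scale differs), 26-connected labelling, then removal of components
   smaller than a sphere of radius `t_small` (default 2 mm, below the
   smallest clinically annotated node class) and of components not
   sharing a voxel with the mediastinum.
4. **False-positive reduction** — per candidate a 9 + 7·|D| feature
   vector (30 for the default D = {0, 1, 2} mm): volume, voxel-face
   surface area, sphericity π^⅓(6V)^⅔/A, maximum interior Euclidean
   distance, long/short axis lengths (full extents of voxel centres
   along the first and third principal components), x and z centroid
   coordinates, y normalised within the lung bounding box; and mean,
   variance, median, max, min, skewness and kurtosis of the intensity
   over the candidate region dilated by a d-mm ball for each d ∈ D
   (zero-variance samples define skewness = kurtosis = 0).  An RBF
   support-vector classifier (C = 1, kernel width 1/n_features, the
   libsvm defaults) is trained on standardised features with the
   negative class weighted by `w_F`; training positives are candidates
   whose centre voxel (region voxel nearest the centroid, robust to
   non-convex regions) lies inside a ground-truth node of short axis
   ≥ `r_target · w_train`.
5. **Evaluation** — free-response operating points: a target node
   (short axis ≥ `r_target`) overlapped by ≥ 1 voxel of any detected
   region is a true positive; a region overlapping no node at all (not
   even a sub-target one) and no lung-cancer label is a false
   positive.  Rates average over volumes (volumes without targets are
   excluded from the rate but keep contributing false positives);
   leave-one-out cross validation sweeps `w_F` into an FROC curve.

## Synthetic data

**Validation phantom.**  Seven 15-mm spheres of 50 H.U. on a 0 H.U.
background in one axial plane, Gaussian-smoothed at σ = 1 mm; then
three 300 H.U. and three −1000 H.U. square poles (15 mm thick, 50 mm
long) drawn afterwards so their edges stay sharp, each contacting one
sphere with 0 / 2 / 4 mm of face intrusion to vary the overlap
severity.  Grid 176×304×56 at 0.625 mm (the published blueprint prints
no grid or coordinates; the layout here keeps sphere centres ≥ 30 mm
apart and sphere centres on voxel centres so the label-mask diameter
is exactly 15 mm).  The phantom is fully deterministic.

**Chest phantom.**  A seeded generator standing in for clinical data:
a soft-tissue body cylinder (−20 H.U.) in −1000 H.U. air, two −900
H.U. lung ellipsoids, two 250 H.U. vessel tubes through the inter-lung
gap, 8 ellipsoidal nodes of 6–12 mm short axis at 50–70 H.U. (one
forced against a vessel and one against a lung — the hard cases the
intensity-targeted filter exists for), 20 brighter 5–7 mm decoy
spheres at 78–92 H.U. that deliberately pass the blob filter and act
as false-positive generators, and additive Gaussian noise (σ = 8
H.U.).  Nodes and decoys are placed by seeded rejection sampling with
bounded retries.  What this phantom does **not** model: ribs and
bones, airway trees, beam hardening, CT noise texture, lesion
heterogeneity, or anatomical shape variability — passing tests on it
demonstrates the pipeline's mechanics (geometry handling, eigenvalue
behaviour next to bright/dark structures, classifier plumbing), not
clinical performance.

**Operating points used in the phantom experiments.**  `r_target` =
8 mm (the phantom's node sizes straddle it) and an SVM negative-class
weight `w_F = 0.5`.  The library default `w_F = 0.075` reflects a
candidate balance of hundreds of false positives per true node, where
down-weighting negatives hard is necessary to preserve sensitivity;
the phantom produces ~2 negatives per positive, and at 0.075 the
negative class would be effectively free, so the operating point is
chosen from the same sweep range to fit that balance.  Detection on
the three seeded phantoms runs at 100% with ≈15 decoy false positives
per volume before, and ≤ ~0.3 after, classification — the numbers the
acceptance script recomputes.

## Problem sizes and runtime

The phantom experiments are sized for a single CPU: three 96×96×64
chest volumes at (0.8, 0.8, 1.0) mm (≈1.5 M voxels after resampling),
tensor evaluation restricted to the dilated mediastinum (~10% of the
grid), 42 directions × ≤24 steps per voxel.  One volume takes ~45 s
through the full pipeline; the complete acceptance run is a few
minutes.

## Known limitations

- Responses scale linearly with `n_directions`; thresholds such as
  `t_blob` are calibrated for the 42-direction default.
- Ray positions are voxel-snapped rather than interpolated; at very
  small `t_len`/`w_reso` ratios adjacent rays can sample the same
  voxels.
- The mediastinum line scan inherits the quirks of its literal
  pseudocode (see stage 2); both are deliberate.
- The single-scale Hessian baseline is not a multi-scale vesselness
  pipeline and is only meant as the comparison point for the radial
  filters.
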