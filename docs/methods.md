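# Methods

## Problem and scope

Whole-brain irradiation (WBI) is delivered with two parallel-opposed
lateral photon fields.  Because the head is laterally thinner at its
anterior and posterior extremes, those regions receive more than the
prescribed dose — hotspots in the frontal and occipital lobes.  The
field-in-field (FIF) technique removes them by adding low-weight
*sub-beams*: copies of the main beams whose multileaf collimator (MLC)
shadows the hotspot regions, with weight shifted from main to sub so
the shadowed regions cool down while everything else is untouched.

`fifplan` implements the semiautomatic two-step version of this
technique end to end: 3D hotspot identification, beam's-eye-view (BEV)
projection, per-leaf-row MLC fitting, closed-form weight assignment,
and the escalation from two to four sub-beams when target coverage
suffers.  Because clinical planning systems and patient data are not
part of the package, it also ships a synthetic head phantom and a
simplified dose engine that reproduce the relevant phenomenology.

## Coordinate frames and projection

Three right-handed frames are chained (all millimetres):

1. **DCS** — DICOM patient frame, LPS axes, head-first supine.
2. **ICS** — DCS translated so the beam isocenter is the origin.
3. **BCS** — gantry/collimator-fixed frame.  At gantry = collimator
   = 0: X′ cross-plane, Y′ vertical pointing from the isocenter toward
   the source, Z′ in-plane (patient longitudinal).  The gantry rotates
   about Z′ and the collimator about Y′, with IEC 61217 senses
   (gantry 90° = beam entering from the patient's left).

The defining contract is that the source sits at (0, SAD, 0) in the
BCS for *every* pair of angles (SAD = 1000 mm).  Points are mapped to
the BEV plane Y′ = 0 by central projection:
`X_BEV = X'·SAD/(SAD − Y')`, likewise for Z_BEV.  The rotation is
validated in the tests against an independently composed product of
explicit 3×3 matrices (1e−9 mm on 10⁴ random points), and the full
DCS→BCS chain is checked to be rigid.

## Synthetic phantom

`make_head_phantom` builds an ellipsoid of water-equivalent density
(1.0) in air with semi-axes (a, b, c) = (70, 95, 80) mm
(lateral/AP/SI) on an isotropic 2.5-mm grid — head-sized, and with the
lateral chord `2a·sqrt(1 − (y/b)² − (z/c)²)` shrinking toward the
AP/SI extremes, which is all the hotspot mechanism needs.  The PTV is
the body eroded by 5 mm (Euclidean distance transform), standing in
for a brain contour and keeping surface/buildup voxels out of the
target.  An optional seeded smooth surface perturbation (amplitude in
mm) roughens the outline for test diversity; generation is
deterministic given parameters and seed.

`make_original_plan` places the isocenter at the PTV centroid (snapped
to a voxel centre so normalization is exact), opposes two 10-MV beams
at gantry 90°/270° with collimator 0°, and gives each a rectangular
jaw/MLC aperture enclosing the projected PTV corners plus a 7-mm
margin — a typical clinical block margin.  The default MLC bank is 14
central 2.5-mm leaf pairs flanked by 16 5-mm pairs per side.
Prescription: 30 Gy in 15 fractions, 100% at the isocenter.

## Dose engine

Per beam and voxel `v` inside the body:

    d(v) = w · A(v) · (SAD/r(v))² · exp(−μ_eff · ℓ(v))

with `r` the source–voxel distance, `ℓ` the radiological depth along
the source ray, and `A` = 1 for rays open in the aperture, else the
MLC/jaw transmission fraction (default 0.015).  Plan dose is the sum
over beams, rescaled to 100% at the isocenter voxel after every
computation, so all thresholds stay in % of prescription.

Numerical choices:

* **Ray integration.**  One ray per voxel centre; the density is
  treated as trilinear samples and integrated with a 256-point
  midpoint rule between the grid-bounding-box entry and the voxel.
  The body surface is therefore a one-voxel linear ramp; there is no
  anti-aliasing at aperture edges (one open/closed decision per voxel
  centre), which is the dominant discretization error there.
  Ray traces are cached per beam geometry, so duplicated sub-beams
  cost only an aperture re-evaluation, and engine `variant()`s with
  different μ/transmission share the cache.
* **Linearity and determinism.**  Dose is exactly linear in beam
  weights before renormalization (the property the closed-form weight
  algebra relies on) and bit-reproducible for identical inputs.
* **μ_eff (default 0.0015 mm⁻¹).**  This is an *effective broad-beam*
  falloff, not the narrow-beam 10-MV attenuation coefficient
  (≈ 0.0035 mm⁻¹): the engine has no scatter model, and a primary-only
  narrow-beam coefficient would exaggerate the thickness→dose gradient
  far beyond what convolution/superposition algorithms compute in
  broad opposed fields.  With 0.0015 mm⁻¹ the default phantom's
  original plan reaches a PTV maximum of ≈ 106–107% of prescription
  with a hotspot of a few percent of the PTV at the AP poles — the
  regime clinical WBI plans show and the regime the two-sub-beam
  branch of the algorithm is designed for.

The engine deliberately omits scatter kernels, electron buildup,
penumbra and MU calculation.  Consequently surface dose is
inverse-square boosted rather than buildup-suppressed, which is one
reason hotspot search and D_max are evaluated over the PTV (see
below); absolute DVH shapes are schematic even though the algorithmic
behaviour (what gets blocked, how weights move) is faithful.

## Hotspot identification and BEV rasterization

A hotspot voxel has dose strictly greater than the threshold `D_th`
(default 105% of prescription; "driven exactly to threshold" therefore
counts as removed).  The search is restricted to the PTV: the reported
dose indices are PTV indices, and the no-buildup engine would
otherwise flag the synthetic body shell that a planning system
suppresses.

For each main beam the 3D hotspot mask is projected into a 1-mm binary
raster in the isocenter plane (extent: jaw rectangle + 10 mm).  For
every hotspot voxel the eight corners are projected and every pixel
overlapped by their bounding rectangle is marked.  The bounding box
contains the convex hull of the projected corners, so the marked
region — and hence the later MLC block — fully shadows the 3D region;
for the lateral-beam, collimator-0 geometry used here the hull is a
near-axis-aligned rectangle, so the over-coverage is below one pixel.
No additional margin is added around the projection.

## MLC fitting

Leaves move independently per pair, driven by the hotspot pixels whose
Z_BEV extent overlaps that pair's band:

* hotspot entirely on one side of the field's vertical centre line
  (X_BEV = 0): that side's leaf advances exactly to the hotspot edge
  nearest the centre line (no over-blocking beyond the rule);
* hotspot crossing the centre line: the distances from the centre
  line to the outer hotspot edges (d₁ left, d₂ right) are compared and
  the leaf with the larger distance sweeps across the centre line to
  cover the row's full hotspot extent; ties go to the left leaf;
* two disjoint intervals on opposite sides: each leaf covers its own
  interval, keeping the centre open.

Tips are quantized *outward* to 0.1 mm (typical machine resolution)
and never retract behind the duplicated main-beam field; jaws are
never moved.  The centre line is X_BEV = 0 of the collimator frame;
for an asymmetric field one could argue for the geometric field
centre instead, but all fields produced here are symmetric.  Fitting
is idempotent, and an exhaustive pixel check in the tests verifies
that no hotspot pixel remains open (200 random rasters).

## Weight assignment and the two-step scheme

Let `D_max` be the original plan's PTV maximum and `D_th` the
threshold, both in % of prescription, with `D_max > D_th`.  Step 1
sets, per main beam `i`:

    f            = (D_max − D_th) / D_max
    w_main,i^FIF = w_main,i · (1 − f) = w_main,i · D_th / D_max
    w_sub,i^FIF  = w_main,i − w_main,i^FIF

Because the engine is linear and the sub-beam aperture equals the main
aperture outside the block, unblocked voxels receive exactly their
original dose while blocked voxels are reduced by the factor `(1 − f)`
(plus a transmission term ≤ T·f·D_max ≈ 0.2 pp), pulling the former
maximum to `D_th`.  With `D_max = 107.3` and `D_th = 105` the split is
0.979/0.021.  If `D_max ≤ D_th` the planner exits with "no FIF
needed" rather than erroring.

The Step-1 plan is accepted unless it reduces the PTV's D95 by more
than a criterion (default 1.0 percentage point, strict comparison).
Otherwise Step 2 rebuilds from the original plan with four sub-beams:

1. a first sub-beam pair blocks the region above the intermediate
   threshold `D_ith = (D_max + D_th)/2`, weighted by the Step-1
   formulae with `D_th` replaced by `D_ith`;
2. the intermediate plan's PTV maximum `w_ithmax` is evaluated on the
   renormalized intermediate dose; if it does not exceed `D_th` the
   second pair is skipped with a notice;
3. a second pair blocks whatever still exceeds `D_th` in the
   intermediate dose, and the main weights are reduced once more:
   `w_main,i^FIF2nd = w_main,i^FIF · D_th / w_ithmax`, with the second
   sub-beam taking the difference.

Splitting the transfer over two shallower blocks means voxels hot only
in the low band lose less dose than under a single deep block, which
is what recovers D95.  The Step-2 weight formula is reconstructed from
the stated invariance contract; a unit test checks its consistency
with the reported FIF-4SF split 0.973/0.013/0.014 under
`D_max ≈ 107.8`, `w_ithmax ≈ 106.5` (tolerance, not ground truth).

## DVH metrics

Voxel-exact (sort-based, no binning): `D_V` is the largest dose `d`
such that at least the fraction `V` of structure voxels receives
`≥ d`; `V_D` is the percentage of voxels with dose `≥ D`;
`HI = (D2% − D98%)/D50%` in percent.  All indices are reported for the
PTV.  The `D_V` tie convention matters only at exact coverage
boundaries and is pinned by enumeration tests.

## Study conditions exercised by the tests

* **Default conditions** (phantom defaults, μ_eff = 0.0015 mm⁻¹):
  original V105 ≈ 4% of the PTV, D_max ≈ 106%; the planner selects the
  two-sub-beam scheme, V105 drops to ≈ 0.02%, and D95/V95 change by
  ≈ 0 pp.  Full-grid runs (≈ 3.4·10⁵ voxels, 2.5 mm) complete in well
  under a minute on one CPU.
* **Severe conditions** (same phantom, μ_eff = 0.0022 mm⁻¹): a deep
  hotspot (D_max ≈ 110%, V105 ≈ 28%) makes Step 1 cost ≈ 2.8 pp of
  D95, tripping the criterion; the four-sub-beam plan recovers to
  ≈ 0.7 pp while still removing the hotspot.
* **Beyond-design conditions**: at the narrow-beam μ_eff = 0.0035 mm⁻¹
  the hotspot covers the entire PTV rim including the lateral shell;
  every leaf row then sweeps across the centre line, the isocenter ray
  itself is blocked, and isocenter renormalization cancels the uniform
  reduction — the plan returns essentially unchanged.  This is the
  correct behaviour of the stated algorithm outside its design regime
  (the method presumes peripheral hotspots that spare the isocenter),
  not a failure mode the package hides.

What passing these tests shows is that the *algorithm* behaves as
specified under controlled conditions.  It does not show clinical
dosimetric accuracy: the phantom has no anatomy or heterogeneity, and
the engine has no scatter, buildup or penumbra.

## Known limitations

* No minimum-MU handling; very small sub-beam weights are reported
  as-is.
* No interdigitation/leaf-gap constraints, tongue-and-groove, or
  rounded leaf-end projection in the MLC model.
* Hotspot/D_max evaluation and all indices are PTV-only by design.
* `D_V` interpolation conventions differ between planning systems;
  values here are voxel-exact lower quantiles.
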