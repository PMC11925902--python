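# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices a user should know before trusting or extending the
results.

## The problem being modelled

Carotid plaques are graded vulnerable (rupture-prone: large lipid/necrotic
core, thin fibrous cap, inflammation, low stiffness) or stable
(calcific-dominant, stiff). The pipeline asks whether three preoperative,
non-invasive measurement families separate the two classes: ultrasound
stiffness metrics (echo-tracking indices and point shear-wave
elastography), CTA-derived plaque composition volumes, and stress indexes
from patient-specific finite-element (FE) simulation of the reconstructed
atherosclerotic wall. Since no patient data are shipped, a synthetic
cohort generator supplies every input with the class structure the
analysis assumes; the pipeline's claims are then verified as *direction*
properties (which group has the higher median, which comparisons are
significant, which are null) rather than as reproductions of specific
patient numbers.

## Synthetic cohort

A patient is a triple (clinical record, vessel geometry, histology raw
measurements). Class-conditional parameters follow the published group
medians where the study states them:

* plaque Young's modulus: lognormal with medians 12.40 kPa (vulnerable)
  and 34.70 kPa (stable), sigma = 0.8 on the log scale (the published IQRs
  are wide); stored on the record as a shear-wave speed via
  c = sqrt(E / 3 rho), rho = 1000 kg/m^3, so the elastography stage must
  invert it.
* requested plaque composition: logit-normal around medians 10.5% / 26%
  calcific and 6% / 1% lipid (vulnerable / stable), sigma = 0.7 in logit
  space, rescaled if calcific+lipid would exceed 85% of the plaque.
* stenosis severity: uniform on [0.55, 0.80] (radius-reduction fraction)
  in *both* classes, so total plaque volume is class-independent by
  construction and its group comparison must come out null.
* distension and diameter medians, female fraction, risk-factor rates and
  the histology severity distributions likewise follow the published
  group tables in direction.
* brachial pressures: 135/78 mmHg with 15/10 mmHg spreads (converted at
  1 mmHg = 0.133322 kPa). The study does not report its pressure
  distributions; these are a modelling choice of this package.

The vessel is a straight common-carotid-like tube (radius 4 mm) with a
raised-cosine stenosis at mid-vessel and modest outward remodelling
(1.5 mm x degree of stenosis at the throat). Calcific voxels are placed
as an eccentric blob abutting the outer plaque boundary and lipid as a
core near the lumen, each at a random angular position per seed; voxel
counts match the requested volume fractions to rounding. An optional
planar Y-bifurcation (branch radii 3.0/2.5 mm) exists for boundary-
condition realism but is off by default. Pre-reconstruction volumes
contain only what CTA segmentation can see: lumen, calcific, lipid.

What is *not* emulated: scanner physics (no Hounsfield units or image
noise), anatomical variability beyond the stenosis parameters, intraplaque
haemorrhage/ulceration, and any correlation structure between histology,
stiffness and composition beyond their shared class label. Passing tests
therefore demonstrate that the pipeline recovers the directions it was
configured to contain — a wiring and correctness check, not clinical
evidence.

### Waveforms

Diameter traces use a raised-cosine systolic upstroke (systole 30% of a
0.9 s cycle) sampled at 100 Hz, which places both extremes exactly on the
sampling grid: each noiseless cycle's max-min equals the configured
distension to machine precision. Distension measurement takes per-cycle
extremes averaged over the first six beats, as an echo-tracking report
does. With additive iid sample noise this estimator is biased *upward* by
extreme-value statistics (about 2 sigma sqrt(2 ln n_samples) in the worst
case, ~26 um at sigma = 10 um); the tests assert that envelope rather
than unbiasedness. No smoothing is applied because the noiseless case is
specified to be exact.

## Wall reconstruction

Per axial station (one per voxel slice, using the smoothed per-slice
lumen centroid as the centre), the outer wall radius is

    R = max( max(r_lumen, r_reference) + t_wall,  extent + margin )

where `r_lumen` is the station's equivalent lumen radius, `r_reference`
the proximal (healthy) lumen radius, `extent` the furthest calcific/lipid
voxel distance and `t_wall` = 1.0 mm, `margin` = 0.3 mm by default. R is
smoothed along the vessel with a 5-station moving average, floored again
by the two constraints so smoothing can neither cut into a component nor
thin the healthy rim. Using the *reference* radius as a floor keeps the
outer wall continuous across the stenosis — the plaque fills the space
between the narrowed lumen and the wall, rather than the wall pinching
inward — which also keeps reconstructed total plaque volume independent
of plaque composition. Stations are stenotic when their lumen area falls
below 90% of the reference or any component is present; stenotic wall
voxels that are not calcific/lipid become fibrous, all others healthy
wall. Input component labels are never changed, and reconstructing an
already-reconstructed volume is a no-op. Components whose nearest lumen
surface distance exceeds 6 mm are rejected as orphans (they would float
outside any plausible wall).

Component volumes are voxel counts times voxel volume; relative volumes
are percentages of the calcific+lipid+fibrous total. A plaque-free vessel
yields a flagged "undefined" relative report that downstream stages treat
as missing.

## Finite-element model

* **Mesh**: every solid voxel splits into six tetrahedra (Freudenthal
  decomposition — conforming across voxels); elements inherit the voxel
  label. Boundary triangles are classified into lumen, proximal/distal
  end, and outer patches by the voxel on their far side.
* **Materials**: isotropic linear elastic, E = 20,000 (calcific), 400
  (fibrous), 550 (healthy wall), 4 (lipid) kPa, shared nu = 0.49.
* **Load and constraints**: the differential carotid pressure (systolic
  minus diastolic, from the patient record) as a uniform normal traction
  on the whole lumen patch, pushing from the lumen into the wall; vessel
  end cross-sections fully fixed. No fluid domain, no pulsatile load, no
  residual stress or axial pre-stretch, no hyperelasticity — the model
  compares plaques under identical simplified conditions rather than
  predicting absolute in vivo stresses.
* **Element technology**: plain linear tetrahedra lock volumetrically at
  nu = 0.49, so the solver uses linear tets with a *nodally averaged
  volumetric strain* (node-based mean dilatation): deviatoric stiffness
  is integrated element-wise; the dilatation entering stiffness and
  stress is the volume-weighted average over the elements sharing each
  node. The equivalent mixed displacement/nodal-pressure saddle system is
  factored directly (sparse LU) because it is markedly sparser than the
  condensed stiffness. The scheme passes the uniform-strain patch test to
  machine precision and converges monotonically on the Lamé benchmark.
  At material interfaces the nodal bulk stiffness is a volume-weighted
  average of the adjacent elements' — a known smoothing of this scheme,
  acceptable here because indexes aggregate over whole components.
* **Stress output**: one tensor per element (constant deviatoric part
  plus the element-averaged nodal dilatation), with the element volume —
  exactly what the cumulative-volume indexes need. Von Mises and maximum
  principal stress come from the deviatoric norm and the largest
  eigenvalue respectively; a symmetry check guards the input.
* **Validation**: patch test (exact); thick-walled cylinder a = 3 mm,
  b = 4 mm, p = 5.33 kPa in plane strain on a body-fitted structured
  mesh, inner-wall hoop stress within 5% (measured ~0.7%) of
  p(a^2+b^2)/(b^2-a^2) = 19.04 kPa at the default (8, 64, 2) resolution,
  with volume-weighted RMS hoop-stress error decreasing monotonically
  over (4, 32, 2) -> (8, 64, 2) -> (16, 128, 2). A voxel staircase
  boundary does not admit pointwise surface-stress checks, hence the
  body-fitted validation mesh; the voxel path is covered by the patch
  test, exact volume oracles and the cohort-level properties.

### Problem sizes

Cohort runs use a desk-scale geometry profile: an 18 mm vessel segment at
1.0 mm voxels with a 2.0 mm healthy wall (~8,000 elements, ~6,600
displacement DOF per patient, under a second per solve). This resolves
the component blobs with tens of voxels — coarse, but sufficient for the
volume-aggregated, direction-level quantities the cohort statistics
consume; single-vessel analyses can use the 0.3 mm default voxel size.

## Stress indexes

VM99/MPS99 are volume-weighted 99th percentiles with a lower-bound
crossing convention and no interpolation: sort elements by stress
ascending, accumulate volumes, return the first value whose cumulative
volume reaches 99% of the component total (equivalently: exclude the 1%
of volume carrying the highest stresses). With equal volumes this is the
inverted-CDF empirical percentile. Means are volume-weighted. The global
index of each parameter is sum_c w_c P_c with w_c the relative volumes of
the calcific/lipid/fibrous components; missing components get zero weight
and the remainder renormalizes; a patient with no plaque has no index.

## Stiffness metrics

With A = pi D^2/4, dA = A_s - A_d, dP = P_s - P_d:
CC = dA/dP [mm^2/kPa]; DC = dA/(A_d dP) [1/kPa];
beta = ln(P_s/P_d)/(dD/D_d); alpha = ln(P_s/P_d)/(dA/A_d);
PWV = sqrt(1/(rho DC)) (Bramwell–Hill), rho = 1050 kg/m^3 blood. The
report's prose descriptions of DC and CC conflict with their printed
units in the source material; the units (and these standard echo-tracking
definitions) win. The area-based alpha convention is a documented choice,
not a claim about any vendor's implementation. Zero diameter excursion
returns DC = CC = 0 with alpha, beta, PWV flagged undefined (NaN), not an
exception. pSWE: E = 3 rho c_s^2 (incompressible, mu = rho c^2, E = 3 mu),
rho = 1000 kg/m^3 tissue.

## Histology grading

Bins as in the module docstring. The prose scale leaves every boundary
ambiguous; boundaries are assigned so each scale is monotone and
exhaustive (10% necrosis -> 1; caps of exactly 200/400/800 um -> 2/1/0;
markers at exactly 5%/10% -> 1/2; 0% marker positivity -> 0). Lower score
always means more stable. No composite score is formed; scales are
compared individually downstream.

## Cohort statistics

Continuous rows: median with a single IQR width (Q3 - Q1, linear
interpolation between order statistics), Mann–Whitney U (exact for tie-free
groups of n <= 8, tie-corrected normal approximation otherwise).
Categorical rows: counts (%); chi-square, or Fisher's exact for 2x2
tables with any expected count below 5; ordinal score variables use
Mann–Whitney on the scores. Which test produced the categorical p-values
in the source tables is unstated; the chi-square/Fisher choice is this
package's documented assumption. Missing values are dropped per variable
with per-variable group sizes reported; p < 0.05 flags significance; no
multiplicity correction is applied (matching the source analysis).
Identical-constant comparisons return p = 1 rather than erroring.

## Exclusion bookkeeping

Real cohorts lose patients at specific stages. `plan_exclusions` draws
the configured number of drops per stage: CTA-segmentation and
reconstruction failures (disjoint, since a patient lost at segmentation
never reaches reconstruction) remove patients from the volume and stress
tables; histology drops are independent and affect only the histology
table; the ultrasound chain keeps everyone. With the study-scale counts
(100 enrolled; 11 histology, 4 CTA, 7 reconstruction) the FE stage
retains 89 patients. Runtime failures of any stage are additionally
logged per patient without corrupting other stages' outputs.

## Known limitations

* Linear elasticity with a static uniform load: absolute stress levels
  are not in vivo predictions; only between-group contrasts under
  identical assumptions are meaningful.
* The mean-dilatation element smooths volumetric stiffness across
  material interfaces (one-node-wide blur).
* The voxel mesher produces staircase boundaries; surface peak stresses
  are mesh-dependent and deliberately not reported (volume-aggregated
  percentiles are).
* The synthetic generator encodes class contrasts marginally; joint
  correlations (e.g. between cap thickness and lipid volume within a
  patient) are not modelled.
* The tortuosity limit that excluded patients from the real
  reconstruction is not modelled; exclusions are injected by count
  instead.
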