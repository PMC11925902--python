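# plaquestress

Image-based biomechanical assessment of carotid atherosclerotic plaque
vulnerability. The package reimplements, end to end and on synthetic data, a
patient-specific pipeline used to separate rupture-prone ("vulnerable",
lipid-rich, soft) from stable (calcific-dominant, stiff) carotid plaques in
patients undergoing endarterectomy:

1. **Synthetic cohort generation** — voxelized CTA-like segmentations of a
   stenosed common-carotid segment (lumen + calcific + lipid labels),
   two-class patient records (pressures, shear-wave speeds, demographics),
   arterial diameter waveforms and raw histology measurements, with the
   class contrasts of the clinical study built into the generating model.
2. **Wall reconstruction** — the full atherosclerotic wall is rebuilt from
   the segmentation: per centerline station the outer contour is the larger
   of (lumen/reference radius + healthy wall thickness) and (furthest
   component extent + fibrous cap margin); the stenotic extent is filled
   with fibrous tissue. Absolute and relative component volumes follow.
3. **Finite-element stress analysis** — the labelled wall is meshed into
   tetrahedra and solved as static, small-strain, isotropic linear
   elasticity (E: calcific 20,000 / fibrous 400 / wall 550 / lipid 4 kPa,
   nu = 0.49) under the differential (pulse) carotid pressure applied as a
   uniform normal traction on the lumen surface, with the vessel ends fixed.
4. **Stress indexes** — per component, the volume-weighted 99th-percentile
   and mean von Mises (VM99, VMmean) and maximum-principal (MPS99, MPSmean)
   stresses; globally, their relative-volume-weighted averages across the
   calcific, lipid and fibrous components.
5. **Stiffness metrics** — an echo-tracking style report (distension,
   diameter, distensibility DC, compliance CC, alpha/beta stiffness, pulse
   wave velocity via Bramwell–Hill) and the point shear-wave elastography
   conversion E = 3 rho c_s^2.
6. **Histology grading** — the semi-quantitative vulnerability scores
   (atheroma/necrosis extent, fibrous cap thickness, inflammation,
   cholesterol, CD68/CD163 immunopositivity).
7. **Cohort statistics** — Shapiro–Wilk normality gating, Mann–Whitney U
   group comparisons, chi-square/Fisher tests for categorical rows, and
   publication-style median (IQR) / count (%) comparison tables.

It is intended for methodologists who want a fully testable, deterministic
desk-scale replica of this class of pipeline — every input the real study
acquired from patients is generated synthetically, so all stages run
without any data download.

## Worked example

Stress analysis of one stenosed vessel (65% radius reduction, 20% calcific
/ 8% lipid plaque by volume) under a 5.33 kPa (40 mmHg) pulse pressure:

```python
import plaquestress as ps

params = ps.GeometryParams(
    lumen_radius=4.0, vessel_length=18.0, stenosis_length=12.0,
    voxel_size=1.0, stenosis_degree=0.65,
    calcific_fraction=0.20, lipid_fraction=0.08, seed=7,
)
labelmap = ps.generate_vessel_labelmap(params)
model = ps.reconstruct_atherosclerotic_wall(
    labelmap, ps.ReconstructionConfig(wall_thickness=2.0)
)
volumes = ps.compute_component_volumes(model)
mesh = ps.mesh_vessel(model)
result = ps.solve_elasticity(mesh, pressure=5.33)   # pulse pressure, kPa
summaries, index = ps.summarise_patient_stress(result, volumes)

for name, s in summaries.items():
    print(f"{name:9s} vol {s.volume:7.1f} mm3  VM99 {s.vm99:6.2f}  "
          f"MPS99 {s.mps99:6.2f}  VMmean {s.vm_mean:5.2f} kPa")
print(f"global    VM99 {index.vm99:.2f} kPa, MPS99 {index.mps99:.2f} kPa")
```

prints

```
calcific  vol    91.0 mm3  VM99  58.34  MPS99  63.52  VMmean 21.79 kPa
lipid     vol    36.0 mm3  VM99   0.82  MPS99   0.09  VMmean  0.32 kPa
fibrous   vol   857.0 mm3  VM99  10.86  MPS99   9.03  VMmean  4.52 kPa
global    VM99 14.89 kPa, MPS99 13.75 kPa
```

The stiff calcific inclusion concentrates load (highest VM99), the soft
lipid core is nearly unloaded, and the global indexes weight the component
values by their relative volumes — the mechanism by which calcific-dominant
stable plaques end up with *higher* global VM99/MPS99 than lipid-rich
vulnerable plaques of the same size.

A whole cohort, through to the five comparison tables, runs from the shell:

```bash
plaquestress run-all --n-vulnerable 43 --n-stable 57 --seed 11 --out out/
```

Other subcommands (`simulate-cohort`, `reconstruct`, `solve`, `indexes`,
`qas`, `histology`, `stats`) expose the individual stages; see
`plaquestress --help`.

## Layout

```
src/plaquestress/
  labels.py       label conventions, LabelVolume (NIfTI I/O)
  synthetic.py    vessel label maps, cohorts, diameter waveforms
  geometry.py     centerline, wall reconstruction, component volumes
  meshing.py      voxel -> tet meshing, validation meshes, surface patches
  elasticity.py   materials, mean-dilatation tet solver, stress invariants
  indices.py      VM99/MPS99/means, global plaque stress indexes
  stiffness.py    echo-tracking report, shear-wave modulus conversion
  histology.py    semi-quantitative vulnerability grading
  stats.py        normality gate, two-group tests, comparison tables
  pipeline.py     per-patient and cohort orchestration, exclusion logs
  validation.py   patch-test and Lamé-cylinder benchmarks
  io.py           VTK / STL / Abaqus exports
  cli.py          command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
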