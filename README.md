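# vox3dmsi

3D reconstruction and voxel-object statistics for serial-section MALDI
mass spectrometry imaging (MSI) of micron-scale 3D cell cultures —
spheroids and patient-derived organoids.

2D MALDI-MSI slices a ~600 µm spheroid into dozens of 20 µm sections,
each a grid of mass spectra.  Analyzing single sections misses the 3D
nature of these models: a small 2D profile may be the tip of a large 3D
object.  `vox3dmsi` rebuilds the volume and makes the *3D object* the
statistical unit:

1. **Ingest** — read per-section centroid imzML files onto a common m/z
   feature axis (peaks snapped within a ppm tolerance), ordered by an
   explicit sample-sheet manifest.
2. **Reconstruct** — RMS-normalize spectra, register consecutive
   sections rigidly on a morphology-defining landmark ion image
   (normalized cross-correlation, multi-resolution gradient descent),
   stack all feature channels into a `(z, y, x, feature)` volume, and
   report before/after adjacent-slice correlation as QC.  Volumes are
   exported as NRRD for 3D rendering.
3. **Segment** — select features (sliding-window intensity threshold;
   ROC-AUC discrimination), then partition voxels by bisecting k-means
   under correlation distance and map leaves to named regions
   (background / cancer / fibroblast / shell / lumen).
4. **Pick objects** — extract 3D connected components of a region mask
   (6/18/26-connectivity), classify by voxel count into V1 (< 10 vx),
   V2 (10–100 vx), V3 (> 100 vx), and compute exact voxel-face volume
   and surface area (one 20 µm voxel = 8000 µm³).
5. **Test** — per-object mean profiles, Welch t-tests with
   Benjamini–Hochberg adjustment and log2 fold changes between object
   groups (volcano analysis), plus Cohen's-d marker concordance for the
   2D workflow.

A synthetic **phantom generator** with complete ground truth (planted
transforms, region labels, object sizes and differential effects)
makes every stage testable without instrument data; see
`docs/methods.md` for the model and its limits.

## Worked example

```python
from vox3dmsi import PhantomSpec, RunConfig, generate_phantom, run_pipeline

dataset, truth = generate_phantom(PhantomSpec(seed=3))
record = run_pipeline(
    RunConfig(landmark_mz=200.0, n_leaves=3, seed=0,
              region_markers={"cancer": 210.0, "fibroblast": 250.0},
              object_region="fibroblast", outdir="run_out"),
    dataset=dataset)

print({k: round(v, 3) for k, v in record["qc"].items()})
table = record["_volcano"]
print(table[table["significant"]][["mz", "log2_fc", "p_adj"]])
```

prints

```
{'corr_before_mean': 0.059, 'corr_before_sd': 0.334,
 'corr_after_mean': 0.893, 'corr_after_sd': 0.062}
      mz   log2_fc         p_adj
0  310.0 -1.704364  1.377504e-11
1  290.0  1.760963  4.415300e-06
2  300.0  1.765075  1.359785e-05
```

Registration lifts the mean adjacent-slice landmark correlation from
0.06 (sections perturbed by up to ±5 px / ±10°) to 0.89, and the
volcano analysis between V2- and V3-sized fibroblast objects recovers
exactly the three features whose log2 fold changes (+2, +2, −2) the
phantom planted — attenuated to ≈ ±1.7 by partial-volume mixing at
object boundaries — with nothing else significant at BH-adjusted
p < 0.01 and |log2 FC| > 1.  `run_out/` then contains the landmark and
label volumes (NRRD), the transform, QC, object and volcano tables
(TSV), and a provenance record (JSON).

The same stages are available from the shell:

```bash
vox3dmsi simulate --mode biculture_spheroid --seed 7 --out sim/
vox3dmsi reconstruct --manifest sim/manifest.tsv --landmark-mz 200 \
    --mz-list mz.txt --out vol.nrrd --qc qc.tsv
vox3dmsi stats --profiles run_out/object_profiles.tsv \
    --a V2 --b V3 --alpha 0.01 --lfc 1 --out volcano.tsv
```

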