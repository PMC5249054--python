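# mcmorph

3D morphometry of breast microcalcifications (MC) in micro-CT volumes:
segmentation, structure-model-index shape analysis, rule-based morphology
categorization, and group-level statistics across histologic classes.

Microcalcifications are small calcium deposits whose *shape* informs
malignancy risk in mammography: fine linear and fine pleomorphic patterns are
suspicious, coarse or round ones mostly benign. Micro-CT of biopsy specimens
(9 µm isotropic voxels) resolves the true 3D structure of each deposit, and
the **structure model index** (SMI) of Hildebrand & Rüegsegger condenses that
structure into one number:

```
SMI = 6 · S′ · V / S²
```

where `V` is the object volume, `S` its surface area and `S′ = dS/dr` the
change of surface area under an infinitesimal uniform dilation. Ideal plates
give SMI 0, cylinders (rods) 3, spheres 4. `mcmorph` computes per-object
`V`, `S`, `S′`, SMI and equivalent diameters, aggregates them per biopsy,
applies a BIRADS-analog rule scheme (fine linear *fl* / fine pleomorphic
*fp* / coarse heterogeneous *ch* / not suspicious *ns*), and compares the
histologic groups A (B1/B2, benign), B (B3/B4, uncertain) and C (B5,
malignant) with Kruskal–Wallis and chi-square tests under Bonferroni
correction.

The package is aimed at researchers quantifying calcification structure in
micro-CT (or validating shape descriptors against phantoms); it ships a
29-sample reference cohort summary table and a synthetic-data module so the
entire pipeline runs and is tested without any external data.

## Worked example

Measure a digitized sphere of radius 180 µm on a 9 µm grid through the full
stack (phantom → threshold → labelling → morphometry):

```python
from mcmorph import (PhantomSpec, make_phantom, threshold_volume,
                     label_components, measure_objects)

vol, truth = make_phantom(PhantomSpec("sphere", radius_um=180.0),
                          (52, 52, 52), spacing=9.0)
labeled = label_components(threshold_volume(vol, method="fixed", fixed_value=500))
obj = measure_objects(labeled)[0]
print(f"voxels={obj.voxel_count}  V={obj.V:.3e} um^3  S={obj.S:.3e} um^2  "
      f"S'={obj.S_prime:.1f} um  SMI={obj.SMI:.3f}  d_sphere={obj.d_sphere:.1f} um")
```

prints

```
voxels=33552  V=2.446e+07 um^3  S=4.064e+05 um^2  S'=4548.6 um  SMI=4.042  d_sphere=360.1 um
```

i.e. the measured volume is within 2% of the analytic `4/3·π·180³`, the
surface within 1% of `4·π·180²`, and the SMI within 0.05 of the spherical
limit 4. The cohort-level analysis runs from the command line:

```sh
mcmorph reproduce --out results_reference
```

```
classification concordance: 25/27 samples (known discordances documented in
classification_expectations.csv)
```

and writes `stats.csv` containing, among others, the four morphology
chi-square tests:

```
chi_square_fl,9.958441558,2,0.006879421057,0.02751768423,True
chi_square_fp,1.237387612,2,0.5386475564,1,False
chi_square_ch,2.967032967,2,0.22683861,0.90735444,False
chi_square_ns,7.154595405,2,0.02795112856,0.1118045142,False
```

The presence of fine linear MC differs significantly between the histologic
groups (p = 0.007, still significant after Bonferroni with m = 4), while the
absence of suspicious MC (p = 0.028) loses significance after correction —
the columns are statistic, df, p, Bonferroni-adjusted p, and significance at
α = 0.05.

Other entry points: `mcmorph simulate` (synthetic cohorts), `mcmorph
segment` / `measure` / `classify` / `stats` (single pipeline stages over
TIFF/CSV files), and `mcmorph run --config pipeline.yaml` for a fully
configured, seeded, deterministic run.

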