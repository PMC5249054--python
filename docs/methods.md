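# Methods

## Scope and model

`mcmorph` quantifies the 3D structure of breast microcalcifications (MC)
segmented from reconstructed micro-CT volumes. The pipeline is

1. **Segmentation** — global threshold (Otsu or fixed) of the grayscale
   volume, 26-connected component labelling, optional minimum-size filter.
2. **Morphometry** — per object: volume `V` (voxel count × h³, exact),
   surface area `S`, surface derivative `S′`, the structure model index
   `SMI = 6·S′·V/S²`, and the sphere/cube equivalent diameters
   `d_sphere = (6V/π)^{1/3}`, `d_cube = V^{1/3}`.
3. **Aggregation** — per biopsy: object count, mean volume, mean and SD of
   SMI (SD with the n−1 denominator; defined as 0 for a single object),
   mean cube diameter, maximum sphere diameter. Samples with exactly one
   MC are flagged excluded (a lone deposit is treated as non-representative
   of the lesion) and are kept in tables but refused by categorization.
4. **Categorization** — independent, co-occurring sample-level flags:
   *fl* (mean d_cube < 200 µm, strict, and mean SMI in the closed interval
   [2.92, 3.08]); *fp* (mean d_cube < 250 µm and SD of SMI > 0.29, strict);
   *ch* (largest object's d_sphere > 500 µm and SD of SMI > 0.5, both
   strict); *ns* when none fires. A secondary per-object mode applies the
   fl rule to individual objects; the SD-based rules are undefined per
   object and evaluate false there.
5. **Statistics** — per-group means/SDs; Kruskal–Wallis (midrank ties,
   χ²_{k−1} reference) for the continuous statistics; Pearson chi-square
   without continuity correction on the 2×3 presence/absence tables;
   Bonferroni over the four-flag family (m = 4 by default); a descriptive
   Kolmogorov–Smirnov normality check (asymptotic p, parameters estimated
   from the data, no Lilliefors correction — flagged approximate).

The SMI interpretation assumes approximately convex, solid objects; for
ideal solids the index is 0 (plate), 3 (cylinder) and 4 (sphere). Values of
digitized objects are reported unclamped — discretization legitimately
pushes them slightly outside [0, 4], and values outside [−0.5, 4.5] are
logged as suspicious.

## Surface estimators and their accuracy

Binary masks have staircase surfaces: the raw marching-cubes mesh of a
digitized sphere overestimates its area by ≈ 8.5%, which alone biases the
sphere SMI by ≈ −0.6. Two numerical choices fix this:

* **Surface area.** The mask is Gaussian-smoothed (σ = 1 voxel, zero-padded
  by 4 voxels) and meshed at iso-level 0.5. Smoothing is deterministic and
  brings a radius-20-voxel sphere's area within 0.5% of `4πr²`; sharp
  cuboids are rounded at their edges and need ≳ 30 voxels per edge for 5%
  accuracy (faces grow quadratically, edge losses linearly).
* **Surface derivative.** The classic surface-dilation construction is
  applied on the mesh itself: every vertex is displaced outward along its
  gradient-based unit normal by ε = 0.25 voxel and
  `S′ = (S(ε) − S)/(ε·h)`. On phantoms this estimator lands within a few
  percent of the analytic `dS/dr` (sphere `8πr`, cylinder `2πL`), giving
  SMI 3.99–4.04 for spheres of radius ≥ 20 voxels. A voxel-domain variant
  (`method="voxel"`: one-voxel Euclidean-ball binary dilation, forward
  difference of the meshed surfaces, Δr = h) is retained for comparison but
  is not the default — the discrete unit ball is the 6-neighbour cross,
  whose anisotropy underestimates `S′` of a sphere by ≈ 13% and biases its
  SMI to ≈ 3.4; erosion-based central differences are avoided entirely
  because erosion annihilates one-voxel-thin structures, which MC often
  are.

Objects thinner than 4 voxels in any bounding-box dimension are first
upsampled by nearest-neighbour replication (factor `ceil(4/thinnest)`), so
σ = 1 smoothing cannot erase them; the replication is shape-preserving and
deterministic. For a single isolated voxel the smoothed mesh approaches the
voxel's inscribed sphere, so its reported surface is ≈ πh² rather than the
6h² of the cube — accuracy at that scale is meaningless, but the value is
deterministic and finite. Objects within 2 voxels of the volume border are
rejected with an instruction to pad (their surface would be truncated);
`measure_objects` pads each object's subvolume automatically.

Measured convergence (tests pin these): sphere SMI error shrinks
monotonically over radii 10 → 20 → 40 voxels and is < 0.4 at r = 20;
a fixed 180 µm sphere changes by < 0.2 SMI when resampled from 9 µm to
4.5 µm voxels. Finite solids differ from the ideal limits by geometry, not
estimator error: a finite cylinder exceeds SMI 3 by ≈ 8·(diameter/length)
from its end caps, and a finite plate exceeds 0 by ≈ 6π·(thickness/lateral)
from its rim — phantom aspect ratios in tests are chosen accordingly.

## Classification-rule conventions

Three boundary behaviours are pinned by the reference cohort itself: the fp
SD threshold is strict (a sample at exactly 0.29 is not fp), the fl SMI
upper bound 3.08 is inclusive, and the fl size bound 200 µm is strict. The
*ch* size predicate uses the **largest** object's sphere-equivalent
diameter: the rule names only "estimated diameter > 500 µm", and the one
coarse-heterogeneous sample in the reference cohort has a mean diameter far
below 500 µm under any convention — only a per-sample maximum is compatible
with a single large deposit driving the flag.

Re-applying the rules to the bundled summary table reproduces the recorded
flags for 25 of 27 evaluable samples. The two discordances are enumerated
in `data/classification_expectations.csv`, not absorbed: sample 3 satisfies
the literal fl rule but is recorded fp-only (suggesting a precedence rule
or per-object evaluation upstream), and sample 15's ch flag depends on
per-object maxima that a summary table cannot supply (the mean-volume proxy
gives ≈ 449 µm < 500 µm).

## Statistical conventions

Chi-square without Yates correction is the variant that reproduces all four
published morphology P-values (0.007 / 0.539 / 0.227 / 0.028) from the
2×3 tables; with correction none match. Bonferroni uses m = 4 (the four
flag tests; configurable), which renders the ns finding (p = 0.028)
non-significant. Kruskal–Wallis defaults to the 27 non-excluded samples;
on that set the battery yields p = 0.113 / 0.879 / 0.778 / 0.962 for
count / volume / mean SMI / SD SMI, close to the published
0.113 / 0.881 / 0.756 / 0.976 whose exact inclusion set and tie-handling
are unstated — the tests therefore only assert non-significance.

## Synthetic data

`make_phantom` samples continuous solids at voxel centers (optionally with
Gaussian intensity noise, seeded) and records the exact voxel count plus
analytic V/S and the ideal SMI limit where closed forms exist. `make_cohort`
draws per-sample MC counts and sample-level mean volumes from log-normals
and per-sample mean SMI from normals, moment-matched to the reference
group summaries (counts 23.2±32.6 / 41.4±52.7 / 33.6±12.8; volumes
106/88/56 ±207/169/50 ×10⁵ µm³; SMI 2.97±0.31 / 2.90±0.28 / 3.03±0.10 for
groups A/B/C). Log-normal families were chosen because both counts and
volumes are strongly right-skewed (SD > mean); only group-level moments are
published, so the within-sample object-volume CV (default 1.0) and
within-sample SMI SD (default 0.32, the published mean SD-of-SMI) are
unidentified defaults, documented here rather than fitted. Aggregates of
simulated samples run through the same `aggregate_sample` code path as real
measurements.

`render_sample` turns simulated (V, SMI) pairs into voxel phantoms — SMI
≤ 1.5 renders as a plate, ≤ 3.5 as a rod, else a sphere — laid out on a
separated cell grid so segmentation recovers one component per planted
object. Rod aspect 12 and plate aspect 60 keep the finite solids' true SMI
near their class values (see above). This rendering is a geometric stand-in
for pipeline validation, not a claim about real calcification shapes, and
the generator does not emulate X-ray physics, reconstruction artifacts,
beam hardening, partial-volume gray levels or tissue background; passing
end-to-end tests therefore demonstrate correctness of the measurement
chain, not segmentation robustness on real scans.

## Problem sizes and determinism

All tests run on phantoms up to ~200³ voxels and cohorts up to 3 000
simulated samples; the complete suite finishes in seconds on one CPU. Every
stochastic component (noise fields, cohort draws) is driven by explicit
integer seeds through `numpy.random.default_rng`, and pipeline runs are
byte-identical given the same config and seed.

## Known limitations

* Absolute object counts on real scans depend on the (unpublished) vendor
  threshold used upstream; only the downstream computation is reproducible,
  which is why the bundled cohort is a summary table, not raw volumes.
* The KS normality p-value is optimistic for estimated parameters.
* Grayscale (partial-volume) morphometry, local/adaptive thresholding,
  fractal dimension and other 3D descriptors are out of scope.
* The SMI of strongly concave or hollow objects is hard to interpret
  (negative `S′` contributions); values are reported unclamped and logged
  when implausible.
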