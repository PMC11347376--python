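# vesselmorph

Quantitative morphometry of blood-vessel cross-sections in histological
sections, plus the formula-backed drug-supply readouts that typically
accompany it in tumor-vasculature studies.

A healthy, perfused capillary cut approximately transversally shows a
circular or mildly elliptic outline; dysfunctional tumor microvessels
diverge from that ideal — indented, angular, collapsed. `vesselmorph`
quantifies that divergence with **elliptic Fourier analysis (EFA)**: a
closed outline traversed at constant speed defines periodic coordinate
functions whose Fourier expansion

```
x(t) = A0 + Σn [ an cos(2πnt/T) + bn sin(2πnt/T) ]
y(t) = C0 + Σn [ cn cos(2πnt/T) + dn sin(2πnt/T) ]
```

is computed exactly for polygons (Kuhl–Giardina segment sums). After
normalizing away start point, rotation, scale and chirality through the
first-harmonic ellipse, the per-harmonic magnitudes

```
Dn = sqrt(an² + bn² + cn² + dn²),  n = 1..5
```

are the **first five Fourier descriptors** of the outline: D1 = √2 for a
circle and decreases toward 1 as the best-fit ellipse elongates, while
D2..D5 capture divergence from a pure ellipse. Per-sample mean descriptor
vectors are compared by hierarchical clustering (Euclidean distance,
average linkage) and classified against a reference panel — either the five
designed shape classes (circular, rectangular, irregular, concave,
indented) or labeled reference samples of the three vessel phenotypes
("normal", "indented", "angular").

The package is aimed at image-analysis scientists quantifying vessel
normalization in tumor sections. Since archival slides cannot ship with
code, a first-class synthetic generator (`vesselmorph.reference_shapes`)
produces the designed shape panel, tumor-like samples as class mixtures,
and rendered vessel fields with ground-truth stain penetration.

Also included (`vesselmorph.supply_quant`): Miles-assay Evans-blue
quantification with hemoglobin correction (A620 − A740), linear standard
curves, caliper tumor volume V = π/6·l·w², doxorubicin %ID/g, tracer
penetration depth from the vessel surface (per-side maxima, averaged),
microvessel density, and positive-area fraction.

## Worked example

```python
import pandas as pd
from vesselmorph import reference_shapes as rs, morphoclass as mc
from vesselmorph.efd_core import descriptor_table

# five-class reference panel: 20 outlines per designed class
contours, labels = rs.make_panel(n_per_class=20, noise=0.03, seed=0)
table = descriptor_table(contours)
table["label"] = labels
print(table.groupby("label")[["D1", "D2", "D3", "D4", "D5"]].mean().round(3))
```

```
                D1     D2     D3     D4     D5
label
circular     1.395  0.014  0.018  0.017  0.018
concave      1.273  0.091  0.088  0.051  0.025
indented     1.393  0.017  0.096  0.016  0.243
irregular    1.373  0.155  0.116  0.119  0.094
rectangular  1.137  0.015  0.121  0.007  0.028
```

Circular outlines sit at D1 ≈ √2 with no higher-harmonic energy; each
designed deviation leaves its own signature (indented: D3/D5 from its
4-fold notches; rectangular: low D1 and a strong third harmonic; concave:
mixed low-order energy from the single invagination).

Classifying synthetic tumor samples against a labeled reference sample set:

```python
specs = rs.default_sample_specs(n_per_group=8, seed=101)
by_sample, truth = rs.make_sample_set(specs)
means = mc.sample_mean_fd(
    descriptor_table([c for v in by_sample.values() for c in v])
)
# reference samples generated independently, labeled by phenotype group
ref, ref_truth = rs.make_sample_set(rs.default_sample_specs(n_per_group=8, seed=1203))
panel = mc.sample_mean_fd(
    descriptor_table([c for v in ref.values() for c in v])
)
panel["label"] = panel["sample_id"].map(ref_truth)

out = mc.classify_samples(means, panel, method="centroid")
out["truth"] = out["sample_id"].map(truth)
print(out.head(5).round(4).to_string(index=False))
```

```
 sample_id   label  distance   method  fallback   truth
angular_00 angular    0.0177 centroid     False angular
angular_01 angular    0.0213 centroid     False angular
angular_02 angular    0.0160 centroid     False angular
angular_03 angular    0.0462 centroid     False angular
angular_04 angular    0.0292 centroid     False angular
```

All 24 samples (8 per phenotype group) are assigned to their true group;
`distance` is the Euclidean distance to the assigned class centroid in
descriptor space.

The same pipeline is available from the shell:

```
vesselmorph simulate --seed 3 --outdir run/
vesselmorph efd run/panel.csv --out run/panel_fd.tsv
vesselmorph efd run/samples.csv --out run/samples_fd.tsv
vesselmorph classify run/samples_fd.tsv --panel run/panel_fd.tsv \
    --panel-truth run/panel_truth.tsv --out-prefix run/out
vesselmorph assays volume calipers.csv --out volumes.csv
```

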