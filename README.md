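# cervimorph

Radiographic phenotyping of cervical sagittal alignment.

Patients with degenerative cervical myelopathy (DCM) show very different
sagittal alignment patterns on lateral radiographs — kyphotic forward-head
postures, balanced lordotic spines, elongated anteriorly displaced necks —
and those structural differences plausibly matter for conservative and
surgical management. `cervimorph` implements, as a tested and reproducible
pipeline, an automated morphometric analysis that:

1. **measures** four sagittal alignment parameters per radiograph from
   expert polygon annotations of the C3–C7 vertebral bodies:
   - *C3 SVA* — horizontal offset of the C3 centroid from the vertical
     plumb line through the posterosuperior corner of C7,
   - *C3–C7 lordosis* — Cobb angle between the C3 inferior and C7 superior
     endplate lines,
   - *C3–C7 vertical length* — |y(C3 centroid) − y(C7 centroid)|,
   - *C3–C7 curved length* — Σᵢ ‖cᵢ₊₁ − cᵢ‖₂ over consecutive centroids;
2. **clusters** cohorts of these measurements (z-scoring, optional PCA,
   k-means with elbow/silhouette model selection, Calinski–Harabasz and
   Davies–Bouldin validation) into alignment phenotypes — *forward-head*,
   *normal*, *long-neck*;
3. **compares** the phenotypes with one-way ANOVA and Bonferroni-corrected
   pairwise t tests, including ANOVA reconstructed purely from published
   (n, mean, SD) summaries;
4. **synthesizes** its own test data: Gaussian parameter cohorts with a
   known three-cluster structure, and geometric spine phantoms whose four
   parameters are known in closed form, so every stage is verifiable
   without access-restricted clinical images.

Landmarks follow a band-extreme rule: the C3 inferior endplate joins the
lowest contour points of the leftmost and rightmost 25% x-bands of the C3
outline, the C7 superior endplate the highest such points, and the C7
posterosuperior corner is the highest point of the posterior band.
Contours come either directly from the polygon vertices (exact, default)
or through a rasterized binary mask and boundary trace.

## Worked example

```python
from cervimorph import synthetic_data as sd, geometry as geo, phenotyping as ph, stats as st

# a spine phantom with known lordosis and SVA, measured back exactly
ann, truth = sd.generate_spine_annotation(
    sd.SpineGeometryConfig(lordosis_deg=24.1, sva=70.6))
landmarks, params = geo.measure_radiograph(ann)
# -> sva 70.6, lordosis 24.1, vertical 476.69, curved 482.12

# a 1318-patient cohort with the published three-cluster structure
cohort = sd.simulate_cohort(sd.table1_config(seed=1))
Z, scaler = ph.standardize(cohort.params)
model = ph.kmeans_fit(Z, 3, seed=0)
summary = st.cluster_summary(cohort.params, model.labels + 1)
print(ph.label_clusters(summary))
# {1: 'normal', 2: 'forward-head', 3: 'long-neck'}
print(st.build_table1(cohort.params, model.labels + 1)[["parameter", "F", "p"]])
#        parameter        F    p
#              sva    95.42  0.0
#     lordosis_deg   988.77  0.0
#  vertical_length   684.22  0.0
#    curved_length  1082.99  0.0
```

The first block shows generator/measurement closure: the phantom is built
so its ground truth is analytic, and the measurement pipeline recovers it.
The second block recovers the three phenotypes from a simulated cohort and
shows that all four parameters separate the clusters (every ANOVA p far
below 0.01, as in the clinical cohort the cluster structure emulates).

The same pipeline runs from a shell:

```sh
cervimorph simulate  --config cfg.yaml --out out/   # cohort or phantom file
cervimorph measure   --config cfg.yaml --out out/   # annotations -> parameters.csv
cervimorph phenotype --config cfg.yaml --out out/   # labels, k-scan, comparison table
```

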