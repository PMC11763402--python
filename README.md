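# histospat

Spatial point-pattern analysis of tumor-cell distributions in H&E histology.

Clear cell renal cell carcinoma (ccRCC) of intermediate grade (ISUP/WHO 2–3)
is poorly stratified by nuclear grading alone: grade shows essentially no
association with metastatic status in such cohorts. This package implements
an alternative read-out based on *where* the tumor cells sit. Starting from
nucleus centroids exported from a digital-pathology tool (QuPath GeoJSON or
measurement TSV), it

1. builds marked spatial point patterns on square regions of interest with
   polygonal holes (cleaved necrosis/vessels/artifacts),
2. estimates each pattern's **pair correlation function (PCF)**
   g(r) = K′(r)/(2πr) with translation edge correction on a fixed radii grid
   (0.5–35 µm in 0.5 µm steps, 70 radii),
3. clusters patients by their mean PCF curves (K-means, average silhouette
   width for K selection) into spatial groups — one closer to complete
   spatial randomness (CSR, g ≈ 1), one clustered — and tests the groups'
   association with metastasis,
4. models inter-cellular interaction with the **Geyer saturation process**
   (density ∝ βⁿ γ^U(x), U(x) = Σᵢ min(s, tᵢ) with tᵢ the r-close neighbor
   count), fitted by maximum pseudolikelihood via Berman–Turner quadrature,
   profiling the interaction radius r and saturation s ∈ {1,2,3} by AIC, and
5. compares fitted **interaction distances** between spatial groups and
   against paired CSR "random cells", using Cochran-sized subsample
   realizations of each pattern.

A synthetic-cohort generator reproduces the statistical structure such a
study assumes (72 patients × 3 ROIs of 750 µm × 750 µm, ≈ 400 tumor cells
per ROI, a spatially random and a clustered regime, metastasis enriched in
the random regime, grade margins 18/54), so the entire pipeline runs and is
tested without any imaging data.

## Worked example

```bash
histospat synth   --out-dir cohort --seed 1
histospat run-all --out-dir cohort --seed 1 --n-realizations 50
```

The first command writes 72 patients / 216 ROI GeoJSON files plus a
manifest. The second ingests them and prints, for seed 1:

```
optimal K = 2; artifacts in cohort
```

with artifacts including `cohort_pcf_matrix.csv` (the 72 × 70 matrix of
per-patient mean PCF values), `groups.csv` (cluster, spatial group 1/2, and
PCA coordinates per patient), `association_tests.json`, and
`interaction_comparisons.json`. On this cohort the association tests give

```
group_vs_metastasis: chi2 stat=8.025 p=0.004614
grade_vs_metastasis: chi2 stat=1.858 p=0.1729
```

i.e. the spatial grouping separates metastatic from non-metastatic patients
(p < 0.01) while grade does not (p > 0.05) — and the interaction-distance comparisons
show larger mean fitted interaction radii in the spatially random group
than in the clustered group, with the clustered group (but not the random
group) differing from its paired "random cells".

As a Python library:

```python
from histospat.synthetic import CohortConfig, generate_cohort
from histospat.pipeline import run_pipeline

records, truth = generate_cohort(CohortConfig(master_seed=1))
result = run_pipeline(records, seed=1)
result.clustering.optimal_k        # 2
result.tests["group_vs_metastasis"].p_value   # 0.004614
```

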