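# nucleograde

Quantitative nuclear morphometry of H&E-stained cervical biopsy
microscopy, for investigating how nuclear structure changes with
advancing CIN (cervical intraepithelial neoplasia) grade.

Histopathological CIN grading rests on visually assessed nuclear
atypia — abnormality of nuclear size, shape and chromatin — which is
known to vary between and within pathologists.  `nucleograde`
implements the corresponding quantitative chain end-to-end:

1. **Segmentation** of nuclei from RGB light-microscopy images
   (grayscale → Gaussian smoothing → Canny edges → morphological
   contour completion → 500-px size filter → logical AND with the
   grayscale image);
2. **63 features per nucleus**: first-order histogram statistics (4),
   gray-level co-occurrence / Haralick features at 16 levels over four
   directions (13), run-length features (5), level-2 Daubechies-2
   wavelet detail statistics (24), Tamura coarseness/contrast/roughness
   (6), local binary pattern moments (2), and morphology — area,
   perimeter, equivalent diameter, convex area, axis lengths,
   eccentricity, solidity, extent (9);
3. **Patient aggregation**: the mean 63-feature vector over all of a
   patient's segmented nuclei (4–5 images per patient);
4. **Group screening** between low-grade and high-grade patient
   groups: two-sided Wilcoxon rank-sum p-value per feature,
   point-biserial correlation r_pb with the 0/1 grade label, and
   Benjamini–Hochberg FDR adjustment over the m = 63 tests, reported
   with per-group mean ± SE.

For feature j with co-occurrence matrix p(i,k), examples of the core
statistics in standard notation:

    ENT  = − Σ_{i,k} p(i,k) · ln p(i,k)               (co-occurrence entropy)
    GLNU = Σ_i [Σ_l Q(i,l)]² / Σ_{i,l} Q(i,l)         (run-length gray-level nonuniformity)
    F_crs = (1/|Ω|) Σ_{(x,y)∈Ω} S_best(x,y),  S_best = 2^k*  (Tamura coarseness)
    r_pb = (M₁ − M₀)/s_n · √(n₁ n₀ / n²)              (point-biserial correlation)

Because clinical slides are not publicly available, the package ships
a seeded **synthetic cohort generator** that emulates the study design
(22 patients per group, 4–5 fields each) with ground-truth masks and
plants the reported group differences — larger, more irregular,
coarser-textured, more inhomogeneous nuclei in the high-grade group —
so every stage is testable without clinical data.

## Worked example

```python
import dataclasses
from nucleograde import CohortSpec, GroupParams, screen_cohort

low  = dataclasses.replace(GroupParams.preset("low_like"),  nuclei_per_image=4, images_per_patient=3)
high = dataclasses.replace(GroupParams.preset("high_like"), nuclei_per_image=4, images_per_patient=3)
spec = CohortSpec(n_patients_per_group=6, seed=7, image_size=(384, 384), low=low, high=high)
report, cohort, per_nucleus = screen_cohort(spec)

print(f"{len(per_nucleus)} nuclei from {cohort.group_sizes} patients")
cols = ["feature", "p_raw", "p_adj", "r_pb", "mean_low", "mean_high"]
keep = ["nucleus_area", "nucleus_equivalent_diameter", "nucleus_minor_axis_length",
        "nucleus_solidity", "tamura_coarseness_1"]
print(report.rows[report.rows.feature.isin(keep)][cols]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"significant after FDR: {len(report.significant_adj)} of 63")
```

prints

```
144 nuclei from (6, 6) patients
                    feature   p_raw   p_adj  r_pb  mean_low  mean_high
               nucleus_area 0.00216 0.00413 0.965  1.07e+03   1.59e+03
nucleus_equivalent_diameter 0.00216 0.00413 0.967      36.7       44.8
  nucleus_minor_axis_length 0.00216 0.00413 0.937      32.6       37.4
           nucleus_solidity 0.00216 0.00413 -0.96         1      0.988
        tamura_coarseness_1  0.0152  0.0217 0.777      14.6         17
significant after FDR: 44 of 63
```

Reading the rows: the high-grade synthetic group plants larger nuclei,
and the screen recovers that — mean nucleus area rises from ~1070 px²
to ~1590 px² (equivalent diameter 36.7 → 44.8 px) with an
FDR-adjusted p ≈ 0.004 and a strongly positive point-biserial
correlation, i.e. higher values in the high-grade group.  Coarser
planted chromatin texture raises Tamura coarseness (14.6 → 17).
Solidity falls with the planted boundary irregularity (its sign under
the standard area/convex-area definition; see `docs/methods.md`).

The same pipeline runs from the shell:

```sh
nucleograde simulate --out cohort --seed 1            # synthetic cohort + ground truth
nucleograde run --out run --seed 1                    # simulate → segment → features → aggregate → stats
nucleograde segment --input img.png --out-masks m/    # single stages...
nucleograde features --manifest cohort/manifest.csv --out nuclei.csv
nucleograde aggregate --features nuclei.csv --out patients.csv
nucleograde stats --patients patients.csv --out report.csv
```

`report.csv` has the 63-row screening schema
`feature, p_raw, p_adj, r_pb, mean_low, se_low, mean_high, se_high`,
rows sorted alphabetically by feature name.

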