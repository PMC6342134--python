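# piosphere

Multi-scale structure of invertebrate trap-survey communities along
distance-to-water gradients.

Permanent water in semi-arid landscapes creates *piospheres*: zones of
concentrated herbivore impact that reshape vegetation and, through it, the
ground-dwelling invertebrate communities sampled by pitfall traps.
`piosphere` implements the statistical chain used to ask how such a
gradient structures a community at several spatial scales at once:

* **Alpha diversity** per trap — abundance, morphospecies richness, and the
  effective number of species ¹D = exp(−Σ pᵢ ln pᵢ) (Hill number of
  order 1).
* **Beta diversity as multivariate dispersion** — modified Gower
  dissimilarities between traps (log₁₀-transformed abundances, so an
  order-of-magnitude change in abundance weighs the same as a
  presence/absence change), embedded by principal coordinates with
  negative-eigenvalue axes retained, then the distance of each trap to the
  centroid of its spatial group at four nested scales (transect, distance
  category, distance category × transect, sample point).
* **Weighted nestedness (WIN/WINE)** and **weighted bipartite modularity**
  Q = (1/F) Σᵢⱼ (Aᵢⱼ − kᵢdⱼ/F)·1{i,j share a module} of per transect ×
  season morphospecies × distance-category matrices, with significance
  against null ensembles of random matrices that conserve the observed row
  and column totals exactly (Patefield sampling), and a seasonal
  comparison of D-values (null − observed) by two-sample permutation test.
* A **synthetic survey generator** with plantable abundance gradients,
  seasonal effects and nested or modular spatial structure, so every
  stage of the chain is testable without any field download.

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.

## Worked example

```python
from piosphere import (GeneratorConfig, SurveyDesign, generate_survey,
                       build_interaction_matrices, patefield_null, wine,
                       optimize_modularity)
from piosphere.community import build_community_matrix
from piosphere.diversity import alpha_table, alpha_summary

cfg = GeneratorConfig(design=SurveyDesign(n_transects=2), n_species=40,
                      target_total=8000, structure="nested",
                      structure_strength=0.8, seed=11)
table = generate_survey(cfg)
print("individuals:", table.total_individuals)

cm = build_community_matrix(table, level="trap", season_filter="wet")
summary = alpha_summary(alpha_table(cm))
print(summary[["distance_m", "abundance_mean", "effective_species_mean"]]
      .round(2).to_string(index=False))

im = build_interaction_matrices(table)[0]
nest = wine(im, patefield_null(im, n_draws=500, seed=1))
print(f"transect {im.transect} {im.season}: WINE={nest.wine:.3f} "
      f"z={nest.z_score:.2f} p={nest.p_value:.4f}")
mod = optimize_modularity(im, restarts=10, seed=2)
print(f"modularity Q={mod.Q:.3f} with {mod.n_modules} modules")
```

Output:

```
individuals: 8106
 distance_m  abundance_mean  effective_species_mean
          0           28.23                    5.55
         50           34.07                    4.55
        100           30.90                    5.14
        150           27.07                    5.28
        250           27.80                    4.34
        500           26.23                    3.87
       1000           17.50                    3.24
transect 1 dry: WINE=0.619 z=4.37 p=0.0000
modularity Q=0.115 with 3 modules
```

Reading this: the survey realized 8,106 individuals; wet-season trap
abundance declines away from water (28.2 → 17.5 individuals per trap from
0 m to 1,000 m, following the planted −0.05/100 m trend) and so does the
effective number of species.  The first transect × season interaction
matrix is significantly nested (WINE = 0.62 — well above the null
expectation of ~0, as expected with planted nested structure at strength
0.8; one-tailed p below 1/500), while its modularity is modest (Q = 0.12).

## Command line

```bash
piosphere generate --out survey.csv --seed 1
piosphere analyze --input survey.csv --out run/ --seed 1
piosphere simulate-power --structure nested --n-seeds 20
```

`analyze` writes per-trap alpha metrics with distance-category summaries
(mean ± SE), dispersion tables for the four scales and both seasons, a
Table-of-structure-results CSV (observed, null mean, normalized value, z,
raw and Benjamini–Hochberg-adjusted p per transect × season × statistic),
seasonal permutation comparisons, module memberships, a model-ready long
table for external mixed-model fitting, and a JSON manifest (config, seed
tree, package versions, exclusion/clamp counts, timings) from which the
whole run can be reproduced.

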