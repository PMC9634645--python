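# pollenflow

Analysis toolkit for fluorescent-dye pollen-analogue experiments in
parapatric plant ecotypes, built around the study system of *Silene
nutans* in southern Belgium: two edaphic ecotypes — calcicolous (Ca, on
calcareous soils) and silicicolous (Si, on siliceous soils) — whose
populations sit 0.7–5 km apart, within the flight range of their shared
nocturnal moth pollinators. Fluorescent powder applied to source-plant
anthers acts as a pollen analogue; dye particles counted on recipient
stigmas trace pollinator-mediated pollen movement within and between
populations and ecotypes.

The package covers the full analysis chain:

- **Dispersal kernel** — the 2-D exponential-power family
  `f(α, β; r) = β exp(−(r/α)^β) / (2π α² Γ(2/β))`, with extent `α` (m)
  and shape `β` (fat-tailed when β < 1). Fitted to mean dye count per
  flower vs distance by chi-squared minimisation with a free scale, with
  multi-start search and an explicit boundary flag for degenerate fits.
  Mean transfer distance by the closed form `δ_k = α·Γ(3/β)/Γ(2/β)`.
- **Spatial autocorrelation** — Moran's *I* with row-standardised
  inverse-distance weights, permutation tests (999 permutations),
  Bonferroni screening, distance-binned correlograms, and spatial checks
  of model residuals.
- **Hurdle count regression** — logit hurdle plus zero-truncated
  Poisson/negative-binomial counts by maximum likelihood, with offsets,
  Wald and likelihood-ratio tests, and the three canonical transfer
  analyses (intrapopulation differences, intra- vs inter-ecotypic
  transfers, directionality of inter-ecotypic flow).
- **Community statistics** — correlation-matrix PCA and sequential
  Bray–Curtis PERMANOVA on seed-predator abundance matrices,
  Mann–Whitney *U* comparisons of camera-derived visitation, chi-square
  tests of germination and chlorosis (hybrid-indicating) proportions.
- **Synthetic data** — landscape, deposition, community, visitation and
  germination generators with known ground truth for recovery tests.

The published per-population and community summary tables are shipped as
package data (`pollenflow.paperdata`); the underlying raw field
observations are not distributed, so the synthetic module provides
structurally matched stand-ins for every estimator.

## Worked example

```python
from pollenflow.kernel import mean_dispersal_distance
from pollenflow.community import permanova
from pollenflow.paperdata import load_seed_predators

# mean dye-transfer distance for a fitted kernel (alpha = 28.9 m, beta = 0.83)
print(round(mean_dispersal_distance(28.9, 0.83), 1))   # 87.4 m

# does ecotype structure the seed-predator community?
res = permanova(load_seed_predators(), factors=("ecotype", "year"), seed=1)
print(res.table[["term", "pseudo_F", "p_perm"]])
#       term  pseudo_F  p_perm
#    ecotype  3.150414   0.009
#       year  1.049538   0.432
```

A kernel with α = 28.9 m and β = 0.83 (fat-tailed) moves dye 87.4 m on
average; the PERMANOVA says ecotype explains significant variation in
the five-taxon seed-predator community (pseudo-F ≈ 3.15) while sampling
year does not (F ≈ 1.05).

The numbered scripts under `analysis/` run the full chain on synthetic
landscapes and the shipped summary tables, writing CSVs under
`results/`:

```sh
python analysis/01_simulate.py        # two synthetic landscapes
python analysis/02_transfer_summary.py
python analysis/03_fit_kernels.py     # per-population kernel/Moran/Gamma table
python analysis/04_hurdle_models.py   # the three transfer analyses
python analysis/05_community_stats.py # PCA, PERMANOVA, U tests, chi-squares
```

There is also a CLI (`pollenflow simulate|fit-kernel|moran|hurdle|community|run-all|validate`)
driving the same functions from a YAML manifest.

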