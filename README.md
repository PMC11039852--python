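# phenophylo

Tools for asking whether the **spring phenology** of woody plants — the
day of year a species first unfolds leaves (FLD) or first flowers (FFD),
and how strongly those dates respond to preseason temperature and
precipitation — is **phylogenetically conserved**: do closely related
species behave more alike than chance predicts, and which evolutionary
model best describes the trait's history on the tree?

The package is aimed at comparative ecologists working with long-term
station phenology records (decades of yearly FLD/FFD observations per
species), daily weather series, and a dated phylogeny of the observed
species. It implements the complete analysis chain as a tested Python
library with a CLI, plus a synthetic-data generator that produces every
input with known ground truth, so the whole chain can be validated end to
end.

## What it computes

**Blomberg's K with a permutation test.** For a trait vector *x* on a
tree with Brownian covariance *C* (shared root-to-ancestor path lengths),

    K = (MSE0 / MSE) / E[MSE0 / MSE]

where MSE0 is the trait variance about the phylogenetically (GLS) estimated
mean, MSE the variance after whitening by *C*, and the denominator the
Brownian expectation of that ratio on this tree. K = 1 matches Brownian
motion; K < 1 weaker, K > 1 stronger resemblance among relatives.
Significance comes from shuffling trait values across tips (default 1000
permutations) and asking how often the shuffled GLS error is as small as
observed.

**Evolutionary-model selection.** Maximum-likelihood fits of white noise
(WN, phylogeny-free), Brownian motion (BM, covariance σ²C), and
Ornstein-Uhlenbeck (OU, drift with pull α toward an optimum; BM is the
α → 0 boundary) are compared by AIC = −2 logL + 2k and Akaike weights
w_i ∝ exp(−Δᵢ/2).

**PSR curves.** Phylogenetic eigenvector regression: the squared patristic
distance matrix is double-centered (Gower) and eigen-decomposed; the trait
is regressed on the first k eigenvectors and the R² is plotted against the
cumulative eigenvalue fraction. A Brownian trait tracks the 45° line; a
phylogeny-free trait rises like k/m. Monte-Carlo BM and WN envelopes give
pointwise null bands, and the signed area to the 45° line summarizes the
tempo of evolution.

**Preseason climate sensitivity.** For each species the preseason is the
window of L days (L = 1…120) ending the day before the long-term mean
phenophase date whose mean temperature (or precipitation) best correlates
(highest |r|) with the year-to-year phenophase dates; the sensitivity is
the OLS slope in days/°C (or days/mm).

**PGLS.** Generalized least squares with error covariance *C* (optionally
Pagel-λ scaled) regresses each phenological trait on plant functional
traits — life form (tree/shrub), pollination (biotic/abiotic), leaf habit
(evergreen/deciduous) — with fixed reference levels (shrub, biotic,
deciduous) so coefficient signs are reproducible.

## Worked example

Generate a synthetic 24-species station (50-year climate, Brownian
baseline dates, a +10-day leaf-out offset for trees, true preseason 30
days at −3 days/°C) and analyze it:

```python
import json
from phenophylo import synthetic_data as sd, pipeline

cfg = sd.SyntheticConfig(seed=7, n_species=24, years=(1995, 2018))
sd.simulate_station(cfg).write("demo")
conf = dict(station="demo", tree="tree.nwk", phenology="phenology.csv",
            climate="climate.csv", functional_traits="functional_traits.csv",
            min_years=20, n_permutations=999, psr_n_sim=100, seed=1)
json.dump(conf, open("demo/config.json", "w"))

rep = pipeline.run_station(pipeline.StationConfig.from_file("demo/config.json"))
print(rep.table1[["trait", "K", "P", "AIC_BM", "AIC_OU", "AIC_WN",
                  "selected", "psr_area"]].round(4).to_string(index=False))
```

```
    trait      K     P   AIC_BM   AIC_OU   AIC_WN selected  psr_area
      FLD 1.6276 0.001 167.7082 169.7082 196.6073       BM    0.0562
      FFD 0.5889 0.003 166.0685 166.2084 172.4449       BM   -0.2319
  FLD-S_T 0.3516 0.050  52.2628  45.0337  46.8581       OU   -0.3978
  FFD-S_T 0.4472 0.015  50.5303  47.8583  49.6535       OU   -0.2663
FLD-S_Prc 0.1686 0.625 123.0832 101.3470  99.2991       WN   -0.4276
FFD-S_Prc 0.5435 0.007  94.9875  92.3308  98.6767       OU   -0.2470
```

The phenophase dates, generated with a Brownian phylogenetic component,
show significant signal (P ≤ 0.003) and select BM; the derived
sensitivity traits carry weaker signal, and the near-zero precipitation
sensitivity (FLD-S_Prc) behaves like white noise. The PGLS life-form rows
recover the injected tree-vs-shrub offset in leaf-out:

```
functional_trait phenological_trait  coefficient  p_value
       life_form                FLD       6.0434   0.0372
       life_form                FFD       3.9039   0.1758
       life_form            FLD-S_T       0.0306   0.9114
       ...
```

(coefficient = days by which trees differ from the shrub reference).

The same analysis is available from the shell:

```
phenophylo make-fixture --config gen.json --seed 7 --out demo/
phenophylo run --config demo/config.json --out results/
phenophylo signal --tree demo/tree.nwk --trait trait.csv --permutations 999
```

`run` writes `table1.csv` (per-trait K, P, AICs, weights, selected model,
PSR area), `table2.csv` (PGLS coefficients and P per functional trait),
`sensitivities.csv` (per-species preseason and slopes), `psr_curves.csv`,
`summaries.csv` (group means/medians/ranges) and `report.json`.

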