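# nichediv

Phylogenetically structured niche-diversification analysis: does
competition for niche space bound species accumulation within clades, or
does niche evolution keep diversification unbounded?

`nichediv` implements a complete pipeline for asking that question with
physiological niches inferred from occurrence data:

1. **Process-based SDM.** A two-compartment (shoot/root) carbon–nitrogen
   plant growth model in the transport-resistance tradition runs on
   monthly environmental forcings (tmin/tmean/tmax, soil moisture,
   radiation, soil N). Resource uptake and growth are limited by
   piecewise-linear response curves; the 24 curve breakpoints are the
   species' *niche traits*. Occurrence probability is the complementary
   log-log of equilibrium biomass, `p_i = 1 − exp(−exp(b₀ + b₁·B_i))`,
   and the 26 free scalars are estimated from presences plus balanced,
   environment-stratified pseudoabsences by differential evolution on
   the Bernoulli likelihood.
2. **Clade metrics.** Clades are defined by tree topology or by a time
   slice (default 33.9 Ma). Per clade: crown age; richness; *clade niche
   size* (mean potential-range union over random fixed-size species
   subsamples); *niche evolution rate* (trace of the contrast-based
   Brownian-motion rate matrix of the niche traits on the clade
   subtree); and the *clade competition index* — the mean over
   within-clade species pairs of rescaled Schoener's D times geographic
   overlap, with a tip-shuffle permutation test of its size-independence.
3. **Comparative statistics.** Felsenstein contrasts, Pagel's λ (ML +
   boundary-halved LRT), Blomberg's K (tip-randomization test),
   phylogenetically corrected PCA for trait selection, PGLS, and
   node-level rate contrasts with ANOVA/Tukey HSD.
4. **Bayesian path analysis.** A fixed a-priori DAG
   (cci→evo, cci→size, evo→size, cci→rich, evo→rich, size→rich,
   age→rich) is fit as three structural regressions with residuals
   ~ MVN(0, σ²V), V the clade-tree Brownian covariance; Gibbs-within-
   Metropolis sampling, diffuse Normal(0, 10²) coefficient priors.
   Total effects are direct effects plus the sum over directed paths of
   edge-coefficient products, computed per posterior draw.

Because the pipeline's empirical inputs are not redistributable, a
first-class synthetic-data module (`nichediv.synthdata`) generates every
input with known truth — birth–death trees (GSA-conditioned), BM traits,
autocorrelated environmental fields, suitability-sampled occurrences,
and path-model datasets — so every stage is recovery-testable.

## Worked example

```python
import numpy as np
from nichediv import synthdata, path_model

scen = synthdata.make_path_scenario(n_clades=100, seed=3)
design, truth = synthdata.simulate_path_dataset(scen)
phylo = path_model.clade_tree_vcv(scen.tree)
fit = path_model.fit_path(
    design, scen.dag, phylo,
    mcmc={"chains": 2, "iterations": 1000, "burnin": 1000, "thin": 1},
    seed=0,
)
te, _ = path_model.total_effects(fit)
print(te[["parameter", "mean", "sd", "significant"]])
print("generating totals:", truth["total_effects"])
```

prints

```
  parameter      mean        sd  significant
0       age -0.230643  0.047257         True
1       cci -0.837201  0.045922         True
2       evo  0.470735  0.125729         True
3      size -0.291682  0.111378         True
generating totals: {'age': -0.21, 'cci': -0.8500000000000001, 'evo': 0.6100000000000001, 'size': -0.3}
```

i.e. at 100 clades the sampler recovers the generating total effects: a
strong negative effect of within-clade competition on richness (bounded
signal), a positive effect of niche evolution rate (unbounded signal),
and negative clade-age and niche-size effects.

The full narrative analysis lives under `analysis/` as numbered scripts
(`01_simulate_dataset.py` … `06_path_analysis.py`); each prints what it
found and writes its tables under `results/`.

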