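# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of `nichediv`.

## The plant growth model and its niche traits

The species distribution model is process-based: occupancy derives from
a plant's modelled carbon economy rather than from a statistical
response surface. The canonical discrete form used here tracks four
pools — shoot carbon `Cs`, root carbon `Cr`, shoot nitrogen `Ns`, root
nitrogen `Nr` — updated once per month:

```
growth  = uc · fG · fC · Cs/(1+Cs) · Ns/(kn+Ns)
uptakeN = un · fN · Cr/(1+Cr) · max(0, 1 − Nr/nmax)
TC = tc·(Cs−Cr)          TN = tn·(Nr−Ns)
Cs += growth − TC − resp·fG·Cs          Cr += TC − resp·fG·Cr
Ns += TN − q·growth                     Nr += uptakeN − TN
```

with all pools clipped at zero. `fC`, `fN`, `fG` are products of
piecewise-linear limitation multipliers of the monthly forcings: carbon
gain is limited by tmin (increasing step), tmean (trapezoid), tmax
(decreasing step), soil moisture (trapezoid) and radiation (step);
nitrogen uptake by tmean (step), soil moisture (trapezoid) and soil N
(step); growth and respiration share one temperature step. That is
9 curves and 24 breakpoints; the breakpoints are the species' niche
traits. Biomass formation needs carbon *and* shoot nitrogen (the
`Ns/(kn+Ns)` factor), transport resistance couples the compartments,
and respiration scales with the same temperature multiplier as growth,
so a site that is too cold for growth is also metabolically inert
rather than a sink.

Structure to note: growth saturates (≤ `uc` per month) while
respiration is linear in the pools, so equilibrium biomass exists and
is bounded by `uc/resp`; it is non-decreasing in any limitation
multiplier (verified by dominance sweeps in the tests). *Equilibrium*
means annual cycles repeated until the relative change of shoot+root
carbon between successive years falls below `tol = 1e-4`, capped at 200
years (fitting uses a shorter spin-up, see below). The kinetic
constants (`uc=1, un=0.5, tc=tn=0.1, resp=0.05, kn=0.2, q=0.2, nmax=5`,
initial pools 0.1) are conventions of this implementation: they set the
biomass scale and time-to-equilibrium, not the niche geometry, and are
exposed in `TTRConfig`.

Occupancy follows a complementary log-log link of biomass,
`p = 1 − exp(−exp(b0 + b1·B))` with `b1 ≥ 0`, taken linearly in
biomass — the simplest faithful reading of a cloglog-of-biomass
occurrence model. The likelihood is Bernoulli over presence and
pseudoabsence sites, probabilities clipped at 1e-12.

### Fitting

The 24 breakpoints plus (b0, b1) are estimated by differential
evolution. Two numerical choices matter:

- **Increment reparameterization.** Each curve is encoded as (first
  breakpoint, non-negative increments), so breakpoint ordering is
  enforced by the box constraints themselves rather than by penalties.
- **Feasible initialization.** A uniform draw over the box almost
  surely sets some limitation multiplier to zero at every site, landing
  the whole population on the flat "no biomass anywhere" likelihood
  plateau. The initial population therefore places breakpoints at
  random quantiles of the *observed* forcing distributions with
  plateaus overlapping the data, so initial members already produce
  spatially varying suitability. This is domain knowledge, not
  tuning: it uses only the fitting data.

Fitting defaults (popsize multiplier 12, ≤120 generations, 40-year
spin-up with a 1e-3 equilibrium tolerance) keep one 400-site fit in the
low minutes on one CPU; the best-member likelihood trace is recorded
and is non-increasing by construction (`updating="deferred"`).

## Occurrence handling

Cleaning removes exact duplicate coordinates and rejects records whose
reported altitude differs from the grid reference by more than 300 m
(the tolerance is a parameter). Rejected records are *reported, not
repaired*: replacing them with nearby estimates is a judgement call an
automated pipeline should not make silently.

Environmental zones are CLARA-style k-medoids (PAM with greedy BUILD
and best-improvement SWAP on random subsamples, candidate medoid sets
scored on the full grid) over all 72 z-standardized monthly forcing
layers. Pseudoabsences are balanced (one per presence), stratified as
evenly as the eligible cells allow across the zones, excluded from a
0.25° buffer around presences — distances are great-circle central
angles in degrees of arc, since a planar reading of "degrees" would
vary with latitude — and restricted to realms containing at least one
presence (realms generalize to any categorical mask; absent a mask the
grid is one realm).

## Projection and niche size

Projected occupancy is `p ≥ 0.5` *and* membership of an environmental
zone present in the species' occurrence records; the latter keeps
predictions inside the data domain of the fit. The 0.5 rule matches
the confusion-matrix convention used in evaluation; it is a choice, as
no principled occupancy rule follows from the model itself. Range size
can be counted in geographic space or in a resampled environmental
space (50 zones × 1000 locations by default, sampled with replacement
so small zones can supply their quota) in which every zone is equally
common; resampled locations are real grid cells, so the within-zone
covariance of the forcings is preserved.

## Clade metrics

- **Clade definitions.** Time-slice clades are the lineages crossing a
  fixed age (default 33.9 Ma); singletons are dropped with a report,
  since overlap and rate metrics are undefined for one species. A
  topology-based partition can be supplied as an explicit clade table —
  it encodes taxonomic judgement no algorithm should fake. Note the
  degenerate corner: a slice younger than a cherry's crown yields two
  singletons, so the smallest tree with a non-trivial slice partition
  has three tips.
- **Clade niche size** is the mean, over random `m`-species subsamples
  (default `m` = smallest clade richness; 10 000 replicates, or
  exhaustive enumeration when there are few subsets), of the union of
  the subsample's occupancy sets. Subsampling removes the mechanical
  richness → range-union correlation.
- **Niche evolution rate** is the trace of the Brownian rate matrix
  estimated from normalized independent contrasts on the clade subtree
  (`R̂ = N⁻¹ Σ u uᵀ`); univariate mode (for clades near the trait-count
  limit) uses the single top-ranked trait.
- **Clade competition index**: Schoener's D is computed between
  *probability* surfaces (each normalized to sum 1), min–max rescaled
  over the species-pair matrix (both raw and rescaled are emitted);
  geographic overlap is 1 minus the min–max-normalized mean cross-record
  great-circle distance (haversine, R = 6371 km); pairwise competition
  is their product and the clade value the mean over unordered
  within-clade pairs. By linearity of expectation the index is
  size-unbiased under random species-to-clade assignment; the
  permutation test verifies this by regressing tip-shuffle null means
  on clade richness (10 000 shuffles by default).

## Comparative statistics

Pagel's λ scales the off-diagonal shared path lengths; the ML search
runs on [0, λ_max] with λ_max the positive-definiteness bound (a cap at
1 is available). The LRT against λ = 0 uses the boundary-halved χ²(1)
p-value. Blomberg's K uses the standard MSE₀/MSE ratio normalized by
its Brownian expectation; significance comes from tip-label
randomization with `p = (#{|K_perm| ≥ K_obs} + 1)/(n_sim + 1)`,
1000 randomizations by default. Trait selection uses phylogenetically
corrected PCA (GLS-centred cross-products under BM): PCs kept to 94%
cumulative variance, candidate traits with |loading| > 0.3 on a kept
PC, ranked by variance-share-weighted loadings, and pruned of
collinear pairs at |r| > 0.8 — a numeric stand-in for reading vector
plots by eye. PGLS goes through statsmodels GLS with the BM tree
covariance; richness enters log-transformed and the competition index
and evolution rate square-root-transformed where the analysis calls
for it. Node-level rate comparisons log-transform per-clade univariate
rates, rescale them by independent contrasts on the clade tree, and
compare terminal nodes (internal nodes with a tip child) by one-way
ANOVA with Tukey-HSD pairwise contrasts.

## Path model

Variables: clade age, competition index, evolution rate, niche size,
richness; the DAG is fixed a priori (cci→evo, cci→size, evo→size,
cci→rich, evo→rich, size→rich, age→rich). Richness is log-transformed
and divided by its maximum ("relative" richness read as
divide-by-maximum; z-scoring makes the alternative divide-by-total
differ only in a constant); all variables are z-scored. Residuals of
each structural equation are MVN(0, σ²V) with V the clade-tree
Brownian covariance (clade tips sit at their crown ages, so V is
generally non-ultrametric; it is used as-is with a warning).

Priors: diffuse Normal(0, 10²) on standardized-scale coefficients —
reading "normal uninformed priors" — and half-normal(2.5) on each
equation's σ (one σ per equation; a shared σ is equally defensible but
less flexible). The sampler whitens each equation once with the
Cholesky factor of V, then alternates a conjugate Gibbs draw of the
coefficient block with a random-walk Metropolis step on log σ; chains
are vectorized. Reference settings follow the literal schedule of
3 chains × 15 000 kept iterations after 25 000 burn-in, thinned by 5;
recovery experiments and the acceptance script use shorter chains
(2 × 1500/1500), which posterior means are insensitive to at the
problem sizes used. Convergence is split-R̂ < 1.1 (arviz), reported per
parameter; an edge is "significant" iff its 95% credible interval
excludes zero. Total effects are computed per posterior draw by
enumerating directed paths; the matrix identity `(I − B)⁻¹ − I` serves
as the algebraic oracle in the tests.

## Synthetic study conditions

The generators define the conditions under which the pipeline is
verified:

- **Trees**: birth–death conditioned on tip count via GSA sampling
  (dendropy), avoiding the bias of stopping at the n-th speciation;
  rescaling to a fixed crown age (300 Myr for the assemblage, deep
  enough for a time-slice partition at 33.9 Ma).
- **Traits**: multivariate BM sampled exactly from
  N(root, R ⊗ V) via matrix square roots.
- **Environment**: each layer is white noise convolved with an
  exponential kernel `exp(−d/range)` (range 5 cells by default),
  combined with a shared seasonal cycle; tmin/tmax are tmean minus/plus
  positive offset fields, so the ordering holds by construction. Grid
  cells are 0.25° — a convenience default, as no resolution is implied
  by the science. Monthly soil N is constant within a year.
- **Occurrences** are drawn with probability proportional to the
  species' modelled suitability (with replacement — duplicate records
  are what the cleaning step exists for).
- **Path datasets** draw exogenous variables from the clade-tree
  correlation (V normalized to unit diagonal so the standardized scale
  is coherent) and build endogenous variables from the structural
  equations, residual sd 0.4. The default coefficients are chosen so
  the implied total effects are cci −0.85, evo +0.61, age −0.21 with a
  negative niche-size effect — the strong-competition /
  positive-evolution configuration of the 10-clade-scale analysis.

**The SDM recovery condition deserves its own paragraph.** The
false-negative benchmark is only meaningful when the generating species
gives it a chance: if a species' suitability is diffuse and covers most
of the grid, (a) probability-proportional presences fall on marginal
cells, so even the *true* parameters classify >10% of presences as
absent, and (b) most balanced pseudoabsences land on genuinely suitable
cells, poisoning the labels. The recovery experiment therefore uses a
restricted-range specialist: envelope breadth 0.12 of the forcing span
and a steep link (b0 = −6, b1 = 1.5), giving ≈20% prevalence, a
decisive occupancy surface (p crosses 0.5 sharply), roughly 10%
pseudoabsence contamination, and a true-parameter held-out
false-negative rate ≈0.03. This mirrors empirical practice, where
species occupy small fractions of a global grid. With a diffuse
generalist instead, the benchmark fails for the truth itself — a
property of presence-only designs, not of the estimator.

What passing these tests does *not* show about real data: the
generators share the model family with the estimators (no model
misspecification), forcings carry no measurement error, occurrence
records have no spatial sampling bias, and the environment is
stationary. Real-data performance degrades with all four.

## Problem sizes

Verification experiments are sized for a single CPU: 200-tip trees with
60–100 replicates for estimator calibration, 200-clade path recoveries
over 8–20 seeds with 2 × 1500/1500 chains, a 50 × 50 grid with 200 + 200
sites for the SDM recovery, 600–4000 permutation replicates for the
competition null. These are the package's documented study sizes; all
scale up linearly through the public parameters.

## Known limitations

- The growth recursion is a canonical discrete form of a
  transport-resistance model, not a reproduction of any published
  parameterization; its kinetic constants are conventions.
- Between-clade competition is not modelled; the competition index is
  a within-clade quantity and underestimates total competitive load.
- The multivariate rate estimator needs richness > trait count; it
  falls back to univariate with a warning rather than regularizing.
- The MCMC sampler is generic Gibbs-within-Metropolis; it is adequate
  for these linear-Gaussian structures but makes no claim of
  efficiency on stiff posteriors.
- Diversification-rate-through-time analysis is out of scope; existing
  specialized tools cover it.
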