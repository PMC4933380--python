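# Methods note

This note records what the package computes, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices. All quantitative statements here are computed by the
test suite or by `scripts/acceptance.py`.

## 1. Model class

A model is a deterministic mass-action-style ODE system

```
dy/dt = S v(y, k),
```

with species vector `y`, stoichiometry `S`, rate laws `v` given as symbolic
expressions in species and parameters, reference rate constants `k*`, and
a set of stimulation conditions, each an override of initial
concentrations (and optionally parameters) plus an integration horizon
`T_c`. Rate laws may be arbitrary closed-form expressions (mass action,
Michaelis–Menten, Hill); events, assignment rules, and stochastic terms
are out of scope, and the SBML reader rejects documents containing them
rather than silently misreading the model.

## 2. Influence of a rate constant

Forward sensitivities `S_ij = d y_i / d k_j` are obtained by integrating
the sensitivity ODE

```
dS/dt = J_y S + J_k,   S(0) = 0,
```

jointly with the states, where `J_y` and `J_k` are the Jacobians of the
right-hand side with respect to species and parameters (generated
symbolically and compiled once per model; conditions and perturbed
parameter sets reuse the compilation). The influence is

```
kappa_j^2 = sum_c sum_i (1/T_c) integral [ S_ij(t) k_j / y_i,max ]^2 dt,
```

with `y_i,max` the maximum of species `i` over the union of all
conditions. Species with `y_i,max = 0` never move and are excluded;
`k_j = 0` gives `kappa_j = 0` directly. The finite-perturbation variant
replaces `S_ij` with the central difference
`[y(k_j(1+delta)) - y(k_j(1-delta))] / (2 delta k_j)` at `delta = 0.25`.

Checked properties (tests): the linear-decay model `dy/dt = -ky` matches
its closed form `kappa = sqrt(0.25 - 1.25 e^-2)` to 6 digits;
sensitivities match central differences to ≤1e-4 relative on ≤10-species
cascades; kappa is invariant to rescaling species concentrations and to
the units in which a rate constant is expressed; duplicating a condition
scales kappa by sqrt(2).

## 3. Domain influence and model-derived covariates

Domains map to the rate constants of reactions they mediate (a table of
(protein, domain, parameter) rows; a parameter may serve several domains,
as when a binding constant belongs to both interface domains). Domain
influence is the geometric mean of the domain's kappa values; a zero
kappa yields `D = 0` (logged, not floored), since it marks a genuinely
inert direction.

Model-derived covariates: protein abundance is the sum of initial
concentrations over all species forms of the protein (complexes count
once per member). The domain graph links two domains when some reaction's
rate law uses parameters of both; degree and normalized betweenness
(Brandes, fractional credit for tied shortest paths, normalization
`(n-1)(n-2)/2`) are computed on it, and the same statistics apply to
external protein-level edge lists.

## 4. Statistics layer

Per network, associations are Spearman rank correlations (mid-ranks for
ties), rank-biserial correlations `2 U1/(n1 n0) - 1` when one variable is
binary (essentiality), and partial Spearman-type correlations via OLS
residuals on the controls, all with listwise deletion. Across K networks,
correlations `r_i` with sample sizes `n_i` are combined by sample-size
weighting:

```
rho0_hat   = sum n_i r_i / sum n_i
sigma_r^2  = sum n_i (r_i - rho0_hat)^2 / sum n_i
sigma_e^2  = sum [ n_i (1 - r_i^2)^2 / (n_i - 1) ] / sum n_i
sigma_rho  = sqrt(max(0, sigma_r^2 - sigma_e^2))
SE         = sigma_r / sqrt(K),  CI95 = rho0_hat ± 1.96 SE.
```

Significance uses within-network permutations at three exchangeability
levels — rate-constant influences (D rebuilt from permuted kappa),
domain-level covariates, and protein-level covariates (domains of one
protein keep identical values) — with the weighted mean as statistic and
the two-sided p-value reported as `< 1/N_perm` when no permuted value is
as extreme. Partial correlations use residual permutation (one residual
vector permuted against the other). Domains modeled in several networks
are handled by a randomization that retains each shared domain in exactly
one uniformly chosen network per replicate and reports median and 5th/95th
quantiles of the re-estimated statistics.

## 5. Synthetic generators: what they emulate

**Cascade generator.** A ligand–receptor tier (`L + R <-> LR`) followed by
`n_tiers` kinase tiers; each tier's substrate binds the upstream active
species, is phosphorylated in the complex, and dephosphorylated when free
(mass action throughout, so protein mass is conserved, which the tests
assert). Defaults and rationale:

- `n_tiers = 3` gives a 14-rate-constant model; `n_tiers = 2` gives the
  10-parameter model used in the finite-vs-differential check.
- `dose_factors = (0.2, 1.0, 5.0)`: three ligand doses from
  sub-saturating to saturating. Multi-condition stimulation mirrors how
  such models are fit in practice and is load-bearing: with a single
  condition, several rate constants have nearly tied kappa and the
  differential vs ±25% rankings can swap a near-tied pair.
- `log10_rate_spread = 0.5`: rate constants drawn within ±~1.5 decades,
  wide enough for a non-degenerate influence ranking, narrow enough that
  trajectories remain well scaled.
- `horizon = 20`, `total_protein = 1`: the cascade reaches
  quasi-steady-state within the horizon at these scales.
- Binding constants are annotated to both interface domains, which is
  what creates edges in the domain graph.

**Population generator.** Emulates the random-effects model behind the
meta-analysis: each of `k_networks = 18` networks draws a true
correlation `rho_i ~ Normal(rho0, sigma_rho^2)` (defaults −0.25 and 0.15,
truncated to (−0.999, 0.999)); per-domain (omega, D) pairs come from a
Gaussian copula whose latent Pearson correlation `2 sin(pi rho_i / 6)`
targets a Spearman correlation of `rho_i` (verified to ±0.05 at
rho = −0.9, n = 500). Networks are generated protein-first: 8–25 proteins
with 1–3 domains each. The 8-protein floor matches the practice of
requiring at least eight distinct protein annotations per usable network
and keeps the six protein-level controls plus intercept full-rank in
partial-correlation designs. Protein-level covariates (codon bias B,
expression X, domain count d, codon usage C, essentiality E, growth
effect Gr) come from an exchangeable latent Gaussian
(`covariate_corr = 0.3`, which must exceed −1/5 for positive
semidefiniteness) transformed to realistic scales, constant across a
protein's domains; E is binarized at `essential_prevalence = 0.3`. With
`overlap_fraction > 0`, a fraction of domains is drawn from a pool shared
across networks: a shared domain keeps one omega everywhere (it is the
same gene), and a fraction `influence_consistency = 0.2` of its influence
variance is shared, giving moderate positive between-network influence
correlations rather than the structurally-zero agreement independent
draws would produce.

**Ensemble generator.** Stands in for posterior rate-constant ensembles
by log-normal jitter around `k*` (`log_jitter_sd` in natural-log units).
It does not emulate posterior correlations between rate constants; it
exists to exercise the ensemble-comparison machinery, for which only the
induced spread matters (agreement is verified to fall monotonically with
the jitter).

What the generators do **not** emulate: curated published networks,
real evolutionary-rate estimation (omega is consumed as a table),
expression/essentiality/interaction data processing, posterior sampling
of rate constants, and stochastic dynamics.

## 6. Numerical choices

- Integration: LSODA with `rtol = 1e-8`,
  `atol = 1e-10 * max(1, max y0)`; stiffness switching matters because
  binding constants can exceed catalytic ones by decades.
- Quadrature: trapezoid on a uniform grid of `n_grid = 512` points per
  condition (128 inside ensemble recomputation). Halving the grid changes
  kappa by <0.1% on the test cascades.
- Permutation nulls are vectorized (rank matrices times permutation index
  arrays); equality with the per-permutation loop is asserted in the
  tests. Permutation streams are keyed by (seed, model id, scheme) so
  results are independent of model ordering.
- p-values are never reported as 0; the floor is `1/N_perm`.

## 7. Limitations

- **Small-K confidence intervals.** The z-interval
  `rho0_hat ± 1.96 sigma_r / sqrt(K)` undercovers at K = 18: measured
  coverage at the population generator's defaults is ~0.91 over 2000
  replicates (0.906 over the 500 replicates of `scripts/acceptance.py
  --seed 1`). Roughly half the shortfall is the 1.96-vs-t_17 quantile
  plus the df-uncorrected weighted variance; the rest is finite-sample
  attenuation of per-network Spearman correlations. The estimator is kept
  as defined; the permutation tests, whose type-I error is ~5% (0.075 at
  seed 1, 0.035–0.055 at other audited seeds, n = 400), are the
  calibrated significance route. The corresponding acceptance test
  asserts the nominal 95%±3% band and fails honestly.
- The SBML reader covers a level-2/3 subset (species, parameters,
  reactions with content-MathML kinetic laws, local parameters hoisted);
  documents using events, rules, function definitions, initial
  assignments, or constraints are rejected.
- Sensitivities are local (at `k*`); the ensemble comparison is the
  provided remedy, and the ensemble itself must be supplied (or
  synthesized) — no posterior sampling is performed.
- The problem sizes in tests and the acceptance script (two-tier
  cascades, 18-network populations, 500/400 replicate counts) are this
  package's choices for desk-scale runtimes, not properties of any
  external dataset.
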