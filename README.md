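# netinflux

Dynamical influence of reaction rate constants and protein domains in ODE
models of biochemical networks, with a random-effects meta-analysis layer
for relating influence to evolutionary rates.

## What it computes

Signaling and metabolic networks are commonly modeled as mass-action ODE
systems. Not every rate constant matters equally for the dynamics: the
**influence** of rate constant `k_i` is defined as

```
kappa_i^2 = sum over conditions c, species y of
            (1/T_c) * integral_0^Tc [ (d y_c(t) / d k_i) * k_i / y_max ]^2 dt
```

evaluated at the model's reference rate constants. The `k_i` factor makes
kappa a logarithmic (unit-free) sensitivity; dividing by `y_max`, the
species' maximum over **all** conditions jointly, puts species on a common
scale; time-averaging over each condition's horizon `T_c` makes conditions
comparable. Species that never leave zero are excluded, and a rate constant
with reference value zero has kappa = 0.

Protein domains are mapped to the rate constants of the reactions they
mediate. The **domain influence** is the geometric mean

```
D_d = (prod over the domain's N_d rate constants of kappa_r)^(1/N_d),
```

appropriate because kappa values span orders of magnitude. A zero kappa
propagates to `D_d = 0`.

Per-network correlations between domain influence and per-domain covariates
(evolutionary rate omega = dN/dS, expression, knockout essentiality,
network degree/betweenness, ...) are combined across K networks by
sample-size-weighted (Hunter–Schmidt) random-effects meta-analysis, with
permutation tests at three exchangeability levels (rate constants, domains,
proteins) and a residual-permutation test for partial correlations.

The package provides six building blocks, importable from `netinflux`:

| area | contents |
| --- | --- |
| model I/O | native YAML model format, best-effort SBML subset reader, stimulation conditions, domain annotations, covariate tables |
| sensitivities | forward sensitivity ODEs (LSODA), influence kappa, finite ±25% perturbation variant |
| influence | domain influence D, key-species restriction, rate-constant-ensemble comparisons |
| network statistics | model-derived protein abundance, domain-graph degree and betweenness, protein edge lists |
| association statistics | Spearman / rank-biserial / partial correlations, Hunter–Schmidt meta-analysis, permutation and randomization tests |
| synthetic data | seeded generators for kinase cascades, multi-network covariate populations, and rate-constant ensembles |

## Worked example

```python
from netinflux.synth import CascadeSpec, make_cascade_network, PopulationSpec, make_meta_population
from netinflux.sensitivity import simulate_with_sensitivities, parameter_influence
from netinflux.influence import domain_influence
from netinflux.stats import meta_correlation, permutation_test

# a two-tier kinase cascade with 10 rate constants, stimulated at three ligand doses
net, annotation, conditions = make_cascade_network(CascadeSpec(n_tiers=2, seed=0))
trajectories = [simulate_with_sensitivities(net, c) for c in conditions]
kappa = parameter_influence(trajectories, net)
domains = domain_influence(kappa, annotation)
print(domains.table)

# a synthetic 18-network population with a planted omega/D rank correlation of -0.25
tables = make_meta_population(PopulationSpec(seed=0))
meta, per_model = meta_correlation(tables, ("omega", "D"))
print(f"rho0 = {meta}")
res = permutation_test(tables, ("omega", "D"), "domain_level", n_perm=10_000, seed=0)
print(f"permutation p = {res.pvalue_str}")
```

Output (deterministic at these seeds):

```
domain_id protein_id      D  N_d
    P0_LB         P0 0.5801    4
    P1_KB         P1 1.0353    6
    P2_KB         P2 0.9199    4
rho0 = -0.27 (-0.36, -0.17)
permutation p = <0.0001
```

The phosphorylation/dephosphorylation constants of the first kinase tier
carry the largest kappa (1.41 and 1.29), and the receptor's ligand-binding
domain is the least influential (D = 0.58). The meta-analysis recovers the
planted negative influence/evolutionary-rate association with a two-sided
permutation p-value below the 1/10000 resolution.

The same computations are exposed on the command line; see
`netinflux --help` and the subcommands `validate`, `influence`, `domains`,
`ensemble-compare`, `meta`, `synth`.

## Methods

Model definitions, parameter defaults and their rationale, numerical
choices, and the limitations of the synthetic generators are described in
[docs/methods.md](docs/methods.md).
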