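"""Synthetic fixtures: signaling cascades, covariate populations, ensembles.

Three generators, all seeded and deterministic:

* :func:`make_cascade_network` builds a mass-action ligand -> receptor ->
  kinase cascade (binding/unbinding plus phosphorylation/dephosphorylation
  per tier), a domain annotation partitioning each protein's rate
  constants among 1-3 domains, and a ligand-addition stimulation
  condition. Total protein mass is conserved along trajectories.

* :func:`make_meta_population` emulates the random-effects model behind
  the meta-analysis: each of K networks gets a true influence/rate
  correlation rho_i ~ Normal(rho0, sigma_rho^2) (truncated to (-1, 1)),
  and per-domain (omega, D) pairs are drawn through a Gaussian copula
  whose latent Pearson correlation 2 sin(pi rho_i / 6) targets a Spearman
  correlation of rho_i. Protein-level covariates (B, X, d, C, E, Gr) are
  drawn from a latent Gaussian with a configurable cross-correlation and
  transformed to realistic scales; they are constant across the domains
  of one protein, and E is binarized at a configurable prevalence.

* :func:`make_parameter_ensemble` stands in for posterior rate-constant
  ensembles by jittering reference values with log-normal factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import DomainAnnotation, validate_covariates
from .network import Parameter, Reaction, ReactionNetwork, Species, StimulationCondition


@dataclass
class CascadeSpec:
    """Parameters of the synthetic signaling cascade."""

    n_tiers: int = 3
    seed: int = 0
    ligand_stimulus: float = 1.0
    #: relative ligand doses defining the stimulation conditions, mirroring
    #: dose-response experiments with sub-saturating through saturating input
    dose_factors: tuple[float, ...] = (0.2, 1.0, 5.0)
    horizon: float = 20.0
    total_protein: float = 1.0
    #: multiplicative spread of the drawn rate constants (log10 scale)
    log10_rate_spread: float = 0.5

    def __post_init__(self) -> None:
        if self.n_tiers < 1:
            raise ValueError("n_tiers must be >= 1")


def make_cascade_network(
    spec: CascadeSpec | None = None, **kwargs
) -> tuple[ReactionNetwork, DomainAnnotation, list[StimulationCondition]]:
    """Build a mass-action signaling cascade with domains and a stimulus.

    Tier 1 is ligand-receptor binding L + R <-> LR. Each later tier t has
    an inactive substrate that binds the upstream active species
    (kinase-binding k3p/k3m), is phosphorylated in the complex (k2p) and
    dephosphorylated in free form (k2m). Those four rate constants are
    the canonical single-domain motif; the tier's domains partition them.
    """
    spec = spec or CascadeSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)

    def draw_k() -> float:
        return float(10 ** rng.normal(0.0, spec.log10_rate_spread))

    species: list[Species] = []
    params: list[Parameter] = []
    reactions: list[Reaction] = []
    ann_rows: list[dict] = []

    # receptor tier: L + R <-> LR, the active species that seeds the cascade
    species.append(Species("L", 0.0, protein_id="LIG"))
    species.append(Species("R", spec.total_protein, protein_id="P0"))
    species.append(Species("LR", 0.0, protein_id="LIG:P0"))
    params += [Parameter("k1p", draw_k()), Parameter("k1m", draw_k())]
    reactions.append(Reaction("bind_L", {"L": -1, "R": -1, "LR": +1}, "k1p*L*R"))
    reactions.append(Reaction("unbind_L", {"LR": -1, "L": +1, "R": +1}, "k1m*LR"))
    ann_rows += [
        {"protein_id": "P0", "domain_id": "P0_LB", "param_id": "k1p"},
        {"protein_id": "P0", "domain_id": "P0_LB", "param_id": "k1m"},
    ]
    upstream_active = "LR"
    upstream_protein = "P0"
    # the upstream domain a downstream substrate docks onto; binding rate
    # constants are annotated to BOTH interface domains (many-to-many)
    upstream_interface = "P0_LB"

    for t in range(1, spec.n_tiers + 1):
        prot = f"P{t}"
        a, astar = f"A{t}", f"A{t}p"
        cplx = f"A{t}_{upstream_active}"
        species += [
            Species(a, spec.total_protein, protein_id=prot),
            Species(astar, 0.0, protein_id=prot),
            Species(cplx, 0.0, protein_id=f"{prot}:{upstream_protein}"),
        ]
        k3p, k3m, k2p, k2m = (f"k3p_t{t}", f"k3m_t{t}", f"k2p_t{t}", f"k2m_t{t}")
        params += [Parameter(k3p, draw_k()), Parameter(k3m, draw_k()),
                   Parameter(k2p, draw_k()), Parameter(k2m, draw_k())]
        reactions += [
            Reaction(f"bind_t{t}", {a: -1, upstream_active: -1, cplx: +1},
                     f"{k3p}*{a}*{upstream_active}"),
            Reaction(f"unbind_t{t}", {cplx: -1, a: +1, upstream_active: +1},
                     f"{k3m}*{cplx}"),
            Reaction(f"phos_t{t}", {cplx: -1, astar: +1, upstream_active: +1},
                     f"{k2p}*{cplx}"),
            Reaction(f"dephos_t{t}", {astar: -1, a: +1}, f"{k2m}*{astar}"),
        ]
        # 1-3 domains per protein, partitioning its four rate constants;
        # the first kinase tier is always the canonical single
        # kinase-binding domain carrying all four
        n_dom = 1 if t == 1 else int(rng.integers(1, 4))
        tier_params = [k2p, k2m, k3p, k3m]
        if n_dom == 1:
            groups = [tier_params]
        elif n_dom == 2:
            groups = [[k2p, k2m], [k3p, k3m]]
        else:
            groups = [[k2p], [k2m], [k3p, k3m]]
        interface_dom = None
        for gi, group in enumerate(groups):
            dom = f"{prot}_KB" if len(groups) == 1 else f"{prot}_dom{gi + 1}"
            for p in group:
                ann_rows.append({"protein_id": prot, "domain_id": dom, "param_id": p})
            if k3p in group:
                interface_dom = dom
        # the binding reaction occurs at the interface of both proteins:
        # its rate constants also belong to the upstream docking domain
        for p in (k3p, k3m):
            ann_rows.append(
                {"protein_id": upstream_protein, "domain_id": upstream_interface, "param_id": p}
            )
        upstream_active = astar
        upstream_protein = prot
        upstream_interface = interface_dom

    net = ReactionNetwork(f"cascade{spec.n_tiers}_seed{spec.seed}", species, params, reactions)
    ann = DomainAnnotation(pd.DataFrame(ann_rows))
    ann.validate_against(net)
    conds = [
        StimulationCondition(f"ligand_x{f:g}", {"L": spec.ligand_stimulus * f}, spec.horizon)
        for f in spec.dose_factors
    ]
    return net, ann, conds


# ---------------------------------------------------------------------------
# random-effects covariate populations
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Parameters of the synthetic multi-network domain population."""

    k_networks: int = 18
    rho0: float = -0.25
    sigma_rho: float = 0.15
    #: proteins per network; the study's models all carried at least eight
    #: distinct protein annotations, and enough proteins keeps six
    #: protein-level controls full-rank in partial-correlation designs
    n_proteins_range: tuple[int, int] = (8, 25)
    #: domains per protein
    domains_per_protein: tuple[int, int] = (1, 3)
    seed: int = 0
    #: exchangeable latent correlation among protein-level covariates
    covariate_corr: float = 0.3
    essential_prevalence: float = 0.3
    #: fraction of domains drawn from a pool shared across networks
    overlap_fraction: float = 0.0
    shared_pool_size: int = 40
    #: cross-network correlation of the influence component not explained by
    #: omega, for shared domains; the default reproduces the moderate
    #: between-model agreement of influence estimates seen in practice
    influence_consistency: float = 0.2

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho0 <= 1.0:
            raise ValueError("rho0 must lie in [-1, 1]")
        if self.sigma_rho < 0:
            raise ValueError("sigma_rho must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        # latent covariate correlation matrix must be PSD: exchangeable
        # correlation c on m variables is PSD iff c >= -1/(m-1)
        m = 6
        if not -1.0 / (m - 1) < self.covariate_corr < 1.0:
            raise ValueError("covariate_corr yields a non-PSD latent correlation matrix")


def _truncated_normal_rho(rng, rho0: float, sigma: float) -> float:
    """Draw rho_i ~ Normal(rho0, sigma^2) truncated to (-0.999, 0.999)."""
    if sigma == 0:
        return float(np.clip(rho0, -0.999, 0.999))
    while True:
        val = rng.normal(rho0, sigma)
        if -0.999 < val < 0.999:
            return float(val)


def spearman_to_latent_pearson(rho_s: float) -> float:
    """Latent Gaussian Pearson correlation that yields Spearman rho_s."""
    return float(2 * np.sin(np.pi * rho_s / 6))


def make_meta_population(spec: PopulationSpec | None = None, **kwargs) -> dict[str, pd.DataFrame]:
    """Generate K per-network covariate tables with planted structure.

    Returns a dict model_id -> covariate table (domain_id, protein_id,
    omega, D, B, X, d, C, E, Gr). omega is on a positive dN/dS scale
    (log-normal, median about 0.1) and D on a positive log-normal scale
    spanning orders of magnitude; only ranks matter downstream.
    """
    spec = spec or PopulationSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    # a shared domain is the same gene in every network that models it:
    # its evolutionary-rate latent is fixed, and part of its influence
    # latent is fixed too, so different networks produce correlated D
    pool_z_omega = rng.standard_normal(spec.shared_pool_size)
    pool_e_infl = rng.standard_normal(spec.shared_pool_size)

    out: dict[str, pd.DataFrame] = {}
    for i in range(spec.k_networks):
        model_id = f"net{i + 1:02d}"
        rho_i = _truncated_normal_rho(rng, spec.rho0, spec.sigma_rho)
        p_lo, p_hi = spec.n_proteins_range
        n_prot = int(rng.integers(p_lo, p_hi + 1))
        d_lo, d_hi = spec.domains_per_protein
        sizes = rng.integers(d_lo, d_hi + 1, size=n_prot)
        prot_of_domain = np.repeat(np.arange(n_prot), sizes)
        n_i = int(sizes.sum())

        # which domains come from the shared pool
        n_shared = min(int(round(spec.overlap_fraction * n_i)), spec.shared_pool_size)
        picks = rng.choice(spec.shared_pool_size, size=n_shared, replace=False)

        # domain-level (omega, D) through the Gaussian copula:
        # z2 = r_lat z1 + sqrt(1 - r_lat^2) e, so (z1, z2) is standard
        # bivariate normal with latent Pearson correlation r_lat within the
        # network regardless of whether the domain is shared
        r_lat = spearman_to_latent_pearson(rho_i)
        z1 = rng.standard_normal(n_i)
        e = rng.standard_normal(n_i)
        if n_shared:
            z1[:n_shared] = pool_z_omega[picks]
            cc = spec.influence_consistency
            e[:n_shared] = np.sqrt(cc) * pool_e_infl[picks] + np.sqrt(1 - cc) * e[:n_shared]
        z2 = r_lat * z1 + np.sqrt(1 - r_lat**2) * e
        omega = np.exp(np.log(0.1) + 0.6 * z1)
        d_infl = np.exp(np.log(1e-2) + 1.5 * z2)

        # protein-level covariates from an exchangeable latent Gaussian
        c = spec.covariate_corr
        m = 6
        corr = np.full((m, m), c)
        np.fill_diagonal(corr, 1.0)
        latent = rng.multivariate_normal(np.zeros(m), corr, size=n_prot, method="cholesky")
        b_breadth = np.clip(np.round(30 + 12 * latent[:, 0]), 1, 60).astype(int)
        x_level = np.exp(5.0 + 1.0 * latent[:, 1])
        degree = np.round(np.exp(1.0 + 0.8 * latent[:, 2])).astype(int)
        between = 1.0 / (1.0 + np.exp(-(latent[:, 3] - 2.0)))  # small fractions in (0, 1)
        essential = (latent[:, 4] < np.quantile(latent[:, 4], spec.essential_prevalence)).astype(int)
        growth = np.clip(1.0 - 0.2 * np.exp(0.8 * latent[:, 5] - 1.0), 0.0, 1.0)

        dom_ids = [f"SHARED_dom{p}" for p in picks]
        dom_ids += [f"{model_id}_dom{j}" for j in range(n_i - len(dom_ids))]

        df = pd.DataFrame(
            {
                "domain_id": dom_ids,
                "protein_id": [f"{model_id}_prot{p}" for p in prot_of_domain],
                "omega": omega,
                "D": d_infl,
                "B": b_breadth[prot_of_domain],
                "X": x_level[prot_of_domain],
                "d": degree[prot_of_domain],
                "C": between[prot_of_domain],
                "E": essential[prot_of_domain],
                "Gr": growth[prot_of_domain],
            }
        )
        out[model_id] = validate_covariates(df)
    return out


def make_parameter_ensemble(
    net: ReactionNetwork,
    n_sets: int,
    log_jitter_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Stand-in rate-constant ensemble: log-normal jitter around k*.

    Returns a DataFrame indexed by set_id with one column per rate
    constant; write with ``df.reset_index().to_csv(path, sep="\\t")`` to
    get the ensemble TSV consumed downstream.
    """
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    rng = np.random.default_rng(seed)
    rate_ids = net.rate_constant_ids
    kstar = np.array([net.parameter_by_id(p).reference_value for p in rate_ids])
    factors = np.exp(rng.normal(0.0, log_jitter_sd, size=(n_sets, len(rate_ids))))
    values = kstar[None, :] * factors
    return pd.DataFrame(values, columns=rate_ids, index=pd.Index([f"set{i}" for i in range(n_sets)], name="set_id"))
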