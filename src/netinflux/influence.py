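"""Domain-level influence and rate-constant-ensemble comparisons.

The influence D_d of a protein domain is the geometric mean of the
influences kappa of the N_d rate constants for reactions the domain
participates in:

    D_d = (prod_r kappa_r)^(1/N_d).

A geometric mean is used because rate-constant sensitivities range over
orders of magnitude; a zero kappa propagates to D_d = 0 rather than being
floored, since a domain containing a dynamically inert rate constant
genuinely has a zero-influence direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import DomainAnnotation
from .network import ReactionNetwork
from .sensitivity import InfluenceTable, SensitivityTrajectory, parameter_influence
from .stats_core import spearman

logger = logging.getLogger(__name__)


@dataclass
class DomainInfluence:
    """Per-domain influence table: rows of (domain_id, protein_id, D, N_d)."""

    model_id: str
    table: pd.DataFrame  # columns: domain_id, protein_id, D, N_d

    def __post_init__(self) -> None:
        required = {"domain_id", "protein_id", "D", "N_d"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DomainInfluence table missing columns {sorted(missing)}")
        if (self.table["D"] < 0).any():
            raise ValueError("domain influence D must be >= 0")
        if (self.table["N_d"] < 1).any():
            raise ValueError("N_d must be >= 1")

    def as_series(self) -> pd.Series:
        return self.table.set_index("domain_id")["D"]


def domain_influence(infl: InfluenceTable, ann: DomainAnnotation) -> DomainInfluence:
    """Aggregate per-parameter kappa to per-domain D via the geometric mean.

    A rate constant annotated to several domains contributes its kappa to
    each of them independently.
    """
    rows = []
    zero_domains = []
    for dom in ann.domain_ids:
        params = ann.params_of_domain(dom)
        missing = [p for p in params if p not in infl.kappa]
        if missing:
            raise KeyError(f"domain {dom!r} references unscored parameters {missing}")
        kappas = np.array([infl.kappa[p] for p in params], dtype=float)
        if np.any(kappas == 0):
            d_val = 0.0
            zero_domains.append(dom)
        else:
            d_val = float(np.exp(np.mean(np.log(kappas))))
        rows.append({
            "domain_id": dom,
            "protein_id": ann.protein_of_domain(dom),
            "D": d_val,
            "N_d": len(params),
        })
    if zero_domains:
        logger.warning(
            "domains with a zero-influence rate constant get D = 0: %s", zero_domains
        )
    return DomainInfluence(infl.model_id, pd.DataFrame(rows))


def restrict_to_key_species(
    trajs: list[SensitivityTrajectory],
    net: ReactionNetwork,
    key_species: list[str],
) -> InfluenceTable:
    """Influence with the species sum restricted to the model's key species.

    y_max is still taken over all conditions for the listed species. With
    the full species list this reproduces the full computation exactly.
    """
    return parameter_influence(trajs, net, species=key_species)


@dataclass
class EnsembleInfluence:
    """Domain influences recomputed under an ensemble of rate-constant sets."""

    model_id: str
    parameter_sets: pd.DataFrame  # index set_id, one column per rate constant
    domain_tables: list[DomainInfluence]

    def __post_init__(self) -> None:
        if len(self.domain_tables) != len(self.parameter_sets):
            raise ValueError("one domain table per parameter set required")
        doms = [tuple(t.table["domain_id"]) for t in self.domain_tables]
        if len(set(doms)) > 1:
            raise ValueError("all ensemble members must score the same domains")

    def d_matrix(self) -> pd.DataFrame:
        """(set, domain) matrix of D values."""
        data = {i: t.as_series() for i, t in enumerate(self.domain_tables)}
        return pd.DataFrame(data).T


def compare_influence_ensembles(
    ens: EnsembleInfluence,
    n_pairs: int = 10_000,
    seed: int | np.random.Generator = 0,
    omega: pd.Series | None = None,
) -> dict:
    """Pairwise agreement of domain influences across an ensemble.

    Samples up to *n_pairs* distinct unordered pairs of parameter sets and
    returns their Spearman correlations of domain influence, the median,
    and — when an evolutionary-rate series *omega* (indexed by domain_id)
    is given — the fraction of sets whose influence/omega Spearman
    correlation is negative.
    """
    n_sets = len(ens.domain_tables)
    if n_sets < 2:
        raise ValueError("ensemble must contain at least two parameter sets")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    total = n_sets * (n_sets - 1) // 2
    if total <= n_pairs:
        pairs = [(i, j) for i in range(n_sets) for j in range(i + 1, n_sets)]
    else:
        seen: set[tuple[int, int]] = set()
        while len(seen) < n_pairs:
            draw = rng.integers(0, n_sets, size=(n_pairs, 2))
            for a, b in draw:
                if a == b:
                    continue
                pair = (min(a, b), max(a, b))
                seen.add(pair)
                if len(seen) == n_pairs:
                    break
        pairs = sorted(seen)

    dmat = ens.d_matrix().to_numpy()
    corrs = np.array([spearman(dmat[i], dmat[j]) for i, j in pairs])

    out = {
        "pair_correlations": corrs,
        "median_pair_correlation": float(np.median(corrs)),
        "n_pairs": len(pairs),
    }
    if omega is not None:
        dom_ids = list(ens.domain_tables[0].table["domain_id"])
        om = omega.reindex(dom_ids).to_numpy(dtype=float)
        keep = np.isfinite(om)
        per_set = np.array([spearman(dmat[i][keep], om[keep]) for i in range(n_sets)])
        out["omega_correlations"] = per_set
        out["fraction_negative_omega_correlation"] = float(np.mean(per_set < 0))
    return out


def load_parameter_ensemble(path) -> pd.DataFrame:
    """Read an ensemble TSV: set_id column plus one column per rate constant."""
    df = pd.read_csv(path, sep="\t")
    if "set_id" not in df.columns:
        raise ValueError("ensemble TSV must have a set_id column")
    return df.set_index("set_id")


def ensemble_influence(
    net: ReactionNetwork,
    conds,
    ann: DomainAnnotation,
    parameter_sets: pd.DataFrame,
    n_grid: int = 128,
) -> EnsembleInfluence:
    """Recompute domain influences for each rate-constant set in an ensemble."""
    from .network import StimulationCondition
    from .sensitivity import CompiledNetwork, simulate_with_sensitivities

    comp = CompiledNetwork(net)
    tables = []
    for set_id, row in parameter_sets.iterrows():
        overrides = {p: float(v) for p, v in row.items()}
        unknown = set(overrides) - set(net.parameter_ids)
        if unknown:
            raise KeyError(f"ensemble set {set_id!r} has unknown parameters {sorted(unknown)}")
        net_i = net.copy()
        net_i.parameters = [
            type(p)(p.id, overrides.get(p.id, p.reference_value), p.is_rate_constant)
            for p in net.parameters
        ]
        comp_i = CompiledNetwork(net_i)
        trajs = [simulate_with_sensitivities(comp_i, c, n_grid) for c in conds]
        infl = parameter_influence(trajs, net_i)
        tables.append(domain_influence(infl, ann))
    return EnsembleInfluence(net.model_id, parameter_sets, tables)
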