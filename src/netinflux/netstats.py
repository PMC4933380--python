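"""Model-derived covariates: abundance, domain-graph degree and betweenness.

Protein abundance inside a model is the sum of initial concentrations of
all species mapped to the protein, counting modified forms and complexes
(a complex contributes its concentration once to each member protein).

The model-derived interaction graph has one node per annotated domain and
an edge between two domains whenever some reaction has rate constants
annotated to both. Degree is the simple degree; betweenness is the
fraction of shortest paths between node pairs passing through a node,
normalized by (n-1)(n-2)/2 with standard Brandes fractional credit for
tied shortest paths. The same statistics apply to protein-level edge
lists from external interaction datasets.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import pandas as pd

from .annotations import DomainAnnotation
from .network import ReactionNetwork


def model_abundance(net: ReactionNetwork) -> dict[str, float]:
    """Per-protein abundance from species initial concentrations.

    Species carrying several protein ids (complexes, encoded as
    colon-separated ids like ``"A:B"``) add their concentration to every
    member protein. Species with no protein mapping are skipped with a
    warning.
    """
    out: dict[str, float] = {}
    unmapped = []
    for sp in net.species:
        if not sp.protein_id:
            unmapped.append(sp.id)
            continue
        for prot in str(sp.protein_id).split(":"):
            out[prot] = out.get(prot, 0.0) + sp.initial_concentration
    if unmapped:
        warnings.warn(f"species without protein mapping ignored: {unmapped}", stacklevel=2)
    return out


def build_domain_graph(ann: DomainAnnotation, net: ReactionNetwork) -> nx.Graph:
    """Domain graph: edge (d1, d2) iff some reaction involves both domains.

    A reaction "involves" a domain when one of its rate-law parameters is
    annotated to that domain.
    """
    ann.validate_against(net)
    laws = net.parsed_rate_laws()
    param_ids = set(net.parameter_ids)

    domains_of_param: dict[str, set[str]] = {}
    for _, row in ann.rows.iterrows():
        domains_of_param.setdefault(row["param_id"], set()).add(row["domain_id"])

    g = nx.Graph()
    g.add_nodes_from(ann.domain_ids)
    for rxn in net.reactions:
        used = {str(s) for s in laws[rxn.id].free_symbols} & param_ids
        doms: set[str] = set()
        for p in used:
            doms |= domains_of_param.get(p, set())
        for d1, d2 in combinations(sorted(doms), 2):
            g.add_edge(d1, d2)
    return g


def degree_and_betweenness(g: nx.Graph) -> pd.DataFrame:
    """Simple degree and normalized betweenness centrality per node.

    Betweenness uses Brandes' algorithm with fractional credit for
    equal-length shortest paths, normalized by (n-1)(n-2)/2 so values lie
    in [0, 1]; disconnected pairs contribute nothing.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=g.number_of_nodes() > 2)
    return pd.DataFrame(
        {"node_id": list(g.nodes), "degree": [deg[v] for v in g.nodes], "betweenness": [btw[v] for v in g.nodes]}
    )


def load_edge_list(*sources) -> nx.Graph:
    """Read protein-level 2-column TSV edge lists, union and deduplicate.

    Self-loops are dropped; multiple datasets are merged into one simple
    undirected graph before computing degree and betweenness.
    """
    g = nx.Graph()
    for src in sources:
        df = pd.read_csv(src, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{src}: edge list needs two columns")
        for a, b in df.iloc[:, :2].itertuples(index=False):
            if a == b:
                continue
            g.add_edge(a, b)
    return g
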