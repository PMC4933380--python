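"""Domain annotations and per-domain covariate tables.

A :class:`DomainAnnotation` maps reaction rate constants to the protein
domains at which the corresponding reactions occur. The mapping is
many-to-many: a rate constant may be assigned to several domains (e.g. a
reaction at a two-protein interface) and a domain typically collects
several rate constants.

The covariate table carries, per domain, the quantities correlated with
dynamical influence downstream: evolutionary rate dN/dS (omega),
expression breadth B and level X, interaction degree d, betweenness C,
knockout essentiality E, and knockout growth rate Gr. All protein-level
columns must be constant across the domains of one protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .network import NetworkValidationError, ReactionNetwork

#: covariate columns defined at the protein level (shared by a protein's domains)
PROTEIN_LEVEL_COLUMNS = ("B", "X", "d", "C", "E", "Gr")
#: all recognised covariate columns, domain-level first
COVARIATE_COLUMNS = ("omega", "D") + PROTEIN_LEVEL_COLUMNS


class CovariateError(ValueError):
    """A covariate table violates its structural contract."""


@dataclass
class DomainAnnotation:
    """Rows of (protein_id, domain_id, param_id)."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["protein_id", "domain_id", "param_id"]))

    def __post_init__(self) -> None:
        required = {"protein_id", "domain_id", "param_id"}
        missing = required - set(self.rows.columns)
        if missing:
            raise NetworkValidationError(f"annotation missing columns: {sorted(missing)}")
        dup = self.rows.duplicated(subset=["domain_id", "param_id"])
        if dup.any():
            warnings.warn(
                f"annotation contains {int(dup.sum())} duplicate (domain, param) rows; deduplicating",
                stacklevel=2,
            )
            self.rows = self.rows.loc[~dup].reset_index(drop=True)

    @property
    def domain_ids(self) -> list[str]:
        return sorted(self.rows["domain_id"].unique())

    def params_of_domain(self, domain_id: str) -> list[str]:
        sub = self.rows.loc[self.rows["domain_id"] == domain_id, "param_id"]
        if sub.empty:
            raise KeyError(domain_id)
        return list(sub)

    def protein_of_domain(self, domain_id: str) -> str:
        sub = self.rows.loc[self.rows["domain_id"] == domain_id, "protein_id"]
        return str(sub.iloc[0])

    def n_d(self, domain_id: str) -> int:
        """Number of rate constants assigned to the domain (N_d >= 1)."""
        return len(self.params_of_domain(domain_id))

    def validate_against(self, net: ReactionNetwork) -> None:
        declared = set(net.parameter_ids)
        unknown = set(self.rows["param_id"]) - declared
        if unknown:
            raise NetworkValidationError(
                f"annotation references unknown parameters: {sorted(unknown)}"
            )
        for dom in self.domain_ids:
            if self.n_d(dom) < 1:
                raise NetworkValidationError(f"domain {dom!r} has no parameters")


def load_domain_annotation(source, net: ReactionNetwork | None = None) -> DomainAnnotation:
    """Read a (protein_id, domain_id, param_id) TSV; validate against *net* if given."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    ann = DomainAnnotation(df)
    if net is not None:
        ann.validate_against(net)
    return ann


def save_domain_annotation(ann: DomainAnnotation, path) -> None:
    ann.rows.to_csv(path, sep="\t", index=False)


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Check the structural contract of a per-domain covariate table.

    Requires domain_id and protein_id; tolerates any subset of the
    covariate columns; enforces protein-level constancy and omega >= 0.
    """
    required = {"domain_id", "protein_id"}
    missing = required - set(df.columns)
    if missing:
        raise CovariateError(f"covariate table missing columns: {sorted(missing)}")
    if df["domain_id"].duplicated().any():
        raise CovariateError("duplicate domain_id rows in covariate table")
    if "omega" in df.columns:
        bad = df["omega"].dropna() < 0
        if bad.any():
            raise CovariateError("omega (dN/dS) must be >= 0 where present")
    for col in PROTEIN_LEVEL_COLUMNS:
        if col not in df.columns:
            continue
        per_protein = df.groupby("protein_id")[col].nunique(dropna=True)
        inconsistent = per_protein[per_protein > 1]
        if not inconsistent.empty:
            raise CovariateError(
                f"protein-level column {col!r} varies within proteins: "
                f"{sorted(inconsistent.index.tolist())}"
            )
    return df


def load_covariates(source) -> pd.DataFrame:
    """Read a per-domain covariate TSV (domain_id, protein_id, omega, D, B, X, d, C, E, Gr)."""
    df = pd.read_csv(source, sep="\t")
    df["domain_id"] = df["domain_id"].astype(str)
    df["protein_id"] = df["protein_id"].astype(str)
    return validate_covariates(df)


def save_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
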