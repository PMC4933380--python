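"""Cross-network association analysis.

Combines per-network correlations between domain influence D, evolutionary
rate omega, and protein-level covariates into Hunter-Schmidt random-effects
estimates, and tests independence with structured permutation schemes:

* ``param_influence`` — permute the rate-constant influences kappa within
  each model and recompute every domain's D (domains share rate constants,
  so their D values are not independent and cannot be permuted directly);
* ``domain_level``   — permute a domain-level variable (evolutionary rate)
  among the model's domains;
* ``protein_level``  — permute protein-level covariates among the model's
  proteins, so that domains of one protein keep identical values.

The permutation statistic is always the Hunter-Schmidt sample-size-weighted
mean correlation across models; two-sided p-values are the fraction of
permuted |mean| at least as extreme as the observed |mean|, reported as
"< 1/N_perm" when no permuted value reaches it.

Also provided: residual permutation for partial correlations, the
between-model correlation of influences on overlapping domains, and the
randomization that keeps every multi-model domain in exactly one model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotations import PROTEIN_LEVEL_COLUMNS, DomainAnnotation
from .stats_core import (
    ConstantInputError,
    MetaAnalysisResult,
    ModelCorrelation,
    _pearson,
    hunter_schmidt_meta,
    partial_correlation_vectors,
    rank_biserial,
    spearman,
)

__all__ = [
    "ModelCorrelation",
    "MetaAnalysisResult",
    "PermutationResult",
    "ModelData",
    "spearman",
    "rank_biserial",
    "partial_correlation",
    "hunter_schmidt_meta",
    "model_correlation",
    "meta_correlation",
    "permutation_test",
    "residual_permutation_test",
    "between_model_influence_correlation",
    "overlap_randomization",
]

SCHEMES = ("param_influence", "domain_level", "protein_level")


@dataclass
class ModelData:
    """One network's inputs to the statistics layer.

    ``table`` is the per-domain covariate table (domain_id, protein_id,
    omega, D, B, X, d, C, E, Gr; missing values allowed). ``kappa`` and
    ``annotation`` are needed only for the param_influence permutation
    scheme, which rebuilds D from permuted rate-constant influences.
    """

    model_id: str
    table: pd.DataFrame
    kappa: pd.Series | None = None
    annotation: DomainAnnotation | None = None


def _as_model_data(records) -> list[ModelData]:
    if isinstance(records, dict):
        out = []
        for mid, val in records.items():
            out.append(val if isinstance(val, ModelData) else ModelData(str(mid), val))
        return out
    return [r if isinstance(r, ModelData) else ModelData(str(i), r) for i, r in enumerate(records)]


def _is_binary(df: pd.DataFrame, var: str) -> bool:
    vals = set(pd.unique(df[var].dropna()))
    return var == "E" or (len(vals) > 0 and vals <= {0, 1, 0.0, 1.0, True, False})


def _complete_cases(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return df.dropna(subset=cols)


def model_correlation(md: ModelData, pair: tuple[str, str]) -> ModelCorrelation:
    """One model's correlation for a pair, after listwise deletion on the pair.

    Spearman for two numeric variables; rank-biserial when one of the pair
    is binary (knockout essentiality).
    """
    a, b = pair
    sub = _complete_cases(md.table, [a, b])
    n = len(sub)
    if n < 3:
        raise ValueError(f"model {md.model_id!r}: fewer than 3 complete cases for {pair}")
    if _is_binary(md.table, b):
        r = rank_biserial(sub[a].to_numpy(float), sub[b].to_numpy(float))
    elif _is_binary(md.table, a):
        r = rank_biserial(sub[b].to_numpy(float), sub[a].to_numpy(float))
    else:
        r = spearman(sub[a].to_numpy(float), sub[b].to_numpy(float))
    return ModelCorrelation(md.model_id, pair, r, n)


def partial_correlation(
    md: ModelData, pair: tuple[str, str], controls: list[str]
) -> ModelCorrelation:
    """Partial correlation of the pair given controls, in one model.

    Listwise deletion runs across the pair and all controls; binary
    controls enter the OLS designs as 0/1.
    """
    a, b = pair
    cols = [a, b, *controls]
    sub = _complete_cases(md.table, cols)
    ctrl = sub[list(controls)].to_numpy(float) if controls else np.empty((len(sub), 0))
    r, _, _ = partial_correlation_vectors(sub[a].to_numpy(float), sub[b].to_numpy(float), ctrl)
    return ModelCorrelation(md.model_id, pair, r, len(sub))


def meta_correlation(
    records, pair: tuple[str, str]
) -> tuple[MetaAnalysisResult, list[ModelCorrelation]]:
    """Per-model correlations for the pair and their Hunter-Schmidt combination."""
    mds = _as_model_data(records)
    corrs = [model_correlation(md, pair) for md in mds]
    return hunter_schmidt_meta(corrs), corrs


@dataclass
class PermutationResult:
    """Observed statistic, permutation null, and the two-sided p-value.

    ``pvalue`` is never exactly zero: when no permuted value is as extreme
    as the observed one, it holds the resolution bound 1/n_perm and
    ``pvalue_str`` reads "< 1/n_perm" (n_exceedances stores the raw count).
    """

    observed: float
    null: np.ndarray = field(repr=False)
    n_perm: int
    n_exceedances: int
    seed: int
    scheme: str

    @property
    def pvalue(self) -> float:
        if self.n_exceedances == 0:
            return 1.0 / self.n_perm
        return self.n_exceedances / self.n_perm

    @property
    def below_resolution(self) -> bool:
        return self.n_exceedances == 0

    @property
    def pvalue_str(self) -> str:
        if self.below_resolution:
            return f"<{1.0 / self.n_perm:g}"
        return f"{self.pvalue:g}"


def _model_rng(seed: int, model_id: str, scheme: str) -> np.random.Generator:
    """Deterministic substream per (seed, model, scheme)."""
    key = [int(seed), zlib.crc32(model_id.encode()), zlib.crc32(scheme.encode())]
    return np.random.default_rng(np.random.SeedSequence(key))


def _perm_matrix(rng: np.random.Generator, values: np.ndarray, n_perm: int) -> np.ndarray:
    """(n_perm, n) matrix whose rows are independent permutations of *values*."""
    return rng.permuted(np.tile(values, (n_perm, 1)), axis=1)


def _corr_rows_vs_fixed(rows: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of *rows* with *fixed*.

    Row-wise means/sds are constant when rows are permutations of one
    vector, but are recomputed here for generality.
    """
    rc = rows - rows.mean(axis=1, keepdims=True)
    fc = fixed - fixed.mean()
    denom = np.sqrt((rc**2).sum(axis=1)) * np.sqrt((fc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (rc @ fc) / denom
    return np.clip(out, -1.0, 1.0)


def _rank_rows(rows: np.ndarray) -> np.ndarray:
    return rankdata(rows, axis=1)


def _null_spearman_perm_x(rng, x: np.ndarray, y: np.ndarray, n_perm: int) -> np.ndarray:
    """Spearman null from permuting x against fixed y."""
    rx = rankdata(x)
    ry = rankdata(y)
    perms = _perm_matrix(rng, rx, n_perm)
    return _corr_rows_vs_fixed(perms, ry)


def _null_rank_biserial(rng, x: np.ndarray, g: np.ndarray, n_perm: int, permute: str) -> np.ndarray:
    """Rank-biserial null, permuting either the numeric side or the groups."""
    ranks = rankdata(x)
    gb = g.astype(bool)
    n1, n0 = int(gb.sum()), int((~gb).sum())
    if permute == "x":
        mat = _perm_matrix(rng, ranks, n_perm)
        u1 = mat[:, gb].sum(axis=1) - n1 * (n1 + 1) / 2
    else:
        gmat = _perm_matrix(rng, gb.astype(float), n_perm)
        u1 = (gmat * ranks[None, :]).sum(axis=1) - n1 * (n1 + 1) / 2
    return 2 * u1 / (n1 * n0) - 1


def _recomputed_d_ranks(
    md: ModelData, domain_ids: list[str], kappa_perms: np.ndarray
) -> np.ndarray:
    """Rank matrix of domain influences rebuilt from permuted kappa rows.

    D = geometric mean of the domain's kappa values; any zero kappa in a
    domain forces D = 0, ranked below every positive D.
    """
    ann = md.annotation
    params = list(md.kappa.index)
    p_index = {p: i for i, p in enumerate(params)}
    n_dom = len(domain_ids)
    w = np.zeros((n_dom, len(params)))
    member = np.zeros((n_dom, len(params)))
    for i, dom in enumerate(domain_ids):
        plist = ann.params_of_domain(dom)
        for p in plist:
            member[i, p_index[p]] = 1.0
        w[i, [p_index[p] for p in plist]] = 1.0 / len(plist)

    zero_mask = kappa_perms == 0
    safe = np.where(zero_mask, 1.0, kappa_perms)
    log_d = np.log(safe) @ w.T  # (n_perm, n_dom)
    has_zero = (zero_mask.astype(float) @ member.T) > 0
    # rank with zero-D domains below all others: set their log D to -inf
    log_d = np.where(has_zero, -np.inf, log_d)
    return _rank_rows(log_d)


def _null_for_model(
    md: ModelData, pair: tuple[str, str], scheme: str, n_perm: int, seed: int
) -> tuple[np.ndarray, int]:
    """Per-model permutation null of the pair correlation; returns (null_r, n)."""
    a, b = pair
    sub = _complete_cases(md.table, [a, b]).reset_index(drop=True)
    n = len(sub)
    if n < 3:
        raise ValueError(f"model {md.model_id!r}: fewer than 3 complete cases for {pair}")
    rng = _model_rng(seed, md.model_id, scheme)
    bin_a, bin_b = _is_binary(md.table, a), _is_binary(md.table, b)

    if scheme == "param_influence":
        if md.kappa is None or md.annotation is None:
            raise ValueError(
                f"model {md.model_id!r}: param_influence scheme needs kappa and annotation"
            )
        if "D" not in pair:
            raise ValueError("param_influence scheme permutes the D side; pair must include 'D'")
        other = a if b == "D" else b
        kappa_perms = _perm_matrix(rng, md.kappa.to_numpy(float), n_perm)
        d_ranks = _recomputed_d_ranks(md, list(sub["domain_id"]), kappa_perms)
        if _is_binary(md.table, other):
            gb = sub[other].to_numpy(float).astype(bool)
            n1, n0 = int(gb.sum()), int((~gb).sum())
            u1 = d_ranks[:, gb].sum(axis=1) - n1 * (n1 + 1) / 2
            return 2 * u1 / (n1 * n0) - 1, n
        return _corr_rows_vs_fixed(d_ranks, rankdata(sub[other].to_numpy(float))), n

    if scheme == "domain_level":
        # permute the domain-level variable: omega when present, else the first
        var = "omega" if "omega" in pair else a
        other = b if var == a else a
        xv = sub[var].to_numpy(float)
        yv = sub[other].to_numpy(float)
        if bin_a or bin_b:
            if _is_binary(md.table, var):
                return _null_rank_biserial(rng, yv, xv, n_perm, permute="g"), n
            return _null_rank_biserial(rng, xv, yv, n_perm, permute="x"), n
        return _null_spearman_perm_x(rng, xv, yv, n_perm), n

    if scheme == "protein_level":
        prot_vars = [v for v in pair if v in PROTEIN_LEVEL_COLUMNS]
        if not prot_vars:
            raise ValueError(f"protein_level scheme needs a protein-level variable in {pair}")
        var = prot_vars[0]
        other = b if var == a else a
        proteins = sub["protein_id"].to_numpy()
        uniq, dom_to_prot = np.unique(proteins, return_inverse=True)
        prot_vals = np.array(
            [sub.loc[proteins == p, var].iloc[0] for p in uniq], dtype=float
        )
        perms = _perm_matrix(rng, prot_vals, n_perm)
        expanded = perms[:, dom_to_prot]  # (n_perm, n_domains)
        yv = sub[other].to_numpy(float)
        if _is_binary(md.table, var):
            gbase = sub[var].to_numpy(float).astype(bool)
            n1, n0 = int(gbase.sum()), int((~gbase).sum())
            ranks = rankdata(yv)
            # n1 varies per permutation: essentiality is permuted per protein,
            # and proteins have different domain counts
            n1s = expanded.sum(axis=1)
            n0s = len(yv) - n1s
            u1 = (expanded * ranks[None, :]).sum(axis=1) - n1s * (n1s + 1) / 2
            with np.errstate(invalid="ignore", divide="ignore"):
                rb = 2 * u1 / (n1s * n0s) - 1
            return np.where((n1s == 0) | (n0s == 0), 0.0, rb), n
        return _corr_rows_vs_fixed(_rank_rows(expanded), rankdata(yv)), n

    raise ValueError(f"unknown permutation scheme {scheme!r}; expected one of {SCHEMES}")


def permutation_test(
    records,
    pair: tuple[str, str],
    scheme: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of independence for a variable pair across models.

    The statistic is the Hunter-Schmidt weighted mean correlation; each
    permutation scrambles the data independently within every model under
    the chosen scheme, and the two-sided p-value compares |mean| against
    the permuted |mean| distribution.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown permutation scheme {scheme!r}; expected one of {SCHEMES}")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very small; p-value resolution is 1/{n_perm}", stacklevel=2)
    mds = _as_model_data(records)
    meta, corrs = meta_correlation(mds, pair)
    weights = np.array([c.n for c in corrs], dtype=float)
    weights /= weights.sum()

    null_cols = []
    for md in mds:
        null_r, _ = _null_for_model(md, pair, scheme, n_perm, seed)
        null_cols.append(null_r)
    null = np.column_stack(null_cols) @ weights
    n_exc = int(np.sum(np.abs(null) >= abs(meta.rho0)))
    return PermutationResult(meta.rho0, null, n_perm, n_exc, seed, scheme)


def residual_permutation_test(
    records,
    pair: tuple[str, str],
    controls: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for the mean partial correlation across models.

    Within each model both targets are regressed on the controls; one
    residual vector is permuted against the other, which breaks the
    pair's association while preserving every relation with the controls.
    """
    mds = _as_model_data(records)
    corrs = []
    nulls = []
    for md in mds:
        a, b = pair
        cols = [a, b, *controls]
        sub = _complete_cases(md.table, cols)
        ctrl = sub[list(controls)].to_numpy(float) if controls else np.empty((len(sub), 0))
        r, ex, ey = partial_correlation_vectors(
            sub[a].to_numpy(float), sub[b].to_numpy(float), ctrl
        )
        corrs.append(ModelCorrelation(md.model_id, pair, r, len(sub)))
        rng = _model_rng(seed, md.model_id, "residual")
        perms = _perm_matrix(rng, ey, n_perm)
        nulls.append(_corr_rows_vs_fixed(perms, ex))
    meta = hunter_schmidt_meta(corrs)
    weights = np.array([c.n for c in corrs], dtype=float)
    weights /= weights.sum()
    null = np.column_stack(nulls) @ weights
    n_exc = int(np.sum(np.abs(null) >= abs(meta.rho0)))
    return PermutationResult(meta.rho0, null, n_perm, n_exc, seed, "residual")


def permute_protein_covariates(
    md: ModelData,
    rng: np.random.Generator,
    columns: list[str] | None = None,
    joint: bool = True,
) -> ModelData:
    """Return a copy of *md* with protein-level covariates permuted among proteins.

    ``joint=True`` applies one permutation of proteins to all listed
    columns (proteins carry their whole covariate tuple); ``joint=False``
    permutes each column independently. Either way, domains of one protein
    keep identical values. For a single-pair statistic the two modes give
    the same null; they differ only for multivariate recomputations.
    """
    cols = [c for c in (columns or list(PROTEIN_LEVEL_COLUMNS)) if c in md.table.columns]
    table = md.table.copy()
    proteins = table["protein_id"].to_numpy()
    uniq, dom_to_prot = np.unique(proteins, return_inverse=True)
    perm = rng.permutation(len(uniq))
    for col in cols:
        vals = np.array([table.loc[proteins == p, col].iloc[0] for p in uniq])
        if not joint:
            perm = rng.permutation(len(uniq))
        table[col] = vals[perm][dom_to_prot]
    return ModelData(md.model_id, table, md.kappa, md.annotation)


def between_model_influence_correlation(
    influences: dict[str, pd.Series], min_overlap: int = 4
) -> tuple[float, pd.DataFrame]:
    """Agreement of domain influences between models sharing domains.

    *influences* maps model_id to a Series of D indexed by domain_id. For
    every model pair with at least *min_overlap* shared domains, the
    Spearman correlation of the shared D values is computed; pair
    correlations are combined by sample-size weighting with n = overlap.
    Returns (weighted mean, per-pair table).
    """
    model_ids = sorted(influences)
    rows = []
    for i, m1 in enumerate(model_ids):
        for m2 in model_ids[i + 1 :]:
            shared = influences[m1].index.intersection(influences[m2].index)
            if len(shared) < min_overlap:
                continue
            try:
                r = spearman(
                    influences[m1].loc[shared].to_numpy(float),
                    influences[m2].loc[shared].to_numpy(float),
                )
            except ConstantInputError:
                continue
            rows.append({"model_1": m1, "model_2": m2, "r": r, "n_overlap": len(shared)})
    if not rows:
        raise ValueError(f"no model pair shares at least {min_overlap} domains")
    df = pd.DataFrame(rows)
    mean = float((df["r"] * df["n_overlap"]).sum() / df["n_overlap"].sum())
    return mean, df


def overlap_randomization(
    records,
    pair: tuple[str, str],
    scheme: str = "domain_level",
    controls: list[str] | None = None,
    n_rep: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    assignment_log: list | None = None,
) -> pd.DataFrame:
    """Re-run the analysis keeping each multi-model domain in one model only.

    Per replicate, every domain_id appearing in several models is retained
    in exactly one uniformly chosen model and deleted from the others; the
    meta-analysis and permutation test are rerun. Returns one row per
    replicate with columns rho0 and pvalue; summarize with
    :func:`randomization_quantiles` (50th with 5th/95th quantiles).
    ``assignment_log``, when a list, receives the per-replicate
    {domain_id: kept model index} dicts for auditing the retention draws.
    """
    mds = _as_model_data(records)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0F0F]))

    domain_models: dict[str, list[int]] = {}
    for idx, md in enumerate(mds):
        for dom in md.table["domain_id"]:
            domain_models.setdefault(str(dom), []).append(idx)
    multi = {d: idxs for d, idxs in domain_models.items() if len(idxs) > 1}

    rows = []
    for rep in range(n_rep):
        keep_in = {d: idxs[rng.integers(len(idxs))] for d, idxs in multi.items()}
        if assignment_log is not None:
            assignment_log.append(dict(keep_in))
        sub_records = []
        for idx, md in enumerate(mds):
            mask = [
                (str(d) not in keep_in) or (keep_in[str(d)] == idx)
                for d in md.table["domain_id"]
            ]
            table = md.table.loc[mask].reset_index(drop=True)
            cols = list(pair) + (controls or [])
            if len(table.dropna(subset=[c for c in cols if c in table.columns])) < max(3, len(controls or []) + 3):
                continue
            sub_records.append(ModelData(md.model_id, table, md.kappa, md.annotation))
        if len(sub_records) < 2:
            continue
        rep_seed = int(rng.integers(2**31 - 1))
        if controls:
            res = residual_permutation_test(sub_records, pair, controls, n_perm, rep_seed)
        else:
            res = permutation_test(sub_records, pair, scheme, n_perm, rep_seed)
        rows.append({"replicate": rep, "rho0": res.observed, "pvalue": res.pvalue})
    return pd.DataFrame(rows)


def randomization_quantiles(df: pd.DataFrame) -> dict[str, tuple[float, float, float]]:
    """Median (5th, 95th) quantiles of rho0 and p over randomization replicates."""
    out = {}
    for col in ("rho0", "pvalue"):
        q = df[col].quantile([0.5, 0.05, 0.95])
        out[col] = (float(q[0.5]), float(q[0.05]), float(q[0.95]))
    return out
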