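"""Correlation primitives and Hunter-Schmidt random-effects meta-analysis.

Per-network association statistics: Spearman rank correlation (mid-ranks
for ties), rank-biserial correlation in its Cliff's-delta form
rb = 2 U1 / (n1 n0) - 1 (half credit for ties), and partial correlation
as the product-moment correlation of OLS residuals after regressing both
target variables on the controls.

Across networks, correlations are combined by the Hunter-Schmidt
random-effects estimator: the population mean correlation is the
sample-size-weighted mean

    rho0_hat   = sum(n_i r_i) / sum(n_i),
    sigma_r^2  = sum(n_i (r_i - rho0_hat)^2) / sum(n_i),
    sigma_e^2  = sum(n_i (1 - r_i^2)^2 / (n_i - 1)) / sum(n_i),
    sigma_rho  = sqrt(max(0, sigma_r^2 - sigma_e^2)),
    SE(rho0)   = sigma_r / sqrt(K),      CI95 = rho0_hat +/- 1.96 SE.

The observed between-study variance sigma_r^2 decomposes into true
population variance sigma_rho^2 plus sampling error sigma_e^2; the
difference is truncated at zero when sampling error exceeds the observed
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class ConstantInputError(ValueError):
    """A correlation is undefined because an input vector is constant."""


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-ranks for ties.

    Computed as the product-moment correlation of average-ranked vectors.
    Raises ConstantInputError when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return _pearson(rankdata(x), rankdata(y))


def rank_biserial(x, group) -> float:
    """Rank-biserial correlation between a numeric vector and a binary grouping.

    rb = 2 U1 / (n1 n0) - 1 where U1 counts pairs in which the group-1
    (essential / affected) value exceeds the group-0 value, with half
    credit for ties. +1 means complete separation with group 1 larger.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(group)
    if set(np.unique(g)) - {0, 1, False, True}:
        raise ValueError("group must be binary (0/1)")
    g = g.astype(bool)
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(x)
    u1 = ranks[g].sum() - n1 * (n1 + 1) / 2  # Mann-Whitney U with tie half-credit
    return float(2 * u1 / (n1 * n0) - 1)


def ols_residuals(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Residuals of an OLS fit of y on [1, controls]."""
    y = np.asarray(y, dtype=float)
    if controls.size:
        design = np.column_stack([np.ones(len(y)), controls])
    else:
        design = np.ones((len(y), 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient control design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation_vectors(x, y, controls: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial correlation of x and y given controls, plus both residual vectors.

    Binary controls enter as 0/1 columns. Raises on rank-deficient designs
    and on (near-)zero-variance residuals, which signal that a target is an
    exact linear function of the controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if controls.ndim == 1:
        controls = controls.reshape(-1, 1) if controls.size else controls.reshape(len(x), 0)
    n_ctrl = controls.shape[1]
    if len(x) < n_ctrl + 3:
        raise ValueError(f"need at least controls+3 = {n_ctrl + 3} complete observations, got {len(x)}")
    ex = ols_residuals(x, controls)
    ey = ols_residuals(y, controls)
    scale_x = max(np.std(x), 1.0)
    scale_y = max(np.std(y), 1.0)
    if np.std(ex) <= 1e-12 * scale_x or np.std(ey) <= 1e-12 * scale_y:
        raise ConstantInputError("a target variable is an exact linear function of the controls")
    return _pearson(ex, ey), ex, ey


@dataclass(frozen=True)
class ModelCorrelation:
    """One network's correlation for a variable pair, with its sample size."""

    model_id: str
    pair: tuple[str, str]
    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")


@dataclass(frozen=True)
class MetaAnalysisResult:
    """Hunter-Schmidt random-effects estimates for one variable pair."""

    rho0: float
    sigma_r_sq: float
    sigma_e_sq: float
    sigma_rho: float
    se: float
    ci95: tuple[float, float]
    k: int

    def __str__(self) -> str:  # compact "rho0 (lo, hi)" display
        lo, hi = self.ci95
        return f"{self.rho0:+.2f} ({lo:+.2f}, {hi:+.2f})"


def hunter_schmidt_meta(corrs: list[ModelCorrelation]) -> MetaAnalysisResult:
    """Combine per-network correlations by sample-size weighting.

    See the module docstring for the estimator; the population variance
    estimate is truncated at zero and the 95% CI is rho0 +/- 1.96 SE.
    """
    if not corrs:
        raise ValueError("no correlations supplied")
    pairs = {c.pair for c in corrs}
    if len(pairs) > 1:
        raise ValueError(f"correlations mix variable pairs: {sorted(pairs)}")
    r = np.array([c.r for c in corrs], dtype=float)
    n = np.array([c.n for c in corrs], dtype=float)
    if np.any(n <= 1):
        raise ValueError("every study needs n > 1")
    w = n / n.sum()
    rho0 = float(w @ r)
    sigma_r_sq = float(w @ (r - rho0) ** 2)
    sigma_e_sq = float((n * (1 - r**2) ** 2 / (n - 1)).sum() / n.sum())
    sigma_rho = float(np.sqrt(max(0.0, sigma_r_sq - sigma_e_sq)))
    k = len(corrs)
    se = float(np.sqrt(sigma_r_sq) / np.sqrt(k))
    ci = (rho0 - 1.96 * se, rho0 + 1.96 * se)
    return MetaAnalysisResult(rho0, sigma_r_sq, sigma_e_sq, sigma_rho, se, ci, k)
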