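"""Simulation with first-order parameter sensitivities and rate-constant influence.

The influence kappa_i of rate constant k_i is a normalized, time-integrated
sensitivity of every species trajectory to k_i, summed over species and
stimulation conditions:

    kappa_i^2 = sum_c sum_y (1/T_c) * integral_0^Tc
                [ (dy_c(t)/dk_i) * k_i / y_max ]^2 dt,   evaluated at k = k*,

with y_max the per-species maximum over ALL conditions jointly. The
k_i / y_max normalization makes the integrand a dimensionless
log-derivative in k, so kappa is invariant under rescaling either the
concentration units of any species or the units of k_i. Normalizing by
y_max rather than y(t) keeps the score defined for species that start at
zero concentration, which is common in signaling models.

Sensitivities dy/dk are obtained by integrating the forward sensitivity
system dS/dt = (df/dy) S + df/dk alongside the state ("differential"
method), or by central finite differences of +/-delta relative
perturbations ("finite" method).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, StimulationCondition

DEFAULT_N_GRID = 512
RTOL = 1e-8


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced non-finite state."""


class CompiledNetwork:
    """Lambdified right-hand side and Jacobians of a network's ODE system.

    Parameter values enter as arguments, so one compilation serves every
    condition and every perturbed parameter set.
    """

    def __init__(self, net: ReactionNetwork):
        self.net = net
        self.species_ids = net.species_ids
        self.param_ids = net.parameter_ids
        self.rate_ids = net.rate_constant_ids
        n, m = len(self.species_ids), len(self.rate_ids)

        sp_syms = [sympy.Symbol(s) for s in self.species_ids]
        par_syms = [sympy.Symbol(p) for p in self.param_ids]
        laws = net.parsed_rate_laws()

        dydt = []
        for sid in self.species_ids:
            expr = sympy.Integer(0)
            for rxn in net.reactions:
                coef = rxn.stoichiometry.get(sid, 0)
                if coef:
                    expr = expr + coef * laws[rxn.id]
            dydt.append(expr)
        f_mat = sympy.Matrix(dydt)
        jy = f_mat.jacobian(sp_syms)
        jk = f_mat.jacobian([sympy.Symbol(r) for r in self.rate_ids]) if m else sympy.zeros(n, 0)

        args = sp_syms + par_syms
        self._f = sympy.lambdify(args, f_mat, modules="numpy")
        self._jy = sympy.lambdify(args, jy, modules="numpy")
        self._jk = sympy.lambdify(args, jk, modules="numpy")
        self.n, self.m = n, m

    def rhs(self, y: np.ndarray, k: np.ndarray) -> np.ndarray:
        return np.asarray(self._f(*y, *k), dtype=float).ravel()

    def jac_y(self, y: np.ndarray, k: np.ndarray) -> np.ndarray:
        return np.asarray(self._jy(*y, *k), dtype=float).reshape(self.n, self.n)

    def jac_k(self, y: np.ndarray, k: np.ndarray) -> np.ndarray:
        return np.asarray(self._jk(*y, *k), dtype=float).reshape(self.n, self.m)

    def condition_state(self, cond: StimulationCondition | None) -> tuple[np.ndarray, np.ndarray]:
        """Initial state and full parameter vector with condition overrides applied."""
        y0 = np.array([s.initial_concentration for s in self.net.species], dtype=float)
        k = np.array([p.reference_value for p in self.net.parameters], dtype=float)
        if cond is not None:
            cond.validate_against(self.net)
            for key, val in cond.overrides.items():
                if key in self.species_ids:
                    y0[self.species_ids.index(key)] = float(val)
                else:
                    k[self.param_ids.index(key)] = float(val)
        return y0, k


@dataclass
class SensitivityTrajectory:
    """State and sensitivity time courses for one stimulation condition."""

    condition_id: str
    times: np.ndarray  # (M+1,), uniform, t0=0, tM=T_c
    y: np.ndarray  # (M+1, n_species)
    sens: np.ndarray  # (M+1, n_species, n_rate_constants)
    species_ids: list[str]
    param_ids: list[str]  # rate constants, in sens column order

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise IntegrationError(f"non-finite concentrations in condition {self.condition_id!r}")
        expected = (len(self.times), len(self.species_ids), len(self.param_ids))
        if self.sens.shape != expected:
            raise ValueError(f"sensitivity array shape {self.sens.shape} != {expected}")

    @property
    def horizon(self) -> float:
        return float(self.times[-1])


@dataclass
class InfluenceTable:
    """Per-rate-constant influence kappa for one network."""

    model_id: str
    kappa: dict[str, float]
    y_max: dict[str, float]
    species_subset: str = "full"  # "full" or "key"
    method: str = "differential"  # "differential" or "finite+-<delta>"
    n_conditions: int = 1

    def __post_init__(self) -> None:
        for pid, val in self.kappa.items():
            if val < 0:
                raise ValueError(f"kappa[{pid!r}] = {val} < 0")

    def as_series(self):
        import pandas as pd

        return pd.Series(self.kappa, name="kappa")


def _atol(y0: np.ndarray) -> float:
    return 1e-10 * max(1.0, float(np.max(y0, initial=0.0)))


def _integrate(fun, y0: np.ndarray, t_eval: np.ndarray, atol: float, label: str) -> np.ndarray:
    sol = solve_ivp(
        fun, (t_eval[0], t_eval[-1]), y0, method="LSODA",
        t_eval=t_eval, rtol=RTOL, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed for {label}: {sol.message}")
    out = sol.y.T
    if not np.all(np.isfinite(out)):
        raise IntegrationError(f"non-finite state for {label}")
    return out


def simulate(net_or_compiled, cond: StimulationCondition, n_grid: int = DEFAULT_N_GRID) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the plain state ODE under one condition.

    Returns (times, y) with y of shape (n_grid+1, n_species).
    """
    comp = net_or_compiled if isinstance(net_or_compiled, CompiledNetwork) else CompiledNetwork(net_or_compiled)
    y0, k = comp.condition_state(cond)
    t_eval = np.linspace(0.0, cond.horizon, n_grid + 1)
    y = _integrate(lambda t, y: comp.rhs(y, k), y0, t_eval, _atol(y0),
                   f"condition {cond.condition_id!r}")
    return t_eval, y


def simulate_with_sensitivities(
    net_or_compiled, cond: StimulationCondition, n_grid: int = DEFAULT_N_GRID
) -> SensitivityTrajectory:
    """Integrate state and forward sensitivities dy/dk under one condition.

    The augmented system is dy/dt = f(y, k), dS/dt = (df/dy) S + df/dk with
    S(0) = 0 (rate constants do not enter initial conditions).
    """
    if n_grid < 16:
        raise ValueError("n_grid must be >= 16")
    comp = net_or_compiled if isinstance(net_or_compiled, CompiledNetwork) else CompiledNetwork(net_or_compiled)
    n, m = comp.n, comp.m
    y0, k = comp.condition_state(cond)
    z0 = np.concatenate([y0, np.zeros(n * m)])

    def rhs(t, z):
        y = z[:n]
        s = z[n:].reshape(n, m)
        dy = comp.rhs(y, k)
        ds = comp.jac_y(y, k) @ s + comp.jac_k(y, k)
        return np.concatenate([dy, ds.ravel()])

    t_eval = np.linspace(0.0, cond.horizon, n_grid + 1)
    z = _integrate(rhs, z0, t_eval, _atol(y0), f"condition {cond.condition_id!r}")
    return SensitivityTrajectory(
        condition_id=cond.condition_id,
        times=t_eval,
        y=z[:, :n],
        sens=z[:, n:].reshape(len(t_eval), n, m),
        species_ids=list(comp.species_ids),
        param_ids=list(comp.rate_ids),
    )


def _species_y_max(trajs: list[SensitivityTrajectory]) -> np.ndarray:
    """Per-species maximum concentration over all conditions jointly."""
    return np.max([t.y.max(axis=0) for t in trajs], axis=0)


def _aggregate_influence(
    trajs: list[SensitivityTrajectory],
    kstar: np.ndarray,
    species_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared kappa aggregation over stored trajectories.

    species_mask selects the species entering the sum; y_max is still taken
    over all conditions for each species. Species with y_max = 0 contribute
    nothing (their normalization is undefined; they are dynamically inert).
    """
    ymax = _species_y_max(trajs)
    active = species_mask & (ymax > 0)
    kappa_sq = np.zeros(len(kstar))
    for traj in trajs:
        t_c = traj.horizon
        # integrand (t, species, param): (sens * k / ymax)^2
        norm = np.where(active, 1.0 / np.where(ymax > 0, ymax, 1.0), 0.0)
        scaled = traj.sens * (kstar[None, None, :] * norm[None, :, None])
        integrals = np.trapezoid(scaled**2, traj.times, axis=0)  # (species, param)
        kappa_sq += integrals[active].sum(axis=0) / t_c
    return np.sqrt(kappa_sq), ymax


def parameter_influence(
    trajs: list[SensitivityTrajectory],
    net: ReactionNetwork,
    species: list[str] | None = None,
) -> InfluenceTable:
    """Aggregate stored sensitivity trajectories into per-parameter kappa.

    *species*, when given, restricts the species sum (the "key species"
    variant); y_max is still computed over all conditions for each species.
    """
    if not trajs:
        raise ValueError("no trajectories supplied")
    ref = trajs[0]
    for t in trajs[1:]:
        if t.species_ids != ref.species_ids or t.param_ids != ref.param_ids:
            raise ValueError("trajectories disagree on species/parameter order")
    rate_ids = ref.param_ids
    kstar = np.array([net.parameter_by_id(p).reference_value for p in rate_ids])

    mask = np.ones(len(ref.species_ids), dtype=bool)
    subset = "full"
    if species is not None:
        if not species:
            raise ValueError("key species list must be nonempty")
        unknown = set(species) - set(ref.species_ids)
        if unknown:
            raise KeyError(f"unknown species ids: {sorted(unknown)}")
        mask = np.array([s in set(species) for s in ref.species_ids])
        subset = "key" if mask.sum() < len(mask) else "full"

    kappa, ymax = _aggregate_influence(trajs, kstar, mask)
    return InfluenceTable(
        model_id=net.model_id,
        kappa=dict(zip(rate_ids, kappa.tolist())),
        y_max=dict(zip(ref.species_ids, ymax.tolist())),
        species_subset=subset,
        method="differential",
        n_conditions=len(trajs),
    )


def finite_perturbation_influence(
    net: ReactionNetwork,
    conds: list[StimulationCondition],
    delta: float = 0.25,
    n_grid: int = DEFAULT_N_GRID,
    species: list[str] | None = None,
) -> InfluenceTable:
    """Influence from finite +/-delta relative perturbations of each rate constant.

    dy/dk is replaced by [y(k (1+delta)) - y(k (1-delta))] / (2 delta k),
    one parameter perturbed at a time; the aggregation is otherwise
    identical to :func:`parameter_influence`. Rate constants with k* = 0
    get kappa = 0 (no relative perturbation is defined).
    """
    if not conds:
        raise ValueError("no stimulation conditions supplied")
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    comp = CompiledNetwork(net)
    rate_ids = comp.rate_ids
    kstar = np.array([net.parameter_by_id(p).reference_value for p in rate_ids])
    rate_cols = [comp.param_ids.index(p) for p in rate_ids]

    trajs: list[SensitivityTrajectory] = []
    for cond in conds:
        t_eval, y_base = simulate(comp, cond, n_grid)
        y0, k_cond = comp.condition_state(cond)
        sens = np.zeros((len(t_eval), comp.n, comp.m))
        for j, (col, kj) in enumerate(zip(rate_cols, kstar)):
            if kj == 0:
                continue
            # perturb around the condition's value of this rate constant
            base = k_cond[col]
            if base == 0:
                continue
            ys = {}
            for sign in (+1, -1):
                k_pert = k_cond.copy()
                k_pert[col] = base * (1 + sign * delta)
                ys[sign] = _integrate(
                    lambda t, y: comp.rhs(y, k_pert), y0, t_eval, _atol(y0),
                    f"condition {cond.condition_id!r}, {rate_ids[j]} * (1{'+' if sign > 0 else '-'}{delta})",
                )
            sens[:, :, j] = (ys[+1] - ys[-1]) / (2 * delta * base)
        trajs.append(
            SensitivityTrajectory(cond.condition_id, t_eval, y_base, sens,
                                  list(comp.species_ids), list(rate_ids))
        )

    table = parameter_influence(trajs, net, species=species)
    table.method = f"finite+-{delta:g}"
    return table
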