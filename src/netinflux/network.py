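"""Reaction-network model objects.

A :class:`ReactionNetwork` is the simulable unit: species with initial
concentrations (optionally mapped to proteins), kinetic parameters with
reference values k*, and reactions carrying integer stoichiometries and
arbitrary arithmetic rate-law expressions over species and parameters.
Mass-action kinetics are not assumed; any finite expression is accepted.

A :class:`StimulationCondition` encodes a biologically relevant stimulus
as t=0 overrides of initial concentrations and/or parameter values plus a
simulation horizon T_c. Mid-course events are deliberately unsupported.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import sympy
from sympy.parsing.sympy_parser import parse_expr, standard_transformations


class NetworkValidationError(ValueError):
    """A network, condition, or annotation violates a structural contract."""


@dataclass(frozen=True)
class Species:
    id: str
    initial_concentration: float
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise NetworkValidationError(
                f"species {self.id!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class Parameter:
    id: str
    reference_value: float
    is_rate_constant: bool = True

    def __post_init__(self) -> None:
        if self.reference_value < 0:
            raise NetworkValidationError(
                f"parameter {self.id!r}: reference value must be >= 0, "
                f"got {self.reference_value}"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, int]
    rate_law: str


_ALLOWED_FUNCS = {
    "exp": sympy.exp,
    "log": sympy.log,
    "ln": sympy.log,
    "sqrt": sympy.sqrt,
    "Abs": sympy.Abs,
    "abs": sympy.Abs,
    "sin": sympy.sin,
    "cos": sympy.cos,
    "tanh": sympy.tanh,
    "Min": sympy.Min,
    "Max": sympy.Max,
    "pow": sympy.Pow,
}


def parse_rate_law(expr: str, symbols: dict[str, sympy.Symbol]) -> sympy.Expr:
    """Parse a rate-law string into a sympy expression.

    Every declared species/parameter id shadows sympy builtins of the same
    name (E, I, gamma, ...), so model ids never collide with constants.
    """
    local = dict(_ALLOWED_FUNCS)
    local.update(symbols)
    try:
        parsed = parse_expr(expr, local_dict=local, transformations=standard_transformations, evaluate=True)
    except Exception as exc:  # sympy raises many types
        raise NetworkValidationError(f"cannot parse rate law {expr!r}: {exc}") from exc
    return parsed


@dataclass
class ReactionNetwork:
    model_id: str
    species: list[Species]
    parameters: list[Parameter]
    reactions: list[Reaction]

    _parsed_laws: dict[str, sympy.Expr] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def parameter_ids(self) -> list[str]:
        return [p.id for p in self.parameters]

    @property
    def rate_constant_ids(self) -> list[str]:
        return [p.id for p in self.parameters if p.is_rate_constant]

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def parameter_by_id(self, pid: str) -> Parameter:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def initial_state(self) -> dict[str, float]:
        return {s.id: s.initial_concentration for s in self.species}

    def reference_values(self) -> dict[str, float]:
        return {p.id: p.reference_value for p in self.parameters}

    def symbols(self) -> dict[str, sympy.Symbol]:
        return {name: sympy.Symbol(name) for name in self.species_ids + self.parameter_ids}

    def parsed_rate_laws(self) -> dict[str, sympy.Expr]:
        if not self._parsed_laws:
            syms = self.symbols()
            self._parsed_laws = {r.id: parse_rate_law(r.rate_law, syms) for r in self.reactions}
        return self._parsed_laws

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        sids = self.species_ids
        pids = self.parameter_ids
        if len(set(sids)) != len(sids):
            dupes = sorted({s for s in sids if sids.count(s) > 1})
            raise NetworkValidationError(f"duplicate species ids: {dupes}")
        if len(set(pids)) != len(pids):
            dupes = sorted({p for p in pids if pids.count(p) > 1})
            raise NetworkValidationError(f"duplicate parameter ids: {dupes}")
        declared = set(sids) | set(pids)

        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkValidationError("duplicate reaction ids")

        for rxn in self.reactions:
            for sid in rxn.stoichiometry:
                if sid not in set(sids):
                    raise NetworkValidationError(
                        f"reaction {rxn.id!r}: stoichiometry references undeclared species {sid!r}"
                    )

        laws = self.parsed_rate_laws()
        for rxn in self.reactions:
            free = {str(s) for s in laws[rxn.id].free_symbols}
            undeclared = free - declared
            if undeclared:
                raise NetworkValidationError(
                    f"reaction {rxn.id!r}: rate law references undeclared symbols {sorted(undeclared)}"
                )

        # rate laws must be finite at the initial state
        subs = {sympy.Symbol(k): v for k, v in {**self.initial_state(), **self.reference_values()}.items()}
        for rxn in self.reactions:
            val = laws[rxn.id].subs(subs)
            try:
                fval = float(val)
            except TypeError as exc:
                raise NetworkValidationError(
                    f"reaction {rxn.id!r}: rate law does not evaluate to a number at the initial state"
                ) from exc
            if not _is_finite(fval):
                raise NetworkValidationError(
                    f"reaction {rxn.id!r}: rate law is non-finite ({fval}) at the initial state"
                )

    def copy(self) -> "ReactionNetwork":
        new = copy.deepcopy(self)
        new._parsed_laws = {}
        return new


def _is_finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass(frozen=True)
class StimulationCondition:
    """One stimulus: t=0 overrides of initials/parameters and a horizon T_c."""

    condition_id: str
    overrides: dict[str, float]
    horizon: float

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise NetworkValidationError(
                f"condition {self.condition_id!r}: horizon T_c must be > 0, got {self.horizon}"
            )

    def validate_against(self, net: ReactionNetwork) -> None:
        declared = set(net.species_ids) | set(net.parameter_ids)
        unknown = set(self.overrides) - declared
        if unknown:
            raise NetworkValidationError(
                f"condition {self.condition_id!r}: overrides reference unknown ids {sorted(unknown)}"
            )


def apply_condition(net: ReactionNetwork, cond: StimulationCondition) -> ReactionNetwork:
    """Return a copy of *net* with the condition's overrides applied.

    The original network is left untouched. Overrides of species ids set
    initial concentrations; overrides of parameter ids set reference values.
    """
    cond.validate_against(net)
    species = []
    for s in net.species:
        if s.id in cond.overrides:
            species.append(replace(s, initial_concentration=float(cond.overrides[s.id])))
        else:
            species.append(s)
    params = []
    for p in net.parameters:
        if p.id in cond.overrides:
            params.append(replace(p, reference_value=float(cond.overrides[p.id])))
        else:
            params.append(p)
    return ReactionNetwork(
        model_id=net.model_id,
        species=species,
        parameters=params,
        reactions=list(net.reactions),
    )
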