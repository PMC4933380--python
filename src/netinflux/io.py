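"""Model input/output.

Two on-disk model representations are supported:

* a native YAML schema mirroring :class:`~netinflux.network.ReactionNetwork`
  (round-trip safe; the format used by the synthetic generators), and
* a best-effort subset of SBML Level 2/3: species, global and local
  parameters, reactions with kinetic laws, and initialAssignment-free
  initial concentrations. Events, algebraic rules, rate rules, delays and
  function definitions are rejected with a clear message rather than
  silently misread.

Stimulation conditions are read from YAML, and S1-Dataset-shaped XLSX
workbooks (one parameter sheet plus one domain sheet per model) from
openpyxl via pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from lxml import etree

from .annotations import DomainAnnotation
from .network import (
    NetworkValidationError,
    Parameter,
    Reaction,
    ReactionNetwork,
    Species,
    StimulationCondition,
)

# ---------------------------------------------------------------------------
# native YAML format
# ---------------------------------------------------------------------------


def network_to_dict(net: ReactionNetwork) -> dict:
    return {
        "model_id": net.model_id,
        "species": [
            {"id": s.id, "initial": s.initial_concentration, **({"protein": s.protein_id} if s.protein_id else {})}
            for s in net.species
        ],
        "parameters": [
            {"id": p.id, "value": p.reference_value, "rate_constant": p.is_rate_constant}
            for p in net.parameters
        ],
        "reactions": [
            {"id": r.id, "stoichiometry": dict(r.stoichiometry), "rate_law": r.rate_law}
            for r in net.reactions
        ],
    }


def network_from_dict(data: dict) -> ReactionNetwork:
    try:
        species = [
            Species(str(s["id"]), float(s["initial"]), s.get("protein"))
            for s in data["species"]
        ]
        params = [
            Parameter(str(p["id"]), float(p["value"]), bool(p.get("rate_constant", True)))
            for p in data["parameters"]
        ]
        reactions = [
            Reaction(
                str(r["id"]),
                {str(k): int(v) for k, v in r["stoichiometry"].items()},
                str(r["rate_law"]),
            )
            for r in data["reactions"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkValidationError(f"malformed native model: {exc}") from exc
    return ReactionNetwork(str(data.get("model_id", "model")), species, params, reactions)


def save_network(net: ReactionNetwork, path) -> None:
    Path(path).write_text(yaml.safe_dump(network_to_dict(net), sort_keys=False))


def load_network(path) -> ReactionNetwork:
    """Load a model from the native YAML format or an SBML file (auto-detected)."""
    text = Path(path).read_text()
    if text.lstrip().startswith("<"):
        return load_sbml(path)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise NetworkValidationError(f"{path}: not a model file")
    return network_from_dict(data)


def load_conditions(path) -> list[StimulationCondition]:
    """Read stimulation conditions from YAML.

    Schema: a list of {id, overrides: {id: value}, horizon}.
    """
    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, dict) and "conditions" in data:
        data = data["conditions"]
    conds = []
    for entry in data:
        conds.append(
            StimulationCondition(
                condition_id=str(entry["id"]),
                overrides={str(k): float(v) for k, v in (entry.get("overrides") or {}).items()},
                horizon=float(entry["horizon"]),
            )
        )
    return conds


def save_conditions(conds: list[StimulationCondition], path) -> None:
    data = [
        {"id": c.condition_id, "overrides": dict(c.overrides), "horizon": c.horizon}
        for c in conds
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# SBML subset
# ---------------------------------------------------------------------------

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_MATHML_OPS = {
    "plus": ("+", True),
    "times": ("*", True),
    "minus": ("-", False),
    "divide": ("/", False),
    "power": ("**", False),
}

_MATHML_FUNCS = {"exp", "ln", "log", "root", "abs", "sin", "cos", "tanh"}


def _mathml_to_expr(node) -> str:
    """Convert a content-MathML element to an infix expression string."""
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise NetworkValidationError("MathML <math> must have one child expression")
        return _mathml_to_expr(children[0])
    if tag == "ci":
        return node.text.strip()
    if tag == "cn":
        sub = [c for c in node if isinstance(c.tag, str)]
        if sub and etree.QName(sub[0]).localname == "sep":  # e-notation: mantissa <sep/> exponent
            mant = node.text.strip()
            expo = sub[0].tail.strip()
            return f"({mant}e{expo})"
        return f"({node.text.strip()})"
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_expr(c) for c in children[1:]]
        if op in _MATHML_OPS:
            sym, nary = _MATHML_OPS[op]
            if op == "minus" and len(args) == 1:
                return f"(-{args[0]})"
            if not nary and len(args) != 2:
                raise NetworkValidationError(f"MathML operator {op!r} expects 2 arguments")
            return "(" + f" {sym} ".join(args) + ")"
        if op in _MATHML_FUNCS:
            fn = {"ln": "log", "abs": "Abs"}.get(op, op)
            return f"{fn}({', '.join(args)})"
        raise NetworkValidationError(f"unsupported MathML construct <{op}>")
    raise NetworkValidationError(f"unsupported MathML element <{tag}>")


def load_sbml(path) -> ReactionNetwork:
    """Read a subset of SBML Level 2/3 into a ReactionNetwork.

    Unsupported constructs (events, rules, function definitions,
    initial assignments, delays) raise NetworkValidationError.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise NetworkValidationError(f"{path}: not an SBML document")
    ns = etree.QName(root).namespace

    def q(tag: str) -> str:
        return f"{{{ns}}}{tag}"

    model = root.find(q("model"))
    if model is None:
        raise NetworkValidationError(f"{path}: SBML file has no <model>")

    for unsupported in ("listOfEvents", "listOfRules", "listOfFunctionDefinitions",
                        "listOfInitialAssignments", "listOfConstraints"):
        if model.find(q(unsupported)) is not None:
            raise NetworkValidationError(
                f"unsupported SBML construct <{unsupported}>: only species, parameters "
                f"and reactions with kinetic laws are handled"
            )

    species = []
    los = model.find(q("listOfSpecies"))
    if los is not None:
        for sp in los.findall(q("species")):
            init = sp.get("initialConcentration", sp.get("initialAmount", "0"))
            species.append(Species(sp.get("id"), float(init), None))

    parameters: list[Parameter] = []
    seen_params: set[str] = set()
    lop = model.find(q("listOfParameters"))
    if lop is not None:
        for pm in lop.findall(q("parameter")):
            pid = pm.get("id")
            parameters.append(Parameter(pid, float(pm.get("value", "0")), True))
            seen_params.add(pid)

    reactions = []
    lor = model.find(q("listOfReactions"))
    if lor is not None:
        for rx in lor.findall(q("reactions")) + lor.findall(q("reaction")):
            rid = rx.get("id")
            stoich: dict[str, int] = {}
            for side, sign in (("listOfReactants", -1), ("listOfProducts", +1)):
                lst = rx.find(q(side))
                if lst is None:
                    continue
                for ref in lst.findall(q("speciesReference")):
                    n = int(float(ref.get("stoichiometry", "1")))
                    sid = ref.get("species")
                    stoich[sid] = stoich.get(sid, 0) + sign * n
            kl = rx.find(q("kineticLaw"))
            if kl is None:
                raise NetworkValidationError(f"reaction {rid!r} has no kinetic law")
            # local parameters are hoisted to global scope, prefixed on clash
            for loc_tag in ("listOfParameters", "listOfLocalParameters"):
                lst = kl.find(q(loc_tag))
                if lst is None:
                    continue
                for pm in list(lst):
                    if not isinstance(pm.tag, str):
                        continue
                    pid = pm.get("id")
                    if pid in seen_params:
                        raise NetworkValidationError(
                            f"reaction {rid!r}: local parameter {pid!r} shadows a global id"
                        )
                    parameters.append(Parameter(pid, float(pm.get("value", "0")), True))
                    seen_params.add(pid)
            math = kl.find(f"{{{_MATHML_NS}}}math")
            if math is None:
                raise NetworkValidationError(f"reaction {rid!r}: kinetic law has no MathML")
            reactions.append(Reaction(rid, {k: v for k, v in stoich.items() if v != 0},
                                      _mathml_to_expr(math)))

    model_id = model.get("id") or model.get("name") or Path(path).stem
    return ReactionNetwork(model_id, species, parameters, reactions)


# ---------------------------------------------------------------------------
# S1-Dataset-shaped XLSX workbooks
# ---------------------------------------------------------------------------


def load_domain_workbook(path) -> dict[str, tuple[pd.DataFrame, DomainAnnotation]]:
    """Read a workbook with one parameter sheet and one domain sheet per model.

    Sheets come in consecutive pairs: ``<model>_params`` (columns param_id,
    influence, reaction_id) followed by ``<model>_domains`` (columns
    protein_id, domain_id, param_id). Returns, per model, the parameter
    table and the parsed annotation.
    """
    sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    out: dict[str, tuple[pd.DataFrame, DomainAnnotation]] = {}
    params_by_model: dict[str, pd.DataFrame] = {}
    for name, df in sheets.items():
        if name.endswith("_params"):
            params_by_model[name[: -len("_params")]] = df
    for name, df in sheets.items():
        if not name.endswith("_domains"):
            continue
        model = name[: -len("_domains")]
        if model not in params_by_model:
            raise NetworkValidationError(f"workbook sheet {name!r} has no matching {model}_params sheet")
        pdf = params_by_model[model]
        if "param_id" not in pdf.columns:
            raise NetworkValidationError(f"sheet {model}_params lacks a param_id column")
        ann = DomainAnnotation(df.astype(str))
        known = set(pdf["param_id"].astype(str))
        unknown = set(ann.rows["param_id"]) - known
        if unknown:
            raise NetworkValidationError(
                f"model {model!r}: domain sheet references parameters absent from "
                f"the parameter sheet: {sorted(unknown)}"
            )
        out[model] = (pdf, ann)
    return out
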