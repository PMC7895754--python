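"""Read/write networks in a native JSON dialect and in SBML L2/L3.

The native dialect is lossless.  SBML export writes Level 3 Version 2 with
generated MathML kinetic laws plus a package annotation that preserves the
structured rate-law description, reaction tags, modules, moieties and marker
panels, so an export/import round trip is exact.  Foreign SBML files are
mapped to recognizable rate-law kinds where possible and to generic
``expression`` laws otherwise.  Events, delays, and algebraic/assignment
rules are rejected explicitly.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .errors import ConfigurationError, UnsupportedFeatureError
from .network import (
    ConservedMoiety,
    Network,
    Parameter,
    RateLaw,
    Reaction,
    Species,
)

NATIVE_SCHEMA = "macpol-network/1"
SBML_L3_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
MACPOL_NS = "https://macpol.invalid/annotation/1"

_SAFE_FUNCS = {
    "exp": math.exp,
    "log": math.log,
    "log10": math.log10,
    "sqrt": math.sqrt,
    "pow": pow,
    "abs": abs,
    "min": min,
    "max": max,
}


def _eval_expression(expression: str, env: Dict[str, float]) -> float:
    scope = dict(_SAFE_FUNCS)
    scope.update(env)
    return eval(expression, {"__builtins__": {}}, scope)  # noqa: S307 - sandboxed


@dataclass
class ModelDocument:
    network: Network
    annotations: Dict[str, object] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# native JSON


def _law_to_dict(law: RateLaw) -> dict:
    d = {"kind": law.kind}
    for k in ("rate_param", "K", "n", "regulator", "expression"):
        v = getattr(law, k)
        if v is not None:
            d[k] = v
    return d


def network_to_dict(network: Network, annotations: Optional[dict] = None) -> dict:
    return {
        "schema": NATIVE_SCHEMA,
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "role": s.role,
                "compartment": s.compartment,
                "initial_amount": s.initial_amount,
                "is_constant": s.is_constant,
                "secreted": s.secreted,
            }
            for s in network.species
        ],
        "parameters": [
            {"id": p.id, "value": p.value, "description": p.description}
            for p in network.parameters
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": [[sid, st] for sid, st in r.reactants],
                "products": [[sid, st] for sid, st in r.products],
                "modifiers": list(r.modifiers),
                "law": _law_to_dict(r.law),
                "tags": list(r.tags),
                "module": r.module,
            }
            for r in network.reactions
        ],
        "moieties": [
            {
                "name": m.name,
                "members": [[sid, w] for sid, w in m.members],
                "total": m.total,
            }
            for m in network.moieties
        ],
        "annotations": annotations or {},
    }


def network_from_dict(d: dict) -> ModelDocument:
    if d.get("schema") != NATIVE_SCHEMA:
        raise ConfigurationError(
            f"not a {NATIVE_SCHEMA} document (schema={d.get('schema')!r})"
        )
    net = Network(
        species=[Species(**s) for s in d.get("species", [])],
        parameters=[Parameter(**p) for p in d.get("parameters", [])],
        reactions=[
            Reaction(
                id=r["id"],
                reactants=[(sid, float(st)) for sid, st in r.get("reactants", [])],
                products=[(sid, float(st)) for sid, st in r.get("products", [])],
                modifiers=list(r.get("modifiers", [])),
                law=RateLaw(**r["law"]),
                tags=list(r.get("tags", [])),
                module=r.get("module"),
            )
            for r in d.get("reactions", [])
        ],
        moieties=[
            ConservedMoiety(
                name=m["name"],
                members=[(sid, float(w)) for sid, w in m.get("members", [])],
                total=m.get("total"),
            )
            for m in d.get("moieties", [])
        ],
    )
    return ModelDocument(network=net, annotations=dict(d.get("annotations", {})))


def write_native(doc: ModelDocument, path) -> None:
    d = network_to_dict(doc.network, doc.annotations)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_native(path) -> ModelDocument:
    with open(path) as fh:
        d = json.load(fh)
    doc = network_from_dict(d)
    doc.provenance = {"source": str(path), "format": "native-json"}
    return doc


# ---------------------------------------------------------------------------
# SBML writing


def _mathml_law(parent: ET.Element, rxn: Reaction) -> None:
    math_el = ET.SubElement(parent, f"{{{MATHML_NS}}}math")
    law = rxn.law

    def ci(p, name):
        e = ET.SubElement(p, f"{{{MATHML_NS}}}ci")
        e.text = f" {name} "

    def cn(p, value):
        e = ET.SubElement(p, f"{{{MATHML_NS}}}cn")
        e.text = f" {value!r} "

    def apply(p, op):
        a = ET.SubElement(p, f"{{{MATHML_NS}}}apply")
        ET.SubElement(a, f"{{{MATHML_NS}}}{op}")
        return a

    if law.kind == "synthesis":
        ci(math_el, law.rate_param)
    elif law.kind == "mass_action":
        a = apply(math_el, "times")
        ci(a, law.rate_param)
        for sid, st in rxn.reactants:
            if st == 1:
                ci(a, sid)
            else:
                pw = apply(a, "power")
                ci(pw, sid)
                cn(pw, st)
    elif law.kind == "first_order_decay":
        a = apply(math_el, "times")
        ci(a, law.rate_param)
        ci(a, rxn.reactants[0][0])
    elif law.kind == "michaelis_menten":
        div = apply(math_el, "divide")
        num = apply(div, "times")
        ci(num, law.rate_param)
        ci(num, law.regulator)
        den = apply(div, "plus")
        cn(den, law.K)
        ci(den, law.regulator)
    elif law.kind in ("hill_activation", "hill_inhibition"):
        div = apply(math_el, "divide")
        num = apply(div, "times")
        ci(num, law.rate_param)
        pw = apply(num, "power")
        if law.kind == "hill_activation":
            ci(pw, law.regulator)
        else:
            cn(pw, law.K)
        cn(pw, law.n)
        den = apply(div, "plus")
        pk = apply(den, "power")
        cn(pk, law.K)
        cn(pk, law.n)
        pa = apply(den, "power")
        ci(pa, law.regulator)
        cn(pa, law.n)
    else:  # expression: emit as a csymbol-free ci fallback; exact form kept in annotation
        ci(math_el, "expression_law")


def write_sbml(doc: ModelDocument, path) -> None:
    ET.register_namespace("", SBML_L3_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(
        f"{{{SBML_L3_NS}}}sbml", {"level": "3", "version": "2"}
    )
    model = ET.SubElement(sbml, f"{{{SBML_L3_NS}}}model", {"id": "macpol_model"})

    notes = ET.SubElement(model, f"{{{SBML_L3_NS}}}notes")
    body = ET.SubElement(notes, "{http://www.w3.org/1999/xhtml}body")
    panel = doc.annotations.get("marker_panel")
    body.text = (
        "Macrophage polarization network. Marker panel: " + json.dumps(panel)
        if panel
        else "Macrophage polarization network."
    )

    ann = ET.SubElement(model, f"{{{SBML_L3_NS}}}annotation")
    extra = ET.SubElement(ann, f"{{{MACPOL_NS}}}document")
    extra.text = json.dumps(
        {
            "annotations": doc.annotations,
            "moieties": [
                {"name": m.name, "members": [[s, w] for s, w in m.members], "total": m.total}
                for m in doc.network.moieties
            ],
        }
    )

    comps = sorted({s.compartment for s in doc.network.species}) or ["cytoplasm"]
    lst = ET.SubElement(model, f"{{{SBML_L3_NS}}}listOfCompartments")
    for c in comps:
        ET.SubElement(
            lst,
            f"{{{SBML_L3_NS}}}compartment",
            {"id": c, "constant": "true", "size": "1"},
        )

    lst = ET.SubElement(model, f"{{{SBML_L3_NS}}}listOfSpecies")
    for s in doc.network.species:
        el = ET.SubElement(
            lst,
            f"{{{SBML_L3_NS}}}species",
            {
                "id": s.id,
                "name": s.name,
                "compartment": s.compartment,
                "initialAmount": repr(float(s.initial_amount)),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "true" if s.is_constant else "false",
                "constant": "true" if s.is_constant else "false",
            },
        )
        sann = ET.SubElement(el, f"{{{SBML_L3_NS}}}annotation")
        sx = ET.SubElement(sann, f"{{{MACPOL_NS}}}species")
        sx.text = json.dumps({"role": s.role, "secreted": s.secreted})

    lst = ET.SubElement(model, f"{{{SBML_L3_NS}}}listOfParameters")
    for p in doc.network.parameters:
        ET.SubElement(
            lst,
            f"{{{SBML_L3_NS}}}parameter",
            {
                "id": p.id,
                "value": repr(float(p.value)),
                "constant": "true",
                "name": p.description or p.id,
            },
        )

    lst = ET.SubElement(model, f"{{{SBML_L3_NS}}}listOfReactions")
    for r in doc.network.reactions:
        el = ET.SubElement(
            lst,
            f"{{{SBML_L3_NS}}}reaction",
            {"id": r.id, "reversible": "false"},
        )
        rann = ET.SubElement(el, f"{{{SBML_L3_NS}}}annotation")
        rx = ET.SubElement(rann, f"{{{MACPOL_NS}}}reaction")
        rx.text = json.dumps(
            {"law": _law_to_dict(r.law), "tags": r.tags, "module": r.module}
        )
        if r.reactants:
            lr = ET.SubElement(el, f"{{{SBML_L3_NS}}}listOfReactants")
            for sid, st in r.reactants:
                ET.SubElement(
                    lr,
                    f"{{{SBML_L3_NS}}}speciesReference",
                    {"species": sid, "stoichiometry": repr(float(st)), "constant": "true"},
                )
        if r.products:
            lp = ET.SubElement(el, f"{{{SBML_L3_NS}}}listOfProducts")
            for sid, st in r.products:
                ET.SubElement(
                    lp,
                    f"{{{SBML_L3_NS}}}speciesReference",
                    {"species": sid, "stoichiometry": repr(float(st)), "constant": "true"},
                )
        if r.modifiers:
            lm = ET.SubElement(el, f"{{{SBML_L3_NS}}}listOfModifiers")
            for sid in r.modifiers:
                ET.SubElement(
                    lm,
                    f"{{{SBML_L3_NS}}}modifierSpeciesReference",
                    {"species": sid},
                )
        kl = ET.SubElement(el, f"{{{SBML_L3_NS}}}kineticLaw")
        _mathml_law(kl, r)

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# SBML reading


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _mathml_to_infix(el: ET.Element) -> str:
    tag = _strip(el.tag)
    if tag == "math":
        children = list(el)
        if len(children) != 1:
            raise UnsupportedFeatureError("MathML math element must have one child")
        return _mathml_to_infix(children[0])
    if tag == "ci":
        return el.text.strip()
    if tag == "cn":
        if el.get("type") in ("e-notation", "rational"):
            parts = [t.strip() for t in el.itertext() if t.strip()]
            if el.get("type") == "e-notation":
                return f"({parts[0]}e{parts[1]})"
            return f"({parts[0]}/{parts[1]})"
        return f"({el.text.strip()})"
    if tag != "apply":
        raise UnsupportedFeatureError(f"unsupported MathML element <{tag}>")
    children = list(el)
    op = _strip(children[0].tag)
    args = [_mathml_to_infix(c) for c in children[1:]]
    binary = {"plus": "+", "times": "*", "minus": "-", "divide": "/"}
    if op in binary:
        if op == "minus" and len(args) == 1:
            return f"(-{args[0]})"
        return "(" + f" {binary[op]} ".join(args) + ")"
    if op == "power":
        return f"({args[0]} ** {args[1]})"
    if op in ("exp", "ln", "log", "root"):
        fn = {"exp": "exp", "ln": "log", "log": "log10", "root": "sqrt"}[op]
        return f"{fn}({args[0]})"
    raise UnsupportedFeatureError(f"unsupported MathML operator <{op}>")


def _recognize_mass_action(expr: str, rxn: Reaction, param_ids) -> Optional[RateLaw]:
    """Detect ``k * prod(reactants)`` patterns in an imported infix expression."""
    import re

    tokens = [t for t in re.split(r"[()*\s]+", expr) if t]
    if any(ch in expr for ch in "+-/"):
        return None
    if "**" in expr:
        return None
    needed = []
    for sid, st in rxn.reactants:
        needed.extend([sid] * int(st) if st == int(st) else [None])
    if None in needed:
        return None
    params = [t for t in tokens if t in param_ids]
    species = [t for t in tokens if t not in param_ids]
    if len(params) == 1 and sorted(species) == sorted(needed):
        return RateLaw("mass_action", rate_param=params[0])
    return None


def read_sbml(path) -> ModelDocument:
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise ConfigurationError(f"malformed SBML XML in {path}: {e}") from None
    root = tree.getroot()
    if _strip(root.tag) != "sbml":
        raise ConfigurationError(f"{path}: not an SBML document")
    model = next((c for c in root if _strip(c.tag) == "model"), None)
    if model is None:
        raise ConfigurationError(f"{path}: SBML document has no <model>")

    unsupported = []
    for el in model.iter():
        t = _strip(el.tag)
        if t in ("listOfEvents", "event"):
            unsupported.append("events")
        elif t in ("assignmentRule", "algebraicRule", "rateRule"):
            unsupported.append(f"{t}")
        elif t == "delay":
            unsupported.append("delays")
    if unsupported:
        raise UnsupportedFeatureError(
            "unsupported SBML constructs: " + ", ".join(sorted(set(unsupported)))
        )

    warnings: List[str] = []
    doc_ann: Dict[str, object] = {}
    moieties: List[ConservedMoiety] = []
    for ann in model.iter():
        if _strip(ann.tag) == "document" and ann.tag.startswith(f"{{{MACPOL_NS}}}"):
            blob = json.loads(ann.text)
            doc_ann = blob.get("annotations", {})
            moieties = [
                ConservedMoiety(
                    name=m["name"],
                    members=[(s, float(w)) for s, w in m["members"]],
                    total=m.get("total"),
                )
                for m in blob.get("moieties", [])
            ]

    species: List[Species] = []
    species_parents = [c for c in model if _strip(c.tag) == "listOfSpecies"]
    for el in (e for lst in species_parents for e in lst):
        if _strip(el.tag) != "species":
            continue
        amount = el.get("initialAmount")
        if amount is None:
            conc = el.get("initialConcentration")
            if conc is not None:
                warnings.append(
                    f"species {el.get('id')}: initialConcentration coerced to copies"
                )
                amount = conc
            else:
                amount = "0"
        extra = {"role": "protein", "secreted": False}
        for a in el.iter():
            if _strip(a.tag) == "species" and a.tag.startswith(f"{{{MACPOL_NS}}}"):
                extra.update(json.loads(a.text))
        comp = el.get("compartment", "cytoplasm")
        if comp not in ("extracellular", "cytoplasm", "nucleus"):
            warnings.append(f"species {el.get('id')}: compartment {comp!r} mapped to cytoplasm")
            comp = "cytoplasm"
        species.append(
            Species(
                id=el.get("id"),
                name=el.get("name", "") or el.get("id"),
                role=extra["role"],
                compartment=comp,
                initial_amount=float(amount),
                is_constant=el.get("boundaryCondition") == "true"
                or el.get("constant") == "true",
                secreted=bool(extra["secreted"]),
            )
        )

    parameters: List[Parameter] = []
    seen_params = set()
    # global parameters live directly under listOfParameters
    for lst in model:
        if _strip(lst.tag) == "listOfParameters":
            for el in lst:
                if _strip(el.tag) != "parameter":
                    continue
                parameters.append(
                    Parameter(
                        id=el.get("id"),
                        value=float(el.get("value", "nan")),
                        description=el.get("name", "") or "",
                    )
                )
                seen_params.add(el.get("id"))

    reactions: List[Reaction] = []
    for lst in model:
        if _strip(lst.tag) != "listOfReactions":
            continue
        for el in lst:
            if _strip(el.tag) != "reaction":
                continue
            rid = el.get("id")
            reactants, products, modifiers = [], [], []
            law: Optional[RateLaw] = None
            tags: List[str] = []
            module = None
            math_el = None
            for child in el:
                t = _strip(child.tag)
                if t == "listOfReactants":
                    reactants = [
                        (sr.get("species"), float(sr.get("stoichiometry", "1")))
                        for sr in child
                    ]
                elif t == "listOfProducts":
                    products = [
                        (sr.get("species"), float(sr.get("stoichiometry", "1")))
                        for sr in child
                    ]
                elif t == "listOfModifiers":
                    modifiers = [sr.get("species") for sr in child]
                elif t == "kineticLaw":
                    for sub in child:
                        st = _strip(sub.tag)
                        if st == "math":
                            math_el = sub
                        elif st in ("listOfLocalParameters", "listOfParameters"):
                            # hoist local parameters to namespaced globals
                            for lp in sub:
                                pid = f"{rid}.{lp.get('id')}"
                                parameters.append(
                                    Parameter(id=pid, value=float(lp.get("value")))
                                )
                                seen_params.add(pid)
                elif t == "annotation":
                    for a in child.iter():
                        if a.tag == f"{{{MACPOL_NS}}}reaction":
                            blob = json.loads(a.text)
                            law = RateLaw(**blob["law"])
                            tags = list(blob.get("tags", []))
                            module = blob.get("module")
            rxn = Reaction(
                id=rid,
                reactants=reactants,
                products=products,
                modifiers=modifiers,
                tags=tags,
                module=module,
            )
            if law is None:
                if math_el is None:
                    raise UnsupportedFeatureError(
                        f"reaction {rid}: missing kinetic law"
                    )
                expr = _mathml_to_infix(math_el)
                # rewrite hoisted local-parameter references
                for pid in list(seen_params):
                    if pid.startswith(f"{rid}."):
                        local = pid.split(".", 1)[1]
                        import re

                        expr = re.sub(rf"\b{re.escape(local)}\b", pid, expr)
                law = _recognize_mass_action(expr, rxn, seen_params) or RateLaw(
                    "expression", expression=expr
                )
            rxn.law = law
            reactions.append(rxn)

    net = Network(
        species=species, reactions=reactions, parameters=parameters, moieties=moieties
    )
    return ModelDocument(
        network=net,
        annotations=doc_ann,
        provenance={"source": str(path), "format": "sbml"},
        warnings=warnings,
    )


def convert(in_path: str, out_path: str) -> ModelDocument:
    """Format-sniffing converter used by the CLI ``convert`` command."""
    doc = (
        read_sbml(in_path)
        if str(in_path).endswith((".xml", ".sbml"))
        else read_native(in_path)
    )
    if str(out_path).endswith((".xml", ".sbml")):
        write_sbml(doc, out_path)
    else:
        write_native(doc, out_path)
    return doc
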