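"""SBML Level 3 Version 2 export/import of the clock model.

The model is exported as 19 species governed by rate rules whose content
MathML is generated from the package's symbolic system, plus the 71
constant parameters and the two compartments.  The paired importer reads
such a document back into evaluable form, which gives a full round-trip
check (imported RHS == native RHS).

The writer/reader pair is deliberately narrow: it covers the MathML
vocabulary the model needs (arithmetic, powers), not the whole SBML
standard.  ``validate_document`` performs structural checks (namespace,
ids, symbol resolution), not XSD schema validation.
"""

from __future__ import annotations

import numpy as np
import sympy as sp
from lxml import etree

from .model import ModelDefinition, symbolic_system
from .parameters import PARAM_NAMES, PARAM_UNITS
from .species import SPECIES, Compartment

__all__ = ["export_sbml", "import_sbml", "validate_document", "ImportedModel"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _species_sid(name: str) -> str:
    sid = name.replace("/", "_").replace("-", "_")
    return sid if sid[0].isalpha() or sid[0] == "_" else "_" + sid


def _mathml(expr: sp.Expr) -> etree._Element:
    """Content MathML for the arithmetic subset used by the kinetic laws."""
    E = lambda tag: etree.SubElement  # noqa: E731 (brevity below)

    def build(e: sp.Expr, parent: etree._Element) -> None:
        if isinstance(e, sp.Symbol):
            ci = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
            ci.text = f" {e.name} "
        elif isinstance(e, (sp.Integer, sp.Float, sp.Rational)) or e.is_Number:
            cn = etree.SubElement(parent, f"{{{MATHML_NS}}}cn")
            if isinstance(e, sp.Integer):
                cn.set("type", "integer")
                cn.text = f" {int(e)} "
            else:
                cn.text = f" {float(e)} "
        elif isinstance(e, sp.Add):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}plus")
            for arg in e.args:
                build(arg, ap)
        elif isinstance(e, sp.Mul):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}times")
            for arg in e.args:
                build(arg, ap)
        elif isinstance(e, sp.Pow):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}power")
            build(e.base, ap)
            build(e.exp, ap)
        else:  # pragma: no cover - defensive
            raise ValueError(f"cannot serialize expression node {e!r}")

    math = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
    build(expr, math)
    return math


def export_sbml(model: ModelDefinition, path=None) -> str:
    """Serialize the model as an SBML L3V2 document (returns XML text)."""
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    doc = etree.SubElement(root, f"{{{SBML_NS}}}model")
    doc.set("id", "two_loop_circadian_clock")
    doc.set("name", "Two-loop mammalian circadian clock")

    lc = etree.SubElement(doc, f"{{{SBML_NS}}}listOfCompartments")
    for comp in ("nucleus", "cytoplasm"):
        c = etree.SubElement(lc, f"{{{SBML_NS}}}compartment")
        c.set("id", comp)
        c.set("constant", "true")
        c.set("size", "1")
        c.set("spatialDimensions", "3")

    ls = etree.SubElement(doc, f"{{{SBML_NS}}}listOfSpecies")
    for s in SPECIES:
        el = etree.SubElement(ls, f"{{{SBML_NS}}}species")
        el.set("id", _species_sid(s.name))
        el.set("name", s.name)
        el.set(
            "compartment",
            "nucleus" if s.compartment is Compartment.NUCLEUS else "cytoplasm",
        )
        el.set("initialConcentration", "1")
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "false")
        el.set("constant", "false")

    lp = etree.SubElement(doc, f"{{{SBML_NS}}}listOfParameters")
    for name in PARAM_NAMES:
        el = etree.SubElement(lp, f"{{{SBML_NS}}}parameter")
        el.set("id", name)
        el.set("value", repr(model.params[name]))
        el.set("constant", "true")
        el.set("name", f"{name} [{PARAM_UNITS[name]}]")

    ys, ps, exprs = symbolic_system()
    lr = etree.SubElement(doc, f"{{{SBML_NS}}}listOfRules")
    for s, expr in zip(SPECIES, exprs):
        rule = etree.SubElement(lr, f"{{{SBML_NS}}}rateRule")
        rule.set("variable", _species_sid(s.name))
        rule.append(_mathml(expr))

    text = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _parse_mathml(el: etree._Element, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    tag = etree.QName(el).localname
    if tag == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ValueError("math element must have one child")
        return _parse_mathml(children[0], symbols)
    if tag == "ci":
        name = el.text.strip()
        if name not in symbols:
            raise ValueError(f"unresolved symbol {name!r} in MathML")
        return symbols[name]
    if tag == "cn":
        txt = el.text.strip()
        return sp.Integer(int(txt)) if el.get("type") == "integer" else sp.Float(txt)
    if tag == "apply":
        children = [c for c in el if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_parse_mathml(c, symbols) for c in children[1:]]
        if op == "plus":
            return sp.Add(*args)
        if op == "times":
            return sp.Mul(*args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return sp.Pow(args[0], args[1])
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")


class ImportedModel:
    """An SBML document read back into evaluable form."""

    def __init__(self, parameters, rate_exprs, species_sids):
        self.parameters = parameters
        self.species_sids = species_sids
        syms = [sp.Symbol(s) for s in species_sids]
        substituted = [e.subs(parameters) for e in rate_exprs]
        self._f = sp.lambdify((syms,), sp.Matrix(substituted), modules="numpy")

    def rhs(self, state: np.ndarray) -> np.ndarray:
        return np.asarray(self._f(tuple(state)), dtype=float).ravel()


def import_sbml(source: str) -> ImportedModel:
    """Parse an exported document; ``source`` is XML text or a file path."""
    if source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    else:
        root = etree.parse(source).getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    params = {}
    for el in model.findall(f".//{{{SBML_NS}}}parameter"):
        params[sp.Symbol(el.get("id"))] = float(el.get("value"))
    sids = [
        el.get("id") for el in model.findall(f".//{{{SBML_NS}}}species")
    ]
    symbols = {s: sp.Symbol(s) for s in sids}
    symbols.update({str(k): k for k in params})
    rules = {}
    for rule in model.findall(f".//{{{SBML_NS}}}rateRule"):
        math = rule.find(f"{{{MATHML_NS}}}math")
        rules[rule.get("variable")] = _parse_mathml(math, symbols)
    exprs = [rules[s] for s in sids]
    return ImportedModel(params, exprs, sids)


def validate_document(text: str) -> list[str]:
    """Structural validation; returns a list of problems (empty if clean)."""
    issues = []
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    if etree.QName(root).namespace != SBML_NS:
        issues.append("root element not in the SBML L3V2 namespace")
    if (root.get("level"), root.get("version")) != ("3", "2"):
        issues.append("level/version attributes are not 3/2")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        return issues + ["missing <model>"]
    sids = [el.get("id") for el in model.findall(f".//{{{SBML_NS}}}species")]
    pids = [el.get("id") for el in model.findall(f".//{{{SBML_NS}}}parameter")]
    if len(set(sids)) != len(sids):
        issues.append("duplicate species ids")
    if len(set(pids)) != len(pids):
        issues.append("duplicate parameter ids")
    defined = set(sids) | set(pids)
    for ci in model.iter(f"{{{MATHML_NS}}}ci"):
        if ci.text.strip() not in defined:
            issues.append(f"MathML references undefined symbol {ci.text.strip()!r}")
    rules = model.findall(f".//{{{SBML_NS}}}rateRule")
    missing = set(sids) - {r.get("variable") for r in rules}
    if missing:
        issues.append(f"species without rate rules: {sorted(missing)}")
    return issues
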