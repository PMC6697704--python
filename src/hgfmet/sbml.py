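"""SBML import/export for pathway models (Level 3, also reads Level 2).

The writer emits standard SBML core — compartments, species, global
parameters, and reactions with mass-action kinetic laws in MathML — so the
document loads in any SBML-aware tool.  The modifier semantics that SBML
core cannot express (feedback factors, node-inhibition factors) travel in
a package annotation namespace; the reader uses that annotation when
present and otherwise falls back to parsing plain mass-action MathML
(a product of one parameter and the reactant/modifier species), which is
sufficient for models exported by other tools in that common form.

Import → export → import is structurally idempotent, and parameter values
round-trip at full ``repr`` precision.
"""

from __future__ import annotations

from lxml import etree

from .network import (
    Modifier,
    ParameterDef,
    PathwayModel,
    ReactionDef,
    SpeciesDef,
)

__all__ = ["export_sbml", "import_sbml", "SbmlError"]

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version2/core"
SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"
SBML_L2_PREFIX = "http://www.sbml.org/sbml/level2"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
HGFMET_NS = "urn:hgfmet:annotations"


class SbmlError(ValueError):
    """Malformed or unsupported SBML content."""


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------- export

def _math_ci(name: str) -> etree._Element:
    el = etree.Element(_q(MATHML_NS, "ci"))
    el.text = f" {name} "
    return el


def _math_cn(value: float) -> etree._Element:
    el = etree.Element(_q(MATHML_NS, "cn"))
    el.text = f" {value!r} "
    return el


def _math_apply(op: str, *args: etree._Element) -> etree._Element:
    ap = etree.Element(_q(MATHML_NS, "apply"))
    ap.append(etree.Element(_q(MATHML_NS, op)))
    for a in args:
        ap.append(a)
    return ap


def _modifier_math(mod: Modifier) -> etree._Element:
    total = None
    for sp in mod.species:
        term = _math_ci(sp)
        total = term if total is None else _math_apply("plus", total, term)
    if mod.kind == "mass":
        return total
    scaled = _math_apply("divide", total, _math_cn(mod.scale))
    if mod.kind == "scaled":
        return scaled
    if mod.kind == "activate":
        return _math_apply("plus", _math_cn(1.0),
                           _math_apply("times", _math_ci(mod.weight_param), scaled))
    if mod.kind == "inhibit":
        return _math_apply(
            "divide", _math_cn(1.0),
            _math_apply("plus", _math_cn(1.0),
                        _math_apply("times", _math_ci(mod.weight_param), scaled)))
    # block: 1 - s * D / (D + K)
    K = _math_ci(mod.k_param) if mod.k_param else _math_cn(mod.k_value)
    dose = total
    occ = _math_apply("divide", dose,
                      _math_apply("plus", _modifier_math(Modifier("mass", mod.species)), K))
    return _math_apply("minus", _math_cn(1.0),
                       _math_apply("times", _math_ci(mod.weight_param), occ))


def _kinetic_math(rxn: ReactionDef) -> etree._Element:
    factors = [_math_ci(rxn.rate_param)]
    for sp, n in rxn.reactants:
        factors.append(_math_ci(sp) if n == 1
                       else _math_apply("power", _math_ci(sp), _math_cn(float(n))))
    for mod in rxn.modifiers:
        factors.append(_modifier_math(mod))
    if len(factors) == 1:
        expr = factors[0]
    else:
        expr = _math_apply("times", *factors)
    math = etree.Element(_q(MATHML_NS, "math"))
    math.append(expr)
    return math


def export_sbml(model: PathwayModel, path: str) -> None:
    """Write the model as an SBML Level 3 document."""
    nsmap = {None: SBML_L3_NS, "hm": HGFMET_NS}
    root = etree.Element(_q(SBML_L3_NS, "sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    mdl = etree.SubElement(root, _q(SBML_L3_NS, "model"))
    mdl.set("id", model.name)

    ann = etree.SubElement(mdl, _q(SBML_L3_NS, "annotation"))
    hm = etree.SubElement(ann, _q(HGFMET_NS, "model"))
    for gname, members in model.conservation_groups.items():
        g = etree.SubElement(hm, _q(HGFMET_NS, "conservationGroup"))
        g.set("name", gname)
        g.set("species", " ".join(members))
    for rname, combo in model.readouts.items():
        g = etree.SubElement(hm, _q(HGFMET_NS, "readout"))
        g.set("name", rname)
        g.set("terms", " ".join(f"{sp}:{w!r}" for sp, w in combo.items()))

    comps = etree.SubElement(mdl, _q(SBML_L3_NS, "listOfCompartments"))
    for cname in sorted({s.compartment for s in model.species}):
        c = etree.SubElement(comps, _q(SBML_L3_NS, "compartment"))
        c.set("id", cname)
        c.set("size", "1")
        c.set("constant", "true")

    sps = etree.SubElement(mdl, _q(SBML_L3_NS, "listOfSpecies"))
    for s in model.species:
        el = etree.SubElement(sps, _q(SBML_L3_NS, "species"))
        el.set("id", s.name)
        el.set("compartment", s.compartment)
        el.set("initialAmount", repr(float(s.initial_amount)))
        el.set("hasOnlySubstanceUnits", "true")
        el.set("boundaryCondition", "true" if s.constant else "false")
        el.set("constant", "false")
        sann = etree.SubElement(el, _q(SBML_L3_NS, "annotation"))
        sinfo = etree.SubElement(sann, _q(HGFMET_NS, "speciesInfo"))
        sinfo.set("role", s.role)
        if s.constant:
            sinfo.set("clamped", "true")

    pars = etree.SubElement(mdl, _q(SBML_L3_NS, "listOfParameters"))
    for p in model.parameters:
        el = etree.SubElement(pars, _q(SBML_L3_NS, "parameter"))
        el.set("id", p.name)
        el.set("value", repr(float(p.value)))
        el.set("constant", "true")
        if p.free:
            pann = etree.SubElement(el, _q(SBML_L3_NS, "annotation"))
            pinfo = etree.SubElement(pann, _q(HGFMET_NS, "parameterInfo"))
            pinfo.set("free", "true")
            if p.bounds is not None:
                pinfo.set("lower", repr(float(p.bounds[0])))
                pinfo.set("upper", repr(float(p.bounds[1])))

    rxns = etree.SubElement(mdl, _q(SBML_L3_NS, "listOfReactions"))
    for rxn in model.reactions:
        el = etree.SubElement(rxns, _q(SBML_L3_NS, "reaction"))
        el.set("id", rxn.name)
        el.set("reversible", "false")
        rann = etree.SubElement(el, _q(SBML_L3_NS, "annotation"))
        rh = etree.SubElement(rann, _q(HGFMET_NS, "rateLaw"))
        rh.set("rateParam", rxn.rate_param)
        for mod in rxn.modifiers:
            me = etree.SubElement(rh, _q(HGFMET_NS, "modifier"))
            me.set("kind", mod.kind)
            me.set("species", " ".join(mod.species))
            if mod.weight_param:
                me.set("weightParam", mod.weight_param)
            me.set("scale", repr(float(mod.scale)))
            if mod.k_param:
                me.set("kParam", mod.k_param)
            me.set("kValue", repr(float(mod.k_value)))
        if rxn.reactants:
            lr = etree.SubElement(el, _q(SBML_L3_NS, "listOfReactants"))
            for sp, n in rxn.reactants:
                sr = etree.SubElement(lr, _q(SBML_L3_NS, "speciesReference"))
                sr.set("species", sp)
                sr.set("stoichiometry", str(n))
                sr.set("constant", "true")
        if rxn.products:
            lp = etree.SubElement(el, _q(SBML_L3_NS, "listOfProducts"))
            for sp, n in rxn.products:
                sr = etree.SubElement(lp, _q(SBML_L3_NS, "speciesReference"))
                sr.set("species", sp)
                sr.set("stoichiometry", str(n))
                sr.set("constant", "true")
        mod_species = sorted({sp for mod in rxn.modifiers for sp in mod.species})
        if mod_species:
            lm = etree.SubElement(el, _q(SBML_L3_NS, "listOfModifiers"))
            for sp in mod_species:
                mr = etree.SubElement(lm, _q(SBML_L3_NS, "modifierSpeciesReference"))
                mr.set("species", sp)
        kl = etree.SubElement(el, _q(SBML_L3_NS, "kineticLaw"))
        kl.append(_kinetic_math(rxn))

    tree = etree.ElementTree(root)
    tree.write(path, pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------- import

def _find_sbml_ns(root: etree._Element) -> str:
    tag = etree.QName(root.tag)
    if tag.localname != "sbml":
        raise SbmlError(f"root element is {tag.localname!r}, not <sbml>")
    ns = tag.namespace or ""
    if ns in (SBML_L3_NS, SBML_L3V1_NS) or ns.startswith(SBML_L2_PREFIX):
        return ns
    raise SbmlError(f"unsupported SBML namespace {ns!r}")


def _parse_plain_mass_action(math: etree._Element, species: set[str],
                             parameters: set[str], reactants: set[str],
                             rxn_id: str) -> tuple[str, list[Modifier]]:
    """Interpret a kinetic law of the form k * X * Y ... (possibly nested
    <times>)."""
    leaves: list[str] = []

    def walk(el: etree._Element) -> None:
        tag = etree.QName(el.tag).localname
        if tag == "math":
            kids = [k for k in el if isinstance(k.tag, str)]
            if len(kids) != 1:
                raise SbmlError(f"reaction {rxn_id}: unsupported kinetic law")
            walk(kids[0])
        elif tag == "ci":
            leaves.append(el.text.strip())
        elif tag == "apply":
            kids = [k for k in el if isinstance(k.tag, str)]
            if not kids or etree.QName(kids[0].tag).localname != "times":
                raise SbmlError(
                    f"reaction {rxn_id}: only mass-action (times of ci) kinetic "
                    "laws are supported without package annotations"
                )
            for k in kids[1:]:
                walk(k)
        else:
            raise SbmlError(
                f"reaction {rxn_id}: unsupported MathML element <{tag}>"
            )

    walk(math)
    rate_params = [x for x in leaves if x in parameters]
    if len(rate_params) != 1:
        raise SbmlError(
            f"reaction {rxn_id}: expected exactly one rate parameter, "
            f"found {rate_params}"
        )
    mods = []
    for x in leaves:
        if x in parameters:
            continue
        if x not in species:
            raise SbmlError(f"reaction {rxn_id}: unknown symbol {x!r}")
        if x not in reactants:
            mods.append(Modifier("mass", (x,)))
    return rate_params[0], mods


def import_sbml(path: str) -> PathwayModel:
    """Read an SBML file into a simulatable :class:`PathwayModel`."""
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    ns = _find_sbml_ns(root)
    mdl = root.find(_q(ns, "model"))
    if mdl is None:
        raise SbmlError("no <model> element")

    species: list[SpeciesDef] = []
    for el in mdl.findall(f"{_q(ns, 'listOfSpecies')}/{_q(ns, 'species')}"):
        name = el.get("id")
        comp = el.get("compartment", "cytosolic")
        if comp not in ("extracellular", "surface", "endosomal", "cytosolic"):
            comp = "cytosolic"
        amt = float(el.get("initialAmount") or el.get("initialConcentration") or 0.0)
        sinfo = el.find(f"{_q(ns, 'annotation')}/{_q(HGFMET_NS, 'speciesInfo')}")
        role = sinfo.get("role") if sinfo is not None else "signaling_inactive"
        clamped = el.get("boundaryCondition") == "true" or (
            sinfo is not None and sinfo.get("clamped") == "true")
        species.append(SpeciesDef(name, comp, role, amt, clamped))

    parameters: list[ParameterDef] = []
    for el in mdl.findall(f"{_q(ns, 'listOfParameters')}/{_q(ns, 'parameter')}"):
        pinfo = el.find(f"{_q(ns, 'annotation')}/{_q(HGFMET_NS, 'parameterInfo')}")
        free = pinfo is not None and pinfo.get("free") == "true"
        bounds = None
        if pinfo is not None and pinfo.get("lower") is not None:
            bounds = (float(pinfo.get("lower")), float(pinfo.get("upper")))
        parameters.append(ParameterDef(el.get("id"), float(el.get("value", 0.0)),
                                       free, bounds))
    # SBML L2/L3 local parameters are promoted to globals with
    # reaction-scoped names so the whole parameterization is addressable.
    local_tags = ("localParameter", "parameter")
    sp_names = {s.name for s in species}
    p_names = {p.name for p in parameters}

    reactions: list[ReactionDef] = []
    for el in mdl.findall(f"{_q(ns, 'listOfReactions')}/{_q(ns, 'reaction')}"):
        rid = el.get("id")
        reactants = [
            (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
            for sr in el.findall(f"{_q(ns, 'listOfReactants')}/{_q(ns, 'speciesReference')}")
        ]
        products = [
            (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
            for sr in el.findall(f"{_q(ns, 'listOfProducts')}/{_q(ns, 'speciesReference')}")
        ]
        kl = el.find(_q(ns, "kineticLaw"))
        if kl is None:
            raise SbmlError(f"reaction {rid}: missing kinetic law")
        for lol in (kl.findall(_q(ns, "listOfLocalParameters")) +
                    kl.findall(_q(ns, "listOfParameters"))):
            for lp in lol:
                if etree.QName(lp.tag).localname not in local_tags:
                    continue
                gname = lp.get("id")
                if gname in p_names:
                    gname = f"{rid}__{lp.get('id')}"
                parameters.append(ParameterDef(gname, float(lp.get("value", 0.0))))
                p_names.add(gname)

        rate_ann = el.find(f"{_q(ns, 'annotation')}/{_q(HGFMET_NS, 'rateLaw')}")
        if rate_ann is not None:
            rate_param = rate_ann.get("rateParam")
            mods = []
            for me in rate_ann.findall(_q(HGFMET_NS, "modifier")):
                mods.append(Modifier(
                    me.get("kind"),
                    tuple(me.get("species").split()),
                    weight_param=me.get("weightParam"),
                    scale=float(me.get("scale", 1.0)),
                    k_param=me.get("kParam"),
                    k_value=float(me.get("kValue", 1e-3)),
                ))
        else:
            math = kl.find(_q(MATHML_NS, "math"))
            if math is None:
                raise SbmlError(f"reaction {rid}: kinetic law has no MathML")
            rate_param, mods = _parse_plain_mass_action(
                math, sp_names, p_names, {sp for sp, _ in reactants}, rid
            )
        reactions.append(ReactionDef(rid, tuple(reactants), tuple(products),
                                     rate_param, tuple(mods)))

    groups: dict[str, tuple[str, ...]] = {}
    readouts: dict[str, dict[str, float]] = {}
    hm = mdl.find(f"{_q(ns, 'annotation')}/{_q(HGFMET_NS, 'model')}")
    if hm is not None:
        for g in hm.findall(_q(HGFMET_NS, "conservationGroup")):
            groups[g.get("name")] = tuple(g.get("species").split())
        for g in hm.findall(_q(HGFMET_NS, "readout")):
            combo = {}
            for term in g.get("terms").split():
                sp, w = term.rsplit(":", 1)
                combo[sp] = float(w)
            readouts[g.get("name")] = combo

    return PathwayModel(species, parameters, reactions, groups, readouts,
                        name=mdl.get("id", "imported"))
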