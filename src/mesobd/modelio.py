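"""Model-document reading, validation and writing.

A model is an XML document (schema shipped as ``schema/model.xsd``)
describing the simulation volume and step, the diffusion landscapes, the
entity templates (particles, reaction sites, features), the reaction
rules, membrane domains, timed entity injections and the output request.

Units in the file are chosen for human editing and converted to SI on
load: lengths in nm, times in ms, viscosities in Pa s, temperatures in K,
and rates in the per-order molar units (M/s, 1/s, 1/(M s)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .dynamics import (
    BoundaryConditionSet,
    LANDSCAPE_TAGS,
    LandscapeSpec,
    MembraneDomain,
    TAG_MEMBRANE,
    TAG_STATIC,
)
from .engine import SimulationConfig, UserEvent
from .model import EntityTemplate, FeatureDef, ParticleTemplate, SiteTemplate
from .reactions import Effect, Guard, ReactionRule

NM = 1e-9
MS = 1e-3

_AXES = {"x": 0, "y": 1, "z": 2}
_OUTPUT_FIELDS = ("position", "orientation", "feature_state", "entity_count")


class ModelError(ValueError):
    """A model document failed schema or cross-reference validation."""


@dataclass
class OutputSpec:
    selected: tuple[str, ...] = ()
    divisor: int = 1
    fields: tuple[str, ...] = ("entity_count",)

    def __post_init__(self):
        if self.divisor < 1:
            raise ModelError("output timepoints divisor must be >= 1")
        for f in self.fields:
            if f not in _OUTPUT_FIELDS:
                raise ModelError(f"unknown output field {f!r}")


@dataclass
class ModelDocument:
    L: float
    dt: float
    n_iter: int
    T: float = 298.15
    n_v: int = 1
    seed: int = 1
    rng_mode: str = "on_demand"
    landscapes: dict = field(default_factory=dict)
    domains: list = field(default_factory=list)
    face_conditions: dict = field(default_factory=dict)
    entities: list = field(default_factory=list)
    rules: list = field(default_factory=list)
    user_events: list = field(default_factory=list)
    output: OutputSpec = field(default_factory=OutputSpec)

    def template(self, tid: str) -> EntityTemplate:
        for t in self.entities:
            if t.id == tid:
                return t
        raise KeyError(tid)


def build_config(document: ModelDocument, **overrides) -> SimulationConfig:
    kw = dict(
        dt=document.dt,
        n_iter=document.n_iter,
        L=document.L,
        n_v=document.n_v,
        T=document.T,
        seed=document.seed,
        rng_mode=document.rng_mode,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# Reading


def _schema() -> etree.XMLSchema:
    path = Path(__file__).parent / "schema" / "model.xsd"
    return etree.XMLSchema(etree.parse(str(path)))


def _err(el, msg: str) -> ModelError:
    line = getattr(el, "sourceline", None)
    where = f" (line {line})" if line else ""
    return ModelError(f"<{el.tag}>{where}: {msg}")


def _get(el, name: str, conv=str, default=None, required=False):
    raw = el.get(name)
    if raw is None:
        if required:
            raise _err(el, f"missing required attribute {name!r}")
        return default
    try:
        return conv(raw)
    except (TypeError, ValueError) as e:
        raise _err(el, f"bad value for attribute {name!r}: {raw!r}") from e


def _vec_nm(el, names) -> np.ndarray:
    return np.array([_get(el, n, float, required=True) for n in names]) * NM


def _parse_conditions(parent) -> BoundaryConditionSet:
    entries = []
    for cond in parent.findall("condition"):
        kind = _get(cond, "type", str, required=True)
        p = _get(cond, "probability", float, default=1.0)
        entries.append((kind, p))
    if not entries:
        return BoundaryConditionSet()
    try:
        return BoundaryConditionSet(entries)
    except ValueError as e:
        raise _err(parent, str(e)) from e


def read_model(source) -> ModelDocument:
    """Parse, unit-normalise and validate a model document.

    ``source`` is a path or a file-like object.  Raises
    :class:`ModelError` naming the offending element for any schema,
    unit or cross-reference failure.
    """
    try:
        tree = etree.parse(source if not isinstance(source, (str, Path)) else str(source))
    except etree.XMLSyntaxError as e:
        raise ModelError(f"malformed XML: {e}") from e
    schema = _schema()
    if not schema.validate(tree):
        first = schema.error_log[0]
        raise ModelError(f"schema violation at line {first.line}: {first.message}")
    root = tree.getroot()

    sim = root.find("simulation")
    doc = ModelDocument(
        L=_get(sim, "side", float, required=True) * NM,
        dt=_get(sim, "dt", float, required=True) * MS,
        n_iter=_get(sim, "iterations", int, required=True),
        T=_get(sim, "temperature", float, default=298.15),
        n_v=_get(sim, "voxels", int, default=1),
        seed=_get(sim, "seed", int, default=1),
        rng_mode=_get(sim, "rng-mode", str, default="on_demand"),
    )
    if doc.L <= 0 or doc.dt <= 0 or doc.n_iter < 0 or doc.n_v < 1:
        raise _err(sim, "side, dt must be > 0; iterations >= 0; voxels >= 1")

    lands = root.find("landscapes")
    if lands is not None:
        for el in lands.findall("landscape"):
            tag = _get(el, "tag", str, required=True)
            if tag not in LANDSCAPE_TAGS:
                raise _err(el, f"unknown landscape tag {tag!r}")
            spec = LandscapeSpec(
                tag=tag,
                viscosity=_get(el, "viscosity", float, default=1e-3),
                membrane_y=_get(el, "membrane-y", float, default=0.0) * NM,
                membrane_thickness=_get(el, "thickness", float, default=5.0) * NM,
                exterior_viscosity=_get(el, "exterior-viscosity", float, default=1e-3),
            )
            doc.landscapes[tag] = spec
        for el in lands.findall("domain"):
            bnd_in = bnd_out = None
            for b in el.findall("boundary"):
                direction = _get(b, "direction", str, required=True)
                conds = _parse_conditions(b)
                if any(kind == "periodic" for kind, _ in conds.entries):
                    raise _err(b, "periodic conditions are not supported on circular domain boundaries")
                if direction == "in":
                    bnd_in = conds
                elif direction == "out":
                    bnd_out = conds
                else:
                    raise _err(b, f"direction must be 'in' or 'out', got {direction!r}")
            doc.domains.append(
                MembraneDomain(
                    id=_get(el, "id", str, required=True),
                    centre=(
                        _get(el, "x", float, required=True) * NM,
                        _get(el, "z", float, required=True) * NM,
                    ),
                    radius=_get(el, "radius", float, required=True) * NM,
                    viscosity=_get(el, "viscosity", float, required=True),
                    boundary_in=bnd_in,
                    boundary_out=bnd_out,
                )
            )

    bounds = root.find("boundaries")
    if bounds is not None:
        for el in bounds.findall("face"):
            axis_name = _get(el, "axis", str, required=True)
            if axis_name not in _AXES:
                raise _err(el, f"axis must be x, y or z, got {axis_name!r}")
            axis = _AXES[axis_name]
            side = _get(el, "side", str, default=None)
            conds = _parse_conditions(el)
            sides = (side,) if side in ("low", "high") else ("low", "high")
            for s in sides:
                doc.face_conditions[(axis, s)] = conds

    ents = root.find("entities")
    site_types: set[str] = set()
    if ents is not None:
        for el in ents.findall("entity"):
            features = []
            for f in el.findall("feature"):
                states = tuple(
                    s.strip() for s in _get(f, "states", str, required=True).split(",")
                )
                features.append(
                    FeatureDef(
                        name=_get(f, "name", str, required=True),
                        states=states,
                        initial_state=_get(f, "initial", str, default=states[0]),
                    )
                )
            particles = []
            for p in el.findall("particle"):
                sites = []
                for s in p.findall("site"):
                    try:
                        site = SiteTemplate(
                            site_type=_get(s, "type", str, required=True),
                            centre=_vec_nm(s, ("cx", "cy", "cz")),
                            normal_point=_vec_nm(s, ("nx", "ny", "nz")),
                            plane_point=_vec_nm(s, ("px", "py", "pz")),
                        )
                    except ValueError as e:
                        raise _err(s, str(e)) from e
                    sites.append(site)
                    site_types.add(site.site_type)
                tag = _get(p, "landscape", str, default="unrestricted")
                if tag not in LANDSCAPE_TAGS:
                    raise _err(p, f"unknown landscape tag {tag!r}")
                try:
                    particles.append(
                        ParticleTemplate(
                            id=_get(p, "id", str, required=True),
                            hydro_radius=_get(p, "radius", float, required=True) * NM,
                            landscape_tag=tag,
                            rel_position=_vec_nm(p, ("x", "y", "z")),
                            sites=tuple(sites),
                        )
                    )
                except ValueError as e:
                    raise _err(p, str(e)) from e
            try:
                doc.entities.append(
                    EntityTemplate(
                        id=_get(el, "id", str, required=True),
                        particles=tuple(particles),
                        features=tuple(features),
                        initial_count=_get(el, "count", int, default=0),
                        placement=_get(el, "placement", str, default="unrestricted"),
                    )
                )
            except ValueError as e:
                raise _err(el, str(e)) from e

    rxs = root.find("reactions")
    if rxs is not None:
        for el in rxs.findall("reaction"):
            guards = tuple(
                Guard(
                    target=_get(g, "target", str, default="a"),
                    feature=_get(g, "feature", str, required=True),
                    state=_get(g, "state", str, default="*"),
                    multiplier=_get(g, "multiplier", float, default=1.0),
                )
                for g in el.findall("guard")
            )
            effects = tuple(
                Effect(
                    target=_get(e2, "target", str, default="a"),
                    feature=_get(e2, "feature", str, required=True),
                    action=_get(e2, "action", str, default="set"),
                    value=_get(e2, "value", str, default=None),
                )
                for e2 in el.findall("effect")
            )
            try:
                rule = ReactionRule(
                    id=_get(el, "id", str, required=True),
                    order=_get(el, "order", int, required=True),
                    rate=_get(el, "rate", float, required=True),
                    product=_get(el, "product", str, default=None),
                    creation_landscape=_get(el, "landscape", str, default="unrestricted"),
                    reactant=_get(el, "reactant", str, default=None),
                    outcome=_get(el, "outcome", str, default="none"),
                    site_a=_get(el, "site-a", str, default=None),
                    site_b=_get(el, "site-b", str, default=None),
                    kind=_get(el, "kind", str, default=""),
                    forward_rule=_get(el, "forward", str, default=None),
                    binding=_get(el, "binding", lambda v: v.lower() == "true", default=False),
                    guards=guards,
                    effects=effects,
                )
            except ValueError as e:
                raise _err(el, str(e)) from e
            doc.rules.append(rule)

    evs = root.find("events")
    if evs is not None:
        for el in evs.findall("event"):
            states = {
                _get(s, "feature", str, required=True): _get(s, "value", str, required=True)
                for s in el.findall("state")
            }
            doc.user_events.append(
                UserEvent(
                    iteration=_get(el, "iteration", int, required=True),
                    template_id=_get(el, "entity", str, required=True),
                    position=_vec_nm(el, ("x", "y", "z")),
                    feature_states=states,
                )
            )

    out = root.find("output")
    if out is not None:
        selected = tuple(_get(s, "entity", str, required=True) for s in out.findall("select"))
        fields = tuple(_get(f, "name", str, required=True) for f in out.findall("field"))
        try:
            doc.output = OutputSpec(
                selected=selected,
                divisor=_get(out, "timepoints", int, default=1),
                fields=fields or ("entity_count",),
            )
        except ModelError as e:
            raise _err(out, str(e)) from e

    _validate_cross_references(doc)
    return doc


def _validate_cross_references(doc: ModelDocument) -> None:
    template_ids = {t.id for t in doc.entities}
    site_owner: dict[str, EntityTemplate] = {}
    for t in doc.entities:
        for _, _, site in t.iter_sites():
            site_owner.setdefault(site.site_type, t)

    needs_membrane = any(
        TAG_MEMBRANE in t.landscape_set or t.placement == TAG_MEMBRANE
        for t in doc.entities
    )
    if (needs_membrane or doc.domains) and TAG_MEMBRANE not in doc.landscapes:
        raise ModelError(
            "membrane particles, placements or domains require a membrane landscape"
        )
    mem = doc.landscapes.get(TAG_MEMBRANE)
    if mem is not None and abs(mem.membrane_y) > doc.L / 2:
        raise ModelError("membrane-y lies outside the simulation volume")

    regions = set(LANDSCAPE_TAGS)
    for t in doc.entities:
        if t.placement not in regions:
            raise ModelError(f"entity {t.id!r}: unknown placement {t.placement!r}")

    rule_ids = set()
    for rule in doc.rules:
        if rule.id in rule_ids:
            raise ModelError(f"duplicate rule id {rule.id!r}")
        rule_ids.add(rule.id)
        if rule.order == 0:
            if rule.product not in template_ids:
                raise ModelError(f"rule {rule.id!r}: unknown product {rule.product!r}")
            if rule.creation_landscape == TAG_MEMBRANE:
                raise ModelError(
                    f"rule {rule.id!r}: zeroth-order creation in the membrane plane "
                    "has no volume; use a 3D creation landscape"
                )
        elif rule.order == 1 and rule.kind == "unbind":
            for st in (rule.site_a, rule.site_b):
                if st not in site_owner:
                    raise ModelError(f"rule {rule.id!r}: unknown site type {st!r}")
            fwd = next((r for r in doc.rules if r.id == rule.forward_rule), None)
            if fwd is None or not fwd.binding:
                raise ModelError(
                    f"rule {rule.id!r}: unbind rules must name a binding rule via "
                    "'forward' (sets the separation distance)"
                )
        elif rule.order == 1:
            if rule.reactant not in template_ids:
                raise ModelError(f"rule {rule.id!r}: unknown reactant {rule.reactant!r}")
            if rule.outcome not in ("none", "remove"):
                raise ModelError(f"rule {rule.id!r}: unknown outcome {rule.outcome!r}")
        elif rule.order == 2:
            for st in (rule.site_a, rule.site_b):
                if st not in site_owner:
                    raise ModelError(f"rule {rule.id!r}: unknown site type {st!r}")
            if rule.product is not None and rule.product not in template_ids:
                raise ModelError(f"rule {rule.id!r}: unknown product {rule.product!r}")
        # guard/effect feature references
        for g in rule.guards + rule.effects:
            owner = None
            if rule.order == 2 or rule.kind == "unbind":
                st = rule.site_a if g.target == "a" else rule.site_b
                owner = site_owner.get(st)
            elif rule.order == 1:
                owner = next((t for t in doc.entities if t.id == rule.reactant), None)
            if owner is None:
                continue
            if g.feature not in {f.name for f in owner.features}:
                raise ModelError(
                    f"rule {rule.id!r}: template {owner.id!r} declares no feature "
                    f"{g.feature!r}"
                )

    for ev in doc.user_events:
        if ev.template_id not in template_ids:
            raise ModelError(f"event at iteration {ev.iteration}: unknown entity {ev.template_id!r}")
        if ev.iteration > doc.n_iter:
            raise ModelError(
                f"event at iteration {ev.iteration} lies beyond the run length {doc.n_iter}"
            )

    for sel in doc.output.selected:
        if sel not in template_ids:
            raise ModelError(f"output selects unknown entity {sel!r}")


# ---------------------------------------------------------------------------
# Writing


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_model(doc: ModelDocument, sink) -> None:
    """Serialise a model document back to the XML dialect (nm / ms units)."""
    root = etree.Element("mesobd-model", version="1")
    etree.SubElement(
        root,
        "simulation",
        side=_fmt(doc.L / NM),
        dt=_fmt(doc.dt / MS),
        iterations=str(doc.n_iter),
        temperature=_fmt(doc.T),
        voxels=str(doc.n_v),
        seed=str(doc.seed),
        **{"rng-mode": doc.rng_mode},
    )
    lands = etree.SubElement(root, "landscapes")
    for tag, spec in doc.landscapes.items():
        attrs = {"tag": tag, "viscosity": _fmt(spec.viscosity)}
        if tag == TAG_MEMBRANE:
            attrs["membrane-y"] = _fmt(spec.membrane_y / NM)
            attrs["thickness"] = _fmt(spec.membrane_thickness / NM)
            attrs["exterior-viscosity"] = _fmt(spec.exterior_viscosity)
        etree.SubElement(lands, "landscape", **attrs)
    for dom in doc.domains:
        el = etree.SubElement(
            lands,
            "domain",
            id=dom.id,
            x=_fmt(dom.centre[0] / NM),
            z=_fmt(dom.centre[1] / NM),
            radius=_fmt(dom.radius / NM),
            viscosity=_fmt(dom.viscosity),
        )
        for direction, conds in (("in", dom.boundary_in), ("out", dom.boundary_out)):
            if conds is None:
                continue
            b = etree.SubElement(el, "boundary", direction=direction)
            for kind, p in conds.entries:
                etree.SubElement(b, "condition", type=kind, probability=_fmt(p))

    bounds = etree.SubElement(root, "boundaries")
    for (axis, side), conds in sorted(doc.face_conditions.items()):
        el = etree.SubElement(
            bounds, "face", axis="xyz"[axis], side=side
        )
        for kind, p in conds.entries:
            etree.SubElement(el, "condition", type=kind, probability=_fmt(p))

    ents = etree.SubElement(root, "entities")
    for t in doc.entities:
        el = etree.SubElement(
            ents, "entity", id=t.id, count=str(t.initial_count), placement=t.placement
        )
        for f in t.features:
            etree.SubElement(
                el, "feature", name=f.name, states=",".join(f.states), initial=f.initial_state
            )
        for p in t.particles:
            pe = etree.SubElement(
                el,
                "particle",
                id=p.id,
                radius=_fmt(p.hydro_radius / NM),
                landscape=p.landscape_tag,
                x=_fmt(p.rel_position[0] / NM),
                y=_fmt(p.rel_position[1] / NM),
                z=_fmt(p.rel_position[2] / NM),
            )
            for s in p.sites:
                etree.SubElement(
                    pe,
                    "site",
                    type=s.site_type,
                    cx=_fmt(s.centre[0] / NM), cy=_fmt(s.centre[1] / NM), cz=_fmt(s.centre[2] / NM),
                    nx=_fmt(s.normal_point[0] / NM), ny=_fmt(s.normal_point[1] / NM), nz=_fmt(s.normal_point[2] / NM),
                    px=_fmt(s.plane_point[0] / NM), py=_fmt(s.plane_point[1] / NM), pz=_fmt(s.plane_point[2] / NM),
                )

    rxs = etree.SubElement(root, "reactions")
    for r in doc.rules:
        attrs = {"id": r.id, "order": str(r.order), "rate": _fmt(r.rate)}
        if r.product is not None:
            attrs["product"] = r.product
        if r.order == 0:
            attrs["landscape"] = r.creation_landscape
        if r.reactant is not None:
            attrs["reactant"] = r.reactant
        if r.outcome != "none":
            attrs["outcome"] = r.outcome
        if r.site_a is not None:
            attrs["site-a"] = r.site_a
        if r.site_b is not None:
            attrs["site-b"] = r.site_b
        if r.kind:
            attrs["kind"] = r.kind
        if r.forward_rule is not None:
            attrs["forward"] = r.forward_rule
        if r.binding:
            attrs["binding"] = "true"
        el = etree.SubElement(rxs, "reaction", **attrs)
        for g in r.guards:
            etree.SubElement(
                el, "guard", target=g.target, feature=g.feature, state=g.state,
                multiplier=_fmt(g.multiplier),
            )
        for e in r.effects:
            a = {"target": e.target, "feature": e.feature, "action": e.action}
            if e.value is not None:
                a["value"] = e.value
            etree.SubElement(el, "effect", **a)

    evs = etree.SubElement(root, "events")
    for ev in doc.user_events:
        el = etree.SubElement(
            evs,
            "event",
            iteration=str(ev.iteration),
            entity=ev.template_id,
            x=_fmt(ev.position[0] / NM),
            y=_fmt(ev.position[1] / NM),
            z=_fmt(ev.position[2] / NM),
        )
        for feat, val in ev.feature_states.items():
            etree.SubElement(el, "state", feature=feat, value=val)

    out = etree.SubElement(root, "output", timepoints=str(doc.output.divisor))
    for sel in doc.output.selected:
        etree.SubElement(out, "select", entity=sel)
    for f in doc.output.fields:
        etree.SubElement(out, "field", name=f)

    data = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if isinstance(sink, (str, Path)):
        Path(sink).write_bytes(data)
    else:
        try:
            sink.write(data)
        except TypeError:
            sink.write(data.decode())


def roundtrip(doc: ModelDocument) -> ModelDocument:
    """write + re-read (used by tests and the validate CLI)."""
    buf = io.BytesIO()
    write_model(doc, buf)
    buf.seek(0)
    return read_model(buf)
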