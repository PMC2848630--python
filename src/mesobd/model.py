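"""Hierarchical representation of molecular species.

The simulator models molecules on three levels:

* **particles** — the geometric building blocks; each carries a
  hydrodynamic radius, a diffusion-landscape tag and any number of
  reaction sites;
* **entities** — permanent molecules assembled from particles; an entity
  never decomposes at run time and carries user-defined feature states;
* **clusters** — the mobile run-time objects: one or more entities held
  together by bonds.  A cluster diffuses as a rigid body; its hydrodynamic
  radius is that of a sphere whose volume is the sum of the member particle
  sphere volumes, and its diffusion landscape is the most limiting landscape
  of its members.

A reaction site is defined by three points in its particle's frame: the
centre point, a second point defining the outward *normal* vector and a
third defining the in-plane *plane* vector perpendicular to the normal.
The two vectors fix the geometry of binding.

Positions are nested: site centre relative to particle centre, particle
relative to entity centre of mass, entity relative to cluster centre of
mass, cluster relative to the centre of the cubic simulation volume.
Orientations are unit quaternions; the model file accepts axis-angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    TAG_MEMBRANE,
    TAG_STATIC,
    effective_landscape,
)
from .geometry import IDENTITY_QUAT, normalize, qmult, qrotate
from .rng import RandomStream

# a site's plane vector may deviate from perpendicularity by at most this
# (cosine of the angle to the normal) before the model is rejected; smaller
# deviations are silently re-orthogonalised
PERP_REJECT_TOL = 1e-3

SiteRef = tuple[int, int]  # (particle index, site index within particle)


class PlacementError(ValueError):
    """Requested position is incompatible with the volume or landscape."""


class OccupancyError(ValueError):
    """A binding operation addressed a site in the wrong occupancy state."""


class UidAllocator:
    """Monotone source of unique run-time identifiers."""

    def __init__(self, start: int = 1):
        self._next = start

    def take(self) -> int:
        uid = self._next
        self._next += 1
        return uid


# ---------------------------------------------------------------------------
# Templates (immutable, defined by the model document)


@dataclass(frozen=True)
class SiteTemplate:
    """Three-point reaction site in the parent particle's frame (m)."""

    site_type: str
    centre: np.ndarray
    normal_point: np.ndarray
    plane_point: np.ndarray
    normal: np.ndarray = field(init=False, repr=False)
    plane: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        centre = np.asarray(self.centre, dtype=float)
        n = np.asarray(self.normal_point, dtype=float) - centre
        p = np.asarray(self.plane_point, dtype=float) - centre
        if np.linalg.norm(n) == 0.0:
            raise ValueError(f"site {self.site_type!r}: normal point equals centre point")
        if np.linalg.norm(p) == 0.0:
            raise ValueError(f"site {self.site_type!r}: plane point equals centre point")
        n = normalize(n)
        p_unit = normalize(p)
        cosang = float(np.dot(n, p_unit))
        if abs(cosang) > PERP_REJECT_TOL:
            raise ValueError(
                f"site {self.site_type!r}: plane vector is not perpendicular to the "
                f"normal vector (cos angle = {cosang:.3g})"
            )
        # Gram-Schmidt: make the pair exactly orthonormal
        p_orth = normalize(p_unit - cosang * n)
        object.__setattr__(self, "centre", centre)
        object.__setattr__(self, "normal_point", np.asarray(self.normal_point, dtype=float))
        object.__setattr__(self, "plane_point", np.asarray(self.plane_point, dtype=float))
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "plane", p_orth)


@dataclass(frozen=True)
class ParticleTemplate:
    id: str
    hydro_radius: float
    landscape_tag: str
    rel_position: np.ndarray
    sites: tuple[SiteTemplate, ...] = ()

    def __post_init__(self):
        if self.hydro_radius <= 0:
            raise ValueError(f"particle {self.id!r}: hydro_radius must be > 0")
        object.__setattr__(self, "rel_position", np.asarray(self.rel_position, dtype=float))
        object.__setattr__(self, "sites", tuple(self.sites))


@dataclass(frozen=True)
class FeatureDef:
    name: str
    states: tuple[str, ...]
    initial_state: str

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 1:
            raise ValueError(f"feature {self.name!r}: needs at least one state")
        if self.initial_state not in self.states:
            raise ValueError(
                f"feature {self.name!r}: initial state {self.initial_state!r} "
                f"not in {self.states}"
            )


@dataclass(frozen=True)
class EntityTemplate:
    id: str
    particles: tuple[ParticleTemplate, ...]
    features: tuple[FeatureDef, ...] = ()
    initial_count: int = 0
    placement: str = "unrestricted"

    def __post_init__(self):
        object.__setattr__(self, "particles", tuple(self.particles))
        object.__setattr__(self, "features", tuple(self.features))
        if len(self.particles) < 1:
            raise ValueError(f"entity {self.id!r}: needs at least one particle")
        pids = [p.id for p in self.particles]
        if len(set(pids)) != len(pids):
            raise ValueError(f"entity {self.id!r}: duplicate particle ids")
        fnames = [f.name for f in self.features]
        if len(set(fnames)) != len(fnames):
            raise ValueError(f"entity {self.id!r}: duplicate feature names")

    @property
    def landscape_set(self) -> frozenset[str]:
        return frozenset(p.landscape_tag for p in self.particles)

    @property
    def hydro_radius(self) -> float:
        return cluster_hydro_radius([p.hydro_radius for p in self.particles])

    def iter_sites(self):
        for pi, particle in enumerate(self.particles):
            for si, site in enumerate(particle.sites):
                yield (pi, si), particle, site


# ---------------------------------------------------------------------------
# Run-time objects


@dataclass
class Bond:
    uid: int
    entity_a: int
    site_a: SiteRef
    entity_b: int
    site_b: SiteRef

    def partners(self):
        return (self.entity_a, self.site_a), (self.entity_b, self.site_b)


@dataclass
class EntityInstance:
    """A live molecule: permanent identity, feature states, bound sites."""

    uid: int
    template: EntityTemplate
    feature_states: dict[str, str]
    rel_com: np.ndarray
    orientation: np.ndarray
    site_bonds: dict[SiteRef, Bond | None]

    @property
    def user_id(self) -> str:
        return self.template.id

    def site_template(self, ref: SiteRef) -> SiteTemplate:
        pi, si = ref
        return self.template.particles[pi].sites[si]

    def site_local_offset(self, ref: SiteRef) -> np.ndarray:
        pi, si = ref
        particle = self.template.particles[pi]
        return particle.rel_position + particle.sites[si].centre

    def is_free(self, ref: SiteRef) -> bool:
        return self.site_bonds[ref] is None


@dataclass
class Cluster:
    """Mobile rigid complex of entities; the unit of diffusion."""

    uid: int
    entities: list[EntityInstance]
    bonds: list[Bond]
    com: np.ndarray
    orientation: np.ndarray
    hydro_radius: float = 0.0
    landscape_set: frozenset[str] = frozenset()
    effective_landscape: str = ""
    D: float = 0.0  # filled in by the engine from the physical context

    def entity(self, uid: int) -> EntityInstance:
        for e in self.entities:
            if e.uid == uid:
                return e
        raise KeyError(f"entity {uid} not in cluster {self.uid}")

    def recompute_derived(self) -> None:
        radii = [
            p.hydro_radius for e in self.entities for p in e.template.particles
        ]
        self.hydro_radius = cluster_hydro_radius(radii)
        self.landscape_set = frozenset(
            p.landscape_tag for e in self.entities for p in e.template.particles
        )
        self.effective_landscape = effective_landscape(self.landscape_set)

    def entity_world_position(self, entity: EntityInstance) -> np.ndarray:
        return self.com + qrotate(self.orientation, entity.rel_com)

    def entity_world_orientation(self, entity: EntityInstance) -> np.ndarray:
        return qmult(self.orientation, entity.orientation)

    def iter_free_sites(self):
        for e in self.entities:
            for ref, bond in e.site_bonds.items():
                if bond is None:
                    yield e, ref, e.site_template(ref)


# ---------------------------------------------------------------------------
# Operations


def cluster_hydro_radius(radii) -> float:
    """Radius of the sphere whose volume is the sum of the member spheres."""
    radii = list(radii)
    if not radii:
        raise ValueError("cannot compute the hydrodynamic radius of no particles")
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all particle radii must be > 0")
    return float(np.cbrt(np.sum(radii**3)))


def instantiate_entity(
    template: EntityTemplate,
    position: np.ndarray,
    rng: RandomStream,
    uids: UidAllocator,
    membrane_y: float | None = None,
    half_side: float | None = None,
) -> Cluster:
    """Create a fresh single-entity cluster at ``position``.

    Features start at their initial states, all sites are free, and the
    orientation is random within the limits of the template's landscape
    (membrane: rotation about y only; static: identity).
    """
    from .dynamics import sample_orientation  # local import to avoid cycle noise

    position = np.asarray(position, dtype=float)
    if half_side is not None and np.any(np.abs(position) > half_side):
        raise PlacementError(
            f"position {position} outside the simulation volume (+-{half_side})"
        )
    tags = template.landscape_set
    eff = effective_landscape(tags)
    if TAG_MEMBRANE in tags:
        if membrane_y is None:
            raise PlacementError(
                f"template {template.id!r} contains membrane particles but no "
                "membrane position was given"
            )
        if abs(position[1] - membrane_y) > 1e-15 + 1e-9 * abs(membrane_y):
            raise PlacementError(
                f"membrane template {template.id!r} must be placed at "
                f"y = {membrane_y}, got y = {position[1]}"
            )
    orientation = sample_orientation(eff, rng)
    entity = EntityInstance(
        uid=uids.take(),
        template=template,
        feature_states={f.name: f.initial_state for f in template.features},
        rel_com=np.zeros(3),
        orientation=IDENTITY_QUAT.copy(),
        site_bonds={ref: None for ref, _, _ in template.iter_sites()},
    )
    cluster = Cluster(
        uid=uids.take(),
        entities=[entity],
        bonds=[],
        com=position.copy(),
        orientation=orientation,
    )
    cluster.recompute_derived()
    return cluster


def _entity_weights(entities) -> np.ndarray:
    # hydrodynamic volume as the universal mass proxy
    return np.array([e.template.hydro_radius**3 for e in entities])


def _rebase_cluster(uid: int, entities: list[EntityInstance], bonds: list[Bond],
                    world_pos: dict[int, np.ndarray], world_q: dict[int, np.ndarray]) -> Cluster:
    """Build a cluster in world frame (identity orientation) from entity poses."""
    w = _entity_weights(entities)
    positions = np.array([world_pos[e.uid] for e in entities])
    com = (w[:, None] * positions).sum(axis=0) / w.sum()
    for e in entities:
        e.rel_com = world_pos[e.uid] - com
        e.orientation = world_q[e.uid]
        if hasattr(e, "_local_cache"):
            e._local_cache = {}
    cluster = Cluster(
        uid=uid,
        entities=entities,
        bonds=bonds,
        com=com,
        orientation=IDENTITY_QUAT.copy(),
    )
    cluster.recompute_derived()
    return cluster


def merge_clusters(a: Cluster, b: Cluster, bond: Bond, uids: UidAllocator) -> Cluster:
    """Fuse two clusters with a new bond; entity identities are retained.

    The merged centre of mass is the hydrodynamic-volume weighted mean of
    the two former centres; every entity keeps its world position and
    orientation, re-expressed relative to the new centre.
    """
    ea = next((e for e in a.entities if e.uid == bond.entity_a), None)
    eb = next((e for e in b.entities if e.uid == bond.entity_b), None)
    if ea is None or eb is None:
        # allow the bond to reference (a, b) in either order
        ea = next((e for e in a.entities if e.uid == bond.entity_b), None)
        eb = next((e for e in b.entities if e.uid == bond.entity_a), None)
        if ea is None or eb is None:
            raise ValueError("bond does not connect the two clusters")
        ref_a, ref_b = bond.site_b, bond.site_a
    else:
        ref_a, ref_b = bond.site_a, bond.site_b
    if not ea.is_free(ref_a) or not eb.is_free(ref_b):
        raise OccupancyError("cannot bind: one of the sites is already bound")

    world_pos = {}
    world_q = {}
    for cl in (a, b):
        for e in cl.entities:
            world_pos[e.uid] = cl.entity_world_position(e)
            world_q[e.uid] = qmult(cl.orientation, e.orientation)
    entities = list(a.entities) + list(b.entities)
    bonds = list(a.bonds) + list(b.bonds) + [bond]
    ea.site_bonds[ref_a] = bond
    eb.site_bonds[ref_b] = bond
    return _rebase_cluster(uids.take(), entities, bonds, world_pos, world_q)


def bond_components(entities: list[EntityInstance], bonds: list[Bond]) -> list[list[EntityInstance]]:
    """Connected components of the entity/bond graph (BFS)."""
    adj: dict[int, set[int]] = {e.uid: set() for e in entities}
    for b in bonds:
        adj[b.entity_a].add(b.entity_b)
        adj[b.entity_b].add(b.entity_a)
    by_uid = {e.uid: e for e in entities}
    seen: set[int] = set()
    comps = []
    for e in entities:
        if e.uid in seen:
            continue
        comp = []
        frontier = [e.uid]
        seen.add(e.uid)
        while frontier:
            u = frontier.pop()
            comp.append(by_uid[u])
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        comps.append(comp)
    return comps


def split_cluster(c: Cluster, bond: Bond, uids: UidAllocator):
    """Remove a bond; return the resulting cluster(s).

    Two clusters result when the bond was a cut edge of the bond graph,
    otherwise a single (re-based) cluster.  Both sites are freed.
    """
    if bond not in c.bonds:
        raise ValueError(f"bond {bond.uid} is not part of cluster {c.uid}")
    remaining = [b for b in c.bonds if b is not bond]
    c.entity(bond.entity_a).site_bonds[bond.site_a] = None
    c.entity(bond.entity_b).site_bonds[bond.site_b] = None

    world_pos = {e.uid: c.entity_world_position(e) for e in c.entities}
    world_q = {e.uid: qmult(c.orientation, e.orientation) for e in c.entities}
    comps = bond_components(c.entities, remaining)
    out = []
    for comp in comps:
        uids_in_comp = {e.uid for e in comp}
        comp_bonds = [b for b in remaining if b.entity_a in uids_in_comp]
        out.append(_rebase_cluster(uids.take(), comp, comp_bonds, world_pos, world_q))
    return tuple(out) if len(out) > 1 else out[0]


def site_world_position(c: Cluster, entity_uid: int, ref: SiteRef) -> np.ndarray:
    """World-frame coordinates of a site centre."""
    e = c.entity(entity_uid)
    local = e.site_local_offset(ref)
    return c.com + qrotate(c.orientation, e.rel_com + qrotate(e.orientation, local))


def site_world_frame(c: Cluster, entity_uid: int, ref: SiteRef):
    """World-frame (centre, normal, plane) of a site."""
    e = c.entity(entity_uid)
    site = e.site_template(ref)
    q = qmult(c.orientation, e.orientation)
    centre = site_world_position(c, entity_uid, ref)
    return centre, qrotate(q, site.normal), qrotate(q, site.plane)
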