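"""The iteration cycle: events, creations, scheduled reactions, Brownian
movement, boundary resolution, voxel re-registration, bimolecular
resolution and output.

Each executed iteration runs the phases in a fixed order:

1. user events scheduled for this iteration;
2. zeroth-order creations from the pre-drawn table;
3. scheduled unimolecular events (in schedule order, guards re-checked);
4. translational and rotational Brownian moves of all non-static clusters,
   in a freshly shuffled order;
5. boundary resolution per cluster;
6. voxel re-registration of all free reactive sites;
7. bimolecular resolution over the voxel candidate pairs;
8. trace output when the iteration index is divisible by the output divisor.

Iterations in which nothing can happen (no mobile cluster and no scheduled
event) are skipped wholesale; output is only produced for executed
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dynamics as dyn
from . import model as _m
from . import reactions as rx
from .geometry import qmult, qrotate, random_quaternion, y_rotation_quat
from .grid import SiteEntry, VoxelGrid, candidate_pairs, validate_voxel_size
from .rng import RandomStream


@dataclass
class SimulationConfig:
    dt: float
    n_iter: int
    L: float
    n_v: int
    T: float = 298.15
    seed: int = 1
    rng_mode: str = "on_demand"
    rng_list_size: int = 250_000
    sigma_mode: str = "current"  # "current" | "initial"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("time step must be > 0")
        if self.n_iter < 0:
            raise ValueError("iteration count must be >= 0")
        if self.L <= 0 or self.n_v < 1:
            raise ValueError("invalid volume or voxel count")
        if self.sigma_mode not in ("current", "initial"):
            raise ValueError("sigma_mode must be 'current' or 'initial'")


@dataclass
class UserEvent:
    iteration: int
    template_id: str
    position: np.ndarray
    feature_states: dict[str, str] = field(default_factory=dict)


class Simulation:
    """A running simulation: state plus the iteration-cycle machinery."""

    def __init__(self, document, config: SimulationConfig | None = None, trace_sink=None):
        from .modelio import build_config  # deferred: modelio imports engine types

        self.document = document
        self.cfg = config or build_config(document)
        self.ctx = dyn.PhysicalContext(T=self.cfg.T)
        self.rng = RandomStream(
            self.cfg.seed, mode=self.cfg.rng_mode, list_size=self.cfg.rng_list_size
        )
        self.uids = _m.UidAllocator()
        self.clusters: dict[int, _m.Cluster] = {}
        self.entity_cluster: dict[int, int] = {}
        self.schedule = rx.EventSchedule()
        self.calibrator = rx.BindingRadiusCalibrator(self.cfg.dt, self.ctx.N_A)
        self.iteration = 0
        self.stats = {
            "created": 0,
            "removed": 0,
            "absorbed": 0,
            "reactions": {},
            "aborted_geometry": 0,
        }
        self.reaction_observers: list = []
        self.output_observers: list = []
        self._site_reg: dict = {}
        self._n_mobile = 0
        self._mat_dirty = True
        self._sites_dirty = True
        self._row_clusters: list[_m.Cluster] = []
        self._com_mat = np.empty((0, 3))
        self._q_mat = np.empty((0, 4))
        self._mobile_rows = np.empty(0, dtype=np.int64)
        self._mobile_D = np.empty(0)
        self._mobile_mem_mask = np.empty(0, dtype=bool)
        self._site_entries: list[SiteEntry] = []
        self._site_rows = np.empty(0, dtype=np.int64)
        self._site_locs = np.empty((0, 3))
        self._site_pos = np.empty((0, 3))

        self.landscapes = dict(document.landscapes)
        self._ensure_default_landscapes()
        self.membrane = self.landscapes.get(dyn.TAG_MEMBRANE)
        self.domains = list(document.domains)
        self.templates = {t.id: t for t in document.entities}
        self.rules = list(document.rules)
        self._uni_rules_by_template: dict[str, list[rx.ReactionRule]] = {}
        self._unbind_rules: list[rx.ReactionRule] = []
        self._bi_rules: list[rx.ReactionRule] = []
        self._site_owner: dict[str, str] = {}
        for t in document.entities:
            for _, _, site in t.iter_sites():
                self._site_owner.setdefault(site.site_type, t.id)
        for rule in self.rules:
            if rule.order == 1 and rule.kind == "unbind":
                self._unbind_rules.append(rule)
            elif rule.order == 1:
                self._uni_rules_by_template.setdefault(rule.reactant, []).append(rule)
            elif rule.order == 2:
                self._bi_rules.append(rule)
        self._reactive_types = {r.site_a for r in self._bi_rules} | {
            r.site_b for r in self._bi_rules
        }

        periodic = self._faces_all("periodic")
        self.grid = VoxelGrid(self.cfg.L, self.cfg.n_v, periodic=periodic)
        self._face_boundaries = self._build_face_boundaries()

        self._trace = None
        if trace_sink is not None:
            from .trace import TraceWriter

            self._trace = TraceWriter(document.output, trace_sink)

        self._initialise()

    # -- setup -------------------------------------------------------------

    def _ensure_default_landscapes(self):
        for tag in dyn.LANDSCAPE_TAGS:
            self.landscapes.setdefault(tag, dyn.LandscapeSpec(tag=tag))

    def _faces_all(self, kind: str) -> bool:
        conds = self.document.face_conditions
        return all(
            conds.get((axis, side), dyn.BoundaryConditionSet()).is_pure == kind
            for axis in range(3)
            for side in ("low", "high")
        )

    def _build_face_boundaries(self) -> list[dyn.PlaneBoundary]:
        half = self.cfg.L / 2.0
        out = []
        conds = self.document.face_conditions
        for axis in range(3):
            for side, level, sign in (("low", -half, -1), ("high", half, +1)):
                out.append(
                    dyn.PlaneBoundary(
                        axis=axis,
                        level=level,
                        outward_sign=sign,
                        conditions=conds.get(
                            (axis, side), dyn.BoundaryConditionSet()
                        ),
                        wrap=self.cfg.L,
                    )
                )
        return out

    def _boundaries_for(self, cluster: _m.Cluster) -> list[dyn.PlaneBoundary]:
        out = list(self._face_boundaries)
        eff = cluster.effective_landscape
        if eff in (dyn.TAG_ABOVE, dyn.TAG_BELOW) and self.membrane is not None:
            sign = -1 if eff == dyn.TAG_ABOVE else +1
            out.append(
                dyn.PlaneBoundary(
                    axis=1,
                    level=self.membrane.membrane_y,
                    outward_sign=sign,
                    conditions=dyn.BoundaryConditionSet([("reflective", 1.0)]),
                )
            )
        return out

    def _region_bounds(self, region: str):
        half = self.cfg.L / 2.0
        y_lo, y_hi = -half, half
        if region in (dyn.TAG_ABOVE, dyn.TAG_BELOW, dyn.TAG_MEMBRANE):
            if self.membrane is None:
                raise ValueError(f"placement {region!r} requires a membrane landscape")
            if region == dyn.TAG_ABOVE:
                y_lo = self.membrane.membrane_y
            elif region == dyn.TAG_BELOW:
                y_hi = self.membrane.membrane_y
        return half, y_lo, y_hi

    def region_volume_litres(self, region: str) -> float:
        half, y_lo, y_hi = self._region_bounds(region)
        if region == dyn.TAG_MEMBRANE:
            raise ValueError("zeroth-order creation in the membrane plane has no volume")
        return self.cfg.L * self.cfg.L * (y_hi - y_lo) * 1e3

    def _sample_position(self, region: str) -> np.ndarray:
        half, y_lo, y_hi = self._region_bounds(region)
        u = self.rng.uniforms(3)
        x = (u[0] - 0.5) * self.cfg.L
        z = (u[2] - 0.5) * self.cfg.L
        if region == dyn.TAG_MEMBRANE:
            y = self.membrane.membrane_y
        else:
            y = y_lo + u[1] * (y_hi - y_lo)
        return np.array([x, y, z])

    def _initialise(self):
        # initial placements, template document order
        for template in self.document.entities:
            region = template.placement
            for _ in range(template.initial_count):
                pos = self._sample_position(region)
                self._create_entity(template, pos, now=0)
        # zeroth-order creation tables
        for rule in self.rules:
            if rule.order == 0 and rule.rate > 0:
                vol = self.region_volume_litres(rule.creation_landscape)
                rx.schedule_zeroth_order(
                    rule, vol, self.cfg.dt, self.cfg.n_iter, self.rng, self.schedule,
                    N_A=self.ctx.N_A,
                )
        # user events
        for ev in self.document.user_events:
            self.schedule.add(
                rx.ReactionEvent(
                    rule=None, targets=(), iteration=ev.iteration, seq=0,
                    kind="user", payload=ev,
                )
            )
        # binding radii from template diffusion coefficients, for grid validation
        max_sigma = 0.0
        for rule in self._bi_rules:
            if rule.rate <= 0:
                continue
            d_mut = self._template_mutual_d(rule)
            sigma = self.calibrator.sigma(rule, d_mut)
            max_sigma = max(max_sigma, sigma)
        if self._bi_rules and max_sigma > 0:
            validate_voxel_size(self.grid.voxel_side, max_sigma)

    def _template_mutual_d(self, rule: rx.ReactionRule) -> float:
        d = 0.0
        for st in (rule.site_a, rule.site_b):
            owner = self._site_owner.get(st)
            if owner is None:
                raise ValueError(f"rule {rule.id!r}: no template owns site type {st!r}")
            t = self.templates[owner]
            d += self._template_d(t)
        return d

    def _template_d(self, template: _m.EntityTemplate) -> float:
        eff = dyn.effective_landscape(template.landscape_set)
        return self._d_for(eff, template.hydro_radius, None)

    def _d_for(self, eff: str, radius: float, com) -> float:
        if eff == dyn.TAG_STATIC:
            return 0.0
        if eff == dyn.TAG_MEMBRANE:
            spec = self.membrane or dyn.LandscapeSpec(tag=dyn.TAG_MEMBRANE, viscosity=1.0)
            mu = spec.viscosity
            if com is not None and self.domains:
                dom = dyn.membrane_domain_of((com[0], com[2]), self.domains)
                if dom is not None:
                    mu = dom.viscosity
            return dyn.diffusion_coefficient_membrane(
                self.ctx, mu, spec.membrane_thickness, spec.exterior_viscosity, radius
            )
        eta = self.landscapes[eff].viscosity
        return dyn.diffusion_coefficient_3d(self.ctx, eta, radius)

    def _refresh_d(self, cluster: _m.Cluster):
        cluster.D = self._d_for(
            cluster.effective_landscape, cluster.hydro_radius, cluster.com
        )

    # -- registry helpers --------------------------------------------------

    def _register(self, cluster: _m.Cluster):
        self.clusters[cluster.uid] = cluster
        for e in cluster.entities:
            self.entity_cluster[e.uid] = cluster.uid
        self._refresh_d(cluster)
        cluster._mobile = (
            cluster.effective_landscape != dyn.TAG_STATIC and cluster.D > 0.0
        )
        if cluster._mobile:
            self._n_mobile += 1
        self._mat_dirty = True
        self._sites_dirty = True

    def _unregister(self, cluster: _m.Cluster, drop_entities: bool = False):
        was = self.clusters.pop(cluster.uid, None)
        if was is not None and getattr(cluster, "_mobile", False):
            self._n_mobile -= 1
        if drop_entities:
            for e in cluster.entities:
                self.entity_cluster.pop(e.uid, None)
        self._mat_dirty = True
        self._sites_dirty = True

    def cluster_of_entity(self, entity_uid: int) -> _m.Cluster | None:
        cuid = self.entity_cluster.get(entity_uid)
        return self.clusters.get(cuid) if cuid is not None else None

    def pair_distance(self, p, q) -> float:
        return self.grid.pair_distance(p, q)

    def sigma_for(self, rule: rx.ReactionRule, d_mut: float, rate: float) -> float:
        """Binding radius for a rule under the configured calibration policy.

        ``current`` (default) calibrates against the reacting clusters'
        present mutual diffusion coefficient; ``initial`` always uses the
        template value pre-computed at start-up.
        """
        if self.cfg.sigma_mode == "initial":
            d_mut = self._template_mutual_d(rule)
        return self.calibrator.sigma(rule, d_mut, rate=rate)

    def entity_count(self, template_id: str) -> int:
        return sum(
            1
            for c in self.clusters.values()
            for e in c.entities
            if e.template.id == template_id
        )

    # -- entity lifecycle --------------------------------------------------

    def _create_entity(self, template, position, now: int, feature_states=None):
        membrane_y = self.membrane.membrane_y if self.membrane else None
        cluster = _m.instantiate_entity(
            template, position, self.rng, self.uids,
            membrane_y=membrane_y, half_side=self.cfg.L / 2.0,
        )
        entity = cluster.entities[0]
        if feature_states:
            entity.feature_states.update(feature_states)
        self._register(cluster)
        self._registry_add_entity(entity)
        self.stats["created"] += 1
        self._schedule_entity_rules(entity, now)
        return cluster

    def _schedule_entity_rules(self, entity: _m.EntityInstance, now: int):
        for rule in self._uni_rules_by_template.get(entity.template.id, ()):
            k_eff = rx.effective_rate(rule, entity.feature_states)
            rx.schedule_unimolecular(
                rule, (("entity", entity.uid),), k_eff, now, self.cfg.dt,
                self.rng, self.schedule,
            )

    def _schedule_bond_rules(self, bond: _m.Bond, ent_a, ent_b, now: int):
        type_a = ent_a.site_template(bond.site_a).site_type
        type_b = ent_b.site_template(bond.site_b).site_type
        for rule in self._unbind_rules:
            if {rule.site_a, rule.site_b} != {type_a, type_b}:
                continue
            if rule.site_a == type_a:
                sa, sb = ent_a.feature_states, ent_b.feature_states
            else:
                sa, sb = ent_b.feature_states, ent_a.feature_states
            k_eff = rx.effective_rate(rule, sa, sb)
            rx.schedule_unimolecular(
                rule,
                (("bond", bond.uid), ("entity", ent_a.uid), ("entity", ent_b.uid)),
                k_eff, now, self.cfg.dt, self.rng, self.schedule,
            )

    def reschedule_entity(self, entity: _m.EntityInstance, now: int):
        """Drop and re-draw every pending event touching this entity."""
        self.schedule.invalidate(("entity", entity.uid))
        self._schedule_entity_rules(entity, now)
        cluster = self.cluster_of_entity(entity.uid)
        if cluster is None:
            return
        for bond in cluster.bonds:
            if entity.uid in (bond.entity_a, bond.entity_b):
                self.schedule.invalidate(("bond", bond.uid))
                ea = cluster.entity(bond.entity_a)
                eb = cluster.entity(bond.entity_b)
                self._schedule_bond_rules(bond, ea, eb, now)

    def remove_entity(self, entity_uid: int, now: int):
        """Entity death: break its bonds and drop it from the simulation."""
        cluster = self.cluster_of_entity(entity_uid)
        if cluster is None:
            return
        self.schedule.invalidate(("entity", entity_uid))
        entity = cluster.entity(entity_uid)
        self._unregister(cluster)
        self.entity_cluster.pop(entity_uid, None)
        survivors = [e for e in cluster.entities if e.uid != entity_uid]
        kept_bonds = []
        for bond in cluster.bonds:
            if entity_uid in (bond.entity_a, bond.entity_b):
                self.schedule.invalidate(("bond", bond.uid))
                cluster.entity(bond.entity_a).site_bonds[bond.site_a] = None
                cluster.entity(bond.entity_b).site_bonds[bond.site_b] = None
                # the surviving partner's site becomes reactive again
                if bond.entity_a == entity_uid:
                    self._registry_add_site(cluster.entity(bond.entity_b), bond.site_b)
                else:
                    self._registry_add_site(cluster.entity(bond.entity_a), bond.site_a)
            else:
                kept_bonds.append(bond)
        self._registry_remove_entity(entity)
        self.stats["removed"] += 1
        if not survivors:
            return
        world_pos = {e.uid: cluster.entity_world_position(e) for e in survivors}
        world_q = {e.uid: qmult(cluster.orientation, e.orientation) for e in survivors}
        for comp in _m.bond_components(survivors, kept_bonds):
            uids_in = {e.uid for e in comp}
            comp_bonds = [b for b in kept_bonds if b.entity_a in uids_in]
            frag = _m._rebase_cluster(
                self.uids.take(), comp, comp_bonds, world_pos, world_q
            )
            self._register(frag)

    # -- reaction execution -----------------------------------------------

    def _count_reaction(self, rule_id: str):
        self.stats["reactions"][rule_id] = self.stats["reactions"].get(rule_id, 0) + 1

    def execute_bimolecular(self, rule, ent_a, ref_a, cl_a, ent_b, ref_b, cl_b):
        if rule.binding:
            try:
                merged, bond = rx.apply_binding_geometry(
                    cl_a, ent_a.uid, ref_a, cl_b, ent_b.uid, ref_b, self.uids
                )
            except rx.GeometryInfeasibleError:
                self.stats["aborted_geometry"] += 1
                return None
            self._unregister(cl_a)
            self._unregister(cl_b)
            self._register(merged)
            self._registry_remove_site(ent_a.uid, ref_a)
            self._registry_remove_site(ent_b.uid, ref_b)
            self._schedule_bond_rules(bond, ent_a, ent_b, self.iteration)
            changed = rx.apply_effects(rule, ent_a, ent_b)
            for e in changed:
                self.reschedule_entity(e, self.iteration)
            self._count_reaction(rule.id)
            info = {
                "rule": rule, "kind": "binding", "bond": bond,
                "cluster": merged, "entities": (ent_a.uid, ent_b.uid),
                "iteration": self.iteration,
            }
            self._notify_reaction(info)
            return info
        # transformation: the reactant pair is replaced by the product
        mid = 0.5 * (
            _m.site_world_position(cl_a, ent_a.uid, ref_a)
            + _m.site_world_position(cl_b, ent_b.uid, ref_b)
        )
        rx.apply_effects(rule, ent_a, ent_b)
        self.remove_entity(ent_a.uid, self.iteration)
        self.remove_entity(ent_b.uid, self.iteration)
        product = None
        if rule.product is not None:
            template = self.templates[rule.product]
            if dyn.TAG_MEMBRANE in template.landscape_set and self.membrane:
                mid[1] = self.membrane.membrane_y
            mid = np.clip(mid, -self.cfg.L / 2.0, self.cfg.L / 2.0)
            product = self._create_entity(template, mid, self.iteration)
        self._count_reaction(rule.id)
        info = {
            "rule": rule, "kind": "transform", "product": product,
            "entities": (ent_a.uid, ent_b.uid), "iteration": self.iteration,
        }
        self._notify_reaction(info)
        return info

    def _execute_unimolecular(self, event: rx.ReactionEvent):
        rule = event.rule
        if rule.kind == "unbind":
            bond_uid = next(t[1] for t in event.targets if t[0] == "bond")
            cluster = None
            bond = None
            for t in event.targets:
                if t[0] == "entity":
                    cluster = self.cluster_of_entity(t[1])
                    break
            if cluster is None:
                return
            bond = next((b for b in cluster.bonds if b.uid == bond_uid), None)
            if bond is None:
                return
            ent_a = cluster.entity(bond.entity_a)
            ent_b = cluster.entity(bond.entity_b)
            forward = next(
                (r for r in self._bi_rules if r.id == rule.forward_rule), None
            )

            def sigma_fn(frag_a, frag_b):
                if forward is None:
                    return 0.0
                self._refresh_d(frag_a)
                self._refresh_d(frag_b)
                return self.calibrator.sigma(forward, frag_a.D + frag_b.D)

            self._unregister(cluster)
            frags = rx.apply_unbinding(cluster, bond, sigma_fn, self.uids)
            for frag in frags:
                self._register(frag)
            self._registry_add_site(ent_a, bond.site_a)
            self._registry_add_site(ent_b, bond.site_b)
            changed = rx.apply_effects(rule, ent_a, ent_b)
            touched = {e.uid: e for e in [ent_a, ent_b, *changed]}
            for e in touched.values():
                self.reschedule_entity(e, self.iteration)
            self._count_reaction(rule.id)
            self._notify_reaction(
                {"rule": rule, "kind": "unbind", "iteration": self.iteration,
                 "entities": (ent_a.uid, ent_b.uid)}
            )
            return
        # entity transformation / removal
        entity_uid = next(t[1] for t in event.targets if t[0] == "entity")
        cluster = self.cluster_of_entity(entity_uid)
        if cluster is None:
            return
        entity = cluster.entity(entity_uid)
        if rx.effective_rate(rule, entity.feature_states) <= 0.0:
            return  # guard no longer satisfied; event dropped
        changed = rx.apply_effects(rule, entity)
        if rule.outcome == "remove":
            self.remove_entity(entity_uid, self.iteration)
        else:
            for e in changed:
                self.reschedule_entity(e, self.iteration)
            if entity not in changed:
                # nothing changed, but the event was consumed; draw the next one
                self.reschedule_entity(entity, self.iteration)
        self._count_reaction(rule.id)
        self._notify_reaction(
            {"rule": rule, "kind": "uni", "entity": entity_uid,
             "iteration": self.iteration}
        )

    def _notify_reaction(self, info):
        for cb in self.reaction_observers:
            cb(self, info)

    # -- movement ----------------------------------------------------------

    def _refresh_matrix(self):
        """Re-pack cluster positions/orientations into contiguous arrays.

        Every cluster's ``com`` and ``orientation`` become views into the
        engine-owned matrices, so vectorised movement updates are visible
        on the objects without per-cluster assignment.  Rebuilt whenever
        the cluster population changes.
        """
        clusters = list(self.clusters.values())
        n = len(clusters)
        self._row_clusters = clusters
        self._com_mat = np.empty((n, 3))
        self._q_mat = np.empty((n, 4))
        mobile_rows = []
        mem_rows = []
        for i, c in enumerate(clusters):
            self._com_mat[i] = c.com
            self._q_mat[i] = c.orientation
            c.com = self._com_mat[i]
            c.orientation = self._q_mat[i]
            c._row = i
            if c.effective_landscape != dyn.TAG_STATIC and c.D > 0.0:
                mobile_rows.append(i)
                if c.effective_landscape == dyn.TAG_MEMBRANE:
                    mem_rows.append(i)
        self._mobile_rows = np.array(mobile_rows, dtype=np.int64)
        self._mobile_D = np.array([clusters[i].D for i in mobile_rows])
        mem_set = set(mem_rows)
        self._mobile_mem_mask = np.array(
            [i in mem_set for i in mobile_rows], dtype=bool
        )
        self._mat_dirty = False
        self._sites_dirty = True

    def _move_clusters(self):
        if self._mat_dirty:
            self._refresh_matrix()
        rows = self._mobile_rows
        n = len(rows)
        if n == 0:
            return
        clusters = self._row_clusters
        perm = self.rng.permutation(n)
        prows = rows[perm]
        mem_mask = self._mobile_mem_mask[perm]
        D = self._mobile_D[perm]
        # membrane domains modulate the local viscosity, hence D, per step
        if self.domains:
            for j in np.where(mem_mask)[0]:
                c = clusters[prows[j]]
                self._refresh_d(c)
                D[j] = c.D
        disp = self.rng.normals((n, 3)) * np.sqrt(2.0 * D * self.cfg.dt)[:, None]
        disp[mem_mask, 1] = 0.0
        starts = self._com_mat[prows].copy()
        self._com_mat[prows] += disp

        # rotational diffusion: full re-orientation, restricted by landscape
        n_free = int(np.count_nonzero(~mem_mask))
        n_mem = n - n_free
        q_new = np.empty((n, 4))
        if n_free:
            q_new[~mem_mask] = random_quaternion(self.rng.normals((n_free, 4)))
        if n_mem:
            q_new[mem_mask] = y_rotation_quat(2.0 * np.pi * self.rng.uniforms(n_mem))
        self._q_mat[prows] = qmult(q_new, self._q_mat[prows])

        # boundary resolution, only for clusters that ended outside their region
        half = self.cfg.L / 2.0
        ends = self._com_mat[prows]
        violated = np.any(np.abs(ends) > half, axis=1)
        if self.membrane is not None:
            y_m = self.membrane.membrane_y
            above = np.array(
                [clusters[r].effective_landscape == dyn.TAG_ABOVE for r in prows]
            )
            below = np.array(
                [clusters[r].effective_landscape == dyn.TAG_BELOW for r in prows]
            )
            violated |= above & (ends[:, 1] < y_m)
            violated |= below & (ends[:, 1] > y_m)
        absorbed = []
        check_domains = bool(self.domains) and any(
            d.boundary_in or d.boundary_out for d in self.domains
        )
        for j in np.nonzero(violated)[0]:
            c = clusters[prows[j]]
            result = dyn.resolve_boundary(
                starts[j], ends[j], self._boundaries_for(c), self.rng
            )
            if result is dyn.ABSORBED:
                absorbed.append(c)
            else:
                self._com_mat[prows[j]] = result
        if check_domains:
            for j in np.where(mem_mask)[0]:
                c = clusters[prows[j]]
                if c in absorbed:
                    continue
                end = self._com_mat[prows[j]]
                res = dyn.resolve_domain_crossing(
                    (starts[j][0], starts[j][2]), (end[0], end[2]),
                    self.domains, self.rng,
                )
                if res is dyn.ABSORBED:
                    absorbed.append(c)
                else:
                    end[0], end[2] = res
        for c in absorbed:
            for e in c.entities:
                self.schedule.invalidate(("entity", e.uid))
                self._registry_remove_entity(e)
            for b in c.bonds:
                self.schedule.invalidate(("bond", b.uid))
            self._unregister(c, drop_entities=True)
            self.stats["absorbed"] += len(c.entities)

    # -- voxel registration and pairing -------------------------------------

    def _registry_add_entity(self, entity: _m.EntityInstance):
        for ref, bond in entity.site_bonds.items():
            if bond is None:
                self._registry_add_site(entity, ref)

    def _registry_add_site(self, entity: _m.EntityInstance, ref: _m.SiteRef):
        site_t = entity.site_template(ref)
        if site_t.site_type not in self._reactive_types:
            return
        entry = SiteEntry(
            cluster_uid=-1, entity_uid=entity.uid, ref=ref,
            site_type=site_t.site_type, position=None,
        )
        self._site_reg[(entity.uid, ref)] = (entry, entity)
        self._sites_dirty = True

    def _registry_remove_site(self, entity_uid: int, ref: _m.SiteRef):
        self._site_reg.pop((entity_uid, ref), None)
        self._sites_dirty = True

    def _registry_remove_entity(self, entity: _m.EntityInstance):
        for ref in entity.site_bonds:
            self._site_reg.pop((entity.uid, ref), None)
        self._sites_dirty = True

    def rebuild_site_registry(self) -> None:
        """Full registry rebuild from scratch (consistency reference)."""
        self._site_reg = {}
        for c in self.clusters.values():
            for e, ref, _ in c.iter_free_sites():
                self._registry_add_site(e, ref)

    def _assemble_sites(self):
        """(Re)build the flat site arrays after a registry or matrix change."""
        reg = self._site_reg
        entries: list[SiteEntry] = []
        site_rows: list[int] = []
        locals_: list[np.ndarray] = []
        clusters = self.clusters
        entity_cluster = self.entity_cluster
        for (euid, ref), (entry, entity) in reg.items():
            c = clusters[entity_cluster[euid]]
            cache = getattr(entity, "_local_cache", None)
            if cache is None:
                cache = {}
                entity._local_cache = cache
            loc = cache.get(ref)
            if loc is None:
                loc = entity.rel_com + qrotate(
                    entity.orientation, entity.site_local_offset(ref)
                )
                cache[ref] = loc
            entry.cluster_uid = c.uid
            entries.append(entry)
            site_rows.append(c._row)
            locals_.append(loc)
        n = len(entries)
        self._site_entries = entries
        self._site_rows = np.array(site_rows, dtype=np.int64)
        self._site_locs = np.asarray(locals_) if n else np.empty((0, 3))
        self._site_pos = np.empty((n, 3))
        for i, entry in enumerate(entries):
            entry.position = self._site_pos[i]  # view; refreshed in place
        self._sites_dirty = False

    def _rebuild_grid(self):
        if self._mat_dirty:
            self._refresh_matrix()
        if self._sites_dirty:
            self._assemble_sites()
        entries = self._site_entries
        if not entries:
            self.grid.rebuild([])
            return
        rows = self._site_rows
        self._site_pos[:] = self._com_mat[rows] + qrotate(
            self._q_mat[rows], self._site_locs
        )
        half = self.cfg.L / 2.0
        if self.grid.periodic:
            wrapped = (self._site_pos + half) % self.cfg.L - half
        else:
            wrapped = np.clip(self._site_pos, -half, half)
        self.grid.rebuild(entries, codes=self.grid.voxel_codes(wrapped))

    # -- the cycle ----------------------------------------------------------

    def step(self) -> None:
        """Execute the next iteration (phases 1-8)."""
        self.iteration += 1
        now = self.iteration
        events = self.schedule.events_at(now)
        # 1. user events; 2. creations; 3. scheduled unimolecular reactions
        for ev in events:
            if ev.kind == "user":
                ue: UserEvent = ev.payload
                template = self.templates[ue.template_id]
                self._create_entity(
                    template, np.asarray(ue.position, dtype=float), now,
                    feature_states=ue.feature_states,
                )
            elif ev.kind == "creation":
                template = self.templates[ev.rule.product]
                pos = self._sample_position(ev.rule.creation_landscape)
                self._create_entity(template, pos, now)
                self._count_reaction(ev.rule.id)
        for ev in events:
            if ev.kind == "uni":
                self._execute_unimolecular(ev)
        # 4-5. movement and boundaries
        self._move_clusters()
        # 6. voxel re-registration
        self._rebuild_grid()
        # 7. bimolecular resolution
        if self._bi_rules and self.grid.entries:
            pairs = candidate_pairs(self.grid, self._bi_rules, self.rng)
            if pairs:
                rx.resolve_bimolecular(self, pairs, self.rng)
        # 8. output
        self._maybe_output()

    def _maybe_output(self):
        spec = self.document.output
        if spec is None:
            divisor = 1
        else:
            divisor = spec.divisor
        if self.iteration % divisor == 0:
            if self._trace is not None:
                self._trace.emit(self)
            for cb in self.output_observers:
                cb(self)

    def has_mobile_cluster(self) -> bool:
        return self._n_mobile > 0

    def next_active_iteration(self, current: int) -> int:
        """Next iteration in which anything can happen.

        With at least one mobile cluster every iteration is active; with
        none, jump to the next scheduled event (or to the end of the run).
        """
        if self.has_mobile_cluster():
            return current + 1
        nxt = self.schedule.next_iteration_after(current)
        if nxt is None:
            return self.cfg.n_iter + 1
        return nxt

    def run(self) -> None:
        """Run to completion (initial output, then the iteration loop)."""
        self._maybe_output()  # iteration 0
        while self.iteration < self.cfg.n_iter:
            nxt = self.next_active_iteration(self.iteration)
            if nxt > self.cfg.n_iter:
                break
            if nxt > self.iteration + 1:
                self.iteration = nxt - 1  # skipped iterations: no state change
            self.step()
        if self._trace is not None:
            self._trace.flush()


def run(document, config: SimulationConfig | None = None, trace_sink=None,
        reaction_observers=(), output_observers=()) -> Simulation:
    """Initialise and run a simulation; returns the finished simulation."""
    sim = Simulation(document, config=config, trace_sink=trace_sink)
    sim.reaction_observers.extend(reaction_observers)
    sim.output_observers.extend(output_observers)
    sim.run()
    return sim
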