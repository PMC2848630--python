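"""Reaction machinery: rules, scheduling, binding-radius calibration,
bimolecular resolution and binding geometry.

Three reaction orders are supported.

* **Zeroth order** (rate k in M/s): molecules appear at a mean rate of
  ``lambda = k * dt * V * N_A`` per time step in a creation region of
  volume V.  Creation times are drawn once, at initialisation, as
  exponential inter-arrival times with rate ``lambda/dt`` and stored in the
  event schedule, which makes the per-step creation counts Poisson(lambda).

* **First order** (rate k in 1/s): a waiting time is drawn from Exp(k) when
  the reactant comes into existence, converted to an iteration index and
  stored in the schedule.  Events whose target is changed by another
  reaction are invalidated and redrawn.

* **Second order** (rate k in 1/(M s)): the Smoluchowski/Andrews-Bray
  binding-radius scheme.  Two reactive sites react when their centres end a
  movement step within the binding radius sigma of each other; sigma is
  calibrated numerically so that the simulated steady-state rate constant
  equals k given the mutual diffusion coefficient and the time step.

Feature-state guards can disable or scale any rule's rate per reactant
state; effects applied on execution can set or shift feature states.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const
from scipy.optimize import brentq

from . import model as _m
from .dynamics import TAG_MEMBRANE, TAG_STATIC
from .geometry import (
    frame_alignment_quat,
    qmult,
    qrotate,
    slerp,
    twist_about_y,
    y_rotation_quat,
)
from .rng import RandomStream

NORMAL_ALIGN_TOL = 1e-9
CENTRE_COINCIDE_TOL = 1e-12  # m


class CalibrationError(RuntimeError):
    """Binding-radius inversion failed for the requested parameters."""


class GeometryInfeasibleError(RuntimeError):
    """Landscape restrictions prevent the required binding alignment."""


# ---------------------------------------------------------------------------
# Rules


@dataclass(frozen=True)
class Guard:
    """Feature-state predicate scaling (or disabling) a rule's rate.

    ``target`` is "a" or "b" (the rule's first or second reactant);
    ``state`` may be "*" to match any state.  The first matching guard wins.
    """

    target: str
    feature: str
    state: str
    multiplier: float


@dataclass(frozen=True)
class Effect:
    """Feature-state assignment applied when a rule executes.

    ``action`` is "set" (to ``value``), "advance" (next state in the
    declared enumeration, saturating) or "retreat" (previous state).
    """

    target: str
    feature: str
    action: str
    value: str | None = None


@dataclass(frozen=True)
class ReactionRule:
    id: str
    order: int
    rate: float
    # order 0
    product: str | None = None
    creation_landscape: str = "unrestricted"
    # order 1 (entity transformation / removal)
    reactant: str | None = None
    outcome: str = "none"  # "none" | "remove"
    # order 1 bond dissociation and order 2
    site_a: str | None = None
    site_b: str | None = None
    kind: str = ""  # "" | "unbind"
    forward_rule: str | None = None  # unbind: rule whose sigma sets the separation
    binding: bool = False
    guards: tuple[Guard, ...] = ()
    effects: tuple[Effect, ...] = ()

    def __post_init__(self):
        if self.order not in (0, 1, 2):
            raise ValueError(f"rule {self.id!r}: order must be 0, 1 or 2")
        if self.rate < 0:
            raise ValueError(f"rule {self.id!r}: rate must be >= 0")
        if self.order == 2 and (self.site_a is None or self.site_b is None):
            raise ValueError(f"rule {self.id!r}: second-order rules need two site types")


def effective_rate(rule: ReactionRule, states_a: dict, states_b: dict | None = None) -> float:
    """Rule rate under the reactants' current feature states.

    Guards are evaluated in declaration order; the first matching guard
    scales the base rate (multiplier 0 disables the rule).  With no
    matching guard the base rate applies.
    """
    for g in rule.guards:
        states = states_a if g.target == "a" else (states_b or {})
        if g.feature not in states:
            continue
        if g.state == "*" or states[g.feature] == g.state:
            return rule.rate * g.multiplier
    return rule.rate


def apply_effects(rule: ReactionRule, entity_a, entity_b=None) -> list:
    """Apply the rule's feature-state effects; returns the changed entities."""
    changed = []
    for eff in rule.effects:
        entity = entity_a if eff.target == "a" else entity_b
        if entity is None:
            continue
        feat = next((f for f in entity.template.features if f.name == eff.feature), None)
        if feat is None:
            raise KeyError(
                f"rule {rule.id!r}: entity {entity.user_id!r} has no feature {eff.feature!r}"
            )
        current = entity.feature_states[eff.feature]
        if eff.action == "set":
            if eff.value not in feat.states:
                raise ValueError(
                    f"rule {rule.id!r}: state {eff.value!r} not in feature {feat.name!r}"
                )
            new = eff.value
        elif eff.action == "advance":
            i = feat.states.index(current)
            new = feat.states[min(i + 1, len(feat.states) - 1)]
        elif eff.action == "retreat":
            i = feat.states.index(current)
            new = feat.states[max(i - 1, 0)]
        else:
            raise ValueError(f"rule {rule.id!r}: unknown effect action {eff.action!r}")
        if new != current:
            entity.feature_states[eff.feature] = new
            if entity not in changed:
                changed.append(entity)
    return changed


# ---------------------------------------------------------------------------
# Event schedule


@dataclass
class ReactionEvent:
    rule: ReactionRule | None
    targets: tuple
    iteration: int
    seq: int
    kind: str = "uni"  # "uni" | "creation" | "user"
    payload: object = None
    cancelled: bool = False


class EventSchedule:
    """Iteration-indexed table of pending events with target invalidation."""

    def __init__(self):
        self._by_iter: dict[int, list[ReactionEvent]] = {}
        self._by_target: dict[tuple, list[ReactionEvent]] = {}
        self._seq = 0
        self._heap: list[int] = []  # lazy min-heap over scheduled iterations

    def add(self, event: ReactionEvent) -> ReactionEvent:
        event.seq = self._seq
        self._seq += 1
        bucket = self._by_iter.setdefault(event.iteration, [])
        if not bucket:
            heapq.heappush(self._heap, event.iteration)
        bucket.append(event)
        for t in event.targets:
            self._by_target.setdefault(t, []).append(event)
        return event

    def invalidate(self, target) -> None:
        """Cancel every pending event that references ``target``."""
        for ev in self._by_target.pop(target, []):
            ev.cancelled = True

    def events_at(self, iteration: int) -> list[ReactionEvent]:
        evs = [e for e in self._by_iter.pop(iteration, []) if not e.cancelled]
        evs.sort(key=lambda e: e.seq)
        for ev in evs:
            for t in ev.targets:
                lst = self._by_target.get(t)
                if lst is not None:
                    self._by_target[t] = [x for x in lst if x is not ev]
                    if not self._by_target[t]:
                        del self._by_target[t]
        return evs

    def pending_for(self, target) -> list[ReactionEvent]:
        return [e for e in self._by_target.get(target, []) if not e.cancelled]

    def next_iteration_after(self, iteration: int):
        """Earliest iteration > ``iteration`` with a live event, or None."""
        while self._heap:
            top = self._heap[0]
            evs = self._by_iter.get(top)
            if evs is None or all(e.cancelled for e in evs):
                heapq.heappop(self._heap)
                self._by_iter.pop(top, None)
                continue
            if top <= iteration:
                heapq.heappop(self._heap)
                if evs:  # still live; re-queue so events_at can find it
                    # iterations at or before `current` should already have
                    # been executed; keep the bucket reachable regardless
                    self._by_iter[top] = evs
                continue
            return top
        return None

    def __len__(self):
        return sum(
            sum(1 for e in evs if not e.cancelled) for evs in self._by_iter.values()
        )


def invalidate_events(schedule: EventSchedule, target) -> None:
    schedule.invalidate(target)


def schedule_zeroth_order(
    rule: ReactionRule,
    volume_litres: float,
    dt: float,
    n_iter: int,
    rng: RandomStream,
    schedule: EventSchedule,
    N_A: float = _const.N_A,
) -> int:
    """Draw all creation times of a zeroth-order rule up front.

    Returns the number of creations scheduled.  ``lambda = k*dt*V*N_A`` is
    the mean number of creations per step; inter-arrival times are
    exponential with rate ``lambda/dt`` so per-step counts are Poisson.
    """
    if volume_litres <= 0:
        raise ValueError("creation volume must be > 0")
    lam = rule.rate * dt * volume_litres * N_A
    if lam <= 0:
        return 0
    rate_per_s = lam / dt
    t_end = n_iter * dt
    t = 0.0
    count = 0
    while True:
        t += rng.next_exponential(rate_per_s)
        if t > t_end:
            break
        iteration = math.ceil(t / dt)
        schedule.add(
            ReactionEvent(rule=rule, targets=(), iteration=iteration, seq=0, kind="creation")
        )
        count += 1
    return count


def schedule_unimolecular(
    rule: ReactionRule,
    targets: tuple,
    k_eff: float,
    now: int,
    dt: float,
    rng: RandomStream,
    schedule: EventSchedule,
) -> ReactionEvent | None:
    """Draw a waiting time from Exp(k_eff) and store the event.

    The event lands at iteration ``now + ceil(t/dt)``.  A zero effective
    rate schedules nothing.
    """
    if k_eff < 0:
        raise ValueError("effective rate must be >= 0")
    if k_eff == 0.0:
        return None
    t = rng.next_exponential(k_eff)
    iteration = now + max(1, math.ceil(t / dt))
    return schedule.add(
        ReactionEvent(rule=rule, targets=targets, iteration=iteration, seq=0, kind="uni")
    )


# ---------------------------------------------------------------------------
# Binding-radius calibration (Smoluchowski model with fixed-step Brownian
# propagation and an absorbing sphere, following Andrews & Bray)


def molar_rate_to_si(k: float, N_A: float = _const.N_A) -> float:
    """Convert a bimolecular rate constant from 1/(M s) to m^3/s."""
    return k * 1e-3 / N_A


def _reduced_grid(sigma: float):
    """Radial quadrature nodes (midpoint rule) in units of the rms step s.

    Fine resolution around the absorbing radius, coarse elsewhere; the
    domain is trimmed to the region the one-step Gaussian kernel can reach.
    """
    nu = min(sigma, 1.0)
    lo = max(0.0, sigma - 7.0)
    fine_lo = max(lo, sigma - 4.0 * nu)
    fine_hi = sigma + 4.0 * nu
    window_hi = sigma + 12.0
    pad_hi = sigma + 18.0
    h_fine = nu / 14.0
    h_coarse = 1.0 / 12.0
    segments = []
    if fine_lo > lo:
        segments.append((lo, fine_lo, h_coarse))
    segments.append((fine_lo, min(fine_hi, window_hi), h_fine))
    if fine_hi < window_hi:
        segments.append((fine_hi, window_hi, h_coarse))
    segments.append((window_hi, pad_hi, h_coarse))
    nodes = []
    widths = []
    for a, b, h in segments:
        if b <= a:
            continue
        n = max(1, int(math.ceil((b - a) / h)))
        hh = (b - a) / n
        nodes.append(a + (np.arange(n) + 0.5) * hh)
        widths.append(np.full(n, hh))
    r = np.concatenate(nodes)
    w = np.concatenate(widths)
    return r, w, window_hi


_SQRT_2PI = math.sqrt(2.0 * math.pi)


def reduced_reaction_rate(sigma: float) -> float:
    """Steady-state absorbed volume per step for a unit rms step length.

    For an absorbing sphere of radius ``sigma`` (in units of the rms
    relative step per axis, ``s = sqrt(2 D_mut dt)``) embedded in a unit-
    density bath, returns the volume (in units of s^3) cleared per time
    step at steady state.  The steady state of the diffuse-then-absorb
    iteration is solved directly as a linear system in the radial density,
    with the far field matched to the harmonic profile ``1 - A/r``.

    Limits: ``2*pi*sigma`` (Smoluchowski) for large sigma and
    ``(4/3)*pi*sigma^3`` (one-step sweep-up) for small sigma.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r, hw, window_hi = _reduced_grid(sigma)
    core = r <= sigma
    tail = r > window_hi
    interior = ~core & ~tail

    # kernel K[j, i]: contribution of linear density w(r_i) to w(r_j) after
    # one radial Gaussian step (method of images at the origin)
    diff = r[None, :] - r[:, None]
    summ = r[None, :] + r[:, None]
    K = (np.exp(-0.5 * diff**2) - np.exp(-0.5 * summ**2)) / _SQRT_2PI * hw[None, :]

    idx_i = np.where(interior)[0]
    idx_t = np.where(tail)[0]
    idx_c = np.where(core)[0]
    n_i = len(idx_i)

    K_ii = K[np.ix_(idx_i, idx_i)]
    K_it = K[np.ix_(idx_i, idx_t)]
    r_t = r[idx_t]

    # absorbed mass per step = 4*pi * sum_core h*r*w'  ->  A = absorbed/(2*pi)
    c_vec = 2.0 * (hw[idx_c] * r[idx_c]) @ K[idx_c, :]
    c_i = c_vec[idx_i]
    c_t = c_vec[idx_t]

    M = np.zeros((n_i + 1, n_i + 1))
    rhs = np.zeros(n_i + 1)
    M[:n_i, :n_i] = np.eye(n_i) - K_ii
    M[:n_i, n_i] = K_it.sum(axis=1)
    rhs[:n_i] = K_it @ r_t
    M[n_i, :n_i] = -c_i
    M[n_i, n_i] = 1.0 + c_t.sum()
    rhs[n_i] = c_t @ r_t

    sol = np.linalg.solve(M, rhs)
    A = sol[n_i]
    return 2.0 * math.pi * A


def compute_binding_radius(
    k: float, D_mut: float, dt: float, N_A: float = _const.N_A
) -> float:
    """Binding radius sigma (m) reproducing rate constant ``k`` at steady state.

    Parameters
    ----------
    k:
        Macroscopic bimolecular rate constant in 1/(M s).
    D_mut:
        Mutual diffusion coefficient (sum of the two reactants' D), m^2/s.
    dt:
        Simulation time step, s.
    """
    if k <= 0:
        raise ValueError("rate constant must be > 0")
    if D_mut <= 0:
        raise ValueError("mutual diffusion coefficient must be > 0")
    if dt <= 0:
        raise ValueError("time step must be > 0")
    s = math.sqrt(2.0 * D_mut * dt)
    k_si = molar_rate_to_si(k, N_A)
    kappa_target = k_si * dt / s**3

    # the reduced rate is bounded above by both limits, so the root lies
    # above both inversions
    lo = max(kappa_target / (2.0 * math.pi), (3.0 * kappa_target / (4.0 * math.pi)) ** (1.0 / 3.0))
    lo = max(lo * 0.999, 1e-12)
    hi = lo * 1.05 + 0.5
    f = lambda x: reduced_reaction_rate(x) - kappa_target
    f_hi = f(hi)
    guard = 0
    while f_hi < 0.0:
        hi *= 1.6
        guard += 1
        if guard > 80 or hi > 1e7:
            raise CalibrationError(
                "binding-radius inversion failed to bracket a root; the requested "
                "rate is too large for this diffusion coefficient and time step "
                "(try a smaller time step)"
            )
        f_hi = f(hi)
    f_lo = f(lo)
    guard = 0
    while f_lo > 0.0:
        # numerical slack can put the analytic lower bound above the root
        lo *= 0.98
        guard += 1
        if guard > 200:
            raise CalibrationError("binding-radius inversion failed near the lower bound")
        f_lo = f(lo)
    sigma_reduced = brentq(f, lo, hi, xtol=1e-12, rtol=1e-9)
    return sigma_reduced * s


class BindingRadiusCalibrator:
    """Cached (rule, mutual D, dt) -> sigma lookups.

    Mutual diffusion coefficients are rounded to 4 significant digits for
    the cache key so that clusters of identical composition share one
    calibration.
    """

    def __init__(self, dt: float, N_A: float = _const.N_A):
        self.dt = dt
        self.N_A = N_A
        self._cache: dict[tuple, float] = {}

    @staticmethod
    def _round_sig(x: float, sig: int = 4) -> float:
        if x == 0.0:
            return 0.0
        return float(f"{x:.{sig}e}")

    def sigma(self, rule: ReactionRule, D_mut: float, rate: float | None = None) -> float:
        k = rule.rate if rate is None else rate
        key = (rule.id, self._round_sig(D_mut), self._round_sig(k))
        hit = self._cache.get(key)
        if hit is None:
            hit = compute_binding_radius(k, D_mut, self.dt, self.N_A)
            self._cache[key] = hit
        return hit

    def max_sigma(self) -> float:
        return max(self._cache.values(), default=0.0)


# ---------------------------------------------------------------------------
# Binding geometry


def _category(tag: str) -> str:
    if tag == TAG_STATIC:
        return "static"
    if tag == TAG_MEMBRANE:
        return "membrane"
    return "free"


def _restricted_rotation(q_full: np.ndarray, fraction: float, category: str) -> np.ndarray:
    if category == "static" or fraction == 0.0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if category == "membrane":
        _, angle = twist_about_y(q_full)
        return y_rotation_quat(fraction * angle)
    return slerp(q_full, fraction)


def _rotate_cluster_about(cluster: _m.Cluster, pivot: np.ndarray, q: np.ndarray) -> None:
    # in place: the engine may hold the cluster's pose as matrix-row views
    cluster.com[:] = pivot + qrotate(q, cluster.com - pivot)
    cluster.orientation[:] = qmult(q, cluster.orientation)


def apply_binding_geometry(
    a: _m.Cluster,
    ea_uid: int,
    ref_a: _m.SiteRef,
    b: _m.Cluster,
    eb_uid: int,
    ref_b: _m.SiteRef,
    uids: _m.UidAllocator,
) -> tuple[_m.Cluster, _m.Bond]:
    """Align two free sites and merge their clusters.

    Rigid transforms superimpose the site centre points, make the normal
    vectors anti-parallel and the plane vectors parallel.  The rotational
    and translational burden is split in proportion to the partners'
    hydrodynamic volumes (bigger clusters move less); membrane partners
    rotate only about y and keep their y coordinate, static partners do not
    move at all.  Raises :class:`GeometryInfeasibleError` when the
    landscape restrictions make the alignment impossible.
    """
    cat_a = _category(a.effective_landscape)
    cat_b = _category(b.effective_landscape)
    wa = a.hydro_radius**3
    wb = b.hydro_radius**3

    # The less restricted partner performs the final, exact alignment; the
    # other partner contributes its volume-weighted share first, within its
    # landscape limits.  Ties go to the smaller cluster finishing (bigger
    # clusters rotate less).
    rank = {"free": 0, "membrane": 1, "static": 2}
    a_side = (a, ea_uid, ref_a, cat_a, wa)
    b_side = (b, eb_uid, ref_b, cat_b, wb)
    if (rank[cat_a], wa) >= (rank[cat_b], wb):
        first, last = a_side, b_side
    else:
        first, last = b_side, a_side
    cf, cl = first[0], last[0]

    # partial alignment by the restricted/larger partner
    c1, n1, p1 = _m.site_world_frame(cf, first[1], first[2])
    c2, n2, p2 = _m.site_world_frame(cl, last[1], last[2])
    q_full_first = frame_alignment_quat(n1, p1, -n2, p2)
    frac_first = last[4] / (first[4] + last[4])
    rot_first = _restricted_rotation(q_full_first, frac_first, first[3])
    _rotate_cluster_about(cf, c1, rot_first)
    c1, n1, p1 = _m.site_world_frame(cf, first[1], first[2])

    # full residual alignment by the less restricted partner
    q_full_last = frame_alignment_quat(n2, p2, -n1, p1)
    rot_last = (
        q_full_last
        if last[3] == "free"
        else _restricted_rotation(q_full_last, 1.0, last[3])
    )
    _rotate_cluster_about(cl, c2, rot_last)

    ca, na, pa = _m.site_world_frame(a, ea_uid, ref_a)
    cb, nb, pb = _m.site_world_frame(b, eb_uid, ref_b)
    if float(np.dot(na, nb)) > -1.0 + NORMAL_ALIGN_TOL or float(np.dot(pa, pb)) < 1.0 - NORMAL_ALIGN_TOL:
        raise GeometryInfeasibleError(
            "landscape restrictions prevent anti-parallel site alignment"
        )

    # translation: t_b - t_a = ca - cb, split per axis by mobility and volume
    delta = ca - cb
    mob_a = np.ones(3)
    mob_b = np.ones(3)
    if cat_a == "static":
        mob_a[:] = 0.0
    elif cat_a == "membrane":
        mob_a[1] = 0.0
    if cat_b == "static":
        mob_b[:] = 0.0
    elif cat_b == "membrane":
        mob_b[1] = 0.0
    t_a = np.zeros(3)
    t_b = np.zeros(3)
    scale = max(np.linalg.norm(ca), np.linalg.norm(cb), 1e-30)
    for ax in range(3):
        denom = mob_a[ax] * wb + mob_b[ax] * wa
        if denom == 0.0:
            if abs(delta[ax]) > 1e-9 * scale + 1e-15:
                raise GeometryInfeasibleError(
                    "both partners are immobile along an axis with a site-centre gap"
                )
            continue
        t_b[ax] = delta[ax] * (mob_b[ax] * wa) / denom
        t_a[ax] = -delta[ax] * (mob_a[ax] * wb) / denom
    a.com += t_a
    b.com += t_b

    bond = _m.Bond(uid=uids.take(), entity_a=ea_uid, site_a=ref_a, entity_b=eb_uid, site_b=ref_b)
    merged = _m.merge_clusters(a, b, bond, uids)
    return merged, bond


def apply_unbinding(
    c: _m.Cluster,
    bond: _m.Bond,
    sigma,
    uids: _m.UidAllocator,
):
    """Dissolve a bond and separate the fragments by the binding radius.

    The fragments are pushed apart along the former normal direction of the
    bond so that the two freed site centres end up ``sigma`` apart, with the
    displacement split by hydrodynamic volume and landscape mobility.
    ``sigma`` may be a float or a callable ``(frag_a, frag_b) -> float``
    (evaluated after the split, when the fragments' diffusion coefficients
    are known).  Returns the resulting cluster(s).
    """
    _, n_a, _ = _m.site_world_frame(c, bond.entity_a, bond.site_a)
    parts = _m.split_cluster(c, bond, uids)
    if not isinstance(parts, tuple):
        return (parts,)
    frag_a = next(p for p in parts if any(e.uid == bond.entity_a for e in p.entities))
    frag_b = next(p for p in parts if any(e.uid == bond.entity_b for e in p.entities))
    if callable(sigma):
        sigma = sigma(frag_a, frag_b)

    cat_a = _category(frag_a.effective_landscape)
    cat_b = _category(frag_b.effective_landscape)
    wa = frag_a.hydro_radius**3
    wb = frag_b.hydro_radius**3
    mob_a = np.zeros(3) if cat_a == "static" else np.ones(3)
    mob_b = np.zeros(3) if cat_b == "static" else np.ones(3)
    if cat_a == "membrane":
        mob_a[1] = 0.0
    if cat_b == "membrane":
        mob_b[1] = 0.0
    # sites separate along the former normal of side a (which points toward b)
    sep = sigma * n_a
    t_a = np.zeros(3)
    t_b = np.zeros(3)
    for ax in range(3):
        denom = mob_a[ax] * wb + mob_b[ax] * wa
        if denom == 0.0:
            continue  # immobile axis: drop this component of the separation
        t_b[ax] = sep[ax] * (mob_b[ax] * wa) / denom
        t_a[ax] = -sep[ax] * (mob_a[ax] * wb) / denom
    frag_a.com += t_a
    frag_b.com += t_b
    return (frag_a, frag_b)


# ---------------------------------------------------------------------------
# Bimolecular resolution


def resolve_bimolecular(sim, pairs, rng: RandomStream) -> list:
    """Execute the eligible candidate pairs of one iteration.

    ``sim`` is the running simulation (engine); ``pairs`` the ordered
    candidate list from the voxel grid.  A site consumed by an earlier
    reaction in the same iteration is skipped; eligibility requires the
    centre-centre distance to be within the rule's binding radius for the
    clusters' current mutual diffusion coefficient and a non-zero effective
    rate under the reactants' feature states.  Returns descriptions of the
    executed reactions.
    """
    executed = []
    consumed: set[tuple[int, _m.SiteRef]] = set()
    if len(pairs) > 8:
        # cheap vectorised prefilter: a binding radius can never exceed the
        # voxel side (validated at start-up), so farther pairs are inert
        pa = np.array([p[0].position for p in pairs])
        pb = np.array([p[1].position for p in pairs])
        d = pa - pb
        grid = sim.grid
        if grid.periodic:
            d -= grid.L * np.round(d / grid.L)
        close = (d * d).sum(axis=1) <= grid.voxel_side**2
        pairs = [p for p, keep in zip(pairs, close) if keep]
    for site_i, site_j, rule in pairs:
        key_i = (site_i.entity_uid, site_i.ref)
        key_j = (site_j.entity_uid, site_j.ref)
        if key_i in consumed or key_j in consumed:
            continue
        cl_i = sim.cluster_of_entity(site_i.entity_uid)
        cl_j = sim.cluster_of_entity(site_j.entity_uid)
        if cl_i is None or cl_j is None or cl_i.uid == cl_j.uid:
            continue
        ent_i = cl_i.entity(site_i.entity_uid)
        ent_j = cl_j.entity(site_j.entity_uid)
        if not ent_i.is_free(site_i.ref) or not ent_j.is_free(site_j.ref):
            continue
        # orient the pair so that "a" is the rule's first site type
        if site_i.site_type == rule.site_a:
            ent_a, ref_a, cl_a = ent_i, site_i.ref, cl_i
            ent_b, ref_b, cl_b = ent_j, site_j.ref, cl_j
            pos_a, pos_b = site_i.position, site_j.position
        else:
            ent_a, ref_a, cl_a = ent_j, site_j.ref, cl_j
            ent_b, ref_b, cl_b = ent_i, site_i.ref, cl_i
            pos_a, pos_b = site_j.position, site_i.position
        k_eff = effective_rate(rule, ent_a.feature_states, ent_b.feature_states)
        if k_eff <= 0.0:
            continue
        sigma = sim.sigma_for(rule, cl_a.D + cl_b.D, k_eff)
        dist = sim.pair_distance(pos_a, pos_b)
        if dist > sigma:
            continue
        info = sim.execute_bimolecular(rule, ent_a, ref_a, cl_a, ent_b, ref_b, cl_b)
        if info is None:
            continue  # geometrically infeasible; reaction aborted
        consumed.add((ent_a.uid, ref_a))
        consumed.add((ent_b.uid, ref_b))
        executed.append(info)
    return executed
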