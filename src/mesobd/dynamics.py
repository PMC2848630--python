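"""Diffusion, landscapes and boundary interaction.

Movement of a cluster is a free Brownian step: each active coordinate of
the displacement is drawn from N(0, 2*D*dt).  The diffusion coefficient D
depends on the cluster's *diffusion landscape*:

* ``unrestricted`` / ``above_membrane`` / ``below_membrane`` — 3D diffusion
  in a fluid of viscosity eta, Stokes-Einstein ``D = kB*T / (6 pi eta r)``.
* ``membrane`` — lateral 2D diffusion of a cylinder of radius r spanning a
  membrane of thickness h and viscosity mu surrounded by a fluid of
  viscosity eta_w, Saffman-Delbrueck
  ``D = kB*T / (4 pi mu h) * (ln(mu h / (eta_w r)) - gamma)``.
* ``static`` — no movement at all (D = 0).

The membrane is the plane y = membrane_y; membrane clusters never move
along y.  Circular membrane domains may override the membrane viscosity
locally and carry their own boundary conditions on their circumference.

Boundary crossing is endpoint-based: a cluster interacts with a boundary
only if its end-of-step position lies on the other side of it, regardless
of the path in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

from .geometry import IDENTITY_QUAT, random_quaternion, y_rotation_quat
from .rng import RandomStream

EULER_GAMMA = float(np.euler_gamma)

TAG_UNRESTRICTED = "unrestricted"
TAG_MEMBRANE = "membrane"
TAG_ABOVE = "above_membrane"
TAG_BELOW = "below_membrane"
TAG_STATIC = "static"
LANDSCAPE_TAGS = (TAG_UNRESTRICTED, TAG_MEMBRANE, TAG_ABOVE, TAG_BELOW, TAG_STATIC)

BOUNDARY_TYPES = ("open", "absorbing", "periodic", "reflective")

DEFAULT_MEMBRANE_THICKNESS = 5e-9  # m
DEFAULT_WATER_VISCOSITY = 1e-3  # Pa s

_PROB_TOL = 1e-12


class LandscapeError(ValueError):
    """Inconsistent or unusable landscape configuration."""


class RegimeError(ValueError):
    """Parameters outside the validity regime of a diffusion formula."""


@dataclass(frozen=True)
class PhysicalContext:
    """Physical constants and the simulation temperature."""

    T: float = 298.15
    k_B: float = _const.k
    N_A: float = _const.N_A
    gamma: float = EULER_GAMMA

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be > 0 K")


@dataclass
class LandscapeSpec:
    """One diffusion landscape and its physical parameters (SI units)."""

    tag: str
    viscosity: float = DEFAULT_WATER_VISCOSITY
    membrane_y: float = 0.0
    membrane_thickness: float = DEFAULT_MEMBRANE_THICKNESS
    exterior_viscosity: float = DEFAULT_WATER_VISCOSITY

    def __post_init__(self):
        if self.tag not in LANDSCAPE_TAGS:
            raise LandscapeError(f"unknown landscape tag {self.tag!r}")
        if self.tag != TAG_STATIC and self.viscosity <= 0:
            raise LandscapeError("viscosity must be > 0")


@dataclass
class MembraneDomain:
    """Circular sub-domain of the membrane plane with its own viscosity."""

    id: str
    centre: tuple[float, float]  # (x, z) in m
    radius: float
    viscosity: float
    boundary_out: "BoundaryConditionSet | None" = None  # crossing inside -> outside
    boundary_in: "BoundaryConditionSet | None" = None  # crossing outside -> inside

    def __post_init__(self):
        if self.radius <= 0:
            raise LandscapeError(f"membrane domain {self.id!r}: radius must be > 0")
        if self.viscosity <= 0:
            raise LandscapeError(f"membrane domain {self.id!r}: viscosity must be > 0")

    def contains(self, x: float, z: float) -> bool:
        # closed disc: a point exactly on the circumference is inside
        dx, dz = x - self.centre[0], z - self.centre[1]
        return dx * dx + dz * dz <= self.radius * self.radius


@dataclass
class BoundaryConditionSet:
    """Mixture of boundary interactions drawn per crossing event."""

    entries: list[tuple[str, float]] = field(default_factory=lambda: [("reflective", 1.0)])

    def __post_init__(self):
        for kind, p in self.entries:
            if kind not in BOUNDARY_TYPES:
                raise ValueError(f"unknown boundary interaction {kind!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError("boundary probabilities must lie in [0, 1]")
        total = sum(p for _, p in self.entries)
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(
                f"boundary interaction probabilities must sum to 1, got {total!r}"
            )

    def draw(self, rng: RandomStream) -> str:
        if len(self.entries) == 1:
            return self.entries[0][0]
        u = rng.next_uniform()
        acc = 0.0
        for kind, p in self.entries:
            acc += p
            if u < acc:
                return kind
        return self.entries[-1][0]

    @property
    def is_pure(self) -> str | None:
        """The single interaction type if deterministic, else None."""
        if len(self.entries) == 1 or any(p == 1.0 for _, p in self.entries):
            for kind, p in self.entries:
                if p == 1.0 or len(self.entries) == 1:
                    return kind
        return None


# ---------------------------------------------------------------------------
# Diffusion coefficients


def diffusion_coefficient_3d(ctx: PhysicalContext, eta: float, r: float) -> float:
    """Stokes-Einstein diffusion coefficient of a sphere of radius r."""
    if r <= 0:
        raise ValueError("hydrodynamic radius must be > 0")
    if eta <= 0:
        raise ValueError("viscosity must be > 0")
    return ctx.k_B * ctx.T / (6.0 * np.pi * eta * r)


def diffusion_coefficient_membrane(
    ctx: PhysicalContext, mu_m: float, h: float, eta_w: float, r: float
) -> float:
    """Saffman-Delbrueck lateral diffusion coefficient of a membrane cylinder.

    Valid only while ``mu_m*h/(eta_w*r) > exp(gamma)``; outside that regime
    the formula would give a non-positive D and a :class:`RegimeError` is
    raised.
    """
    if min(mu_m, h, eta_w, r) <= 0:
        raise ValueError("all Saffman-Delbrueck parameters must be > 0")
    arg = mu_m * h / (eta_w * r)
    log_term = np.log(arg) - ctx.gamma
    if log_term <= 0:
        raise RegimeError(
            "Saffman-Delbrueck regime violated: mu_m*h/(eta_w*r) = "
            f"{arg:.4g} <= exp(gamma); use a larger membrane viscosity/thickness "
            "or a smaller inclusion radius"
        )
    return ctx.k_B * ctx.T / (4.0 * np.pi * mu_m * h) * log_term


_PRECEDENCE = {TAG_STATIC: 0, TAG_MEMBRANE: 1, TAG_ABOVE: 2, TAG_BELOW: 2, TAG_UNRESTRICTED: 3}


def effective_landscape(tags) -> str:
    """Most limiting landscape of a set: static > membrane > half-spaces > unrestricted."""
    tags = set(tags)
    if not tags:
        raise LandscapeError("empty landscape set")
    unknown = tags - set(LANDSCAPE_TAGS)
    if unknown:
        raise LandscapeError(f"unknown landscape tags {sorted(unknown)}")
    if TAG_STATIC in tags:
        return TAG_STATIC
    if TAG_MEMBRANE in tags:
        return TAG_MEMBRANE
    if TAG_ABOVE in tags and TAG_BELOW in tags:
        raise LandscapeError(
            "cluster restricted to both half-spaces (above and below the membrane): "
            "the valid region is empty"
        )
    if TAG_ABOVE in tags:
        return TAG_ABOVE
    if TAG_BELOW in tags:
        return TAG_BELOW
    return TAG_UNRESTRICTED


# ---------------------------------------------------------------------------
# Brownian updates


def sample_displacement(D: float, dt: float, tag: str, rng: RandomStream) -> np.ndarray:
    """One Brownian displacement vector for a cluster with coefficient D."""
    if D < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if dt <= 0:
        raise ValueError("time step must be > 0")
    if tag == TAG_STATIC or D == 0.0:
        return np.zeros(3)
    step = np.sqrt(2.0 * D * dt) * rng.normals(3)
    if tag == TAG_MEMBRANE:
        step[1] = 0.0
    return step


def sample_orientation(tag: str, rng: RandomStream) -> np.ndarray:
    """Random re-orientation appropriate for a landscape.

    Returned as a quaternion to be composed with the cluster's current
    orientation: a uniform random rotation for 3D landscapes, a uniform
    rotation about +y for membrane clusters, and the identity for static
    clusters.
    """
    if tag == TAG_STATIC:
        return IDENTITY_QUAT.copy()
    if tag == TAG_MEMBRANE:
        angle = 2.0 * np.pi * rng.next_uniform()
        return y_rotation_quat(angle)
    return random_quaternion(rng.normals(4))


# ---------------------------------------------------------------------------
# Membrane domains


def membrane_domain_of(p, domains: list[MembraneDomain]) -> MembraneDomain | None:
    """Innermost (smallest-radius) domain containing the membrane point p=(x, z).

    Equal radii are tie-broken deterministically by domain id.
    """
    x, z = p
    best = None
    for dom in domains:
        if dom.contains(x, z):
            if best is None or (dom.radius, dom.id) < (best.radius, best.id):
                best = dom
    return best


# ---------------------------------------------------------------------------
# Boundary resolution


@dataclass
class PlaneBoundary:
    """Axis-aligned plane with direction-dependent interaction sets.

    ``axis`` is 0/1/2 for x/y/z; ``level`` the plane coordinate.  ``high``
    applies to crossings towards +axis (end coordinate > level while start
    was inside), ``low`` to crossings towards -axis.  ``wrap`` is the
    translation length used by periodic interactions.
    """

    axis: int
    level: float
    outward_sign: int  # +1 if "outside" is coord > level, -1 otherwise
    conditions: BoundaryConditionSet
    wrap: float = 0.0

    def violated(self, p: np.ndarray) -> bool:
        c = p[self.axis]
        return (c - self.level) * self.outward_sign > 0


class Absorbed:
    """Sentinel: the cluster crossed an absorbing (or outer open) boundary."""

    def __repr__(self):  # pragma: no cover
        return "<absorbed>"


ABSORBED = Absorbed()

_MAX_BOUNDARY_ITER = 100


def resolve_boundary(
    start: np.ndarray,
    end: np.ndarray,
    boundaries: list[PlaneBoundary],
    rng: RandomStream,
):
    """Resolve all boundary crossings of one movement step.

    Returns the final position, or :data:`ABSORBED` if the cluster left the
    simulation.  Crossings are detected from the end position only; when
    several planes are violated simultaneously the one intersected first
    along the start-end segment is handled first, and the test repeats until
    the end position is valid.
    """
    start = np.asarray(start, dtype=float).copy()
    end = np.asarray(end, dtype=float).copy()
    for _ in range(_MAX_BOUNDARY_ITER):
        crossed = [b for b in boundaries if b.violated(end)]
        if not crossed:
            return end
        # order by intersection parameter along the segment
        def _t(b: PlaneBoundary) -> float:
            d = end[b.axis] - start[b.axis]
            if d == 0.0:
                return np.inf
            return (b.level - start[b.axis]) / d

        crossed.sort(key=_t)
        b = crossed[0]
        kind = b.conditions.draw(rng)
        if kind == "absorbing":
            return ABSORBED
        if kind == "open":
            # an outer open face lets the cluster leave the tracked volume
            return ABSORBED
        if kind == "periodic":
            shift = -b.outward_sign * b.wrap
            start[b.axis] += shift
            end[b.axis] += shift
        elif kind == "reflective":
            end[b.axis] = 2.0 * b.level - end[b.axis]
    raise RuntimeError(
        "boundary resolution did not converge after "
        f"{_MAX_BOUNDARY_ITER} iterations; the movement step is too large "
        "for the simulation volume"
    )


def resolve_domain_crossing(
    start_xz: tuple[float, float],
    end_xz: tuple[float, float],
    domains: list[MembraneDomain],
    rng: RandomStream,
):
    """Resolve membrane-domain circumference crossings for a membrane cluster.

    Endpoint-based like plane boundaries.  Reflective interactions mirror
    the end point radially about the circle; periodic interactions are not
    supported on circular boundaries (rejected at model load).
    """
    x0, z0 = start_xz
    x1, z1 = end_xz
    for _ in range(_MAX_BOUNDARY_ITER):
        moved = False
        for dom in domains:
            was_in = dom.contains(x0, z0)
            is_in = dom.contains(x1, z1)
            if was_in == is_in:
                continue
            cond = dom.boundary_out if was_in else dom.boundary_in
            if cond is None:
                continue
            kind = cond.draw(rng)
            if kind == "absorbing":
                return ABSORBED
            if kind == "open":
                continue
            if kind == "reflective":
                dx, dz = x1 - dom.centre[0], z1 - dom.centre[1]
                r = np.hypot(dx, dz)
                if r == 0.0:
                    continue
                r_new = 2.0 * dom.radius - r
                if r_new <= 0.0:
                    r_new = 0.5 * dom.radius  # pathological overshoot through centre
                x1 = dom.centre[0] + dx / r * r_new
                z1 = dom.centre[1] + dz / r * r_new
                moved = True
        if not moved:
            return (x1, z1)
    raise RuntimeError("membrane-domain boundary resolution did not converge")
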