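"""Programmatic model builders.

:func:`generate_example_model` emits the membrane receptor-clustering
demonstration model: membrane-bound receptors R, scaffold molecules B and
ligands A diffusing above the membrane.  B carries two R-binding sites and
one A-binding site that only becomes available once both R sites are
occupied (tracked by a feature state).  All binding reactions share one
rate constant and are irreversible.

The remaining builders produce minimal, single-purpose models used for
validation: free diffusion (3D and membrane), zeroth-order creation,
first-order decay and the irreversible well-mixed A+B association box.
They compute viscosities so that the requested diffusion coefficients are
met exactly, and derive box sizes and time steps from the requested
kinetic regime rather than hard-coding geometry.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import constants as _const
from scipy.optimize import brentq

from .dynamics import (
    BoundaryConditionSet,
    DEFAULT_MEMBRANE_THICKNESS,
    DEFAULT_WATER_VISCOSITY,
    LandscapeSpec,
    PhysicalContext,
    TAG_ABOVE,
    TAG_MEMBRANE,
    TAG_STATIC,
    TAG_UNRESTRICTED,
    diffusion_coefficient_membrane,
)
from .model import EntityTemplate, FeatureDef, ParticleTemplate, SiteTemplate
from .modelio import ModelDocument, OutputSpec
from .reactions import Effect, Guard, ReactionRule, molar_rate_to_si

NM = 1e-9


def _site(site_type, centre, normal_dir, plane_dir):
    centre = np.asarray(centre, dtype=float)
    return SiteTemplate(
        site_type=site_type,
        centre=centre,
        normal_point=centre + np.asarray(normal_dir, dtype=float),
        plane_point=centre + np.asarray(plane_dir, dtype=float),
    )


def _viscosity_for_d3(D: float, r: float, T: float = 298.15) -> float:
    ctx = PhysicalContext(T=T)
    return ctx.k_B * ctx.T / (6.0 * math.pi * D * r)


def _membrane_viscosity_for_d(
    D: float, r: float, h: float = DEFAULT_MEMBRANE_THICKNESS,
    eta_w: float = DEFAULT_WATER_VISCOSITY, T: float = 298.15,
) -> float:
    ctx = PhysicalContext(T=T)

    def f(mu):
        return diffusion_coefficient_membrane(ctx, mu, h, eta_w, r) - D

    # D(mu) rises from 0 at the regime edge to a maximum at
    # mu = e^(1+gamma) * eta_w * r / h and then falls as ~ln(mu)/mu;
    # solve on the physical decreasing branch (more viscous = slower)
    mu_peak = math.exp(1.0 + ctx.gamma) * eta_w * r / h
    if f(mu_peak) < 0:
        raise ValueError(
            f"requested membrane D={D:g} m^2/s exceeds the Saffman-Delbrueck "
            "maximum for this geometry"
        )
    return brentq(f, mu_peak, 1e9, rtol=1e-12)


def generate_example_model(
    n_a: int = 1000,
    n_b: int = 1000,
    n_r: int = 100,
    side: float | None = None,
    dt: float = 1e-6,
    n_iter: int = 5000,
    rate: float = 5e6,
    seed: int = 1,
    n_v: int = 16,
    timepoints: int = 100,
) -> ModelDocument:
    """The three-species membrane complex-assembly model.

    With the default counts the box side is 200 nm; when the counts are
    scaled the side shrinks with the cube root of the scale so that all
    concentrations are preserved.  The binding sequence is
    R + B -> RB, R + RB -> 2RB, then (and only then) 2RB + A -> 2RB-A;
    availability of the A site is gated by B's ``rbound`` feature.
    """
    if side is None:
        scale = n_b / 1000.0
        side = 200e-9 * scale ** (1.0 / 3.0)
    membrane_y = -side / 4.0

    r_template = EntityTemplate(
        id="R",
        particles=(
            ParticleTemplate(
                id="core",
                hydro_radius=2 * NM,
                landscape_tag=TAG_MEMBRANE,
                rel_position=np.zeros(3),
                sites=(_site("R_b", (0, 2 * NM, 0), (0, 1, 0), (1, 0, 0)),),
            ),
        ),
        initial_count=n_r,
        placement=TAG_MEMBRANE,
    )
    b_template = EntityTemplate(
        id="B",
        particles=(
            ParticleTemplate(
                id="core",
                hydro_radius=2 * NM,
                landscape_tag=TAG_ABOVE,
                rel_position=np.zeros(3),
                sites=(
                    _site("B_r", (-1.5 * NM, -1 * NM, 0), (0, -1, 0), (1, 0, 0)),
                    _site("B_r", (+1.5 * NM, -1 * NM, 0), (0, -1, 0), (1, 0, 0)),
                    _site("B_a", (0, 2 * NM, 0), (0, 1, 0), (1, 0, 0)),
                ),
            ),
        ),
        features=(FeatureDef(name="rbound", states=("0", "1", "2"), initial_state="0"),),
        initial_count=n_b,
        placement=TAG_ABOVE,
    )
    a_template = EntityTemplate(
        id="A",
        particles=(
            ParticleTemplate(
                id="core",
                hydro_radius=2 * NM,
                landscape_tag=TAG_ABOVE,
                rel_position=np.zeros(3),
                sites=(_site("A_b", (0, -2 * NM, 0), (0, -1, 0), (1, 0, 0)),),
            ),
        ),
        initial_count=n_a,
        placement=TAG_ABOVE,
    )

    rules = [
        ReactionRule(
            id="bind_rb",
            order=2,
            rate=rate,
            site_a="B_r",
            site_b="R_b",
            binding=True,
            effects=(Effect(target="a", feature="rbound", action="advance"),),
        ),
        ReactionRule(
            id="bind_ab",
            order=2,
            rate=rate,
            site_a="B_a",
            site_b="A_b",
            binding=True,
            guards=(
                Guard(target="a", feature="rbound", state="2", multiplier=1.0),
                Guard(target="a", feature="rbound", state="*", multiplier=0.0),
            ),
        ),
    ]

    return ModelDocument(
        L=side,
        dt=dt,
        n_iter=n_iter,
        n_v=n_v,
        seed=seed,
        landscapes={
            TAG_MEMBRANE: LandscapeSpec(
                tag=TAG_MEMBRANE, viscosity=1.0, membrane_y=membrane_y
            ),
            TAG_ABOVE: LandscapeSpec(tag=TAG_ABOVE, viscosity=DEFAULT_WATER_VISCOSITY),
        },
        entities=[r_template, b_template, a_template],
        rules=rules,
        output=OutputSpec(
            selected=("B",),
            divisor=max(1, n_iter // timepoints),
            fields=("feature_state", "entity_count"),
        ),
    )


def free_diffusion_model(
    n: int = 1000,
    D: float = 1e-12,
    dt: float = 1e-4,
    n_iter: int = 1000,
    side: float = 1e-5,
    landscape: str = TAG_UNRESTRICTED,
    seed: int = 1,
    radius: float = 2e-9,
) -> ModelDocument:
    """Inert tracers with an exactly prescribed diffusion coefficient.

    The landscape viscosity is solved from the requested D, so measured
    mean-squared displacements can be compared against 6*D*t (3D) or
    4*D*t (membrane) without rounding slack.
    """
    landscapes = {}
    if landscape == TAG_MEMBRANE:
        mu = _membrane_viscosity_for_d(D, radius)
        landscapes[TAG_MEMBRANE] = LandscapeSpec(
            tag=TAG_MEMBRANE, viscosity=mu, membrane_y=0.0
        )
        placement = TAG_MEMBRANE
    else:
        eta = _viscosity_for_d3(D, radius)
        landscapes[landscape] = LandscapeSpec(tag=landscape, viscosity=eta)
        placement = landscape
    template = EntityTemplate(
        id="T",
        particles=(
            ParticleTemplate(
                id="core",
                hydro_radius=radius,
                landscape_tag=landscape,
                rel_position=np.zeros(3),
            ),
        ),
        initial_count=n,
        placement=placement,
    )
    return ModelDocument(
        L=side,
        dt=dt,
        n_iter=n_iter,
        n_v=1,
        seed=seed,
        landscapes=landscapes,
        entities=[template],
        output=OutputSpec(selected=("T",), divisor=1, fields=("position",)),
    )


def creation_model(
    k0: float = 1e-6,
    dt: float = 1e-3,
    n_iter: int = 10_000,
    side: float = 1e-6,
    seed: int = 1,
) -> ModelDocument:
    """Zeroth-order creation of immobile product molecules.

    With the defaults the creation volume is 1 fL, giving a mean of
    ``k0*dt*V*N_A = 0.602`` molecules per step.
    """
    template = EntityTemplate(
        id="X",
        particles=(
            ParticleTemplate(
                id="core",
                hydro_radius=1e-9,
                landscape_tag=TAG_STATIC,
                rel_position=np.zeros(3),
            ),
        ),
        initial_count=0,
        placement=TAG_UNRESTRICTED,
    )
    rule = ReactionRule(
        id="create_x", order=0, rate=k0, product="X", creation_landscape=TAG_UNRESTRICTED
    )
    return ModelDocument(
        L=side,
        dt=dt,
        n_iter=n_iter,
        n_v=1,
        seed=seed,
        entities=[template],
        rules=[rule],
        output=OutputSpec(selected=("X",), divisor=1, fields=("entity_count",)),
    )


def decay_model(
    n: int = 10_000,
    k1: float = 1.0,
    dt: float = 1e-4,
    n_iter: int = 100_000,
    side: float = 1e-6,
    seed: int = 1,
) -> ModelDocument:
    """First-order decay of a population of immobile molecules."""
    template = EntityTemplate(
        id="X",
        particles=(
            ParticleTemplate(
                id="core",
                hydro_radius=1e-9,
                landscape_tag=TAG_STATIC,
                rel_position=np.zeros(3),
            ),
        ),
        initial_count=n,
        placement=TAG_UNRESTRICTED,
    )
    rule = ReactionRule(id="decay_x", order=1, rate=k1, reactant="X", outcome="remove")
    return ModelDocument(
        L=side,
        dt=dt,
        n_iter=n_iter,
        n_v=1,
        seed=seed,
        entities=[template],
        rules=[rule],
        output=OutputSpec(selected=("X",), divisor=max(1, n_iter // 10), fields=("entity_count",)),
    )


def bimolecular_box_model(
    n_a: int = 1000,
    n_b: int = 1000,
    k: float = 3e8,
    D_each: float = 1e-11,
    reduced_step: float = 0.1,
    steps_to_half: int = 16000,
    run_factor: float = 1.25,
    seed: int = 1,
    timepoints: int = 12,
    radius: float = 2e-9,
) -> ModelDocument:
    """Irreversible A + B -> AB association in a periodic box.

    The time step is set so that the rms relative step per axis is
    ``reduced_step`` times the Smoluchowski radius ``k_SI/(4 pi D_mut)``,
    and the box side so that the mass-action half-life of the reaction
    spans ``steps_to_half`` iterations.  Both species share one diffusion
    coefficient, enforced through the landscape viscosity.
    """
    D_mut = 2.0 * D_each
    k_si = molar_rate_to_si(k)
    sigma_smol = k_si / (4.0 * math.pi * D_mut)
    s = reduced_step * sigma_smol
    dt = s * s / (2.0 * D_mut)
    t_half = steps_to_half * dt
    c0_m3 = 1.0 / (k_si * t_half)  # molecules per m^3 (k_si*c' = 1/t_half)
    side = (n_a / c0_m3) ** (1.0 / 3.0)
    n_v = max(3, int(side / (1.25 * sigma_smol)))
    n_iter = int(math.ceil(run_factor * steps_to_half))

    eta = _viscosity_for_d3(D_each, radius)
    landscapes = {TAG_UNRESTRICTED: LandscapeSpec(tag=TAG_UNRESTRICTED, viscosity=eta)}

    def species(tid, site_type, count):
        return EntityTemplate(
            id=tid,
            particles=(
                ParticleTemplate(
                    id="core",
                    hydro_radius=radius,
                    landscape_tag=TAG_UNRESTRICTED,
                    rel_position=np.zeros(3),
                    sites=(_site(site_type, (0, 0, 0), (0, 1, 0), (1, 0, 0)),),
                ),
            ),
            initial_count=count,
            placement=TAG_UNRESTRICTED,
        )

    rule = ReactionRule(
        id="assoc", order=2, rate=k, site_a="A_s", site_b="B_s", binding=True
    )
    periodic = BoundaryConditionSet([("periodic", 1.0)])
    faces = {(axis, side_) for axis in range(3) for side_ in ("low", "high")}
    return ModelDocument(
        L=side,
        dt=dt,
        n_iter=n_iter,
        n_v=n_v,
        seed=seed,
        landscapes=landscapes,
        face_conditions={key: periodic for key in faces},
        entities=[species("A", "A_s", n_a), species("B", "B_s", n_b)],
        rules=[rule],
        output=OutputSpec(
            selected=(),
            divisor=max(1, n_iter // timepoints),
            fields=("position", "entity_count"),
        ),
    )
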