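import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    from mesobd.rng import RandomStream

    return RandomStream(123)


@pytest.fixture
def uids():
    from mesobd.model import UidAllocator

    return UidAllocator()


@pytest.fixture
def ctx():
    from mesobd.dynamics import PhysicalContext

    return PhysicalContext()


def make_template(
    tid="X",
    radius=1e-9,
    landscape="unrestricted",
    sites=(),
    features=(),
    count=0,
    placement="unrestricted",
    n_particles=1,
    particle_offsets=None,
):
    """Small entity-template builder shared across the suite."""
    from mesobd.model import EntityTemplate, ParticleTemplate

    particles = []
    for i in range(n_particles):
        off = (
            np.zeros(3)
            if particle_offsets is None
            else np.asarray(particle_offsets[i], dtype=float)
        )
        particles.append(
            ParticleTemplate(
                id=f"p{i}",
                hydro_radius=radius,
                landscape_tag=landscape,
                rel_position=off,
                sites=tuple(sites) if i == 0 else (),
            )
        )
    return EntityTemplate(
        id=tid,
        particles=tuple(particles),
        features=tuple(features),
        initial_count=count,
        placement=placement,
    )


def make_site(site_type="s", centre=(0, 0, 0), normal=(0, 1, 0), plane=(1, 0, 0)):
    from mesobd.model import SiteTemplate

    centre = np.asarray(centre, dtype=float)
    return SiteTemplate(
        site_type=site_type,
        centre=centre,
        normal_point=centre + np.asarray(normal, dtype=float) * 1e-9,
        plane_point=centre + np.asarray(plane, dtype=float) * 1e-9,
    )


@pytest.fixture
def template_factory():
    return make_template


@pytest.fixture
def site_factory():
    return make_site
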