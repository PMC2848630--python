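"""Molecular hierarchy: radii, merge/split, nested coordinates."""

import numpy as np
import pytest

from mesobd import model as m
from mesobd.geometry import quat_from_axis_angle

from conftest import make_site, make_template

NM = 1e-9


def _single(uids, rng, radius=1e-9, landscape="unrestricted", pos=(0, 0, 0), sites=(),
            features=(), tid="X", membrane_y=None):
    t = make_template(tid=tid, radius=radius, landscape=landscape, sites=sites,
                      features=features)
    return m.instantiate_entity(
        t, np.asarray(pos, dtype=float), rng, uids, membrane_y=membrane_y
    )


class TestHydroRadius:
    def test_single_particle_identity(self):
        assert m.cluster_hydro_radius([1e-9]) == pytest.approx(1e-9)

    def test_two_unit_particles(self):
        assert m.cluster_hydro_radius([1e-9, 1e-9]) == pytest.approx(
            2 ** (1 / 3) * 1e-9, rel=1e-12
        )

    def test_eight_unit_particles(self):
        assert m.cluster_hydro_radius([1e-9] * 8) == pytest.approx(2e-9, rel=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            m.cluster_hydro_radius([])


class TestInstantiate:
    def test_radius_features_and_free_sites(self, uids, rng):
        c = _single(
            uids, rng, sites=(make_site(),),
            features=(m.FeatureDef("bindstate", ("0R", "1R"), "0R"),),
        )
        assert c.hydro_radius == pytest.approx(1e-9)
        e = c.entities[0]
        assert e.feature_states["bindstate"] == "0R"
        assert all(b is None for b in e.site_bonds.values())

    def test_membrane_template_must_sit_on_membrane(self, uids, rng):
        t = make_template(landscape="membrane")
        with pytest.raises(m.PlacementError):
            m.instantiate_entity(t, np.array([0, 1e-9, 0]), rng, uids, membrane_y=0.0)

    def test_position_outside_volume_rejected(self, uids, rng):
        t = make_template()
        with pytest.raises(m.PlacementError):
            m.instantiate_entity(t, np.array([2e-6, 0, 0]), rng, uids, half_side=1e-6)


def _bond(uids, ca, cb):
    return m.Bond(
        uid=uids.take(),
        entity_a=ca.entities[0].uid,
        site_a=(0, 0),
        entity_b=cb.entities[0].uid,
        site_b=(0, 0),
    )


class TestMergeSplit:
    def test_merged_radius(self, uids, rng):
        a = _single(uids, rng, sites=(make_site(),))
        b = _single(uids, rng, sites=(make_site(),), pos=(3e-9, 0, 0))
        merged = m.merge_clusters(a, b, _bond(uids, a, b), uids)
        assert merged.hydro_radius == pytest.approx(2 ** (1 / 3) * 1e-9, rel=1e-12)

    def test_static_partner_dominates_landscape(self, uids, rng):
        a = _single(uids, rng, sites=(make_site(),))
        b = _single(uids, rng, sites=(make_site(),), landscape="static", tid="S")
        merged = m.merge_clusters(a, b, _bond(uids, a, b), uids)
        assert merged.effective_landscape == "static"

    def test_entity_identities_and_world_positions_preserved(self, uids, rng):
        a = _single(uids, rng, sites=(make_site(),), pos=(1e-9, 2e-9, 0))
        b = _single(uids, rng, sites=(make_site(),), pos=(-3e-9, 0, 1e-9))
        uids_before = {a.entities[0].uid, b.entities[0].uid}
        pos_before = {
            a.entities[0].uid: a.entity_world_position(a.entities[0]),
            b.entities[0].uid: b.entity_world_position(b.entities[0]),
        }
        merged = m.merge_clusters(a, b, _bond(uids, a, b), uids)
        assert {e.uid for e in merged.entities} == uids_before
        for e in merged.entities:
            np.testing.assert_allclose(
                merged.entity_world_position(e), pos_before[e.uid], atol=1e-21
            )

    def test_occupied_site_cannot_rebind(self, uids, rng):
        a = _single(uids, rng, sites=(make_site(),))
        b = _single(uids, rng, sites=(make_site(),))
        bond = _bond(uids, a, b)
        merged = m.merge_clusters(a, b, bond, uids)
        c = _single(uids, rng, sites=(make_site(),))
        bad = m.Bond(
            uid=uids.take(),
            entity_a=merged.entities[0].uid,
            site_a=(0, 0),
            entity_b=c.entities[0].uid,
            site_b=(0, 0),
        )
        with pytest.raises(m.OccupancyError):
            m.merge_clusters(merged, c, bad, uids)

    def test_merge_then_split_restores_memberships(self, uids, rng):
        a = _single(uids, rng, sites=(make_site(),))
        b = _single(uids, rng, sites=(make_site(),), pos=(2e-9, 0, 0))
        ua, ub = a.entities[0].uid, b.entities[0].uid
        bond = _bond(uids, a, b)
        merged = m.merge_clusters(a, b, bond, uids)
        fa, fb = m.split_cluster(merged, bond, uids)
        got = {frozenset(e.uid for e in f.entities) for f in (fa, fb)}
        assert got == {frozenset([ua]), frozenset([ub])}
        for f in (fa, fb):
            for e in f.entities:
                assert all(bv is None for bv in e.site_bonds.values())

    def test_split_non_cut_edge_keeps_one_cluster(self, uids, rng):
        import networkx as nx

        sites3 = tuple(make_site(site_type=f"s{i}") for i in range(3))
        clusters = [
            _single(uids, rng, sites=sites3, pos=(i * 1e-9, 0, 0), tid=f"T{i}")
            for i in range(3)
        ]
        # triangle: 0-1, 1-2, 2-0
        bonds = []
        merged = clusters[0]
        for i, j, sa, sb in ((0, 1, 0, 0), (1, 2, 1, 0), (2, 0, 1, 1)):
            bond = m.Bond(
                uid=uids.take(),
                entity_a=clusters[i].entities[0].uid,
                site_a=(0, sa),
                entity_b=clusters[j].entities[0].uid,
                site_b=(0, sb),
            )
            bonds.append(bond)
        merged = m.merge_clusters(clusters[0], clusters[1], bonds[0], uids)
        merged = m.merge_clusters(merged, clusters[2], bonds[1], uids)
        # close the triangle: intra-cluster bond
        ea = merged.entity(bonds[2].entity_a)
        eb = merged.entity(bonds[2].entity_b)
        ea.site_bonds[bonds[2].site_a] = bonds[2]
        eb.site_bonds[bonds[2].site_b] = bonds[2]
        merged.bonds.append(bonds[2])

        result = m.split_cluster(merged, bonds[0], uids)
        assert not isinstance(result, tuple)
        # oracle: connected components of the remaining bond graph
        gph = nx.Graph()
        gph.add_nodes_from(e.uid for e in result.entities)
        gph.add_edges_from((b.entity_a, b.entity_b) for b in result.bonds)
        assert nx.number_connected_components(gph) == 1
        assert len(result.entities) == 3

    def test_particle_count_conserved_across_split(self, uids, rng):
        a = _single(uids, rng, sites=(make_site(),))
        b = _single(uids, rng, sites=(make_site(),))
        bond = _bond(uids, a, b)
        merged = m.merge_clusters(a, b, bond, uids)
        n_before = sum(len(e.template.particles) for e in merged.entities)
        parts = m.split_cluster(merged, bond, uids)
        n_after = sum(
            len(e.template.particles) for f in parts for e in f.entities
        )
        assert n_before == n_after

    def test_derived_properties_match_recomputation(self, uids, rng):
        a = _single(uids, rng, sites=(make_site(),), radius=1.5e-9)
        b = _single(uids, rng, sites=(make_site(),), radius=0.7e-9, landscape="static")
        merged = m.merge_clusters(a, b, _bond(uids, a, b), uids)
        r, ls, eff = merged.hydro_radius, merged.landscape_set, merged.effective_landscape
        merged.recompute_derived()
        assert merged.hydro_radius == r
        assert merged.landscape_set == ls
        assert merged.effective_landscape == eff


class TestSiteWorldPosition:
    def test_trivial_identity_chain(self, uids, rng):
        c = _single(uids, rng, sites=(make_site(centre=(0, 0, 0)),), pos=(5e-9, 0, 0))
        c.orientation = np.array([1.0, 0, 0, 0])
        np.testing.assert_allclose(
            m.site_world_position(c, c.entities[0].uid, (0, 0)),
            [5e-9, 0, 0],
            atol=1e-21,
        )

    def test_offset_chain_addition(self, uids, rng):
        site = make_site(centre=(0, 0, 1e-9))
        t = make_template(sites=(site,), particle_offsets=[(0, 1e-9, 0)])
        c = m.instantiate_entity(t, np.zeros(3), rng, m.UidAllocator())
        c.orientation = np.array([1.0, 0, 0, 0])
        c.entities[0].rel_com = np.array([1e-9, 0, 0])
        np.testing.assert_allclose(
            m.site_world_position(c, c.entities[0].uid, (0, 0)),
            [1e-9, 1e-9, 1e-9],
            atol=1e-21,
        )

    def test_cluster_rotation_about_y(self, uids, rng):
        c = _single(uids, rng, sites=(make_site(centre=(1e-9, 0, 0)),), pos=(0, 0, 0))
        c.orientation = quat_from_axis_angle([0, 1, 0], np.pi / 2)
        np.testing.assert_allclose(
            m.site_world_position(c, c.entities[0].uid, (0, 0)),
            [0, 0, -1e-9],
            atol=1e-18,
        )

    def test_nested_transform_matches_scipy(self, uids, rng):
        from scipy.spatial.transform import Rotation

        nprng = np.random.default_rng(17)
        site = make_site(centre=tuple(nprng.standard_normal(3) * NM))
        t = make_template(sites=(site,), particle_offsets=[nprng.standard_normal(3) * NM])
        c = m.instantiate_entity(t, nprng.standard_normal(3) * NM, rng, uids)
        e = c.entities[0]
        e.rel_com = nprng.standard_normal(3) * NM
        qc, qe = c.orientation, e.orientation
        Rc = Rotation.from_quat([qc[1], qc[2], qc[3], qc[0]])
        Re = Rotation.from_quat([qe[1], qe[2], qe[3], qe[0]])
        local = t.particles[0].rel_position + site.centre
        expected = c.com + Rc.apply(e.rel_com + Re.apply(local))
        np.testing.assert_allclose(
            m.site_world_position(c, e.uid, (0, 0)), expected, atol=1e-20
        )


class TestSiteTemplateValidation:
    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            m.SiteTemplate(
                site_type="s",
                centre=np.zeros(3),
                normal_point=np.zeros(3),
                plane_point=np.array([1e-9, 0, 0]),
            )

    def test_grossly_nonperpendicular_plane_rejected(self):
        with pytest.raises(ValueError):
            m.SiteTemplate(
                site_type="s",
                centre=np.zeros(3),
                normal_point=np.array([0, 1e-9, 0]),
                plane_point=np.array([1e-9, 1e-9, 0]),
            )

    def test_small_deviation_is_reorthogonalised(self):
        s = m.SiteTemplate(
            site_type="s",
            centre=np.zeros(3),
            normal_point=np.array([0, 1e-9, 0]),
            plane_point=np.array([1e-9, 1e-13, 0]),
        )
        assert abs(float(np.dot(s.normal, s.plane))) < 1e-12
        assert np.linalg.norm(s.plane) == pytest.approx(1.0)
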