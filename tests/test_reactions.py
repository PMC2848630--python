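"""Reaction machinery: scheduling, guards, calibration, binding geometry."""

import math

import numpy as np
import pytest
from scipy import stats

from mesobd import model as m
from mesobd import reactions as rx
from mesobd.geometry import qmult, qconj, twist_about_y
from mesobd.model import UidAllocator, instantiate_entity
from mesobd.rng import RandomStream

from conftest import make_site, make_template


class _FixedUniform(RandomStream):
    def __init__(self, value):
        super().__init__(0)
        self._value = value

    def next_uniform(self):
        return self._value


def _rule(**kw):
    base = dict(id="r", order=2, rate=1e6, site_a="a", site_b="b", binding=True)
    base.update(kw)
    return rx.ReactionRule(**base)


class TestZerothOrder:
    def test_lambda_value(self, rng):
        # k=1e-6 M/s, dt=1e-3 s, V=1e-15 L -> lambda = 0.602 per step
        rule = rx.ReactionRule(id="c", order=0, rate=1e-6, product="X")
        sched = rx.EventSchedule()
        n = rx.schedule_zeroth_order(rule, 1e-15, 1e-3, 10_000, rng, sched)
        lam = 1e-6 * 1e-3 * 1e-15 * 6.02214076e23
        assert lam == pytest.approx(0.602, abs=0.001)
        assert abs(n - lam * 10_000) < 3 * math.sqrt(lam * 10_000)
        assert len(sched) == n

    def test_zero_rate_schedules_nothing(self, rng):
        rule = rx.ReactionRule(id="c", order=0, rate=0.0, product="X")
        sched = rx.EventSchedule()
        assert rx.schedule_zeroth_order(rule, 1e-15, 1e-3, 1000, rng, sched) == 0

    def test_counts_are_poisson_dispersed(self, rng):
        rule = rx.ReactionRule(id="c", order=0, rate=1e-6, product="X")
        sched = rx.EventSchedule()
        n_iter = 20_000
        rx.schedule_zeroth_order(rule, 1e-15, 1e-3, n_iter, rng, sched)
        counts = np.zeros(n_iter + 1, dtype=int)
        for evs in sched._by_iter.values():
            for ev in evs:
                counts[ev.iteration] += 1
        per_step = counts[1:]
        disp = per_step.var(ddof=1) / per_step.mean()
        lo = stats.chi2.ppf(0.005, n_iter - 1) / (n_iter - 1)
        hi = stats.chi2.ppf(0.995, n_iter - 1) / (n_iter - 1)
        assert lo < disp < hi


class TestUnimolecular:
    def test_iteration_from_inversion(self):
        # u = e^-1 at k=1/s gives t=1 s -> iteration 1000 at dt=1 ms
        stream = _FixedUniform(math.exp(-1.0))
        sched = rx.EventSchedule()
        rule = rx.ReactionRule(id="d", order=1, rate=1.0, reactant="X")
        ev = rx.schedule_unimolecular(rule, (("entity", 1),), 1.0, 0, 1e-3, stream, sched)
        assert ev.iteration == 1000

    def test_zero_rate_schedules_nothing(self, rng):
        sched = rx.EventSchedule()
        rule = rx.ReactionRule(id="d", order=1, rate=0.0, reactant="X")
        assert (
            rx.schedule_unimolecular(rule, (("entity", 1),), 0.0, 0, 1e-3, rng, sched)
            is None
        )

    def test_waiting_time_mean(self, rng):
        sched = rx.EventSchedule()
        rule = rx.ReactionRule(id="d", order=1, rate=10.0, reactant="X")
        n = 100_000
        its = [
            rx.schedule_unimolecular(rule, (("entity", i),), 10.0, 0, 1e-4, rng, sched).iteration
            for i in range(n)
        ]
        mean_t = np.mean(its) * 1e-4
        assert abs(mean_t - 0.1) < 3 * 0.1 / math.sqrt(n) + 1e-4

    def test_invalidation_removes_only_target(self, rng):
        sched = rx.EventSchedule()
        rule = rx.ReactionRule(id="d", order=1, rate=1.0, reactant="X")
        e1 = rx.schedule_unimolecular(rule, (("entity", 1),), 1.0, 0, 1e-3, rng, sched)
        e2 = rx.schedule_unimolecular(rule, (("entity", 2),), 1.0, 0, 1e-3, rng, sched)
        rx.invalidate_events(sched, ("entity", 1))
        assert e1.cancelled and not e2.cancelled
        assert sched.pending_for(("entity", 1)) == []
        assert sched.pending_for(("entity", 2)) == [e2]

    def test_bond_invalidation(self, rng):
        sched = rx.EventSchedule()
        rule = rx.ReactionRule(
            id="u", order=1, rate=1.0, kind="unbind", site_a="a", site_b="b",
            forward_rule="f",
        )
        ev = rx.schedule_unimolecular(rule, (("bond", 9),), 1.0, 0, 1e-3, rng, sched)
        rx.invalidate_events(sched, ("bond", 9))
        assert ev.cancelled

    def test_events_execute_in_schedule_order(self, rng):
        sched = rx.EventSchedule()
        rule = rx.ReactionRule(id="d", order=1, rate=1.0, reactant="X")
        evs = [
            sched.add(rx.ReactionEvent(rule, (("entity", i),), 5, 0)) for i in range(5)
        ]
        got = sched.events_at(5)
        assert [e.targets for e in got] == [e.targets for e in evs]


class TestEffectiveRate:
    def test_no_guards_gives_base(self):
        assert rx.effective_rate(_rule(), {"f": "x"}) == 1e6

    def test_disabling_guard(self):
        r = _rule(guards=(rx.Guard("a", "state", "closed", 0.0),))
        assert rx.effective_rate(r, {"state": "closed"}) == 0.0
        assert rx.effective_rate(r, {"state": "open"}) == 1e6

    def test_first_matching_guard_wins(self):
        r = _rule(
            guards=(
                rx.Guard("a", "rbound", "2", 1.0),
                rx.Guard("a", "rbound", "*", 0.0),
            )
        )
        assert rx.effective_rate(r, {"rbound": "2"}) == 1e6
        assert rx.effective_rate(r, {"rbound": "0"}) == 0.0
        assert rx.effective_rate(r, {"rbound": "1"}) == 0.0

    def test_identity_multiplier(self):
        r = _rule(guards=(rx.Guard("a", "f", "*", 1.0),))
        assert rx.effective_rate(r, {"f": "x"}) == 1e6

    def test_guard_on_second_reactant(self):
        r = _rule(guards=(rx.Guard("b", "g", "on", 2.0),))
        assert rx.effective_rate(r, {}, {"g": "on"}) == 2e6


class TestBindingRadius:
    def test_smoluchowski_limit(self):
        k, D = 5e6, 2e-12
        k_si = rx.molar_rate_to_si(k)
        sigma_smol = k_si / (4 * math.pi * D)
        dt = (0.01 * sigma_smol) ** 2 / (2 * D)  # s/sigma ~ 0.01
        sigma = rx.compute_binding_radius(k, D, dt)
        assert sigma == pytest.approx(sigma_smol, rel=0.01)
        assert sigma_smol == pytest.approx(0.330e-9, rel=0.01)

    def test_ballistic_limit(self):
        # s >> sigma: the absorbed volume per step fixes sigma^3
        k, D, dt = 5e6, 2e-10, 1e-6
        sigma = rx.compute_binding_radius(k, D, dt)
        k_si = rx.molar_rate_to_si(k)
        sigma_ball = (3 * k_si * dt / (4 * math.pi)) ** (1 / 3)
        s = math.sqrt(2 * D * dt)
        assert s / sigma > 10
        assert sigma == pytest.approx(sigma_ball, rel=0.02)

    def test_monotone_in_rate(self):
        D, dt = 2e-12, 1e-7
        sigmas = [rx.compute_binding_radius(k, D, dt) for k in (1e5, 1e6, 1e7, 1e8)]
        assert all(a < b for a, b in zip(sigmas, sigmas[1:]))

    def test_reduced_rate_bounded_by_both_limits(self):
        for sig in (0.05, 0.5, 2.0, 20.0):
            kappa = rx.reduced_reaction_rate(sig)
            assert kappa < 2 * math.pi * sig
            assert kappa < 4 / 3 * math.pi * sig**3
            assert kappa > 0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rx.compute_binding_radius(0.0, 1e-12, 1e-6)
        with pytest.raises(ValueError):
            rx.compute_binding_radius(1e6, -1e-12, 1e-6)

    def test_calibrator_caches(self):
        cal = rx.BindingRadiusCalibrator(1e-7)
        r = _rule(rate=1e7)
        s1 = cal.sigma(r, 2e-12)
        s2 = cal.sigma(r, 2e-12)
        assert s1 == s2
        assert cal.max_sigma() == s1


def _free_cluster(uids, rng, site, pos, landscape="unrestricted", tid="X", radius=1e-9,
                  membrane_y=None):
    t = make_template(tid=tid, radius=radius, landscape=landscape, sites=(site,))
    return instantiate_entity(
        t, np.asarray(pos, dtype=float), rng, uids, membrane_y=membrane_y
    )


class TestBindingGeometry:
    def _check_aligned(self, merged, ea, ref_a, eb, ref_b):
        ca, na, pa = m.site_world_frame(merged, ea, ref_a)
        cb, nb, pb = m.site_world_frame(merged, eb, ref_b)
        assert np.linalg.norm(ca - cb) <= 1e-12
        assert float(np.dot(na, nb)) <= -1 + 1e-9
        assert float(np.dot(pa, pb)) >= 1 - 1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_free_partners_align_exactly(self, seed, uids):
        rng = RandomStream(seed)
        a = _free_cluster(uids, rng, make_site("a", centre=(0.5, 0.2, -0.1)), (0, 0, 0))
        b = _free_cluster(uids, rng, make_site("b", centre=(-0.3, 0.4, 0.2)), (3e-9, 1e-9, 0), tid="Y")
        merged, bond = rx.apply_binding_geometry(
            a, a.entities[0].uid, (0, 0), b, b.entities[0].uid, (0, 0), uids
        )
        self._check_aligned(merged, bond.entity_a, bond.site_a, bond.entity_b, bond.site_b)
        assert merged.hydro_radius == pytest.approx(2 ** (1 / 3) * 1e-9, rel=1e-9)

    def test_membrane_partner_only_twists_about_y(self, uids):
        rng = RandomStream(3)
        mem = _free_cluster(
            uids, rng, make_site("r", centre=(0, 2e-9, 0), normal=(0, 1, 0)),
            (0, 0, 0), landscape="membrane", tid="R", membrane_y=0.0,
        )
        q_before = mem.orientation.copy()
        free = _free_cluster(
            uids, rng, make_site("b", centre=(0, -1e-9, 0), normal=(0, -1, 0)),
            (2e-9, 3e-9, 0), tid="B",
        )
        merged, bond = rx.apply_binding_geometry(
            mem, mem.entities[0].uid, (0, 0), free, free.entities[0].uid, (0, 0), uids
        )
        self._check_aligned(merged, bond.entity_a, bond.site_a, bond.entity_b, bond.site_b)
        # the membrane entity's world orientation changed only by a y-twist
        e_mem = merged.entity(mem.entities[0].uid)
        q_after = qmult(merged.orientation, e_mem.orientation)
        delta = qmult(q_after, qconj(q_before))
        tw, _ = twist_about_y(delta)
        assert np.allclose(delta, tw, atol=1e-9) or np.allclose(delta, -tw, atol=1e-9)
        # and its y position did not move
        assert merged.entity_world_position(e_mem)[1] == pytest.approx(0.0, abs=1e-15)

    def test_both_normals_plus_y_end_antiparallel(self, uids):
        rng = RandomStream(11)
        a = _free_cluster(uids, rng, make_site("a", normal=(0, 1, 0)), (0, 0, 0))
        b = _free_cluster(uids, rng, make_site("b", normal=(0, 1, 0)), (2e-9, 0, 0), tid="Y")
        merged, bond = rx.apply_binding_geometry(
            a, a.entities[0].uid, (0, 0), b, b.entities[0].uid, (0, 0), uids
        )
        _, na, _ = m.site_world_frame(merged, bond.entity_a, bond.site_a)
        _, nb, _ = m.site_world_frame(merged, bond.entity_b, bond.site_b)
        assert float(np.dot(na, nb)) <= -1 + 1e-9

    def test_two_static_misaligned_partners_abort(self, uids):
        rng = RandomStream(5)
        a = _free_cluster(uids, rng, make_site("a", normal=(0, 1, 0)), (0, 0, 0),
                          landscape="static")
        b = _free_cluster(uids, rng, make_site("b", normal=(1, 0, 0), plane=(0, 1, 0)),
                          (2e-9, 0, 0), landscape="static", tid="Y")
        with pytest.raises(rx.GeometryInfeasibleError):
            rx.apply_binding_geometry(
                a, a.entities[0].uid, (0, 0), b, b.entities[0].uid, (0, 0), uids
            )


class TestUnbinding:
    def test_separation_distance_is_sigma(self, uids):
        rng = RandomStream(7)
        a = _free_cluster(uids, rng, make_site("a"), (0, 0, 0))
        b = _free_cluster(uids, rng, make_site("b"), (2e-9, 0, 0), tid="Y")
        ea, eb = a.entities[0].uid, b.entities[0].uid
        merged, bond = rx.apply_binding_geometry(a, ea, (0, 0), b, eb, (0, 0), uids)
        sigma = 0.7e-9
        fa, fb = rx.apply_unbinding(merged, bond, sigma, uids)
        pa = m.site_world_position(fa, ea, (0, 0))
        pb = m.site_world_position(fb, eb, (0, 0))
        assert np.linalg.norm(pa - pb) == pytest.approx(sigma, abs=1e-12 * 1e-9 + 1e-21)

    def test_particles_conserved(self, uids):
        rng = RandomStream(8)
        a = _free_cluster(uids, rng, make_site("a"), (0, 0, 0))
        b = _free_cluster(uids, rng, make_site("b"), (2e-9, 0, 0), tid="Y")
        merged, bond = rx.apply_binding_geometry(
            a, a.entities[0].uid, (0, 0), b, b.entities[0].uid, (0, 0), uids
        )
        frags = rx.apply_unbinding(merged, bond, 1e-9, uids)
        assert sum(len(f.entities) for f in frags) == 2
        for f in frags:
            for e in f.entities:
                assert all(v is None for v in e.site_bonds.values())


class TestEffects:
    def test_advance_and_saturate(self):
        feat = m.FeatureDef("n", ("0", "1", "2"), "0")
        t = make_template(features=(feat,))
        rng = RandomStream(0)
        c = instantiate_entity(t, np.zeros(3), rng, UidAllocator())
        e = c.entities[0]
        rule = _rule(effects=(rx.Effect("a", "n", "advance"),))
        rx.apply_effects(rule, e)
        assert e.feature_states["n"] == "1"
        rx.apply_effects(rule, e)
        rx.apply_effects(rule, e)
        assert e.feature_states["n"] == "2"  # saturates at the last state

    def test_set_unknown_state_rejected(self):
        feat = m.FeatureDef("n", ("0", "1"), "0")
        t = make_template(features=(feat,))
        c = instantiate_entity(t, np.zeros(3), RandomStream(0), UidAllocator())
        rule = _rule(effects=(rx.Effect("a", "n", "set", "9"),))
        with pytest.raises(ValueError):
            rx.apply_effects(rule, c.entities[0])
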