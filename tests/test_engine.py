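"""Iteration cycle: determinism, skipping, conservation, boundaries."""

import io

import numpy as np
import pytest

from mesobd import engine as E
from mesobd.dynamics import BoundaryConditionSet
from mesobd.examples import (
    bimolecular_box_model,
    creation_model,
    decay_model,
    free_diffusion_model,
    generate_example_model,
)
from mesobd.modelio import ModelDocument, OutputSpec, build_config


def _empty_model(n_iter=10):
    return ModelDocument(L=1e-6, dt=1e-4, n_iter=n_iter, n_v=1, seed=1)


class TestStep:
    def test_empty_model_only_counts_iterations(self):
        sim = E.Simulation(_empty_model())
        sim.run()
        # no events and nothing mobile: every iteration is skipped
        assert sim.iteration == 0
        assert len(sim.clusters) == 0

    def test_static_cluster_never_moves(self):
        doc = free_diffusion_model(n=5, n_iter=50, side=1e-6)
        for p in doc.entities[0].particles:
            object.__setattr__(p, "landscape_tag", "static")
        sim = E.Simulation(doc)
        before = {c.uid: c.com.copy() for c in sim.clusters.values()}
        sim.run()
        for c in sim.clusters.values():
            np.testing.assert_array_equal(c.com, before[c.uid])

    def test_entity_count_conserved_without_reactions(self):
        doc = free_diffusion_model(n=50, n_iter=100, side=1e-6)
        sim = E.Simulation(doc)
        sim.run()
        assert sim.entity_count("T") == 50

    def test_elapsed_time_is_iteration_times_dt(self):
        doc = free_diffusion_model(n=3, n_iter=20, side=1e-6)
        times = []
        E.run(doc, output_observers=[lambda s: times.append(s.iteration * s.cfg.dt)])
        assert times == [pytest.approx(i * doc.dt) for i in range(len(times))]


class TestDeterminism:
    def test_identical_seed_gives_identical_trace(self):
        doc1 = generate_example_model(n_a=30, n_b=30, n_r=5, n_iter=200, seed=9)
        doc2 = generate_example_model(n_a=30, n_b=30, n_r=5, n_iter=200, seed=9)
        s1, s2 = io.StringIO(), io.StringIO()
        E.Simulation(doc1, trace_sink=s1).run()
        E.Simulation(doc2, trace_sink=s2).run()
        assert s1.getvalue() == s2.getvalue()
        assert len(s1.getvalue()) > 0

    def test_different_seed_differs(self):
        doc1 = generate_example_model(n_a=30, n_b=30, n_r=5, n_iter=200, seed=1)
        doc2 = generate_example_model(n_a=30, n_b=30, n_r=5, n_iter=200, seed=2)
        s1, s2 = io.StringIO(), io.StringIO()
        E.Simulation(doc1, trace_sink=s1).run()
        E.Simulation(doc2, trace_sink=s2).run()
        assert s1.getvalue() != s2.getvalue()


class TestIterationSkipping:
    def test_jumps_to_next_event_when_all_static(self):
        doc = decay_model(n=5, k1=0.5, dt=1e-3, n_iter=100_000, seed=4)
        sim = E.Simulation(doc)
        event_iters = sorted(
            ev.iteration
            for evs in sim.schedule._by_iter.values()
            for ev in evs
            if not ev.cancelled
        )
        executed = []
        real_step = sim.step

        def counting_step():
            executed.append(sim.iteration + 1)
            real_step()

        sim.step = counting_step
        sim.run()
        # only iterations holding a scheduled event were executed
        assert executed == [i for i in event_iters if i <= doc.n_iter]

    def test_mobile_cluster_forces_every_iteration(self):
        doc = free_diffusion_model(n=1, n_iter=25, side=1e-6)
        sim = E.Simulation(doc)
        assert sim.next_active_iteration(7) == 8

    def test_no_events_terminates(self):
        sim = E.Simulation(_empty_model(n_iter=1000))
        assert sim.next_active_iteration(0) == 1001


class TestBoundariesInEngine:
    def test_reflective_box_conserves_and_confines(self):
        doc = free_diffusion_model(n=40, D=1e-11, dt=1e-3, n_iter=200, side=2e-7)
        sim = E.Simulation(doc)
        sim.run()
        assert sim.entity_count("T") == 40
        for c in sim.clusters.values():
            assert np.all(np.abs(c.com) <= 1e-7 * (1 + 1e-12))

    def test_absorbing_box_only_loses(self):
        doc = free_diffusion_model(n=40, D=1e-11, dt=1e-3, n_iter=200, side=2e-7)
        absorbing = BoundaryConditionSet([("absorbing", 1.0)])
        doc.face_conditions = {
            (ax, side): absorbing for ax in range(3) for side in ("low", "high")
        }
        sim = E.Simulation(doc)
        sim.run()
        remaining = sim.entity_count("T")
        assert remaining < 40
        assert sim.stats["absorbed"] == 40 - remaining

    def test_periodic_box_conserves(self):
        doc = bimolecular_box_model(n_a=20, n_b=20, steps_to_half=200, seed=3)
        doc.rules = []  # no reactions: particles only wrap around
        sim = E.Simulation(doc)
        sim.run()
        assert sim.entity_count("A") == 20 and sim.entity_count("B") == 20


class TestUserEvents:
    def test_injection_at_iteration(self):
        doc = free_diffusion_model(n=1, n_iter=50, side=1e-6)
        doc.user_events = [
            E.UserEvent(iteration=10, template_id="T", position=np.zeros(3))
        ]
        counts = {}
        sim = E.Simulation(doc)
        sim.output_observers.append(
            lambda s: counts.setdefault(s.iteration, s.entity_count("T"))
        )
        sim.run()
        assert counts[9] == 1
        assert counts[10] == 2
        assert counts[50] == 2


class TestRegistryConsistency:
    def test_incremental_site_registry_matches_rebuild(self):
        doc = generate_example_model(n_a=40, n_b=40, n_r=8, n_iter=400, seed=2)
        sim = E.Simulation(doc)
        sim.run()
        incremental = set(sim._site_reg.keys())
        sim.rebuild_site_registry()
        assert incremental == set(sim._site_reg.keys())

    def test_bound_sites_never_registered(self):
        doc = generate_example_model(n_a=40, n_b=40, n_r=8, n_iter=400, seed=2)
        sim = E.Simulation(doc)
        sim.run()
        for (euid, ref) in sim._site_reg:
            cluster = sim.cluster_of_entity(euid)
            assert cluster is not None
            assert cluster.entity(euid).is_free(ref)


class TestZerothOrderInEngine:
    def test_creation_count_matches_expectation(self):
        doc = creation_model(n_iter=2000)
        sim = E.Simulation(doc)
        lam = 1e-6 * 1e-3 * 1e-15 * sim.ctx.N_A
        sim.run()
        total = sim.entity_count("X")
        assert abs(total - lam * 2000) < 4 * np.sqrt(lam * 2000)


class TestReversibleBinding:
    def test_dissociation_runs_and_conserves_entities(self):
        from mesobd.reactions import ReactionRule

        doc = bimolecular_box_model(n_a=100, n_b=100, steps_to_half=300, seed=5)
        doc.n_iter = 600
        doc.rules.append(
            ReactionRule(
                id="dis", order=1, rate=2e5, kind="unbind",
                site_a="A_s", site_b="B_s", forward_rule="assoc",
            )
        )
        sim = E.Simulation(doc)
        sim.run()
        assert sim.stats["reactions"].get("assoc", 0) > 0
        assert sim.stats["reactions"].get("dis", 0) > 0
        n_a = sum(
            1 for c in sim.clusters.values() for e in c.entities
            if e.template.id == "A"
        )
        assert n_a == 100
        # every bond-referencing site pair is mutually consistent
        for c in sim.clusters.values():
            for bond in c.bonds:
                assert c.entity(bond.entity_a).site_bonds[bond.site_a] is bond
                assert c.entity(bond.entity_b).site_bonds[bond.site_b] is bond


class TestSkipReplayEquivalence:
    def test_forcing_skipped_iterations_changes_nothing(self):
        """Replaying skipped iterations one by one yields the identical end state."""
        import io as _io

        def run_one(force_every_iteration):
            doc = decay_model(n=50, k1=0.5, dt=1e-3, n_iter=20_000, seed=13)
            sink = _io.StringIO()
            sim = E.Simulation(doc, trace_sink=sink)
            if force_every_iteration:
                sim.next_active_iteration = lambda current: current + 1
            sim.run()
            survivors = sorted(
                e.uid for c in sim.clusters.values() for e in c.entities
            )
            return survivors, sim.stats["reactions"]

        assert run_one(False) == run_one(True)


class TestSigmaPolicy:
    def test_initial_mode_ignores_current_diffusion(self):
        doc = bimolecular_box_model(n_a=5, n_b=5, steps_to_half=200, seed=1)
        sim_cur = E.Simulation(doc, config=build_config(doc, sigma_mode="current"))
        doc2 = bimolecular_box_model(n_a=5, n_b=5, steps_to_half=200, seed=1)
        sim_ini = E.Simulation(doc2, config=build_config(doc2, sigma_mode="initial"))
        rule = sim_cur._bi_rules[0]
        d_template = sim_cur._template_mutual_d(rule)
        # a merged, slower pair would recalibrate under "current" ...
        s_cur = sim_cur.sigma_for(rule, d_template / 4.0, rule.rate)
        # ... but not under "initial"
        s_ini = sim_ini.sigma_for(rule, d_template / 4.0, rule.rate)
        s_ref = sim_ini.calibrator.sigma(rule, d_template)
        assert s_ini == s_ref
        assert s_cur != s_ini
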