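"""Layered simulated annealing: moves, acceptance, recording, reproducibility."""

import numpy as np
import pytest

import cyclopep.annealer as annealer_mod
from cyclopep.annealer import (AnnealSchedule, GoodBackboneCriteria, LayerSpec,
                               default_schedule, layer_accept,
                               low_rmsd_annealing, propose_move, run_annealing)
from cyclopep.energy import score_terms
from cyclopep.fixtures import closed_backbone
from cyclopep.geometry import TorsionConformation, forward_kinematics, \
    wrap_degrees
from cyclopep.ramachandran import default_glycine_map
from cyclopep.stability import kabsch_rmsd


@pytest.fixture(scope="module")
def gly_map():
    return default_glycine_map()


def toroidal_delta(a, b):
    return wrap_degrees(np.asarray(a) - np.asarray(b))


class TestProposeMove:
    def test_zero_radius_is_identity(self, gly_map, rng):
        conf = closed_backbone(6, seed=1)
        out = propose_move(conf, 0.0, gly_map, rng)
        assert np.allclose(out.phi, conf.phi)
        assert np.allclose(out.psi, conf.psi)

    def test_displacement_bounded_by_radius(self, gly_map, rng):
        conf = closed_backbone(6, seed=1)
        for _ in range(50):
            out = propose_move(conf, 20.0, gly_map, rng)
            d = np.hypot(toroidal_delta(out.phi, conf.phi),
                         toroidal_delta(out.psi, conf.psi))
            assert np.all(d <= 20.0 + 1e-9)

    def test_disk_uniformity_chi_square(self, gly_map):
        # accepted displacements of an interior residue should be uniform
        # in the disk: counts in equal-area annuli follow a flat multinomial
        rng = np.random.default_rng(77)
        conf = TorsionConformation([-61.0], [-41.0])  # far inside the map
        k = 25.0
        r = []
        for _ in range(10_000):
            out = propose_move(conf, k, gly_map, rng)
            r.append(np.hypot(toroidal_delta(out.phi, conf.phi),
                              toroidal_delta(out.psi, conf.psi))[0])
        r = np.array(r)
        edges = k * np.sqrt(np.linspace(0, 1, 11))  # 10 equal-area annuli
        counts, _ = np.histogram(r, bins=edges)
        expected = len(r) / 10
        chi2 = np.sum((counts - expected) ** 2 / expected)
        # 9 dof; 27.9 is the 0.1% upper tail
        assert chi2 < 27.9

    def test_prohibited_moves_keep_old_torsions(self, gly_map):
        # a residue already at the edge of the allowed region, with a huge
        # radius, must never be left on a prohibited point
        rng = np.random.default_rng(5)
        conf = TorsionConformation([-61.0, 170.0], [-41.0, 0.0])
        for _ in range(100):
            out = propose_move(conf, 170.0, gly_map, rng)
            for i in range(2):
                assert gly_map.is_allowed(out.phi[i], out.psi[i]) or (
                    out.phi[i] == conf.phi[i] and out.psi[i] == conf.psi[i])


class TestLayerAccept:
    def test_downhill_always_accepted(self, rng):
        assert layer_accept(5.0, 4.9, -np.inf, 0.01, rng)

    def test_below_threshold_always_accepted(self, rng):
        assert layer_accept(1.0, 2.0, 3.0, 1e-9, rng)

    def test_equal_energy_accepted_with_probability_one(self, rng):
        # exp(0) = 1: the stochastic branch always passes
        for _ in range(100):
            assert layer_accept(1.0, 1.0, -np.inf, 0.5, rng)

    def test_uphill_acceptance_rate_matches_boltzmann(self):
        rng = np.random.default_rng(123)
        n, hits = 100_000, 0
        for _ in range(n):
            hits += layer_accept(0.0, 1.0, -np.inf, 1.0, rng)
        assert hits / n == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_non_positive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            layer_accept(0.0, 1.0, 0.0, 0.0, rng)


class TestRunAnnealing:
    def test_infinite_temperature_accepts_everything(self, gly_map):
        # with sky-high temperatures and thresholds every proposal passes:
        # the trajectory is a prohibited-region-respecting random walk, and
        # nothing special is recorded (criteria made unreachable)
        sched = AnnealSchedule(
            steps=50,
            layers=(LayerSpec("rama", 1e9, 1e9, 1e9),
                    LayerSpec("cyclic", 1e9, 1e9, 1e9)))
        crit = GoodBackboneCriteria(max_cyclic_error=-1.0,
                                    polish_closure=False)
        init = closed_backbone(6, seed=1)
        counters = {}
        run_annealing(init, sched, crit, gly_map, seed=3, counters=counters)
        # every step evaluated both layers: no rejections short-circuited
        assert counters["rama"] == counters["cyclic"]

    def test_layer_short_circuit(self, gly_map):
        # evaluation counts must form a funnel: each layer fires no more
        # often than the cheaper layer before it, because a rejection
        # short-circuits the rest
        sched = default_schedule(7, steps=400)
        init = closed_backbone(7, seed=1)
        counters = {}
        crit = GoodBackboneCriteria(max_cyclic_error=-1.0,
                                    polish_closure=False)
        run_annealing(init, sched, crit, gly_map, seed=3, counters=counters)
        order = [l.name for l in sched.layers]
        counts = [counters.get(nm, 0) for nm in order]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > counts[-1]  # some rejections actually happened

    def test_reproducibility_bitwise(self, gly_map):
        init = closed_backbone(7, seed=4)
        sched = default_schedule(7, steps=300)
        crit = GoodBackboneCriteria(min_strong_hbonds=0)
        a = run_annealing(init, sched, crit, gly_map, seed=9)
        b = run_annealing(init, sched, crit, gly_map, seed=9)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.conformation.phi, y.conformation.phi)
            assert np.array_equal(x.conformation.psi, y.conformation.psi)
            assert x.breakdown.total == y.breakdown.total

    def test_recorded_candidates_satisfy_criteria_posthoc(self, gly_map):
        init = closed_backbone(7, seed=4)
        sched = default_schedule(7, steps=800)
        crit = GoodBackboneCriteria(min_strong_hbonds=0)
        cands = run_annealing(init, sched, crit, gly_map, seed=2)
        for c in cands:
            # independent re-scoring from scratch
            bd = score_terms(forward_kinematics(c.conformation), gly_map)
            assert bd.cyclic_err <= crit.max_cyclic_error
            assert bd.rep <= crit.max_rep_energy_per_res * 7 + 1e-9

    def test_zero_step_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(steps=0)

    def test_prohibited_initial_rejected(self, gly_map):
        bad = TorsionConformation(np.full(6, 180.0), np.full(6, 0.0))
        assert not gly_map.is_allowed(180.0, 0.0)
        with pytest.raises(ValueError):
            run_annealing(bad, default_schedule(6, steps=10), maps=gly_map)


class TestAcceptanceMonotonicity:
    def test_hotter_layer_accepts_no_fewer_moves(self):
        # for a fixed proposal/uniform stream, raising T can only turn
        # rejections into acceptances
        rng_stream = np.random.default_rng(8).random(2000)
        for T_cold, T_hot in [(0.1, 1.0), (0.5, 5.0)]:
            accept_cold = accept_hot = 0
            for i, u in enumerate(rng_stream):
                dE = 1.0 + (i % 7) * 0.3  # uphill moves
                accept_cold += u < np.exp(-dE / T_cold)
                accept_hot += u < np.exp(-dE / T_hot)
            assert accept_hot >= accept_cold


class TestLowRmsdAnnealing:
    def test_start_at_reference_records_near_zero_rmsd(self, gly_map):
        conf = closed_backbone(6, seed=6)
        ref = forward_kinematics(conf)
        sched = default_schedule(6, steps=400)
        cands = low_rmsd_annealing(conf, ref, sched, maps=gly_map, seed=3)
        assert cands
        rmsds = [kabsch_rmsd(forward_kinematics(c.conformation), ref)
                 for c in cands]
        assert min(rmsds) < 0.75

    def test_two_layer_contract_no_energy_evaluations(self, gly_map):
        conf = closed_backbone(6, seed=6)
        ref = forward_kinematics(conf)
        sched = default_schedule(6, steps=100)
        counters = {}
        low_rmsd_annealing(conf, ref, sched, maps=gly_map, seed=3,
                           counters=counters)
        assert "rep" not in counters
        assert "hbond" not in counters
        assert "misc" not in counters
        assert counters.get("rmsd", 0) > 0

    def test_biased_arm_stays_closer_than_free_arm(self, gly_map):
        conf = closed_backbone(6, seed=6)
        ref = forward_kinematics(conf)
        sched = default_schedule(6, steps=500)
        crit = GoodBackboneCriteria(min_strong_hbonds=0)
        biased = low_rmsd_annealing(conf, ref, sched, crit, maps=gly_map,
                                    seed=11)
        free = run_annealing(conf, sched, crit, gly_map, seed=11)
        if biased and free:
            rb = np.mean([kabsch_rmsd(forward_kinematics(c.conformation),
                                      ref) for c in biased])
            rf = np.mean([kabsch_rmsd(forward_kinematics(c.conformation),
                                      ref) for c in free])
            assert rb <= rf + 1e-9

    def test_size_mismatch_raises(self, gly_map):
        conf = closed_backbone(6, seed=6)
        ref = forward_kinematics(closed_backbone(7, seed=1))
        with pytest.raises(ValueError):
            low_rmsd_annealing(conf, ref, default_schedule(6, steps=10),
                               maps=gly_map)
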