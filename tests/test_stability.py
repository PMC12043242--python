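"""RMSD machinery, PNear, filtering, reshaping, compactness, FES."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cyclopep.fixtures import closed_backbone, fixture_generator
from cyclopep.geometry import TorsionConformation, forward_kinematics
from cyclopep.stability import (EnergyLandscape, backbone_radius,
                                cyclic_min_rmsd, free_energy_surface,
                                hbond_intersections, kabsch_rmsd, pnear,
                                radius_of_gyration, rama_stability_filter,
                                reshape_landscape, R_GAS)


def rotation_grid_rmsd_oracle(P, Q, refine=True):
    """Independent superposition oracle: Euler-angle grid + local refine."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def rmsd_of(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((P - Q @ R.T) ** 2, axis=1)))

    best, best_angles = np.inf, None
    for a in np.arange(-180, 180, 30.0):
        for b in np.arange(-90, 91, 30.0):
            for c in np.arange(-180, 180, 30.0):
                r = rmsd_of(np.deg2rad([a, b, c]))
                if r < best:
                    best, best_angles = r, np.deg2rad([a, b, c])
    if refine:
        res = minimize(rmsd_of, best_angles, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return best


@pytest.fixture(scope="module")
def ring7():
    return forward_kinematics(closed_backbone(7, seed=1))


class TestKabsch:
    def test_identical_structures_zero(self, ring7):
        assert kabsch_rmsd(ring7, ring7) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_copy_zero(self, ring7):
        R = Rotation.random(random_state=5).as_matrix()
        moved = ring7.transformed(R, np.array([1.0, 2.0, 3.0]))
        assert kabsch_rmsd(ring7, moved) == pytest.approx(0.0, abs=1e-6)

    def test_matches_rotation_grid_oracle(self, rng):
        for seed in range(3):
            a = forward_kinematics(closed_backbone(7, seed=10 + seed))
            conf = a.provenance
            jit = TorsionConformation(conf.phi + rng.normal(0, 4, 7),
                                      conf.psi + rng.normal(0, 4, 7))
            b = forward_kinematics(jit)
            mine = kabsch_rmsd(a, b)
            oracle = rotation_grid_rmsd_oracle(a.heavy_coords(),
                                               b.heavy_coords())
            assert mine == pytest.approx(oracle, abs=1e-3)

    def test_size_mismatch_raises(self, ring7):
        other = forward_kinematics(closed_backbone(6, seed=2))
        with pytest.raises(ValueError):
            kabsch_rmsd(ring7, other)


class TestCyclicMinRmsd:
    def test_relabeled_copy_found_at_offset(self, ring7):
        rolled = ring7.relabeled(2)
        r, k = cyclic_min_rmsd(ring7, rolled)
        assert r == pytest.approx(0.0, abs=1e-6)
        # rolling back by n-2 recovers the original labeling
        assert k == (ring7.n - 2) % ring7.n

    def test_never_exceeds_fixed_labeling(self, ring7, rng):
        jit = TorsionConformation(ring7.provenance.phi + rng.normal(0, 8, 7),
                                  ring7.provenance.psi + rng.normal(0, 8, 7))
        b = forward_kinematics(jit)
        assert cyclic_min_rmsd(ring7, b)[0] <= kabsch_rmsd(ring7, b) + 1e-12

    def test_equals_brute_force_over_relabelings(self, ring7, rng):
        jit = TorsionConformation(ring7.provenance.phi + rng.normal(0, 5, 7),
                                  ring7.provenance.psi + rng.normal(0, 5, 7))
        b = forward_kinematics(jit)
        brute = min(kabsch_rmsd(ring7, b.relabeled(k)) for k in range(7))
        assert cyclic_min_rmsd(ring7, b)[0] == pytest.approx(brute, abs=1e-12)

    def test_symmetry(self, ring7, rng):
        jit = TorsionConformation(ring7.provenance.phi + rng.normal(0, 5, 7),
                                  ring7.provenance.psi + rng.normal(0, 5, 7))
        b = forward_kinematics(jit)
        ab = cyclic_min_rmsd(ring7, b)[0]
        ba = cyclic_min_rmsd(b, ring7)[0]
        assert ab == pytest.approx(ba, abs=1e-9)


class TestPNear:
    def test_all_zero_rmsd_gives_one(self):
        assert pnear(energies=[0, 5, -3], rmsds=[0, 0, 0],
                     lambda_=0.5, kT=0.62) == pytest.approx(1.0)

    def test_single_record_closed_form(self):
        lam = 0.5
        assert pnear(energies=[0.0], rmsds=[lam], lambda_=lam,
                     kT=0.62) == pytest.approx(np.exp(-1))

    def test_two_record_half_split(self):
        assert pnear(energies=[0, 0], rmsds=[0, 1e6], lambda_=0.5,
                     kT=0.62) == pytest.approx(0.5)

    def test_energy_shift_invariance(self, rng):
        e = rng.normal(0, 5, 50)
        r = np.abs(rng.normal(1, 1, 50))
        a = pnear(energies=e, rmsds=r, lambda_=1.5, kT=0.62)
        b = pnear(energies=e + 123.456, rmsds=r, lambda_=1.5, kT=0.62)
        assert a == pytest.approx(b, abs=1e-12)

    def test_log_space_matches_naive_on_small_energies(self, rng):
        e = rng.normal(0, 1, 30)
        r = np.abs(rng.normal(1, 0.5, 30))
        lam, kt = 1.5, 0.62
        naive = (np.sum(np.exp(-r ** 2 / lam ** 2) * np.exp(-e / kt))
                 / np.sum(np.exp(-e / kt)))
        assert pnear(energies=e, rmsds=r, lambda_=lam, kT=kt) == \
            pytest.approx(naive, rel=1e-12)

    def test_extreme_energies_stay_finite(self):
        v = pnear(energies=[-5000.0, -4990.0], rmsds=[0.1, 4.0],
                  lambda_=0.5, kT=0.62)
        assert 0 < v <= 1

    def test_monotone_in_rmsd(self, rng):
        e = rng.normal(0, 2, 20)
        r = np.abs(rng.normal(2, 1, 20))
        base = pnear(energies=e, rmsds=r, lambda_=1.5, kT=0.62)
        r2 = r.copy()
        r2[3] *= 0.5  # moving one record closer cannot decrease PNear
        assert pnear(energies=e, rmsds=r2, lambda_=1.5, kT=0.62) >= base

    def test_empty_landscape_raises(self):
        with pytest.raises(ValueError):
            pnear(energies=[], rmsds=[], lambda_=0.5, kT=0.62)

    def test_two_funnel_fixture_matches_naive_formula(self):
        ls = fixture_generator("two_funnel_landscape")
        naive = (np.sum(np.exp(-ls.rmsds ** 2 / ls.lambda_ ** 2)
                        * np.exp(-ls.energies / ls.kT))
                 / np.sum(np.exp(-ls.energies / ls.kT)))
        assert pnear(ls) == pytest.approx(naive, rel=1e-6)


class TestRamaStabilityFilter:
    def test_all_glycine_keeps_fully_allowed_members_at_every_offset(self):
        from cyclopep.ramachandran import default_glycine_map
        g = default_glycine_map()
        pool = [closed_backbone(5, seed=s) for s in range(4)]
        fully_allowed = [c for c in pool
                         if all(g.is_allowed(c.phi[i], c.psi[i])
                                for i in range(5))]
        assert fully_allowed  # at least one usable member
        kept = rama_stability_filter("GGGGG", fully_allowed)
        assert len(kept) == 5 * len(fully_allowed)

    def test_proline_restricts(self):
        pool = [closed_backbone(5, seed=s) for s in range(4)]
        kept_g = rama_stability_filter("GGGGG", pool)
        kept_p = rama_stability_filter("PGGGG", pool)
        assert len(kept_p) < len(kept_g)

    def test_survivors_reverify_by_independent_lookup(self):
        from cyclopep.ramachandran import map_for_residue
        seq = "AGaGA"
        pool = [closed_backbone(5, seed=s) for s in range(6)]
        kept = rama_stability_filter(seq, pool)
        for conf, k in kept:
            for p, aa in enumerate(seq):
                r = (p + k) % 5
                assert map_for_residue(aa).is_allowed(conf.phi[r],
                                                      conf.psi[r])

    def test_offset_completeness(self):
        hook = []
        pool = [closed_backbone(5, seed=1)]
        rama_stability_filter("GGGGG", pool, count_hook=hook)
        assert len(hook) == 5  # exactly n offset tests per candidate

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rama_stability_filter("GGG", [closed_backbone(5, seed=1)])


class TestReshaping:
    def test_new_native_has_zero_rmsd(self):
        structs = [forward_kinematics(closed_backbone(6, seed=s))
                   for s in range(4)]
        energies = np.array([1.0, -2.0, 0.5, 3.0])
        ls = EnergyLandscape(list(range(4)), energies, np.zeros(4),
                            structures=dict(enumerate(structs)))
        out = reshape_landscape(ls)
        assert out.rmsds[1] == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(out.energies, ls.energies)

    def test_reshaping_can_raise_pnear_on_off_native_funnel(self):
        # deep funnel sits off-native: re-anchoring the native at the energy
        # minimum moves the Boltzmann weight close to zero RMSD
        structs = {i: forward_kinematics(closed_backbone(6, seed=i))
                   for i in range(5)}
        rmsds = np.array([cyclic_min_rmsd(structs[0], structs[i])[0]
                          for i in range(5)])
        energies = np.array([0.0, -8.0, -7.5, 2.0, 3.0])
        ls = EnergyLandscape(list(range(5)), energies, rmsds,
                            structures=structs, lambda_=0.5)
        before = pnear(ls)
        after = pnear(reshape_landscape(ls))
        assert after > before

    def test_requires_structures(self):
        ls = EnergyLandscape([0], np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            reshape_landscape(ls)


class TestCompactness:
    def test_single_atom_zero_radius(self):
        from cyclopep.geometry import BackboneStructure
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_unit_square_radius(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
                       dtype=float)
        assert radius_of_gyration(pts) == pytest.approx(np.sqrt(2) / 2)

    def test_two_point_rg(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        assert radius_of_gyration(pts) == pytest.approx(0.5)

    def test_backbone_radius_rigid_invariance(self, ring7):
        R = Rotation.random(random_state=2).as_matrix()
        moved = ring7.transformed(R, np.array([4.0, 4.0, 4.0]))
        assert backbone_radius(moved) == pytest.approx(
            backbone_radius(ring7), abs=1e-9)


class TestHbondIntersections:
    def test_single_bond_no_crossing(self):
        assert hbond_intersections([(0, 3)], 7) == 0

    def test_known_crossing_and_non_crossing(self):
        # chords drawn inside the 7-ring (0-based residues)
        assert hbond_intersections([(0, 3), (1, 5)], 7) == 1
        assert hbond_intersections([(0, 3), (4, 6)], 7) == 0

    def test_shared_endpoint_never_crosses(self):
        assert hbond_intersections([(0, 3), (3, 5)], 7) == 0

    def test_matches_brute_force(self, rng):
        def crosses(c1, c2, n):
            i, j = c1
            k, l = c2
            if len({i, j, k, l}) < 4:
                return False
            def between(x, lo, hi):
                return 0 < (x - lo) % n < (hi - lo) % n
            return between(k, i, j) != between(l, i, j)

        n = 9
        for _ in range(20):
            bonds = [tuple(rng.choice(n, 2, replace=False))
                     for _ in range(5)]
            brute = sum(crosses(bonds[a], bonds[b], n)
                        for a in range(5) for b in range(a + 1, 5))
            assert hbond_intersections(bonds, n) == brute

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            hbond_intersections([(0, 9)], 7)


class TestFES:
    def test_single_cell_gives_zero_free_energy(self):
        grid = free_energy_surface([1.0] * 10, [2.0] * 10, temperature=300.0)
        occupied = ~grid.free_energy.mask
        assert occupied.sum() == 1
        assert grid.free_energy.compressed()[0] == pytest.approx(0.0)

    def test_two_equal_cells(self):
        rmsd = [0.0] * 5 + [10.0] * 5
        rg = [0.0] * 5 + [10.0] * 5
        grid = free_energy_surface(rmsd, rg, temperature=300.0)
        vals = grid.free_energy.compressed()
        expect = -R_GAS * 300.0 * np.log(0.5)
        assert np.allclose(vals, expect)

    def test_boltzmann_normalization(self, rng):
        rmsd, rg = fixture_generator("bivariate_samples", seed=4)
        grid = free_energy_surface(rmsd, rg, temperature=300.0)
        s = np.sum(np.exp(-grid.free_energy.compressed()
                          / (R_GAS * 300.0)))
        assert s == pytest.approx(1.0, abs=1e-9)

    def test_minimum_at_the_mode(self):
        rmsd, rg = fixture_generator("bivariate_samples", seed=9)
        grid = free_energy_surface(rmsd, rg, temperature=300.0)
        imin = grid.minimum_cell
        assert grid.probability[imin] == grid.probability.max()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            free_energy_surface([], [], 300.0)
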