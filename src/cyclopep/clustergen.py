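"""ClusterGen: genetic-algorithm energy-landscape sampling for macrocycles.

For rings too large for exhaustive threading (15-24 residues), alternative
conformations of a designed sequence are generated by a genetic algorithm:

1. *Initialization.*  Backbones come from two layered-SA trajectories --
   one targeting low energy and, when a designed (native) structure exists,
   one targeting low RMSD to it.  All samples are locally relaxed, sorted
   by energy, energy-clustered (greedy leader with an RMSD cutoff on the
   ascending-energy order), and the 2*N_GA(0) lowest-energy cluster centers
   form the initial population.
2. *Generations.*  Each generation produces children by window crossover
   (swap a cyclic window of torsions between two parents, accepted only if
   closure can be restored within the window) and window mutation (disk
   perturbation inside a cyclic window, closure restored the same way),
   relaxes the children, merges them with the parents, re-clusters, and
   keeps the N_GA(i) lowest-energy centers.  Because parents compete with
   children, the best energy never increases.
3. *Recording.*  Every selected cluster center with energy below the
   recording ceiling (0 by default) joins the landscape, with its RMSD to
   the native; with no native, RMSDs are computed at the end against the
   lowest-energy record (prediction mode).

Population schedules follow the published profiles: constant 500 for
15-residue rings, 750 - 5i for 20, 1000 - 10i for 24, over 50 generations;
desk-scale profiles shrink these for testing.  The local relaxation is a
bounded torsion-space minimization of (energy + w * E_cyc), a stand-in for
an external Cartesian relax, with PDB export hooks available in the io
layer for users who have one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .annealer import (GoodBackboneCriteria, default_schedule,
                       low_rmsd_annealing, sample_backbones)
from .energy import DEFAULT_PARAMS, EnergyParams, score_terms
from .geometry import (BackboneStructure, ClosureError, TorsionConformation,
                       close_backbone, cyclic_error, forward_kinematics)
from .ramachandran import (RamachandranMap, default_glycine_map,
                           enumerate_initial_configurations, map_for_residue)
from .stability import EnergyLandscape, cyclic_min_rmsd, lambda_for_size

__all__ = [
    "GAConfig",
    "Individual",
    "EnergyModel",
    "BackboneEnergyModel",
    "population_schedule",
    "init_population",
    "energy_cluster",
    "crossover",
    "mutate",
    "next_generation",
    "run_clustergen",
    "predict_structure",
]


def population_schedule(profile: str) -> Callable[[int], int]:
    """Published N_GA schedules by size profile.

    '15': constant 500; '20': 750 - 5i; '24': 1000 - 10i (generation i).
    """
    table = {
        "15": lambda i: 500,
        "20": lambda i: 750 - 5 * i,
        "24": lambda i: 1000 - 10 * i,
    }
    if profile not in table:
        raise ValueError(f"unknown population profile {profile!r}")
    return table[profile]


@dataclass
class GAConfig:
    """Knobs of the ClusterGen run; defaults are desk-scale."""

    generations: int = 50
    n_ga: Callable[[int], int] | int = 500
    cluster_rmsd_cutoff: float = 1.5      # Angstrom
    crossover_rate: float = 0.5
    mutation_rate: float = 0.5
    mutation_radius: float = 30.0         # degrees
    record_energy_ceiling: float = 0.0    # kcal/mol
    offspring_factor: float = 2.0         # children per current population
    closure_tolerance: float = 1e-6
    relax_maxfev: int = 200
    relax_closure_weight: float = 1e3
    init_sa_runs: int = 20                # SA trajectories per init arm
    sa_steps: int = 2000
    sa_criteria: GoodBackboneCriteria | None = None
    seed: int = 0

    def population(self, i: int) -> int:
        n = self.n_ga(i) if callable(self.n_ga) else int(self.n_ga)
        if n <= 0:
            raise ValueError(f"population schedule hit {n} at generation {i}")
        return n


@dataclass
class Individual:
    """One population member: torsions, built structure, relaxed energy."""

    conformation: TorsionConformation
    structure: BackboneStructure
    energy: float
    rmsd_to_native: float | None = None


# ---------------------------------------------------------------------------
# energy models


class EnergyModel:
    """Protocol: anything with ``score(conf) -> float`` (lower is better)."""

    def score(self, conf: TorsionConformation) -> float:  # pragma: no cover
        raise NotImplementedError


class BackboneEnergyModel(EnergyModel):
    """Weighted backbone E_total for a chirality-coded sequence."""

    def __init__(self, sequence: str, params: EnergyParams = DEFAULT_PARAMS):
        self.sequence = sequence
        self.params = params
        self.maps = [map_for_residue(aa) for aa in sequence]

    def score(self, conf: TorsionConformation) -> float:
        struct = forward_kinematics(conf)
        bd = score_terms(struct, self.maps, self.params)
        return bd.total if np.isfinite(bd.rama) else 1e6


def _closure_nullspace(conf: TorsionConformation, eps: float = 1e-4
                       ) -> np.ndarray:
    """Orthonormal basis of the closure Jacobian's null space (2n x m).

    Directions in torsion space along which the ring stays closed to first
    order; the manifold of closed conformations has dimension 2n - 6 (the
    9 closure residuals carry 3 redundancies from orthonormality).
    """
    from .geometry import cyclic_error_residuals

    x0 = conf.as_vector()
    r0 = cyclic_error_residuals(conf)
    J = np.empty((r0.size, x0.size))
    for j in range(x0.size):
        x = x0.copy()
        x[j] += eps
        J[:, j] = (cyclic_error_residuals(
            TorsionConformation.from_vector(x, conf.geometry)) - r0) / eps
    _, s, Vt = np.linalg.svd(J)
    # at a closed point 3 of the 9 residuals are redundant (orthonormality
    # identities of the frame product), leaving rank 6; finite differences
    # leave O(eps) ghosts there, so the rank cut must be generous
    rank = int(np.sum(s > max(1e-3 * s[0], 1e-6)))
    return Vt[rank:].T


def relax(conf: TorsionConformation, model: EnergyModel, config: GAConfig,
          rounds: int = 10) -> Individual:
    """Bounded local refinement along the closure manifold.

    Each round minimizes the model energy within the tangent null space of
    the closure Jacobian (a small Powell solve; a mild cyclic-error penalty
    absorbs the manifold's curvature), then re-closes exactly.  This walks
    downhill without ever paying the full closure penalty that blocks naive
    coordinate descent.  Surrogate for an external Cartesian relax.
    """
    w = config.relax_closure_weight
    if cyclic_error(conf) <= config.closure_tolerance:
        current = conf.copy()  # GA children arrive already closed
    else:
        try:
            current = close_backbone(conf, tolerance=config.closure_tolerance,
                                     anchor_weight=0.05)
        except ClosureError:
            s = forward_kinematics(conf)
            return Individual(conf.copy(), s, math.inf)
    energy = float(model.score(current))
    budget = max(config.relax_maxfev // rounds, 40)
    for _ in range(rounds):
        Q = _closure_nullspace(current)
        if Q.shape[1] == 0:
            break
        x0 = current.as_vector()

        def objective(z):
            c = TorsionConformation.from_vector(x0 + Q @ z, current.geometry)
            return model.score(c) + w * cyclic_error(c)

        res = minimize(objective, np.zeros(Q.shape[1]), method="Powell",
                       bounds=[(-25.0, 25.0)] * Q.shape[1],
                       options={"maxfev": budget, "xtol": 1e-3, "ftol": 1e-5})
        cand = TorsionConformation.from_vector(x0 + Q @ res.x,
                                               current.geometry)
        try:
            # tangent steps stay near the manifold: a plain (un-anchored)
            # solve already lands on the nearest closed point
            cand = close_backbone(cand, tolerance=config.closure_tolerance,
                                  anchor_weight=0.0)
        except ClosureError:
            break
        cand_energy = float(model.score(cand))
        if cand_energy >= energy - 1e-6:
            break
        current, energy = cand, cand_energy
    return Individual(current, forward_kinematics(current), energy)


# ---------------------------------------------------------------------------
# clustering and initialization


def energy_cluster(individuals: Sequence[Individual], cutoff: float
                   ) -> list[Individual]:
    """Greedy leader clustering on the ascending-energy order.

    Walk the energy-sorted list; an individual founds a new cluster iff its
    cyclic-minimum RMSD to every existing center is >= cutoff.  Returns the
    centers in ascending energy order.  Deterministic.
    """
    ordered = sorted(individuals, key=lambda d: d.energy)
    centers: list[Individual] = []
    for ind in ordered:
        close = False
        for c in centers:
            r, _ = cyclic_min_rmsd(c.structure, ind.structure, shortcut=cutoff)
            if r < cutoff:
                close = True
                break
        if not close:
            centers.append(ind)
    return centers


def _model_annealing(start: TorsionConformation, model: EnergyModel,
                     config: GAConfig, maps, seed: int,
                     keep: int = 2) -> list[TorsionConformation]:
    """Low-energy SA arm for a custom energy model.

    Layered like the backbone sampler but with two tests -- cyclic error,
    then a Metropolis test on the model energy (hot start, geometric
    cooling) -- since a custom model defines its own notion of "low
    energy".  Returns up to ``keep`` distinct low-energy snapshots with
    cyclic error below the polish trigger, best first.
    """
    from .annealer import layer_accept, propose_move

    rng = np.random.default_rng(seed)
    steps = config.sa_steps
    k0, k1 = 60.0, 1.0
    cycT0, cycTf = 10.0, 0.005
    T0, Tf = 100.0, 0.5
    cur = start.copy()
    curE = model.score(cur)
    curC = cyclic_error(cur)
    snaps: list[tuple[float, TorsionConformation]] = []
    for t in range(steps):
        frac = t / max(steps - 1, 1)
        prop = propose_move(cur, k0 + (k1 - k0) * frac, maps, rng)
        propC = cyclic_error(prop)
        if not layer_accept(curC, propC, 0.1,
                            cycT0 * (cycTf / cycT0) ** frac, rng):
            continue
        propE = model.score(prop)
        if not layer_accept(curE, propE, -math.inf,
                            T0 * (Tf / T0) ** frac, rng):
            continue
        cur, curE, curC = prop, propE, propC
        if curC < 0.5 and (len(snaps) < keep or curE < snaps[-1][0]):
            snaps.append((curE, cur.copy()))
            snaps.sort(key=lambda s: s[0])
            del snaps[keep:]
    return [c for _, c in snaps]


def _closed_starts(n: int, config: GAConfig, maps, seed: int):
    """Closed conformations seeding the SA arms (bin-center starts)."""
    rng = np.random.default_rng(seed)
    starts = []
    for conf in enumerate_initial_configurations(
            n, limit=config.init_sa_runs, seed=seed):
        starts.append(conf)
    rng.shuffle(starts)
    return starts[:config.init_sa_runs]


def init_population(sequence: str, native: BackboneStructure | None,
                    config: GAConfig, model: EnergyModel | None = None,
                    maps=None) -> list[Individual]:
    """SA-seeded, relaxed, energy-clustered initial population.

    Two SA arms feed the pool: the low-energy layered SA always, and the
    low-RMSD SA only when a native structure is supplied.  Prediction mode
    (no native) therefore runs unbiased.  Returns at most 2 * N_GA(0)
    cluster centers, ascending energy.
    """
    n = len(sequence)
    model = model or BackboneEnergyModel(sequence)
    maps = maps if maps is not None else default_glycine_map()
    starts = _closed_starts(n, config, maps, config.seed)

    if isinstance(model, BackboneEnergyModel):
        # the layered backbone sampler IS the low-energy SA for this model
        sched = default_schedule(n, steps=config.sa_steps)
        crit = config.sa_criteria or GoodBackboneCriteria(
            polish_tolerance=config.closure_tolerance)
        cands = sample_backbones(starts, sched, crit, maps=maps,
                                 params=model.params, seed=config.seed + 1)
        confs = [c.conformation for c in cands]
    else:
        # custom model: anneal directly on its energy (cyclic test + model
        # Metropolis test)
        confs = []
        for k, start in enumerate(starts):
            confs.extend(_model_annealing(start, model, config, maps,
                                          seed=config.seed + 31 * k + 1))

    if native is not None:
        from .geometry import measure_torsions
        nat_conf = native.provenance or measure_torsions(native)
        for k in range(config.init_sa_runs):
            lr = low_rmsd_annealing(nat_conf, native, sched, maps=maps,
                                    seed=config.seed + 1000 + k)
            confs.extend(c.conformation for c in lr)

    if not confs:
        raise RuntimeError("simulated annealing produced no candidates")

    pool = [relax(c, model, config) for c in confs]
    pool = [d for d in pool if np.isfinite(d.energy)]
    centers = energy_cluster(pool, config.cluster_rmsd_cutoff)
    return centers[: 2 * config.population(0)]


# ---------------------------------------------------------------------------
# variation operators


def _window(n: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean torsion-vector mask for a random cyclic window of residues."""
    length = int(rng.integers(2, max(n // 2, 3)))
    start = int(rng.integers(0, n))
    idx = (start + np.arange(length)) % n
    mask = np.zeros(2 * n, dtype=bool)
    mask[2 * idx] = True
    mask[2 * idx + 1] = True
    return mask


def crossover(parent_a: Individual, parent_b: Individual,
              rng: np.random.Generator, tolerance: float = 1e-6
              ) -> TorsionConformation | None:
    """Swap a cyclic torsion window from b into a; gate on re-closure.

    The closure solve is restricted to the window torsions, so torsions
    outside the exchanged region stay exactly the receiving parent's.
    Returns the closed offspring conformation, or None when the window
    cannot restore closure (the exchange-feasibility gate).
    """
    a = parent_a.conformation
    b = parent_b.conformation
    if a.n != b.n:
        raise ValueError("parents differ in size")
    mask = _window(a.n, rng)
    x = a.as_vector()
    x[mask] = b.as_vector()[mask]
    child = TorsionConformation.from_vector(x, a.geometry)
    try:
        return close_backbone(child, tolerance=tolerance, free_mask=mask)
    except ClosureError:
        return None


def mutate(ind: Individual, radius: float, rng: np.random.Generator,
           maps=None, tolerance: float = 1e-6, max_tries: int = 10
           ) -> TorsionConformation | None:
    """Disk-perturb torsions inside a random cyclic window, then re-close.

    Each window residue moves uniformly within ``radius`` degrees; a
    proposal landing in a prohibited Ramachandran region is redrawn (up to
    ``max_tries``) and then skipped.  Closure is restored within the window;
    None when that fails.
    """
    if radius <= 0:
        raise ValueError("mutation radius must be positive")
    conf = ind.conformation
    n = conf.n
    maps = maps if maps is not None else default_glycine_map()
    if isinstance(maps, RamachandranMap):
        maps = [maps] * n
    mask = _window(n, rng)
    res_idx = np.nonzero(mask[::2])[0]
    phi = conf.phi.copy()
    psi = conf.psi.copy()
    for i in res_idx:
        for _ in range(max_tries):
            u, th = rng.random(), rng.random() * 2 * np.pi
            r = radius * math.sqrt(u)
            p = phi[i] + r * math.cos(th)
            q = psi[i] + r * math.sin(th)
            if maps[i].is_allowed(p, q):
                phi[i], psi[i] = p, q
                break
    child = TorsionConformation(phi, psi, conf.geometry)
    try:
        return close_backbone(child, tolerance=tolerance, free_mask=mask)
    except ClosureError:
        return None


# ---------------------------------------------------------------------------
# generations


def _record(accumulator: list, centers: Sequence[Individual],
            native: BackboneStructure | None, ceiling: float):
    for ind in centers:
        if ind.energy < ceiling:
            rmsd = None
            if native is not None:
                if ind.rmsd_to_native is None:
                    ind.rmsd_to_native = cyclic_min_rmsd(
                        native, ind.structure)[0]
                rmsd = ind.rmsd_to_native
            accumulator.append((ind, rmsd))


def next_generation(population: list[Individual], config: GAConfig, i: int,
                    native: BackboneStructure | None, model: EnergyModel,
                    rng: np.random.Generator, maps=None,
                    accumulator: list | None = None) -> list[Individual]:
    """One GA generation: variation, relaxation, merge, cluster, select."""
    if not population:
        raise RuntimeError("population extinct")
    n_children = int(round(config.offspring_factor * len(population)))
    children: list[Individual] = []
    total_rate = config.crossover_rate + config.mutation_rate
    for _ in range(n_children):
        do_cross = rng.random() < config.crossover_rate / max(total_rate, 1e-12)
        conf = None
        if do_cross and len(population) >= 2:
            ia, ib = rng.choice(len(population), size=2, replace=False)
            conf = crossover(population[ia], population[ib], rng,
                             config.closure_tolerance)
        else:
            ia = int(rng.integers(0, len(population)))
            conf = mutate(population[ia], config.mutation_radius, rng, maps,
                          config.closure_tolerance)
        if conf is None:
            continue
        child = relax(conf, model, config)
        if np.isfinite(child.energy):
            children.append(child)
    merged = list(population) + children
    centers = energy_cluster(merged, config.cluster_rmsd_cutoff)
    selected = centers[: config.population(i)]
    if accumulator is not None:
        _record(accumulator, selected, native, config.record_energy_ceiling)
    return selected


def run_clustergen(sequence: str, native: BackboneStructure | None,
                   config: GAConfig, model: EnergyModel | None = None,
                   maps=None) -> EnergyLandscape:
    """Full ClusterGen run; returns the recorded energy landscape.

    Centers recorded across generations (energy < ceiling) form the
    landscape.  With a native, RMSDs are cyclic-minimum Kabsch against it;
    without one, they are computed against the lowest-energy record at the
    end, exactly as the prediction protocol reshapes its landscape.
    Reproducible for a fixed config.seed.
    """
    n = len(sequence)
    model = model or BackboneEnergyModel(sequence)
    maps = maps if maps is not None else default_glycine_map()
    rng = np.random.default_rng(config.seed + 7)

    population = init_population(sequence, native, config, model, maps)
    accumulator: list = []
    _record(accumulator, population, native, config.record_energy_ceiling)
    for i in range(config.generations):
        population = next_generation(population, config, i, native, model,
                                     rng, maps, accumulator)

    # deduplicate identical individuals recorded in several generations
    seen = {}
    for ind, rmsd in accumulator:
        key = id(ind)
        seen[key] = (ind, rmsd)
    records = list(seen.values())
    ids = list(range(len(records)))
    energies = np.array([r[0].energy for r in records])
    structures = {i: records[i][0].structure for i in ids}

    if native is not None:
        rmsds = np.array([r[1] for r in records], dtype=float)
        nat = native
    else:
        imin = int(np.argmin(energies)) if len(records) else 0
        nat = records[imin][0].structure if records else None
        rmsds = np.array([cyclic_min_rmsd(nat, records[i][0].structure)[0]
                          for i in ids]) if records else np.empty(0)
    return EnergyLandscape(ids, energies, rmsds, native=nat,
                           lambda_=lambda_for_size(n), structures=structures)


def predict_structure(sequence: str, config: GAConfig,
                      model: EnergyModel | None = None, maps=None
                      ) -> tuple[list[Individual], bool]:
    """Sequence-only structure prediction.

    Runs ClusterGen without a native, clusters the 50 lowest-energy records
    at a 1.5 A cutoff, and returns up to the 5 lowest-energy cluster
    centers (ascending energy) plus a flag that is True when fewer than 5
    could be produced.
    """
    landscape = run_clustergen(sequence, None, config, model, maps)
    order = np.argsort(landscape.energies)[:50]
    pool = [Individual(None, landscape.structures[landscape.ids[int(k)]],
                       float(landscape.energies[int(k)]))
            for k in order]
    centers = energy_cluster(pool, 1.5)
    top = centers[:5]
    return top, len(top) < 5
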