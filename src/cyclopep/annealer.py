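"""Layered simulated annealing over torsion space.

A proposed move perturbs every residue independently within a disk of
radius k_t in (phi, psi) space; residues whose displaced point falls in a
prohibited (disallowed-map) region keep their old torsions.  The resulting
configuration must then pass an ordered sequence of energy tests --
Ramachandran, repulsion, cyclic error, H-bond energy, and (for the
small-macrocycle profile) the miscellaneous pair terms -- each with its own
Metropolis criterion: pass if the new layer energy is below the current one
or below the layer threshold, otherwise pass with probability
exp((E_cur - E_new)/T).  A failure at any layer rejects the move without
evaluating the more expensive layers behind it.

This is deliberately *not* a thermodynamically correct Metropolis-Hastings
sampler; the layering exists to discover low-energy closed backbones
cheaply.  Configurations with low repulsive energy, low cyclic error and
enough strong H-bonds are recorded as good backbone candidates (at most one
per torsion-bin string per run, keeping the lowest E_total, with a final
least-squares closure polish re-checked against the criteria).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import bin_string, canonicalize
from .energy import (DEFAULT_PARAMS, EnergyBreakdown, EnergyParams,
                     detect_hbonds, hbond_count_and_energy, misc_energy,
                     rama_energy, rep_energy)
from .geometry import (BackboneStructure, ClosureError, TorsionConformation,
                       close_backbone, cyclic_error, forward_kinematics,
                       wrap_degrees)
from .ramachandran import RamachandranMap, TorsionBinScheme, default_glycine_map
from .stability import kabsch_rmsd

__all__ = [
    "LayerSpec",
    "AnnealSchedule",
    "GoodBackboneCriteria",
    "BackboneCandidate",
    "propose_move",
    "layer_accept",
    "run_annealing",
    "sample_backbones",
    "low_rmsd_annealing",
    "default_schedule",
]

LAYER_NAMES = ("rama", "rep", "cyclic", "hbond", "misc")


@dataclass(frozen=True)
class LayerSpec:
    """One acceptance layer: a name, a pass threshold, and a cooling pair."""

    name: str
    threshold: float
    T0: float
    Tf: float

    def temperature(self, frac: float) -> float:
        """Geometric cooling T0 -> Tf over the run; frac in [0, 1]."""
        return self.T0 * (self.Tf / self.T0) ** frac


@dataclass
class AnnealSchedule:
    """Move-radius schedule, ordered layers, and run bookkeeping."""

    steps: int = 5000
    k_start: float = 40.0  # move-disk radius, degrees
    k_end: float = 0.5
    layers: tuple = (
        LayerSpec("rama", 0.0, 5.0, 0.5),
        LayerSpec("rep", 0.0, 20.0, 1.0),
        LayerSpec("cyclic", 0.1, 10.0, 0.005),
        LayerSpec("hbond", -2.0, 2.0, 0.3),
    )
    max_repeats: int = 3

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("schedule must have at least one step")
        if any(l.T0 <= 0 or l.Tf <= 0 for l in self.layers):
            raise ValueError("layer temperatures must be positive")
        names = [l.name for l in self.layers]
        if any(nm not in LAYER_NAMES for nm in names):
            raise ValueError(f"layer names must be among {LAYER_NAMES}")

    def move_radius(self, t: int) -> float:
        """Linear shrink from k_start to k_end (non-increasing in t)."""
        frac = t / max(self.steps - 1, 1)
        return self.k_start + (self.k_end - self.k_start) * frac


def default_schedule(n: int, steps: int = 5000, with_misc: bool | None = None
                     ) -> AnnealSchedule:
    """Default layered schedule for an n-residue ring.

    The misc layer (attractive + electrostatic + solvation) is appended for
    the small-macrocycle profile (n <= 7) as a final cheap-last test.
    Rama and rep thresholds scale with n.
    """
    if with_misc is None:
        with_misc = n <= 7
    layers = [
        LayerSpec("rama", 2.0 * n, 5.0, 0.5),
        LayerSpec("rep", 1.0 * n, 20.0, 1.0),
        LayerSpec("cyclic", 0.1, 10.0, 0.005),
        LayerSpec("hbond", -2.0, 2.0, 0.3),
    ]
    if with_misc:
        layers.append(LayerSpec("misc", 0.0, 2.0, 0.3))
    return AnnealSchedule(steps=steps, layers=tuple(layers))


@dataclass(frozen=True)
class GoodBackboneCriteria:
    """Thresholds a configuration must meet to be recorded as a candidate.

    When ``polish_closure`` is on (the default), any accepted configuration
    whose cyclic error is below ``polish_trigger`` is first refined by the
    local closure solve; the criteria are then verified on the *polished*
    conformation.  Without polishing, the raw cyclic error must already be
    below ``max_cyclic_error``.
    """

    max_cyclic_error: float = 0.01
    max_rep_energy_per_res: float = 0.5
    min_strong_hbonds: int | None = None  # default max(2, ceil(n/5))
    polish_closure: bool = True
    polish_trigger: float = 0.5
    polish_tolerance: float = 1e-9

    def min_hbonds_for(self, n: int) -> int:
        if self.min_strong_hbonds is not None:
            return self.min_strong_hbonds
        return max(2, math.ceil(n / 5))


@dataclass
class BackboneCandidate:
    """A recorded good backbone: torsions, energies, H-bonds, bin string."""

    conformation: TorsionConformation
    breakdown: EnergyBreakdown
    hbond_count: int
    bin_string: str
    step_found: int


# ---------------------------------------------------------------------------
# elementary operations


def propose_move(current: TorsionConformation, k_t: float,
                 maps: RamachandranMap | Sequence[RamachandranMap],
                 rng: np.random.Generator) -> TorsionConformation:
    """Uniform disk move of radius k_t per residue, prohibited points kept.

    Every residue is displaced independently by a uniform draw from the disk
    of radius ``k_t`` degrees (toroidal wrap); a residue whose displaced
    point leaves its allowed Ramachandran region retains its old torsions.
    Random draws are consumed for every residue regardless of rejection, so
    the proposal stream is reproducible.
    """
    if k_t < 0:
        raise ValueError("move radius must be non-negative")
    n = current.n
    u = rng.random(n)
    theta = rng.random(n) * 2.0 * np.pi
    r = k_t * np.sqrt(u)
    dphi = r * np.cos(theta)
    dpsi = r * np.sin(theta)
    phi = wrap_degrees(current.phi + dphi)
    psi = wrap_degrees(current.psi + dpsi)
    if isinstance(maps, RamachandranMap):
        bad = ~np.isfinite(maps.energy(phi, psi))
    else:
        bad = np.array([not maps[i].is_allowed(phi[i], psi[i])
                        for i in range(n)])
    phi = np.where(bad, current.phi, phi)
    psi = np.where(bad, current.psi, psi)
    return TorsionConformation(phi, psi, current.geometry)


def layer_accept(E_current: float, E_new: float, threshold: float, T: float,
                 rng: np.random.Generator) -> bool:
    """Per-layer Metropolis test.

    Pass if E_new < E_current or E_new < threshold; otherwise pass with
    probability exp((E_current - E_new)/T).  A random number is consumed
    only on the stochastic branch.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if E_new < E_current or E_new < threshold:
        return True
    return rng.random() < math.exp(min((E_current - E_new) / T, 0.0))


# ---------------------------------------------------------------------------
# the annealing loop


class _LayerEnergies:
    """Lazy per-layer energy evaluation with cheapest-first ordering."""

    def __init__(self, conf: TorsionConformation, maps, params: EnergyParams,
                 counters: dict | None = None):
        self.conf = conf
        self.maps = maps
        self.params = params
        self._struct = None
        self._cache: dict[str, float] = {}
        self._bonds = None
        self.counters = counters

    @property
    def struct(self) -> BackboneStructure:
        if self._struct is None:
            self._struct = forward_kinematics(self.conf)
        return self._struct

    def bonds(self):
        if self._bonds is None:
            self._bonds = detect_hbonds(self.struct, self.params)
        return self._bonds

    def energy(self, name: str) -> float:
        if name not in self._cache:
            if self.counters is not None:
                self.counters[name] = self.counters.get(name, 0) + 1
            if name == "rama":
                v = rama_energy(self.conf, self.maps)
            elif name == "rep":
                v = rep_energy(self.struct, self.params)
            elif name == "cyclic":
                v = cyclic_error(self.conf)
            elif name == "hbond":
                v = hbond_count_and_energy(self.bonds(), params=self.params)[1]
            elif name == "misc":
                v = sum(misc_energy(self.struct, self.params))
            else:
                raise ValueError(f"unknown layer {name!r}")
            self._cache[name] = float(v)
        return self._cache[name]

    def breakdown(self) -> EnergyBreakdown:
        attr, elec, solv = misc_energy(self.struct, self.params)
        count, hb = hbond_count_and_energy(self.bonds(), params=self.params)
        return EnergyBreakdown(
            rama=self.energy("rama"), rep=self.energy("rep"),
            attractive=attr, elec=elec, solv=solv, hbond=hb,
            cyclic_err=self.energy("cyclic"), hbond_count=count)


def _meets(state: _LayerEnergies, criteria, params) -> bool:
    n = state.conf.n
    if not np.isfinite(state.energy("rama")):
        return False  # refinement must not strand a residue off its map
    if state.energy("cyclic") > criteria.max_cyclic_error:
        return False
    if state.energy("rep") > criteria.max_rep_energy_per_res * n:
        return False
    count, _ = hbond_count_and_energy(state.bonds(), params=params)
    return count >= criteria.min_hbonds_for(n)


def _refine_for_record(conf: TorsionConformation, criteria, maps,
                       params: EnergyParams) -> TorsionConformation | None:
    """Polish an SA state into an exactly closed, clash-acceptable record.

    Anchored closure solve first (nearest closed conformation); if that
    introduced clashes, a short bounded minimization of
    0.45*rama + rep + w*E_cyc repairs them; a final free closure solve
    drives the cyclic error to the recording tolerance.  Returns None when
    any stage fails -- the trajectory itself is never touched.
    """
    from scipy.optimize import minimize

    n = conf.n
    try:
        c1 = close_backbone(conf, tolerance=1e-6, anchor_weight=0.05)
    except ClosureError:
        return None
    if rep_energy(forward_kinematics(c1), params) > \
            criteria.max_rep_energy_per_res * n:
        w = 1.0 / max(criteria.polish_tolerance, 1e-9)

        def obj(x):
            c = TorsionConformation.from_vector(x, conf.geometry)
            ra = rama_energy(c, maps)
            if not np.isfinite(ra):
                return 1e6
            return (0.45 * ra + rep_energy(forward_kinematics(c), params)
                    + 1e3 * cyclic_error(c))

        res = minimize(obj, c1.as_vector(), method="Powell",
                       options={"maxfev": 250, "xtol": 1e-3, "ftol": 1e-4})
        c1 = TorsionConformation.from_vector(res.x, conf.geometry)
    try:
        return close_backbone(c1, tolerance=criteria.polish_tolerance,
                              anchor_weight=0.05)
    except ClosureError:
        return None


def _record_candidate(records: dict, state: _LayerEnergies, criteria,
                      scheme: TorsionBinScheme, step: int,
                      params: EnergyParams):
    n = state.conf.n
    # recording-side scoring is criteria verification, not a layer test:
    # keep it out of the instrumentation counters
    state = _LayerEnergies(state.conf, state.maps, params)
    # cheap screens on the raw configuration first
    trigger = (criteria.polish_trigger if criteria.polish_closure
               else criteria.max_cyclic_error)
    if state.energy("cyclic") > trigger:
        return
    if state.energy("rep") > criteria.max_rep_energy_per_res * n:
        return
    count, _ = hbond_count_and_energy(state.bonds(), params=params)
    if count < criteria.min_hbonds_for(n):
        return
    if criteria.polish_closure and state.energy("cyclic") > criteria.polish_tolerance:
        conf = _refine_for_record(state.conf, criteria, state.maps, params)
        if conf is None:
            return
        state = _LayerEnergies(conf, state.maps, params)
    if not _meets(state, criteria, params):
        return
    bd = state.breakdown()
    count, _ = hbond_count_and_energy(state.bonds(), params=params)
    key = canonicalize(bin_string(state.conf, scheme))
    prev = records.get(key)
    if prev is None or bd.total < prev.breakdown.total:
        records[key] = BackboneCandidate(state.conf.copy(), bd, count, key, step)


def run_annealing(initial: TorsionConformation,
                  schedule: AnnealSchedule,
                  criteria: GoodBackboneCriteria | None = None,
                  maps: RamachandranMap | Sequence[RamachandranMap] | None = None,
                  params: EnergyParams = DEFAULT_PARAMS,
                  seed: int = 0,
                  scheme: TorsionBinScheme | None = None,
                  counters: dict | None = None) -> list[BackboneCandidate]:
    """One layered-SA run; returns the recorded good backbone candidates.

    Layers are evaluated in schedule order (cheapest first); a rejection
    short-circuits the remaining layers.  A full run that records nothing
    can simply be repeated by the caller with a fresh seed, up to
    ``schedule.max_repeats`` times (see :func:`sample_backbones`).
    Bit-reproducible for a fixed (initial, schedule, seed).
    """
    criteria = criteria or GoodBackboneCriteria()
    maps = maps if maps is not None else default_glycine_map()
    scheme = scheme or TorsionBinScheme()
    rng = np.random.default_rng(seed)

    current = _LayerEnergies(initial.copy(), maps, params, counters)
    if not np.isfinite(current.energy("rama")):
        raise ValueError("initial torsions fall in a prohibited region")
    records: dict[str, BackboneCandidate] = {}

    for t in range(schedule.steps):
        frac = t / max(schedule.steps - 1, 1)
        prop_conf = propose_move(current.conf, schedule.move_radius(t), maps, rng)
        proposal = _LayerEnergies(prop_conf, maps, params, counters)
        ok = True
        for layer in schedule.layers:
            T = layer.temperature(frac)
            if not layer_accept(current.energy(layer.name),
                                proposal.energy(layer.name),
                                layer.threshold, T, rng):
                ok = False
                break
        if ok:
            current = proposal
            _record_candidate(records, current, criteria, scheme, t, params)
    return list(records.values())


def sample_backbones(initials, schedule: AnnealSchedule,
                     criteria: GoodBackboneCriteria | None = None,
                     maps=None, params: EnergyParams = DEFAULT_PARAMS,
                     seed: int = 0, scheme: TorsionBinScheme | None = None,
                     stop_after: int | None = None) -> list[BackboneCandidate]:
    """Run layered SA from each initial configuration, with re-runs.

    An initial configuration that records no candidate is re-annealed with a
    derived seed, up to ``schedule.max_repeats`` total attempts.  Stops early
    once ``stop_after`` candidates have been collected (if given).
    """
    criteria = criteria or GoodBackboneCriteria()
    out: list[BackboneCandidate] = []
    ss = np.random.SeedSequence(seed)
    for idx, init in enumerate(initials):
        for rep in range(schedule.max_repeats):
            run_seed = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(idx, rep)).generate_state(1)[0]
            cands = run_annealing(init, schedule, criteria, maps, params,
                                  seed=int(run_seed), scheme=scheme)
            if cands:
                out.extend(cands)
                break
        if stop_after is not None and len(out) >= stop_after:
            break
    return out


def low_rmsd_annealing(sequence_conf: TorsionConformation,
                       reference: BackboneStructure,
                       schedule: AnnealSchedule,
                       criteria: GoodBackboneCriteria | None = None,
                       maps=None, params: EnergyParams = DEFAULT_PARAMS,
                       seed: int = 0, scheme: TorsionBinScheme | None = None,
                       counters: dict | None = None) -> list[BackboneCandidate]:
    """Reference-biased SA with exactly two layers: cyclic error, then RMSD.

    Identical loop to :func:`run_annealing`, but the only acceptance tests
    are the cyclic-error layer and a Metropolis test on backbone-heavy-atom
    RMSD to ``reference``; no energy layers run.  Recorded candidates still
    satisfy the closure criterion; their H-bond requirement is waived (the
    purpose is low-RMSD coverage of the landscape, not H-bond quality).
    """
    if reference.n != sequence_conf.n:
        raise ValueError("reference size mismatch")
    # recording here only demands closure: this arm exists for low-RMSD
    # landscape coverage, and energies are handled by the relax stage later
    criteria = criteria or GoodBackboneCriteria(
        min_strong_hbonds=0, max_rep_energy_per_res=float("inf"))
    maps = maps if maps is not None else default_glycine_map()
    scheme = scheme or TorsionBinScheme()
    rng = np.random.default_rng(seed)

    cyc_layer = LayerSpec("cyclic", 0.1, 1.0, 0.01)
    rmsd_layer = LayerSpec("hbond", 0.5, 2.0, 0.05)  # reused cooling shape

    def rmsd_of(state: _LayerEnergies) -> float:
        if counters is not None:
            counters["rmsd"] = counters.get("rmsd", 0) + 1
        return kabsch_rmsd(state.struct, reference)

    current = _LayerEnergies(sequence_conf.copy(), maps, params, counters)
    current_rmsd = rmsd_of(current)
    records: dict[str, BackboneCandidate] = {}

    def record_first_seen(state, step):
        # coverage sampling: keep the first representative of each bin
        # class (for the starting class that is the reference itself)
        fresh: dict[str, BackboneCandidate] = {}
        _record_candidate(fresh, state, criteria, scheme, step, params)
        for key, cand in fresh.items():
            records.setdefault(key, cand)

    record_first_seen(current, -1)
    for t in range(schedule.steps):
        frac = t / max(schedule.steps - 1, 1)
        prop_conf = propose_move(current.conf, schedule.move_radius(t), maps, rng)
        proposal = _LayerEnergies(prop_conf, maps, params, counters)
        if not layer_accept(current.energy("cyclic"), proposal.energy("cyclic"),
                            cyc_layer.threshold, cyc_layer.temperature(frac),
                            rng):
            continue
        prop_rmsd = rmsd_of(proposal)
        if not layer_accept(current_rmsd, prop_rmsd, rmsd_layer.threshold,
                            rmsd_layer.temperature(frac), rng):
            continue
        current, current_rmsd = proposal, prop_rmsd
        record_first_seen(current, t)
    return list(records.values())
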