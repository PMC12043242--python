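"""Backbone energy terms for poly-glycine macrocycle sampling.

The sampler is energy-model-agnostic; what it needs from this module is a
set of cheap per-term backbone scores that can be evaluated layer by layer:
Ramachandran first (torsions only), then repulsion (bare N/CA/C' is enough),
then H-bonds (needs O and amide H), then the miscellaneous pair terms
(attraction, electrostatics, solvation).  The weighted total used for
clustering and selection is

    E_total = 0.45 * E_rama + E_rep + E_hbond + E_other,
    E_other = E_attractive + E_elec + E_solv.

Pair terms act only on heavy-atom pairs separated by at least four covalent
bonds on the *cyclic* bond graph (C' of residue n is bonded to N of residue
1).  The functional forms here are simplified, documented surrogates for a
full all-atom force field: a 12-6 Lennard-Jones split at its minimum into a
repulsive-only and an attractive-only branch, Coulomb electrostatics with a
distance-dependent dielectric, a Gaussian-overlap desolvation penalty for
polar atoms, and a distance-and-angle-ramped H-bond well.  All constants
live in :class:`EnergyParams` and are exposed through the YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import networkx as nx
import numpy as np

from .geometry import BackboneStructure, TorsionConformation, cyclic_error
from .ramachandran import RamachandranMap, default_glycine_map

__all__ = [
    "EnergyParams",
    "EnergyBreakdown",
    "HBond",
    "pair_list",
    "rama_energy",
    "rep_energy",
    "misc_energy",
    "score_terms",
    "detect_hbonds",
    "hbond_count_and_energy",
    "hbond_energy",
]

HEAVY_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class EnergyParams:
    """All surrogate force-field constants in one configurable block."""

    # van der Waals radii (Angstrom) and LJ well depth (kcal/mol)
    radius: tuple = (("N", 1.55), ("CA", 1.70), ("C", 1.70), ("O", 1.52))
    lj_eps: float = 0.15
    pair_cutoff: float = 6.0
    # partial charges (e)
    charge: tuple = (("N", -0.47), ("CA", 0.16), ("C", 0.51), ("O", -0.51))
    dielectric_slope: float = 10.0   # eps_r = slope * d
    coulomb_k: float = 332.0637      # kcal A / mol / e^2
    # Gaussian-overlap desolvation for polar atoms (N, O)
    solv_scale: float = 0.6          # kcal/mol per buried polar contact
    solv_width: float = 1.0          # Angstrom
    # H-bond geometry and depth; full depth at plateau distance/angle
    hb_depth: float = 1.5            # kcal/mol
    hb_dist_max: float = 2.5         # H...O Angstrom
    hb_dist_plateau: float = 2.2
    hb_angle_min: float = 120.0      # N-H...O degrees
    hb_angle_plateau: float = 150.0
    strong_hb_cutoff: float = -0.5   # kcal/mol

    def radius_of(self, name: str) -> float:
        return dict(self.radius)[name]

    def charge_of(self, name: str) -> float:
        return dict(self.charge)[name]


DEFAULT_PARAMS = EnergyParams()

PROHIBITED = float("inf")


@dataclass
class EnergyBreakdown:
    """Per-term backbone energies (kcal/mol) plus the cyclic error."""

    rama: float = 0.0
    rep: float = 0.0
    attractive: float = 0.0
    elec: float = 0.0
    solv: float = 0.0
    hbond: float = 0.0
    cyclic_err: float = 0.0
    hbond_count: int = 0

    @property
    def other(self) -> float:
        return self.attractive + self.elec + self.solv

    @property
    def total(self) -> float:
        """E_total = 0.45*E_rama + E_rep + E_hbond + E_other."""
        return 0.45 * self.rama + self.rep + self.hbond + self.other

    @property
    def prohibited(self) -> bool:
        return not np.isfinite(self.rama)


@dataclass(frozen=True)
class HBond:
    """A backbone amide-H to carbonyl-O hydrogen bond."""

    donor_residue: int     # 0-based residue of the amide N-H
    acceptor_residue: int  # 0-based residue of the C=O
    distance: float        # H...O, Angstrom
    angle: float           # N-H...O, degrees
    energy: float          # kcal/mol, <= 0


# ---------------------------------------------------------------------------
# bond graph and pair list


@lru_cache(maxsize=64)
def _pair_indices(n: int, include_O: bool) -> tuple:
    """Heavy-atom pairs >= 4 covalent bonds apart on the cyclic bond graph.

    Atoms are indexed residue-major in the order N, CA, C(, O); returns
    (idx_a, idx_b, name_a, name_b) arrays.
    """
    names = HEAVY_ATOMS if include_O else HEAVY_ATOMS[:3]
    per = len(names)

    g = nx.Graph()
    for i in range(n):
        g.add_edge((i, "N"), (i, "CA"))
        g.add_edge((i, "CA"), (i, "C"))
        if include_O:
            g.add_edge((i, "C"), (i, "O"))
        g.add_edge((i, "C"), ((i + 1) % n, "N"))  # cyclic peptide bond
    dist = dict(nx.all_pairs_shortest_path_length(g))

    atoms = [(i, nm) for i in range(n) for nm in names]
    ia, ib, na, nb = [], [], [], []
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            if dist[atoms[a]][atoms[b]] >= 4:
                ia.append(a)
                ib.append(b)
                na.append(atoms[a][1])
                nb.append(atoms[b][1])
    return (np.array(ia, dtype=int), np.array(ib, dtype=int),
            tuple(na), tuple(nb), per)


def pair_list(struct: BackboneStructure) -> list:
    """All and only heavy-atom pairs with cyclic bond-graph distance >= 4.

    Returned as ``((res_a, name_a), (res_b, name_b))`` tuples, 0-based.
    """
    include_O = struct.O is not None
    ia, ib, na, nb, per = _pair_indices(struct.n, include_O)
    names = HEAVY_ATOMS if include_O else HEAVY_ATOMS[:3]
    out = []
    for a, b in zip(ia, ib):
        out.append(((a // per, names[a % per]), (b // per, names[b % per])))
    return out


def _stacked_coords(struct: BackboneStructure, include_O: bool) -> np.ndarray:
    arrs = [struct.N, struct.CA, struct.C] + ([struct.O] if include_O else [])
    return np.stack(arrs, axis=1).reshape(-1, 3)


@lru_cache(maxsize=64)
def _pair_params(n: int, include_O: bool, params: EnergyParams):
    ia, ib, na, nb, per = _pair_indices(n, include_O)
    rmin = np.array([params.radius_of(a) + params.radius_of(b)
                     for a, b in zip(na, nb)])
    qq = np.array([params.charge_of(a) * params.charge_of(b)
                   for a, b in zip(na, nb)])
    polar = np.array([(a in ("N", "O")) and (b in ("N", "O"))
                      for a, b in zip(na, nb)])
    return ia, ib, rmin, qq, polar


def _pair_distances(struct, include_O, params):
    ia, ib, rmin, qq, polar = _pair_params(struct.n, include_O, params)
    xyz = _stacked_coords(struct, include_O)
    d = np.linalg.norm(xyz[ia] - xyz[ib], axis=1)
    return d, rmin, qq, polar


def rep_energy(struct: BackboneStructure,
               params: EnergyParams = DEFAULT_PARAMS) -> float:
    """Repulsive-only Lennard-Jones branch: positive, zero beyond contact."""
    include_O = struct.O is not None
    d, rmin, _, _ = _pair_distances(struct, include_O, params)
    d = np.maximum(d, 0.5)  # cap the singularity for pathological overlaps
    x = rmin / d
    lj = params.lj_eps * (x ** 12 - 2.0 * x ** 6)
    return float(np.sum(np.where(d < rmin, lj + params.lj_eps, 0.0)))


def misc_energy(struct: BackboneStructure,
                params: EnergyParams = DEFAULT_PARAMS) -> tuple[float, float, float]:
    """(attractive, electrostatic, solvation) pair terms within the cutoff."""
    include_O = struct.O is not None
    d, rmin, qq, polar = _pair_distances(struct, include_O, params)
    within = d < params.pair_cutoff
    d = np.maximum(d, 0.5)
    x = rmin / d
    lj = params.lj_eps * (x ** 12 - 2.0 * x ** 6)
    attr = np.where(within, np.where(d < rmin, -params.lj_eps, lj), 0.0)
    elec = np.where(within,
                    params.coulomb_k * qq / (params.dielectric_slope * d * d),
                    0.0)
    solv = np.where(within & polar,
                    params.solv_scale
                    * np.exp(-((d - rmin) / params.solv_width) ** 2),
                    0.0)
    return float(attr.sum()), float(elec.sum()), float(solv.sum())


# ---------------------------------------------------------------------------
# Ramachandran term


def rama_energy(conf: TorsionConformation,
                maps: RamachandranMap | Sequence[RamachandranMap] | None = None
                ) -> float:
    """Sum of per-residue map lookups; +inf (prohibited) outside the maps."""
    if maps is None:
        maps = default_glycine_map()
    if isinstance(maps, RamachandranMap):
        e = maps.energy(conf.phi, conf.psi)
        return float(np.sum(e)) if np.all(np.isfinite(e)) else PROHIBITED
    total = 0.0
    for i in range(conf.n):
        e = maps[i].energy(conf.phi[i], conf.psi[i])
        if not np.isfinite(e):
            return PROHIBITED
        total += e
    return total


# ---------------------------------------------------------------------------
# H-bonds


def detect_hbonds(struct: BackboneStructure,
                  params: EnergyParams = DEFAULT_PARAMS) -> list[HBond]:
    """Geometric backbone H-bond detection.

    Donor: amide N-H of residue i; acceptor: carbonyl O of residue j with
    j != i and j != i-1 (those atoms are covalent neighbours of the donor
    group).  Criteria: H...O below ``hb_dist_max`` and N-H...O above
    ``hb_angle_min``.  Energy ramps linearly to ``-hb_depth`` as the
    distance reaches the plateau and the angle opens to 180 degrees.
    """
    if struct.O is None or struct.H is None:
        raise ValueError("H-bond detection needs O and H atoms")
    n = struct.n
    H = struct.H
    O = struct.O
    N = struct.N
    have_h = ~np.isnan(H[:, 0])

    diff = H[:, None, :] - O[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    # N-H...O angle at H: between the H->N and H->O directions
    hn = N - H
    hn /= np.linalg.norm(hn, axis=1, keepdims=True)
    ho = -diff / np.maximum(dist[:, :, None], 1e-9)
    ang = np.degrees(np.arccos(np.clip(np.einsum("ik,ijk->ij", hn, ho),
                                       -1.0, 1.0)))

    bonds = []
    for i in range(n):
        if not have_h[i]:
            continue
        for j in range(n):
            if j == i or j == (i - 1) % n:
                continue
            d = dist[i, j]
            a = ang[i, j]
            if d < params.hb_dist_max and a > params.hb_angle_min:
                fd = np.clip((params.hb_dist_max - d)
                             / (params.hb_dist_max - params.hb_dist_plateau),
                             0.0, 1.0)
                fa = np.clip((a - params.hb_angle_min)
                             / (params.hb_angle_plateau - params.hb_angle_min),
                             0.0, 1.0)
                bonds.append(HBond(i, j, float(d), float(a),
                                   float(-params.hb_depth * fd * fa)))
    return bonds


def hbond_count_and_energy(bonds: Sequence[HBond],
                           strong_cutoff: float | None = None,
                           params: EnergyParams = DEFAULT_PARAMS
                           ) -> tuple[int, float]:
    """(number of strong H-bonds, total H-bond energy in kcal/mol)."""
    cut = params.strong_hb_cutoff if strong_cutoff is None else strong_cutoff
    energy = float(sum(b.energy for b in bonds))
    count = sum(1 for b in bonds if b.energy <= cut)
    return count, energy


def hbond_energy(struct: BackboneStructure,
                 params: EnergyParams = DEFAULT_PARAMS) -> float:
    return hbond_count_and_energy(detect_hbonds(struct, params), params=params)[1]


# ---------------------------------------------------------------------------
# full breakdown


def score_terms(struct: BackboneStructure,
                maps: RamachandranMap | Sequence[RamachandranMap] | None = None,
                params: EnergyParams = DEFAULT_PARAMS) -> EnergyBreakdown:
    """Full per-term backbone energy breakdown for a built structure.

    The Ramachandran term uses the structure's provenance torsions when
    available, otherwise torsions measured from the coordinates.  A residue
    outside its map marks the whole breakdown prohibited (rama = +inf);
    the sampler uses that as a rejection sentinel.
    """
    from .geometry import measure_torsions

    conf = struct.provenance or measure_torsions(struct)
    rama = rama_energy(conf, maps)
    rep = rep_energy(struct, params)
    attr, elec, solv = misc_energy(struct, params)
    bonds = detect_hbonds(struct, params)
    count, hb = hbond_count_and_energy(bonds, params=params)
    return EnergyBreakdown(rama=rama, rep=rep, attractive=attr, elec=elec,
                           solv=solv, hbond=hb,
                           cyclic_err=cyclic_error(conf), hbond_count=count)
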