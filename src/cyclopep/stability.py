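"""Stability analytics: RMSD machinery, PNear, filtering, reshaping, FES.

An *energy landscape* is a set of alternative conformations for one
sequence, each carrying an energy and a backbone-heavy-atom RMSD to a native
(designed) structure.  The folding-funnel statistic

    PNear = sum_i exp(-RMSD_i^2 / lambda^2) exp(-E_i / kT)
            / sum_j exp(-E_j / kT)

measures the fraction of Boltzmann weight near the native state; kT defaults
to 0.62 kcal/mol (37 C) and lambda is 0.5 A for 7-residue rings, 1.5 A for
15, and 2.0 A for 20-24.  PNear > 0.9 is the conventional stability bar.

RMSDs use Kabsch superposition of the N, C-alpha, C', O atoms; because the
ring has no distinguished first residue, the cyclic minimum over all n
residue relabelings is available (and is the default for backbone pools).

Also here: the small-macrocycle Ramachandran-stability filter (threading a
chirality-coded sequence onto a backbone pool at all n offsets), landscape
reshaping (re-anchor the native at the sampled energy minimum), backbone
compactness and H-bond chord-crossing analytics, and the free-energy-surface
histogram F = -RT ln P(RMSD, Rg) on a 50 x 50 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.special import logsumexp

from .geometry import BackboneStructure
from .ramachandran import map_for_residue

__all__ = [
    "EnergyLandscape",
    "FESGrid",
    "KT_BODY",
    "lambda_for_size",
    "kabsch_rmsd",
    "cyclic_min_rmsd",
    "pnear",
    "rama_stability_filter",
    "reshape_landscape",
    "backbone_radius",
    "radius_of_gyration",
    "hbond_intersections",
    "free_energy_surface",
]

#: kT at 37 C in kcal/mol, the PNear Boltzmann factor
KT_BODY = 0.62

#: gas constant, kcal/mol/K (for the FES)
R_GAS = 0.0019872041


def lambda_for_size(n: int) -> float:
    """Funnel width lambda (Angstrom) by macrocycle size class."""
    if n <= 9:
        return 0.5
    if n <= 17:
        return 1.5
    return 2.0


# ---------------------------------------------------------------------------
# RMSD


def _paired_coords(a: BackboneStructure, b: BackboneStructure):
    if a.n != b.n:
        raise ValueError("structures differ in residue count")
    return a.heavy_coords(), b.heavy_coords()


def _kabsch_from_arrays(P: np.ndarray, Q: np.ndarray) -> float:
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    _, rssd = Rotation.align_vectors(P, Q)
    return float(rssd / np.sqrt(len(P)))


def kabsch_rmsd(a: BackboneStructure, b: BackboneStructure) -> float:
    """Minimal RMSD over proper rigid superposition of N/CA/C'/O atoms."""
    P, Q = _paired_coords(a, b)
    return _kabsch_from_arrays(P, Q)


def cyclic_min_rmsd(a: BackboneStructure, b: BackboneStructure,
                    shortcut: float | None = None) -> tuple[float, int]:
    """Minimum Kabsch RMSD over the n cyclic relabelings of ``b``.

    Returns (rmsd, best offset).  If ``shortcut`` is given and the
    fixed-labeling RMSD (offset 0) is already below it, that value is
    returned immediately -- useful inside clustering where only
    "is it within the cutoff" matters.
    """
    P, Q = _paired_coords(a, b)
    n = a.n
    best = _kabsch_from_arrays(P, Q)
    best_k = 0
    if shortcut is not None and best < shortcut:
        return best, 0
    Qr = Q.reshape(n, 4, 3)
    for k in range(1, n):
        r = _kabsch_from_arrays(P, np.roll(Qr, -k, axis=0).reshape(-1, 3))
        if r < best:
            best, best_k = r, k
    return best, best_k


# ---------------------------------------------------------------------------
# landscapes and PNear


@dataclass
class EnergyLandscape:
    """Records of (id, energy, RMSD-to-native) plus the PNear parameters."""

    ids: list
    energies: np.ndarray
    rmsds: np.ndarray
    native: BackboneStructure | None = None
    lambda_: float = 0.5
    kT: float = KT_BODY
    structures: dict = field(default_factory=dict)  # id -> BackboneStructure
    bin_strings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.rmsds = np.asarray(self.rmsds, dtype=float)
        if len(self.ids) != len(self.energies) or len(self.ids) != len(self.rmsds):
            raise ValueError("ids, energies, rmsds must have equal length")
        if np.any(self.rmsds < 0):
            raise ValueError("RMSDs must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "energy": self.energies,
                           "rmsd": self.rmsds})
        if self.bin_strings:
            df["bin_string"] = [self.bin_strings.get(i, "") for i in self.ids]
        return df

    def save(self, path):
        with open(path, "w") as fh:
            fh.write("# id\tenergy_kcal_mol\trmsd_A\tbin_string\n")
            for i, e, r in zip(self.ids, self.energies, self.rmsds):
                fh.write(f"{i}\t{e:.6f}\t{r:.6f}\t"
                         f"{self.bin_strings.get(i, '')}\n")

    @classmethod
    def load(cls, path, lambda_: float = 0.5, kT: float = KT_BODY
             ) -> "EnergyLandscape":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["id", "energy", "rmsd", "bin_string"])
        ls = cls(list(df["id"]), df["energy"].to_numpy(),
                 df["rmsd"].to_numpy(), lambda_=lambda_, kT=kT)
        if df["bin_string"].notna().any():
            ls.bin_strings = {i: str(b) for i, b in
                              zip(df["id"], df["bin_string"]) if pd.notna(b)}
        return ls


def pnear(landscape: EnergyLandscape | None = None, *,
          energies=None, rmsds=None, lambda_: float | None = None,
          kT: float | None = None) -> float:
    """Boltzmann folding-funnel statistic, computed in log space.

    Accepts either an :class:`EnergyLandscape` or raw arrays.  Invariant to
    a constant shift of all energies; always in (0, 1].
    """
    if landscape is not None:
        energies = landscape.energies
        rmsds = landscape.rmsds
        lambda_ = landscape.lambda_ if lambda_ is None else lambda_
        kT = landscape.kT if kT is None else kT
    energies = np.asarray(energies, dtype=float)
    rmsds = np.asarray(rmsds, dtype=float)
    if energies.size == 0:
        raise ValueError("empty landscape")
    if lambda_ is None or lambda_ <= 0 or kT is None or kT <= 0:
        raise ValueError("lambda and kT must be positive")
    logw = -energies / kT
    log_num = logsumexp(logw - rmsds ** 2 / lambda_ ** 2)
    log_den = logsumexp(logw)
    return float(np.exp(log_num - log_den))


def reshape_landscape(landscape: EnergyLandscape) -> EnergyLandscape:
    """Re-anchor the native at the lowest-energy sampled structure.

    The new native is the argmin-energy record; every RMSD is recomputed
    against it with cyclic-minimum Kabsch.  Energies are untouched.
    Requires the landscape to carry its structures.
    """
    if not landscape.structures:
        raise ValueError("landscape carries no structures; cannot reshape")
    imin = int(np.argmin(landscape.energies))
    new_native = landscape.structures[landscape.ids[imin]]
    rmsds = np.array([
        cyclic_min_rmsd(new_native, landscape.structures[i])[0]
        for i in landscape.ids])
    return EnergyLandscape(list(landscape.ids), landscape.energies.copy(),
                           rmsds, native=new_native, lambda_=landscape.lambda_,
                           kT=landscape.kT, structures=dict(landscape.structures),
                           bin_strings=dict(landscape.bin_strings))


# ---------------------------------------------------------------------------
# Ramachandran-stability filtering (small macrocycles)


def rama_stability_filter(sequence: str, pool: Iterable,
                          count_hook: list | None = None) -> list:
    """Thread a chirality-coded sequence onto a backbone pool.

    For each candidate and each of its n cyclic offsets, the pair
    (candidate, offset) is kept iff every residue's (phi, psi) lies in the
    allowed Ramachandran region of the amino acid threaded at that position
    (uppercase = L, lowercase = D; glycine accepts everything its symmetric
    map allows).  Offset k places sequence position p on backbone residue
    (p + k) mod n.  The survivors are the landscape-ready compatible set.
    """
    maps = [map_for_residue(aa) for aa in sequence]
    n = len(sequence)
    kept = []
    for cand in pool:
        conf = cand.conformation if hasattr(cand, "conformation") else cand
        if conf.n != n:
            raise ValueError("sequence length does not match pool member size")
        for k in range(n):
            if count_hook is not None:
                count_hook.append((id(cand), k))
            ok = True
            for p in range(n):
                r = (p + k) % n
                if not maps[p].is_allowed(conf.phi[r], conf.psi[r]):
                    ok = False
                    break
            if ok:
                kept.append((cand, k))
    return kept


# ---------------------------------------------------------------------------
# compactness and H-bond topology


def backbone_radius(struct: BackboneStructure) -> float:
    """RMS distance of the backbone N/CA/C'/O atoms from their centroid."""
    xyz = struct.heavy_coords() if struct.O is not None else np.concatenate(
        [struct.N, struct.CA, struct.C])
    xyz = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(xyz ** 2, axis=1))))


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None
                       ) -> float:
    """Radius of gyration; unweighted by default, mass-weighted if given."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (m, 3) array")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = np.average(coords, axis=0, weights=masses)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1),
                                    weights=masses)))


def hbond_intersections(bonds: Sequence, n: int) -> int:
    """Count crossing pairs among H-bond chords drawn inside the ring.

    Bonds are (donor, acceptor) residue pairs (or HBond objects) with
    indices in 0..n-1.  Chords (i, j) and (k, l) cross iff exactly one of
    k, l lies strictly between i and j in cyclic order; chords sharing an
    endpoint never cross.
    """
    chords = []
    for b in bonds:
        i, j = (b.donor_residue, b.acceptor_residue) if hasattr(
            b, "donor_residue") else tuple(b)
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError("residue index out of range")
        chords.append((i, j))

    def between(x, lo, hi):
        # strictly between lo and hi walking forward around the ring
        span = (hi - lo) % n
        return 0 < (x - lo) % n < span

    count = 0
    for a in range(len(chords)):
        i, j = chords[a]
        for b_ in range(a + 1, len(chords)):
            k, l = chords[b_]
            if len({i, j, k, l}) < 4:
                continue
            if between(k, i, j) != between(l, i, j):
                count += 1
    return count


# ---------------------------------------------------------------------------
# free energy surface


@dataclass
class FESGrid:
    """F = -RT ln P on a 50 x 50 (RMSD, Rg) histogram; empty cells masked."""

    rmsd_edges: np.ndarray
    rg_edges: np.ndarray
    free_energy: np.ma.MaskedArray
    temperature: float
    probability: np.ndarray

    @property
    def minimum_cell(self) -> tuple[int, int]:
        idx = np.unravel_index(np.ma.argmin(self.free_energy),
                               self.free_energy.shape)
        return int(idx[0]), int(idx[1])

    def save(self, path):
        with open(path, "w") as fh:
            fh.write("# free energy surface, kcal/mol; INF = unoccupied\n")
            fh.write("# rmsd_edges " + " ".join(f"{v:.6g}" for v in
                                                self.rmsd_edges) + "\n")
            fh.write("# rg_edges " + " ".join(f"{v:.6g}" for v in
                                              self.rg_edges) + "\n")
            fh.write(f"# temperature_K {self.temperature:g}\n")
            for row in self.free_energy.filled(np.inf):
                fh.write(" ".join("INF" if not np.isfinite(v) else f"{v:.6g}"
                                  for v in row) + "\n")


def free_energy_surface(rmsd_samples, rg_samples, temperature: float = 300.0,
                        bins: int = 50) -> FESGrid:
    """2-D free energy surface over (RMSD, Rg) samples.

    P is the per-cell probability of the 50 x 50 histogram spanning the
    sample ranges; F = -RT ln P on occupied cells, masked elsewhere.  The
    global F minimum therefore sits in the modal cell, and
    sum over occupied cells of exp(-F/RT) equals 1.

    Samples are taken in whatever length unit they arrive in (this package
    uses Angstrom); changing the unit rescales the bin edges and shifts F by
    a constant only.
    """
    rmsd = np.asarray(rmsd_samples, dtype=float)
    rg = np.asarray(rg_samples, dtype=float)
    if rmsd.size == 0 or rmsd.shape != rg.shape:
        raise ValueError("need equal-length, non-empty sample vectors")
    H, xe, ye = np.histogram2d(rmsd, rg, bins=bins)
    P = H / H.sum()
    with np.errstate(divide="ignore"):
        F = -R_GAS * temperature * np.log(P)
    masked = np.ma.masked_array(F, mask=(P == 0))
    return FESGrid(xe, ye, masked, temperature, P)
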