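"""Ramachandran maps, the six-bin partition, and initial-configuration math.

Backbone sampling runs on a permissive, symmetrized glycine Ramachandran
map: a (phi, psi) energy grid whose allowed region covers the basins
reachable by both L- and D-amino acids (glycine, being achiral, has a map
symmetric under (phi, psi) -> (-phi, -psi)).  Residue-specific maps obey the
mirror rule: a D-amino acid's map is the point reflection of its L
counterpart's.

The packaged default grids (10-degree resolution, plain text, swappable by
the user) are a documented analytic approximation: each map is built from a
small set of Gaussian basins on the torus, normalized so the deepest basin
sits at zero, flattened by a global scale, and cut off to define the allowed
region.  The glycine basins are placed at the six torsion-bin centers, which
makes the map exactly symmetric by construction.

The six-bin partition assigns every allowed grid cell to its nearest bin
center under the toroidal metric.  Bin strings over the six labels, compared
modulo cyclic rotation, are the clustering key downstream; the number of
rotation-unique assignments of bin centers to an n-ring is the necklace
count (1/n) sum_i 6^gcd(i, n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import IdealGeometry, TorsionConformation, wrap_degrees

__all__ = [
    "RamachandranMap",
    "TorsionBinScheme",
    "DEFAULT_BIN_CENTERS",
    "default_glycine_map",
    "map_for_residue",
    "assign_bin",
    "count_unique_initial_configurations",
    "enumerate_initial_configurations",
]

GRID_STEP = 10.0
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Bin centers (phi, psi) in degrees; the set is symmetric under point
#: reflection, with mirror partners 1<->2, 3<->4, 5<->6.
DEFAULT_BIN_CENTERS = (
    (-61.0, -41.0),   # 1: right-handed alpha (L)
    (61.0, 41.0),     # 2: left-handed alpha (D mirror)
    (-135.0, 135.0),  # 3: beta
    (135.0, -135.0),  # 4: mirrored beta
    (-61.0, 141.0),   # 5: polyproline-II-like
    (61.0, -141.0),   # 6: mirrored PPII
)


def toroidal_dist2(phi1, psi1, phi2, psi2):
    """Squared distance on the (phi, psi) torus, degrees^2."""
    dphi = wrap_degrees(np.asarray(phi1) - phi2)
    dpsi = wrap_degrees(np.asarray(psi1) - psi2)
    return dphi ** 2 + dpsi ** 2


@dataclass
class RamachandranMap:
    """Energy grid over (phi, psi) with an allowed-region mask.

    ``grid[i, j]`` is the energy at node (phi_nodes[i], psi_nodes[j]);
    disallowed nodes hold +inf.  Queries interpolate bilinearly with
    toroidal wraparound; a query touching any disallowed corner node is
    itself disallowed.
    """

    grid: np.ndarray
    step: float = GRID_STEP
    symmetrized: bool = False
    name: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be square")
        m = int(round(360.0 / self.step))
        if self.grid.shape[0] != m:
            raise ValueError("grid size inconsistent with step")

    @property
    def nodes(self) -> np.ndarray:
        return -180.0 + self.step * np.arange(self.grid.shape[0])

    def _node_index(self, angle):
        return np.floor((np.asarray(angle) + 180.0) / self.step).astype(int)

    def energy(self, phi, psi):
        """Bilinear toroidal interpolation; +inf on disallowed queries."""
        phi = wrap_degrees(phi)
        psi = wrap_degrees(psi)
        m = self.grid.shape[0]
        i0 = self._node_index(phi) % m
        j0 = self._node_index(psi) % m
        i1 = (i0 + 1) % m
        j1 = (j0 + 1) % m
        fi = (np.asarray(phi) + 180.0) / self.step - np.floor(
            (np.asarray(phi) + 180.0) / self.step)
        fj = (np.asarray(psi) + 180.0) / self.step - np.floor(
            (np.asarray(psi) + 180.0) / self.step)
        g = self.grid
        with np.errstate(invalid="ignore"):
            val = ((1 - fi) * (1 - fj) * g[i0, j0] + fi * (1 - fj) * g[i1, j0]
                   + (1 - fi) * fj * g[i0, j1] + fi * fj * g[i1, j1])
        bad = ~(np.isfinite(g[i0, j0]) & np.isfinite(g[i1, j0])
                & np.isfinite(g[i0, j1]) & np.isfinite(g[i1, j1]))
        val = np.where(bad, np.inf, val)
        return val if val.ndim else float(val)

    def is_allowed(self, phi, psi):
        e = self.energy(phi, psi)
        return np.isfinite(e) if np.ndim(e) else math.isfinite(e)

    @property
    def allowed_mask(self) -> np.ndarray:
        return np.isfinite(self.grid)

    @property
    def allowed_fraction(self) -> float:
        return float(self.allowed_mask.mean())

    def mirrored(self, name: str = "") -> "RamachandranMap":
        """Point reflection (phi, psi) -> (-phi, -psi) on the grid."""
        m = self.grid.shape[0]
        idx = (-np.arange(m)) % m
        return RamachandranMap(self.grid[np.ix_(idx, idx)], self.step,
                               self.symmetrized, name or f"mirror({self.name})")

    # -- plain-text round trip ------------------------------------------------

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(f"# phi_min phi_max step\n# -180 180 {self.step:g}\n")
            for row in self.grid.T:  # row-major psi x phi
                fh.write(" ".join("INF" if not math.isfinite(v) else f"{v:.6g}"
                                  for v in row) + "\n")

    @classmethod
    def load(cls, path, symmetrized: bool = False, name: str = "") -> "RamachandranMap":
        rows = []
        step = GRID_STEP
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split()
                    if len(parts) == 3 and parts[0].lstrip("-").isdigit():
                        step = float(parts[2])
                    continue
                rows.append([np.inf if t.upper() == "INF" else float(t)
                             for t in line.split()])
        grid = np.array(rows).T  # rows were psi-major
        return cls(grid, step=step, symmetrized=symmetrized, name=name)


# ---------------------------------------------------------------------------
# packaged default maps


def build_map_from_basins(basins, cutoff: float = 2.5, flatten: float = 0.25,
                          margin_cells: int = 2, margin_penalty: float = 1.0,
                          step: float = GRID_STEP, symmetrized: bool = False,
                          name: str = "") -> RamachandranMap:
    """Analytic basin construction for the packaged default grids.

    ``basins`` is a sequence of (phi0, psi0, sigma_deg) triples.  Raw energy
    is -log of the basin mixture, shifted to zero at its minimum, scaled by
    ``flatten`` (a permissive, flattened surface), and disallowed where the
    raw energy exceeds ``cutoff`` -- except for a soft margin of
    ``margin_cells`` grid cells around the allowed core, which stays finite
    at an extra ``margin_penalty`` per cell.  The margin tolerates the small
    torsion drift that closure refinement and relaxation introduce without
    opening the genuinely forbidden regions.
    """
    m = int(round(360.0 / step))
    nodes = -180.0 + step * np.arange(m)
    P, S = np.meshgrid(nodes, nodes, indexing="ij")
    dens = np.zeros_like(P)
    for (p0, s0, sig) in basins:
        d2 = toroidal_dist2(P, S, p0, s0)
        dens += np.exp(-d2 / (2.0 * sig ** 2))
    e = -np.log(dens + 1e-300)
    e -= e.min()
    core = e <= cutoff
    grid = np.where(core, flatten * e, np.inf)
    ring = core.copy()
    for k in range(1, margin_cells + 1):
        grown = ring.copy()
        for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
            grown |= np.roll(ring, sh, axis=ax)
        new = grown & ~ring
        grid[new] = flatten * cutoff + k * margin_penalty
        ring = grown
    return RamachandranMap(grid, step=step, symmetrized=symmetrized, name=name)


_GLY_BASINS = [(p, s, 32.0) for (p, s) in DEFAULT_BIN_CENTERS]
_GENERIC_L_BASINS = [(-63.0, -41.0, 22.0), (-135.0, 135.0, 28.0),
                     (-65.0, 145.0, 22.0), (61.0, 41.0, 14.0)]
_PRO_BASINS = [(-63.0, -35.0, 14.0), (-63.0, 145.0, 14.0)]


def _data_path(fname: str) -> Path:
    return Path(resources.files("cyclopep").joinpath("data", fname))


def build_default_grids(outdir=None):
    """(Re)generate the packaged plain-text grid files."""
    outdir = Path(outdir) if outdir else _data_path("").parent / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    build_map_from_basins(_GLY_BASINS, cutoff=2.6, symmetrized=True,
                          name="GLY").save(outdir / "rama_gly.dat")
    build_map_from_basins(_GENERIC_L_BASINS, cutoff=2.2,
                          name="generic-L").save(outdir / "rama_generic.dat")
    build_map_from_basins(_PRO_BASINS, cutoff=2.0,
                          name="PRO-L").save(outdir / "rama_pro.dat")


_MAP_CACHE: dict = {}


def _load_packaged(fname: str, symmetrized: bool, name: str) -> RamachandranMap:
    key = fname
    if key not in _MAP_CACHE:
        _MAP_CACHE[key] = RamachandranMap.load(_data_path(fname),
                                               symmetrized=symmetrized, name=name)
    return _MAP_CACHE[key]


def default_glycine_map() -> RamachandranMap:
    """The permissive, symmetrized glycine map used for backbone sampling."""
    m = _load_packaged("rama_gly.dat", symmetrized=True, name="GLY")
    return m


def map_for_residue(aa: str) -> RamachandranMap:
    """Map for a one-letter, case-chirality-coded residue.

    Uppercase = L, lowercase = D (point reflection of the L map); 'G' is the
    achiral symmetric glycine map and has no lowercase form.  'P'/'p' get the
    restricted proline map; all other residues share the generic map.
    """
    if not isinstance(aa, str) or len(aa) != 1:
        raise ValueError("residue code must be a single letter")
    upper = aa.upper()
    if upper not in AA_ALPHABET:
        raise ValueError(f"unknown residue code {aa!r}")
    if upper == "G":
        if aa == "g":
            raise ValueError("glycine is achiral: no D form 'g'")
        return default_glycine_map()
    if upper == "P":
        base = _load_packaged("rama_pro.dat", symmetrized=False, name="PRO-L")
    else:
        base = _load_packaged("rama_generic.dat", symmetrized=False,
                              name="generic-L")
    if aa.islower():
        key = "D:" + upper
        if key not in _MAP_CACHE:
            _MAP_CACHE[key] = base.mirrored(name=base.name.replace("-L", "-D"))
        return _MAP_CACHE[key]
    return base


# ---------------------------------------------------------------------------
# the six-bin partition


@dataclass
class TorsionBinScheme:
    """Six labelled bins partitioning the allowed region by nearest center."""

    centers: tuple = DEFAULT_BIN_CENTERS
    map: RamachandranMap = field(default_factory=default_glycine_map)

    #: label of the mirror partner of each bin (1-based)
    MIRROR = {1: 2, 2: 1, 3: 4, 4: 3, 5: 6, 6: 5}

    def __post_init__(self):
        if len(self.centers) != 6:
            raise ValueError("need exactly 6 bin centers")

    def assign(self, phi: float, psi: float) -> tuple[int, bool]:
        """(label in 1..6, allowed flag); disallowed points fall back to the
        nearest center under the toroidal metric."""
        d2 = [toroidal_dist2(phi, psi, p0, s0) for (p0, s0) in self.centers]
        label = int(np.argmin(d2)) + 1
        return label, bool(self.map.is_allowed(phi, psi))


def assign_bin(phi: float, psi: float,
               scheme: TorsionBinScheme | None = None) -> int:
    """Deterministic bin label (1..6) for a torsion pair."""
    scheme = scheme or TorsionBinScheme()
    return scheme.assign(phi, psi)[0]


# ---------------------------------------------------------------------------
# initial configurations


def count_unique_initial_configurations(n: int) -> int:
    """Necklace count (1/n) * sum_{i=1..n} 6^gcd(i, n), exactly.

    The number of assignments of six bin labels to an n-residue ring, two
    assignments being identified when one is a cyclic rotation of the other.
    For n = 7 this is 39,996.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(6 ** math.gcd(i, n) for i in range(1, n + 1))
    assert total % n == 0
    return total // n


def _min_rotation(s: tuple) -> tuple:
    return min(tuple(s[k:] + s[:k]) for k in range(len(s)))


def enumerate_initial_configurations(n: int, limit: int = 100_000,
                                     seed: int = 0,
                                     scheme: TorsionBinScheme | None = None,
                                     geometry: IdealGeometry | None = None):
    """Yield one bin-center conformation per rotation-equivalence class.

    If the total class count fits in ``limit`` every canonical class is
    produced (in lexicographic order); otherwise ``limit`` distinct classes
    are sampled with the given seed.  Each yielded conformation has its
    (phi, psi) set to the chosen bin centers.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    scheme = scheme or TorsionBinScheme()
    centers = np.asarray(scheme.centers)
    geometry = geometry or IdealGeometry()

    def conf_from_labels(labels):
        pts = centers[np.array(labels)]
        return TorsionConformation(pts[:, 0], pts[:, 1], geometry)

    total = count_unique_initial_configurations(n)
    if total <= limit:
        for s in itertools.product(range(6), repeat=n):
            if _min_rotation(s) == s:
                yield conf_from_labels(s)
    else:
        rng = np.random.default_rng(seed)
        seen = set()
        while len(seen) < limit:
            s = tuple(rng.integers(0, 6, size=n).tolist())
            s = _min_rotation(s)
            if s not in seen:
                seen.add(s)
                yield conf_from_labels(s)
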