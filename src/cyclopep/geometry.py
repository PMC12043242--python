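"""Rigid-geometry backbone kinematics for cyclic peptides.

A peptide backbone with ideal bond lengths, ideal bond angles and a fixed
planar peptide bond (omega = 180 deg) is fully determined by its per-residue
(phi, psi) torsion angles.  This module builds the local-frame machinery that
turns a torsion assignment into Cartesian coordinates and, more importantly,
into a *cyclic error* -- a single non-negative scalar that vanishes exactly
when the chain of N, C-alpha, C' atoms closes into a macrocycle with a
matching terminal reference frame.

Frame convention
----------------
One local coordinate system sits at each of the 3n backbone atoms: the origin
at the atom, x pointing toward the next atom along the chain, y chosen so the
atom after next lies in the first quadrant of the xy plane, z by the
right-hand rule.  Moving from system i to system i+1 costs a translation by
the bond length, an xy-plane rotation by (pi - bond angle), and an yz-plane
(about-x) rotation by the torsion angle.  System 1 is anchored at the
C-alpha of residue n, so that the product of per-residue matrices

    M_i = T(theta_C') R(omega) T(theta_N) R(phi_i) T(theta_Ca) R(psi_i)

walks the frame around the whole ring.  The per-residue displacement

    q = T(theta_C') R(omega) T(theta_N) [d_N,0,0]^T
        + T(theta_C') [d_C',0,0]^T + [d_Ca,0,0]^T

is torsion-independent; for the default ideal geometry
q = [3.5620, 1.3322, 0]^T.

Angles are stored internally in radians and exposed in degrees everywhere,
wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "IdealGeometry",
    "TorsionConformation",
    "BackboneStructure",
    "DegenerateGeometryError",
    "ClosureError",
    "wrap_degrees",
    "plane_rotation",
    "torsion_rotation",
    "step_vector",
    "residue_matrix",
    "cyclic_error",
    "cyclic_error_residuals",
    "forward_kinematics",
    "measure_torsions",
    "measure_omegas",
    "dihedral",
    "close_backbone",
]

E1 = np.array([1.0, 0.0, 0.0])
E2 = np.array([0.0, 1.0, 0.0])


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is undefined because three atoms are collinear."""


class ClosureError(RuntimeError):
    """Raised when the local closure solve does not reach the tolerance."""


def wrap_degrees(x):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    x = np.asarray(x, dtype=float)
    w = x - 360.0 * np.floor((x + 180.0) / 360.0)
    w = np.where(w <= -180.0, w + 360.0, w)  # guard the open end
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class IdealGeometry:
    """Ideal backbone bond lengths (Angstrom), bond angles and omega (degrees).

    Defaults are the standard ideal values: N-Ca 1.458, Ca-C' 1.524,
    C'-N 1.329 A; bond angles 121.7 (at N), 111.2 (at Ca), 116.2 (at C')
    degrees; trans peptide bond omega = 180 degrees.
    """

    d_N: float = 1.458
    d_Ca: float = 1.524
    d_Cp: float = 1.329
    theta_N: float = 121.7
    theta_Ca: float = 111.2
    theta_Cp: float = 116.2
    omega: float = 180.0

    def __post_init__(self):
        for name in ("d_N", "d_Ca", "d_Cp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("theta_N", "theta_Ca", "theta_Cp"):
            v = getattr(self, name)
            if not 0.0 < v <= 180.0:
                raise ValueError(f"{name} must lie in (0, 180] degrees")


DEFAULT_GEOMETRY = IdealGeometry()


@dataclass
class TorsionConformation:
    """Per-residue (phi, psi) torsions plus the fixed ideal geometry.

    ``phi`` and ``psi`` are exposed in degrees, wrapped to (-180, 180].
    """

    phi: np.ndarray
    psi: np.ndarray
    geometry: IdealGeometry = field(default_factory=IdealGeometry)

    def __post_init__(self):
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        if phi.shape != psi.shape or phi.ndim != 1:
            raise ValueError("phi and psi must be 1-D and of equal length")
        self.phi = wrap_degrees(phi)
        self.psi = wrap_degrees(psi)

    @property
    def n(self) -> int:
        return len(self.phi)

    def as_vector(self) -> np.ndarray:
        """Interleaved torsion vector [phi_1, psi_1, ..., phi_n, psi_n]."""
        return np.column_stack([self.phi, self.psi]).ravel()

    @classmethod
    def from_vector(cls, x: np.ndarray, geometry: IdealGeometry | None = None
                    ) -> "TorsionConformation":
        x = np.asarray(x, dtype=float).reshape(-1, 2)
        return cls(x[:, 0], x[:, 1], geometry or DEFAULT_GEOMETRY)

    def mirrored(self) -> "TorsionConformation":
        """Mirror image: every torsion negated (also a valid closed ring)."""
        return TorsionConformation(-self.phi, -self.psi, self.geometry)

    def rotated(self, k: int) -> "TorsionConformation":
        """Cyclically relabel residues so old residue k+1 becomes residue 1."""
        return TorsionConformation(np.roll(self.phi, -k), np.roll(self.psi, -k),
                                   self.geometry)

    def copy(self) -> "TorsionConformation":
        return TorsionConformation(self.phi.copy(), self.psi.copy(), self.geometry)


ATOM_NAMES = ("N", "CA", "C", "O", "H")

# carbonyl O / amide H ideal placement (used only for H-bonds and RMSD)
D_CO = 1.231
ANGLE_CA_C_O = 120.1
D_NH = 1.010


@dataclass
class BackboneStructure:
    """Cartesian backbone coordinates (Angstrom) for an n-residue ring.

    Each of ``N``, ``CA``, ``C``, ``O``, ``H`` is an (n, 3) array; ``O`` and
    ``H`` may be ``None`` for bare N/CA/C' chains.  ``provenance`` keeps the
    torsions used to build the structure when it came from forward
    kinematics.
    """

    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray | None = None
    H: np.ndarray | None = None
    provenance: TorsionConformation | None = None

    @property
    def n(self) -> int:
        return len(self.CA)

    def heavy_coords(self) -> np.ndarray:
        """(4n, 3) array ordered residue-by-residue as N, CA, C, O."""
        if self.O is None:
            raise ValueError("structure has no carbonyl O atoms")
        return np.stack([self.N, self.CA, self.C, self.O], axis=1).reshape(-1, 3)

    def atom(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"structure has no {name} atoms")
        return arr

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "BackboneStructure":
        def mv(a):
            return None if a is None else a @ rotation.T + translation
        return BackboneStructure(mv(self.N), mv(self.CA), mv(self.C),
                                 mv(self.O), mv(self.H), self.provenance)

    def relabeled(self, k: int) -> "BackboneStructure":
        """Cyclic residue relabeling (old residue k+1 becomes residue 1)."""
        def rl(a):
            return None if a is None else np.roll(a, -k, axis=0)
        return BackboneStructure(rl(self.N), rl(self.CA), rl(self.C),
                                 rl(self.O), rl(self.H), None)


# ---------------------------------------------------------------------------
# elementary rotations


def plane_rotation(theta_next: float) -> np.ndarray:
    """Counterclockwise xy-plane rotation by (180 - theta_next) degrees.

    ``theta_next`` is the bond angle at the atom being stepped onto; it must
    lie in (0, 180].  At 180 degrees the chain is straight and the matrix is
    the identity.
    """
    if not 0.0 < theta_next <= 180.0:
        raise ValueError("bond angle must lie in (0, 180] degrees")
    a = np.pi - np.deg2rad(theta_next)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def torsion_rotation(phi_next: float) -> np.ndarray:
    """Counterclockwise yz-plane (about-x) rotation by ``phi_next`` degrees."""
    a = np.deg2rad(phi_next)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _geom_matrices(geom: IdealGeometry):
    """Cache the torsion-independent factors for a given geometry."""
    key = geom
    cached = _GEOM_CACHE.get(key)
    if cached is None:
        T_Cp = plane_rotation(geom.theta_Cp)
        T_N = plane_rotation(geom.theta_N)
        T_Ca = plane_rotation(geom.theta_Ca)
        R_om = torsion_rotation(geom.omega)
        head = T_Cp @ R_om @ T_N          # factor in front of R(phi)
        q = (head @ np.array([geom.d_N, 0.0, 0.0])
             + T_Cp @ np.array([geom.d_Cp, 0.0, 0.0])
             + np.array([geom.d_Ca, 0.0, 0.0]))
        cached = (head, T_Ca, q, T_Cp, T_N, R_om)
        _GEOM_CACHE[key] = cached
    return cached


_GEOM_CACHE: dict = {}


def step_vector(geom: IdealGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Per-residue C-alpha -> C-alpha displacement q (Angstrom).

    Torsion-independent because translations along x commute with about-x
    rotations.  For the default ideal geometry q = [3.5620, 1.3322, 0].
    """
    return _geom_matrices(geom)[2].copy()


def residue_matrix(phi: float, psi: float,
                   geom: IdealGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Rotation M(phi, psi) carrying frame i's axes across one residue."""
    head, T_Ca, _, _, _, _ = _geom_matrices(geom)
    return head @ torsion_rotation(phi) @ T_Ca @ torsion_rotation(psi)


def _residue_matrices(conf: TorsionConformation) -> np.ndarray:
    """(n, 3, 3) stack of residue matrices, vectorized over residues."""
    head, T_Ca, _, _, _, _ = _geom_matrices(conf.geometry)
    phi = np.deg2rad(conf.phi)
    psi = np.deg2rad(conf.psi)
    n = conf.n
    Rphi = np.zeros((n, 3, 3))
    Rpsi = np.zeros((n, 3, 3))
    for R, ang in ((Rphi, phi), (Rpsi, psi)):
        c, s = np.cos(ang), np.sin(ang)
        R[:, 0, 0] = 1.0
        R[:, 1, 1] = c
        R[:, 1, 2] = -s
        R[:, 2, 1] = s
        R[:, 2, 2] = c
    return head @ Rphi @ T_Ca @ Rpsi


def _residuals_raw(phi_deg: np.ndarray, psi_deg: np.ndarray,
                   geom: IdealGeometry) -> np.ndarray:
    """Fast closure-residual kernel on raw torsion arrays (degrees)."""
    head, T_Ca, q, _, _, _ = _geom_matrices(geom)
    n = len(phi_deg)
    phi = np.deg2rad(phi_deg)
    psi = np.deg2rad(psi_deg)
    cph, sph = np.cos(phi), np.sin(phi)
    cps, sps = np.cos(psi), np.sin(psi)
    R = np.zeros((n, 2, 3, 3))
    R[:, 0, 0, 0] = 1.0
    R[:, 0, 1, 1] = cph
    R[:, 0, 1, 2] = -sph
    R[:, 0, 2, 1] = sph
    R[:, 0, 2, 2] = cph
    R[:, 1, 0, 0] = 1.0
    R[:, 1, 1, 1] = cps
    R[:, 1, 1, 2] = -sps
    R[:, 1, 2, 1] = sps
    R[:, 1, 2, 2] = cps
    M = head @ R[:, 0] @ T_Ca @ R[:, 1]
    P = M[0]
    origin = q + P @ q
    for i in range(1, n - 1):
        P = P @ M[i]
        origin = origin + P @ q
    P = P @ M[-1]
    out = np.empty(9)
    out[:3] = origin
    out[3:6] = P[:, 0] - E1
    out[6:] = P[:, 1] - E2
    return out


def cyclic_error_residuals(conf: TorsionConformation) -> np.ndarray:
    """9-vector whose squared norm is the cyclic error.

    Components 0-2: terminal-origin offset (Angstrom); 3-5 and 6-8: mismatch
    of the terminal frame's x and y axes (dimensionless).
    """
    if conf.n < 3:
        raise ValueError("need at least 3 residues")
    return _residuals_raw(conf.phi, conf.psi, conf.geometry)


def cyclic_error(conf: TorsionConformation) -> float:
    """Cyclic error E_cyc >= 0; zero iff the ring closes with matching frame.

    E_cyc = ||q + M1 q + ... + M1...M_{n-1} q||^2
            + ||M1...Mn e1 - e1||^2 + ||M1...Mn e2 - e2||^2.

    The origin term carries Angstrom^2 units while the axis terms are
    dimensionless; they are summed without re-weighting.
    """
    r = cyclic_error_residuals(conf)
    return float(r @ r)


# ---------------------------------------------------------------------------
# forward kinematics


def _place_oxygens_hydrogens(N, CA, C, skip_h: Sequence[int] = ()):
    """Ideal planar O and H placement on an N/CA/C' ring.

    O sits in the Ca-C'-N(next) plane on the side opposite N(next), with
    C'-O 1.231 A and angle Ca-C'-O 120.1 deg.  H sits in the peptide plane
    bisecting the C'(prev)-N-Ca angle (reversed), with N-H 1.010 A.
    Residues listed in ``skip_h`` (e.g. prolines) get NaN H rows.
    """
    n = len(CA)
    N_next = np.roll(N, -1, axis=0)
    u = CA - C
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = N_next - C
    v -= (np.sum(v * u, axis=1, keepdims=True)) * u
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    ang = np.deg2rad(ANGLE_CA_C_O)
    O = C + D_CO * (np.cos(ang) * u - np.sin(ang) * v)

    C_prev = np.roll(C, 1, axis=0)
    a = C_prev - N
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = CA - N
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    bis = a + b
    bis /= np.linalg.norm(bis, axis=1, keepdims=True)
    H = N - D_NH * bis
    for i in skip_h:
        H[i] = np.nan
    return O, H


def forward_kinematics(conf: TorsionConformation, place_oh: bool = True,
                       skip_h: Sequence[int] = ()) -> BackboneStructure:
    """Generate Cartesian coordinates from torsions by frame composition.

    The chain starts at the C-alpha of residue n (frame 1) and walks
    C'(n), N(1), CA(1), C'(1), ... placing each atom in the running frame.
    The returned structure is translated so N of residue 1 sits at the
    origin.  For closed conformations the terminal frame coincides with the
    start; for open ones residue n's C-alpha keeps its anchoring position.
    """
    if conf.n < 3:
        raise ValueError("need at least 3 residues")
    g = conf.geometry
    head, T_Ca, _, T_Cp, T_N, R_om = _geom_matrices(g)
    n = conf.n
    phi = conf.phi
    psi = conf.psi

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))

    A = np.eye(3)
    o = np.zeros(3)
    CA[n - 1] = o
    p_Ca = np.array([g.d_Ca, 0.0, 0.0])
    p_Cp = np.array([g.d_Cp, 0.0, 0.0])
    p_N = np.array([g.d_N, 0.0, 0.0])
    for i in range(n):
        # Ca(prev) -> C'(prev): rotate at C' by (theta_C', omega)
        o = o + A @ p_Ca
        C[i - 1] = o
        A = A @ T_Cp @ R_om
        # C'(prev) -> N(i): rotate at N by (theta_N, phi_i)
        o = o + A @ p_Cp
        N[i] = o
        A = A @ T_N @ torsion_rotation(phi[i])
        # N(i) -> Ca(i): rotate at Ca by (theta_Ca, psi_i)
        o = o + A @ p_N
        if i < n - 1:
            CA[i] = o
        A = A @ T_Ca @ torsion_rotation(psi[i])

    shift = N[0].copy()
    N -= shift
    CA -= shift
    C -= shift
    O = H = None
    if place_oh:
        O, H = _place_oxygens_hydrogens(N, CA, C, skip_h=skip_h)
    return BackboneStructure(N, CA, C, O, H, provenance=conf.copy())


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) of four points, standard convention.

    Raises :class:`DegenerateGeometryError` when either inner triple is
    collinear, instead of returning NaN.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    m0 = np.linalg.norm(n0)
    m1 = np.linalg.norm(n1)
    if m0 < 1e-9 or m1 < 1e-9:
        raise DegenerateGeometryError("collinear atoms: dihedral undefined")
    b1u = b1 / np.linalg.norm(b1)
    x = n0 @ n1
    y = np.cross(n0, n1) @ b1u
    return float(wrap_degrees(np.degrees(np.arctan2(y, x))))


def measure_torsions(struct: BackboneStructure,
                     geometry: IdealGeometry | None = None
                     ) -> TorsionConformation:
    """Measure (phi, psi) from coordinates, treating the chain as cyclic.

    phi_i = dihedral(C'(i-1), N_i, CA_i, C'_i);
    psi_i = dihedral(N_i, CA_i, C'_i, N_{i+1}).  Inverse of
    :func:`forward_kinematics` on ideal-geometry closed structures.
    """
    n = struct.n
    if n < 3:
        raise ValueError("need at least 3 residues")
    phi = np.empty(n)
    psi = np.empty(n)
    for i in range(n):
        phi[i] = dihedral(struct.C[i - 1], struct.N[i], struct.CA[i], struct.C[i])
        psi[i] = dihedral(struct.N[i], struct.CA[i], struct.C[i],
                          struct.N[(i + 1) % n])
    return TorsionConformation(phi, psi, geometry or DEFAULT_GEOMETRY)


def measure_omegas(struct: BackboneStructure) -> np.ndarray:
    """Peptide-bond torsions omega_i = dihedral(CA_i, C'_i, N_{i+1}, CA_{i+1})."""
    n = struct.n
    return np.array([
        dihedral(struct.CA[i], struct.C[i], struct.N[(i + 1) % n],
                 struct.CA[(i + 1) % n])
        for i in range(n)
    ])


def close_backbone(initial: TorsionConformation, tolerance: float = 1e-6,
                   free_mask: np.ndarray | None = None,
                   max_nfev: int = 2000,
                   anchor_weight: float = 0.02) -> TorsionConformation:
    """Find an exactly closed conformation near ``initial``.

    Two-stage trust-region least-squares solve over the 2n torsions (or the
    subset selected by ``free_mask``, a boolean array over the interleaved
    torsion vector).  The closure system is underdetermined (9 residuals,
    up to 2n unknowns), so a first pass augments it with weak displacement
    anchors ``anchor_weight * (x - x0)`` that pull toward the *nearest*
    closed conformation; a second, anchor-free pass then drives the cyclic
    error to machine precision.  Deterministic.  Raises
    :class:`ClosureError` if the final cyclic error exceeds ``tolerance``.
    """
    if initial.n < 4:
        raise ValueError("need at least 4 residues to close")
    x0 = initial.as_vector()
    if cyclic_error(initial) <= tolerance:
        return initial.copy()
    if free_mask is None:
        free = np.ones(x0.size, dtype=bool)
    else:
        free = np.asarray(free_mask, dtype=bool)
        if free.shape != x0.shape:
            raise ValueError("free_mask must match the torsion vector shape")

    geom = initial.geometry

    def closure_resid(xf):
        x = x0.copy()
        x[free] = xf
        return _residuals_raw(x[0::2], x[1::2], geom)

    xf = x0[free]
    if anchor_weight > 0:
        def anchored(z):
            return np.concatenate([closure_resid(z),
                                   anchor_weight * (z - x0[free])])
        xf = least_squares(anchored, xf, method="trf", xtol=1e-8, ftol=1e-8,
                           gtol=1e-8, max_nfev=max_nfev).x

    # damped Gauss-Newton with pseudo-inverse steps: quadratic convergence
    # on the underdetermined 9-residual system, far cheaper than a full
    # trust-region solve; fall back to TRF only if it stalls
    z = xf.copy()
    r = closure_resid(z)
    err = float(r @ r)
    eps = 1e-6
    target = min(tolerance * 1e-6, 1e-16)  # quadratic tail is nearly free
    for _ in range(30):
        if err <= target:
            break
        J = np.empty((9, z.size))
        for j in range(z.size):
            zp = z.copy()
            zp[j] += eps
            J[:, j] = (closure_resid(zp) - r) / eps
        step = np.linalg.pinv(J, rcond=1e-8) @ r
        improved = False
        damp = 1.0
        for _ in range(6):
            zn = z - damp * step
            rn = closure_resid(zn)
            en = float(rn @ rn)
            if en < err:
                z, r, err = zn, rn, en
                improved = True
                break
            damp *= 0.5
        if not improved:
            break
    if err > tolerance:
        sol = least_squares(closure_resid, xf, method="trf", xtol=1e-12,
                            ftol=1e-12, gtol=1e-12, max_nfev=max_nfev)
        z = sol.x
    x = x0.copy()
    x[free] = z
    out = TorsionConformation.from_vector(x, geom)
    err = cyclic_error(out)
    if err > tolerance:
        raise ClosureError(f"closure solve stalled at E_cyc = {err:.3e}")
    return out
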