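"""Deterministic synthetic fixtures: closed rings, landscapes, toy systems.

Everything the tests (and examples) need is generated programmatically:

- ``closed_backbone``: an exactly closed n-ring obtained by locally closing
  a bin-center initial configuration;
- ``helical_turn``: a handcrafted synthetic structure carrying exactly one
  ideal-geometry H-bond (H...O 2.0 A, N-H...O 160 deg) between residues 1
  and 4, everything else far apart -- a detection oracle, not a physical
  backbone;
- ``two_funnel_landscape``: an analytic landscape built from two Gaussian
  energy funnels (one at the native, one off-native) whose PNear is
  hand-computable from the records;
- ``planted_minimum_system``: a 6-residue toy whose energy is a sum of
  per-residue torsion wells centered on a closed target conformation --
  the global minimum is the target itself, at energy -depth;
- ``bivariate_samples``: seeded Gaussian (RMSD, Rg) clouds for FES tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .clustergen import EnergyModel
from .geometry import (BackboneStructure, TorsionConformation,
                       close_backbone)
from .ramachandran import enumerate_initial_configurations, toroidal_dist2
from .stability import EnergyLandscape

__all__ = ["fixture_generator", "PlantedWellModel", "closed_backbone"]


def closed_backbone(n: int, seed: int = 0, tolerance: float = 1e-9,
                    require_allowed: bool = True) -> TorsionConformation:
    """An exactly closed conformation near a random bin-center start.

    With ``require_allowed`` (default) every residue of the returned ring
    lies inside the allowed region of the sampling (glycine) map, so the
    fixture is a legal annealer start.
    """
    from .ramachandran import default_glycine_map

    gly = default_glycine_map()
    rng = np.random.default_rng(seed)
    # walk the enumeration from a seeded offset for variety
    skip = int(rng.integers(0, 50))
    gen = enumerate_initial_configurations(n, limit=10 ** 6, seed=seed)
    for conf in itertools.islice(gen, skip, skip + 200):
        jitter = rng.uniform(-15, 15, size=2 * n)
        start = TorsionConformation(conf.phi + jitter[:n],
                                    conf.psi + jitter[n:], conf.geometry)
        try:
            out = close_backbone(start, tolerance=tolerance)
        except Exception:
            continue
        if require_allowed and not all(
                gly.is_allowed(out.phi[i], out.psi[i]) for i in range(n)):
            continue
        return out
    raise RuntimeError(f"no closure found for n={n}, seed={seed}")


class PlantedWellModel(EnergyModel):
    """Sum of per-residue toroidal torsion wells with a planted minimum.

    E(conf) = k * sum_i d_torus((phi_i, psi_i), (phi*_i, psi*_i))^2 - depth;
    uniquely minimized (value -depth) at the planted closed conformation.
    """

    def __init__(self, target: TorsionConformation, depth: float = 5.0,
                 k: float = 0.002):
        self.target = target
        self.depth = float(depth)
        self.k = float(k)

    def score(self, conf: TorsionConformation) -> float:
        d2 = toroidal_dist2(conf.phi, conf.psi, self.target.phi,
                            self.target.psi)
        return float(self.k * np.sum(d2) - self.depth)


def _helical_turn_structure() -> BackboneStructure:
    """Synthetic 4-residue structure with one planted H-bond (see module doc).

    Residues sit far apart on a wide arc; the amide H of residue 4 is
    placed 2.0 A from the carbonyl O of residue 1 with an N-H...O angle of
    160 degrees, by construction.
    """
    n = 4
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    H = np.zeros((n, 3))
    # spread residues on a circle of radius 20 A so nothing else interacts
    for i in range(n):
        ang = 2 * np.pi * i / n
        base = 20.0 * np.array([math.cos(ang), math.sin(ang), 0.0])
        N[i] = base
        CA[i] = base + [1.458, 0.0, 0.0]
        C[i] = base + [2.0, 1.3, 0.0]
        O[i] = base + [2.0, 1.3, 1.231]
        H[i] = base + [-0.6, -0.8, 0.0]
    # plant the bond: O(1) fixed; position H(4) and N(4) to hit 2.0 A / 160 deg
    O[0] = np.array([0.0, 0.0, 5.0])
    H[3] = O[0] + np.array([0.0, 0.0, 2.0])          # H...O = 2.0 A
    ang = math.radians(180.0 - 160.0)                # N-H...O = 160 deg
    nh = np.array([math.sin(ang), 0.0, math.cos(ang)])
    N[3] = H[3] + 1.010 * nh
    CA[3] = N[3] + np.array([1.458, 0.0, 0.0])
    return BackboneStructure(N, CA, C, O, H)


def _two_funnel_landscape(n_records: int = 60, native_depth: float = -10.0,
                          decoy_depth: float = -8.0, decoy_rmsd: float = 3.0,
                          lambda_: float = 0.5) -> EnergyLandscape:
    """Analytic two-funnel landscape; deterministic, no randomness needed."""
    ids, energies, rmsds = [], [], []
    m = n_records // 2
    for j in range(m):
        r = 2.0 * j / m
        ids.append(f"native{j}")
        rmsds.append(r)
        energies.append(native_depth + 4.0 * r)      # funnel walls rise
    for j in range(n_records - m):
        r = decoy_rmsd + 2.0 * j / m
        ids.append(f"decoy{j}")
        rmsds.append(r)
        energies.append(decoy_depth + 4.0 * (r - decoy_rmsd))
    return EnergyLandscape(ids, np.array(energies), np.array(rmsds),
                           lambda_=lambda_)


def fixture_generator(kind: str, n: int = 7, seed: int = 0, **kwargs):
    """Dispatch for the named fixture kinds (see module docstring)."""
    if kind == "closed_backbone":
        return closed_backbone(n, seed=seed, **kwargs)
    if kind == "helical_turn":
        return _helical_turn_structure()
    if kind == "two_funnel_landscape":
        return _two_funnel_landscape(**kwargs)
    if kind == "planted_minimum_system":
        target = closed_backbone(n if n != 7 else 6, seed=seed)
        return PlantedWellModel(target, **kwargs), target
    if kind == "bivariate_samples":
        rng = np.random.default_rng(seed)
        size = kwargs.get("size", 10_000)
        mean = kwargs.get("mean", (2.0, 6.0))
        sd = kwargs.get("sd", (0.5, 0.4))
        rmsd = rng.normal(mean[0], sd[0], size)
        rg = rng.normal(mean[1], sd[1], size)
        return np.abs(rmsd), np.abs(rg)
    raise ValueError(f"unknown fixture kind {kind!r}")
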