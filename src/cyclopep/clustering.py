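"""Torsion-bin-string clustering of backbone candidates.

Each residue of a candidate is assigned one of six Ramachandran bin labels,
producing a length-n word over "1".."6".  Because the ring has no first
residue, two words that are cyclic rotations of each other describe the same
backbone class; the canonical form is the lexicographically smallest
rotation (move the smallest label to position 1, break ties by position 2,
and so on -- which is exactly the lexicographic minimum).  Within each class
the candidate with the lowest weighted total energy is kept as the
representative.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .ramachandran import TorsionBinScheme
from .geometry import TorsionConformation

__all__ = ["bin_string", "canonicalize", "rotations", "cluster_candidates",
           "cluster_table"]


def bin_string(conf: TorsionConformation,
               scheme: TorsionBinScheme | None = None) -> str:
    """Per-residue bin labels of a conformation, as a string over 1..6."""
    scheme = scheme or TorsionBinScheme()
    return "".join(str(scheme.assign(conf.phi[i], conf.psi[i])[0])
                   for i in range(conf.n))


def rotations(s: str) -> list[str]:
    """All n cyclic rotations of a string."""
    return [s[k:] + s[:k] for k in range(len(s))]


def canonicalize(s: str) -> str:
    """Lexicographically smallest rotation (Booth's algorithm); idempotent."""
    if not s:
        raise ValueError("empty bin string")
    # Booth's least-rotation in O(n)
    t = s + s
    n = len(s)
    f = [-1] * len(t)
    k = 0
    for j in range(1, len(t)):
        sj = t[j]
        i = f[j - k - 1]
        while i != -1 and sj != t[k + i + 1]:
            if sj < t[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != t[k + i + 1]:
            if sj < t[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return t[k:k + n]


def cluster_candidates(candidates: Iterable,
                       scheme: TorsionBinScheme | None = None) -> dict:
    """Group candidates by canonical bin string; keep lowest-E_total member.

    Candidates must expose ``.conformation`` and ``.breakdown.total`` (the
    annealer's ``BackboneCandidate`` does).  Ties in energy keep the
    first-seen candidate, so the result is deterministic for a fixed input
    order.
    """
    scheme = scheme or TorsionBinScheme()
    classes: dict[str, object] = {}
    for cand in candidates:
        key = getattr(cand, "bin_string", None)
        if key is None:
            key = bin_string(cand.conformation, scheme)
        key = canonicalize(key)
        prev = classes.get(key)
        if prev is None or cand.breakdown.total < prev.breakdown.total:
            classes[key] = cand
    return classes


def cluster_table(classes: Mapping[str, object],
                  class_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Flat export of a cluster map: one row per class representative."""
    rows = []
    for key, cand in sorted(classes.items()):
        bd = cand.breakdown
        rows.append({
            "bin_string": key,
            "size": (class_sizes or {}).get(key, 1),
            "E_total": bd.total, "E_rama": bd.rama, "E_rep": bd.rep,
            "E_hbond": bd.hbond, "E_other": bd.other,
            "cyclic_error": bd.cyclic_err,
            "hbond_count": getattr(cand, "hbond_count", bd.hbond_count),
            "torsions": ";".join(
                f"{p:.2f},{q:.2f}" for p, q in
                zip(cand.conformation.phi, cand.conformation.psi)),
        })
    return pd.DataFrame(rows)
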