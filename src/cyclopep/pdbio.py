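"""PDB reading/writing for cyclic backbones with mixed L/D chirality.

D-amino acids are written with their standard three-letter names (DAL,
DSN, ...) and recognised on input both by those names and -- optionally --
by positive-phi handedness when a file uses L names for D residues.
Structures are backbone-only (N, CA, C, O, H); the ring closure is noted
with a CONECT record between C' of the last residue and N of the first.
Reading tolerates missing carbonyl O atoms by rebuilding them from the
ideal planar placement.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .geometry import (BackboneStructure, _place_oxygens_hydrogens,
                       measure_torsions)

__all__ = ["read_pdb", "write_pdb", "PDBFormatError",
           "L_NAMES", "D_NAMES"]


class PDBFormatError(ValueError):
    """Structured parse failure, carrying the offending residue/line info."""


L_NAMES = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
#: standard PDB chemical-component names for D-amino acids
D_NAMES = {
    "a": "DAL", "r": "DAR", "n": "DSG", "d": "DAS", "c": "DCY",
    "q": "DGN", "e": "DGL", "h": "DHI", "i": "DIL", "l": "DLE",
    "k": "DLY", "m": "MED", "f": "DPN", "p": "DPR", "s": "DSN",
    "t": "DTH", "w": "DTR", "y": "DTY", "v": "DVA",
}
_NAME_TO_CODE = {v: k for k, v in L_NAMES.items()}
_NAME_TO_CODE.update({v: k for k, v in D_NAMES.items()})


def read_pdb(path, infer_chirality: bool = False
             ) -> tuple[BackboneStructure, str]:
    """Parse backbone atoms and a chirality-coded sequence from a PDB file.

    Returns (structure, sequence); residues are taken in file order with
    1-based numbering in the file mapped to 0-based internally.  Missing O
    atoms are rebuilt by the ideal planar rule (a warning is attached).
    With ``infer_chirality`` on, residues carrying L names but a positive
    phi torsion are flagged as D (lowercase) -- a fallback for files that do
    not use D component names.  Off by default because L residues can
    legitimately visit positive-phi regions.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        model = parser.get_structure("pep", str(path))[0]
    chain = next(iter(model))
    N, CA, C, O, H, codes = [], [], [], [], [], []
    for res in chain:
        resname = res.get_resname().strip()
        if resname == "HOH":
            continue
        code = _NAME_TO_CODE.get(resname)
        if code is None:
            raise PDBFormatError(
                f"unknown residue name {resname!r} at position "
                f"{res.id[1]}")
        for nm, store in (("N", N), ("CA", CA), ("C", C)):
            if nm not in res:
                raise PDBFormatError(
                    f"residue {res.id[1]} ({resname}) misses atom {nm}")
            store.append(res[nm].get_coord().astype(float))
        O.append(res["O"].get_coord().astype(float) if "O" in res else None)
        H.append(res["H"].get_coord().astype(float) if "H" in res else None)
        codes.append(code)
    if len(CA) < 3:
        raise PDBFormatError("fewer than 3 residues")
    N, CA, C = np.array(N), np.array(CA), np.array(C)

    rebuilt_O, rebuilt_H = _place_oxygens_hydrogens(N, CA, C)
    O = np.array([o if o is not None else rebuilt_O[i]
                  for i, o in enumerate(O)])
    H = np.array([h if h is not None else rebuilt_H[i]
                  for i, h in enumerate(H)])
    struct = BackboneStructure(N, CA, C, O, H)

    if infer_chirality:
        conf = measure_torsions(struct)
        codes = [
            c.lower() if (c.isupper() and c != "G" and conf.phi[i] > 0) else c
            for i, c in enumerate(codes)]
    return struct, "".join(codes)


def write_pdb(struct: BackboneStructure, sequence: str | None, path,
              cyclic: bool = True) -> None:
    """Write backbone ATOM records, TER, and the ring-closure CONECT.

    D residues get their D component names; ``sequence`` defaults to
    poly-glycine.  Atom order per residue is N, CA, C, O(, H).
    """
    n = struct.n
    sequence = sequence or "G" * n
    if len(sequence) != n:
        raise ValueError("sequence length does not match structure")
    lines = []
    serial = 1
    serials = {}
    for i in range(n):
        aa = sequence[i]
        resname = D_NAMES.get(aa) if aa.islower() else L_NAMES.get(aa)
        if resname is None:
            raise ValueError(f"unknown residue code {aa!r}")
        atoms = [("N", struct.N[i]), ("CA", struct.CA[i]), ("C", struct.C[i])]
        if struct.O is not None:
            atoms.append(("O", struct.O[i]))
        if struct.H is not None and not np.isnan(struct.H[i][0]):
            atoms.append(("H", struct.H[i]))
        for name, xyz in atoms:
            el = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s}{resname:>4s} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {el:>2s}")
            serials[(i, name)] = serial
            serial += 1
    lines.append(f"TER   {serial:5d}")
    if cyclic:
        lines.append(f"CONECT{serials[(n - 1, 'C')]:5d}"
                     f"{serials[(0, 'N')]:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
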