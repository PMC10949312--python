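"""Structure reading/writing and the uniform chain model.

Wraps gemmi for PDB/mmCIF parsing and exposes a minimal residue/atom model
sufficient for backbone geometry: ordered residues, one-letter sequence,
per-atom coordinates and B-factors (which carry pLDDT for predicted models).
Only one polymer chain is analyzed per call; waters and hetero ligands are
dropped, and for alternate locations the highest-occupancy conformer wins
(first on ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np


class StructureError(Exception):
    """Raised for unreadable files, missing chains, or empty structures."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Angstrom
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    seqnum: int                 # author residue number
    index: int                  # 0-based position in chain
    aa: str                     # one-letter code, X for nonstandard
    atoms: dict[str, Atom] = field(default_factory=dict)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        return self.atoms.get(name)

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atoms.get(name)
        return None if a is None else a.coord

    @property
    def label(self) -> str:
        """Author-facing residue label, e.g. 'C66'."""
        return f"{self.aa}{self.seqnum}{self.icode}"


@dataclass
class Structure:
    id: str
    residues: list[Residue]
    source_format: str = "pdb"

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self, start: int = 0, stop: int | None = None) -> np.ndarray:
        """Stacked CA coordinates for residues [start, stop)."""
        stop = len(self.residues) if stop is None else stop
        rows = []
        for r in self.residues[start:stop]:
            ca = r.coord("CA")
            if ca is None:
                raise StructureError(f"residue {r.label} has no CA atom")
            rows.append(ca)
        return np.asarray(rows, dtype=float)

    def subset(self, indices: list[int] | range, new_id: str | None = None) -> "Structure":
        """A new Structure over the given residue indices, re-enumerated."""
        residues = []
        for k, i in enumerate(indices):
            src = self.residues[i]
            residues.append(Residue(src.seqnum, k, src.aa, dict(src.atoms), src.icode))
        return Structure(new_id or self.id, residues, self.source_format)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply a rigid transform x -> R x + t to every atom."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        residues = []
        for r in self.residues:
            atoms = {
                n: Atom(a.name, a.element, rotation @ a.coord + translation, a.bfactor)
                for n, a in r.atoms.items()
            }
            residues.append(Residue(r.seqnum, r.index, r.aa, atoms, r.icode))
        return Structure(self.id, residues, self.source_format)


def _one_letter(resname: str) -> str:
    code = gemmi.find_tabulated_residue(resname)
    if code is not None and code.is_amino_acid():
        letter = gemmi.find_tabulated_residue(resname).one_letter_code.upper()
        if letter.isalpha():
            return letter
    return "X"


def _pick_altloc(res: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Highest-occupancy altloc per atom name, first wins ties."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            chosen[atom.name] = atom
    return chosen


def read_structure(path: str | Path, chain: str | None = None) -> Structure:
    """Read one polymer chain from a PDB or mmCIF file.

    The requested chain is returned, or the first polymer chain if none is
    given. Waters and hetero ligands are excluded; for NMR-style multi-model
    files only the first model is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    source_format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]

    gchain = None
    if chain is not None:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise StructureError(f"chain {chain!r} not found in {path}")
    else:
        for c in model:
            if any(_is_standard_aa(r) for r in c):
                gchain = c
                break
        if gchain is None:
            raise StructureError(f"no polymer chain with amino acids in {path}")

    residues: list[Residue] = []
    for gres in gchain:
        if not _is_standard_aa(gres):
            continue
        atoms: dict[str, Atom] = {}
        for name, gatom in _pick_altloc(gres).items():
            pos = gatom.pos
            atoms[name] = Atom(
                name=name,
                element=gatom.element.name,
                coord=np.array([pos.x, pos.y, pos.z]),
                bfactor=gatom.b_iso,
            )
        residues.append(
            Residue(
                seqnum=gres.seqid.num,
                index=len(residues),
                aa=_one_letter(gres.name),
                atoms=atoms,
                icode=(gres.seqid.icode or "").strip(),
            )
        )
    if not residues:
        raise StructureError(f"no standard amino-acid residues in {path}")
    return Structure(id=path.stem, residues=residues, source_format=source_format)


def _is_standard_aa(gres: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(gres.name)
    if info is not None and info.is_water():
        return False
    # amino acid (standard or modified) with at least a CA atom
    if info is not None and info.is_amino_acid():
        return True
    return False


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_structure(s: Structure, path: str | Path, chain_id: str = "A") -> None:
    """Write fixed-width PDB ATOM records (fixtures and debugging)."""
    lines = []
    serial = 1
    for res in s.residues:
        resname = _THREE.get(res.aa, "UNK")
        for atom in res.atoms.values():
            x, y, z = atom.coord
            elem = (atom.element or atom.name[0]).rjust(2)
            name = atom.name
            # PDB atom-name column convention: 1-char elements start col 14
            name_field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {name_field}"
                f" {resname:<3s} {chain_id}{res.seqnum:4d}{res.icode or ' ':1s}  "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{atom.bfactor:6.2f}"
                f"          {elem}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def mean_plddt(s: Structure) -> float:
    """Mean CA B-factor; for AlphaFold-style models this is the mean pLDDT."""
    values = []
    for r in s.residues:
        ca = r.atom("CA")
        if ca is None:
            raise StructureError(f"residue {r.label} has no CA atom")
        values.append(ca.bfactor)
    return float(np.mean(values))
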