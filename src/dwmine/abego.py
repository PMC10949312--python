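"""Backbone dihedrals and the ABEGO conformational alphabet.

Each residue is mapped to one of five Ramachandran regions: A (right-handed
helical), B (extended/beta), G (left-handed helical), E (left-handed
extended), or O for cis-peptide conformations. Residues whose torsions are
undefined (chain termini, missing backbone atoms) receive '-'. The bin
boundaries are a convention, not a physical constant; they are exposed in
:class:`dwmine.config.AbegoBins`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AbegoBins
from .structure_io import Structure

ALPHABET = "ABEGO"


@dataclass(frozen=True)
class Dihedrals:
    """Backbone torsions in degrees, IUPAC sign convention; None = undefined."""

    phi: float | None
    psi: float | None
    omega: float | None


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(b1 / np.linalg.norm(b1), n1)
    x = n1 @ n2
    y = m1 @ n2
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def compute_dihedrals(s: Structure) -> list[Dihedrals]:
    """Per-residue (phi, psi, omega).

    phi(i) uses C(i-1),N(i),CA(i),C(i); psi(i) uses N(i),CA(i),C(i),N(i+1);
    omega(i) uses CA(i-1),C(i-1),N(i),CA(i). Any missing atom leaves the
    affected torsions undefined rather than raising.
    """
    n = len(s.residues)
    out: list[Dihedrals] = []
    for i, res in enumerate(s.residues):
        N, CA, C = res.coord("N"), res.coord("CA"), res.coord("C")
        prev = s.residues[i - 1] if i > 0 else None
        nxt = s.residues[i + 1] if i < n - 1 else None
        def defined(*points) -> bool:
            return all(p is not None for p in points)

        phi = psi = omega = None
        if prev is not None and defined(prev.coord("C"), N, CA, C):
            phi = dihedral(prev.coord("C"), N, CA, C)
        if nxt is not None and defined(N, CA, C, nxt.coord("N")):
            psi = dihedral(N, CA, C, nxt.coord("N"))
        if prev is not None and defined(prev.coord("CA"), prev.coord("C"), N, CA):
            omega = dihedral(prev.coord("CA"), prev.coord("C"), N, CA)
        out.append(Dihedrals(phi, psi, omega))
    return out


def assign_letter(d: Dihedrals, bins: AbegoBins | None = None) -> str:
    """One ABEGO letter for a torsion triple.

    O (cis peptide) takes precedence over the phi/psi bins; an undefined
    phi or psi yields '-'.
    """
    bins = bins or AbegoBins()
    if d.omega is not None and abs(d.omega) < bins.cis_omega:
        return "O"
    if d.phi is None or d.psi is None:
        return "-"
    if d.phi < 0:
        return "A" if bins.a_psi_low < d.psi <= bins.a_psi_high else "B"
    return "G" if bins.g_psi_low < d.psi <= bins.g_psi_high else "E"


def abego_string(s: Structure, bins: AbegoBins | None = None) -> str:
    """The ABEGO string of a structure, one letter per residue."""
    return "".join(assign_letter(d, bins) for d in compute_dihedrals(s))
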