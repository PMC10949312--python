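"""Spatial side-chain constellation search.

Given a query set of residues (e.g. a putative Cys/Asp/Asp/His catalytic
cluster), find residue tuples of the same amino-acid types in a target
structure whose side chains superpose onto the query within an RMSD
threshold (1.0 Angstrom by default). Candidate tuples are pruned by pairwise
CB-CB distances before superposition; chemically symmetric side-chain atoms
(Asp OD1/OD2 and the like) are tried in both labelings and the lower RMSD
kept. A pruning-free brute-force enumerator serves as the ground-truth
oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .structure_io import Residue, Structure
from .superpose import kabsch

# non-hydrogen side-chain atoms considered per residue type (CA/CB added
# separately); the atom set actually used per pair is the intersection of
# what both residues resolve
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "A": (),
    "C": ("SG",),
    "D": ("CG", "OD1", "OD2"),
    "E": ("CG", "CD", "OE1", "OE2"),
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "G": (),
    "H": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "I": ("CG1", "CG2", "CD1"),
    "K": ("CG", "CD", "CE", "NZ"),
    "L": ("CG", "CD1", "CD2"),
    "M": ("CG", "SD", "CE"),
    "N": ("CG", "OD1", "ND2"),
    "P": ("CG", "CD"),
    "Q": ("CG", "CD", "OE1", "NE2"),
    "R": ("CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "S": ("OG",),
    "T": ("OG1", "CG2"),
    "V": ("CG1", "CG2"),
    "W": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
}

# two-fold symmetric atom pairs whose crystallographic naming is arbitrary
SYMMETRIC_SWAPS: dict[str, tuple[tuple[str, str], ...]] = {
    "D": (("OD1", "OD2"),),
    "E": (("OE1", "OE2"),),
    "F": (("CD1", "CD2"), ("CE1", "CE2")),
    "Y": (("CD1", "CD2"), ("CE1", "CE2")),
    "R": (("NH1", "NH2"),),
}


@dataclass
class QueryResidue:
    aa: str
    atoms: dict[str, np.ndarray]
    label: str = ""


@dataclass
class ConstellationQuery:
    residues: list[QueryResidue]

    def __post_init__(self) -> None:
        if len(self.residues) < 3:
            raise ValueError("a constellation query needs at least 3 residues")
        for r in self.residues:
            if len(r.atoms) < 2:
                raise ValueError(f"query residue {r.label or r.aa} has fewer than 2 atoms")


@dataclass
class ConstellationHit:
    structure_id: str
    mapping: list[tuple[str, str]]  # (query residue label, target residue label)
    rmsd: float


def query_from_structure(s: Structure, seqnums: list[int]) -> ConstellationQuery:
    """Build a query from author residue numbers of a structure."""
    by_num = {r.seqnum: r for r in s.residues}
    residues = []
    for num in seqnums:
        if num not in by_num:
            raise ValueError(f"residue {num} not in structure {s.id}")
        res = by_num[num]
        residues.append(QueryResidue(res.aa, _usable_atoms(res), res.label))
    return ConstellationQuery(residues)


def _usable_atoms(res: Residue) -> dict[str, np.ndarray]:
    names = ("CA", "CB") + SIDE_CHAIN_ATOMS.get(res.aa, ())
    return {n: res.atoms[n].coord for n in names if n in res.atoms}


def _swap_variants(aa: str, names: list[str]) -> list[list[str]]:
    """All relabelings of ``names`` under the residue's symmetric atom swaps."""
    variants = [list(names)]
    for a, b in SYMMETRIC_SWAPS.get(aa, ()):
        if a in names and b in names:
            new = []
            for v in variants:
                swapped = [b if n == a else a if n == b else n for n in v]
                new.append(swapped)
            variants.extend(new)
    return variants


def _tuple_rmsd(query: list[QueryResidue], targets: list[Residue]) -> float | None:
    """Best superposition RMSD over shared atoms, trying symmetric labelings."""
    per_res = []
    for q, t in zip(query, targets):
        t_atoms = _usable_atoms(t)
        shared = [n for n in q.atoms if n in t_atoms]
        if len(shared) < 2:
            return None
        per_res.append((q, t_atoms, shared))
    q_coords = np.concatenate([[q.atoms[n] for n in shared] for q, _, shared in per_res])

    best = None
    variant_sets = [_swap_variants(q.aa, shared) for q, _, shared in per_res]
    for combo in itertools.product(*variant_sets):
        rows = []
        for (q, t_atoms, _), names in zip(per_res, combo):
            rows.extend(t_atoms[n] for n in names)
        t_coords = np.asarray(rows)
        _, rmsd = kabsch(t_coords, q_coords)
        if best is None or rmsd < best:
            best = rmsd
    return best


def _collect_hits(
    q: ConstellationQuery,
    s: Structure,
    tuples: "itertools.product | list",
    threshold: float,
) -> list[ConstellationHit]:
    hits = []
    for targets in tuples:
        if len({t.index for t in targets}) != len(targets):
            continue
        rmsd = _tuple_rmsd(q.residues, list(targets))
        if rmsd is not None and rmsd <= threshold:
            hits.append(
                ConstellationHit(
                    structure_id=s.id,
                    mapping=[(qr.label or qr.aa, t.label) for qr, t in zip(q.residues, targets)],
                    rmsd=float(rmsd),
                )
            )
    hits.sort(key=lambda h: (h.rmsd, h.mapping))
    return hits


def search_constellation(
    q: ConstellationQuery,
    s: Structure,
    threshold: float = 1.0,
    prune_tolerance: float = 1.5,
) -> list[ConstellationHit]:
    """Find all residue tuples matching the query within ``threshold`` RMSD.

    Candidates are restricted to residues of the query amino-acid types and
    pruned by pairwise CB-CB distances (within ``prune_tolerance`` of the
    query's); survivors are verified by superposition of the shared atoms.
    """
    candidates = [[r for r in s.residues if r.aa == qr.aa and _usable_atoms(r)]
                  for qr in q.residues]
    if any(not c for c in candidates):
        return []

    def anchor(atoms: dict[str, np.ndarray]) -> np.ndarray | None:
        return atoms.get("CB", atoms.get("CA"))

    q_anchor = [anchor(qr.atoms) for qr in q.residues]
    nq = len(q.residues)
    q_dist = np.zeros((nq, nq))
    for i in range(nq):
        for j in range(i + 1, nq):
            q_dist[i, j] = q_dist[j, i] = np.linalg.norm(q_anchor[i] - q_anchor[j])

    # depth-first enumeration with pairwise distance pruning
    pruned: list[tuple[Residue, ...]] = []
    stack: list[tuple[Residue, ...]] = [()]
    while stack:
        partial = stack.pop()
        depth = len(partial)
        if depth == nq:
            pruned.append(partial)
            continue
        for cand in candidates[depth]:
            if any(c.index == cand.index for c in partial):
                continue
            a_c = anchor(_usable_atoms(cand))
            ok = True
            for k, prev in enumerate(partial):
                a_p = anchor(_usable_atoms(prev))
                d = np.linalg.norm(a_c - a_p)
                if abs(d - q_dist[depth, k]) > prune_tolerance:
                    ok = False
                    break
            if ok:
                stack.append(partial + (cand,))
    return _collect_hits(q, s, pruned, threshold)


def brute_force_constellation(
    q: ConstellationQuery,
    s: Structure,
    threshold: float = 1.0,
    max_residues: int = 200,
) -> list[ConstellationHit]:
    """Exhaustive enumeration without pruning; the oracle for the pruned search."""
    if len(s.residues) > max_residues:
        raise ValueError(
            f"brute force limited to {max_residues} residues (got {len(s.residues)})"
        )
    candidates = [[r for r in s.residues if r.aa == qr.aa and _usable_atoms(r)]
                  for qr in q.residues]
    if any(not c for c in candidates):
        return []
    return _collect_hits(q, s, itertools.product(*candidates), threshold)
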