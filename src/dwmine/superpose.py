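"""Optimal rigid-body superposition (Kabsch) and the reference-fragment filter.

The Kabsch algorithm finds the proper rotation minimizing the RMSD between
two equal-length point sets; candidate P-loops are kept when their CA trace
superposes onto the reference fragment within a distance threshold
(2.0 Angstrom by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .motif_search import MotifMatch


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray     # (3,3), proper orthonormal
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ReferenceFragment:
    """An ordered CA trace of a reference P-loop (14 residues)."""

    source: str
    ca_coords: np.ndarray  # (14, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca_coords", np.asarray(self.ca_coords, float))
        if self.ca_coords.shape != (14, 3):
            raise ValueError("reference fragment must have exactly 14 CA coordinates")


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns the rigid transform (proper rotation, reflections corrected by
    flipping the sign of the smallest singular value) and the resulting RMSD
    sqrt(sum ||R m_i + t - t_i||^2 / N).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape:
        raise ValueError(f"point-set shapes differ: {mobile.shape} vs {target.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    diff = mobile @ R.T + t - target
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return RigidTransform(R, t), rmsd


def filter_by_reference(
    matches: list[MotifMatch],
    ref: ReferenceFragment,
    threshold: float = 2.0,
) -> list[MotifMatch]:
    """Set ``rmsd_to_ref`` on every match and keep those within ``threshold``."""
    for m in matches:
        if len(m.ca_coords) != len(ref.ca_coords):
            raise ValueError(
                f"match length {len(m.ca_coords)} != reference length {len(ref.ca_coords)}"
            )
        _, rmsd = kabsch(m.ca_coords, ref.ca_coords)
        m.rmsd_to_ref = rmsd
    return [m for m in matches if m.rmsd_to_ref <= threshold]


def load_reference(path: str | Path | None = None) -> ReferenceFragment:
    """Load a reference P-loop fragment.

    Without arguments, loads the packaged synthetic stand-in: an
    ideal-geometry 14-residue fragment built from the canonical P-loop
    torsion recipe (see its provenance field). Given a path, loads a JSON
    file with ``source`` and ``ca_coords`` keys, e.g. one produced by
    :func:`reference_from_structure` from a local copy of the F1-ATPase
    crystal structure.
    """
    if path is None:
        text = resources.files("dwmine.data").joinpath("ref_ploop_synthetic.json").read_text()
    else:
        text = Path(path).read_text()
    data = json.loads(text)
    return ReferenceFragment(source=data["source"], ca_coords=np.asarray(data["ca_coords"]))


def reference_from_structure(
    s, first_seqnum: int = 166, last_seqnum: int = 179, source: str | None = None
) -> ReferenceFragment:
    """Extract a 14-CA reference fragment from a Structure by author numbering.

    With the defaults this extracts the canonical P-loop of the F1-ATPase
    alpha subunit (chain A of PDB entry 1bmf, residues 166-179) from a
    locally available copy of that structure.
    """
    coords = [
        r.coord("CA")
        for r in s.residues
        if first_seqnum <= r.seqnum <= last_seqnum and r.coord("CA") is not None
    ]
    if len(coords) != 14:
        raise ValueError(f"expected 14 residues in range, found {len(coords)}")
    return ReferenceFragment(
        source=source or f"{s.id} residues {first_seqnum}-{last_seqnum}",
        ca_coords=np.asarray(coords),
    )


def save_reference(ref: ReferenceFragment, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"source": ref.source, "ca_coords": ref.ca_coords.tolist()}, indent=1)
    )
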