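"""Fixture generators with machine-readable ground truth.

Everything the pipeline is tested on is built here: backbones chained from
torsion recipes (so the intended conformation string is known exactly),
idealized hydrogen-bonded beta-sheets assembled from an analytic strand
template (so the designed N-H...O=C pairings are known exactly), chimeric
dual-P-loop positives and tandem-repeat decoys, conservation MSAs with
planted columns, and side-chain constellations. Linkers between rigidly
placed fragments are geometrically unconstrained by design: only the
hydrogen-bond geometry and the torsions of scored regions matter to the
pipeline under test, which keeps the ground truth exact.

All randomness flows through one seeded numpy Generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .abego import Dihedrals, assign_letter
from .structure_io import Atom, Residue, Structure
from .symmetry_conservation import AA20, Msa

# ---------------------------------------------------------------------------
# torsion recipes and the internal-to-Cartesian (NeRF) backbone builder

# region-center torsions per conformation letter (phi, psi, omega)
REGION_CENTERS: dict[str, tuple[float, float, float]] = {
    "A": (-60.0, -45.0, 180.0),
    "B": (-120.0, 130.0, 180.0),
    "E": (75.0, 170.0, 180.0),
    "G": (75.0, 10.0, 180.0),
    "O": (-60.0, -45.0, 0.0),
}

# ideal backbone geometry (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5


@dataclass
class TorsionRecipe:
    torsions: list[tuple[float, float, float]]  # (phi, psi, omega) per residue

    @classmethod
    def from_abego(cls, letters: str) -> "TorsionRecipe":
        return cls([REGION_CENTERS[c] for c in letters])

    @property
    def intended_abego(self) -> str:
        """The conformation string the built backbone must reproduce."""
        n = len(self.torsions)
        out = []
        for i, (phi, psi, omega) in enumerate(self.torsions):
            d = Dihedrals(
                phi if i > 0 else None,
                psi if i < n - 1 else None,
                omega if i > 0 else None,
            )
            out.append(assign_letter(d))
        return "".join(out)


def place_atom(p1, p2, p3, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Next atom from three predecessors by bond length, angle and torsion."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    recipe: TorsionRecipe,
    sequence: str | None = None,
    structure_id: str = "synthetic",
    bfactor: float = 90.0,
) -> Structure:
    """Chain N/CA/C/O atoms from a torsion recipe with ideal geometry.

    Round-trip guarantee: recomputing dihedrals on the result reproduces the
    recipe at interior residues to well under half a degree.
    """
    n = len(recipe.torsions)
    sequence = sequence or "A" * n
    coords: list[dict[str, np.ndarray]] = []
    for i in range(n):
        phi, psi, omega = recipe.torsions[i]
        if i == 0:
            N = np.zeros(3)
            CA = np.array([_B_N_CA, 0.0, 0.0])
            ang = math.radians(_A_N_CA_C)
            C = CA + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            prev = coords[i - 1]
            psi_prev = recipe.torsions[i - 1][1]
            N = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
            CA = place_atom(prev["CA"], prev["C"], N, _B_N_CA, _A_C_N_CA, omega)
            C = place_atom(prev["C"], N, CA, _B_CA_C, _A_N_CA_C, phi)
        O = place_atom(N, CA, C, _B_C_O, _A_CA_C_O, psi + 180.0)
        coords.append({"N": N, "CA": CA, "C": C, "O": O})
    residues = []
    for i, atom_coords in enumerate(coords):
        atoms = {
            name: Atom(name, name[0], coord, bfactor)
            for name, coord in atom_coords.items()
        }
        residues.append(Residue(seqnum=i + 1, index=i, aa=sequence[i], atoms=atoms))
    return Structure(structure_id, residues)


# ---------------------------------------------------------------------------
# idealized beta-sheets from an analytic strand template

# strand template constants: rise per residue, N/C x-offset from CA, N/C
# y-offset, carbonyl tilt along the strand, pleat amplitude
_RISE, _XB, _YC, _TILT, _PLEAT = 3.4, 1.2, 0.5, 0.15, 0.6
_YO = math.sqrt(_B_C_O**2 - _TILT**2)


def _template_residue(k: int) -> dict[str, np.ndarray]:
    """Backbone atoms of local strand residue k; groups alternate +/- y."""
    s = 1.0 if k % 2 == 0 else -1.0
    x = _RISE * k
    return {
        "N": np.array([x - _XB, s * _YC, 0.0]),
        "CA": np.array([x, 0.0, _PLEAT * s]),
        "C": np.array([x + _XB, s * _YC, 0.0]),
        "O": np.array([x + _XB + _TILT, s * (_YC + _YO), 0.0]),
    }


@dataclass
class SheetSpec:
    n_strands: int
    strand_length: int
    topology: str | list[str] = "antiparallel"  # per adjacent pair, or one for all
    registers: list[int] | None = None          # per adjacent pair
    spacing: float = 4.8                        # inter-strand CA-CA distance
    linker_length: int = 3

    def __post_init__(self) -> None:
        if self.n_strands < 1:
            raise ValueError("need at least one strand")
        if not 4.5 <= self.spacing <= 5.5:
            raise ValueError("inter-strand spacing must be within [4.5, 5.5] Angstrom")
        n_pairs = max(self.n_strands - 1, 0)
        if isinstance(self.topology, str):
            if self.topology == "mixed":
                self.topology = ["antiparallel" if k % 2 == 0 else "parallel"
                                 for k in range(n_pairs)]
            else:
                self.topology = [self.topology] * n_pairs
        if len(self.topology) != n_pairs:
            raise ValueError("one topology entry per adjacent strand pair")
        if self.registers is None:
            self.registers = [self.default_register(k) for k in range(n_pairs)]
        if len(self.registers) != n_pairs:
            raise ValueError("one register per adjacent strand pair")

    def default_register(self, pair: int) -> int:
        L = self.strand_length
        if self.topology[pair] == "antiparallel":
            # i + j register: both i and j carry the pair's facing parity, so
            # the register is even; pick the one giving the most rungs
            facing = 0 if pair % 2 == 0 else 1
            best_r, best_n = 2 * facing, 0
            for r in range(2 * facing, 2 * L - 2, 2):
                n = sum(
                    1
                    for i in range(facing, L, 2)
                    if 0 <= r - i < L and (r - i) % 2 == facing
                )
                if n > best_n:
                    best_r, best_n = r, n
            return best_r
        return 1  # parallel i - j register (must be odd)


@dataclass
class SheetTruth:
    """Construction ground truth for a built sheet."""

    strand_ranges: list[tuple[int, int]]            # global residue index spans
    designed_hbonds: list[tuple[int, int]]          # (donor, acceptor), global
    pair_rungs: list[list[tuple[int, int]]]         # local (i, j) per adjacent pair
    expected_sheets: list[set[int]]                 # partition of strand blocks
    joining_hbonds: dict[int, list[tuple[int, int]]] = field(default_factory=dict)


def _pair_rungs(spec: SheetSpec, pair: int) -> list[tuple[int, int]]:
    """Designed rung positions (local i on strand ``pair``, local j on pair+1)."""
    L = spec.strand_length
    R = spec.registers[pair]
    rungs = []
    if spec.topology[pair] == "antiparallel":
        facing = 0 if pair % 2 == 0 else 1       # parity of both i and j
        for i in range(L):
            if i % 2 != facing:
                continue
            j = R - i
            if 0 <= j < L and j % 2 == facing:
                rungs.append((i, j))
    else:
        facing_i = 1 if pair % 2 == 0 else 0     # parity of i is opposite the pair's
        for i in range(1, L - 1):
            if i % 2 != facing_i:
                continue
            j = i - R
            if 0 <= j < L:
                rungs.append((i, j))
    return rungs


def _rung_bonds(spec: SheetSpec, pair: int, gi: int, gj: int,
                i: int, j: int) -> list[tuple[int, int]]:
    """Global (donor, acceptor) bonds implied by one rung."""
    if spec.topology[pair] == "antiparallel":
        return [(gi + i, gj + j), (gj + j, gi + i)]
    return [(gj + j, gi + i - 1), (gi + i + 1, gj + j)]


def _make_linker(n: int, origin: np.ndarray, seq_aa: str = "G") -> list[dict[str, np.ndarray]]:
    """Geometrically unconstrained spacer residues near ``origin``."""
    out = []
    for k in range(n):
        x = origin[0] + 3.5 * k
        z = origin[2] + (0.4 if k % 2 else -0.4)
        out.append(
            {
                "N": np.array([x - 1.2, origin[1] + 0.3, z]),
                "CA": np.array([x, origin[1], z + 0.5]),
                "C": np.array([x + 1.2, origin[1] + 0.3, z]),
                "O": np.array([x + 1.2, origin[1] + 1.5, z]),
            }
        )
    return out


def _orientations_and_offsets(spec: SheetSpec, origin: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-strand (diagonal orientation matrix, translation)."""
    placements = []
    sx, sy = 1.0, 1.0
    x, y = float(origin[0]), float(origin[1])
    for k in range(spec.n_strands):
        sz = sx * sy  # keep det = +1
        placements.append((np.diag([sx, sy, sz]), np.array([x, y, origin[2]])))
        if k == spec.n_strands - 1:
            break
        R = spec.registers[k]
        if spec.topology[k] == "antiparallel":
            x = x + sx * (_RISE * R + _TILT)
            sx, sy = -sx, -sy
        else:
            x = x + sx * _RISE * R
            sy = -sy
        y += spec.spacing
    return placements


def build_sheet(
    spec: SheetSpec,
    origin: np.ndarray | None = None,
    structure_id: str = "sheet",
) -> tuple[Structure, SheetTruth]:
    """Idealized hydrogen-bonded sheet with exact designed-bond bookkeeping.

    Strands are rigid placements of an analytic pleated-strand template at
    the requested spacing, orientations and registers; adjacent strands are
    x-aligned so the designed rung bonds satisfy the electrostatic H-bond
    criterion exactly. A linker precedes every strand (the residue before
    each strand start has its carbonyl oriented so the reconstructed amide
    hydrogen of the strand's first residue points across the sheet).
    """
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    placements = _orientations_and_offsets(spec, origin)
    L = spec.strand_length
    nl = spec.linker_length

    fragments: list[list[dict[str, np.ndarray]]] = []
    strand_starts: list[int] = []
    cursor = 0
    for k, (rot, trans) in enumerate(placements):
        linker = _make_linker(nl, np.array([origin[0], origin[1] - 15.0 - 12.0 * k, origin[2] - 20.0]))
        # orient the last linker carbonyl for the strand's first-residue donor
        u = np.array([-_TILT, _YO, 0.0])
        linker[-1]["O"] = linker[-1]["C"] - rot @ u
        fragments.append(linker)
        cursor += nl
        strand_starts.append(cursor)
        strand = [
            {name: rot @ coord + trans for name, coord in _template_residue(i).items()}
            for i in range(L)
        ]
        fragments.append(strand)
        cursor += L

    residues = []
    for frag in fragments:
        for atom_coords in frag:
            i = len(residues)
            atoms = {n: Atom(n, n[0], c, 90.0) for n, c in atom_coords.items()}
            residues.append(Residue(seqnum=i + 1, index=i, aa="V", atoms=atoms))
    structure = Structure(structure_id, residues)

    designed: list[tuple[int, int]] = []
    pair_rungs: list[list[tuple[int, int]]] = []
    joining: dict[int, list[tuple[int, int]]] = {}
    for pair in range(spec.n_strands - 1):
        rungs = _pair_rungs(spec, pair)
        pair_rungs.append(rungs)
        gi, gj = strand_starts[pair], strand_starts[pair + 1]
        bonds = []
        for i, j in rungs:
            bonds.extend(_rung_bonds(spec, pair, gi, gj, i, j))
        designed.extend(bonds)
        joining[pair] = bonds

    # expected sheet partition: strands connect when their pair has a rung
    parent = list(range(spec.n_strands))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair, rungs in enumerate(pair_rungs):
        if rungs:
            parent[find(pair)] = find(pair + 1)
    comp: dict[int, set[int]] = {}
    for k in range(spec.n_strands):
        comp.setdefault(find(k), set()).add(k)
    expected = sorted(comp.values(), key=min)

    truth = SheetTruth(
        strand_ranges=[(s, s + L - 1) for s in strand_starts],
        designed_hbonds=sorted(designed),
        pair_rungs=pair_rungs,
        expected_sheets=expected,
        joining_hbonds=joining,
    )
    return structure, truth


def two_block_sheet_spec(block: int = 6, strand_length: int = 6) -> SheetSpec:
    """Twelve strands as two six-strand blocks sharing exactly one bridge pair.

    The register of the middle adjacent pair is reduced so only a single rung
    (two hydrogen bonds) joins the blocks.
    """
    spec = SheetSpec(n_strands=2 * block, strand_length=strand_length)
    mid = block - 1
    # smallest register of the facing parity leaves exactly one in-range rung
    spec.registers[mid] = 2 if mid % 2 else 0
    assert len(_pair_rungs(spec, mid)) == 1
    return spec


# ---------------------------------------------------------------------------
# chimeric dual-P-loop fixtures

PLOOP_PATTERN = "BBBEBBGAGAAAAA"
HELIX_RECIPE = "A" * 14


def ploop_fragment_coords(pattern: str = PLOOP_PATTERN) -> list[dict[str, np.ndarray]]:
    """A padded P-loop fragment from region-center torsions (pad + motif + pad)."""
    recipe = TorsionRecipe.from_abego("A" + pattern + "A")
    built = build_backbone(recipe)
    return [
        {name: a.coord.copy() for name, a in r.atoms.items()} for r in built.residues
    ]


def reference_ploop_ca(pattern: str = PLOOP_PATTERN) -> np.ndarray:
    """CA trace of the 14 motif residues of the idealized P-loop fragment."""
    frag = ploop_fragment_coords(pattern)
    return np.asarray([frag[i]["CA"] for i in range(1, 15)])


@dataclass
class DualPloopTruth:
    n_motif_matches: int
    n_pass_rmsd: int
    shares_sheet: bool
    sheet_size: int
    motif_start_indices: list[int]


def build_dual_ploop(
    share_sheet: bool,
    corrupt_one: bool = False,
    structure_id: str | None = None,
) -> tuple[Structure, DualPloopTruth]:
    """Chimera with two P-loop fragments whose flanking strands sit on one
    common sheet (positive) or two disjoint sheets (tandem-repeat decoy).

    With ``corrupt_one`` the second fragment is rebuilt at helix torsions so
    it no longer spells the motif.
    """
    L, nl = 6, 3
    if share_sheet:
        block_specs = [SheetSpec(n_strands=6, strand_length=L, linker_length=nl)]
        origins = [np.zeros(3)]
        # chain slots: strands 0,1 | motif 1 | strands 2,3 | motif 2 | strands 4,5
        motif_after_strand = [1, 3]
        strand_sources = [(0, k) for k in range(6)]
        sheet_size = 6
    else:
        block_specs = [
            SheetSpec(n_strands=3, strand_length=L, linker_length=nl),
            SheetSpec(n_strands=3, strand_length=L, linker_length=nl),
        ]
        origins = [np.zeros(3), np.array([80.0, 0.0, 0.0])]
        motif_after_strand = [1, 4]  # after A1 and after B1 (global strand slots)
        strand_sources = [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]
        sheet_size = 0

    built_blocks = [
        build_sheet(spec, origin=orig) for spec, orig in zip(block_specs, origins)
    ]

    def strand_fragment(block_idx: int, strand_idx: int) -> tuple[list[dict], list[dict]]:
        st, tr = built_blocks[block_idx]
        first, last = tr.strand_ranges[strand_idx]
        linker = [
            {n: a.coord.copy() for n, a in st.residues[i].atoms.items()}
            for i in range(first - block_specs[block_idx].linker_length, first)
        ]
        strand = [
            {n: a.coord.copy() for n, a in st.residues[i].atoms.items()}
            for i in range(first, last + 1)
        ]
        return linker, strand

    motif_frames = []
    for m in range(2):
        pattern = HELIX_RECIPE if (corrupt_one and m == 1) else PLOOP_PATTERN
        frag = ploop_fragment_coords(pattern)
        # well above the sheet plane and apart from each other in z
        shift = np.array([10.0, 2.0, 30.0 + 35.0 * m])
        motif_frames.append(
            [{n: c + shift for n, c in res.items()} for res in frag]
        )

    fragments: list[list[dict]] = []
    motif_starts: list[int] = []
    strand_spans: list[tuple[int, int]] = []
    cursor = 0
    next_motif = 0
    for slot, (b, k) in enumerate(strand_sources):
        linker, strand = strand_fragment(b, k)
        fragments.append(linker)
        cursor += len(linker)
        strand_spans.append((cursor, cursor + len(strand) - 1))
        fragments.append(strand)
        cursor += len(strand)
        if next_motif < 2 and slot == motif_after_strand[next_motif]:
            frag = motif_frames[next_motif]
            motif_starts.append(cursor + 1)  # skip the leading pad residue
            fragments.append(frag)
            cursor += len(frag)
            next_motif += 1

    residues = []
    for frag in fragments:
        for atom_coords in frag:
            i = len(residues)
            atoms = {n: Atom(n, n[0], c, 92.0) for n, c in atom_coords.items()}
            residues.append(Residue(seqnum=i + 1, index=i, aa="A", atoms=atoms))
    sid = structure_id or ("dual_shared" if share_sheet else "dual_decoy")
    structure = Structure(sid, residues)

    n_motifs = 1 if corrupt_one else 2
    truth = DualPloopTruth(
        n_motif_matches=n_motifs,
        n_pass_rmsd=n_motifs,
        shares_sheet=share_sheet and not corrupt_one,
        sheet_size=sheet_size if (share_sheet and not corrupt_one) else 0,
        motif_start_indices=motif_starts[:n_motifs] if corrupt_one else motif_starts,
    )
    return structure, truth


def build_helix_bundle(n_res: int = 40, structure_id: str = "helix_bundle") -> Structure:
    return build_backbone(TorsionRecipe.from_abego("A" * n_res), structure_id=structure_id)


def standard_fixture_set() -> list[tuple[Structure, DualPloopTruth | None]]:
    """Ten structures: 3 shared-sheet positives, 4 tandem decoys, 3 negatives."""
    out: list[tuple[Structure, DualPloopTruth | None]] = []
    for k in range(3):
        out.append(build_dual_ploop(True, structure_id=f"positive_{k}"))
    for k in range(4):
        out.append(build_dual_ploop(False, structure_id=f"decoy_{k}"))
    out.append(build_dual_ploop(True, corrupt_one=True, structure_id="negative_corrupt"))
    out.append((build_helix_bundle(structure_id="negative_helix"), None))
    plain, _ = build_sheet(SheetSpec(3, 6), structure_id="negative_sheet")
    out.append((plain, None))
    return out


# ---------------------------------------------------------------------------
# MSAs with planted conservation

def build_msa(
    n_rows: int,
    length: int,
    conserved_columns: dict[int, str] | list[int],
    gap_rows: int = 0,
    rng: np.random.Generator | int = 0,
    n_deletions: int = 12,
) -> Msa:
    """Alignment with planted zero-entropy columns and fragment rows.

    ``conserved_columns`` maps 1-based column positions to a fixed amino
    acid (a bare list draws one per column); the last ``gap_rows`` rows get
    ``n_deletions`` gaps against the full-length representative (row 0).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    aa = np.array(list(AA20))
    if isinstance(conserved_columns, list):
        conserved_columns = {c: str(rng.choice(aa)) for c in conserved_columns}
    rows = []
    for r in range(n_rows):
        seq = rng.choice(aa, size=length)
        for col, letter in conserved_columns.items():
            seq[col - 1] = letter
        rows.append("".join(seq))
    for r in range(n_rows - gap_rows, n_rows):
        positions = rng.choice(length, size=n_deletions, replace=False)
        row = list(rows[r])
        for p in positions:
            row[p] = "-"
        rows[r] = "".join(row)
    names = ["ref"] + [f"seq{k}" for k in range(1, n_rows)]
    return Msa(names, rows, ref_row=0)


# ---------------------------------------------------------------------------
# side-chain constellations

# idealized local side-chain geometry (CA at origin); hand-made but fixed
_SC_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "C": {
        "N": (-1.458, 0.0, 0.0), "CA": (0.0, 0.0, 0.0), "C": (0.551, 1.421, 0.0),
        "O": (1.702, 1.671, 0.0), "CB": (0.504, -0.872, 1.147),
        "SG": (1.773, -1.961, 0.735),
    },
    "D": {
        "N": (-1.458, 0.0, 0.0), "CA": (0.0, 0.0, 0.0), "C": (0.551, 1.421, 0.0),
        "O": (1.702, 1.671, 0.0), "CB": (0.504, -0.872, 1.147),
        "CG": (1.540, -1.898, 0.690), "OD1": (2.598, -1.571, 0.113),
        "OD2": (1.287, -3.109, 0.888),
    },
    "H": {
        "N": (-1.458, 0.0, 0.0), "CA": (0.0, 0.0, 0.0), "C": (0.551, 1.421, 0.0),
        "O": (1.702, 1.671, 0.0), "CB": (0.504, -0.872, 1.147),
        "CG": (1.531, -1.882, 0.665), "ND1": (2.839, -1.743, 1.064),
        "CD2": (1.390, -3.013, -0.062), "CE1": (3.525, -2.789, 0.637),
        "NE2": (2.689, -3.618, -0.023),
    },
    "S": {
        "N": (-1.458, 0.0, 0.0), "CA": (0.0, 0.0, 0.0), "C": (0.551, 1.421, 0.0),
        "O": (1.702, 1.671, 0.0), "CB": (0.504, -0.872, 1.147),
        "OG": (1.655, -1.817, 0.794),
    },
}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_constellation(
    residue_specs: list[tuple[str, tuple[float, float, float]]],
    rng: np.random.Generator | int = 0,
    structure_id: str = "constellation",
) -> Structure:
    """Structure of full-side-chain residues at the given CA positions.

    Each residue is the idealized template for its type under a random
    (seeded) rigid orientation.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    residues = []
    for i, (aa, ca_pos) in enumerate(residue_specs):
        if aa not in _SC_TEMPLATES:
            raise ValueError(f"no side-chain template for {aa!r}")
        rot = _random_rotation(rng)
        ca_pos = np.asarray(ca_pos, float)
        atoms = {}
        for name, local in _SC_TEMPLATES[aa].items():
            coord = rot @ np.asarray(local) + ca_pos
            atoms[name] = Atom(name, name[0], coord, 90.0)
        residues.append(Residue(seqnum=i + 1, index=i, aa=aa, atoms=atoms))
    return Structure(structure_id, residues)


CATALYTIC_QUERY_SPECS: list[tuple[str, tuple[float, float, float]]] = [
    ("C", (0.0, 0.0, 0.0)),
    ("D", (7.5, 1.0, 0.5)),
    ("D", (3.5, 6.5, -1.0)),
    ("H", (5.0, 3.0, 5.5)),
]


# ---------------------------------------------------------------------------
# tandem repeats and deletion pairs for alignment metrics

DOMAIN_ABEGO = "A" * 10 + "B" * 8 + "GG" + "A" * 12 + "GG" + "B" * 8  # 40 residues


def build_tandem_repeat(
    mutate_fraction: float = 0.0,
    rng: np.random.Generator | int = 0,
    structure_id: str = "tandem",
) -> Structure:
    """One domain followed by an identical rigid copy offset in space.

    ``mutate_fraction`` of the second copy's residues get a different amino
    acid (structure unchanged), fixing the ground-truth half-vs-half identity.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    recipe = TorsionRecipe.from_abego(DOMAIN_ABEGO)
    n = len(DOMAIN_ABEGO)
    seq1 = "".join(rng.choice(list(AA20), size=n))
    domain = build_backbone(recipe, sequence=seq1)
    seq2 = list(seq1)
    if mutate_fraction > 0:
        k = int(round(mutate_fraction * n))
        sites = rng.choice(n, size=k, replace=False)
        for s in sites:
            choices = [a for a in AA20 if a != seq2[s]]
            seq2[s] = str(rng.choice(choices))
    residues = []
    for r in domain.residues:
        atoms = {n_: Atom(a.name, a.element, a.coord.copy(), a.bfactor)
                 for n_, a in r.atoms.items()}
        residues.append(Residue(r.seqnum, r.index, r.aa, atoms))
    offset = np.array([60.0, 5.0, 0.0])
    for r in domain.residues:
        i = len(residues)
        atoms = {n_: Atom(a.name, a.element, a.coord + offset, a.bfactor)
                 for n_, a in r.atoms.items()}
        residues.append(Residue(i + 1, i, "".join(seq2)[r.index], atoms))
    return Structure(structure_id, residues)


def build_deletion_pair(
    rng: np.random.Generator | int = 0,
) -> tuple[Structure, Structure, list[tuple[int, int]]]:
    """A 60-residue fold and the same fold with residues 25-34 removed.

    Returns both structures and the true residue pairing.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    abego = "A" * 12 + "B" * 8 + "GG" + "A" * 14 + "GG" + "B" * 8 + "GG" + "A" * 12
    recipe = TorsionRecipe.from_abego(abego[:60])
    seq = "".join(rng.choice(list(AA20), size=60))
    full = build_backbone(recipe, sequence=seq, structure_id="full")
    keep = list(range(0, 25)) + list(range(35, 60))
    reduced = full.subset(keep, new_id="deleted")
    true_pairs = [(i, k) for k, i in enumerate(keep)]
    return full, reduced, true_pairs
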