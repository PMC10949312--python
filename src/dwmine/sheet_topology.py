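"""Backbone hydrogen bonds and beta-sheet topology.

Hydrogen bonds are scored with the Kabsch-Sander electrostatic model (the
DSSP energy), with the amide hydrogen rebuilt from the preceding carbonyl.
Bonds feed the classic bridge rules: a pair of residues forms a parallel or
antiparallel beta-bridge when the two required N-H...O=C bonds are present;
consecutive bridges form ladders, bulges join ladders across small gaps, and
sheets are the connected components of strands linked by bridges. The output
answers the mining question: do two P-loop candidates sit on one continuous
sheet, or on two separate ones (a tandem-repeat decoy)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import Config
from .motif_search import MotifMatch
from .structure_io import Structure

logger = logging.getLogger(__name__)

# Kabsch-Sander constants: partial charges 0.42 and 0.20, dimensional factor
# 332 (kcal*A/mol/e^2); E = 0.084 * 332 * (1/rON + 1/rCH - 1/rOH - 1/rCN).
KS_Q1Q2_F = 0.084 * 332.0
_MIN_DIST = 0.5  # Angstrom; closer atom pairs are treated as clashes, no bond


@dataclass(frozen=True)
class HBond:
    donor_res: int      # residue index on the N-H side
    acceptor_res: int   # residue index on the C=O side
    energy: float       # kcal/mol


@dataclass
class Strand:
    id: int
    first_res: int
    last_res: int  # inclusive

    def __contains__(self, res_index: int) -> bool:
        return self.first_res <= res_index <= self.last_res

    @property
    def length(self) -> int:
        return self.last_res - self.first_res + 1


@dataclass
class SheetGraph:
    strands: list[Strand]
    bridges: list[tuple[int, int, str]]   # (res_i, res_j, "parallel"|"antiparallel")
    sheets: list[frozenset[int]]          # strand-id sets, one per sheet

    def strand_of(self, res_index: int) -> Strand | None:
        for st in self.strands:
            if res_index in st:
                return st
        return None

    def sheet_of_strand(self, strand_id: int) -> int | None:
        for k, ids in enumerate(self.sheets):
            if strand_id in ids:
                return k
        return None


def reconstruct_amide_h(s: Structure, nh_bond_length: float = 1.0) -> list[np.ndarray | None]:
    """Amide H per residue: on N, along the previous residue's O->C direction.

    The first residue and prolines have no donor hydrogen (None).
    """
    out: list[np.ndarray | None] = []
    for i, res in enumerate(s.residues):
        if i == 0 or res.aa == "P":
            out.append(None)
            continue
        prev = s.residues[i - 1]
        N = res.coord("N")
        C, O = prev.coord("C"), prev.coord("O")
        if N is None or C is None or O is None:
            out.append(None)
            continue
        direction = C - O
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            out.append(None)
            continue
        out.append(N + nh_bond_length * direction / norm)
    return out


def hbond_energy(N, H, C, O) -> float:
    """Kabsch-Sander electrostatic energy (kcal/mol) for one N-H...O=C pair."""
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return 0.0
    return KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def detect_hbonds(s: Structure, cutoff: float = -0.5, nh_bond_length: float = 1.0) -> list[HBond]:
    """All backbone N-H...O=C bonds with Kabsch-Sander energy below ``cutoff``.

    Bonds between sequence neighbours (|i-j| < 2) are not reported; residues
    missing C or O are skipped as acceptors with a warning.
    """
    n = len(s.residues)
    hpos = reconstruct_amide_h(s, nh_bond_length)
    ca = []
    for r in s.residues:
        c = r.coord("CA")
        ca.append(c if c is not None else np.full(3, np.nan))
    ca = np.asarray(ca)
    valid_ca = np.all(np.isfinite(ca), axis=1)

    acceptors = []
    for j, res in enumerate(s.residues):
        if res.coord("C") is None or res.coord("O") is None:
            logger.warning("residue %s lacks C/O backbone atoms; skipped as acceptor", res.label)
            acceptors.append(False)
        else:
            acceptors.append(True)

    # CA-CA proximity prefilter (donor-acceptor pairs beyond 9 A cannot bond)
    idx = np.flatnonzero(valid_ca)
    tree = cKDTree(ca[idx])
    pairs = tree.query_pairs(r=9.0, output_type="ndarray")

    bonds: list[HBond] = []
    for a, b in pairs:
        i, j = int(idx[a]), int(idx[b])
        for donor, acceptor in ((i, j), (j, i)):
            if abs(donor - acceptor) < 2:
                continue
            if hpos[donor] is None or not acceptors[acceptor]:
                continue
            res_d, res_a = s.residues[donor], s.residues[acceptor]
            N = res_d.coord("N")
            if N is None:
                continue
            e = hbond_energy(N, hpos[donor], res_a.coord("C"), res_a.coord("O"))
            if e < cutoff:
                bonds.append(HBond(donor, acceptor, float(e)))
    bonds.sort(key=lambda h: (h.donor_res, h.acceptor_res))
    return bonds


def _find_bridges(hbonds: list[HBond], n_res: int) -> list[tuple[int, int, str]]:
    hb = {(b.donor_res, b.acceptor_res) for b in hbonds}

    def has(d: int, a: int) -> bool:
        return (d, a) in hb

    candidates: set[tuple[int, int]] = set()
    for d, a in hb:
        # every (i, j) whose bridge clauses could reference this bond
        for i, j in ((a + 1, d), (d - 1, a), (d, a + 1), (a, d - 1),
                     (d, a), (a, d), (d + 1, a - 1), (a - 1, d + 1)):
            lo, hi = min(i, j), max(i, j)
            if 0 <= lo and hi < n_res and hi - lo >= 3:
                candidates.add((lo, hi))

    bridges: list[tuple[int, int, str]] = []
    for i, j in sorted(candidates):
        parallel = (has(j, i - 1) and has(i + 1, j)) or (has(i, j - 1) and has(j + 1, i))
        antiparallel = (has(i, j) and has(j, i)) or (has(i - 1, j + 1) and has(j - 1, i + 1))
        if parallel:
            bridges.append((i, j, "parallel"))
        elif antiparallel:
            bridges.append((i, j, "antiparallel"))
    return bridges


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_sheet_graph(
    hbonds: list[HBond],
    s: Structure,
    min_strand_length: int = 1,
) -> SheetGraph:
    """Assemble strands and sheets from backbone hydrogen bonds.

    Strands are maximal runs of bridge-bearing residues; beta-bulges join two
    runs into one strand when the bridge gap is at most 1 residue on one
    strand and at most 4 on the partner strand. Sheets are connected
    components of strands linked by bridges.
    """
    n = len(s.residues)
    bridges = _find_bridges(hbonds, n)
    if not bridges:
        return SheetGraph([], [], [])

    bearing = sorted({i for i, _, _ in bridges} | {j for _, j, _ in bridges})
    uf = _UnionFind(bearing)
    bearing_set = set(bearing)
    for r in bearing:
        if r + 1 in bearing_set:
            uf.union(r, r + 1)

    # beta-bulge rule: same-type bridge pairs with a small gap on one strand
    # and a moderate gap on the other join their runs
    by_type: dict[str, list[tuple[int, int]]] = {"parallel": [], "antiparallel": []}
    for i, j, t in bridges:
        by_type[t].append((i, j))
    for t, pairs in by_type.items():
        for k, (i1, j1) in enumerate(pairs):
            for i2, j2 in pairs[k + 1 :]:
                for (a1, b1), (a2, b2) in (((i1, j1), (i2, j2)), ((j1, i1), (j2, i2))):
                    ga = abs(a2 - a1) - 1
                    gb = abs(b2 - b1) - 1
                    if 0 <= ga <= 4 and 0 <= gb <= 4 and (ga <= 1 or gb <= 1):
                        uf.union(a1, a2)
                        uf.union(b1, b2)

    groups: dict[int, list[int]] = {}
    for r in bearing:
        groups.setdefault(uf.find(r), []).append(r)
    spans = sorted((min(g), max(g)) for g in groups.values())
    strands = [
        Strand(id=k, first_res=a, last_res=b)
        for k, (a, b) in enumerate(spans)
        if b - a + 1 >= min_strand_length
    ]

    def strand_id_of(res: int) -> int | None:
        for st in strands:
            if res in st:
                return st.id
        return None

    graph = nx.Graph()
    graph.add_nodes_from(st.id for st in strands)
    for i, j, _ in bridges:
        si, sj = strand_id_of(i), strand_id_of(j)
        if si is not None and sj is not None and si != sj:
            graph.add_edge(si, sj)
    sheets = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: min(c),
    )
    return SheetGraph(strands=strands, bridges=bridges, sheets=sheets)


def flanking_strands(m: MotifMatch, g: SheetGraph) -> tuple[Strand | None, Strand | None]:
    """The nearest strands before and after (or overlapping) the motif start.

    ``before`` is the strand ending last among those entirely before the
    motif start; ``after`` is the earliest strand that reaches the motif
    start or beyond — the motif's own leading beta run, when it bonds into a
    sheet, is its after-flank.
    """
    before = None
    after = None
    for st in g.strands:
        if st.last_res < m.start_index:
            if before is None or st.last_res > before.last_res:
                before = st
        else:
            if after is None or st.first_res < after.first_res:
                after = st
    return before, after


def ploops_share_sheet(
    matches: list[MotifMatch],
    g: SheetGraph,
) -> dict[int, set[int]]:
    """Sheets carrying two or more P-loop candidates.

    A match belongs to every sheet containing either of its flanking strands.
    Returns {sheet index: set of match indices} restricted to sheets holding
    at least two distinct matches — the dual-P-loop criterion.
    """
    sheet_members: dict[int, set[int]] = {}
    for mi, m in enumerate(matches):
        for st in flanking_strands(m, g):
            if st is None:
                continue
            sheet = g.sheet_of_strand(st.id)
            if sheet is not None:
                sheet_members.setdefault(sheet, set()).add(mi)
    return {sheet: ms for sheet, ms in sheet_members.items() if len(ms) >= 2}


def export_strands_tsv(g: SheetGraph, s: Structure, path) -> None:
    """One row per strand: sheet id, strand id, author first/last residue."""
    import pandas as pd

    rows = []
    for st in g.strands:
        rows.append(
            {
                "sheet": g.sheet_of_strand(st.id),
                "strand": st.id,
                "first_resnum": s.residues[st.first_res].seqnum,
                "last_resnum": s.residues[st.last_res].seqnum,
            }
        )
    pd.DataFrame(rows, columns=["sheet", "strand", "first_resnum", "last_resnum"]).to_csv(
        path, sep="\t", index=False
    )


def sheet_graph_to_json(g: SheetGraph) -> dict:
    return {
        "strands": [[st.id, st.first_res, st.last_res] for st in g.strands],
        "bridges": [list(b) for b in g.bridges],
        "sheets": [sorted(c) for c in g.sheets],
    }
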