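import numpy as np
import pytest

from dwmine.motif_search import MotifMatch
from dwmine.sheet_topology import (
    SheetGraph,
    Strand,
    build_sheet_graph,
    detect_hbonds,
    flanking_strands,
    hbond_energy,
    ploops_share_sheet,
    reconstruct_amide_h,
)
from dwmine.synthetic_data import (
    SheetSpec,
    build_backbone,
    build_sheet,
    TorsionRecipe,
    two_block_sheet_spec,
)
from conftest import random_rotation

SHEET_SPECS = [
    SheetSpec(2, 6),
    SheetSpec(3, 6),
    SheetSpec(2, 8, topology="parallel"),
    SheetSpec(4, 6, topology="parallel"),
    SheetSpec(4, 7, topology="mixed"),
    SheetSpec(6, 6),
    two_block_sheet_spec(),
]


def brute_force_sheet_partition(bridges, strands):
    """Independent union-find over strand blocks touched by bridges."""
    def block_of(res):
        for k, st in enumerate(strands):
            if st.first_res <= res <= st.last_res:
                return k
        return None

    parent = list(range(len(strands)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in bridges:
        bi, bj = block_of(i), block_of(j)
        if bi is not None and bj is not None and bi != bj:
            parent[find(bi)] = find(bj)
    comp = {}
    for k in range(len(strands)):
        comp.setdefault(find(k), set()).add(k)
    return sorted(comp.values(), key=min)


@pytest.mark.parametrize("spec", SHEET_SPECS, ids=lambda s: f"{s.n_strands}x{s.strand_length}-{s.topology[0] if s.topology else 'NA'}")
def test_designed_bonds_recovered_and_partition_matches(spec):
    s, truth = build_sheet(spec)
    hbonds = detect_hbonds(s)
    detected = {(b.donor_res, b.acceptor_res) for b in hbonds}
    assert set(truth.designed_hbonds) <= detected

    g = build_sheet_graph(hbonds, s)
    assert len(g.strands) == spec.n_strands
    # each detected strand lies within exactly one designed strand block
    block_of_strand = {}
    for st in g.strands:
        blocks = [
            k for k, (a, b) in enumerate(truth.strand_ranges)
            if a <= st.first_res and st.last_res <= b
        ]
        assert len(blocks) == 1
        block_of_strand[st.id] = blocks[0]
    detected_partition = sorted(
        ({block_of_strand[i] for i in sheet} for sheet in g.sheets), key=min
    )
    assert detected_partition == truth.expected_sheets
    # cross-check against an independent union-find over the bridges
    oracle = brute_force_sheet_partition(
        g.bridges, [Strand(k, a, b) for k, (a, b) in enumerate(truth.strand_ranges)]
    )
    assert oracle == truth.expected_sheets


def test_energies_match_direct_formula():
    s, truth = build_sheet(SheetSpec(2, 6))
    hpos = reconstruct_amide_h(s)
    for b in detect_hbonds(s):
        N = s.residues[b.donor_res].coord("N")
        H = hpos[b.donor_res]
        C = s.residues[b.acceptor_res].coord("C")
        O = s.residues[b.acceptor_res].coord("O")
        q = 0.084 * 332.0
        expected = q * (
            1 / np.linalg.norm(O - N) + 1 / np.linalg.norm(C - H)
            - 1 / np.linalg.norm(O - H) - 1 / np.linalg.norm(C - N)
        )
        assert b.energy == pytest.approx(expected, abs=1e-9)
        assert b.energy < -0.5


def test_isolated_strand_has_no_interstrand_bonds():
    s, _ = build_sheet(SheetSpec(1, 6))
    assert detect_hbonds(s) == []
    g = build_sheet_graph([], s)
    assert g.strands == [] and g.sheets == []


def test_distant_strands_do_not_bond():
    a, _ = build_sheet(SheetSpec(1, 6))
    b, _ = build_sheet(SheetSpec(1, 6), origin=np.array([0.0, 20.0, 0.0]))
    residues = []
    for src in (a, b):
        for r in src.residues:
            from dwmine.structure_io import Residue
            i = len(residues)
            residues.append(Residue(i + 1, i, r.aa, dict(r.atoms)))
    from dwmine.structure_io import Structure
    merged = Structure("far", residues)
    inter = [
        hb for hb in detect_hbonds(merged)
        if (hb.donor_res < len(a.residues)) != (hb.acceptor_res < len(a.residues))
    ]
    assert inter == []


def test_two_block_sheet_merges_and_splits():
    spec = two_block_sheet_spec()
    s, truth = build_sheet(spec, structure_id="twelve")
    hbonds = detect_hbonds(s)
    g = build_sheet_graph(hbonds, s)
    assert [len(c) for c in g.sheets] == [12]
    joining = set(truth.joining_hbonds[5])
    reduced = [b for b in hbonds if (b.donor_res, b.acceptor_res) not in joining]
    g2 = build_sheet_graph(reduced, s)
    assert sorted(len(c) for c in g2.sheets) == [6, 6]


def test_proline_never_donates():
    s, truth = build_sheet(SheetSpec(2, 6))
    donor = truth.designed_hbonds[0][0]
    s.residues[donor].aa = "P"
    detected = {(b.donor_res, b.acceptor_res) for b in detect_hbonds(s)}
    assert all(d != donor for d, _ in detected)


def test_rigid_invariance_of_sheet_graph(rng):
    s, _ = build_sheet(SheetSpec(3, 6))
    g = build_sheet_graph(detect_hbonds(s), s)
    moved = s.transformed(random_rotation(rng), rng.normal(size=3) * 50)
    g2 = build_sheet_graph(detect_hbonds(moved), moved)
    assert [(x.first_res, x.last_res) for x in g.strands] == [
        (x.first_res, x.last_res) for x in g2.strands
    ]
    assert g.sheets == g2.sheets
    assert sorted(g.bridges) == sorted(g2.bridges)


def test_adding_bonds_never_splits_sheets():
    s, truth = build_sheet(two_block_sheet_spec())
    hbonds = detect_hbonds(s)
    joining = set(truth.joining_hbonds[5])
    without = [b for b in hbonds if (b.donor_res, b.acceptor_res) not in joining]
    g_small = build_sheet_graph(without, s)
    g_full = build_sheet_graph(hbonds, s)
    # every sheet of the richer graph is a union of sheets of the poorer one
    for sheet in g_small.sheets:
        assert any(sheet <= big for big in g_full.sheets)


def _strand_graph(strands, sheets):
    return SheetGraph(
        strands=[Strand(k, a, b) for k, (a, b) in enumerate(strands)],
        bridges=[],
        sheets=[frozenset(c) for c in sheets],
    )


def _match_at(start, length=14):
    return MotifMatch(start, length, "B" * length, np.zeros((length, 3)), rmsd_to_ref=0.0)


class TestFlankingAndSharing:
    def test_flanks_before_and_after(self):
        g = _strand_graph([(40, 46), (50, 55)], [{0, 1}])
        before, after = flanking_strands(_match_at(50), g)
        assert (before.first_res, before.last_res) == (40, 46)
        assert (after.first_res, after.last_res) == (50, 55)

    def test_no_strand_before(self):
        g = _strand_graph([(60, 66)], [{0}])
        before, after = flanking_strands(_match_at(50), g)
        assert before is None and after.first_res == 60

    def test_no_strand_after(self):
        g = _strand_graph([(10, 16)], [{0}])
        before, after = flanking_strands(_match_at(50), g)
        assert after is None and before.last_res == 16

    def test_two_matches_one_sheet(self):
        g = _strand_graph([(0, 5), (20, 25), (40, 45)], [{0, 1, 2}])
        shared = ploops_share_sheet([_match_at(8), _match_at(28)], g)
        assert shared == {0: {0, 1}}

    def test_two_matches_disjoint_sheets(self):
        g = _strand_graph([(0, 5), (20, 25), (40, 45), (60, 65)], [{0, 1}, {2, 3}])
        shared = ploops_share_sheet([_match_at(8), _match_at(48)], g)
        assert shared == {}

    def test_single_match_never_shares(self):
        g = _strand_graph([(0, 5), (20, 25)], [{0, 1}])
        assert ploops_share_sheet([_match_at(8)], g) == {}


def test_helix_produces_no_bridges():
    s = build_backbone(TorsionRecipe.from_abego("A" * 25))
    hbonds = detect_hbonds(s)
    assert hbonds  # the helical i+4 -> i ladder is real hydrogen bonding
    g = build_sheet_graph(hbonds, s)
    assert g.strands == [] and g.sheets == []
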