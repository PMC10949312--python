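import itertools

import numpy as np
import pytest

from dwmine.align_cluster import (
    align_pair,
    all_vs_all_tm,
    d0_from_length,
    greedy_cluster,
    pick_representative,
    tm_score,
)
from dwmine.superpose import kabsch
from dwmine.synthetic_data import (
    TorsionRecipe,
    build_backbone,
    build_deletion_pair,
)
from conftest import random_rotation


def test_d0_closed_form():
    # 1.24 * 85^(1/3) - 1.8, evaluated independently
    assert d0_from_length(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-12)
    assert d0_from_length(100) == pytest.approx(3.652069, abs=1e-5)
    with pytest.raises(ValueError):
        d0_from_length(15)


def test_tm_identity_is_one(rng):
    coords = rng.normal(size=(40, 3)) * 8
    pairs = [(i, i) for i in range(40)]
    assert tm_score(pairs, coords, coords, 40) == pytest.approx(1.0)


def test_tm_all_distances_at_d0_gives_half():
    """Each aligned pair at exactly d0 contributes 1/2 per the score formula."""
    n = 20
    d0 = d0_from_length(n)
    a = np.zeros((n, 3))
    a[:, 0] = np.arange(n) * 3.8
    b = a.copy()
    # displacements of size d0 with zero net translation and rotation moment
    signs = np.resize([1.0, -1.0, -1.0, 1.0], n)
    b[:, 2] += d0 * signs
    pairs = [(i, i) for i in range(n)]
    fixed = tm_score(pairs, a, b, n, superpose=False)
    assert fixed == pytest.approx(0.5, abs=1e-12)
    assert tm_score(pairs, a, b, n) >= fixed - 1e-12


def test_tm_rigid_invariance(rng):
    a = rng.normal(size=(30, 3)) * 6
    b = a + rng.normal(size=(30, 3)) * 1.0
    pairs = [(i, i) for i in range(30)]
    base = tm_score(pairs, a, b, 30)
    moved = a @ random_rotation(rng).T + rng.normal(size=3) * 25
    assert tm_score(pairs, moved, b, 30) == pytest.approx(base, abs=1e-6)
    assert base <= 1.0


def _fold(n=60, seed=0):
    abego = "A" * 12 + "B" * 8 + "GG" + "A" * 14 + "GG" + "B" * 8 + "GG" + "A" * 12
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    return build_backbone(TorsionRecipe.from_abego(abego[:n]), sequence=seq)


def test_align_pair_self_identity():
    s = _fold()
    res = align_pair(s, s)
    assert res.tm_by_A == pytest.approx(1.0, abs=1e-9)
    assert res.tm_by_B == pytest.approx(1.0, abs=1e-9)
    assert res.pairs == [(i, i) for i in range(len(s))]


def test_align_pair_rigid_copy(rng):
    s = _fold()
    moved = s.transformed(random_rotation(rng), rng.normal(size=3) * 30)
    res = align_pair(s, moved)
    assert res.tm("min") == pytest.approx(1.0, abs=1e-6)


def test_align_pair_pairs_strictly_increasing():
    full, reduced, _ = build_deletion_pair(3)
    res = align_pair(full, reduced)
    a_idx = [p[0] for p in res.pairs]
    b_idx = [p[1] for p in res.pairs]
    assert a_idx == sorted(set(a_idx)) and b_idx == sorted(set(b_idx))


def test_deletion_fixture_recovery_beats_oracle():
    """The aligner recovers the true pairing around an internal deletion and
    reaches at least the TM of a refinement seeded with the true pairs."""
    full, reduced, true_pairs = build_deletion_pair(0)
    res = align_pair(full, reduced)
    recovered = len(set(true_pairs) & set(res.pairs))
    assert recovered >= 48  # of 50 true pairs
    oracle = tm_score(true_pairs, full.ca_coords(), reduced.ca_coords(), len(reduced))
    assert res.tm_by_B >= oracle - 0.02


def test_align_pair_symmetry():
    full, reduced, _ = build_deletion_pair(1)
    ab = align_pair(full, reduced)
    ba = align_pair(reduced, full)
    assert ab.tm_by_A == pytest.approx(ba.tm_by_B, abs=1e-3)
    assert ab.tm_by_B == pytest.approx(ba.tm_by_A, abs=1e-3)


def test_align_pair_rejects_short_or_degenerate():
    short = build_backbone(TorsionRecipe.from_abego("A" * 10))
    with pytest.raises(ValueError):
        align_pair(short, short)


def _table(values):
    return {pair: v for pair, v in values.items()}


class TestClustering:
    def test_all_similar_one_cluster(self):
        ids = ["a", "b", "c"]
        table = {("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): 0.9}
        assert greedy_cluster(ids, table) == [["a", "b", "c"]]

    def test_single_linkage_chains(self):
        ids = ["a", "b", "c"]
        table = {("a", "b"): 0.6, ("b", "c"): 0.6, ("a", "c"): 0.2}
        assert greedy_cluster(ids, table) == [["a", "b", "c"]]

    def test_all_below_threshold_singletons(self):
        ids = ["a", "b", "c"]
        table = {("a", "b"): 0.3, ("b", "c"): 0.2, ("a", "c"): 0.1}
        assert greedy_cluster(ids, table) == [["a"], ["b"], ["c"]]

    def test_missing_pair_raises(self):
        with pytest.raises(KeyError):
            greedy_cluster(["a", "b"], {})

    def test_agreement_with_brute_force_components(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            ids = [f"s{k}" for k in range(n)]
            table = {
                (a, b): float(rng.uniform(0, 1))
                for a, b in itertools.combinations(ids, 2)
            }
            clusters = greedy_cluster(ids, table, 0.5)
            # brute force: repeated closure over the edge relation
            comp = {i: {i} for i in ids}
            changed = True
            while changed:
                changed = False
                for (a, b), v in table.items():
                    if v >= 0.5 and comp[a] is not comp[b]:
                        merged = comp[a] | comp[b]
                        for m in merged:
                            comp[m] = merged
                        changed = True
            expected = sorted({frozenset(c) for c in comp.values()}, key=min)
            assert [frozenset(c) for c in clusters] == expected

    def test_partition_property(self, rng):
        ids = [f"s{k}" for k in range(8)]
        table = {
            (a, b): float(rng.uniform(0, 1)) for a, b in itertools.combinations(ids, 2)
        }
        clusters = greedy_cluster(ids, table, 0.5)
        flat = [m for c in clusters for m in c]
        assert sorted(flat) == sorted(ids)


class TestRepresentative:
    def test_singleton(self):
        assert pick_representative(["x"], {}) == "x"

    def test_largest_mean_tm_wins(self):
        table = {("a", "b"): 0.9, ("a", "c"): 0.7, ("b", "c"): 0.8}
        # means: a = 0.80, b = 0.85, c = 0.75
        assert pick_representative(["a", "b", "c"], table) == "b"

    def test_tie_prefers_smallest_id(self):
        table = {("a", "b"): 0.8}
        assert pick_representative(["a", "b"], table) == "a"


def test_all_vs_all_clusters_folds(rng):
    helixy = build_backbone(TorsionRecipe.from_abego("A" * 40), structure_id="a_helix")
    helixy2 = helixy.transformed(random_rotation(rng), rng.normal(size=3) * 15)
    helixy2.id = "b_helix"
    other = _fold(seed=9)
    other.id = "c_fold"
    ids, table = all_vs_all_tm([helixy, helixy2, other])
    clusters = greedy_cluster(ids, table, 0.5)
    by_member = {m: tuple(c) for c in clusters for m in c}
    assert by_member["a_helix"] == by_member["b_helix"]
    assert by_member["c_fold"] != by_member["a_helix"]
    rep = pick_representative(list(by_member["a_helix"]), table)
    assert rep in ("a_helix", "b_helix")
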