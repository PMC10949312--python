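import math

import numpy as np
import pytest

from dwmine.structure_io import write_structure
from dwmine.symmetry_conservation import (
    Msa,
    filter_msa,
    half_alignment,
    half_identity,
    net_charge,
    read_msa,
    site_entropy,
    top_conserved,
)
from dwmine.synthetic_data import (
    TorsionRecipe,
    build_backbone,
    build_helix_bundle,
    build_msa,
    build_tandem_repeat,
)


def msa_from_rows(*rows, ref_row=0):
    return Msa([f"r{k}" for k in range(len(rows))], list(rows), ref_row)


class TestFilterMsa:
    def test_identical_row_kept(self):
        m = msa_from_rows("ACDEF", "ACDEF")
        assert len(filter_msa(m).rows) == 2

    def test_eleven_deletions_dropped(self):
        ref = "A" * 20
        row = "-" * 11 + "A" * 9
        m = msa_from_rows(ref, row)
        assert filter_msa(m, max_gaps=10).rows == [ref]

    def test_exactly_ten_deletions_kept(self):
        ref = "A" * 20
        row = "-" * 10 + "A" * 10
        assert len(filter_msa(msa_from_rows(ref, row), max_gaps=10).rows) == 2

    def test_insertions_against_ref_not_counted(self):
        # column 2 is a gap in the representative: other rows' residues there
        # are insertions and the representative's own gap is not a deletion
        m = msa_from_rows("AC-EF", "ACKEF", "A--EF")
        kept = filter_msa(m, max_gaps=0)
        assert kept.rows == ["AC-EF", "ACKEF"]

    def test_max_gaps_zero_limit(self):
        m = msa_from_rows("ACDEF", "AC-EF", "ACDEF")
        assert filter_msa(m, max_gaps=0).rows == ["ACDEF", "ACDEF"]

    def test_monotone_in_max_gaps(self):
        rows = ["ACDEFGHIKL"] + [
            "ACDEF" + "-" * k + "GHIKL"[k:] if k <= 5 else "ACDEFGHIKL"
            for k in range(5)
        ]
        m = msa_from_rows(*rows)
        kept_sizes = [len(filter_msa(m, g).rows) for g in range(6)]
        assert kept_sizes == sorted(kept_sizes)

    def test_ref_row_index_tracked_after_filtering(self):
        m = msa_from_rows("---DEFGHIK", "ACDDEFGHIK", "AC-DEFGHIK", ref_row=1)
        kept = filter_msa(m, max_gaps=1)
        assert kept.names == ["r1", "r2"]  # r0 has 3 deletions vs the ref
        assert kept.rows[kept.ref_row] == "ACDDEFGHIK"


class TestSiteEntropy:
    def test_pure_column_zero(self):
        m = msa_from_rows("D", "D", "D", "D")
        (e,) = site_entropy(m).entries
        assert e.entropy == 0.0
        assert e.coverage == 1.0

    def test_uniform_twenty_way(self):
        rows = list("ACDEFGHIKLMNPQRSTVWY")
        m = msa_from_rows(*rows)
        (e,) = site_entropy(m).entries
        assert e.entropy == pytest.approx(math.log(20), abs=1e-12)

    def test_three_to_one_column(self):
        m = msa_from_rows("D", "D", "D", "E")
        (e,) = site_entropy(m).entries
        assert e.entropy == pytest.approx(0.5623351446, abs=1e-9)

    def test_gaps_excluded_and_coverage(self):
        m = msa_from_rows("D", "D", "-", "-")
        (e,) = site_entropy(m).entries
        assert e.entropy == 0.0
        assert e.coverage == 0.5

    def test_row_permutation_invariance(self):
        rows = ["ACD", "AKD", "QCD", "AC-"]
        e1 = [x.entropy for x in site_entropy(msa_from_rows(*rows)).entries]
        e2 = [x.entropy for x in site_entropy(msa_from_rows(rows[0], *rows[:0:-1])).entries]
        assert e1 == pytest.approx(e2)

    def test_resnum_tracks_ungapped_reference(self):
        m = msa_from_rows("A-CD", "AKCD")
        entries = site_entropy(m).entries
        assert [e.resnum for e in entries] == [1, 2, 3]
        assert [e.aa for e in entries] == ["A", "C", "D"]


class TestTopConserved:
    def test_planted_columns_recovered(self):
        msa = build_msa(30, 120, list(range(61, 71)), rng=5)
        profile = site_entropy(msa)
        assert sorted(top_conserved(profile, (61, 100), 10)) == list(range(61, 71))

    def test_short_window_returns_all(self):
        msa = build_msa(10, 50, [5], rng=2)
        profile = site_entropy(msa)
        got = top_conserved(profile, (5, 8), 10)
        assert len(got) == 4

    def test_n_zero_empty(self):
        msa = build_msa(10, 50, [5], rng=2)
        assert top_conserved(site_entropy(msa), (1, 50), 0) == []

    def test_ascending_entropy_order(self):
        msa = build_msa(40, 80, list(range(10, 15)), rng=7)
        profile = site_entropy(msa)
        top = top_conserved(profile, (1, 80), 12)
        by_num = {e.resnum: e.entropy for e in profile.entries}
        entropies = [by_num[r] for r in top]
        assert entropies == sorted(entropies)


def test_read_msa_fasta_and_a3m(tmp_path):
    fasta = tmp_path / "aln.fasta"
    fasta.write_text(">ref\nAC-DE\n>other\nACKDE\n")
    m = read_msa(fasta, ref_name="ref")
    assert m.rows == ["AC-DE", "ACKDE"]
    a3m = tmp_path / "aln.a3m"
    a3m.write_text(">ref\nACDE\n>other\nACkDE\n")  # lowercase = insertion
    m2 = read_msa(a3m)
    assert m2.rows == ["ACDE", "ACDE"]


class TestHalfIdentity:
    def test_exact_tandem_repeat_is_100(self):
        s = build_tandem_repeat(0.0, rng=0)
        ha = half_alignment(s, [(1, 40)], [(41, 80)])
        assert ha.identity == pytest.approx(100.0)
        assert not ha.low_similarity

    def test_half_mutated_repeat_is_50(self):
        s = build_tandem_repeat(0.5, rng=1)
        assert half_identity(s, ([(1, 40)], [(41, 80)])) == pytest.approx(50.0, abs=5.0)

    def test_unrelated_halves_flagged(self):
        helix = build_helix_bundle(40)
        strandy = build_backbone(
            TorsionRecipe.from_abego("B" * 18 + "GG" + "B" * 20),
            structure_id="strands",
        )
        residues = []
        from dwmine.structure_io import Atom, Residue, Structure

        for src, shift in ((helix, 0.0), (strandy, 80.0)):
            for r in src.residues:
                i = len(residues)
                atoms = {
                    n: Atom(a.name, a.element, a.coord + np.array([shift, 0, 0]), a.bfactor)
                    for n, a in r.atoms.items()
                }
                residues.append(Residue(i + 1, i, r.aa, atoms))
        s = Structure("chimera", residues)
        ha = half_alignment(s, [(1, 40)], [(41, 80)])
        assert ha.low_similarity
        assert ha.tm < 0.5

    def test_swap_symmetry(self):
        s = build_tandem_repeat(0.3, rng=2)
        a = half_identity(s, ([(1, 40)], [(41, 80)]))
        b = half_identity(s, ([(41, 80)], [(1, 40)]))
        assert a == pytest.approx(b, abs=0.5)

    def test_overlapping_halves_rejected(self):
        s = build_tandem_repeat(0.0, rng=0)
        with pytest.raises(ValueError):
            half_identity(s, ([(1, 45)], [(40, 80)]))

    def test_short_half_rejected(self):
        s = build_tandem_repeat(0.0, rng=0)
        with pytest.raises(ValueError):
            half_identity(s, ([(1, 10)], [(41, 80)]))


class TestNetCharge:
    def test_glycines_zero(self):
        s = build_backbone(TorsionRecipe.from_abego("A" * 5), sequence="GGGGG")
        assert net_charge(s) == 0

    def test_hand_count(self):
        s = build_backbone(TorsionRecipe.from_abego("A" * 5), sequence="KKRDE")
        assert net_charge(s) == 1

    def test_histidine_excluded(self):
        s = build_backbone(TorsionRecipe.from_abego("A" * 4), sequence="HHKD")
        assert net_charge(s) == 0

    def test_empty_range(self):
        s = build_backbone(TorsionRecipe.from_abego("A" * 5), sequence="KKRDE")
        assert net_charge(s, (100, 200)) == 0

    def test_subrange_author_numbering(self):
        s = build_backbone(TorsionRecipe.from_abego("A" * 5), sequence="KKRDE")
        assert net_charge(s, (1, 3)) == 3
        assert net_charge(s, [(1, 2), (4, 5)]) == 0
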