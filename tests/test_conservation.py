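"""Shannon conservation entropy, structure mapping, pairwise
identity/similarity, and the UPGMA dendrogram."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermocontacts.conservation import (AlignmentBlock, ConservationError,
                                         MAX_ENTROPY_BITS, build_dendrogram,
                                         identity_similarity_matrix,
                                         map_profiles_to_alignment,
                                         map_to_structure,
                                         pairwise_identity_similarity,
                                         shannon_entropy)
from thermocontacts.structure_io import ResidueLabel

from conftest import make_model


def _msa(rows, ids=None):
    return AlignmentBlock(ids=ids or [f"s{i}" for i in range(len(rows))],
                          rows=list(rows))


class TestEntropy:
    def test_conserved_column_zero(self):
        prof = shannon_entropy(_msa(["A", "A", "A", "A"]))
        assert prof.raw_bits[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_symbol_column_one_bit(self):
        prof = shannon_entropy(_msa(["A", "A", "V", "V"]))
        assert prof.raw_bits[0] == pytest.approx(1.0)
        assert prof.normalized[0] == pytest.approx(1 / MAX_ENTROPY_BITS)

    def test_uniform_column_maximal(self):
        rows = list("ACDEFGHIKLMNPQRSTVWY")
        prof = shannon_entropy(_msa(rows))
        assert prof.normalized[0] == pytest.approx(1.0)

    def test_all_gap_column_missing_not_zero(self):
        prof = shannon_entropy(_msa(["A-", "V-", "L-"]))
        assert np.isnan(prof.raw_bits[1])
        assert not np.isnan(prof.raw_bits[0])

    def test_gap_policy_exclude_renormalizes(self):
        # A, A, gap, gap -> distribution {A: 1.0} -> H = 0
        prof = shannon_entropy(_msa(["A", "A", "-", "-"]))
        assert prof.raw_bits[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.low_confidence[0] == False  # noqa: E712 (exactly 50% gaps)

    def test_majority_gap_column_flagged(self):
        prof = shannon_entropy(_msa(["A", "-", "-", "-"]))
        assert prof.low_confidence[0]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                    min_size=4, max_size=12),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, column, rnd):
        shuffled = column[:]
        rnd.shuffle(shuffled)
        h1 = shannon_entropy(_msa(list(column))).raw_bits[0]
        h2 = shannon_entropy(_msa(list(shuffled))).raw_bits[0]
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_single_sequence_rejected(self):
        with pytest.raises(ConservationError):
            shannon_entropy(_msa(["ACD"]))


def _chain_model(seq3):
    return make_model([(name, [("CA", "C", (10.0 * i, 0, 0))])
                       for i, name in enumerate(seq3)])


class TestMapToStructure:
    def test_gap_free_query_identity_mapping(self):
        model = _chain_model(["ALA", "GLY", "SER"])
        msa = _msa(["AGS", "AGT", "AGA"], ids=["query", "h1", "h2"])
        prof = shannon_entropy(msa)
        mapping = map_to_structure(prof, msa, "query", model, "A")
        assert len(mapping) == 3
        assert mapping[ResidueLabel("A", 1, "", "ALA")] == \
            pytest.approx(prof.normalized[0])

    def test_internal_gap_columns_skipped(self):
        model = _chain_model(["ALA", "GLY", "SER"])
        msa = _msa(["A-G-S", "AVGLS", "AIGMS"], ids=["query", "h1", "h2"])
        prof = shannon_entropy(msa)
        mapping = map_to_structure(prof, msa, "query", model, "A")
        assert len(mapping) == 3
        # column 2 (G, conserved) lands on residue 2
        assert mapping[ResidueLabel("A", 2, "", "GLY")] == \
            pytest.approx(prof.normalized[2])

    def test_absent_query_rejected(self):
        model = _chain_model(["ALA"])
        msa = _msa(["A", "V"], ids=["h1", "h2"])
        prof = shannon_entropy(msa)
        with pytest.raises(ConservationError, match="not in alignment"):
            map_to_structure(prof, msa, "query", model, "A")

    def test_gross_length_mismatch_rejected(self):
        model = _chain_model(["ALA", "GLY", "SER", "VAL", "LEU"])
        msa = _msa(["AG", "AV"], ids=["query", "h1"])
        prof = shannon_entropy(msa)
        with pytest.raises(ConservationError, match="does not map"):
            map_to_structure(prof, msa, "query", model, "A")


class TestPairwise:
    def test_identical_sequences_100(self):
        pid, psim = pairwise_identity_similarity("ACDEFGHIKL", "ACDEFGHIKL")
        assert pid == pytest.approx(100.0)
        assert psim == pytest.approx(100.0)

    def test_three_of_four_identity(self):
        pid, _ = pairwise_identity_similarity("AAAA", "AAAV")
        assert pid == pytest.approx(75.0)

    def test_similar_not_identical_counted(self):
        # I/L scores +2 in BLOSUM62: similar but not identical
        pid, psim = pairwise_identity_similarity("AAIA", "AALA")
        assert pid == pytest.approx(75.0)
        assert psim == pytest.approx(100.0)

    def test_symmetric_and_identity_le_similarity(self):
        a, b = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "MKSAYIARQRQISFVKFHFSRQLEERLGLIEVQAP"
        pid_ab, psim_ab = pairwise_identity_similarity(a, b)
        pid_ba, psim_ba = pairwise_identity_similarity(b, a)
        assert pid_ab == pytest.approx(pid_ba)
        assert psim_ab == pytest.approx(psim_ba)
        assert pid_ab <= psim_ab

    def test_empty_sequence_rejected(self):
        with pytest.raises(ConservationError):
            pairwise_identity_similarity("", "AAA")


class TestDendrogram:
    def test_closest_pair_becomes_sister_clade(self):
        from io import StringIO
        from Bio import Phylo

        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        newick = build_dendrogram(d, ["A", "B", "C"])
        tree = Phylo.read(StringIO(newick), "newick")
        ab = tree.common_ancestor(["A", "B"])
        assert {leaf.name for leaf in ab.get_terminals()} == {"A", "B"}

    def test_zero_distance_cherry_has_zero_height(self):
        d = np.array([[0, 0, 5], [0, 0, 5], [5, 5, 0]], dtype=float)
        newick = build_dendrogram(d, ["A", "B", "C"])
        assert "A:0" in newick and "B:0" in newick

    def test_four_taxon_merge_order_matches_hand_upgma(self):
        # hand agglomeration: merge (A,B) at 2; then (AB,C) at avg(6,6)=6;
        # then (ABC,D) at avg(10,10,10)=10
        from io import StringIO
        from Bio import Phylo

        d = np.array([[0, 2, 6, 10],
                      [2, 0, 6, 10],
                      [6, 6, 0, 10],
                      [10, 10, 10, 0]], dtype=float)
        newick = build_dendrogram(d, ["A", "B", "C", "D"])
        tree = Phylo.read(StringIO(newick), "newick")
        ab = tree.common_ancestor(["A", "B"])
        assert {l.name for l in ab.get_terminals()} == {"A", "B"}
        abc = tree.common_ancestor(["A", "B", "C"])
        assert {l.name for l in abc.get_terminals()} == {"A", "B", "C"}

    def test_ultrametric_heights_recovered(self):
        from io import StringIO
        from Bio import Phylo

        d = np.array([[0, 2, 6, 10],
                      [2, 0, 6, 10],
                      [6, 6, 0, 10],
                      [10, 10, 10, 0]], dtype=float)
        tree = Phylo.read(StringIO(build_dendrogram(d, list("ABCD"))), "newick")
        # root-to-leaf depth is half the largest merge distance
        depths = tree.depths()
        leaf_depths = {c.name: v for c, v in depths.items() if c.name}
        assert all(v == pytest.approx(5.0) for v in leaf_depths.values())

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ConservationError, match="symmetric"):
            build_dendrogram(d, ["A", "B"])


class TestProfileAlignment:
    def _profile(self, chain, names, values):
        return {ResidueLabel(chain, i + 1, "", n): v
                for i, (n, v) in enumerate(zip(names, values))}

    def test_gap_free_row_equals_profile(self):
        msa = _msa(["AGS"], ids=["h1"])
        prof = self._profile("A", ["ALA", "GLY", "SER"], [0.1, 0.2, 0.3])
        out = map_profiles_to_alignment({"h1": prof}, msa)
        assert list(out.loc["h1"]) == [0.1, 0.2, 0.3]

    def test_terminal_gap_leaves_missing_cells(self):
        # one homolog carries a 2-column C-terminal extension
        msa = _msa(["AGSVL", "AGS--"], ids=["long", "short"])
        long_prof = self._profile("A", ["ALA", "GLY", "SER", "VAL", "LEU"],
                                  [1, 2, 3, 4, 5])
        short_prof = self._profile("B", ["ALA", "GLY", "SER"], [7, 8, 9])
        out = map_profiles_to_alignment({"long": long_prof,
                                         "short": short_prof}, msa)
        assert list(out.loc["long"]) == [1, 2, 3, 4, 5]
        assert list(out.loc["short"][:3]) == [7, 8, 9]
        assert out.loc["short"][3:].isna().all()

    def test_known_indel_pattern_cell_by_cell(self):
        msa = _msa(["AG-S", "A-GS", "AGGS"], ids=["h1", "h2", "h3"])
        p1 = self._profile("A", ["ALA", "GLY", "SER"], [1, 2, 3])
        p2 = self._profile("B", ["ALA", "GLY", "SER"], [4, 5, 6])
        p3 = self._profile("C", ["ALA", "GLY", "GLY", "SER"], [7, 8, 9, 10])
        out = map_profiles_to_alignment({"h1": p1, "h2": p2, "h3": p3}, msa)
        expected = [[1, 2, np.nan, 3],
                    [4, np.nan, 5, 6],
                    [7, 8, 9, 10]]
        assert np.allclose(out.to_numpy(), expected, equal_nan=True)

    def test_absent_homolog_rejected(self):
        msa = _msa(["AGS"], ids=["h1"])
        with pytest.raises(ConservationError):
            map_profiles_to_alignment(
                {"missing": self._profile("A", ["ALA"], [1.0])}, msa)
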