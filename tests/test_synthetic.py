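"""Generator contracts: determinism, exact schedule bookkeeping, planted
ground truth."""

import numpy as np
import pytest

from thermocontacts.contacts import contact_frequencies, assemble_matrix
from thermocontacts.synthetic import (SyntheticEnsembleSpec,
                                      SyntheticLadderSpec, SyntheticError,
                                      schedule_occupancy, synth_contact_ladder,
                                      synth_ensemble, synth_feature_clusters,
                                      synth_msa)


class TestEnsembleGenerator:
    def test_empty_schedule_no_contacts(self):
        spec = SyntheticEnsembleSpec(n_residues=6, n_frames=3, seed=0,
                                     temperatures=(300.0,), schedule={})
        model, handles = synth_ensemble(spec)
        table = contact_frequencies(handles[300.0], model)
        assert table.frequencies == {}

    def test_occupancy_ladder_matches_matrix_row(self):
        ladder = (283.0, 305.0, 327.0, 349.0, 371.0, 393.0)
        occupancies = (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)
        spec = SyntheticEnsembleSpec(
            n_residues=8, n_frames=10, seed=0, temperatures=ladder,
            schedule={(0, 4, "hydrophobic"):
                      {t: q for t, q in zip(ladder, occupancies)}})
        model, handles = synth_ensemble(spec)
        matrix = assemble_matrix([contact_frequencies(handles[t], model)
                                  for t in ladder])
        assert list(matrix.values[0]) == list(occupancies)

    def test_conflicting_residue_use_rejected(self):
        with pytest.raises(SyntheticError, match="unsatisfiable"):
            synth_ensemble(SyntheticEnsembleSpec(
                n_residues=10, n_frames=2, seed=0, temperatures=(300.0,),
                schedule={(0, 4, "salt_bridge"): 1.0,
                          (4, 8, "hydrophobic"): 1.0}))

    def test_hub_residue_hosts_several_hydrophobic_contacts(self):
        # one residue at the centre of a hydrophobic star: allowed as long
        # as its proxy-atom pool lasts, and every spoke stays exact
        spec = SyntheticEnsembleSpec(
            n_residues=20, n_frames=4, seed=0, temperatures=(300.0,),
            schedule={(0, 4, "hydrophobic"): 1.0,
                      (0, 8, "hydrophobic"): 0.75,
                      (0, 12, "hydrophobic"): 0.5,
                      (0, 16, "hydrophobic"): 0.25})
        model, handles = synth_ensemble(spec)
        table = contact_frequencies(handles[300.0], model, ["hydrophobic"])
        assert sorted(table.frequencies.values()) == [0.25, 0.5, 0.75, 1.0]

    def test_proxy_pool_exhaustion_rejected(self):
        schedule = {(0, 4 * (k + 1), "hydrophobic"): 1.0 for k in range(5)}
        with pytest.raises(SyntheticError, match="unsatisfiable"):
            synth_ensemble(SyntheticEnsembleSpec(
                n_residues=24, n_frames=2, seed=0, temperatures=(300.0,),
                schedule=schedule))

    def test_sequence_separation_violation_rejected(self):
        with pytest.raises(SyntheticError, match="separation"):
            SyntheticEnsembleSpec(n_residues=10, n_frames=2, seed=0,
                                  temperatures=(300.0,),
                                  schedule={(3, 5, "hbond"): 1.0})

    def test_deterministic_frames(self):
        spec = SyntheticEnsembleSpec(
            n_residues=8, n_frames=5, seed=9, temperatures=(300.0,),
            schedule={(0, 4, "cation_pi"): 0.6})
        _, h1 = synth_ensemble(spec)
        _, h2 = synth_ensemble(spec)
        assert np.array_equal(h1[300.0].frames_array(), h2[300.0].frames_array())

    @pytest.mark.parametrize("itype", ["salt_bridge", "hydrophobic", "hbond",
                                       "cation_pi", "pi_stack"])
    def test_every_interaction_type_recoverable(self, itype):
        spec = SyntheticEnsembleSpec(
            n_residues=8, n_frames=4, seed=0, temperatures=(300.0,),
            schedule={(0, 4, itype): [0, 2]})
        model, handles = synth_ensemble(spec)
        table = contact_frequencies(handles[300.0], model, [itype])
        assert list(table.frequencies.values()) == [0.5]
        truth = schedule_occupancy(spec, 300.0)
        assert table.frequencies == truth


class TestLadderGenerator:
    def test_noise_free_melting_row_strictly_decreasing(self):
        matrix, labels = synth_contact_ladder(
            SyntheticLadderSpec(n_melting=1, n_forming=0, n_inert=1,
                                sigma=0.0, seed=0))
        melting_key = next(k for k, v in labels.items() if v == "melting")
        row = matrix.values[matrix.keys.index(melting_key)]
        assert np.all(np.diff(row) < 0)

    def test_fixed_seed_bit_identical(self):
        spec = SyntheticLadderSpec(seed=5)
        m1, _ = synth_contact_ladder(spec)
        m2, _ = synth_contact_ladder(spec)
        assert np.array_equal(m1.values, m2.values)

    def test_values_clipped_to_unit_interval(self):
        matrix, _ = synth_contact_ladder(SyntheticLadderSpec(sigma=0.3, seed=1))
        assert matrix.values.min() >= 0.0 and matrix.values.max() <= 1.0

    def test_midpoint_outside_ladder_rejected(self):
        with pytest.raises(SyntheticError, match="midpoints"):
            SyntheticLadderSpec(melting_midpoints=(100.0, 200.0))

    def test_label_counts_match_spec(self):
        spec = SyntheticLadderSpec(n_melting=5, n_forming=3, n_inert=7, seed=0)
        matrix, labels = synth_contact_ladder(spec)
        counts = {lab: sum(1 for v in labels.values() if v == lab)
                  for lab in ("melting", "forming", "inert")}
        assert counts == {"melting": 5, "forming": 3, "inert": 7}
        assert len(matrix.keys) == 15


class TestMsaGenerator:
    def test_constant_column_zero_entropy(self):
        from thermocontacts.conservation import shannon_entropy

        msa = synth_msa([{"W": 1.0}], 100, seed=0)
        assert shannon_entropy(msa).raw_bits[0] == pytest.approx(0.0, abs=1e-12)

    def test_query_row_gap_free(self):
        msa = synth_msa([{"A": 0.5, "-": 0.5}] * 10, 50, seed=1)
        assert "-" not in msa.rows[0]
        assert msa.ids[0] == "query"

    def test_bad_distribution_rejected(self):
        with pytest.raises(SyntheticError, match="sums"):
            synth_msa([{"A": 0.6, "V": 0.6}], 10, seed=0)

    def test_unknown_symbol_rejected(self):
        with pytest.raises(SyntheticError, match="symbols"):
            synth_msa([{"B": 1.0}], 10, seed=0)

    def test_deterministic(self):
        a = synth_msa([{"A": 0.5, "V": 0.5}] * 5, 30, seed=7)
        b = synth_msa([{"A": 0.5, "V": 0.5}] * 5, 30, seed=7)
        assert a.rows == b.rows


class TestFeatureClusterGenerator:
    def test_sizes_and_labels(self):
        table, labels = synth_feature_clusters(
            np.array([[0, 0, 0], [5, 5, 5]]), 1.0, [10, 15], seed=0)
        assert len(table) == 25
        assert list(np.bincount(labels)) == [10, 15]

    def test_fixed_seed_identical_table(self):
        args = (np.array([[0, 0, 0], [3, 3, 3]]), 0.5, [8, 8])
        t1, _ = synth_feature_clusters(*args, seed=3)
        t2, _ = synth_feature_clusters(*args, seed=3)
        assert np.array_equal(t1.to_numpy(), t2.to_numpy())

    def test_wrong_center_dimension_rejected(self):
        with pytest.raises(SyntheticError):
            synth_feature_clusters(np.zeros((2, 2)), 1.0, [5, 5], seed=0)
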