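"""Typed contact detection and frequency aggregation."""

import numpy as np
import pytest

from thermocontacts.contacts import (ContactError, ContactKey,
                                     ContactFrequencyTable, GeometryConfig,
                                     assemble_matrix, contact_frequencies,
                                     detect_contacts_frame)
from thermocontacts.structure_io import ResidueLabel, ensemble_from_arrays
from thermocontacts.synthetic import (SyntheticEnsembleSpec, synth_ensemble,
                                      schedule_occupancy)

from conftest import make_model


def _salt_pair(distance):
    """ARG NH1 at `distance` Angstrom from ASP OD1, residues 1 and 10."""
    return make_model([
        ("A", 1, "ARG", [("CA", "C", (0, 0, 0)), ("NH1", "N", (2, 0, 0))]),
        ("A", 10, "ASP", [("CA", "C", (10, 0, 0)),
                          ("OD1", "O", (2 + distance, 0, 0))]),
    ])


class TestDetectFrame:
    def test_salt_bridge_inside_cutoff(self):
        model = _salt_pair(3.5)
        found = detect_contacts_frame(model.coords, model, ["salt_bridge"])
        assert len(found) == 1
        (key,) = found
        assert key.itype == "salt_bridge"
        assert key.res_a.name == "ARG" and key.res_b.name == "ASP"

    def test_salt_bridge_outside_cutoff(self):
        model = _salt_pair(4.5)
        assert detect_contacts_frame(model.coords, model, ["salt_bridge"]) == set()

    def test_sequence_separation_excludes_local_pairs(self):
        # LEU 10 and VAL 12 side-chain carbons 4.0 A apart: |i-j| <= 2
        model = make_model([
            ("A", 10, "LEU", [("CA", "C", (0, 0, 0)), ("CD1", "C", (2, 0, 0))]),
            ("A", 11, "GLY", [("CA", "C", (50, 0, 0))]),
            ("A", 12, "VAL", [("CA", "C", (10, 0, 0)), ("CG1", "C", (6, 0, 0))]),
        ])
        assert detect_contacts_frame(model.coords, model, ["hydrophobic"]) == set()
        # same geometry but different chains: detected
        model2 = make_model([
            ("A", 10, "LEU", [("CA", "C", (0, 0, 0)), ("CD1", "C", (2, 0, 0))]),
            ("B", 12, "VAL", [("CA", "C", (10, 0, 0)), ("CG1", "C", (6, 0, 0))]),
        ])
        assert len(detect_contacts_frame(model2.coords, model2, ["hydrophobic"])) == 1

    def test_unknown_type_lists_supported(self):
        model = _salt_pair(3.5)
        with pytest.raises(ContactError, match="salt_bridge"):
            detect_contacts_frame(model.coords, model, ["disulfide"])

    def test_key_canonicalization_symmetric(self):
        a = ResidueLabel("B", 5, "", "ARG")
        b = ResidueLabel("A", 90, "", "ASP")
        assert ContactKey.make(a, b, "salt_bridge") == \
            ContactKey.make(b, a, "salt_bridge")
        assert ContactKey.make(a, b, "salt_bridge").res_a.chain == "A"

    def test_raising_cutoff_never_removes_contacts(self):
        rng = np.random.default_rng(5)
        atoms = [("A", i + 1, "LEU", [("CA", "C", rng.uniform(0, 20, 3)),
                                      ("CD1", "C", rng.uniform(0, 20, 3))])
                 for i in range(8)]
        model = make_model(atoms)
        base = detect_contacts_frame(model.coords, model, ["hydrophobic"],
                                     GeometryConfig(hydrophobic_cutoff=4.5))
        wider = detect_contacts_frame(model.coords, model, ["hydrophobic"],
                                      GeometryConfig(hydrophobic_cutoff=6.5))
        assert base <= wider


class TestFrequencies:
    def test_scheduled_three_of_four_frames(self):
        spec = SyntheticEnsembleSpec(
            n_residues=8, n_frames=4, seed=0, temperatures=(300.0,),
            schedule={(0, 4, "hydrophobic"): [0, 1, 2]})
        model, handles = synth_ensemble(spec)
        table = contact_frequencies(handles[300.0], model, ["hydrophobic"])
        assert list(table.frequencies.values()) == [0.75]

    def test_always_present_contact_is_one(self):
        spec = SyntheticEnsembleSpec(
            n_residues=8, n_frames=6, seed=0, temperatures=(300.0,),
            schedule={(0, 4, "salt_bridge"): 1.0})
        model, handles = synth_ensemble(spec)
        table = contact_frequencies(handles[300.0], model, ["salt_bridge"])
        assert list(table.frequencies.values()) == [1.0]

    def test_modular_schedule_against_independent_count(self):
        n = 500
        spec = SyntheticEnsembleSpec(
            n_residues=8, n_frames=n, seed=0, temperatures=(300.0,),
            schedule={(0, 4, "hbond"): (lambda f: f % 5 == 0)})
        model, handles = synth_ensemble(spec)
        table = contact_frequencies(handles[300.0], model, ["hbond"])
        expected = sum(1 for f in range(n) if f % 5 == 0) / n
        assert list(table.frequencies.values()) == [expected] == [0.2]

    def test_stride_zero_frames_error(self, scheduled_ensemble):
        spec, model, handles = scheduled_ensemble
        h = handles[283.0]
        with pytest.raises(ContactError):
            contact_frequencies(h, model, stride=0)

    def test_frequencies_exact_across_full_ladder(self, scheduled_ensemble):
        spec, model, handles = scheduled_ensemble
        for t, handle in handles.items():
            table = contact_frequencies(handle, model)
            truth = schedule_occupancy(spec, t)
            present = {k: v for k, v in truth.items() if v > 0}
            assert table.frequencies == present


class TestAssembleMatrix:
    def _table(self, temp, freqs):
        return ContactFrequencyTable(temperature=temp, frequencies=freqs,
                                     n_frames=10)

    def _key(self, n1, n2):
        return ContactKey.make(ResidueLabel("A", n1, "", "LEU"),
                               ResidueLabel("A", n2, "", "VAL"), "hydrophobic")

    def test_union_of_contacts(self):
        shared, only1, only2 = self._key(1, 10), self._key(2, 20), self._key(3, 30)
        m = assemble_matrix([self._table(300.0, {shared: 0.5, only1: 0.2}),
                             self._table(350.0, {shared: 0.4, only2: 0.9})])
        assert len(m.keys) == 3
        assert m.values.shape == (3, 2)
        row2 = m.keys.index(only2)
        assert m.values[row2, 0] == 0.0 and m.values[row2, 1] == 0.9

    def test_columns_sorted_by_temperature(self):
        k = self._key(1, 10)
        m = assemble_matrix([self._table(390.0, {k: 0.1}),
                             self._table(283.0, {k: 0.9}),
                             self._table(330.0, {k: 0.5})])
        assert list(m.temperatures) == [283.0, 330.0, 390.0]
        assert list(m.values[0]) == [0.9, 0.5, 0.1]

    def test_duplicate_temperature_rejected(self):
        k = self._key(1, 10)
        with pytest.raises(ContactError, match="duplicate"):
            assemble_matrix([self._table(300.0, {k: 0.5}),
                             self._table(300.0, {k: 0.6})])

    def test_six_tables_give_six_columns(self, scheduled_ensemble):
        spec, model, handles = scheduled_ensemble
        tables = [contact_frequencies(h, model) for h in handles.values()]
        m = assemble_matrix(tables)
        assert m.values.shape[1] == 6
        # matrix rows match the schedule occupancy vectors exactly
        for key in m.keys:
            row = m.values[m.keys.index(key)]
            truth = [schedule_occupancy(spec, t)[key] for t in m.temperatures]
            assert list(row) == truth
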