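"""Shared fixtures: constructed PDB text, programmatic structure models,
and synthetic ensembles with known contact schedules."""

from __future__ import annotations

import numpy as np
import pytest

from thermocontacts.structure_io import ResidueRecord, StructureModel


def make_model(residue_specs, chain="A"):
    """Build a StructureModel from
    ``[(resname, [(atom_name, element, (x, y, z)), ...]), ...]``
    (or ``(chain, number, resname, atoms)`` tuples for full control)."""
    residues, names, elements, coords = [], [], [], []
    for i, spec in enumerate(residue_specs):
        if len(spec) == 2:
            ch, num, resname, atoms = chain, i + 1, spec[0], spec[1]
        else:
            ch, num, resname, atoms = spec
        start = len(names)
        for nm, el, xyz in atoms:
            names.append(nm)
            elements.append(el)
            coords.append(xyz)
        residues.append(ResidueRecord(chain=ch, number=num, icode="",
                                      name=resname, atom_start=start,
                                      atom_stop=len(names)))
    return StructureModel(residues=residues,
                          atom_names=np.asarray(names, dtype=object),
                          elements=np.asarray(elements, dtype=object),
                          coords=np.asarray(coords, dtype=float))


TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
ATOM      4  O   ALA A   1      13.339   7.615  -5.862  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.527   6.220  -4.108  1.00  0.00           C
ATOM      6  N   GLY A   2      12.841   7.585  -3.667  1.00  0.00           N
ATOM      7  CA  GLY A   2      13.807   8.612  -3.301  1.00  0.00           C
ATOM      8  C   GLY A   2      13.253   9.980  -3.679  1.00  0.00           C
ATOM      9  O   GLY A   2      12.047  10.152  -3.880  1.00  0.00           O
ATOM     10  N   SER A   3      14.138  10.968  -3.771  1.00  0.00           N
ATOM     11  CA  SER A   3      13.752  12.330  -4.122  1.00  0.00           C
ATOM     12  C   SER A   3      13.119  13.047  -2.933  1.00  0.00           C
ATOM     13  O   SER A   3      13.607  12.940  -1.804  1.00  0.00           O
ATOM     14  CB  SER A   3      14.969  13.119  -4.607  1.00  0.00           C
ATOM     15  OG  SER A   3      15.522  12.518  -5.770  1.00  0.00           O
TER      16      SER A   3
HETATM   17  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture(scope="session")
def scheduled_ensemble():
    """Toy ensemble with a known contact schedule over the default ladder."""
    from thermocontacts.synthetic import SyntheticEnsembleSpec, synth_ensemble

    ladder = (283.0, 305.0, 327.0, 349.0, 371.0, 393.0)
    melting = {t: q for t, q in zip(ladder, (1.0, 0.8, 0.6, 0.4, 0.2, 0.0))}
    spec = SyntheticEnsembleSpec(
        n_residues=14, n_frames=20, seed=11, temperatures=ladder,
        schedule={
            (0, 4, "salt_bridge"): melting,
            (2, 7, "hydrophobic"): 0.75,
            (5, 10, "hbond"): 0.5,
            (3, 11, "hydrophobic"): 1.0,
        })
    from thermocontacts.synthetic import synth_ensemble
    model, handles = synth_ensemble(spec)
    return spec, model, handles


@pytest.fixture(scope="session")
def planted_ladder():
    from thermocontacts.synthetic import SyntheticLadderSpec, synth_contact_ladder

    spec = SyntheticLadderSpec(seed=3)
    matrix, labels = synth_contact_ladder(spec)
    return spec, matrix, labels
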