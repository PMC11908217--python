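"""Shared definition of the synthetic study system.

One protease-like toy chain of 40 residues observed over the six-rung
283-393 K temperature ladder, 60 frames per rung, with:

* a stable hydrophobic core wired as two overlapping stars (hub residues
  11 and 15, numbering 1-based) whose mean contact frequencies stay above
  the 0.75 network threshold;
* three salt bridges that melt with staggered midpoints as temperature
  rises;
* two hydrogen bonds that form only toward the hot end of the ladder;
* backbone flexibility that grows with temperature, with planted hotspot
  residues (5 and 35) that respond more strongly than the rest;
* a 300-sequence family alignment whose columns are strongly conserved at
  the network-core positions and variable at the termini.

Every script under analysis/ regenerates this system from the fixed seed,
so stages can run independently and still agree.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from thermocontacts.structure_io import extract_sequence
from thermocontacts.synthetic import (SyntheticEnsembleSpec, synth_ensemble,
                                      synth_msa)

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"

LADDER = (283.0, 305.0, 327.0, 349.0, 371.0, 393.0)
SEED = 2026
N_RESIDUES = 40
N_FRAMES = 60

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# hydrophobic core (LEU hubs 10, 14 -> VAL spokes; 0-based indices)
CORE_EDGES = {
    (10, 20): 1.0, (10, 24): 0.95, (10, 28): 0.9,
    (14, 20): 0.9, (14, 24): 0.85,
    (18, 28): 0.8, (18, 32): 0.8,
}

# melting salt bridges: occupancy ladders with staggered midpoints
MELTING_SALT = {
    (0, 4): (1.0, 0.8, 0.5, 0.2, 0.05, 0.0),     # melts early
    (1, 5): (1.0, 0.95, 0.8, 0.5, 0.2, 0.05),    # melts mid-ladder
    (2, 6): (1.0, 1.0, 0.95, 0.8, 0.5, 0.2),     # melts late
}

# hydrogen bonds that assemble near the hot end
FORMING_HBONDS = {
    (34, 38): (0.0, 0.0, 0.05, 0.2, 0.5, 0.8),
    (35, 39): (0.0, 0.0, 0.0, 0.1, 0.3, 0.6),
}

HOTSPOT_RESIDUES = (4, 34)          # 0-based: residues 5 and 35
BACKBONE_JITTER = {t: 0.15 + 0.5 * (t - LADDER[0]) / (LADDER[-1] - LADDER[0])
                   for t in LADDER}


def build_spec() -> SyntheticEnsembleSpec:
    schedule = {}
    for (i, j), q in CORE_EDGES.items():
        schedule[(i, j, "hydrophobic")] = q
    for (i, j), occ in MELTING_SALT.items():
        schedule[(i, j, "salt_bridge")] = dict(zip(LADDER, occ))
    for (i, j), occ in FORMING_HBONDS.items():
        schedule[(i, j, "hbond")] = dict(zip(LADDER, occ))
    profile = np.ones(N_RESIDUES)
    profile[list(HOTSPOT_RESIDUES)] = 3.0
    return SyntheticEnsembleSpec(
        n_residues=N_RESIDUES, n_frames=N_FRAMES, temperatures=LADDER,
        schedule=schedule, seed=SEED,
        backbone_jitter=BACKBONE_JITTER, jitter_profile=profile)


def build_ensembles():
    return synth_ensemble(build_spec())


def build_msa(model, n_sequences: int = 300):
    """Family MSA around the study sequence: conserved core, variable ends."""
    seq = extract_sequence(model, "A")
    core = {i for pair in CORE_EDGES for i in pair}
    specs = []
    for i, ch in enumerate(seq):
        if i in core:                      # nearly invariant
            p_major = 0.98
        elif i < 4 or i >= N_RESIDUES - 4:  # variable termini
            p_major = 0.30
        else:
            p_major = 0.75
        p = {a: (1 - p_major) / 19 for a in AA20 if a != ch}
        p[ch] = p_major
        specs.append(p)
    msa = synth_msa(specs, n_sequences, seed=SEED + 1)
    msa.rows[0] = seq                      # query row = the structure itself
    return msa
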