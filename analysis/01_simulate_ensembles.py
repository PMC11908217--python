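"""Generate the study system: toy ensembles over the 283-393 K ladder plus
the family alignment, and record the planted ground truth.

Writes the reference structure (PDB), the alignment (FASTA) and the contact
schedule's per-temperature occupancies (the quantities later stages must
recover) under results/study/inputs/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import LADDER, RESULTS, build_ensembles, build_msa, build_spec

from thermocontacts.structure_io import write_pdb
from thermocontacts.synthetic import schedule_occupancy


def main():
    out = RESULTS / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    spec = build_spec()
    model, handles = build_ensembles()
    write_pdb(model, out / "reference.pdb")
    msa = build_msa(model)
    msa.to_fasta(out / "family_alignment.fasta")

    truth = {}
    for t in LADDER:
        occ = schedule_occupancy(spec, t)
        truth[f"{t:g}"] = {str(k): v for k, v in occ.items()}
    (out / "contact_schedule_truth.json").write_text(
        json.dumps(truth, indent=2))

    n_frames = sum(h.n_frames for h in handles.values())
    print(f"study system: {len(model.residues)} residues, "
          f"{len(handles)} temperature rungs ({LADDER[0]:g}-{LADDER[-1]:g} K), "
          f"{n_frames} frames total")
    print(f"scheduled contacts: {len(spec.schedule)} "
          f"({sum(1 for k in spec.schedule if k[2] == 'hydrophobic')} "
          f"hydrophobic core, "
          f"{sum(1 for k in spec.schedule if k[2] == 'salt_bridge')} melting "
          f"salt bridges, "
          f"{sum(1 for k in spec.schedule if k[2] == 'hbond')} forming "
          f"hydrogen bonds)")
    print(f"family alignment: {msa.n_sequences} sequences x "
          f"{msa.n_columns} columns")
    print(f"inputs written to {out}")


if __name__ == "__main__":
    main()
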