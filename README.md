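# thermocontacts

Temperature-sensitive contact analysis of protein conformational ensembles.

Enzymes adapted to different thermal niches — psychrophilic, mesophilic,
thermophilic — balance stability against flexibility through their
noncovalent interaction networks. Given conformational ensembles of one
protein sampled at several temperatures (an ordered temperature ladder),
this package quantifies that balance residue by residue:

* **Typed contact frequencies.** Salt bridges, hydrophobic contacts,
  hydrogen bonds (heavy-atom proxy), cation-π and π-stacking contacts are
  detected per frame from geometric criteria and aggregated into a
  contact × temperature frequency matrix, with entries in [0, 1].
* **Thermal contact modes.** PCA of that matrix (observations =
  temperatures, variables = contacts, centered per contact) yields modes of
  coordinated temperature response. Each mode is labelled *melting*
  (its top-loading contacts weaken with temperature), *forming*
  (they strengthen), or *mixed*.
* **Hydrophobic interaction networks.** Contacts whose mean hydrophobic
  frequency across the ladder exceeds 0.75 define an undirected residue
  graph. Closeness centrality
  `C_i = (n − 1) / Σ_j d(i, j)` (hop-count shortest paths; component-scaled
  on disconnected graphs) ranks residues by how central they are to the
  hydrophobic core, and the top-20% subnetwork extracts its backbone.
* **Flexibility.** Per-residue Cα RMSF at each temperature, after iterative
  superposition onto the converged mean structure; the per-residue
  *temperature-sensitivity score* is the population standard deviation of
  RMSF across the ladder.
* **Conservation.** Per-column Shannon entropy `H = −Σ_a p_a log₂ p_a` of a
  family alignment, normalized by log₂ 20 and mapped onto structure
  residues through the query row; plus global-alignment identity/similarity
  matrices and a UPGMA dendrogram.
* **Integrated clustering.** k-means (default k = 4, elbow suggestion
  reported alongside) over the standardized per-residue features
  {entropy, sensitivity, closeness centrality}, separating e.g.
  variable/flexible surface residues from the conserved, network-central
  core.

A synthetic-data module generates every input with known ground truth —
toy ensembles whose contact schedules are satisfied geometrically frame by
frame, contact ladders with planted logistic melting/forming curves,
alignment columns with specified symbol distributions, and planted feature
clusters — so the whole stack is testable without molecular-dynamics data.

## Layout

```
src/thermocontacts/   the library: structure_io, contacts, flexibility,
                      thermal_modes, networks, conservation, clustering,
                      synthetic, pipeline, cli
analysis/             numbered drivers reproducing the study narrative on
                      the synthetic system (01_simulate_ensembles ...
                      07_cluster_residues), writing tables to results/study/
tests/                pytest suite (unit, property and end-to-end checks)
scripts/acceptance.py recomputes the headline quantities (below)
docs/methods.md       models, parameters, numerical choices, limitations
```

## Worked example

```bash
python analysis/01_simulate_ensembles.py
python analysis/05_hydrophobic_network.py
```

prints (abridged):

```
study system: 40 residues, 6 temperature rungs (283-393 K), 360 frames total
scheduled contacts: 12 (7 hydrophobic core, 3 melting salt bridges,
                    2 forming hydrogen bonds)
hydrophobic graph: 7 residues, 7 stable edges (mean frequency > 0.75)
closeness ranking: A:LEU11=0.600, A:VAL29=0.545, A:VAL21=0.462, ...
top-20% subnetwork: 2 residues, 1 edges; hubs retained: ['A:LEU11', 'A:VAL29']
```

The study system plants a hydrophobic core wired as two overlapping stars;
`A:LEU11` is the designed hub, and its top closeness centrality (0.600,
i.e. on average 1/0.6 ≈ 1.7 hops from every other core residue) confirms
the network stage recovers it. Likewise `analysis/04_thermal_modes.py`
reports the two leading PCA modes of a planted 100-contact ladder labelled
`['melting', 'forming']` with 100% of the planted contacts recovered in the
matching mode's top-loading set, and `analysis/03_flexibility.py` shows
mean RMSF rising monotonically from 0.275 Å at 283 K to 1.174 Å at 393 K
with the two planted hotspot residues topping the sensitivity ranking.

There is also a CLI for running the stages against real inputs from a YAML
config (`thermocontacts all config.yaml`; subcommands `simulate`,
`contacts`, `rmsf`, `modes`, `network`, `conserve`, `cluster`).

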