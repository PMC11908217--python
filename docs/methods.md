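# Methods

## Scope and data model

The package analyses per-temperature conformational ensembles of a single
protein over an ordered temperature ladder (default six rungs, 283–393 K).
Residues are identified throughout by the author triple
(chain, residue number, insertion code) so outputs line up with the
residue labels used in the structural literature. Crystal structures carry
no hydrogens, so every geometric criterion is defined on heavy atoms;
trajectory and crystal inputs are thereby treated uniformly. Waters are
excluded on reading; other heteroatoms are kept but flagged and excluded
from polymer-residue operations. Alternate locations keep the
highest-occupancy conformer (tie: first encountered). For multi-chain
structures the first polymer chain is analysed unless a chain is named in
the run config; the choice is logged.

## Contact detection

A typed contact is an unordered residue pair whose criterion holds in a
frame; it counts once per (pair, type, frame) no matter how many atom
pairs satisfy it. Defaults (all configurable in `GeometryConfig`):

| type | criterion | cutoff |
|---|---|---|
| salt_bridge | Arg/Lys/His side-chain N — Asp/Glu carboxylate O | 4.0 Å |
| hydrophobic | side-chain C of {A,V,L,I,M,F,W,P} — same | 4.5 Å |
| hbond | heavy-atom proxy: any N/O — any N/O of another residue | 3.5 Å |
| cation_pi | Arg/Lys cationic-group centroid — aromatic ring centroid (F,Y,W,H) | 6.0 Å |
| pi_stack | ring centroid — ring centroid | 5.5 Å |

These are the de facto defaults of the contact-fingerprinting tools in
common use; the source tools do not print their cutoffs, so the config is
the single source of truth here. Same-chain pairs closer than three
positions in author numbering are excluded so trivially persistent local
contacts do not dominate the networks. Frequencies are per-temperature
fractions of sampled frames (stride configurable, default 1, no frame
weighting); assembling tables across temperatures takes the union of
contacts with absent entries as 0 and columns sorted by temperature.

## Thermal contact modes

PCA runs over the matrix with temperatures as observations and contacts
as variables. Contacts are centered but not variance-scaled: frequencies
already share the [0, 1] scale, and unit-variance scaling would inflate
noise from near-constant contacts. Contacts with zero variance across the
ladder (variance below 1e-20, i.e. float-rounding level) are set aside as
"temperature-stable" — they carry no mode information. With six rungs at
most five modes exist; the default is two. Sign ambiguity is fixed by
orienting every mode so the linear-regression slope of its temperature
scores against temperature is non-negative; melting contacts then load
negatively and forming contacts positively.

A mode is labelled by its top-`k` contacts by |loading| (default k = 20,
ties broken by canonical contact order): *melting* if ≥ 75% of their
frequency profiles correlate negatively (Spearman) with temperature,
*forming* if ≥ 75% positively, else *mixed*. The observed frequency rows
are used rather than mode-only reconstructions because the score profile
of a higher mode is a residual curve and need not be monotone even when
every one of its top contacts is; for the leading mode the two readings
coincide up to the column means.

## Interaction networks

The hydrophobic graph keeps pairs whose mean hydrophobic frequency across
the ladder exceeds 0.75 (edge weight = that mean). Closeness centrality
uses unweighted hop counts — the defining formula is written over path
lengths, and edge weight carries only display information — with the
component-scaled generalization
`C_i = (r_i − 1)/Σd × (r_i − 1)/(n − 1)` (r_i = size of i's component) on
disconnected graphs, which reduces exactly to `(n − 1)/Σd` when the graph
is connected; isolated nodes score 0. A weighted mode (distance = 1/weight)
exists but is off by default. The top-CC subnetwork keeps the top
⌈fraction × n⌉ nodes (default 20%, ties by residue order) and the edges
among them.

## Flexibility

Frames are rigid-body fitted (Kabsch, via quaternion alignment) to an
iteratively refined mean structure: fit all frames to the current
reference, recompute the mean, repeat to a 1e-6 Å fixed point. RMSF is the
per-Cα root-mean-square deviation from the time-average position. All Cα
atoms enter the fit by default (a mask is available; terminal trimming is
deliberately not applied). A configurable leading fraction of frames can
be discarded as equilibration; the default uses all frames. The
temperature-sensitivity score is the *population* standard deviation of
RMSF across the rungs — the ladder is the entire population of conditions,
not a sample from one.

## Conservation

Column entropy uses the 20 amino acids; X is always excluded. Gaps are
excluded by default with probabilities renormalized over the observed
amino acids (a gap-as-21st-symbol mode exists); all-gap columns are
recorded as missing, never zero, and columns over 50% gaps are flagged
low-confidence. Normalization divides by log₂ 20 so the scale is fixed
across families rather than per-column. Structure mapping requires the
query row; its non-gap columns map in order onto the chain's polymer
residues, with more than 5% unmapped residues an error.

Pairwise identity/similarity uses global alignment with BLOSUM62 and
affine gaps (open 10, extend 0.5); identity is identical pairs over
aligned (gap-free) positions, similarity additionally counts
matrix-positive pairs. The dendrogram is UPGMA (average linkage) over
distance = 100 − identity, emitted as an ultrametric newick tree (node
height = half the merge distance). Identity values obtained this way from
sequence alignment are not interchangeable with values derived from
structural superposition; comparisons against structure-derived numbers
are reported, not asserted.

## Residue clustering

The three features (normalized entropy, sensitivity in Å, closeness
centrality) are z-scored before k-means — they are on incommensurate
scales. Residues missing entropy are dropped (logged); residues absent
from the hydrophobic graph get centrality 0. k-means is Lloyd's algorithm
with k-means++ seeding, 25 restarts, tolerance 1e-6, deterministic given
the seed; the default k = 4 with the elbow suggestion reported alongside.
Cluster labels are arbitrary, so reports reorder them by descending mean
sensitivity (cluster 1 = most temperature-sensitive).

The elbow statistic is the discrete second difference
`WCSS(k−1) − 2·WCSS(k) + WCSS(k+1)`, maximized over interior k. Its known
behaviour: it flags the true k reliably when the successive WCSS drops up
to k* are comparable (symmetric, well-separated clusters — fully stable at
eight-σ separation in three dimensions) but can prefer the dominant split
when the cluster geometry is strongly uneven or separation is marginal
(~30% of realizations pick k = 3 for four symmetric blobs at exactly
five σ), and on structureless data it usually, not always, stays at the
smallest interior k. Scale-invariant variants (log or relative curvature)
were evaluated and are more stable near the noise floor but lose the
small-k preference on structureless data; the plain second difference is
kept and the suggestion is always reported next to the default k rather
than silently adopted.

## Synthetic data

The generators define the study conditions and are pure functions of
spec + seed.

**Toy ensembles.** Residues sit on a 20 Å Cα grid so nothing interacts by
accident; each scheduled contact owns a private zone (14 Å apart along z)
where its two proxy features sit at cutoff − 0.3 Å in scheduled frames and
cutoff + 3 Å otherwise. Hence recovered frequencies equal schedule
occupancies *exactly* — the oracle for the whole contact stack. ON/OFF
margins are chosen so no criterion of another type fires incidentally
(e.g. salt bridges at 3.7 Å stay outside the 3.5 Å hydrogen-bond proxy).
A residue can host several contacts by drawing proxy atoms from its pool
(Leu 4, Val 3, Arg 3, Asp 2, Ser/Thr/Lys 1, aromatic rings single-use);
conflicting residue types, exhausted pools or local pairs raise a
schedule-unsatisfiable error. Optional Gaussian backbone jitter (per-rung
σ, per-residue multipliers for hotspots) adds flexibility signal without
touching the proxies. What this emulates: occupancy statistics of typed
contacts and thermal trends therein. What it does not: physical energetics,
solvent, correlated motions, or realistic geometry beyond the criteria —
passing tests certify the analysis stack, not molecular dynamics.

**Contact ladders.** Melting contacts follow `1/(1 + exp((T − Tm)/w))`
with midpoints staggered across 300–345 K (w = 10 K); forming contacts
follow the rising mirror with midpoints 378–390 K (w = 6 K) and a 0.85
plateau; inert contacts sit at a uniform-random constant. The asymmetry
is essential, not cosmetic: a forming family that exactly mirrors the
melting family (same midpoints and amplitude) is perfectly anticorrelated
with it after centering and collapses into the *same* principal
component — there would be no two-mode structure to recover. Contacts
that break progressively across the ladder while new ones assemble only
near the hot extreme are also the physically expected picture. Truncated
Gaussian noise (default σ = 0.02) is added and values clipped to [0, 1].
Under these defaults the two leading modes recover ≥ 18/20 of each planted
group across 60 seeds.

**Alignments.** Columns are sampled independently from given symbol
distributions over the amino acids and gap; the first row is the
designated query, resampled gap-free. Empirical column entropies converge
to the spec entropies (within 0.01 at 10⁵ sequences). **Feature tables**
are Gaussian blobs with known labels.

## Problem sizes

The shipped study system uses 40 residues × 60 frames × 6 rungs and a
300-sequence alignment; oracle comparisons use 50 random graphs (n = 30),
10⁴-frame jitter ensembles and 10⁵-sequence sampled columns. These sizes
put every closed-form or oracle comparison well inside its sampling
tolerance while the full suite runs in seconds.

## Known limitations

* The hydrogen-bond criterion is a donor/acceptor-agnostic heavy-atom
  proxy; with hydrogens present a directional criterion would be stricter.
* Ensembles are taken as direct per-temperature samples; no reweighting
  across rungs is attempted, and enhanced-sampling inputs would need such
  weights before the frequencies are comparable.
* Sequence-based identity and the structure-based variant differ; the
  dendrogram over published structure-derived identities is therefore an
  input-table computation, not a sequence recomputation.
* The elbow suggestion inherits the instabilities described above and is
  advisory; the clustering default k is fixed at 4.
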