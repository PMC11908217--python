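"""Sequence conservation from multiple sequence alignments.

Per-column Shannon entropy H = -sum_a p_a log2 p_a over the 20 amino acids
(low entropy = high conservation), normalized by log2(20) so the scale is
fixed across protein families; mapping of columns onto structure residues
through a designated query row; pairwise global-alignment identity and
similarity; and a UPGMA dendrogram over an identity-derived distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .structure_io import StructureModel, ResidueLabel, THREE_TO_ONE

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."
MAX_ENTROPY_BITS = float(np.log2(20))


class ConservationError(ValueError):
    pass


@dataclass
class AlignmentBlock:
    """An MSA: ids and equal-length rows over the 20 aa + gap + X."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ConservationError("ids/rows length mismatch")
        if not self.rows:
            raise ConservationError("empty alignment")
        width = len(self.rows[0])
        cleaned = []
        for row in self.rows:
            if len(row) != width:
                raise ConservationError("alignment rows differ in length")
            row = row.upper().replace(".", "-")
            row = "".join(c if (c in AMINO_ACIDS or c == "-") else "X"
                          for c in row)
            cleaned.append(row)
        self.rows = cleaned

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise ConservationError(
                f"sequence {seq_id!r} not in alignment; ids: {self.ids[:5]}...")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    @classmethod
    def from_file(cls, path: str | Path, fmt: str | None = None) -> "AlignmentBlock":
        from Bio import AlignIO

        path = Path(path)
        if fmt is None:
            fmt = "stockholm" if path.suffix in (".sto", ".stk", ".stockholm") \
                else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls(ids=[r.id for r in aln], rows=[str(r.seq) for r in aln])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


@dataclass
class ConservationProfile:
    """Per-column entropy (bits and normalized); NaN = all-gap column."""

    raw_bits: np.ndarray
    normalized: np.ndarray
    low_confidence: np.ndarray          # >50% gap columns
    residue_map: dict[ResidueLabel, float] = field(default_factory=dict)


def shannon_entropy(msa: AlignmentBlock,
                    gap_policy: str = "exclude") -> ConservationProfile:
    """Per-column Shannon entropy of an alignment.

    ``gap_policy='exclude'`` (default) renormalizes column probabilities
    over the observed amino acids; ``'count'`` treats the gap as a 21st
    symbol. Columns that are entirely gaps have undefined entropy and are
    recorded as NaN, not zero. X (unknown) residues are always excluded
    from the distribution.
    """
    if msa.n_sequences < 2:
        raise ConservationError("need at least two sequences")
    if gap_policy not in ("exclude", "count"):
        raise ConservationError(f"unknown gap policy {gap_policy!r}")
    n_cols = msa.n_columns
    raw = np.full(n_cols, np.nan)
    lowconf = np.zeros(n_cols, dtype=bool)
    for j in range(n_cols):
        col = msa.column(j)
        counts = {}
        n_gap = 0
        for c in col:
            if c == "-":
                n_gap += 1
                if gap_policy == "count":
                    counts["-"] = counts.get("-", 0) + 1
            elif c in AMINO_ACIDS:
                counts[c] = counts.get(c, 0) + 1
        lowconf[j] = n_gap > len(col) / 2
        total = sum(counts.values())
        if total == 0:
            continue  # all-gap column -> NaN
        p = np.array(list(counts.values()), dtype=float) / total
        raw[j] = float(-(p * np.log2(p)).sum())
    return ConservationProfile(raw_bits=raw,
                               normalized=raw / MAX_ENTROPY_BITS,
                               low_confidence=lowconf)


def map_to_structure(profile: ConservationProfile, msa: AlignmentBlock,
                     query_id: str, model: StructureModel, chain: str, *,
                     max_unmapped_fraction: float = 0.05,
                     ) -> dict[ResidueLabel, float]:
    """Map normalized column entropies onto structure residues.

    The MSA must contain the structure's own sequence as the designated
    query row; its non-gap columns map 1:1, in order, onto the chain's
    polymer residues. More than ``max_unmapped_fraction`` residues without
    a column is an error (with a diagnostic dump).
    """
    query = msa.row(query_id)
    residues = model.polymer_residues(chain)
    if not residues:
        raise ConservationError(f"chain {chain!r} has no polymer residues")
    cols = [j for j, c in enumerate(query) if c != "-"]
    n_res = len(residues)
    if len(cols) < n_res * (1 - max_unmapped_fraction) or len(cols) > n_res:
        seq = "".join(THREE_TO_ONE.get(r.name, "X") for r in residues)
        raise ConservationError(
            "query row does not map onto the chain: "
            f"{len(cols)} non-gap columns vs {n_res} residues\n"
            f"query: {query}\nchain sequence: {seq}")
    mapping: dict[ResidueLabel, float] = {}
    for res, j in zip(residues, cols):
        mapping[res.label] = float(profile.normalized[j])
    n_unmapped = n_res - len(cols)
    if n_unmapped:
        logger.info("%d residues without an alignment column", n_unmapped)
    profile.residue_map = mapping
    return mapping


def pairwise_identity_similarity(seq_a: str, seq_b: str, *,
                                 matrix: str = "BLOSUM62",
                                 open_gap: float = 10.0,
                                 extend_gap: float = 0.5,
                                 ) -> tuple[float, float]:
    """Global-alignment identity and similarity percentages.

    Identity = identical aligned residue pairs / aligned (gap-free)
    positions x 100; similarity additionally counts substitution-matrix-
    positive pairs. Affine gaps (default open 10, extend 0.5).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not seq_a or not seq_b:
        raise ConservationError("empty sequence")
    sub = substitution_matrices.load(matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    aligned = identical = similar = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for ca, cb in zip(seq_a[a0:a1], seq_b[b0:b1]):
            aligned += 1
            if ca == cb:
                identical += 1
            try:
                score = sub[ca, cb]
            except (KeyError, IndexError):
                score = -1
            if score > 0:
                similar += 1
    if aligned == 0:
        raise ConservationError("no aligned positions")
    return 100.0 * identical / aligned, 100.0 * similar / aligned


def identity_similarity_matrix(seqs: dict[str, str], **kwargs
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric identity and similarity matrices over named sequences."""
    ids = list(seqs)
    n = len(ids)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid, psim = pairwise_identity_similarity(seqs[ids[i]], seqs[ids[j]],
                                                     **kwargs)
            ident[i, j] = ident[j, i] = pid
            simil[i, j] = simil[j, i] = psim
    return (pd.DataFrame(ident, index=ids, columns=ids),
            pd.DataFrame(simil, index=ids, columns=ids))


def build_dendrogram(distances: pd.DataFrame | np.ndarray,
                     labels: list[str] | None = None) -> str:
    """UPGMA (average-linkage) tree over a distance matrix, as newick.

    The matrix must be symmetric with a zero diagonal. A natural distance
    is ``100 - identity``. Merge ties resolve deterministically by scipy's
    stable ordering.
    """
    if isinstance(distances, pd.DataFrame):
        if labels is None:
            labels = list(distances.index)
        distances = distances.to_numpy(dtype=float)
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ConservationError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-9):
        raise ConservationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distances), 0, atol=1e-9):
        raise ConservationError("distance matrix diagonal must be zero")
    if labels is None:
        labels = [f"seq{i}" for i in range(distances.shape[0])]
    Z = linkage(squareform(distances, checks=False), method="average")
    root = to_tree(Z)

    # ultrametric height of a node is half its merge distance
    def newick(node, parent_height: float) -> str:
        height = 0.0 if node.is_leaf() else node.dist / 2.0
        length = parent_height - height
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = newick(node.left, height)
        right = newick(node.right, height)
        return f"({left},{right}):{length:.6g}"

    h = root.dist / 2.0
    return f"({newick(root.left, h)},{newick(root.right, h)});"


def map_profiles_to_alignment(profiles: dict[str, dict[ResidueLabel, float]],
                              msa: AlignmentBlock) -> pd.DataFrame:
    """Spread per-residue profiles of several homologs over MSA columns.

    Each homolog's per-residue values (in residue order) fill its row's
    non-gap columns; gap columns are missing (NaN). Used for cross-homolog
    heatmaps of sensitivity, centrality or entropy on a common axis.
    """
    out = pd.DataFrame(np.nan, index=list(profiles),
                       columns=range(msa.n_columns))
    for sid, prof in profiles.items():
        row = msa.row(sid)   # raises if absent
        cols = [j for j, c in enumerate(row) if c != "-"]
        ordered = [prof[k] for k in sorted(prof, key=lambda r: r.sort_key)]
        if len(cols) != len(ordered):
            raise ConservationError(
                f"{sid}: profile has {len(ordered)} residues but the "
                f"alignment row has {len(cols)} non-gap columns")
        for j, v in zip(cols, ordered):
            out.loc[sid, j] = v
    return out
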