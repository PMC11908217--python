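"""Residue feature integration and k-means clustering.

Per-residue features — normalized conservation entropy, temperature-
sensitivity score (std of RMSF across the ladder, Angstrom), and closeness
centrality — are z-scored (the three are on incommensurate scales) and
clustered with k-means. The elbow of the within-cluster sum-of-squares
(WCSS) curve, located at the maximum of the discrete second difference,
suggests the cluster count; the default k is 4.

Cluster labels themselves are arbitrary; reported labels are reordered by
descending mean sensitivity so cluster 1 is always the most temperature-
sensitive group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .structure_io import ResidueLabel

logger = logging.getLogger(__name__)

FEATURES = ("entropy", "sensitivity", "cc")


class ClusteringError(ValueError):
    pass


def residue_index(labels) -> pd.Index:
    """Object-dtype index of residue labels (labels are tuples, which pandas
    would otherwise expand into a MultiIndex)."""
    arr = np.empty(len(labels), dtype=object)
    arr[:] = list(labels)
    return pd.Index(arr, name="residue")


def assemble_features(entropy: dict[ResidueLabel, float],
                      sensitivity: dict[ResidueLabel, float],
                      cc: dict[ResidueLabel, float]) -> pd.DataFrame:
    """Join the three per-residue tables into one feature table.

    Residues absent from the hydrophobic graph get closeness 0; residues
    without an entropy value (unmapped alignment columns) are dropped with
    a logged count. Returns a DataFrame indexed by residue label with raw
    feature columns and z-scored ``z_*`` copies.
    """
    common = [r for r in sensitivity if r in entropy]
    dropped = len(sensitivity) - len(common)
    if dropped:
        logger.info("dropped %d residues without entropy values", dropped)
    if not common:
        raise ClusteringError("no residues shared between feature tables")
    common.sort(key=lambda r: r.sort_key)
    table = pd.DataFrame({
        "entropy": [entropy[r] for r in common],
        "sensitivity": [sensitivity[r] for r in common],
        "cc": [cc.get(r, 0.0) for r in common],
    }, index=residue_index(common))
    table = table.dropna()
    return standardize(table)


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Add z-scored copies of the feature columns (population std)."""
    z = StandardScaler().fit_transform(table[list(FEATURES)].to_numpy())
    for i, name in enumerate(FEATURES):
        table[f"z_{name}"] = z[:, i]
    return table


def _zmatrix(table: pd.DataFrame) -> np.ndarray:
    cols = [f"z_{n}" for n in FEATURES]
    if not all(c in table.columns for c in cols):
        table = standardize(table.copy())
    return table[[f"z_{n}" for n in FEATURES]].to_numpy()


def wcss_curve(table: pd.DataFrame, k_range=range(1, 9), *,
               seed: int = 0, n_init: int = 25) -> tuple[dict[int, float], int]:
    """Best-of-restarts WCSS per k, and the elbow-suggested k.

    The suggested k maximizes the discrete second difference
    WCSS(k-1) - 2 WCSS(k) + WCSS(k+1) over interior k values.
    """
    Z = _zmatrix(table)
    ks = sorted(k_range)
    if ks[0] < 1 or ks[-1] > len(Z):
        raise ClusteringError(
            f"k range {ks[0]}..{ks[-1]} invalid for {len(Z)} rows")
    wcss: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6)
        km.fit(Z)
        wcss[k] = float(km.inertia_)
    if len(ks) < 3:
        return wcss, ks[-1]
    curvature = {ks[i]: wcss[ks[i - 1]] - 2 * wcss[ks[i]] + wcss[ks[i + 1]]
                 for i in range(1, len(ks) - 1)}
    suggested = max(curvature, key=lambda k: (curvature[k], -k))
    return wcss, suggested


@dataclass
class ClusterAssignment:
    """k-means labels (1..k, ordered by descending mean sensitivity)."""

    labels: dict[ResidueLabel, int]
    centers: np.ndarray                 # (k, 3) in standardized space
    inertia: float
    k: int
    wcss: dict[int, float] = field(default_factory=dict)


def kmeans_cluster(table: pd.DataFrame, k: int = 4, *,
                   seed: int = 0, n_init: int = 25) -> ClusterAssignment:
    """Cluster residues in standardized feature space with k-means."""
    Z = _zmatrix(table)
    if k < 1:
        raise ClusteringError("k must be >= 1")
    if k > len(Z):
        raise ClusteringError(f"k={k} exceeds {len(Z)} residues")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6)
    raw = km.fit_predict(Z)
    # order clusters by descending mean (raw) sensitivity
    sens = table["sensitivity"].to_numpy()
    means = [sens[raw == c].mean() if np.any(raw == c) else -np.inf
             for c in range(k)]
    order = np.argsort(means)[::-1]
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    labels = {res: relabel[int(c)] for res, c in zip(table.index, raw)}
    centers = km.cluster_centers_[order]
    return ClusterAssignment(labels=labels, centers=centers,
                             inertia=float(km.inertia_), k=k)
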