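"""End-to-end orchestration: contacts -> flexibility -> thermal modes ->
hydrophobic networks -> conservation -> residue clustering.

A :class:`RunConfig` (YAML on disk) names the inputs — a structure, one
trajectory per temperature, an MSA with the structure's sequence as query —
and the analysis parameters. :func:`run_all` executes every stage, writes
each stage's tables, and leaves a manifest of parameters and seeds so a
rerun with the same config is reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .clustering import assemble_features, kmeans_cluster, wcss_curve
from .contacts import (GeometryConfig, INTERACTION_TYPES, assemble_matrix,
                       contact_frequencies)
from .conservation import AlignmentBlock, map_to_structure, shannon_entropy
from .flexibility import rmsf_profile, temperature_sensitivity
from .networks import (build_hydrophobic_graph, closeness_centrality,
                       edges_frame, top_cc_subnetwork, write_graphml)
from .structure_io import StructureModel, load_structure, open_ensemble, write_pdb
from .thermal_modes import compute_thermal_modes, top_contacts

logger = logging.getLogger(__name__)


class TrajectoryEntry(BaseModel):
    temperature: float = Field(gt=0)
    path: str


class RunConfig(BaseModel):
    """Validated run configuration (round-trips through YAML losslessly)."""

    structure: str
    trajectories: list[TrajectoryEntry]
    msa: Optional[str] = None
    msa_query: Optional[str] = None
    chain: Optional[str] = None
    output_dir: str = "results/run"

    contact_types: list[str] = list(INTERACTION_TYPES)
    stride: int = Field(default=1, ge=1)
    hydrophobic_threshold: float = Field(default=0.75, ge=0.0, le=1.0)
    top_cc_fraction: float = Field(default=0.20, gt=0.0, le=1.0)
    n_modes: int = Field(default=2, ge=1)
    top_k_contacts: int = Field(default=20, ge=2)
    k_clusters: int = Field(default=4, ge=1)
    seed: int = Field(default=0, ge=0)
    geometry: dict = {}

    @field_validator("contact_types")
    @classmethod
    def _known_types(cls, v):
        unknown = set(v) - set(INTERACTION_TYPES)
        if unknown:
            raise ValueError(f"unknown contact types: {sorted(unknown)}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh,
                           sort_keys=False)


def project_to_bfactor(model: StructureModel, scalar: dict, path: str | Path,
                       ) -> Path:
    """Write the model with a per-residue scalar in the B-factor column.

    The scalar is min-max scaled to [0, 99.99] (the column's width limit);
    residues without a value get 0.
    """
    labels = {r.label for r in model.residues}
    overlap = labels & set(scalar)
    if not overlap:
        raise ValueError("no overlap between scalar keys and model residues")
    vals = np.array([scalar[k] for k in overlap], dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    span = hi - lo
    per_atom = np.zeros(model.n_atoms)
    for i, r in enumerate(model.residues):
        if r.label in scalar:
            v = (scalar[r.label] - lo) / span * 99.99 if span > 0 else 99.99
            per_atom[r.atom_start:r.atom_stop] = v
    return write_pdb(model, path, bfactors=per_atom)


def run_all(config: RunConfig, *, model: StructureModel | None = None,
            ensembles: dict | None = None,
            msa: AlignmentBlock | None = None) -> dict:
    """Run every stage; returns a dict of in-memory stage results.

    ``model``/``ensembles``/``msa`` may be passed directly (e.g. synthetic
    inputs); otherwise they are loaded from the paths in the config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = GeometryConfig(**config.geometry)

    if model is None:
        model = load_structure(config.structure)
    chain = config.chain or model.chains[0]
    if config.chain is None:
        logger.info("no chain specified; using first polymer chain %r", chain)

    if ensembles is None:
        ensembles = {e.temperature: open_ensemble(model, e.path, e.temperature)
                     for e in config.trajectories}
    temps = sorted(ensembles)

    # --- contacts ---------------------------------------------------
    tables = [contact_frequencies(ensembles[t], model, config.contact_types,
                                  geometry, stride=config.stride)
              for t in temps]
    matrix = assemble_matrix(tables)
    matrix.to_tidy_frame().to_csv(out / "contact_frequencies.csv", index=False)
    matrix.to_wide_frame().to_csv(out / "contact_matrix.csv")

    # --- flexibility ------------------------------------------------
    profiles = [rmsf_profile(ensembles[t], model, chain) for t in temps]
    sensitivity = temperature_sensitivity(profiles)
    rows = [(str(r), p.temperature, v) for p in profiles
            for r, v in zip(p.residues, p.values)]
    import pandas as pd
    pd.DataFrame(rows, columns=["residue", "temperature", "rmsf"]).to_csv(
        out / "rmsf.csv", index=False)
    pd.DataFrame({"residue": [str(r) for r in sensitivity.residues],
                  "sensitivity": sensitivity.values}).to_csv(
        out / "sensitivity.csv", index=False)

    # --- thermal modes ----------------------------------------------
    modes = None
    try:
        modes = compute_thermal_modes(matrix, config.n_modes,
                                      top_k=config.top_k_contacts)
        mode_rows = []
        for m in range(modes.n_modes):
            for key, loading in top_contacts(modes, m, config.top_k_contacts):
                mode_rows.append((str(key), m + 1, loading, modes.labels[m]))
        pd.DataFrame(mode_rows, columns=["contact", "mode", "loading",
                                         "label"]).to_csv(
            out / "thermal_modes_top_contacts.csv", index=False)
        with open(out / "thermal_modes.json", "w") as fh:
            json.dump({
                "explained_variance_ratio":
                    modes.explained_variance_ratio.tolist(),
                "labels": modes.labels,
                "temperatures": modes.temperatures.tolist(),
                "scores": modes.scores.tolist(),
            }, fh, indent=2)
    except ValueError as exc:
        logger.warning("thermal modes skipped: %s", exc)

    # --- hydrophobic network ----------------------------------------
    graph = build_hydrophobic_graph(matrix, config.hydrophobic_threshold)
    cc = closeness_centrality(graph)
    sub = top_cc_subnetwork(graph, cc, config.top_cc_fraction) \
        if graph.number_of_nodes() else graph
    edges_frame(graph).to_csv(out / "hydrophobic_edges.csv", index=False)
    edges_frame(sub).to_csv(out / "top_cc_subnetwork_edges.csv", index=False)
    cc.as_series().to_csv(out / "closeness_centrality.csv")
    if graph.number_of_nodes():
        write_graphml(graph, out / "hydrophobic_network.graphml")

    # --- conservation ------------------------------------------------
    entropy_map = None
    if msa is None and config.msa:
        msa = AlignmentBlock.from_file(config.msa)
    if msa is not None:
        profile = shannon_entropy(msa)
        entropy_map = map_to_structure(profile, msa,
                                       config.msa_query or msa.ids[0],
                                       model, chain)
        pd.DataFrame({"residue": [str(r) for r in entropy_map],
                      "normalized_entropy": list(entropy_map.values())}
                     ).to_csv(out / "conservation.csv", index=False)
        project_to_bfactor(model, entropy_map, out / "entropy_bfactor.pdb")

    # --- clustering --------------------------------------------------
    clusters = None
    if entropy_map is not None:
        cc_map = {r: cc.centrality.get(r, 0.0) for r in entropy_map}
        features = assemble_features(entropy_map, sensitivity.as_dict(), cc_map)
        kmax = min(8, len(features))
        wcss, suggested = wcss_curve(features, range(1, kmax + 1),
                                     seed=config.seed)
        clusters = kmeans_cluster(features, min(config.k_clusters,
                                                len(features)),
                                  seed=config.seed)
        features_out = features.copy()
        features_out.index = [str(r) for r in features_out.index]
        features_out["cluster"] = [clusters.labels[r] for r in features.index]
        features_out.to_csv(out / "residue_clusters.csv")
        with open(out / "clustering.json", "w") as fh:
            json.dump({"wcss": {str(k): v for k, v in wcss.items()},
                       "suggested_k": suggested,
                       "k": clusters.k,
                       "centers": clusters.centers.tolist()}, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "temperatures": temps,
        "n_contacts": len(matrix.keys),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"matrix": matrix, "sensitivity": sensitivity, "modes": modes,
            "graph": graph, "centrality": cc, "entropy": entropy_map,
            "clusters": clusters, "manifest": manifest}
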