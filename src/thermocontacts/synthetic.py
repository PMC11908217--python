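"""Synthetic inputs with known ground truth for every pipeline stage.

These generators stand in for the microsecond-scale MD ensembles and the
~3000-sequence family alignments that the analyses normally consume. They
are geometric/statistical constructions, not physical simulations: each one
is a pure function of its spec and seed, and each emits its ground truth in
machine-readable form so downstream recovery can be asserted exactly.

* :func:`synth_ensemble` builds a toy polymer whose side-chain proxy atoms
  satisfy each scheduled contact's geometric criterion exactly in scheduled
  frames and violate it otherwise, so recovered contact frequencies equal
  schedule occupancies exactly.
* :func:`synth_contact_ladder` plants logistic melting/forming frequency
  curves plus inert contacts over a temperature ladder.
* :func:`synth_msa` samples alignment columns from specified symbol
  distributions (hence known entropies).
* :func:`synth_feature_clusters` plants Gaussian blobs in the
  {entropy, sensitivity, closeness} feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import standardize
from .contacts import ContactFrequencyMatrix, ContactKey, GeometryConfig
from .structure_io import (EnsembleHandle, ResidueLabel, ResidueRecord,
                           StructureModel, ensemble_from_arrays)

#: Default temperature ladder (K): six rungs spanning 283-393 K.
DEFAULT_LADDER = (283.0, 305.0, 327.0, 349.0, 371.0, 393.0)

_RING_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

# participant residue names per contact type; a residue's moving proxy
# "feature" is either a single atom drawn from its pool or an aromatic
# ring (centroid-defined, usable by one contact only)
_TYPE_TEMPLATES = {
    "salt_bridge": ("ARG", "ASP"),
    "hydrophobic": ("LEU", "VAL"),
    "hbond": ("SER", "THR"),
    "cation_pi": ("LYS", "PHE"),
    "pi_stack": ("PHE", "TYR"),
}

#: proxy atoms available per participant residue; pool size bounds how many
#: scheduled contacts one residue can host
_PROXY_POOLS = {
    "ARG": ("NH1", "NH2", "NE"),
    "ASP": ("OD1", "OD2"),
    "LEU": ("CD1", "CD2", "CG", "CB"),
    "VAL": ("CG1", "CG2", "CB"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "LYS": ("NZ",),
    "PHE": _RING_NAMES,     # the whole ring, single use
    "TYR": _RING_NAMES,
}
_RING_RESIDUES = {"PHE", "TYR"}

_GRID_SPACING = 20.0   # A between consecutive Calphas: no accidental contacts
_ZONE_SPACING = 14.0   # A between contact zones along z
_ON_MARGIN = 0.3       # ON distance = cutoff - margin
_OFF_MARGIN = 3.0      # OFF distance = cutoff + margin


class SyntheticError(ValueError):
    pass


PresenceRule = float | Mapping[float, object] | Sequence[int] | Callable[[int], bool]


@dataclass
class SyntheticEnsembleSpec:
    """Spec for a toy polymer ensemble with scheduled contacts.

    ``schedule`` maps ``(i, j, interaction_type)`` residue-index pairs to a
    presence rule: an occupancy fraction (the first ``round(q * n_frames)``
    frames are ON at every temperature), an explicit frame collection, a
    per-frame predicate, or a ``{temperature: rule}`` mapping for
    temperature-dependent occupancy.
    """

    n_residues: int
    n_frames: int
    schedule: dict[tuple[int, int, str], PresenceRule]
    temperatures: Sequence[float] = DEFAULT_LADDER
    seed: int = 0
    chain: str = "A"
    params: GeometryConfig = field(default_factory=GeometryConfig)
    #: per-temperature Gaussian jitter sigma (A) applied to backbone atoms
    #: only, so scheduled contacts stay exact; a float applies everywhere
    backbone_jitter: float | Mapping[float, float] = 0.0
    #: per-residue multiplier on the jitter (flexibility "hotspots")
    jitter_profile: Sequence[float] | None = None

    def __post_init__(self):
        if self.seed is None:
            raise SyntheticError("seed is mandatory")
        if self.jitter_profile is not None \
                and len(self.jitter_profile) != self.n_residues:
            raise SyntheticError("jitter_profile needs one value per residue")
        if self.n_residues < 1 or self.n_frames < 1:
            raise SyntheticError("need >= 1 residue and >= 1 frame")
        for (i, j, itype) in self.schedule:
            if itype not in _TYPE_TEMPLATES:
                raise SyntheticError(f"unsupported contact type {itype!r}")
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise SyntheticError(f"residue index out of range: {(i, j)}")
            if abs(i - j) < self.params.min_sequence_separation:
                raise SyntheticError(
                    f"pair {(i, j)} violates the sequence-separation rule")


def _presence_array(rule: PresenceRule, n_frames: int, temperature: float
                    ) -> np.ndarray:
    if isinstance(rule, Mapping):
        sub = rule.get(temperature)
        if sub is None:
            return np.zeros(n_frames, dtype=bool)
        return _presence_array(sub, n_frames, temperature)
    if callable(rule):
        return np.array([bool(rule(f)) for f in range(n_frames)])
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        q = float(rule)
        if not (0.0 <= q <= 1.0):
            raise SyntheticError(f"occupancy {q} outside [0, 1]")
        n_on = int(round(q * n_frames))
        out = np.zeros(n_frames, dtype=bool)
        out[:n_on] = True
        return out
    out = np.zeros(n_frames, dtype=bool)
    out[np.asarray(list(rule), dtype=int)] = True
    return out


def synth_ensemble(spec: SyntheticEnsembleSpec
                   ) -> tuple[StructureModel, dict[float, EnsembleHandle]]:
    """Build the toy polymer model and one in-memory ensemble per temperature.

    Residues sit on a widely spaced grid (Calphas 20 A apart) so only the
    scheduled proxy atoms can ever satisfy a contact criterion. Each
    scheduled pair owns a private "contact zone" offset along z; in ON
    frames its two proxy features sit at (cutoff - 0.3) A separation, in
    OFF frames at (cutoff + 3) A.
    """
    # assign residue names; a residue may host several contacts (drawing a
    # fresh proxy atom from its pool each time) but only under one residue
    # type, and a ring feature is usable once
    resnames = {i: "GLY" for i in range(spec.n_residues)}
    entries = sorted(spec.schedule.items(), key=lambda kv: kv[0])
    allocations: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    pool_cursor: dict[int, int] = {}
    for (i, j, itype), _ in entries:
        name_i, name_j = _TYPE_TEMPLATES[itype]
        feats = []
        for idx, nm in ((i, name_i), (j, name_j)):
            if resnames[idx] not in ("GLY", nm):
                raise SyntheticError(
                    f"residue {idx} would need to be both {resnames[idx]} "
                    f"and {nm}; the schedule is geometrically unsatisfiable")
            resnames[idx] = nm
            if nm in _RING_RESIDUES:
                if pool_cursor.get(idx, 0) > 0:
                    raise SyntheticError(
                        f"aromatic ring of residue {idx} scheduled twice; "
                        "the schedule is geometrically unsatisfiable")
                pool_cursor[idx] = 1
                feats.append(_RING_NAMES)
            else:
                pool = _PROXY_POOLS[nm]
                cur = pool_cursor.get(idx, 0)
                if cur >= len(pool):
                    raise SyntheticError(
                        f"residue {idx} ({nm}) has no free proxy atoms for "
                        "another contact; the schedule is geometrically "
                        "unsatisfiable")
                pool_cursor[idx] = cur + 1
                feats.append((pool[cur],))
        allocations.append(tuple(feats))

    # build atoms: backbone N/CA/C/O per residue + the allocated proxies
    proxies_per_res: dict[int, list[str]] = {i: [] for i in range(spec.n_residues)}
    for ((i, j, _), _), (feat_i, feat_j) in zip(entries, allocations):
        for nm in feat_i:
            if nm not in proxies_per_res[i]:
                proxies_per_res[i].append(nm)
        for nm in feat_j:
            if nm not in proxies_per_res[j]:
                proxies_per_res[j].append(nm)

    names, elements, coords = [], [], []
    residues = []
    proxy_atom_index: dict[tuple[int, str], int] = {}
    for i in range(spec.n_residues):
        ca = np.array([i * _GRID_SPACING, 0.0, 0.0])
        start = len(names)
        for nm, el, off in (("N", "N", (-1.2, 0.9, 0.0)),
                            ("CA", "C", (0.0, 0.0, 0.0)),
                            ("C", "C", (1.2, 0.9, 0.0)),
                            ("O", "O", (1.3, 2.1, 0.0))):
            names.append(nm)
            elements.append(el)
            coords.append(ca + np.asarray(off))
        for nm in proxies_per_res[i]:
            proxy_atom_index[(i, nm)] = len(names)
            names.append(nm)
            elements.append(nm[0])
            coords.append(ca + np.array([0.0, 2.5, 0.0]))  # placeholder
        residues.append(ResidueRecord(chain=spec.chain, number=i + 1, icode="",
                                      name=resnames[i], atom_start=start,
                                      atom_stop=len(names)))

    base = np.asarray(coords, dtype=float)
    model = StructureModel(residues=residues,
                           atom_names=np.asarray(names, dtype=object),
                           elements=np.asarray(elements, dtype=object),
                           coords=base.copy())

    # per-entry zone geometry
    zones = []
    for rank, (((i, j, itype), rule), (feat_i, feat_j)) in enumerate(
            zip(entries, allocations)):
        cutoff = spec.params.cutoff(itype)
        center = np.array([(i + j) / 2.0 * _GRID_SPACING, 0.0,
                           (rank + 1) * _ZONE_SPACING])
        zones.append((i, j, rule, center, cutoff, feat_i, feat_j))

    def place(coord_frame: np.ndarray, res: int, feature_names, pos: np.ndarray):
        """Place a proxy feature (atom or ring) so its centroid is at pos."""
        if len(feature_names) == 1:
            coord_frame[proxy_atom_index[(res, feature_names[0])]] = pos
        else:  # hexagonal ring in the y-z plane, centroid exactly at pos
            r = 1.39
            for a, nm in enumerate(feature_names):
                ang = 2 * np.pi * a / len(feature_names)
                coord_frame[proxy_atom_index[(res, nm)]] = pos + np.array(
                    [0.0, r * np.cos(ang), r * np.sin(ang)])

    backbone_idx = np.array([k for k in range(model.n_atoms)
                             if str(model.atom_names[k]) in
                             ("N", "CA", "C", "O")], dtype=int)
    multiplier = np.ones(spec.n_residues) if spec.jitter_profile is None \
        else np.asarray(spec.jitter_profile, dtype=float)

    handles: dict[float, EnsembleHandle] = {}
    for t_index, temp in enumerate(spec.temperatures):
        frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
        for (i, j, rule, center, cutoff, feat_i, feat_j) in zones:
            on = _presence_array(rule, spec.n_frames, temp)
            for f in range(spec.n_frames):
                d = cutoff - _ON_MARGIN if on[f] else cutoff + _OFF_MARGIN
                half = np.array([d / 2.0, 0.0, 0.0])
                place(frames[f], i, feat_i, center - half)
                place(frames[f], j, feat_j, center + half)
        sigma = spec.backbone_jitter.get(temp, 0.0) \
            if isinstance(spec.backbone_jitter, Mapping) \
            else float(spec.backbone_jitter)
        if sigma > 0:
            rng = np.random.default_rng((spec.seed, t_index))
            noise = rng.normal(0.0, sigma,
                               (spec.n_frames, len(backbone_idx), 3))
            noise *= multiplier[model.atom_residue_index[backbone_idx]][None, :, None]
            frames[:, backbone_idx, :] += noise
        handles[float(temp)] = ensemble_from_arrays(model, frames, temp)
    return model, handles


def schedule_occupancy(spec: SyntheticEnsembleSpec, temperature: float
                       ) -> dict[ContactKey, float]:
    """Ground-truth contact frequency of every scheduled pair at one rung."""
    out = {}
    resnames = {}
    for (i, j, itype), _ in sorted(spec.schedule.items(), key=lambda kv: kv[0]):
        name_i, name_j = _TYPE_TEMPLATES[itype]
        resnames[i], resnames[j] = name_i, name_j
    for (i, j, itype), rule in spec.schedule.items():
        on = _presence_array(rule, spec.n_frames, temperature)
        key = ContactKey.make(
            ResidueLabel(spec.chain, i + 1, "", resnames[i]),
            ResidueLabel(spec.chain, j + 1, "", resnames[j]), itype)
        out[key] = float(on.mean())
    return out


# ----------------------------------------------------------------------
@dataclass
class SyntheticLadderSpec:
    """Spec for a contact-frequency matrix with planted thermal responses.

    Melting contacts follow f(T) = 1/(1 + exp((T - Tm)/w)) (decreasing),
    with midpoints staggered across the ladder; forming contacts follow the
    mirrored (rising) curve with midpoints concentrated toward the hot end
    of the ladder and a sub-unit plateau. The asymmetry is deliberate: a
    forming family that exactly mirrors the melting family (same midpoints,
    same amplitude) is perfectly anticorrelated with it after centering and
    collapses into the *same* principal component, so no two-mode structure
    would exist to recover. Contacts that break early and contacts that
    assemble only near the hot extreme are also the physically expected
    picture. Inert contacts sit at a constant random level. Gaussian noise
    (sigma) is added and the result clipped to [0, 1].
    """

    n_melting: int = 20
    n_forming: int = 20
    n_inert: int = 60
    temperatures: Sequence[float] = DEFAULT_LADDER
    melting_midpoints: tuple[float, float] = (300.0, 345.0)
    melting_width: float = 10.0                  # logistic width w (K)
    forming_midpoints: tuple[float, float] = (378.0, 390.0)
    forming_width: float = 6.0
    forming_amplitude: float = 0.85
    sigma: float = 0.02
    itype: str = "hydrophobic"
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise SyntheticError("noise sigma must be >= 0")
        t = np.asarray(self.temperatures, dtype=float)
        for pair in (self.melting_midpoints, self.forming_midpoints):
            m = np.asarray(pair, dtype=float)
            if np.any(m < t.min()) or np.any(m > t.max()):
                raise SyntheticError("midpoints must lie within the ladder span")
        if not (0 < self.forming_amplitude <= 1):
            raise SyntheticError("forming amplitude must be in (0, 1]")


def synth_contact_ladder(spec: SyntheticLadderSpec
                         ) -> tuple[ContactFrequencyMatrix,
                                    dict[ContactKey, str]]:
    """Planted melting/forming/inert contact matrix and its truth labels."""
    rng = np.random.default_rng(spec.seed)
    temps = np.asarray(spec.temperatures, dtype=float)
    n_total = spec.n_melting + spec.n_forming + spec.n_inert
    if n_total < 2:
        raise SyntheticError("need at least two contacts")

    melt_tm = np.linspace(*spec.melting_midpoints, max(spec.n_melting, 1))
    form_tm = np.linspace(*spec.forming_midpoints, max(spec.n_forming, 1))

    keys, rows, labels = [], [], {}
    # residue numbering: each contact gets a private, well-separated pair
    def make_key(idx: int) -> ContactKey:
        a = ResidueLabel("A", 3 * idx + 1, "", "LEU")
        b = ResidueLabel("B", 3 * idx + 2, "", "VAL")
        return ContactKey.make(a, b, spec.itype)

    idx = 0
    for c in range(spec.n_melting):
        rows.append(1.0 / (1.0 + np.exp((temps - melt_tm[c]) / spec.melting_width)))
        keys.append(make_key(idx)); labels[keys[-1]] = "melting"; idx += 1
    for c in range(spec.n_forming):
        rows.append(spec.forming_amplitude /
                    (1.0 + np.exp(-(temps - form_tm[c]) / spec.forming_width)))
        keys.append(make_key(idx)); labels[keys[-1]] = "forming"; idx += 1
    for c in range(spec.n_inert):
        level = rng.uniform(0.1, 0.9)
        rows.append(np.full_like(temps, level))
        keys.append(make_key(idx)); labels[keys[-1]] = "inert"; idx += 1

    values = np.asarray(rows)
    if spec.sigma > 0:
        values = values + rng.normal(0.0, spec.sigma, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    order = sorted(range(len(keys)), key=lambda i: keys[i].sort_key)
    matrix = ContactFrequencyMatrix(keys=[keys[i] for i in order],
                                    temperatures=temps,
                                    values=values[order])
    return matrix, labels


# ----------------------------------------------------------------------
def synth_msa(column_specs: Sequence[Mapping[str, float]], n_sequences: int,
              seed: int, query_id: str = "query"):
    """Sample an alignment whose columns follow given symbol distributions.

    Each spec is a probability map over amino acids and ``-``. The first
    row is the designated query, resampled gap-free (probabilities
    renormalized over amino acids). Empirical column entropies converge to
    the spec entropies as ``n_sequences`` grows.
    """
    from .conservation import AlignmentBlock, AMINO_ACIDS

    if n_sequences < 2:
        raise SyntheticError("need at least two sequences")
    rng = np.random.default_rng(seed)
    cols = []
    query = []
    for spec in column_specs:
        symbols = list(spec)
        probs = np.asarray([spec[s] for s in symbols], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise SyntheticError(
                f"column distribution sums to {probs.sum()}, not 1")
        bad = [s for s in symbols if s != "-" and s not in AMINO_ACIDS]
        if bad:
            raise SyntheticError(f"unknown symbols in column spec: {bad}")
        cols.append(rng.choice(symbols, size=n_sequences, p=probs))
        aa = [(s, p) for s, p in zip(symbols, probs) if s != "-"]
        if not aa:
            raise SyntheticError("column spec has no amino-acid mass; "
                                 "cannot build a gap-free query row")
        aa_syms, aa_p = zip(*aa)
        aa_p = np.asarray(aa_p) / sum(aa_p)
        query.append(str(rng.choice(aa_syms, p=aa_p)))
    matrix = np.stack(cols, axis=1)          # (n_seq, n_cols)
    rows = ["".join(query)] + ["".join(r) for r in matrix[1:]]
    ids = [query_id] + [f"seq{i:05d}" for i in range(1, n_sequences)]
    return AlignmentBlock(ids=ids, rows=rows)


# ----------------------------------------------------------------------
def synth_feature_clusters(centers: np.ndarray, spreads, sizes,
                           seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian blobs in {entropy, sensitivity, cc} space with known labels."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[1] != 3:
        raise SyntheticError("centers must be in 3-feature space")
    sizes = np.atleast_1d(np.asarray(sizes, dtype=int))
    spreads = np.broadcast_to(np.asarray(spreads, dtype=float),
                              (len(centers),))
    if len(sizes) != len(centers):
        raise SyntheticError("one size per center required")
    rng = np.random.default_rng(seed)
    points, labels = [], []
    for c, (center, spread, size) in enumerate(zip(centers, spreads, sizes)):
        points.append(rng.normal(center, spread, size=(size, 3)))
        labels.extend([c] * size)
    X = np.vstack(points)
    from .clustering import residue_index
    index = residue_index([ResidueLabel("A", i + 1, "", "GLY")
                           for i in range(len(X))])
    table = pd.DataFrame(X, columns=["entropy", "sensitivity", "cc"],
                         index=index)
    return standardize(table), np.asarray(labels)
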