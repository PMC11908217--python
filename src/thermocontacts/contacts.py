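"""Typed noncovalent residue-residue contact detection and frequencies.

A *contact* is a typed, unordered residue pair whose geometric criterion is
satisfied in a frame. Criteria are heavy-atom distance rules (crystal
structures carry no hydrogens, so trajectory and crystal inputs are treated
uniformly):

=============  =============================================================
salt_bridge    Arg/Lys/His side-chain N within 4.0 A of Asp/Glu carboxylate O
hydrophobic    side-chain C of {ALA,VAL,LEU,ILE,MET,PHE,TRP,PRO} within
               4.5 A of another such C
hbond          heavy-atom proxy: any N/O within 3.5 A of an N/O of another
               residue
cation_pi      Arg/Lys cationic-group centroid within 6.0 A of an aromatic
               ring centroid (PHE/TYR/TRP/HIS)
pi_stack       two aromatic ring centroids within 5.5 A
=============  =============================================================

All cutoffs are configurable (:class:`GeometryConfig`). Pairs separated by
two or fewer positions in sequence within the same chain are excluded, so
trivially persistent local contacts do not dominate the networks. A contact
counts once per (pair, type) per frame no matter how many atom pairs satisfy
the criterion. Frequencies are fractions of sampled frames, computed per
temperature independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import EnsembleHandle, ResidueLabel, StructureModel

INTERACTION_TYPES = ("salt_bridge", "hydrophobic", "hbond", "cation_pi", "pi_stack")

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
BASIC_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_SIDECHAIN_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
CATIONIC_GROUP_ATOMS = {
    "ARG": ("CZ", "NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class GeometryConfig:
    """Distance cutoffs (Angstrom) for the typed contact criteria."""

    salt_bridge_cutoff: float = 4.0
    hydrophobic_cutoff: float = 4.5
    hbond_cutoff: float = 3.5
    cation_pi_cutoff: float = 6.0
    pi_stack_cutoff: float = 5.5
    min_sequence_separation: int = 3  # same-chain |i-j| <= 2 excluded

    def cutoff(self, itype: str) -> float:
        return getattr(self, f"{itype}_cutoff")


class ContactKey(NamedTuple):
    """Canonically ordered typed residue pair (A before B)."""

    res_a: ResidueLabel
    res_b: ResidueLabel
    itype: str

    @classmethod
    def make(cls, a: ResidueLabel, b: ResidueLabel, itype: str) -> "ContactKey":
        if a.sort_key == b.sort_key:
            raise ValueError(f"self-contact not allowed: {a}")
        if b.sort_key < a.sort_key:
            a, b = b, a
        return cls(a, b, itype)

    def __str__(self) -> str:
        return f"{self.res_a}--{self.res_b}[{self.itype}]"

    @property
    def sort_key(self):
        return (self.res_a.sort_key, self.res_b.sort_key, self.itype)


class ContactError(ValueError):
    pass


def _is_sidechain_carbon(name: str) -> bool:
    return name.startswith("C") and name not in BACKBONE_NAMES


class ContactDetector:
    """Precomputes per-model atom groupings for fast per-frame detection."""

    def __init__(self, model: StructureModel,
                 types: Iterable[str] = INTERACTION_TYPES,
                 params: GeometryConfig | None = None):
        self.model = model
        self.params = params or GeometryConfig()
        self.types = tuple(types)
        unknown = [t for t in self.types if t not in INTERACTION_TYPES]
        if unknown:
            raise ContactError(
                f"unknown interaction type(s) {unknown}; "
                f"supported: {list(INTERACTION_TYPES)}")

        res = model.residues
        self._labels = [r.label for r in res]
        self._chain = np.array([r.chain for r in res], dtype=object)
        # author residue number carries the sequence-separation rule
        self._seqpos = np.array([r.number for r in res], dtype=int)

        names = model.atom_names
        elements = model.elements
        res_of = model.atom_residue_index

        def group(mask: np.ndarray):
            idx = np.nonzero(mask)[0]
            return idx, res_of[idx]

        mask_basic = np.zeros(model.n_atoms, dtype=bool)
        mask_acid = np.zeros(model.n_atoms, dtype=bool)
        mask_hyd = np.zeros(model.n_atoms, dtype=bool)
        mask_no = np.zeros(model.n_atoms, dtype=bool)
        for k in range(model.n_atoms):
            r = res[res_of[k]]
            if r.is_hetero:
                continue
            nm = str(names[k])
            if nm in BASIC_SIDECHAIN_N.get(r.name, ()):
                mask_basic[k] = True
            if nm in ACIDIC_SIDECHAIN_O.get(r.name, ()):
                mask_acid[k] = True
            if r.name in HYDROPHOBIC_RESIDUES and _is_sidechain_carbon(nm):
                mask_hyd[k] = True
            if str(elements[k]) in ("N", "O"):
                mask_no[k] = True
        self._basic = group(mask_basic)
        self._acid = group(mask_acid)
        self._hyd = group(mask_hyd)
        self._no = group(mask_no)

        # ring / cationic-group member atom indices per residue
        self._rings: list[tuple[int, np.ndarray]] = []
        self._cations: list[tuple[int, np.ndarray]] = []
        for i, r in enumerate(res):
            if r.is_hetero:
                continue
            ring_names = AROMATIC_RING_ATOMS.get(r.name)
            if ring_names:
                idx = [model.atom_index(i, nm) for nm in ring_names]
                idx = [k for k in idx if k is not None]
                if len(idx) >= 3:
                    self._rings.append((i, np.asarray(idx)))
            cat_names = CATIONIC_GROUP_ATOMS.get(r.name)
            if cat_names:
                idx = [model.atom_index(i, nm) for nm in cat_names]
                idx = [k for k in idx if k is not None]
                if idx:
                    self._cations.append((i, np.asarray(idx)))

    # ------------------------------------------------------------------
    def _allowed_pair(self, ri: int, rj: int) -> bool:
        if ri == rj:
            return False
        if self._chain[ri] == self._chain[rj]:
            if abs(int(self._seqpos[ri]) - int(self._seqpos[rj])) \
                    < self.params.min_sequence_separation:
                return False
        return True

    def _emit(self, out: set, ri: int, rj: int, itype: str) -> None:
        if self._allowed_pair(ri, rj):
            out.add(ContactKey.make(self._labels[ri], self._labels[rj], itype))

    def detect(self, coords: np.ndarray) -> set[ContactKey]:
        """Detect all requested contact types in one frame."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.model.n_atoms, 3):
            raise ContactError(
                f"frame shape {coords.shape} does not match model "
                f"({self.model.n_atoms} atoms)")
        out: set[ContactKey] = set()
        p = self.params

        def cross(ga, gb, cutoff, itype):
            idx_a, res_a = ga
            idx_b, res_b = gb
            if len(idx_a) == 0 or len(idx_b) == 0:
                return
            ta = cKDTree(coords[idx_a])
            tb = cKDTree(coords[idx_b])
            for ia, neigh in enumerate(ta.query_ball_tree(tb, cutoff)):
                for ib in neigh:
                    self._emit(out, int(res_a[ia]), int(res_b[ib]), itype)

        if "salt_bridge" in self.types:
            cross(self._basic, self._acid, p.salt_bridge_cutoff, "salt_bridge")
        if "hydrophobic" in self.types:
            cross(self._hyd, self._hyd, p.hydrophobic_cutoff, "hydrophobic")
        if "hbond" in self.types:
            cross(self._no, self._no, p.hbond_cutoff, "hbond")
        if "cation_pi" in self.types and self._cations and self._rings:
            cat_c = np.stack([coords[idx].mean(axis=0) for _, idx in self._cations])
            ring_c = np.stack([coords[idx].mean(axis=0) for _, idx in self._rings])
            d = np.linalg.norm(cat_c[:, None, :] - ring_c[None, :, :], axis=-1)
            for ia, ib in zip(*np.nonzero(d <= p.cation_pi_cutoff)):
                self._emit(out, self._cations[ia][0], self._rings[ib][0], "cation_pi")
        if "pi_stack" in self.types and len(self._rings) >= 2:
            ring_c = np.stack([coords[idx].mean(axis=0) for _, idx in self._rings])
            d = np.linalg.norm(ring_c[:, None, :] - ring_c[None, :, :], axis=-1)
            for ia, ib in zip(*np.nonzero(d <= p.pi_stack_cutoff)):
                if ia < ib:
                    self._emit(out, self._rings[ia][0], self._rings[ib][0], "pi_stack")
        return out


def detect_contacts_frame(coords: np.ndarray, model: StructureModel,
                          types: Iterable[str] = INTERACTION_TYPES,
                          params: GeometryConfig | None = None) -> set[ContactKey]:
    """One-shot per-frame detection (builds a detector; for many frames use
    :class:`ContactDetector` or :func:`contact_frequencies` directly)."""
    return ContactDetector(model, types, params).detect(coords)


@dataclass
class ContactFrequencyTable:
    """Per-temperature contact frequencies (fractions of sampled frames)."""

    temperature: float
    frequencies: dict[ContactKey, float]
    n_frames: int

    def __post_init__(self):
        for k, f in self.frequencies.items():
            if not (0.0 <= f <= 1.0):
                raise ContactError(f"frequency out of [0,1] for {k}: {f}")


def contact_frequencies(ensemble: EnsembleHandle, model: StructureModel,
                        types: Iterable[str] = INTERACTION_TYPES,
                        params: GeometryConfig | None = None,
                        stride: int = 1) -> ContactFrequencyTable:
    """Aggregate per-frame detections to frequencies at one temperature."""
    if stride < 1:
        raise ContactError("stride must be >= 1")
    detector = ContactDetector(model, types, params)
    counts: dict[ContactKey, int] = {}
    n_sampled = 0
    for i, frame in enumerate(ensemble.iter_frames()):
        if i % stride:
            continue
        n_sampled += 1
        for key in detector.detect(frame):
            counts[key] = counts.get(key, 0) + 1
    if n_sampled == 0:
        raise ContactError("no frames sampled after striding")
    freqs = {k: c / n_sampled for k, c in sorted(counts.items(),
                                                 key=lambda kv: kv[0].sort_key)}
    return ContactFrequencyTable(temperature=ensemble.temperature,
                                 frequencies=freqs, n_frames=n_sampled)


@dataclass
class ContactFrequencyMatrix:
    """Contacts x temperatures frequency matrix.

    Rows are the union of contacts over all temperatures in canonical key
    order; a contact absent at a temperature has entry 0.
    """

    keys: list[ContactKey]
    temperatures: np.ndarray       # strictly increasing
    values: np.ndarray             # (n_contacts, n_temperatures)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ContactError("temperatures must be strictly increasing")
        if self.values.shape != (len(self.keys), len(self.temperatures)):
            raise ContactError("matrix shape mismatch")

    def restrict_to_type(self, itype: str) -> "ContactFrequencyMatrix":
        rows = [i for i, k in enumerate(self.keys) if k.itype == itype]
        return ContactFrequencyMatrix(
            keys=[self.keys[i] for i in rows],
            temperatures=self.temperatures,
            values=self.values[rows] if rows else
            np.empty((0, len(self.temperatures))),
        )

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for i, k in enumerate(self.keys):
            for j, t in enumerate(self.temperatures):
                rows.append((str(k.res_a), str(k.res_b), k.itype,
                             float(t), float(self.values[i, j])))
        return pd.DataFrame(rows, columns=["resA", "resB", "type",
                                           "temperature", "frequency"])

    def to_wide_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=[str(k) for k in self.keys],
                            columns=[f"{t:g}" for t in self.temperatures])


def assemble_matrix(tables: Sequence[ContactFrequencyTable]) -> ContactFrequencyMatrix:
    """Union contacts across per-temperature tables into one matrix."""
    if len(tables) < 2:
        raise ContactError("need at least two per-temperature tables")
    temps = [t.temperature for t in tables]
    if len(set(temps)) != len(temps):
        raise ContactError(f"duplicate temperatures in tables: {sorted(temps)}")
    order = np.argsort(temps)
    tables = [tables[i] for i in order]
    keys = sorted({k for t in tables for k in t.frequencies},
                  key=lambda k: k.sort_key)
    values = np.zeros((len(keys), len(tables)))
    index = {k: i for i, k in enumerate(keys)}
    for j, t in enumerate(tables):
        for k, f in t.frequencies.items():
            values[index[k], j] = f
    return ContactFrequencyMatrix(keys=keys,
                                  temperatures=np.array(sorted(temps)),
                                  values=values)
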