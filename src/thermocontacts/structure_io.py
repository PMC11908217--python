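"""Structure and ensemble I/O.

Reads PDB structures into a lightweight residue/atom model and exposes a
frame-stream contract over conformational ensembles (multi-model PDB or a
binary trajectory container such as DCD/XTC), one ensemble per temperature.

All downstream analyses key residues by *author* numbering, i.e. the
``(chain, residue number, insertion code)`` triple printed in the PDB file,
so that results line up with residue labels used in the literature
(e.g. "ARG10 - ASP183").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Standard amino acids, 3-letter -> 1-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "SOL"}


class ResidueLabel(NamedTuple):
    """Identity of a residue: chain, author number, insertion code, name."""

    chain: str
    number: int
    icode: str
    name: str

    def __str__(self) -> str:  # "A:ARG10" / "A:ARG10A" with icode
        return f"{self.chain}:{self.name}{self.number}{self.icode.strip()}"

    @property
    def sort_key(self):
        return (self.chain, self.number, self.icode)


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a :class:`StructureModel`.

    ``atom_start:atom_stop`` is the half-open slice of the model's atom
    arrays belonging to this residue.
    """

    chain: str
    number: int
    icode: str
    name: str
    atom_start: int
    atom_stop: int
    is_standard: bool = True
    is_hetero: bool = False

    @property
    def label(self) -> ResidueLabel:
        return ResidueLabel(self.chain, self.number, self.icode, self.name)


class StructureError(ValueError):
    pass


@dataclass
class StructureModel:
    """A protein structure as ordered residues over flat atom arrays."""

    residues: list[ResidueRecord]
    atom_names: np.ndarray          # (n_atoms,) str
    elements: np.ndarray            # (n_atoms,) str
    coords: np.ndarray              # (n_atoms, 3) float, Angstrom
    source: Path | None = None
    atom_residue_index: np.ndarray = field(default=None)  # (n_atoms,) int

    def __post_init__(self):
        if self.atom_residue_index is None:
            idx = np.empty(len(self.atom_names), dtype=int)
            for i, r in enumerate(self.residues):
                idx[r.atom_start:r.atom_stop] = i
            self.atom_residue_index = idx
        keys = [(r.chain, r.number, r.icode) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (chain, number, icode) residue keys")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def polymer_residues(self, chain: str | None = None) -> list[ResidueRecord]:
        out = [r for r in self.residues if not r.is_hetero]
        if chain is not None:
            out = [r for r in out if r.chain == chain]
        return out

    def residue_atoms(self, i: int) -> slice:
        r = self.residues[i]
        return slice(r.atom_start, r.atom_stop)

    def atom_index(self, res_index: int, name: str) -> int | None:
        r = self.residues[res_index]
        for k in range(r.atom_start, r.atom_stop):
            if self.atom_names[k] == name:
                return k
        return None

    def calpha_indices(self, chain: str | None = None) -> np.ndarray:
        """Atom indices of Calpha atoms of polymer residues, residue order."""
        idx = []
        for i, r in enumerate(self.residues):
            if r.is_hetero or (chain is not None and r.chain != chain):
                continue
            k = self.atom_index(i, "CA")
            if k is not None:
                idx.append(k)
        return np.asarray(idx, dtype=int)


def load_structure(path: str | Path, *, exclude_waters: bool = True) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Waters are excluded by default; other heteroatoms are retained but
    flagged. Alternate locations keep the highest-occupancy conformer
    (tie: first encountered). Hydrogens are dropped — all geometric
    criteria downstream are defined on heavy atoms.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    model = next(structure.get_models(), None)
    if model is None:
        raise StructureError(f"{path}: no models found")

    residues: list[ResidueRecord] = []
    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    n_polymer = 0
    for chain in model:
        for res in chain:
            hetfield, resseq, icode = res.id
            resname = res.get_resname().strip()
            if exclude_waters and resname in WATER_NAMES:
                continue
            is_het = hetfield.strip() != ""
            is_std = resname in THREE_TO_ONE
            start = len(names)
            for atom in res.get_atoms():
                if atom.is_disordered():
                    children = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: -a.get_occupancy() if a.get_occupancy() else 0.0,
                    )
                    atom = children[0]
                el = (atom.element or "").strip().upper()
                if el == "H" or atom.get_name().startswith("H"):
                    continue
                names.append(atom.get_name().strip())
                elements.append(el or atom.get_name()[0])
                coords.append(np.asarray(atom.get_coord(), dtype=float))
            if len(names) == start:
                continue
            residues.append(ResidueRecord(
                chain=chain.id.strip() or "A", number=int(resseq),
                icode=icode.strip(), name=resname,
                atom_start=start, atom_stop=len(names),
                is_standard=is_std, is_hetero=is_het,
            ))
            if not is_het:
                n_polymer += 1
    if n_polymer == 0:
        raise StructureError(f"{path}: no polymer residues found")
    residues.sort(key=lambda r: (r.chain, r.number, r.icode))
    # re-pack atoms in residue order
    order = np.concatenate([np.arange(r.atom_start, r.atom_stop) for r in residues])
    packed = []
    pos = 0
    for r in residues:
        n = r.atom_stop - r.atom_start
        packed.append(ResidueRecord(r.chain, r.number, r.icode, r.name,
                                    pos, pos + n, r.is_standard, r.is_hetero))
        pos += n
    return StructureModel(
        residues=packed,
        atom_names=np.asarray(names, dtype=object)[order],
        elements=np.asarray(elements, dtype=object)[order],
        coords=np.asarray(coords, dtype=float)[order],
        source=path,
    )


def extract_sequence(model: StructureModel, chain: str) -> str:
    """One-letter sequence of a chain's polymer residues, in residue order.

    Nonstandard residues map to ``X`` (with a logged note).
    """
    if chain not in model.chains:
        raise StructureError(
            f"unknown chain {chain!r}; available chains: {model.chains}")
    residues = model.polymer_residues(chain)
    if not residues:
        raise StructureError(f"chain {chain!r} has no polymer residues")
    letters = []
    for r in residues:
        one = THREE_TO_ONE.get(r.name)
        if one is None:
            logger.info("nonstandard residue %s mapped to X", r.label)
            one = "X"
        letters.append(one)
    return "".join(letters)


class EnsembleError(ValueError):
    pass


@dataclass
class EnsembleHandle:
    """Streaming access to one per-temperature conformational ensemble.

    Frames are ``(n_atoms, 3)`` coordinate arrays aligned to the reference
    model's atom order. Iteration order is deterministic.
    """

    model: StructureModel
    temperature: float
    n_frames: int
    _coords: np.ndarray | None = None          # in-memory (n_frames, n_atoms, 3)
    _universe: object | None = None            # MDAnalysis Universe backend

    def __post_init__(self):
        if self.temperature is None or self.temperature <= 0:
            raise EnsembleError(
                f"temperature must be positive (got {self.temperature})")
        if self.n_frames < 1:
            raise EnsembleError("ensemble must contain at least one frame")

    def iter_frames(self) -> Iterator[np.ndarray]:
        if self._coords is not None:
            for f in self._coords:
                yield np.array(f, dtype=float)
        else:
            for ts in self._universe.trajectory:
                yield np.array(ts.positions, dtype=float)

    def frames_array(self) -> np.ndarray:
        """Materialize all frames as (n_frames, n_atoms, 3)."""
        if self._coords is not None:
            return np.array(self._coords, dtype=float)
        return np.stack(list(self.iter_frames()))


def ensemble_from_arrays(model: StructureModel, coords: np.ndarray,
                         temperature: float) -> EnsembleHandle:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[1] != model.n_atoms:
        raise EnsembleError(
            f"atom-count mismatch: frames have "
            f"{coords.shape[1] if coords.ndim == 3 else '?'} atoms, "
            f"model has {model.n_atoms}")
    return EnsembleHandle(model=model, temperature=float(temperature),
                          n_frames=coords.shape[0], _coords=coords)


def open_ensemble(model: StructureModel, trajectory: str | Path,
                  temperature: float) -> EnsembleHandle:
    """Open a trajectory (multi-model PDB, DCD, XTC, ...) against ``model``.

    Frames stream through MDAnalysis; nothing requires holding the whole
    trajectory in memory.
    """
    import MDAnalysis as mda

    if temperature is None or temperature <= 0:
        raise EnsembleError(f"temperature must be positive (got {temperature})")
    trajectory = Path(trajectory)
    # topology built from the model itself: the source file may contain
    # atoms (waters, hydrogens, altlocs) the model excludes
    u = _model_universe(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u.load_new(str(trajectory))
        except (ValueError, OSError) as exc:
            raise EnsembleError(
                f"cannot open trajectory {trajectory} against model with "
                f"{model.n_atoms} atoms: {exc}") from exc
    if len(u.atoms) != model.n_atoms:
        raise EnsembleError(
            f"atom-count mismatch: trajectory has {len(u.atoms)} atoms, "
            f"model has {model.n_atoms}")
    return EnsembleHandle(model=model, temperature=float(temperature),
                          n_frames=len(u.trajectory), _universe=u)


def write_pdb(model: StructureModel, path: str | Path,
              bfactors: np.ndarray | None = None,
              frames: np.ndarray | None = None) -> Path:
    """Write the model (optionally multi-frame) to PDB.

    ``bfactors`` is a per-atom array placed in the B-factor column.
    ``frames`` is an optional (n_frames, n_atoms, 3) array written as a
    multi-model PDB.
    """
    import MDAnalysis as mda

    path = Path(path)
    u = _model_universe(model)
    if bfactors is not None:
        u.atoms.tempfactors = np.asarray(bfactors, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if frames is None:
            u.atoms.write(str(path))
        else:
            frames = np.asarray(frames, dtype=float)
            with mda.Writer(str(path), n_atoms=model.n_atoms, multiframe=True) as w:
                for f in frames:
                    u.atoms.positions = f
                    w.write(u.atoms)
    return path


def per_atom_chains(model: StructureModel) -> list[str]:
    return [model.residues[i].chain for i in model.atom_residue_index]


def _model_universe(model: StructureModel):
    """MDAnalysis Universe built from the model's atom arrays."""
    import MDAnalysis as mda

    n_res = len(model.residues)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(model.n_atoms, n_residues=n_res,
                               atom_resindex=model.atom_residue_index,
                               residue_segindex=np.zeros(n_res, dtype=int),
                               trajectory=True)
        u.add_TopologyAttr("names", [str(n) for n in model.atom_names])
        u.add_TopologyAttr("elements", [str(e) for e in model.elements])
        u.add_TopologyAttr("resnames", [r.name for r in model.residues])
        u.add_TopologyAttr("resids", [r.number for r in model.residues])
        u.add_TopologyAttr("icodes", [r.icode for r in model.residues])
        u.add_TopologyAttr("chainIDs", per_atom_chains(model))
        u.add_TopologyAttr("segids", ["SYSTEM"])
        u.add_TopologyAttr("occupancies", np.ones(model.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(model.n_atoms))
        u.add_TopologyAttr("record_types",
                           ["HETATM" if model.residues[i].is_hetero else "ATOM"
                            for i in model.atom_residue_index])
        u.atoms.positions = model.coords
    return u
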