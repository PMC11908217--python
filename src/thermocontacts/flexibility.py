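"""Per-residue flexibility: Calpha RMSF per temperature and the
temperature-sensitivity score.

RMSF_i = sqrt( <|x_i(t) - <x_i>|^2>_t ) over frames rigid-body fitted to an
iteratively refined mean structure. The temperature-sensitivity score of a
residue is the population standard deviation of its RMSF across the
temperature ladder (the ladder is the whole population, not a sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import EnsembleHandle, ResidueLabel, StructureModel


class FlexibilityError(ValueError):
    pass


def _fit_frame(frame: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of one frame onto a reference."""
    import warnings

    fc = frame.mean(axis=0)
    rc = ref.mean(axis=0)
    with warnings.catch_warnings():
        # collinear atom sets leave the rotation underdetermined; any
        # optimum gives the same fitted coordinates
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref - rc, frame - fc)
    return rot.apply(frame - fc) + rc


def superpose_frames(frames: np.ndarray, *, tol: float = 1e-6,
                     max_iter: int = 20) -> np.ndarray:
    """Iteratively superpose frames onto their converged mean structure.

    Each round fits every frame to the current reference (first frame
    initially), recomputes the mean, and repeats until the mean moves less
    than ``tol`` (Angstrom RMS) or ``max_iter`` rounds. Deterministic.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise FlexibilityError("expected (n_frames, n_atoms, 3) array")
    n_frames, n_atoms, _ = frames.shape
    if n_frames < 2:
        raise FlexibilityError("need at least two frames to superpose")
    if n_atoms < 3:
        raise FlexibilityError("need at least three atoms to superpose")
    ref = frames[0]
    aligned = frames
    for _ in range(max_iter):
        aligned = np.stack([_fit_frame(f, ref) for f in frames])
        mean = aligned.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((mean - ref) ** 2, axis=1)))
        ref = mean
        if shift < tol:
            break
    return aligned


@dataclass
class RMSFProfile:
    """Per-residue Calpha RMSF (Angstrom) at one temperature."""

    temperature: float
    residues: list[ResidueLabel]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise FlexibilityError("RMSF must be non-negative")
        if len(self.residues) != len(self.values):
            raise FlexibilityError("residue/value length mismatch")

    def as_dict(self) -> dict[ResidueLabel, float]:
        return dict(zip(self.residues, self.values.tolist()))


def rmsf(aligned: np.ndarray) -> np.ndarray:
    """Root-mean-square fluctuation per atom of an aligned frame stack."""
    aligned = np.asarray(aligned, dtype=float)
    if aligned.ndim != 3 or aligned.shape[0] < 2:
        raise FlexibilityError(
            "RMSF requires an aligned (n_frames>=2, n_atoms, 3) stack")
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=-1), axis=0))


def rmsf_profile(ensemble: EnsembleHandle, model: StructureModel,
                 chain: str | None = None, *,
                 discard_fraction: float = 0.0,
                 fit_mask: np.ndarray | None = None) -> RMSFProfile:
    """Calpha RMSF of one per-temperature ensemble.

    ``discard_fraction`` drops the leading fraction of frames (e.g. an
    equilibration period); ``fit_mask`` optionally restricts the atoms used
    for the superposition fit (RMSF is still reported for all Calphas).
    """
    ca = model.calpha_indices(chain)
    if len(ca) < 3:
        raise FlexibilityError("fewer than three Calpha atoms")
    frames = ensemble.frames_array()[:, ca, :]
    if discard_fraction:
        start = int(len(frames) * discard_fraction)
        frames = frames[start:]
    if fit_mask is not None:
        # fit on masked atoms, apply transform to all: do full fit on mask,
        # then re-fit full coordinates using the same reference subset
        aligned_sub = superpose_frames(frames[:, fit_mask, :])
        ref = aligned_sub.mean(axis=0)
        aligned = np.stack([
            _apply_subset_fit(f, f[fit_mask], ref) for f in frames])
    else:
        aligned = superpose_frames(frames)
    values = rmsf(aligned)
    labels = [model.residues[i].label
              for i in model.atom_residue_index[ca]]
    return RMSFProfile(temperature=ensemble.temperature,
                       residues=labels, values=values)


def _apply_subset_fit(frame: np.ndarray, sub: np.ndarray,
                      ref_sub: np.ndarray) -> np.ndarray:
    import warnings

    fc = sub.mean(axis=0)
    rc = ref_sub.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref_sub - rc, sub - fc)
    return rot.apply(frame - fc) + rc


@dataclass
class SensitivityProfile:
    """Per-residue std of RMSF across the temperature ladder (Angstrom)."""

    residues: list[ResidueLabel]
    values: np.ndarray
    temperatures: np.ndarray

    def as_dict(self) -> dict[ResidueLabel, float]:
        return dict(zip(self.residues, np.asarray(self.values).tolist()))


def temperature_sensitivity(profiles: Sequence[RMSFProfile]) -> SensitivityProfile:
    """Population standard deviation of RMSF across temperatures, per residue."""
    if len(profiles) < 2:
        raise FlexibilityError("need RMSF profiles at >= 2 temperatures")
    ref = profiles[0].residues
    for p in profiles[1:]:
        if p.residues != ref:
            missing = set(map(str, ref)).symmetric_difference(map(str, p.residues))
            raise FlexibilityError(
                f"residue sets differ between profiles: {sorted(missing)}")
    stack = np.stack([p.values for p in profiles])
    return SensitivityProfile(
        residues=list(ref),
        values=stack.std(axis=0, ddof=0),
        temperatures=np.array(sorted(p.temperature for p in profiles)),
    )
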