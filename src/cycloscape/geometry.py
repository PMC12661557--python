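"""Backbone geometry: superposed RMSD, radius of gyration, alignment.

All distances are in Å. Structures are plain ``(n_atoms, 3)`` float arrays
accompanied by per-atom labels ``(residue_index, atom_name)``; only the
backbone heavy atoms N, CA, C, O enter any computation. Atom correspondence
is positional (label order), with no permutation or ring-symmetry search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "BACKBONE_ATOMS",
    "Trajectory",
    "ObservableSeries",
    "backbone_rmsd",
    "batch_rmsd",
    "superpose",
    "radius_of_gyration",
    "observables",
    "align_trajectory",
    "ensemble_spread",
    "select_temperature_frames",
]


@dataclass
class Trajectory:
    """A multi-frame structure: ``frames`` is (n_frames, n_atoms, 3) in Å.

    ``atom_labels`` is a list of ``(residue_index, atom_name)`` tuples shared
    by every frame. ``tag`` identifies the simulation the frames came from.
    """

    frames: np.ndarray
    atom_labels: list[tuple[int, str]]
    timestep_ps: float = 0.0
    tag: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atom_labels):
            raise ValueError("atom count does not match atom_labels")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def backbone_indices(self) -> np.ndarray:
        names = np.array([name for _, name in self.atom_labels])
        return np.flatnonzero(np.isin(names, BACKBONE_ATOMS))

    def subset(self, frame_indices: np.ndarray) -> "Trajectory":
        return replace(self, frames=self.frames[frame_indices])


@dataclass
class ObservableSeries:
    """Per-frame backbone RMSD to a reference and radius of gyration (Å)."""

    rmsd: np.ndarray
    rg: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        self.rg = np.asarray(self.rg, dtype=float)
        if self.rmsd.shape != self.rg.shape:
            raise ValueError("rmsd and rg must have equal length")
        if np.any(self.rmsd < 0):
            raise ValueError("rmsd values must be nonnegative")

    def __len__(self) -> int:
        return self.rmsd.size


def _backbone_view(coords: np.ndarray, labels) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if labels is None:
        return coords
    names = np.array([name for _, name in labels])
    return coords[np.isin(names, BACKBONE_ATOMS)]


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimally superpose ``mobile`` onto ``target`` (Kabsch).

    Returns the transformed copy of ``mobile`` and the resulting RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(
            f"coordinate shapes differ: {mobile.shape} vs {target.shape}"
        )
    mob_c = mobile.mean(axis=0)
    tar_c = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tar_c, mobile - mob_c)
    moved = rot.apply(mobile - mob_c) + tar_c
    # residual computed from coordinates, not the rssd trace formula, to
    # avoid catastrophic cancellation near zero deviation
    rmsd = np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))
    return moved, float(rmsd)


def batch_rmsd(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superposed RMSD of many frames to one reference, vectorized Kabsch.

    ``frames`` is (F, N, 3), ``reference`` (N, 3); returns (F,) RMSDs in Å.
    """
    frames = np.asarray(frames, dtype=float)
    ref = np.asarray(reference, dtype=float)
    a = frames - frames.mean(axis=1, keepdims=True)
    b = ref - ref.mean(axis=0)
    R = _batch_rotations(frames, ref)
    # residuals from the rotated coordinates, not the SVD trace formula:
    # the latter loses ~7 digits to cancellation near zero deviation
    moved = np.einsum("fni,fij->fnj", a, R)
    return np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=2), axis=1))


def _batch_rotations(frames: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrices superposing each centered frame onto target."""
    a = frames - frames.mean(axis=1, keepdims=True)
    b = target - target.mean(axis=0)
    H = np.einsum("fni,nj->fij", a, b)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    # rotation applied as x @ R maps frame coords onto the target
    return np.einsum("fij,fjk,fkl->fil", U, D, Vt)


def backbone_rmsd(frame: np.ndarray, reference: np.ndarray, labels=None) -> float:
    """Minimum RMSD over rigid motions between two backbones (Å).

    If ``labels`` is given, both coordinate sets are first restricted to
    backbone heavy atoms (N, CA, C, O); correspondence is by array order.
    """
    a = _backbone_view(frame, labels)
    b = _backbone_view(reference, labels)
    if a.shape != b.shape:
        raise ValueError("frame and reference must have identical atom sets")
    _, rmsd = superpose(a, b)
    return rmsd


def radius_of_gyration(frame: np.ndarray, labels=None) -> float:
    """Unweighted root-mean-square distance of atoms from their centroid (Å)."""
    coords = _backbone_view(frame, labels)
    if coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def observables(
    traj: Trajectory,
    reference: np.ndarray,
    skip_fraction: float = 0.10,
) -> ObservableSeries:
    """Per-frame RMSD-to-reference and Rg after discarding early frames.

    The first ``floor(skip_fraction * n_frames)`` frames are dropped to
    reduce bias from the starting conformation.
    """
    if not 0 <= skip_fraction < 1:
        raise ValueError("skip_fraction must be in [0, 1)")
    n_skip = int(np.floor(skip_fraction * traj.n_frames))
    if n_skip >= traj.n_frames:
        raise ValueError("skip_fraction discards every frame")
    idx = traj.backbone_indices()
    frames = traj.frames[n_skip:, idx]
    ref = np.asarray(reference, dtype=float)
    if ref.shape[0] == traj.n_atoms:
        ref = ref[idx]
    elif ref.shape[0] != idx.size:
        raise ValueError("reference atom count matches neither trajectory nor backbone")
    rmsd = batch_rmsd(frames, ref)
    centered = frames - frames.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum(centered**2, axis=2), axis=1))
    return ObservableSeries(rmsd=rmsd, rg=rg, tag=traj.tag)


def align_trajectory(traj: Trajectory, reference_frame_index: int = 0) -> Trajectory:
    """Superpose every frame onto one chosen frame (backbone heavy atoms).

    The rotation/translation is fitted on the backbone atoms and applied to
    all atoms; the chosen frame itself is unchanged.
    """
    if not 0 <= reference_frame_index < traj.n_frames:
        raise ValueError(f"reference_frame_index {reference_frame_index} out of range")
    bb = traj.backbone_indices()
    target = traj.frames[reference_frame_index, bb]
    tar_c = target.mean(axis=0)
    mob_c = traj.frames[:, bb].mean(axis=1, keepdims=True)
    R = _batch_rotations(traj.frames[:, bb], target)
    aligned = np.einsum("fni,fij->fnj", traj.frames - mob_c, R) + tar_c
    return replace(traj, frames=aligned)


def ensemble_spread(models: list[np.ndarray], labels=None) -> tuple[float, float]:
    """Mean and s.d. of backbone RMSD of models 2..n to model 1.

    Quantifies the conformational variability of an NMR-style ensemble
    around its first (best-representative) model.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    first = models[0]
    rmsds = np.array([backbone_rmsd(m, first, labels) for m in models[1:]])
    return float(rmsds.mean()), float(rmsds.std())


def select_temperature_frames(
    traj: Trajectory,
    temperature_series: np.ndarray,
    target_K: float = 300.0,
    tol_K: float = 0.5,
) -> Trajectory:
    """Keep frames whose recorded temperature is within ``tol_K`` of target.

    Demultiplexes a simulated-tempering trajectory down to its target-
    temperature segments; frame order is preserved. Returns a zero-frame
    trajectory (with a warning) when nothing matches.
    """
    temps = np.asarray(temperature_series, dtype=float)
    if temps.size != traj.n_frames:
        raise ValueError("temperature series length must equal n_frames")
    keep = np.flatnonzero(np.abs(temps - target_K) <= tol_K)
    if keep.size == 0:
        warnings.warn(
            f"no frame within {tol_K} K of {target_K} K; returning empty trajectory",
            stacklevel=2,
        )
    return traj.subset(keep)
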