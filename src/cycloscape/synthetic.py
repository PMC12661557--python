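"""Synthetic cyclic-peptide conformational ensembles with planted structure.

Generates toy backbone ensembles whose ground truth is known exactly:
an idealized ring reference, metastable basins planted at prescribed
backbone-RMSD displacements from it, Markov-chain basin occupancy with
tunable kinetics, and isotropic Gaussian intra-basin noise. Several
independent runs per protocol, with protocol-to-protocol population
shifts, emulate the repeat-run / multi-force-field structure of an
enhanced-sampling study — so every downstream stage (profiles, JSD
convergence, PCA clustering, star prediction, combination ranking) can
be validated against planted truth without any molecular dynamics.

The ring geometry is idealized (regular polygon with fixed local atom
offsets), not chemically realistic: all downstream math is coordinate-
generic, so bond lengths and angles never enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import BACKBONE_ATOMS, Trajectory, backbone_rmsd

__all__ = [
    "RingReference",
    "BasinSpec",
    "SyntheticTrajectory",
    "make_ring_reference",
    "make_basin",
    "simulate_trajectory",
    "simulate_protocol_set",
]

# CA-CA spacing of adjacent residues along the ring, Å (typical peptide value)
_CA_SPACING = 3.8
# angular offsets of N and C from CA, as fractions of the inter-residue angle
_N_FRACTION = -0.35
_C_FRACTION = 0.35
# carbonyl O displacement from C: radially outward and out of plane, Å
_O_RADIAL = 0.9
_O_AXIAL = 0.85


@dataclass
class RingReference:
    """An idealized closed peptide ring of N/CA/C/O backbone atoms."""

    coordinates: np.ndarray
    atom_labels: list[tuple[int, str]]
    n_residues: int

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class BasinSpec:
    """A metastable basin: a centroid structure, its population and width.

    ``target_rmsd`` is the backbone RMSD (after optimal superposition) of
    the centroid from the reference; ``noise_sigma`` the per-coordinate
    Gaussian spread of frames around the centroid, both in Å.
    """

    centroid: np.ndarray
    target_rmsd: float
    population: float
    noise_sigma: float

    def __post_init__(self) -> None:
        if self.target_rmsd < 0 or self.noise_sigma < 0:
            raise ValueError("target_rmsd and noise_sigma must be nonnegative")
        if not 0 <= self.population <= 1:
            raise ValueError("population must be a probability")


@dataclass
class SyntheticTrajectory:
    """Generated frames plus the ground-truth basin occupancy per frame."""

    frames: np.ndarray
    true_labels: np.ndarray
    seed: int
    protocol_tag: str = ""
    atom_labels: list[tuple[int, str]] = field(default_factory=list)

    def to_trajectory(self, timestep_ps: float = 10.0) -> Trajectory:
        return Trajectory(
            frames=self.frames,
            atom_labels=self.atom_labels,
            timestep_ps=timestep_ps,
            tag=self.protocol_tag,
        )


def make_ring_reference(n_residues: int) -> RingReference:
    """Deterministic idealized ring of ``n_residues`` × 4 backbone atoms.

    Residues sit equally spaced on a circle sized so adjacent CA atoms
    are ~3.8 Å apart; N and C flank each CA along the circle and O
    projects outward/axially from C. The last residue's C and the first
    residue's N end up well under 2 Å apart (ring closure).
    """
    if not 3 <= n_residues <= 50:
        raise ValueError("n_residues must be in [3, 50]")
    dtheta = 2 * np.pi / n_residues
    radius = _CA_SPACING / (2 * np.sin(dtheta / 2))

    def on_circle(theta: float, r: float = radius, z: float = 0.0) -> np.ndarray:
        return np.array([r * np.cos(theta), r * np.sin(theta), z])

    coords = []
    labels = []
    for i in range(n_residues):
        theta = i * dtheta
        coords.append(on_circle(theta + _N_FRACTION * dtheta))
        coords.append(on_circle(theta))
        coords.append(on_circle(theta + _C_FRACTION * dtheta))
        coords.append(on_circle(theta + _C_FRACTION * dtheta, radius + _O_RADIAL, _O_AXIAL))
        labels.extend((i, name) for name in BACKBONE_ATOMS)
    return RingReference(
        coordinates=np.array(coords), atom_labels=labels, n_residues=n_residues
    )


def make_basin(
    reference: RingReference,
    target_rmsd: float,
    population: float,
    noise_sigma: float,
    seed: int,
) -> BasinSpec:
    """Plant a basin centroid at an exact RMSD displacement from the reference.

    A random direction in 3N coordinate space is drawn, its net translation
    removed, and its amplitude solved (bisection) so the superposed backbone
    RMSD of the centroid from the reference equals ``target_rmsd`` to 1e−6 Å.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be nonnegative")
    ref = reference.coordinates
    if target_rmsd == 0:
        return BasinSpec(ref.copy(), 0.0, population, noise_sigma)
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(ref.shape)
    direction -= direction.mean(axis=0)  # remove net translation
    direction /= np.linalg.norm(direction)

    def gap(alpha: float) -> float:
        return backbone_rmsd(ref + alpha * direction, ref) - target_rmsd

    hi = target_rmsd * np.sqrt(ref.shape[0])
    while gap(hi) < 0:
        hi *= 2.0
    # rmsd grows monotonically with amplitude at slope ≤ 1/√N, so a tight
    # tolerance on alpha guarantees the 1e−6 Å tolerance on the planted RMSD
    alpha = brentq(gap, 0.0, hi, xtol=1e-9)
    return BasinSpec(ref + alpha * direction, target_rmsd, population, noise_sigma)


def _transition_matrix(populations: np.ndarray, stay_prob: float) -> np.ndarray:
    """Lazy chain T = s·I + (1−s)·1pᵀ; stationary distribution = populations."""
    k = populations.size
    return stay_prob * np.eye(k) + (1 - stay_prob) * np.tile(populations, (k, 1))


def simulate_trajectory(
    basins: list[BasinSpec],
    stay_prob: float,
    n_frames: int,
    seed: int,
    atom_labels: list[tuple[int, str]] | None = None,
    protocol_tag: str = "",
) -> SyntheticTrajectory:
    """Markov-chain hopping between basins with Gaussian intra-basin noise.

    Each step stays in the current basin with probability ``stay_prob``;
    otherwise the next basin is drawn from the stationary populations
    (possibly re-selecting the current one), which makes the specified
    populations the exact stationary distribution of the chain. Frames
    are the occupied basin's centroid plus isotropic N(0, σ²) noise.
    """
    if not basins:
        raise ValueError("need at least one basin")
    if not 0 <= stay_prob <= 1:
        raise ValueError("stay_prob must be a probability")
    pops = np.array([b.population for b in basins])
    if abs(pops.sum() - 1.0) > 1e-9:
        raise ValueError("basin populations must sum to 1")
    rng = np.random.default_rng(seed)
    k = len(basins)
    labels = np.empty(n_frames, dtype=int)
    state = rng.choice(k, p=pops)
    for t in range(n_frames):
        labels[t] = state
        if rng.random() >= stay_prob:
            state = rng.choice(k, p=pops)
    shape = basins[0].centroid.shape
    frames = np.empty((n_frames,) + shape)
    for j, basin in enumerate(basins):
        idx = np.flatnonzero(labels == j)
        if idx.size == 0:
            continue
        noise = (
            rng.standard_normal((idx.size,) + shape) * basin.noise_sigma
            if basin.noise_sigma > 0
            else 0.0
        )
        frames[idx] = basin.centroid + noise
    return SyntheticTrajectory(
        frames=frames,
        true_labels=labels,
        seed=seed,
        protocol_tag=protocol_tag,
        atom_labels=atom_labels or [],
    )


def simulate_protocol_set(
    base_basins: list[BasinSpec],
    protocol_population_shifts: dict[str, list[float]],
    runs_per_protocol: int,
    n_frames: int,
    seed: int,
    stay_prob: float = 0.95,
    atom_labels: list[tuple[int, str]] | None = None,
) -> list[SyntheticTrajectory]:
    """One trajectory per (protocol, run); runs differ only by seed.

    Each protocol reuses the base basin centroids and widths but replaces
    the stationary populations with its shift vector, emulating different
    simulation conditions ranking the same conformational states
    differently.
    """
    trajectories = []
    seed_stream = np.random.default_rng(seed)
    for tag, shift in protocol_population_shifts.items():
        shift = np.asarray(shift, dtype=float)
        if shift.size != len(base_basins):
            raise ValueError(f"shift vector for {tag!r} has wrong length")
        if abs(shift.sum() - 1.0) > 1e-9:
            raise ValueError(f"shift vector for {tag!r} must sum to 1")
        basins = [
            BasinSpec(b.centroid, b.target_rmsd, p, b.noise_sigma)
            for b, p in zip(base_basins, shift)
        ]
        for run in range(runs_per_protocol):
            run_seed = int(seed_stream.integers(0, 2**31 - 1))
            traj = simulate_trajectory(
                basins,
                stay_prob,
                n_frames,
                run_seed,
                atom_labels=atom_labels,
                protocol_tag=f"{tag}/run{run + 1}",
            )
            trajectories.append(traj)
    return trajectories
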