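"""Density profiles and free-energy maps from observable series.

A 1D RMSD density profile is a normalized histogram over explicit, shared
bin edges — shared edges are mandatory so two profiles are comparable.
A 2D free-energy map converts the (Rg, RMSD) sampling density into
F = −kT·ln(ρ), shifted so the lowest occupied bin sits at F = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ObservableSeries

#: Boltzmann constant in kJ/(mol·K).
KB_KJ_PER_MOL_K = 0.0083144621

__all__ = [
    "KB_KJ_PER_MOL_K",
    "DensityProfile",
    "FreeEnergyMap",
    "default_bin_edges",
    "density_profile",
    "free_energy_map",
    "cluster_populations",
]


@dataclass
class DensityProfile:
    """Normalized 1D histogram: Σ density·width = 1."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_edges.size != self.density.size + 1:
            raise ValueError("need len(bin_edges) == len(density) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("densities must be nonnegative")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def masses(self) -> np.ndarray:
        """Per-bin probability masses (density × width); sums to 1."""
        return self.density * self.widths


@dataclass
class FreeEnergyMap:
    """2D free-energy surface over (Rg, RMSD) or any two observables.

    ``rho`` holds normalized bin probabilities (summing to 1 over occupied
    bins); ``F`` is −kT·ln(rho) shifted to min 0, NaN on unoccupied bins,
    with ``occupied`` flagging which bins carry data.
    """

    rg_edges: np.ndarray
    rmsd_edges: np.ndarray
    rho: np.ndarray
    F: np.ndarray
    occupied: np.ndarray
    kT: float

    def min_free_energy_bin(self) -> tuple[int, int]:
        """(i, j) index of the occupied bin with the lowest free energy."""
        masked = np.where(self.occupied, self.F, np.inf)
        return tuple(np.unravel_index(np.argmin(masked), masked.shape))


def default_bin_edges(values: np.ndarray, width: float = 0.1) -> np.ndarray:
    """Fixed-width edges over [0, max + width], shared across compared profiles."""
    values = np.asarray(values, dtype=float)
    hi = float(values.max()) + width
    n = int(np.ceil(hi / width))
    return np.linspace(0.0, n * width, n + 1)


def density_profile(values, bin_edges) -> DensityProfile:
    """Histogram ``values`` over the given edges, normalized to unit mass.

    Out-of-range values are clipped into the end bins so no sample is lost
    (required for profiles compared across trajectories of different reach).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot build a density profile from no values")
    edges = np.asarray(bin_edges, dtype=float)
    lo, hi = edges[0], edges[-1]
    # nudge into the outer bins: np.histogram's last bin is closed on both sides
    clipped = np.clip(values, lo, np.nextafter(hi, lo))
    counts, _ = np.histogram(clipped, bins=edges)
    density = counts / (counts.sum() * np.diff(edges))
    return DensityProfile(bin_edges=edges, density=density)


def free_energy_map(
    series: ObservableSeries,
    n_bins: int = 100,
    temperature_K: float = 300.0,
    rg_edges: np.ndarray | None = None,
    rmsd_edges: np.ndarray | None = None,
) -> FreeEnergyMap:
    """Build an (Rg, RMSD) free-energy map from per-frame observables.

    A 2D histogram (``n_bins`` per axis, data-driven [min, max] ranges
    unless explicit edges are supplied) is converted via F = −kT·ln(ρ)
    and shifted so the deepest occupied bin has F = 0. Empty bins are
    flagged unoccupied rather than given infinite F.
    """
    if len(series) == 0:
        raise ValueError("empty observable series")
    def _edges(x: np.ndarray) -> np.ndarray:
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:  # constant observable: give the bins nonzero width
            lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, n_bins + 1)

    if rg_edges is None:
        rg_edges = _edges(series.rg)
    if rmsd_edges is None:
        rmsd_edges = _edges(series.rmsd)
    counts, rg_e, rmsd_e = np.histogram2d(series.rg, series.rmsd, bins=[rg_edges, rmsd_edges])
    occupied = counts > 0
    rho = counts / counts.sum()
    kT = KB_KJ_PER_MOL_K * temperature_K
    F = np.full_like(rho, np.nan)
    with np.errstate(divide="ignore"):
        F[occupied] = -kT * np.log(rho[occupied])
    F[occupied] -= F[occupied].min()
    return FreeEnergyMap(rg_edges=rg_e, rmsd_edges=rmsd_e, rho=rho, F=F, occupied=occupied, kT=kT)


def cluster_populations(labels, noise_label: int = -1, report_threshold: float = 0.02):
    """Fraction of frames per cluster id, noise reported separately.

    Returns ``(populations, noise_fraction, unreported)`` where
    ``populations`` maps cluster id → fraction of all frames, and
    ``unreported`` lists ids whose fraction falls below the display
    threshold (conventionally 2%).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    n = labels.size
    ids, counts = np.unique(labels[labels != noise_label], return_counts=True)
    populations = {int(i): float(c) / n for i, c in zip(ids, counts)}
    noise_fraction = float(np.sum(labels == noise_label)) / n
    unreported = [i for i, f in populations.items() if f < report_threshold]
    return populations, noise_fraction, unreported
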