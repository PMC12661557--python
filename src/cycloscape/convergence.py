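"""Jensen–Shannon-divergence convergence diagnostics.

A run is compared to the mean RMSD density profile of all runs; its JSD
curve tracks that divergence along growing trajectory prefixes. All runs
of a protocol converge when every curve ends below a threshold (0.05 by
default). The same machinery, applied across protocols after merging and
frame-count equalization, yields inter-protocol agreement matrices.

JSD here is computed on bin probability masses with base-2 logarithms,
so it is bounded in [0, 1]: 0 for identical profiles, 1 for profiles
with disjoint support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ObservableSeries
from .landscape import DensityProfile, default_bin_edges, density_profile

__all__ = [
    "JSDCurve",
    "AgreementMatrix",
    "jsd",
    "subsample_even",
    "mean_profile",
    "jsd_curves",
    "converged",
    "agreement",
]


@dataclass
class JSDCurve:
    """Divergence of one run's profile from the mean profile along prefixes.

    ``fractions[i]`` is the trajectory fraction covered by prefix i (last
    value 1.0); ``jsd[i]`` the divergence at that prefix.
    """

    fractions: np.ndarray
    jsd: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.jsd = np.asarray(self.jsd, dtype=float)
        if self.fractions.shape != self.jsd.shape:
            raise ValueError("fractions and jsd must have equal length")

    @property
    def final(self) -> float:
        """End-point divergence (full trajectory)."""
        return float(self.jsd[-1])


@dataclass
class AgreementMatrix:
    """Symmetric matrix of summarized end-point JSDs between protocols."""

    labels: list[str]
    values: np.ndarray
    summary: str = "mean"

    def as_dict(self) -> dict:
        return {
            "labels": self.labels,
            "summary": self.summary,
            "matrix": self.values.tolist(),
        }


def _kl_base2(p: np.ndarray, m: np.ndarray) -> float:
    # 0·log(0/x) := 0; m > 0 wherever p > 0 by construction of the midpoint
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / m[mask])))


def jsd(P: DensityProfile, Q: DensityProfile) -> float:
    """Jensen–Shannon divergence between two profiles, in [0, 1].

    JSD(P‖Q) = ½·KL(P‖M) + ½·KL(Q‖M) with M = (P+Q)/2, evaluated on bin
    probability masses with log base 2. Requires identical bin edges.
    """
    if P.bin_edges.size != Q.bin_edges.size or not np.allclose(P.bin_edges, Q.bin_edges):
        raise ValueError("profiles must share identical bin edges")
    p = P.masses
    q = Q.masses
    m = 0.5 * (p + q)
    value = 0.5 * _kl_base2(p, m) + 0.5 * _kl_base2(q, m)
    return float(min(max(value, 0.0), 1.0))


def subsample_even(n_total: int, n_keep: int) -> np.ndarray:
    """Evenly spaced frame indices floor(i·L/m), deterministic."""
    if n_keep > n_total:
        raise ValueError("cannot subsample to more frames than available")
    return (np.arange(n_keep) * n_total) // n_keep


def _equalized_values(runs: list[np.ndarray]) -> list[np.ndarray]:
    n_min = min(v.size for v in runs)
    return [v[subsample_even(v.size, n_min)] for v in runs]


def mean_profile(runs: list[ObservableSeries | np.ndarray], bin_edges) -> DensityProfile:
    """Pool all runs with equal weight and histogram the result.

    Each run is evenly subsampled to the shortest run's length before
    concatenation, so every run contributes the same number of frames.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs for a mean profile")
    values = [np.asarray(r.rmsd if isinstance(r, ObservableSeries) else r, dtype=float) for r in runs]
    pooled = np.concatenate(_equalized_values(values))
    return density_profile(pooled, bin_edges)


def jsd_curves(
    runs: list[ObservableSeries | np.ndarray],
    bin_edges=None,
    n_windows: int = 100,
    recompute_mean: bool = True,
) -> list[JSDCurve]:
    """JSD curve of every run against the mean profile, along prefixes.

    For each of ``n_windows`` equally spaced prefix endpoints, the run's
    profile over frames [0, t_i) is compared with the mean profile built
    from the same prefix fraction of every run. With
    ``recompute_mean=False`` the full-trajectory mean profile is held
    fixed instead.
    """
    values = [np.asarray(r.rmsd if isinstance(r, ObservableSeries) else r, dtype=float) for r in runs]
    tags = [r.tag if isinstance(r, ObservableSeries) else "" for r in runs]
    if bin_edges is None:
        bin_edges = default_bin_edges(np.concatenate(values))
    n_min = min(v.size for v in values)
    if n_min < n_windows:
        raise ValueError(f"runs too short for {n_windows} prefix windows")
    fractions = np.arange(1, n_windows + 1) / n_windows
    full_mean = mean_profile(values, bin_edges)
    curves = []
    for k, run in enumerate(values):
        out = np.empty(n_windows)
        for i, frac in enumerate(fractions):
            prefix = run[: max(1, int(np.floor(frac * run.size)))]
            p = density_profile(prefix, bin_edges)
            if recompute_mean:
                prefixes = [v[: max(1, int(np.floor(frac * v.size)))] for v in values]
                q = mean_profile(prefixes, bin_edges)
            else:
                q = full_mean
            out[i] = jsd(p, q)
        curves.append(JSDCurve(fractions=fractions, jsd=out, tag=tags[k]))
    return curves


def converged(curves: list[JSDCurve], threshold: float = 0.05) -> tuple[list[bool], bool]:
    """Per-run and overall convergence verdicts from end-point JSDs.

    A run has converged when its final divergence is at or below the
    threshold; the protocol as a whole only when every run has.
    """
    if not curves:
        raise ValueError("no curves given")
    per_run = [c.final <= threshold for c in curves]
    return per_run, all(per_run)


def agreement(
    groups: dict[str, list[ObservableSeries | np.ndarray]],
    summary: str = "mean",
    bin_edges=None,
) -> AgreementMatrix:
    """Pairwise inter-protocol agreement matrix of end-point JSDs.

    For every pair of protocols, the runs of each are merged into one
    series, both merged series are evenly subsampled to the same frame
    count, their average profile is built, and each protocol's JSD to
    that average is recorded; the matrix entry is the mean or max of the
    two. Diagonal entries are 0 by construction.
    """
    if summary not in ("mean", "max"):
        raise ValueError("summary must be 'mean' or 'max'")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups)
    merged = {}
    for tag, runs in groups.items():
        values = [np.asarray(r.rmsd if isinstance(r, ObservableSeries) else r, dtype=float) for r in runs]
        merged[tag] = np.concatenate(_equalized_values(values)) if len(values) > 1 else values[0]
    if bin_edges is None:
        bin_edges = default_bin_edges(np.concatenate(list(merged.values())))
    n = len(labels)
    mat = np.zeros((n, n))
    reducer = np.mean if summary == "mean" else np.max
    for i in range(n):
        for j in range(i + 1, n):
            a, b = merged[labels[i]], merged[labels[j]]
            n_min = min(a.size, b.size)
            a = a[subsample_even(a.size, n_min)]
            b = b[subsample_even(b.size, n_min)]
            avg = density_profile(np.concatenate([a, b]), bin_edges)
            entry = reducer([
                jsd(density_profile(a, bin_edges), avg),
                jsd(density_profile(b, bin_edges), avg),
            ])
            mat[i, j] = mat[j, i] = entry
    return AgreementMatrix(labels=labels, values=mat, summary=summary)
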