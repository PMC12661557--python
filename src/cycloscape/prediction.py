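"""Blind native-structure prediction from PCA-space clustering.

Pipeline: align the trajectory to its first frame, run PCA on the
flattened backbone coordinates keeping the minimal number of components
reaching 80% cumulative variance, cluster the retained-component scores
(HDBSCAN by default, k-means as the alternative), and pick a star:

* green — the global lowest-free-energy point of the PC1/PC2 density map
  falls inside the most populated cluster; the prediction is that
  cluster's medoid frame.
* cyan + yellow — the lowest-FE point lies in a different cluster; a cyan
  star marks the lowest-FE cluster's medoid, a yellow star the most
  populated cluster's medoid, and the yellow star is retained as the
  prediction.

The experimental reference structure is never consulted before
:func:`evaluate_prediction`; everything upstream is blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN, KMeans
from sklearn.decomposition import PCA

from .geometry import Trajectory, backbone_rmsd, radius_of_gyration
from .landscape import cluster_populations

__all__ = [
    "PCAProjection",
    "ClusterSet",
    "StarReport",
    "pca_project",
    "cluster_frames",
    "select_star",
    "evaluate_prediction",
    "predict",
]


@dataclass
class PCAProjection:
    """Retained-component scores of PCA on flattened backbone coordinates."""

    components_retained: int
    cumulative_variance: float
    scores: np.ndarray
    mean_structure: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]


@dataclass
class ClusterSet:
    """Per-frame cluster labels with populations and medoid frames.

    Cluster ids are 1-based, ordered by decreasing population; −1 marks
    noise (unclustered frames, HDBSCAN only). ``centroid_frame`` maps each
    id to the frame nearest its cluster's mean score vector (the medoid),
    so a concrete structure can be written out for any cluster.
    """

    labels: np.ndarray
    populations: dict[int, float]
    centroid_frame: dict[int, int]
    method: str
    noise_fraction: float = 0.0

    def most_populated(self, tiebreak_fe: dict[int, float] | None = None) -> int:
        """Id of the largest cluster; ties go to lower centroid FE, then lower id."""
        best = max(self.populations.values())
        tied = sorted(i for i, f in self.populations.items() if f == best)
        if len(tied) > 1 and tiebreak_fe:
            tied.sort(key=lambda i: (tiebreak_fe.get(i, np.inf), i))
        return tied[0]


@dataclass
class StarReport:
    """Outcome of the star-selection rule, with optional evaluation fields."""

    star_kind: str  # "green" or "cyan+yellow"
    predicted_frame: int
    lowest_fe_frame: int
    lowest_fe_cluster: int
    most_populated_cluster: int
    cyan_frame: int | None = None
    yellow_frame: int | None = None
    rmsd_to_reference: float | None = None
    rg: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def pca_project(aligned: Trajectory, variance_target: float = 0.80) -> PCAProjection:
    """PCA of flattened backbone coordinates, minimal components to target.

    The trajectory must already be aligned (and the equilibration skip
    applied); PCA on unaligned frames mixes rigid-body motion into the
    leading components.
    """
    if aligned.n_frames < 2:
        raise ValueError("PCA needs at least two frames")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    bb = aligned.backbone_indices()
    X = aligned.frames[:, bb, :].reshape(aligned.n_frames, -1)
    if np.allclose(X, X[0], atol=1e-12):
        # degenerate ensemble with no motion: one all-zero component
        return PCAProjection(
            components_retained=1,
            cumulative_variance=1.0,
            scores=np.zeros((aligned.n_frames, 1)),
            mean_structure=X[0].copy(),
        )
    pca = PCA()
    scores_full = pca.fit_transform(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    if variance_target >= 1.0:
        nonzero = pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]
        k = max(1, int(np.sum(nonzero)))
    else:
        k = int(np.searchsorted(cumvar, variance_target) + 1)
        k = min(k, cumvar.size)
    return PCAProjection(
        components_retained=k,
        cumulative_variance=float(cumvar[k - 1]),
        scores=scores_full[:, :k],
        mean_structure=pca.mean_,
    )


def _medoid(scores: np.ndarray, members: np.ndarray) -> int:
    center = scores[members].mean(axis=0)
    d2 = np.sum((scores[members] - center) ** 2, axis=1)
    return int(members[np.argmin(d2)])  # argmin takes the first on ties


def cluster_frames(
    projection: PCAProjection,
    method: str = "hdbscan",
    min_cluster_size: int | None = None,
    n_clusters: int | None = None,
    **params,
) -> ClusterSet:
    """Cluster retained-PC scores with HDBSCAN or k-means.

    HDBSCAN's ``min_cluster_size`` defaults to max(50, 2% of frames),
    matching the convention of not reporting clusters below 2% of the
    ensemble. Cluster ids are reassigned 1..k by decreasing population.
    """
    scores = projection.scores
    n = scores.shape[0]
    if n == 0:
        raise ValueError("no frames to cluster")
    if method == "hdbscan":
        if min_cluster_size is None:
            min_cluster_size = max(50, int(0.02 * n))
        min_cluster_size = min(min_cluster_size, n)
        params.setdefault("copy", True)
        raw = HDBSCAN(min_cluster_size=min_cluster_size, **params).fit_predict(scores)
        if np.all(raw == -1):
            raise RuntimeError(
                "HDBSCAN found no cluster (all frames labelled noise); "
                f"min_cluster_size={min_cluster_size}, n_frames={n} — "
                "lower min_cluster_size or check that the ensemble has structure"
            )
    elif method == "kmeans":
        if n_clusters is None:
            n_clusters = 1
        uniq = np.unique(scores, axis=0).shape[0]
        raw = KMeans(
            n_clusters=min(n_clusters, uniq), n_init=10, random_state=0, **params
        ).fit_predict(scores)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    # relabel by decreasing population: biggest cluster gets id 1
    ids, counts = np.unique(raw[raw != -1], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = np.array([mapping.get(int(r), -1) for r in raw])
    populations, noise_fraction, _ = cluster_populations(labels)
    centroid_frame = {
        cid: _medoid(scores, np.flatnonzero(labels == cid)) for cid in populations
    }
    return ClusterSet(
        labels=labels,
        populations=populations,
        centroid_frame=centroid_frame,
        method=method,
        noise_fraction=noise_fraction,
    )


def _pc_density_per_frame(scores: np.ndarray, n_bins: int = 100, n_pcs: int = 2) -> np.ndarray:
    """Sampling density of each frame's bin in PC space (first ``n_pcs`` PCs).

    The free energy at a frame is −kT·ln of this density; since only the
    argmin/argmax matter here, densities are returned directly.
    """
    use = scores[:, : min(n_pcs, scores.shape[1])]
    edges = []
    digit = []
    for d in range(use.shape[1]):
        lo, hi = use[:, d].min(), use[:, d].max()
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        e = np.linspace(lo, hi, n_bins + 1)
        edges.append(e)
        digit.append(np.clip(np.digitize(use[:, d], e) - 1, 0, n_bins - 1))
    flat = np.zeros(use.shape[0], dtype=int)
    for d in digit:
        flat = flat * n_bins + d
    counts = np.bincount(flat, minlength=n_bins ** use.shape[1])
    return counts[flat].astype(float)


def select_star(
    clusters: ClusterSet,
    projection: PCAProjection,
    n_bins: int = 100,
    density_pcs: int = 2,
) -> StarReport:
    """Apply the green / cyan+yellow star rule on the PCA density map.

    The global lowest-free-energy frame is the first frame in the densest
    bin of the PC1/PC2 histogram. If its cluster is the most populated
    cluster, a single green star marks that cluster's medoid. Otherwise a
    cyan star marks the lowest-FE cluster's medoid and a yellow star the
    most populated cluster's medoid; yellow is the retained prediction.
    """
    if not clusters.populations:
        raise ValueError("cluster set is empty")
    density = _pc_density_per_frame(projection.scores, n_bins=n_bins, n_pcs=density_pcs)
    # restrict to clustered frames so noise cannot carry the FE minimum
    clustered = clusters.labels != -1
    masked = np.where(clustered, density, -np.inf)
    fe_frame = int(np.argmax(masked))
    fe_cluster = int(clusters.labels[fe_frame])
    centroid_fe = {
        cid: -density[frame] for cid, frame in clusters.centroid_frame.items()
    }
    top = clusters.most_populated(tiebreak_fe=centroid_fe)
    if fe_cluster == top:
        return StarReport(
            star_kind="green",
            predicted_frame=clusters.centroid_frame[top],
            lowest_fe_frame=fe_frame,
            lowest_fe_cluster=fe_cluster,
            most_populated_cluster=top,
        )
    return StarReport(
        star_kind="cyan+yellow",
        predicted_frame=clusters.centroid_frame[top],
        lowest_fe_frame=fe_frame,
        lowest_fe_cluster=fe_cluster,
        most_populated_cluster=top,
        cyan_frame=clusters.centroid_frame[fe_cluster],
        yellow_frame=clusters.centroid_frame[top],
    )


def evaluate_prediction(
    star: StarReport,
    traj: Trajectory,
    reference: np.ndarray,
    nmr_models: list[np.ndarray] | None = None,
) -> tuple[float, float]:
    """Score the prediction against the reference (evaluation only).

    Returns the backbone RMSD of the predicted frame to the reference
    (first deposited model) and, if an NMR ensemble is supplied, the
    minimum RMSD over all its models (always ≤ the first value when the
    reference is model 1). Also fills the report's evaluation fields.
    """
    bb = traj.backbone_indices()
    frame = traj.frames[star.predicted_frame, bb]
    ref = np.asarray(reference, dtype=float)
    if ref.shape[0] == traj.n_atoms:
        ref = ref[bb]
    r1 = backbone_rmsd(frame, ref)
    rmin = r1
    if nmr_models:
        for model in nmr_models:
            m = np.asarray(model, dtype=float)
            if m.shape[0] == traj.n_atoms:
                m = m[bb]
            rmin = min(rmin, backbone_rmsd(frame, m))
    star.rmsd_to_reference = r1
    star.rg = radius_of_gyration(frame)
    return r1, rmin


def predict(
    traj: Trajectory,
    skip_fraction: float = 0.10,
    variance_target: float = 0.80,
    method: str = "hdbscan",
    **cluster_params,
) -> tuple[StarReport, ClusterSet, PCAProjection, Trajectory]:
    """Full blind pipeline: skip → align → PCA → cluster → star.

    Returns the star report together with the intermediate objects and the
    post-skip aligned trajectory (whose frame indexing the report uses).
    """
    from .geometry import align_trajectory

    n_skip = int(np.floor(skip_fraction * traj.n_frames))
    trimmed = traj.subset(np.arange(n_skip, traj.n_frames))
    aligned = align_trajectory(trimmed, 0)
    projection = pca_project(aligned, variance_target)
    clusters = cluster_frames(projection, method=method, **cluster_params)
    star = select_star(clusters, projection)
    return star, clusters, projection, aligned
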