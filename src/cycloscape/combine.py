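"""Equal-weight combination of simulations and median-RMSD ranking.

Different force fields or sampling protocols each give a slightly
different conformational ensemble for the same peptide. Concatenating
trajectories — after evenly subsampling every one to the common minimum
frame count, so each simulation carries equal weight — yields a
consensus ensemble on which the blind prediction pipeline is re-run.
Enumerating all subsets of the available simulations and scoring each
subset by the median predicted-structure RMSD over the peptide set
identifies robust combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .convergence import subsample_even
from .geometry import Trajectory

__all__ = [
    "CombinationReport",
    "equalize_and_concatenate",
    "enumerate_subsets",
    "rank_combinations",
]


@dataclass
class CombinationReport:
    """One simulation subset scored across the peptide set."""

    subset: tuple[str, ...]
    per_peptide_rmsd: dict[str, float]
    median_rmsd: float = field(init=False)
    min_rmsd: float = field(init=False)
    max_rmsd: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.array(list(self.per_peptide_rmsd.values()), dtype=float)
        if values.size == 0:
            raise ValueError("report needs at least one peptide")
        self.median_rmsd = float(np.median(values))
        self.min_rmsd = float(values.min())
        self.max_rmsd = float(values.max())


def equalize_and_concatenate(trajs: list[Trajectory]) -> Trajectory:
    """Concatenate trajectories after equalizing their frame counts.

    Every trajectory is evenly subsampled (indices floor(i·L/m)) to the
    minimum frame count among the inputs, so each contributes exactly the
    same number of frames to the combined ensemble.
    """
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories to combine")
    labels0 = trajs[0].atom_labels
    for t in trajs[1:]:
        if t.atom_labels != labels0:
            raise ValueError("trajectories must share identical atom labels")
    n_min = min(t.n_frames for t in trajs)
    pieces = [t.frames[subsample_even(t.n_frames, n_min)] for t in trajs]
    tag = "+".join(t.tag for t in trajs if t.tag)
    return Trajectory(
        frames=np.concatenate(pieces, axis=0),
        atom_labels=labels0,
        timestep_ps=trajs[0].timestep_ps,
        tag=tag,
    )


def enumerate_subsets(tags: list[str], sizes="all") -> list[tuple[str, ...]]:
    """All size-k subsets of ``tags`` for each requested k, in deterministic order.

    ``sizes`` is a list of subset sizes, or ``"all"`` for every size from
    2 to len(tags). Subsets preserve the input tag order.
    """
    if len(set(tags)) != len(tags):
        raise ValueError("tags must be distinct")
    if sizes == "all":
        sizes = range(2, len(tags) + 1)
    subsets: list[tuple[str, ...]] = []
    for k in sizes:
        if not 1 <= k <= len(tags):
            raise ValueError(f"subset size {k} out of range for {len(tags)} tags")
        subsets.extend(itertools.combinations(tags, k))
    return subsets


def rank_combinations(
    predictions: dict[tuple[tuple[str, ...], str], float],
) -> list[CombinationReport]:
    """Rank simulation subsets by median predicted-structure RMSD.

    ``predictions`` maps (subset, peptide) → RMSD of the retained star to
    that peptide's reference. Every subset must be evaluated on the same
    peptide set. Reports are sorted by ascending median, ties broken by
    max RMSD and then lexicographic subset.
    """
    by_subset: dict[tuple[str, ...], dict[str, float]] = {}
    for (subset, peptide), rmsd in predictions.items():
        by_subset.setdefault(tuple(subset), {})[peptide] = float(rmsd)
    peptide_sets = {frozenset(v) for v in by_subset.values()}
    if len(peptide_sets) > 1:
        raise ValueError("every subset must be evaluated on the same peptides")
    reports = [CombinationReport(subset=s, per_peptide_rmsd=v) for s, v in by_subset.items()]
    reports.sort(key=lambda r: (r.median_rmsd, r.max_rmsd, r.subset))
    return reports
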