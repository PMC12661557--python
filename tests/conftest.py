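import numpy as np
import pytest

from cycloscape import make_basin, make_ring_reference, simulate_trajectory


@pytest.fixture(scope="session")
def ring7():
    return make_ring_reference(7)


@pytest.fixture(scope="session")
def two_basin_traj(ring7):
    """20k-frame ensemble with a 60/40 split between well-separated basins."""
    near = make_basin(ring7, 0.8, 0.6, 0.25, seed=11)
    far = make_basin(ring7, 3.5, 0.4, 0.25, seed=12)
    traj = simulate_trajectory(
        [near, far], stay_prob=0.95, n_frames=20000, seed=13,
        atom_labels=ring7.atom_labels,
    )
    return traj, (near, far)


def brute_force_rmsd(a, b, levels=4, step0_deg=10.0):
    """Minimum RMSD over rotations by coarse-to-fine Euler-grid search.

    Independent of the Kabsch path: centers both point sets, scans a full
    Euler-angle grid, then refines around the best orientation.
    """
    from scipy.spatial.transform import Rotation

    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)

    def grid(center, half_span, step):
        ax = [np.arange(-half_span, half_span + 1e-9, step) + c for c in center]
        angles = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        rots = Rotation.from_euler("zyx", angles)
        mats = rots.as_matrix()
        moved = np.einsum("rij,nj->rni", mats, a)
        rmsds = np.sqrt(np.mean(np.sum((moved - b[None]) ** 2, axis=2), axis=1))
        k = int(np.argmin(rmsds))
        return angles[k], float(rmsds[k])

    step = np.deg2rad(step0_deg)
    center, best = grid((0.0, 0.0, 0.0), np.pi, step)
    for _ in range(levels):
        span, step = 2 * step, step / 4
        center, best = grid(tuple(center), span, step)
    return best
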