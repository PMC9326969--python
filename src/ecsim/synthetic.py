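"""Synthetic trajectories with known conformational structure.

Two regimes mimic what MD trajectories of real proteins look like after
coordinate extraction:

* :func:`make_multibasin` — a system hopping between k recurring
  conformational states ("basins"), visited in contiguous dwell blocks,
  with isotropic Gaussian thermal noise around each basin center;
* :func:`make_drift` — a linearly progressing trajectory (a Gaussian random
  walk of the coordinate vector) that explores conformational space sparsely
  and never revisits it.

Neither generator models bonds or force-field physics — they provide ground
truth (basin labels, centers) for testing medoid recovery, diversity gain
and basin coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajectory_io import FrameMatrix, write_matrix, write_xyz


@dataclass
class SyntheticTrajectory:
    """Generated frames plus the ground truth they were built from."""

    frames: FrameMatrix
    basin_labels: np.ndarray
    centers: np.ndarray
    params: dict


def make_multibasin(n_frames: int = 1000, n_atoms: int = 30,
                    k_basins: int = 3, basin_spread: float = 20.0,
                    noise_sd: float = 1.0, seed: int = 0) -> SyntheticTrajectory:
    """Trajectory dwelling in ``k_basins`` recurring conformational states.

    Basin centers are sampled uniformly in a cube of edge ``basin_spread``
    (Angstrom); frames are assigned to basins in contiguous blocks whose
    order is a seeded permutation (mimicking MD dwell periods), and each
    frame is its center plus isotropic Gaussian noise of sd ``noise_sd``.
    """
    if k_basins < 1:
        raise ValueError("k_basins must be >= 1")
    if basin_spread <= 0:
        raise ValueError("basin_spread must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_frames < 1 or n_atoms < 1:
        raise ValueError("n_frames and n_atoms must be positive")
    m = 3 * n_atoms
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, basin_spread, size=(k_basins, m))
    block_order = rng.permutation(k_basins)
    sizes = np.full(k_basins, n_frames // k_basins)
    sizes[: n_frames % k_basins] += 1
    labels = np.repeat(block_order, sizes)
    values = centers[labels] + rng.normal(0.0, noise_sd, size=(n_frames, m))
    frames = FrameMatrix(values=values)
    params = dict(mode="multibasin", n_frames=n_frames, n_atoms=n_atoms,
                  k_basins=k_basins, basin_spread=basin_spread,
                  noise_sd=noise_sd, seed=seed)
    return SyntheticTrajectory(frames=frames, basin_labels=labels,
                               centers=centers, params=params)


def make_drift(n_frames: int = 1000, n_atoms: int = 30, step_sd: float = 0.1,
               seed: int = 0, n_segments: int = 4) -> SyntheticTrajectory:
    """Linearly progressing trajectory: a random walk of the coordinates.

    Frame i+1 adds N(0, step_sd^2) noise per coordinate to frame i, so the
    expected squared displacement between frames i and i+g is
    ``g * 3 * n_atoms * step_sd**2``.  Labels split the time axis into
    ``n_segments`` quantile blocks (a drifting trajectory has no basins; the
    segments stand in as coarse "epochs").
    """
    if step_sd <= 0:
        raise ValueError("step_sd must be positive")
    if n_frames < 1 or n_atoms < 1 or n_segments < 1:
        raise ValueError("n_frames, n_atoms and n_segments must be positive")
    m = 3 * n_atoms
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, size=(n_frames, m))
    steps[0] = 0.0
    values = np.cumsum(steps, axis=0)
    labels = (np.arange(n_frames) * n_segments) // n_frames
    frames = FrameMatrix(values=values)
    params = dict(mode="drift", n_frames=n_frames, n_atoms=n_atoms,
                  step_sd=step_sd, seed=seed, n_segments=n_segments)
    return SyntheticTrajectory(frames=frames, basin_labels=labels,
                               centers=values[:1].copy(), params=params)


def write_fixture(traj: SyntheticTrajectory, prefix, fmt: str = "matrix") -> dict:
    """Write a trajectory (matrix or XYZ) plus a basin-label sidecar TSV.

    Returns the paths written, keyed by role.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "matrix":
        traj_path = prefix.with_suffix(".csv")
        write_matrix(traj.frames, traj_path)
    elif fmt == "xyz":
        traj_path = prefix.with_suffix(".xyz")
        write_xyz(traj.frames, traj_path)
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")
    labels_path = prefix.parent / (prefix.name + "_labels.tsv")
    with open(labels_path, "w") as fh:
        fh.write("frame\tbasin\n")
        for i, lab in enumerate(traj.basin_labels):
            fh.write(f"{i}\t{int(lab)}\n")
    return {"trajectory": traj_path, "labels": labels_path}
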