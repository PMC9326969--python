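"""Scoring frame selections by average pairwise RMSD and ranking methods.

Diversity of a selected frame set is measured as the mean root-mean-square
deviation over all unordered pairs of selected frames (larger = more
diverse), with a population-form standard deviation over the pair RMSDs.
Frames are assumed pre-aligned; an optional Kabsch superposition flag is
available for unaligned input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata


@dataclass(frozen=True)
class EvalReport:
    """Average pairwise RMSD statistics of one frame selection (Angstrom)."""

    avg_rmsd: float
    std_rmsd: float
    n_pairs: int
    pairwise: np.ndarray | None = None


def _as_values(frames) -> np.ndarray:
    return np.asarray(getattr(frames, "values", frames), dtype=float)


def pair_rmsd(frame_a, frame_b, superpose: bool = False) -> float:
    """RMSD between two frames: sqrt((1/n_atoms) * sum_atoms |r_a - r_b|^2).

    Computed on raw coordinates without superposition by default; with
    ``superpose=True`` both frames are centered and frame_b is optimally
    rotated onto frame_a (Kabsch) first.
    """
    ra = np.asarray(frame_a, dtype=float).ravel()
    rb = np.asarray(frame_b, dtype=float).ravel()
    if ra.shape != rb.shape:
        raise ValueError(f"frame length mismatch: {ra.size} vs {rb.size}")
    if ra.size == 0 or ra.size % 3 != 0:
        raise ValueError("frame length must be a positive multiple of 3")
    A = ra.reshape(-1, 3)
    B = rb.reshape(-1, 3)
    if superpose:
        A = A - A.mean(axis=0)
        B = B - B.mean(axis=0)
        rot, _ = Rotation.align_vectors(A, B)
        B = rot.apply(B)
    return float(np.sqrt(((A - B) ** 2).sum() / A.shape[0]))


def selection_rmsd_stats(frames, order, superpose: bool = False,
                         keep_pairwise: bool = False) -> EvalReport:
    """Average pairwise RMSD of the frames listed in ``order``.

    std is the root-mean-square of (pair RMSD - average) over all pairs
    (population form, divide by the number of pairs).
    """
    values = _as_values(frames)
    order = np.asarray(order, dtype=int)
    if order.size < 2:
        raise ValueError("need at least 2 selected frames")
    if len(set(order.tolist())) != order.size:
        raise ValueError("duplicate frame indices in selection")
    sub = values[order]
    if superpose:
        k = order.size
        rmsds = np.array([pair_rmsd(sub[i], sub[j], superpose=True)
                          for i in range(k) for j in range(i + 1, k)])
    else:
        n_atoms = sub.shape[1] // 3
        rmsds = pdist(sub) / np.sqrt(n_atoms)
    avg = float(rmsds.mean())
    std = float(np.sqrt(((rmsds - avg) ** 2).mean()))
    return EvalReport(avg_rmsd=avg, std_rmsd=std, n_pairs=rmsds.size,
                      pairwise=rmsds if keep_pairwise else None)


def rank_methods(rmsd_table, method_names=None) -> pd.DataFrame:
    """Rank selection methods by RMSD across cases; count wins.

    ``rmsd_table`` is methods x cases (higher RMSD = more diverse = better).
    Per case, rank 1 goes to the highest RMSD; exact ties share the win
    (both counted) and receive average ranks.  Returns a DataFrame with
    ``wins`` and ``rank_sum`` per method.
    """
    if isinstance(rmsd_table, pd.DataFrame):
        table = rmsd_table.to_numpy(dtype=float)
        if method_names is None:
            method_names = list(rmsd_table.index)
    else:
        table = np.asarray(rmsd_table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 1:
        raise ValueError("rmsd_table must be a methods x cases matrix "
                         "with at least one case")
    if not np.isfinite(table).all():
        raise ValueError("rmsd_table has missing or non-finite cells")
    n_methods, _ = table.shape
    if method_names is None:
        method_names = [f"method_{i}" for i in range(n_methods)]
    ranks = np.apply_along_axis(lambda col: rankdata(-col, method="average"),
                                0, table)
    wins = (table == table.max(axis=0, keepdims=True)).sum(axis=1)
    return pd.DataFrame({"wins": wins.astype(int),
                         "rank_sum": ranks.sum(axis=1)},
                        index=pd.Index(method_names, name="method"))


def random_selection_baseline(frames, k: int, n_draws: int, seed: int,
                              superpose: bool = False) -> np.ndarray:
    """Average pairwise RMSD of ``n_draws`` uniform random k-subsets.

    A seeded stand-in baseline: any diversity picker worth running should
    beat the bulk of this distribution.
    """
    values = _as_values(frames)
    n = values.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for i in range(n_draws):
        # sorted subset: the statistic is order-invariant and sorting fixes
        # the floating-point summation order
        order = np.sort(rng.choice(n, size=k, replace=False))
        out[i] = selection_rmsd_stats(values, order,
                                      superpose=superpose).avg_rmsd
    return out
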