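"""Medoid finding and ECS-MeDiv diversity selection.

The complementary similarity of frame i is the extended similarity of the
whole set with frame i removed.  A central, heavily connected frame holds
the set together: remove it and the remaining frames score a LOW similarity.
The medoid is therefore the argmin of the complementary similarities.

ECS-MeDiv (Extended Continuous Similarity – Medoid Diversity) then grows a
diverse subset:

1. start from the medoid;
2. repeatedly add the candidate whose inclusion gives the selected set the
   LOWEST extended similarity (ties within an absolute 1e-12 are broken by
   the lowest mean pairwise similarity to the already-selected frames, then
   by lowest frame index);
3. stop after ``n_select`` picks (or when the pool is exhausted).

Both stages work on a single maintained column-sum vector, so each step
costs O(N * m) — no pairwise similarity matrix is ever built, which is what
makes the whole selection scale linearly in the number of frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import (
    NormalizedMatrix,
    normalize,
    resolve_index,
    sims_from_sums,
)

#: absolute tolerance under which two extended similarities count as tied
TIE_TOL = 1e-12


@dataclass(frozen=True)
class TiebreakRecord:
    """Audit entry for one tie resolved by the pairwise-similarity rule."""

    step: int
    candidates: tuple
    pairwise_means: tuple
    chosen: int


@dataclass
class SelectionResult:
    """Ordered diversity selection with its per-step similarity trace.

    ``step_similarity[k]`` is the extended similarity of the first k+1
    chosen frames; the first entry is NaN (a single frame has no set
    similarity).
    """

    order: list
    step_similarity: list
    index: str
    gamma: float = 0.0
    weighted: bool = False
    tiebreaks: list = field(default_factory=list)


def _as_normalized(frames) -> NormalizedMatrix:
    if isinstance(frames, NormalizedMatrix):
        return frames
    return normalize(frames)


def _pair_sims(row: np.ndarray, others: np.ndarray, index: str,
               gamma: float, weighted: bool) -> np.ndarray:
    """Pairwise (N=2) extended similarities of ``row`` against each row of
    ``others``, in the shared global scaling (no renormalization)."""
    return sims_from_sums(row[None, :] + others, 2, index, gamma=gamma,
                          weighted=weighted)


def complementary_similarities(frames, index: str, gamma: float = 0.0,
                               weighted: bool = False) -> np.ndarray:
    """Leave-one-out extended similarity for every frame, in one pass.

    Entry i is the similarity of all frames except i (object count N-1),
    computed by subtracting row i from the total column-sum vector — total
    cost O(N * m) instead of the naive O(N^2 * m).
    """
    norm = _as_normalized(frames)
    n = norm.n_objects
    if n < 3:
        raise ValueError("complementary similarity needs at least 3 frames "
                         "(each leave-one-out set must have >= 2 members)")
    index = resolve_index(index)
    total = norm.values.sum(axis=0)
    loo_sums = total[None, :] - norm.values
    return sims_from_sums(loo_sums, n - 1, index, gamma=gamma,
                          weighted=weighted)


def find_medoid(frames, index: str, gamma: float = 0.0,
                weighted: bool = False) -> int:
    """Frame with the lowest complementary similarity (ties: lowest index)."""
    comp = complementary_similarities(frames, index, gamma=gamma,
                                      weighted=weighted)
    return int(np.argmin(comp))


def ecs_mediv_select(frames, n_select: int, index: str, gamma: float = 0.0,
                     weighted: bool = False) -> SelectionResult:
    """Select ``n_select`` maximally diverse frames with ECS-MeDiv.

    Fully deterministic: no randomness anywhere, all ties resolved by the
    documented pairwise-then-lowest-index rule.
    """
    norm = _as_normalized(frames)
    n = norm.n_objects
    index = resolve_index(index)
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must be in [1, {n}], got {n_select}")
    if n == 2:
        # degenerate: no medoid is defined; return both frames in index order
        sim = float(_pair_sims(norm.values[0], norm.values[1:2], index,
                               gamma, weighted)[0])
        order = [0, 1][:n_select]
        sims = [float("nan"), sim][:n_select]
        return SelectionResult(order=order, step_similarity=sims, index=index,
                               gamma=gamma, weighted=weighted)

    values = norm.values
    order = [find_medoid(norm, index, gamma=gamma, weighted=weighted)]
    step_similarity = [float("nan")]
    tiebreaks: list[TiebreakRecord] = []
    selected_mask = np.zeros(n, dtype=bool)
    selected_mask[order[0]] = True
    running = values[order[0]].copy()

    while len(order) < n_select:
        k = len(order) + 1  # object count after adding a candidate
        cand_sums = running[None, :] + values
        sims = sims_from_sums(cand_sums, k, index, gamma=gamma,
                              weighted=weighted)
        sims[selected_mask] = np.inf
        best = sims.min()
        tied = np.flatnonzero(sims <= best + TIE_TOL)
        if tied.size == 1:
            choice = int(tied[0])
        else:
            sel_rows = values[order]
            means = np.array([
                _pair_sims(values[c], sel_rows, index, gamma, weighted).mean()
                for c in tied
            ])
            choice = int(tied[int(np.argmin(means))])  # argmin -> lowest index
            tiebreaks.append(TiebreakRecord(
                step=len(order), candidates=tuple(int(c) for c in tied),
                pairwise_means=tuple(float(v) for v in means), chosen=choice))
        order.append(choice)
        step_similarity.append(float(sims[choice]))
        selected_mask[choice] = True
        running += values[choice]

    return SelectionResult(order=order, step_similarity=step_similarity,
                           index=index, gamma=gamma, weighted=weighted,
                           tiebreaks=tiebreaks)
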