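"""Extended continuous similarity indices over sets of conformations.

An extended (n-ary) similarity index assigns a single similarity value to an
arbitrary number of objects at once, instead of averaging pairwise
comparisons.  For real-valued data (e.g. Cartesian coordinates of MD frames)
the recipe is:

1. min-max normalize the whole frame matrix to [0, 1] with ONE global
   min/max pair, so that relative L1 distances between frames are preserved;
2. sum each column of the normalized matrix;
3. classify every column sum s_j through the coincidence criterion
   Delta_j = |2 s_j - N|: columns with Delta_j > gamma are similarity
   columns (1-similarity ``a`` when s_j > N/2, 0-similarity ``d``
   otherwise), the rest are dissimilarity columns ``bc``;
4. accumulate both the column *counts* per class and the *weighted* totals:
   every similarity column carries f_s(Delta) = Delta/N toward its class,
   and every column carries its residual disagreement
   f_d(Delta) = 1 - (Delta - (N mod 2))/N toward the dissimilarity total —
   each column's unit mass splits into an agreement part and a disagreement
   part.  A column where all N frames coincide at an extreme has Delta = N:
   full similarity weight 1, zero disagreement; a column balanced at
   Delta = 0 contributes pure disagreement;
5. plug the totals into any of 16 classical similarity formulas
   (Jaccard-Tanimoto, Rogers-Tanimoto, Consonni-Todeschini, ...).  The
   "nonweighted" family (the default, and the variant used for the cRT and
   cCT2 indices throughout) puts the weighted totals in the numerator over
   raw column counts in the denominator; the "weighted" family uses
   weighted totals in both.

For two binary vectors Delta is either N (weight exactly 1) or 0 (weight
exactly 1), so the counters reduce to the 2x2 contingency counts and each
extended index coincides with its classical binary namesake — that limit is
the main correctness oracle used by the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical names of the 16 supported indices.
INDEX_NAMES: tuple[str, ...] = (
    "AC", "BUB", "CT1", "CT2", "CT3", "CT4", "Fai", "Gle",
    "Ja", "Ja0", "JT", "RR", "RT", "SM", "SS1", "SS2",
)

_CANONICAL = {name.lower(): name for name in INDEX_NAMES}


def resolve_index(name: str) -> str:
    """Return the canonical spelling of an index name (case-insensitive)."""
    try:
        return _CANONICAL[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown similarity index {name!r}; choose from {', '.join(INDEX_NAMES)}"
        ) from None


def resolve_indices(names) -> list[str]:
    """Expand a name, a comma-separated string, or ``'all'`` to canonical names."""
    if isinstance(names, str):
        names = [n for chunk in names.split(",") for n in [chunk.strip()] if n]
    out: list[str] = []
    for n in names:
        if n.strip().lower() == "all":
            out.extend(INDEX_NAMES)
        else:
            out.append(resolve_index(n))
    return out


@dataclass(frozen=True)
class NormalizedMatrix:
    """Frame matrix rescaled to [0, 1] by a single global min/max pair.

    ``values[i, j] = (q[i, j] - global_min) / (global_max - global_min)``;
    the extrema are taken over *all* entries of the matrix so that the
    scaling is uniform and distance orderings between frames are preserved.
    """

    values: np.ndarray
    global_min: float
    global_max: float
    n_objects: int

    def __post_init__(self):
        v = self.values
        if v.ndim != 2:
            raise ValueError("normalized matrix must be 2-D")
        if not np.isfinite(v).all():
            raise ValueError("normalized matrix contains non-finite values")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("normalized values must lie in [0, 1]")
        if self.global_min > self.global_max:
            raise ValueError("global_min must not exceed global_max")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ColumnSumVector:
    """Per-column sums of a normalized matrix plus the object count N."""

    sums: np.ndarray
    n_objects: int

    def __post_init__(self):
        s = np.asarray(self.sums, dtype=float)
        if s.ndim != 1:
            raise ValueError("column sums must be 1-D")
        if s.size and (s.min() < -1e-9 or s.max() > self.n_objects + 1e-9):
            raise ValueError("column sums must lie in [0, N]")


@dataclass(frozen=True)
class CounterSet:
    """Similarity/dissimilarity counter totals feeding every index formula.

    ``a`` / ``d`` / ``bc`` hold the 1-similarity, 0-similarity and
    dissimilarity totals in the family selected by ``weighted`` (raw column
    counts when False), with ``p = a + d + bc``.  The weighted totals
    ``w_a`` / ``w_d`` / ``w_bc`` are always carried alongside, because the
    index numerators use them in both families.  Constructing a CounterSet
    without explicit weighted totals assumes the binary limit (weights 1),
    where both families coincide.
    """

    a: float
    d: float
    bc: float
    p: float
    gamma: float = 0.0
    weighted: bool = False
    w_a: float = None
    w_d: float = None
    w_bc: float = None

    def __post_init__(self):
        if min(self.a, self.d, self.bc) < 0:
            raise ValueError("counters must be non-negative")
        if self.p <= 0:
            raise ValueError("counter total p must be positive")
        if abs((self.a + self.d + self.bc) - self.p) > 1e-9 * max(1.0, self.p):
            raise ValueError("counter partition violated: a + d + bc != p")
        for name in ("w_a", "w_d", "w_bc"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, float(getattr(self, name[2:])))

    @property
    def w_p(self) -> float:
        return self.w_a + self.w_d + self.w_bc


def _as_array(frames) -> np.ndarray:
    values = getattr(frames, "values", frames)
    return np.asarray(values, dtype=float)


def normalize(frames) -> NormalizedMatrix:
    """Min-max scale a frame matrix to [0, 1] with one global min/max pair.

    A constant matrix (max == min) maps to all zeros: there is no scale to
    recover, and zeros keep the downstream counters well defined.
    """
    q = _as_array(frames)
    if q.ndim != 2 or q.shape[0] < 1:
        raise ValueError("frame matrix must be 2-D with at least one row")
    if not np.isfinite(q).all():
        raise ValueError("frame matrix contains non-finite values")
    lo = float(q.min())
    hi = float(q.max())
    if hi == lo:
        vals = np.zeros_like(q)
    else:
        vals = (q - lo) / (hi - lo)
    return NormalizedMatrix(values=vals, global_min=lo, global_max=hi,
                            n_objects=q.shape[0])


def column_sums(norm: NormalizedMatrix) -> ColumnSumVector:
    """Sum each column of the normalized matrix (left-to-right, axis 0)."""
    return ColumnSumVector(sums=norm.values.sum(axis=0),
                           n_objects=norm.n_objects)


def _raw_counters(sums: np.ndarray, n_objects: int, gamma: float):
    """Vectorized counter classification over the last axis of ``sums``.

    Returns (a, d, bc, w_a, w_d, w_bc): the column counts per class and the
    weighted totals.  Counts put each column wholly in one class by the
    coincidence criterion; the weighted totals split each column's unit
    mass into agreement (f_s(Delta) = Delta/N, toward w_a or w_d, gated by
    Delta > gamma) and residual disagreement (f_d(Delta), clipped to [0, 1],
    toward w_bc from every column) — the continuous analogue of the binary
    contingency counts, which it reproduces exactly for N = 2 binary data.
    ``sums`` may be 1-D (one set) or 2-D (rows = independent sets evaluated
    together, as in leave-one-out or candidate scans).
    """
    n = n_objects
    delta = np.abs(2.0 * sums - n)
    is_sim = delta > gamma
    is_a = is_sim & (sums > n / 2.0)
    is_d = is_sim & ~is_a
    w_sim = delta / n
    w_dis = np.clip(1.0 - (delta - (n % 2)) / n, 0.0, 1.0)
    a = is_a.sum(axis=-1).astype(float)
    d = is_d.sum(axis=-1).astype(float)
    bc = (~is_sim).sum(axis=-1).astype(float)
    w_a = np.where(is_a, w_sim, 0.0).sum(axis=-1)
    w_d = np.where(is_d, w_sim, 0.0).sum(axis=-1)
    w_bc = w_dis.sum(axis=-1)
    return a, d, bc, w_a, w_d, w_bc


def classify_counters(cs: ColumnSumVector, gamma: float = 0.0,
                      weighted: bool = False) -> CounterSet:
    """Classify column sums into a/d/bc counters (both families).

    A column j is a similarity column when Delta_j = |2 s_j - N| exceeds the
    coincidence threshold ``gamma`` (strictly), landing in ``a`` if
    s_j > N/2 and in ``d`` otherwise; all remaining columns count toward
    ``bc``.  The returned CounterSet exposes column counts as a/d/bc when
    ``weighted`` is False and the f_s/f_d-weighted totals when True; the
    weighted totals are carried either way.
    """
    if cs.n_objects < 2:
        raise ValueError("similarity undefined for fewer than two objects")
    if not 0 <= gamma < cs.n_objects:
        raise ValueError("gamma must satisfy 0 <= gamma < N")
    sums = np.asarray(cs.sums, dtype=float)
    a, d, bc, w_a, w_d, w_bc = _raw_counters(sums, cs.n_objects, gamma)
    if weighted:
        shown = (float(w_a), float(w_d), float(w_bc))
    else:
        shown = (float(a), float(d), float(bc))
    return CounterSet(a=shown[0], d=shown[1], bc=shown[2], p=sum(shown),
                      gamma=gamma, weighted=weighted,
                      w_a=float(w_a), w_d=float(w_d), w_bc=float(w_bc))


def _safe_ratio(num, den):
    """num/den with the 0/0 (and 0-denominator) convention -> 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    ok = den > 0
    out = np.zeros(np.broadcast(num, den).shape)
    np.divide(num, den, out=out, where=ok)
    return out


def _index_values(index: str, na, nd, nbc, wa, wd, wbc, weighted: bool):
    """Evaluate one index on (arrays of) counter totals.

    Numerators always use the weighted totals (wa, wd, wbc); denominators
    use the column counts (na, nd, nbc) for the nonweighted family and the
    weighted totals for the weighted family.  In the binary limit both
    coincide with the classical contingency-count formulas.
    """
    wa = np.asarray(wa, dtype=float)
    wd = np.asarray(wd, dtype=float)
    wbc = np.asarray(wbc, dtype=float)
    if weighted:
        da, dd, dbc = wa, wd, wbc
    else:
        da = np.asarray(na, dtype=float)
        dd = np.asarray(nd, dtype=float)
        dbc = np.asarray(nbc, dtype=float)
    dp = da + dd + dbc
    if index == "AC":
        ratio = np.clip(_safe_ratio(wa + wd, dp), 0.0, 1.0)
        out = (2.0 / np.pi) * np.arcsin(np.sqrt(ratio))
    elif index == "BUB":
        out = _safe_ratio(np.sqrt(wa * wd) + wa, np.sqrt(da * dd) + da + dbc)
    elif index == "CT1":
        out = _safe_ratio(np.log1p(wa + wd), np.log1p(dp))
    elif index == "CT2":
        out = _safe_ratio(np.log1p(dp) - np.log1p(wbc), np.log1p(dp))
    elif index == "CT3":
        out = _safe_ratio(np.log1p(wa), np.log1p(dp))
    elif index == "CT4":
        out = _safe_ratio(np.log1p(wa), np.log1p(da + dbc))
    elif index == "Fai":
        out = _safe_ratio(wa + wd / 2.0, dp)
    elif index == "Gle":
        out = _safe_ratio(2.0 * wa, 2.0 * da + dbc)
    elif index == "Ja":
        out = _safe_ratio(3.0 * wa, 3.0 * da + dbc)
    elif index == "Ja0":
        out = _safe_ratio(3.0 * (wa + wd), 3.0 * (da + dd) + dbc)
    elif index == "JT":
        out = _safe_ratio(wa, da + dbc)
    elif index == "RR":
        out = _safe_ratio(wa, dp)
    elif index == "RT":
        out = _safe_ratio(wa + wd, dp + dbc)
    elif index == "SM":
        out = _safe_ratio(wa + wd, dp)
    elif index == "SS1":
        out = _safe_ratio(wa, da + 2.0 * dbc)
    elif index == "SS2":
        out = _safe_ratio(2.0 * (wa + wd), dp + da + dd)
    else:  # pragma: no cover
        raise ValueError(f"unknown index {index!r}")
    # guard the [0, 1] range against round-off and the f_d(0) = 1 + 1/N
    # overshoot possible for odd N on exact-coincidence columns
    return np.clip(out, 0.0, 1.0)


def sims_from_sums(sums: np.ndarray, n_objects: int, index: str,
                   gamma: float = 0.0, weighted: bool = False) -> np.ndarray:
    """Extended similarity per row of a stack of column-sum vectors.

    The workhorse behind leave-one-out and candidate scans: one vectorized
    classification over all rows, O(rows * m).
    """
    index = resolve_index(index)
    counters = _raw_counters(np.asarray(sums, dtype=float), n_objects, gamma)
    na, nd, nbc, wa, wd, wbc = counters
    return np.asarray(_index_values(index, na, nd, nbc, wa, wd, wbc, weighted))


def extended_similarity(counters: CounterSet, index: str) -> float:
    """Compute one extended similarity index from a counter set.

    Formulas with a vanishing denominator (e.g. JT with a = bc = 0) return
    0 — no positive similarity evidence — with a logged warning.
    """
    index = resolve_index(index)
    if counters.a == 0 and counters.bc == 0 and index in (
            "JT", "Gle", "Ja", "SS1", "CT4", "BUB"):
        logger.warning("%s is 0/0 for counters a=0, bc=0; returning 0", index)
    return float(_index_values(index, counters.a, counters.d, counters.bc,
                               counters.w_a, counters.w_d, counters.w_bc,
                               counters.weighted))


def similarity_of_set(frames, index: str, gamma: float = 0.0,
                      weighted: bool = False) -> float:
    """Extended similarity of a whole set of frames.

    ``frames`` may be a raw FrameMatrix / array (normalized here with its
    own global min/max) or an already-:class:`NormalizedMatrix` — subset
    evaluations must pass the latter so that every subset reuses the global
    scaling of the full trajectory.
    """
    norm = frames if isinstance(frames, NormalizedMatrix) else normalize(frames)
    counters = classify_counters(column_sums(norm), gamma=gamma,
                                 weighted=weighted)
    return extended_similarity(counters, index)


def pairwise_similarity(frame_a, frame_b, index: str, gamma: float = 0.0,
                        weighted: bool = False) -> float:
    """Extended similarity of a 2-frame subset, in the global scaling.

    Both rows must come from the same globally normalized matrix; they are
    NOT renormalized here (a per-pair min/max would break comparability
    across pairs).
    """
    ra = np.asarray(frame_a, dtype=float).ravel()
    rb = np.asarray(frame_b, dtype=float).ravel()
    if ra.shape != rb.shape:
        raise ValueError(f"row length mismatch: {ra.size} vs {rb.size}")
    return float(sims_from_sums(ra + rb, 2, index, gamma=gamma,
                                weighted=weighted))
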