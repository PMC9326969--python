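"""Independent reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way (bit counting,
explicit subset enumeration, from-scratch recomputation) and must stay
independent of the vectorized/incremental code paths it checks.
"""

import math

import numpy as np

from ecsim import NormalizedMatrix, pairwise_similarity, similarity_of_set

TIE_TOL = 1e-12


def contingency_counts(x, y):
    """2x2 contingency counts (a, b+c, d, p) of two binary vectors."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    a = int(np.sum((x == 1) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    bc = int(np.sum(x != y))
    return a, d, bc, x.size


def classical_binary_index(name, a, d, bc, p):
    """Classical pairwise similarity coefficients from contingency counts.

    Written directly from the textbook definitions; 0/0 forms -> 0.
    """

    def div(num, den):
        return num / den if den > 0 else 0.0

    if name == "AC":
        return (2.0 / math.pi) * math.asin(math.sqrt((a + d) / p))
    if name == "BUB":
        root = math.sqrt(a * d)
        return div(root + a, root + a + bc)
    if name == "CT1":
        return math.log1p(a + d) / math.log1p(p)
    if name == "CT2":
        return (math.log1p(p) - math.log1p(bc)) / math.log1p(p)
    if name == "CT3":
        return math.log1p(a) / math.log1p(p)
    if name == "CT4":
        return div(math.log1p(a), math.log1p(a + bc))
    if name == "Fai":
        return (a + d / 2.0) / p
    if name == "Gle":
        return div(2 * a, 2 * a + bc)
    if name == "Ja":
        return div(3 * a, 3 * a + bc)
    if name == "Ja0":
        return div(3 * (a + d), 3 * (a + d) + bc)
    if name == "JT":
        return div(a, a + bc)
    if name == "RR":
        return a / p
    if name == "RT":
        return (a + d) / (p + bc)
    if name == "SM":
        return (a + d) / p
    if name == "SS1":
        return div(a, a + 2 * bc)
    if name == "SS2":
        return 2 * (a + d) / (p + a + d)
    raise ValueError(name)


def _subset(norm, rows):
    return NormalizedMatrix(values=norm.values[list(rows)],
                            global_min=norm.global_min,
                            global_max=norm.global_max,
                            n_objects=len(rows))


def naive_complementary(norm, index, gamma=0.0, weighted=False):
    """Leave-one-out similarities by explicit recomputation per frame."""
    n = norm.n_objects
    out = np.empty(n)
    for i in range(n):
        rows = [j for j in range(n) if j != i]
        out[i] = similarity_of_set(_subset(norm, rows), index,
                                   gamma=gamma, weighted=weighted)
    return out


def naive_ecs_mediv(norm, n_select, index, gamma=0.0, weighted=False):
    """From-scratch diversity selection: similarity recomputed per candidate
    per step, with the same tiebreak rules as the production algorithm.

    Returns (order, step_similarities).
    """
    n = norm.n_objects
    comp = naive_complementary(norm, index, gamma=gamma, weighted=weighted)
    order = [int(np.argmin(comp))]
    sims = [float("nan")]
    while len(order) < n_select:
        values = {}
        for c in range(n):
            if c in order:
                continue
            values[c] = similarity_of_set(_subset(norm, order + [c]), index,
                                          gamma=gamma, weighted=weighted)
        lowest = min(values.values())
        tied = sorted(c for c, v in values.items() if v <= lowest + TIE_TOL)
        if len(tied) == 1:
            choice = tied[0]
        else:
            means = {
                c: float(np.mean([
                    pairwise_similarity(norm.values[c], norm.values[s], index,
                                        gamma=gamma, weighted=weighted)
                    for s in order]))
                for c in tied
            }
            choice = min(tied, key=lambda c: (means[c], c))
        order.append(choice)
        sims.append(values[choice])
    return order, sims
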