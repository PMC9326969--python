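# Methods

## Extended continuous similarity

`ecsim` measures the similarity of a *set* of conformations — any number of
them at once — from the column sums of their coordinate matrix. The input is
an N × m matrix Q (N frames, m = 3·n_atoms Cartesian coordinates in Å);
frames are assumed pre-aligned (coordinates extracted from a simulation in a
common reference frame).

**Normalization.** All similarity machinery operates on values in [0, 1], so
Q is min-max scaled with a single global pair: n(q) = (q − min Q)/(max Q −
min Q). Using one global pair (not per-column) is essential: the map is then
affine with a positive slope, so for any two frame pairs the ordering of
their L1 distances is exactly preserved, and subset evaluations (pairs,
leave-one-out sets, growing selections) remain comparable as long as they
reuse the full-set min/max — which every subset routine in the package does.
A constant matrix (max = min) maps to all zeros rather than erroring, so
degenerate inputs still flow through.

**Counters.** Let s_j be the j-th column sum and Δ_j = |2 s_j − N| the
coincidence margin (0 when the column is perfectly balanced, N when all
frames coincide at an extreme). Columns with Δ_j > γ are similarity columns
— 1-similarity (a) if s_j > N/2, 0-similarity (d) otherwise — and the rest
are dissimilarity (b+c) columns. Two families of totals are accumulated:

* **counts** — one unit per column to its class; a + d + (b+c) = m always;
* **weighted totals** — each similarity column contributes its margin
  fraction f_s(Δ) = Δ/N to w_a or w_d, and *every* column contributes its
  residual disagreement f_d(Δ) = 1 − (Δ − (N mod 2))/N (clipped to [0, 1])
  to w_(b+c). Each column's unit mass thus splits into an agreement part
  and a disagreement part.

For two binary vectors Δ is either 2 (weight exactly 1, disagreement 0) or
0 (agreement 0, disagreement 1), so both families collapse onto the 2×2
contingency counts — the binary classical limit, enforced to 1e−12 in the
tests against an independent bit-counting oracle.

The split-mass weighting is what makes the continuous extension
informative. If dissimilarity mass were granted only to columns with
Δ_j ≤ γ, then at the default γ = 0 a continuous trajectory would have *no*
dissimilarity columns at all (Δ_j = 0 has measure zero), every
dissimilarity total would vanish, and indices such as Rogers–Tanimoto or
Consonni–Todeschini 2 would be identically 1 for every set of frames —
useless for ranking candidate selections. The clip on f_d handles the odd-N
corner (Δ < 1 would otherwise push f_d above 1).

**Index families.** The 16 indices (AC, BUB, CT1–CT4, Fai, Gle, Ja, Ja0,
JT, RR, RT, SM, SS1, SS2) are classical coefficients evaluated on the
counters. The default **nonweighted** family — the variant used for cRT and
cCT2 throughout — puts the weighted totals in the numerators over raw
column counts in the denominators; the opt-in **weighted** family uses
weighted totals in both. Examples (nonweighted):

    cRT  = (w_a + w_d) / (p + (b+c))          p = a + d + (b+c) = m
    cCT2 = [ln(1+p) − ln(1+w_(b+c))] / ln(1+p)
    cJT  = w_a / (a + (b+c))

Values are clipped to [0, 1] as a numerical safeguard. 0/0 forms (e.g. JT
with a = b+c = 0) return 0 — absence of similarity evidence — with a logged
warning.

**Parameters.**

| parameter  | default | meaning |
|------------|---------|---------|
| `gamma`    | 0       | coincidence threshold on Δ = \|2s − N\|; columns with Δ ≤ γ count as dissimilar. 0 reproduces the plain partition; exact Δ = 0 is measure-zero for continuous data. |
| `weighted` | False   | index family; the nonweighted family is the working default for MD data. |
| `index`    | —       | any of the 16 names, case-insensitive; cRT and cCT2 are the recommended workhorses. |

## Medoid and ECS-MeDiv selection

The **complementary similarity** of frame i is the extended similarity of
the set with frame i removed, computed for all i in one pass by subtracting
each row from the total column-sum vector (O(N·m) instead of the naive
O(N²·m); equality with explicit leave-one-out recomputation is tested to
1e−12). The **medoid** is the argmin (ties: lowest frame index). Low
complementary similarity marks a frame that holds the set together: with a
dominant, well-separated basin the medoid lands in that basin (tested over
seeds). Note that on a single isotropic Gaussian cloud the medoid is *not*
reliably the frame nearest the centroid — in high dimension all frames
concentrate in a thin distance shell, and coordinate-wise coincidence does
not reproduce that shell's ordering; the package makes no such claim.

**ECS-MeDiv** grows a diverse subset of size k:

1. start from the medoid;
2. at each step add the candidate c minimizing the extended similarity of
   (selected ∪ {c}), evaluated for all candidates at once from a maintained
   running column sum (one O(N·m) pass per step);
3. candidates within 1e−12 (absolute) of the minimum are tied; ties are
   broken by the lowest mean pairwise (N = 2) similarity to the selected
   frames using the same index, remaining ties by lowest frame index. Every
   tiebreak is recorded in an audit trail;
4. stop after k picks or pool exhaustion.

The algorithm is fully deterministic, never revisits selected frames
(already-selected candidates are excluded; adding an exact duplicate cannot
minimize the set similarity while a distinct candidate exists), and matches
a from-scratch reference implementation exactly on random inputs for all 16
indices. For N = 2 no medoid is defined and the selection degenerates to
both frames in index order. The 1e−12 tie tolerance treats floating-point
round-off as equality without merging genuinely distinct candidates; the
pairwise tiebreak reuses the driving index to keep the algorithm
single-parameter.

## Diversity scoring

`pair_rmsd` implements RMSD(a, b) = sqrt((1/n_atoms) Σ ‖r_a − r_b‖²) on raw
(unnormalized) coordinates with **no superposition by default** — frames
extracted from a trajectory share a frame of reference, and fitting would
silently change the quantity being compared. An optional `superpose=True`
performs a Kabsch alignment first (never increases the value; tested on
random rigid transforms). `selection_rmsd_stats` averages over all k(k−1)/2
unordered pairs; the standard deviation is the population form (divide by
the number of pairs) — the simplest consistent estimator given that only
the set of pair RMSDs is in play. `rank_methods` ranks methods per case
(rank 1 = highest average RMSD, i.e. most diverse), counts wins with exact
ties sharing the win, and sums average ranks. `random_selection_baseline`
draws seeded uniform k-subsets as the null distribution a picker must beat.

## Synthetic trajectories

`make_multibasin` emulates a simulation revisiting k conformational states:
basin centers sampled uniformly in a cube of edge `basin_spread` (default
20 Å), frames assigned to basins in contiguous dwell blocks whose order is
a seeded permutation, coordinates = center + isotropic Gaussian noise
(default 1 Å). `make_drift` emulates a linearly progressing trajectory: a
Gaussian random walk per coordinate (E‖x_{i+g} − x_i‖² = 3·n_atoms·g·σ²,
tested against the closed form). Defaults — 1000 frames, 30 atoms — match
the scale of a typical per-trajectory analysis (1000 frames; 30 atoms is
10 residues' worth of backbone).

What the generators deliberately do not model: bond geometry, force-field
physics, anisotropic or correlated fluctuations, solvent, and basin shapes
beyond isotropic Gaussians. Tests passing on these fixtures therefore
demonstrate the *selection machinery* (ground-truth basin coverage,
diversity gain over random, scaling) — not force-field realism.

One empirical caveat from the fixtures: only indices crediting both 1- and
0-coincidence (AC, CT1, CT2, Fai, Ja0, RT, SM, SS2) reliably score
within-basin pairs above between-basin pairs; a-only indices (JT, RR, CT3,
CT4, Gle, Ja, SS1, BUB) ignore agreement at low normalized coordinates and
can invert the ordering for basins near the global minimum. This is the
practical reason the symmetric cRT and cCT2 are the recommended defaults.

## Numerical choices and limitations

* Counters and column sums accumulate in float64 with a fixed left-to-right
  summation order; the incremental running sums agree with from-scratch
  recomputation to well below the 1e−12 tie tolerance at these problem
  sizes.
* Column sums exactly at N/2 classify as dissimilarity columns (strict
  Δ > γ); for continuous data this boundary has measure zero, for binary
  data it reproduces the classical counters.
* Whole-trajectory cost is O(N·m) per selection step and O(N·m) for the
  medoid; the fitted log-log wall-time exponent over N ∈ {1000…8000} is
  ≈ 1.1 (pure linearity plus constant vectorization overhead).
* The PDB reader keeps altLoc ' '/'A' only and selects backbone atoms by
  exact name match {N, CA, C}; no element inference, no topology
  perception. Vendor trajectory formats (dcd/xtc/dtr) are out of scope —
  convert to the matrix or XYZ interchange first.
* Problem sizes in the test suite (e.g. leave-one-out oracles at N ≤ 50,
  naive-selection oracles at N = 100, scaling fits up to N = 8000) were
  chosen to exercise every code path at sizes where the brute-force oracles
  are still exact and fast; the library itself has no hard-coded size
  limits.
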