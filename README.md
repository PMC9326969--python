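# ecsim — extended continuous similarity and diverse frame selection for MD trajectories

Molecular-dynamics simulations routinely produce thousands to hundreds of
thousands of frames, from which a handful of representative, structurally
diverse conformations must be picked — for ensemble docking, for reporting,
or simply to summarize the sampled conformational space. The standard route
(cluster the pairwise-RMSD matrix, keep one frame per cluster) costs
O(N²) in the number of frames and becomes the bottleneck long before the
simulation itself does.

`ecsim` implements a linearly scaling alternative built on **extended
continuous similarity indices**: similarity measures defined over an
*arbitrary number* of real-valued conformations at once, computed from the
column sums of the min-max-normalized coordinate matrix instead of from
pairwise comparisons. On top of them sits **ECS-MeDiv**
(Extended Continuous Similarity – Medoid Diversity), a deterministic
diversity picker that

1. seeds the selection with the **medoid** — the frame whose removal leaves
   the least similar remaining set (lowest *complementary similarity*), and
2. repeatedly adds the candidate frame whose inclusion gives the selected
   set the *lowest* extended similarity, breaking ties by the lowest mean
   pairwise similarity to the already-selected frames.

Both stages maintain a single running column-sum vector, so each step is one
O(N·m) pass — no pairwise matrix is ever built.

## The model in brief

For N frames with m = 3·n_atoms coordinates each, stacked into a matrix Q:

- **Normalization**: n(q) = (q − min Q)/(max Q − min Q) with *one* global
  min/max pair, an affine map that preserves every inter-frame L1-distance
  ordering.
- **Column sums**: s_j = Σ_i n(q_ij), j = 1..m.
- **Counters**: with Δ_j = |2 s_j − N|, each column is a 1-similarity
  (*a*, s_j > N/2), 0-similarity (*d*, s_j < N/2) or dissimilarity (*b+c*)
  column (coincidence threshold γ, default 0). Every column also splits its
  unit mass continuously: f_s(Δ) = Δ/N toward its similarity class and the
  residual disagreement f_d(Δ) = 1 − (Δ − N mod 2)/N toward the
  dissimilarity total. For two binary vectors these reduce exactly to the
  classical 2×2 contingency counts.
- **Indices**: 16 classical coefficients (Jaccard–Tanimoto, Rogers–Tanimoto,
  Consonni–Todeschini 1–4, Sokal–Michener, …) evaluated on the counters;
  e.g. the extended continuous Rogers–Tanimoto index is
  cRT = (a + d)/(p + (b+c)). All indices live in [0, 1].

Selection quality is scored by the **average pairwise RMSD** of the chosen
frames (larger = more diverse), with a population standard deviation over
the pairs, and methods are compared by per-case ranks and "wins".

## Worked example

```python
import numpy as np
from ecsim import (make_multibasin, normalize, similarity_of_set,
                   ecs_mediv_select, selection_rmsd_stats,
                   random_selection_baseline)

# synthetic trajectory: 1000 frames, 30 atoms, 4 conformational basins
traj = make_multibasin(n_frames=1000, n_atoms=30, k_basins=4,
                       basin_spread=20.0, noise_sd=1.0, seed=7)
norm = normalize(traj.frames)

print("whole-set cRT :", round(similarity_of_set(norm, "RT"), 4))
print("whole-set cCT2:", round(similarity_of_set(norm, "CT2"), 4))

sel = ecs_mediv_select(norm, n_select=6, index="RT")
report = selection_rmsd_stats(traj.frames, sel.order)
base = random_selection_baseline(traj.frames, k=6, n_draws=1000, seed=1)
print("selected frames        :", sel.order)
print("avg pairwise RMSD (Å)  :", round(report.avg_rmsd, 3))
print("random-median RMSD (Å) :", round(float(np.median(base)), 3))
```

Output:

```
whole-set cRT : 0.1746
whole-set cCT2: 0.042
selected frames        : [70, 506, 358, 904, 411, 700]
avg pairwise RMSD (Å)  : 13.018
random-median RMSD (Å) : 11.632
```

The whole-set similarities are low — the trajectory hops between four
well-separated basins, so coordinate columns rarely coincide. The six
ECS-MeDiv frames spread across basins and beat the median random six-frame
draw by ~1.4 Å of average pairwise RMSD, i.e. the picker returns a
noticeably more diverse ensemble than chance.

The same workflow is available from the shell:

```bash
ecsim synth --mode multibasin --n-frames 1000 --seed 7 -o scratch/fix
ecsim select -i scratch/fix.csv --atoms all --index RT -n 6 -o scratch/sel.tsv
ecsim evaluate -i scratch/fix.csv --atoms all --selection scratch/sel.tsv \
      --baseline-draws 1000
```

Real trajectories enter as multi-model PDB (`--atoms backbone` keeps the
N, Cα, C backbone atoms), XYZ blocks, or a plain delimited matrix with one
frame per row. See `examples/` for short narrative scripts, one per
capability.

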