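# vdjtraj

Trajectory inference for paired single-cell transcriptome + immune
receptor (scRNA-seq + scVDJ-seq) data.

During T- and B-cell development, V(D)J recombination progresses in a
stereotyped way — for the TCR alpha locus, proximal V/J segments recombine
before distal ones — so the *identity* of the recombined V, D and J genes
carries information about where a cell sits along its developmental
trajectory, and about the fate it will adopt. Most trajectory tools ignore
this because gene calls are categorical. `vdjtraj` converts them into a
continuous **VDJ feature space**: cells are grouped into overlapping KNN
neighborhoods ("pseudobulks") in a reduced expression space, and each
neighborhood is described by its V/D/J **usage fractions** per
(locus, segment) category. Trajectory inference then runs on that feature
space with a diffusion map and an **absorbing Markov chain**, and the
results are projected back onto single cells.

Who it is for: immunologists and computational biologists analysing
paired 10x/AIRR TCR data who want pseudotime *and* per-cell branch
(fate) probabilities informed by receptor usage rather than expression
alone.

## Method at a glance

1. **Preprocess** (`setup_vdj_cells`): keep productive contigs, classify
   each cell's chain status from its (VDJ-class, VJ-class) chain counts
   (`single_pair`, `orphan_*`, `extra_*`, `ambiguous`), keep allowed
   statuses, and resolve each locus to the main chain with the highest UMI
   count.
2. **Pseudobulk** (`knn_graph`, `make_neighborhoods`, `vdj_feature_space`):
   exact KNN neighborhoods (index cell + its k neighbors) over PCA-like
   coordinates; per-neighborhood usage fractions
   `x[nhood, locus_seg:gene] ∈ [0,1]`, each populated category summing
   to 1.
3. **Trajectory** (`MarkovTrajectory(...).fit()`): adaptive Gaussian
   kernel `w_ij = exp(-d_ij² / σ_i σ_j)` with `σ_i` the distance to the
   ka-th neighbor; row-stochastic operator `P`; multiscale embedding
   scaling eigenvector `ψ_i` by `λ_i/(1-λ_i)`; per-dimension max-min
   waypoints; iterative waypoint-perspective pseudotime; a directed KNN
   chain oriented by pseudotime with backward edges pruned beyond a local
   scale; terminal states detected unsupervised (or supplied); branch
   probabilities `B = (I-Q)⁻¹ R` from the fundamental matrix.
4. **Project** (`TrajectoryResults.project`): each cell takes the mean
   pseudotime and fate probabilities of its containing neighborhoods;
   fate probabilities are renormalised to sum to one.

The model/results split follows the statsmodels convention:
`MarkovTrajectory` holds the data and parameters, `fit()` returns a
`TrajectoryResults` with `pseudotime`, `branch_probs`, `terminal_states`,
`summary()` and `project()`.

## Worked example

```python
from vdjtraj import (
    simulate_bifurcating_repertoire, setup_vdj_cells, knn_graph,
    make_neighborhoods, vdj_feature_space, MarkovTrajectory,
)

sim = simulate_bifurcating_repertoire(n_cells=2000, seed=7)
cells = setup_vdj_cells(sim.contigs, sim.metadata)   # 1814 of 2000 retained
graph = knn_graph(sim.space.loc[cells.index], k=30)
nhoods = make_neighborhoods(graph, proportion=0.25, seed=1)
fs = vdj_feature_space(cells, nhoods)
result = MarkovTrajectory.from_feature_space(fs, root_label="DP_P").fit()
print(result.summary())
```

```
Absorbing Markov chain trajectory results
=============================================
states:            213
root:              cell01592
terminal states:   cell01775, cell01254
fates:             CD4_T, CD8_T
diffusion comps:   10 (k_dm=30, ka=10)
multiscale eigs:   6
waypoints:         213
pseudotime range:  [0, 5.507]

mean branch probability by fate:
  CD4_T                0.3115
  CD8_T                0.6885
```

The simulated thymocyte dataset bifurcates from double-positive
precursors (DP(P) → DP(Q) → ABT(ENTRY)) into CD4+ and CD8+ single-positive
T cells; the model finds one terminal state per fate (the neighborhood
labels name the fates) and every state's two fate probabilities sum to 1.
`result.project(nhoods, cells=cells)` yields the per-cell table
(`cell_id, cell_type, pseudotime, prob_CD4_T, prob_CD8_T`); on this run
its pseudotime has Kendall τ ≈ 0.93 against the simulation's latent time
and ~97% of committed cells place majority probability on their true
fate.

The same workflow runs from the shell on AIRR TSV / 10x contig CSV /
combined-receptor-string inputs:

```sh
vdjtraj simulate --kind bifurcating --n-cells 2000 --seed 7 --out data/
vdjtraj run --contigs data/contigs.tsv --dialect airr \
    --metadata data/metadata.csv --coords data/coords.csv \
    --root-label DP_P --proportion 0.25 --seed 1 --out runs/demo
vdjtraj compare runs/demo/cell_trajectory.csv runs/other/cell_trajectory.csv
```

`run` writes the cell table, feature space, pseudobulk and cell
trajectories and a manifest with every resolved parameter; the
per-stage subcommands (`preprocess`, `pseudobulk`, `trajectory`,
`project`) compose to byte-identical outputs. `compare` reports Pearson,
Lin's concordance, Kendall τ-b, MAE and a Bland-Altman summary between
two runs.

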