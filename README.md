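# nmcoupling

Node sizes inside a single brain atlas vary widely, and graph metrics
computed on functional connectivity networks inherit that variability.
`nmcoupling` is a Python package for quantifying this effect in
ICA-based resting-state fMRI analyses: it measures each functional
node's size, computes weighted graph metrics on proportionally
thresholded functional-network-connectivity (FNC) graphs, and
correlates the two across subjects — the **node-metric coupling (NMC)**
statistic — with group-level significance calibration and group
comparisons. It is aimed at neuroimaging researchers who work with
component-based (ICN) connectomes and want either to control for node
size as a confound or to explore NMC as a group-difference marker.

## What it computes

* **Node size**: the number of voxels in a component's spatial map above
  `3.5 x SD` of the map (`nodesize`).
* **FNC graphs**: Pearson correlation of component time courses, then
  proportional thresholding that keeps the strongest-|r| fraction `pt`
  of edges with signed weights (`connectivity`).
* **Six weighted graph metrics** (`metrics`): node degree
  `k_i = Σ_j |w_ij|`, participation coefficient
  `y_i = 1 − Σ_m (k_i^m / k_i)²`, closeness centrality
  `(n−1) / Σ_j d_ij`, global efficiency `mean(1/d_ij)`, characteristic
  path length `mean(d_ij)`, and the Onnela weighted clustering
  coefficient — with `d_ij` the Dijkstra shortest path over lengths
  `1/|w|`.
* **NMC** (`stats`): Pearson r across subjects within a group between a
  component's size and each metric, a 6 x C grid per group; Bonferroni
  critical-r calibration (0.12 / 0.20 / 0.26 for groups of 947 / 368 /
  213 at α = 0.05 over 6 x 53 tests), Fisher z group comparisons, Welch
  t-tests with BH-FDR for global metrics and cell-wise FNC differences.
* **Synthetic cohorts** (`synthetic`): multi-group cohorts with exact
  planted node sizes and a tunable size→connectivity coupling, so every
  stage has ground truth. See `docs/methods.md` for the model.

## Worked example

Generate a small three-group cohort (60/40/30 subjects, 20 components)
with a planted coupling of strength 0.4, run the full chain in memory,
and summarize NMC per group:

```python
from nmcoupling import desk_preset, generate_cohort
from nmcoupling.pipeline import analyze_cohort

cohort = generate_cohort(desk_preset(seed=1, coupling_beta=0.4))
analysis = analyze_cohort(cohort)
for group, rep in analysis.significance.items():
    grid = analysis.nmc[group].r
    print(f"{group}: n={rep.n}  critical_r={rep.critical_r:.3f}  "
          f"mean degree-NMC={grid.loc['degree'].mean():+.3f}  "
          f"significant cells={int(rep.significant.to_numpy().sum())}/120")
```

```
HC: n=60  critical_r=0.441  mean degree-NMC=+0.875  significant cells=54/120
MCI: n=40  critical_r=0.532  mean degree-NMC=+0.850  significant cells=54/120
AD: n=30  critical_r=0.603  mean degree-NMC=+0.851  significant cells=40/120
```

Each group's NMC grid is 6 metrics x 20 components (120 cells). The
planted coupling makes node size and weighted degree strongly correlated
(≈ +0.85 across groups); the critical r rises as group size falls, so
the smallest group flags fewer cells at the same underlying coupling —
the sample-size asymmetry the calibration is designed to expose. With
`coupling_beta=0` the grids hover near zero and essentially no cell is
flagged.

The same chain runs from the shell, either from simulated or on-disk
inputs (NIfTI maps, TSV time courses/labels/partition):

```bash
nmc run --desk-sim --seed 1 --beta 0.4 --out results/demo
nmc nodesize --maps MAPS/ --groups groups.tsv --partition partition.tsv --out sizes.tsv
```

`nmc run` writes sizes, per-group mean FNC, metric tables, NMC grids,
significance masks, group comparisons and a JSON run report.

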