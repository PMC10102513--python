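# gazenet

Complex-network analysis of gaze time series recorded during rapid
automatized naming (RAN) tasks.

In RAN, a participant names a 5 × 10 matrix of stimuli (numbers,
characters, colors or objects) aloud, as fast as possible, scanning
left-to-right and top-to-bottom, while an eye tracker samples gaze
position at ~90 Hz. Classic analysis reduces such a recording to a
handful of event statistics — fixation counts and durations, saccade
amplitudes, regressions, total naming time. `gazenet` instead treats the
recording as a two-dimensional time series and maps it to a **gaze
proximity network**: every gaze sample *(x_m, y_m)* becomes a node, and
nodes *m* and *w* are connected when their screen distance falls below a
proximity threshold θ_mw,

```
g_mw = 1  if d_mw ≤ θ_mw,   0 otherwise,
```

with θ set from the distribution of neighbor distances (a global
distance quantile by default, per-pair adaptive k-NN radii as an
alternative). The network is then summarized by nine graph-topological
parameters: average degree m/n, diameter, characteristic path length L,
clustering coefficient C, global efficiency, degree assortativity,
modularity Q of the best Louvain partition, community number, and
small-worldness

```
SW = 1 − (ΔC² + ΔL²)/2,
ΔC = (C_latt − C_obs)/(C_latt − C_rand),  ΔL = (L_obs − L_rand)/(L_latt − L_rand),
```

where the lattice and random null models are matched on network size
and edge budget. Gaze networks built this way are assortative, modular,
and small-world: fixations form densely connected clusters, saccades
link neighboring clusters, and regressions provide sparse long-range
shortcuts.

The package also computes the six classic eye-movement metrics
(dispersion-based I-DT fixation detection: gaze held ≥ 100 ms within a
40 px box), the nonparametric statistics for comparing task types
(Friedman tests with Kendall's W, Wilcoxon signed-rank post hocs with
Bonferroni correction, rank-based robust regression with R²), and a
synthetic RAN gaze simulator so the full pipeline can be exercised and
tested without access to tracker data.

Who it is for: researchers analyzing serial-naming or other structured
scanning eye-tracking protocols who want ROI-free, network-domain
descriptors next to the classic event metrics.

## Worked example

```python
from gazenet import (SimulationConfig, simulate_subject, preprocess,
                     traditional_metrics, build_gcn, topology_profile)

cfg = SimulationConfig(seed=3).with_task("N-num")   # number-naming profile
rec = simulate_subject(cfg)                          # one synthetic child
series = preprocess(rec.series)                      # drop invalid samples

m = traditional_metrics(series)
print(f"naming time {m.total_time:.1f} s, {m.fixation_counts} fixations, "
      f"{m.regression_counts} regressions")

graph = build_gcn(series)                            # Eq. above, rho = 1/30
prof = topology_profile(graph, seed=1)               # nine parameters + nulls
print(f"n={prof.n} m={prof.m} avg_degree={prof.avg_degree:.1f} "
      f"diameter={prof.diameter:.0f} L={prof.char_path_length:.2f}")
print(f"C={prof.clustering:.2f} AC={prof.assortativity:.2f} "
      f"Q={prof.modularity:.2f} communities={prof.community_number} "
      f"SW={prof.small_worldness:.2f}")
```

Output:

```
naming time 15.8 s, 52 fixations, 0 regressions
n=1388 m=32086 avg_degree=23.1 diameter=15 L=6.43
C=0.86 AC=0.56 Q=0.89 communities=18 SW=0.95
```

Read: a 15.8 s recording yields a 1388-node network whose average degree
(edges per node) is ≈ 1.5 × naming time in seconds — average degree is
essentially a clock. The network is strongly clustered (C = 0.86),
assortative (AC > 0: fixation cores connect to fixation cores), highly
modular (Q = 0.89 with 18 communities ≈ one or two per stimulus
neighborhood), and small-world (SW = 0.95 ≥ 0.4) because regressions
and row transitions shortcut the otherwise lattice-like scan.

A command-line interface mirrors the library:

```sh
gazenet simulate --subjects 5 --outdir runs/sim
gazenet metrics runs/sim/S001_N-num.csv
gazenet build runs/sim/S001_N-num.csv --out runs/S001.csv
gazenet topology runs/sim/S001_N-num.csv --seed 1
gazenet run-all --subjects 10 --seed 3 --outdir runs/full
```

`run-all` writes per-recording metrics and profiles, the cohort table,
the statistical report (Friedman/Kendall-W per parameter, pairwise
Wilcoxon, per-task rank regressions), and a provenance record; re-runs
with the same seed are bit-identical.

## Layout

- `gazenet.gaze_io` — gaze CSV reading/writing, preprocessing policy
- `gazenet.simulate` — synthetic RAN gaze generator (the study conditions)
- `gazenet.events` — I-DT fixations, saccades, regressions, six metrics
- `gazenet.network` — proximity-network construction, export/import
- `gazenet.topology` — nine descriptors, null models, communities
- `gazenet.stats` — Friedman/W, Wilcoxon post hocs, rank regression
- `gazenet.pipeline` / `gazenet.cli` — orchestration and CLI

Methodological details, parameter defaults and known limitations are
documented in `docs/methods.md`.
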