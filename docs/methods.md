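# Methods

This note documents the models, algorithms, parameter choices and
numerical conventions implemented in `gazenet`, and what the synthetic
data generator does and does not emulate.

## 1. From gaze samples to a proximity network

A preprocessed recording is an ordered sequence of valid gaze samples
(x_m, y_m) in screen pixels (origin top-left, y downward) at a nominal
90 Hz. Each sample is a node, in temporal order; nodes m, w are joined
when their Euclidean distance d_mw is at most a proximity threshold
θ_mw. Two threshold realizations are provided because the underlying
idea — "a threshold set by the distribution of neighbors" — admits both:

- **density mode (default).** One global θ per recording: the ρ-quantile
  of the n(n−1)/2 pairwise distances, so the network carries
  m = ρ·n(n−1)/2 edges exactly (up to distance ties). With the default
  ρ = 1/30, average degree m/n = (n−1)/60 is an almost deterministic
  linear function of the number of samples, hence of naming time
  (≈ 1.5 edges/node per second at 90 Hz). We chose this as the default
  because it reproduces the empirical signature of gaze networks built
  from real RAN data: average-degree-versus-naming-time regressions
  with slope ≈ 1.5 and R² ≈ 0.99, alongside assortativity ≈ 0.6–0.7 and
  diameter ≈ 15 at these recording lengths.
- **knn mode.** Per-pair adaptive thresholds: r_i is the distance from
  node i to its k-th nearest other node (k = round(ρ·n), default
  ρ = 1/30), and θ_mw = mean(r_m, r_w) (min/max selectable). Degree then
  adapts to local sampling density; the degree–time relation holds with
  slope ≈ 1.45 but ≈ 1.4 % residual geometric scatter.

The comparison is non-strict (d ≤ θ) by default. In knn mode with k = 1,
two mutual nearest neighbors satisfy d = r_m = r_w = θ exactly, and a
strict `<` would disconnect exactly the closest pairs — a degeneracy we
judge unintended; strict mode remains available for literal runs.
Coincident samples break distance-rank ties by node index, so r_i = 0
only when at least k exact duplicates exist.

Pairwise distances are evaluated in row chunks (≈ 5·10⁶ entries per
chunk) so memory stays flat in n; a 60 s recording (n ≈ 5800) builds in
about a second.

## 2. Eye events and classic metrics

Fixations are detected with the dispersion-threshold algorithm (I-DT):
a window of consecutive samples grows while the bounding box of its
members stays within 40 px on both axes, and is emitted as a fixation
once its time span reaches 100 ms. Both thresholds are inclusive
("at least 100 ms", box edge counts as inside). The 40 px / 100 ms
defaults are the standard criterion for this stimulus geometry; both
are parameters. A velocity-based detector was deliberately not used:
the criterion is a dispersion statement, and at 90 Hz velocity
estimates are noisy.

Saccades are consecutive-fixation transitions; amplitude is the
distance between the two centroids. A saccade is a **regression** when
it lands at least one stimulus-cell width (default 160 px) to the left
of its launch point within the same row (|Δy| < half a row height), or
at least half a row height (default 90 px) above it. This
operationalizes "backward movement toward previously visited items"
for a left-to-right, top-to-bottom scan; the row-wrap jump (down-left
at the end of a row) is deliberately not a regression under either
clause. Thresholds are configurable.

The six classic metrics are: total naming time (recording span, s),
average fixation duration (ms), fixation count, average saccade
amplitude (px), saccade count, and regression count. Averages of empty
event sets are reported as NaN, counts as 0. In this pipeline
saccade count = fixation count − 1 identically (no event gaps), which
matters for the regression analyses below. Event detection never
removes samples: networks are built from the full preprocessed series.

## 3. Topological descriptors

Nine parameters per network:

1. **Average degree** m/n — the printed edges-per-node convention, half
   the textbook mean degree 2m/n; the conventional form is available
   via `convention="full"`.
2. **Diameter** — max hop distance, largest connected component.
3. **Characteristic path length L** — mean hop distance over ordered
   pairs of the largest component.
4. **Clustering C** — node average of 2E_i/(k_i(k_i−1)); nodes with
   degree < 2 contribute 0. A per-edge (1/m) normalization is exposed
   behind `prefactor="m"` for literal replication, but the node average
   is the default: on gaze networks with m ≫ n a 1/m average would be
   ≪ 0.1, inconsistent with the C ≈ 0.72–0.75 such networks actually
   show.
5. **Global efficiency** — mean of 1/d over all ordered pairs with
   1/∞ := 0, so disconnection degrades rather than breaks the measure.
6. **Assortativity AC** — Newman's edge-end degree correlation,
   computed from the m edge-end pairs; identical to the Pearson
   correlation over the 2m orientation-expanded pairs. Undefined (NaN)
   on degree-regular graphs.
7. **Modularity Q** — Newman–Girvan quality of the best partition found
   by seeded Louvain (igraph's multilevel implementation, 10 restarts,
   best Q kept, Q recomputed from the returned labels). The
   single-community partition (Q = 0) is the floor, so Q ∈ [0, 1] holds.
8. **Community number** — label count of that partition. Note that any
   modularity-maximizing community count is algorithm- and
   resolution-dependent; values from different software are not
   expected to agree exactly.
9. **Small-worldness** — see below.

All-pairs distance statistics are computed by a compiled BFS kernel
that accumulates Σ1/d, Σd and max d per source without materializing
the n × n matrix.

### Null models and small-worldness

SW compares the observed C and L against a lattice and a random
benchmark with the same node and edge budget:

- **Random null:** degree-preserving double-edge-swap randomization
  (10·m swap trials per realization, igraph's rewire), 10 realizations;
  C_rand and L_rand are ensemble means.
- **Lattice null:** the deterministic regular ring lattice with the
  same n and m — complete bands at ring offsets 1..⌊m/n⌋ plus the
  leftover edges spread evenly at the next offset. We intentionally do
  *not* constrain the lattice to the observed degree sequence: gaze
  networks concentrate degree in fixation clusters, and any
  construction forced to reproduce that heterogeneous sequence on a
  ring must strand some stubs and pair them at long range; even a
  handful of such shortcuts collapses the lattice's characteristic
  path length below the observed one, which inverts the meaning of ΔL.
  The regular lattice is the benchmark that actually maximizes L at
  fixed edge budget, which is the quantity the null exists to bound.
  (A ring lattice is a fixed point of the construction.)

Then ΔC = (C_latt − C_obs)/(C_latt − C_rand) and
ΔL = (L_obs − L_rand)/(L_latt − L_rand), each clipped to [0, 1], and
SW = 1 − (ΔC² + ΔL²)/2 (the squared form, default) or
1 − √((ΔC² + ΔL²)/2) (the square-root form, selectable). SW ∈ [0, 1];
values above 0.4 are conventionally called small-world, but the
measure is continuous. Zero or negative null denominators yield NaN.
For null realizations with n > 1500, L is estimated from BFS out of
256 random sources; the sampling standard error (< 0.01 hops) is far
below the spread between realizations.

On synthetic RAN cohorts the clipped ΔC is typically 0 (the observed
clustering exceeds even the lattice's, because fixations are spatially
coherent cliques) and ΔL ≈ 0.3–0.4, giving SW ≈ 0.9–0.95. Real child
recordings carry calibration drift and head-movement noise that lower
C_obs and raise L_obs, which plausibly accounts for the lower
(0.6–0.7) small-worldness real cohorts show; the qualitative claim
(SW ≥ 0.4 throughout) is shared.

## 4. Statistics

- **Friedman / Kendall's W.** Within-subject mid-ranks across the k
  task conditions, tie-corrected statistic χ² on k−1 df;
  W = χ²/(N(k−1)) ∈ [0, 1], read as small/medium/large at 0.1/0.3/0.5.
  For very small designs the χ² tail is anticonservative, so when
  (k!)^N ≤ 2·10⁵ the p-value is computed exactly by enumerating all
  within-block rank permutations ("auto" mode); cohort-scale runs use
  the χ² tail.
- **Wilcoxon signed-rank post hocs.** One test per unordered task pair
  (6 for four tasks). Zero differences dropped, mid-ranks on ties;
  exact distribution when n ≤ 25 without ties, otherwise normal
  approximation with continuity correction and tie-corrected variance.
  The reported statistic is W⁺ (positive-rank sum), alongside the
  normal deviate z — published post hoc values on this design have been
  printed on both scales, so both are emitted. Bonferroni multiplies
  raw p by the number of pairs, capped at 1.
- **Rank-based regression.** Slopes minimize Jaeckel's rank dispersion
  D(β) = Σ a(R(e_i)) e_i with Wilcoxon scores
  a(i) = √12 (i/(n+1) − ½); the intercept is the median residual.
  Optimization starts at the OLS solution and runs BFGS with the exact
  subgradient −Xᵀa(R(e)), polished by a derivative-free Powell pass
  (the objective is convex piecewise-linear). Standard errors use the
  Koul–Sievers–McKean window estimate of the score scale τ (uniform
  kernel at bandwidth 0.5·σ̂·n^(−1/5), σ̂ the normalized MAD, with the
  √(n/(n−p−1)) degrees-of-freedom correction); t = β/(τ√((XᵀX)⁻¹_jj))
  on n−p−1 df. The headline R² is the robust coefficient of
  determination (D₀−D₁)/(D₀−D₁+(n−p−1)τ/2), the dispersion analogue of
  SSR/(SSR+SSE) and the quantity rank-regression software reports; the
  plain dispersion ratio 1−D₁/D₀ is returned alongside. Exactly aliased
  predictors (in this pipeline, saccade count = fixation count − 1) are
  detected by pivoted QR and either raise (default) or are dropped and
  recorded (`on_collinear="drop"`, used by the cohort report).
- Two-sided tests throughout; α = 0.05. Normality (Shapiro–Wilk per
  parameter × task) and variance homogeneity (Levene across tasks) are
  recorded in the report as a screening trail but do not gate the
  nonparametric workflow.

## 5. The synthetic RAN generator

The generator emulates the behavior the task instructions induce, not
oculomotor physics. One recording is a sequence of fixation episodes:
the 50 stimulus cells of a 5 × 10 grid (default 160 × 180 px spacing,
centered on a 1920 × 1080 screen) visited in row-major order, each with
a log-normal dwell (default median 320 ms, σ = 0.35 on the log scale —
right-skewed dwell distributions are the empirical norm), optionally a
second offset fixation on the same stimulus (refixation probability
0.12, offset 30 px), and with probability 0.08 a brief regression to
one of the previous eight cells before the scan resumes. Consecutive
episodes are joined by 2–3 linearly interpolated in-flight samples
(a 20–30 ms saccade at 90 Hz), fixation samples carry 5 px Gaussian
jitter around an 8 px-jittered episode center, and each sample is
invalid (tracking loss) with probability 0.02. Task types scale the
dwell median (numbers 0.85, characters 1.0, objects 1.6, colors 1.55)
and refixation probability (×1.5 for the non-alphanumeric pair),
encoding the extra conceptual-processing cost of object/color naming;
the magnitudes are free choices exposed in the config, set once to
yield naming times of roughly 13–30 s per task for a typical subject.
Cohorts draw per-subject log-normal multipliers (σ = 0.18) for dwell
and revisit tendencies once per subject, shared across that subject's
tasks, from per-subject RNG streams seeded as (cohort seed, subject
index) so cohorts are reproducible and extendable without perturbing
existing subjects.

What the generator does **not** emulate — and therefore what passing
tests do and do not show: no main-sequence saccade kinematics, no
calibration drift or slow head-movement artifacts, no blink waveforms,
no naming-audio coupling, no pseudo-random stimulus-identity effects
within the grid. Real recordings are noisier; on real data one should
expect lower clustering, higher path length, and lower (but still
supra-threshold) small-worldness than the synthetic figures, as
discussed above. No distributional facts about the original raw gaze
recordings were available to fit the generator against; its parameters
are exposed, not asserted.

## 6. Numerical conventions and degenerate inputs

- Preprocessing drops invalid samples (no interpolation — the network
  must not contain invented gazes); off-screen samples are kept by
  default, with drop/clip policies available.
- Recordings shorter than the fixation duration threshold yield zero
  fixations (not an error); averages over empty event sets are NaN.
- Networks need ≥ 2 valid samples; single-node radii are an error.
- Diameter and L are reported on the largest connected component;
  efficiency integrates disconnection via 1/∞ = 0.
- Louvain restarts and edge-swap randomization are driven by explicit
  seeds end to end; the pipeline derives per-recording child seeds from
  the master seed by stable hashing (CRC32, < 2³¹), so adding a subject
  never changes another's results.
- Problem sizes used by the bundled reproduction script: 20 subjects ×
  4 tasks (~80 networks of 1200–3500 nodes) for the architecture
  minima, 10 null realizations per family per network; 30 subjects for
  the degree–time regression. These sizes give stable minima and a
  well-conditioned regression while keeping a full run in the
  ten-minute range on one CPU.

## 7. Known limitations

- The proximity-threshold rule the original method cites is not fully
  specified in the literature available to us; both implemented
  realizations are declared stand-ins validated against the qualitative
  architecture and the degree–time signature, not against the authors'
  code.
- Community number depends on the chosen maximizer and resolution;
  cross-software comparisons of that one parameter are fragile.
- The lattice null matches n and m but not the degree sequence (see
  §3); small-worldness values are therefore comparable within this
  package, not across packages using other lattice constructions.
- Statistics assume complete blocks (every subject × every task);
  incomplete cohorts fail the Friedman stage explicitly rather than
  silently dropping subjects.
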