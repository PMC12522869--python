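# Methods

## The placement model

A vial's laying surface is discretised into `N` egg-sized sites (default
`N = 5770`, the vial-surface-to-egg area ratio for the standard vials the
assays use). A vial receives `E` eggs, laid sequentially. The first egg
lands on a uniformly random site. Every subsequent egg:

* with probability `K` (the *clustering preference*, `0 ≤ K ≤ 1`) is placed
  with an already-laid egg: a site is chosen uniformly among the currently
  occupied **sites** (not eggs) and the egg is added to it;
* otherwise lands on a uniformly random site among all `N`. A random
  placement may coincidentally hit an occupied site, in which case the egg
  joins that cluster — this is what produces the small amount of clustering
  seen even at `K = 0`.

Eggs sharing a site form a contact cluster; a site holding one egg is a
singly laid egg. There is no lattice adjacency or continuous contact
geometry: "clustered" means co-occupancy of one site. This is the literal
reading of the placement rule, and the `K = 1` limit (every egg on one site,
one all-egg cluster) is consistent with it. Spatially explicit edge
preference is deliberately not modelled.

Two limits anchor the implementation:

* `K = 1`: exactly one occupied site holding all `E` eggs, every seed.
* `K = 0`: independent uniform placement. Each site then holds
  `Binomial(E, 1/N)` eggs, so the expected number of multi-occupied sites is
  exactly

  `N · [1 − (1 − 1/N)^E − (E/N)(1 − 1/N)^(E−1)]`,

  implemented as `expected_null_multisites` and used as the analytic oracle
  for the Monte-Carlo simulator (≈ 0.85 sites at `E = 100`, ≈ 4.56 at
  `E = 233`, the largest egg count the assays produced). The tests also
  validate the full simulator against an exhaustive enumeration of every
  placement/decision sequence for tiny vials (`N ≤ 6`, `E ≤ 4`).

How much clustering random laying produces depends on the scale it is quoted
on; `null_clustering_statistics` exposes three readings (expected
multi-occupied sites per vial, clusters per egg, expected proportion of eggs
clustered), which differ by factors of a few — at `E = 233` they are 4.56,
0.020 and 0.039 respectively. No single percentage is privileged.

Randomness: all simulation flows through `numpy.random.Generator`
(PCG64 via `default_rng`). Ensembles derive per-replicate substreams from a
single root seed with `SeedSequence.spawn`, so one integer seed reproduces an
entire analysis bit-for-bit within a release.

## Estimating K per vial

`K` is estimated by a grid scan over `K ∈ {0.0, 0.1, …, 1.0}`. For each grid
value, `n_reps = 10` replicate vials are simulated with `E` matched to the
vial's observed egg count, and the simulated cluster-size sample is compared
with the observed one using a two-sample Kolmogorov–Smirnov test. The
best-fit `K` is the grid value with the highest (least significant)
p-value — the simulated distribution least distinguishable from the data.

Numerical choices:

* **Sample definition.** The compared samples are per-site egg counts
  *including* singletons (size-1 entries). Singletons carry most of the
  signal separating low `K` values, and excluding them would leave
  low-clustering vials with empty samples.
* **Pooling.** The replicate simulations are pooled into one sample before
  the KS test (default); a per-replicate mode that averages the replicate
  p-values is available (`mode="mean-p"`). Both are exposed because
  "averaging replicate simulations" is ambiguous between the two; pooling
  uses the replicate information more efficiently.
* **Ties.** Cluster sizes are small integers, so ties are pervasive. The
  default p-value is the asymptotic two-sample KS value, which is
  conservative under ties. An exact permutation p-value (enumeration of all
  group reassignments of the pooled sample, valid under ties) is available
  for small samples and anchors the unit tests.
* **Tie-break.** When several grid values attain the maximal p-value, the
  smallest `K` wins (parsimony toward the null). This matters mostly for
  tiny vials whose distributions are uninformative.
* **Zero-egg vials** cannot be scanned and are skipped with a logged
  warning; in the real assays such vials were likewise excluded.

Parameter recovery (synthetic check, `recovery_experiment`): cohorts of 30
vials generated at `K = 0.4` with 50–150 eggs recover the truth within ±0.1
for ≈ 98% of vials and a per-cohort median of 0.4 in 10/10 seeds at the
problem sizes used here.

## Testing nonrandomness

Per treatment, each vial's proportion of eggs in clusters is paired with the
same statistic from a matched `K = 0` simulation (same egg count), and the
paired differences are tested with a two-sided Wilcoxon signed-rank test
(normal approximation). The reported `z` carries the sign of the mean
difference; the effect size is `r = |z| / √n` with `n` the number of vials.

The paired null is a **single** matched replicate per vial by default.
Under the `K = 0` hypothesis the observed and null statistics are then
exchangeable, so the signed-rank symmetry assumption holds and the test is
exactly calibrated (measured 5.25% rejection at nominal 5% over 400
simulated cohorts). Averaging several null replicates per vial — the other
natural choice — shrinks the null's sampling variance, skews the paired
differences, and inflates the type-I rate to ≈ 8.5% in the same simulation;
it remains available (`n_null_reps`) for effect-size description but is not
the testing default. Power is effectively 1 against `K = 0.4` cohorts of 30
vials. Zero differences are discarded (`wilcox` rule); a test where *all*
differences are zero raises a degenerate-test error rather than returning a
p-value. The choice of paired statistic (proportion clustered, number of
clusters, largest cluster) is configurable; proportion clustered is the
default. No multiple-testing correction is applied across treatments.

## Empirical metrics

* `proportion_clustered`: eggs in sites of ≥ 2 eggs over all eggs laid.
  Undefined (raised) for zero-egg vials — such vials count toward laying
  likelihood but are excluded from clustering proportions.
* `vial_summary`: per-timepoint eggs per female (`n_eggs / group_size`),
  cluster count, largest cluster, and latency to first egg,
  interval-censored at the observation grid (reported as the first
  observation time with eggs).
* `join_metrics`: a newly laid egg joins the existing treatment eggs when it
  shares an (eye-scored) `cluster_id` with one — this overrides
  coordinates — or when its nearest edge-to-edge Euclidean distance is
  ≤ a configurable tolerance (default 0: contact is recorded as distance
  zero). The trial distance is the mean of per-new-egg minimum distances to
  any existing egg (the nearest-edge-pairs reading); a mean over all
  new × existing pairs is available behind a flag. Coordinates are planar
  and unit-agnostic (the caller declares pixels or mm); no auto-scaling.
* `maternity_mix`: among focal eggs located in clusters (≥ 2 eggs sharing a
  `cluster_id`), the fraction whose cluster contains at least one non-focal
  egg. Undefined when no focal egg is clustered, or when the input contains
  no non-focal eggs at all (e.g. single-female data). An unlabelled
  clustered egg is a schema error, not a silent exclusion.
* `rebalance_subsample`: deterministic (seeded) random subset holding all 30
  solitary vials, 15 pair vials, 8 four-female vials and 4 eight-female
  vials — 30/30/32/32 flies — to equalise per-treatment sampling effort by
  flies rather than vials.
* `viability_metrics` emits a tidy per-vial table (viability = adults/eggs
  paired with final clustering proportion) for downstream
  correlation/regression; model fitting itself (GLM/LM/LME, Pearson) is out
  of scope and left to standard statistics packages.

All metrics are invariant to the row order of their input tables.

## The synthetic-data generator

The generator produces datasets with the statistical structure the analysis
assumes, so the full pipeline is exercisable and parameter recovery
checkable without the archived experimental data. Defaults are the study
conditions:

| group size | true K | eggs/female (mean ± SD) | laying likelihood |
|---:|---:|---:|---:|
| 1 | 0.0 | 7 ± 10 | 0.667 |
| 2 | 0.3 | 9 ± 9  | 0.833 |
| 4 | 0.4 | 18 ± 8 | 0.967 |
| 8 | 0.5 | 19 ± 5 | 1.000 |

30 vials per treatment; observation timepoints 2, 4, 7, 10, 22, 24 h
post-mating; egg-to-adult viability 0.77, independent of clustering by
default (a dependence knob exists for power studies); existing-cluster
treatments of 1/4/7/10 eggs placed in contact at the dish edge with
20/17/20/21 trials; mixed-maternity probability 0.795 over 28 vials.

Design choices:

* **Counts.** Vial egg totals are negative-binomial, moment-matched to the
  stated per-female mean ± SD (solitary females have SD > mean, so Poisson
  is untenable); the match is to the first two moments only — the full count
  distribution of the real assay is unknown.
* **Timepoints.** One placement sequence is simulated per vial and truncated
  at each observation time, guaranteeing monotone within-vial egg counts.
  Cumulative laying follows a light/dark intensity profile (relative
  intensity 0.15 during the 12-h dark window), producing the night-time
  plateau; the exact shape is cosmetic and configurable.
* **Join trials.** Each trial draws 1–19 new eggs; an egg joins the existing
  cluster (distance 0, shared cluster id) with a treatment-dependent
  probability, else lands at a gamma-distributed positive distance. The
  assays report no joining *probabilities*, only that joining is commoner and
  distances shorter at clustered treatments; the defaults (0.15/0.40/0.33/
  0.40, mean non-join distances 11/7/7.5/6.5 mm) reproduce that ordering,
  including the intermediate value at 7 eggs, and are this package's own
  choice.
* **Maternity.** Every focal-containing cluster holds exactly two focal
  eggs and is independently mixed (gains 1–3 non-focal eggs) with the
  configured probability, which makes the per-vial proportion of focal
  clustered eggs in mixed clusters an exactly unbiased estimate of that
  probability. (An earlier per-egg construction required pairing leftover
  "pure" eggs and biased the estimate upward; the cluster-level construction
  avoids this.) Non-focal background clusters and singletons are added for
  realism.

What the generator does **not** emulate: spatial edge preference, diel
rhythm beyond the plateau, between-vial heterogeneity in K, female identity
within grouped vials, and any clustering–viability dependence (off by
default). Tests passing on synthetic data therefore demonstrate that the
pipeline measures what the generator encodes — not that the biological data
satisfy the generator's assumptions.

## Problem sizes

The validation experiments use 10,000 Monte-Carlo replicates for the
null-occupancy comparison, 10 seeds × 30 vials for K recovery, and 100
cohorts of 30 vials for each calibration arm — sizes at which every check's
Monte-Carlo error is small relative to its tolerance while the whole suite
runs in well under a minute of simulation time.

## Known limitations

* The asymptotic KS p-value under heavy ties is conservative; p-value
  *curves* are therefore flat near their peak for small vials, and best-K
  estimates from vials with few eggs are coarse (the tie-break biases them
  toward 0).
* `K` is estimated on the 0.1 grid only; no continuous optimisation or
  posterior is attempted.
* The closed-form null oracle covers `K = 0` only; intermediate `K` values
  are validated by enumeration at tiny sizes and by Monte-Carlo
  monotonicity checks.
* Coordinates carry no units internally; mixing pixel- and mm-scaled files
  in one analysis is the caller's responsibility.
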