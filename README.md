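# eggcluster

Stochastic null models, clustering-preference inference and oviposition
metrics for *Drosophila melanogaster* egg-clustering experiments.

Gravid female fruit flies lay eggs one at a time and can place each egg in
contact with already-laid eggs (a *cluster*: two or more eggs whose main
bodies touch) or on free substrate. Whether females do this non-randomly,
and how the tendency responds to social context — how many other females are
present, and whether eggs or clusters already exist on the substrate — is a
question about plasticity in reproductive decisions. This package provides
the full analysis pipeline for that question: a stochastic placement model,
an inference procedure for the clustering preference, a nonrandomness test,
the empirical response-variable metrics, and a synthetic-data generator so
the whole pipeline is testable end to end without the archived experimental
data. It is aimed at behavioural ecologists analysing within-patch
oviposition patterns.

## The model and the inference

The vial's laying surface is discretised into *N* = 5770 egg-sized sites.
*E* eggs are laid sequentially: the first lands uniformly at random, and each
later egg

* joins an occupied site (chosen uniformly among occupied sites) with
  probability *K* — the **clustering preference** — or
* lands uniformly among all *N* sites with probability 1 − *K* (possibly
  colliding with an occupied site by chance).

*K* = 0 is the random-laying null: the expected number of multi-occupied
sites then has the closed form *N*[1 − (1 − 1/N)^E − (E/N)(1 − 1/N)^(E−1)]
(≈ 4.56 for the maximal observed *E* = 233), so random laying produces almost
exclusively singly laid eggs when *E* ≪ *N*. *K* = 1 stacks all eggs into one
cluster.

Per vial, *K* is estimated by simulating the model on a grid
*K* ∈ {0, 0.1, …, 1} with *E* matched to the vial's egg count and taking the
*K* whose simulated cluster-size distribution is least distinguishable from
the observed one (highest two-sample Kolmogorov–Smirnov p-value).
Nonrandomness is tested by pairing each vial's proportion of clustered eggs
with a matched *K* = 0 simulation and applying a two-sided Wilcoxon
signed-rank test, with effect size *r* = |z|/√n.

## Worked example

Generate a synthetic social-density experiment at its default study
conditions (true *K* = 0.0/0.3/0.4/0.5 for groups of 1/2/4/8 females) and
recover the clustering preferences:

```python
import eggcluster as ec

config = ec.SyntheticConfig()
obs, viability, truth = ec.generate_social_density_experiment(config, seed=20250102)
final = [o for o in obs if o.timepoint_h == 24 and o.n_eggs > 0]
pairs = [(o.vial_id, ec.ClusterSizeDistribution(o.cluster_sizes, o.n_eggs))
         for o in final]
curves = ec.scan_vials(pairs, seed=20250103)
```

Summarising `curves` by treatment (this is `analysis/02_fit_clustering_preference.py`)
prints:

```
 group_size  true_k  median_best_k  mean_best_k  n_vials
          1     0.0            0.0        0.000       19
          2     0.3            0.3        0.292       25
          4     0.4            0.4        0.436       28
          8     0.5            0.5        0.513       30
```

The grid scan recovers each treatment's generating preference: solitary
vials sit at the random-laying null, grouped vials in the 0.3–0.5 band, with
the recovered *K* increasing with group size. The matching nonrandomness
test (`analysis/03_test_nonrandomness.py`) rejects the null for every
grouped treatment with large effect sizes, and not for solitary vials:

```
 group_size  true_k      z       p_value  effect_r  n_vials
          1     0.0 -1.000  3.173105e-01     0.204       24
          2     0.3  4.200  2.667045e-05     0.824       26
          4     0.4  4.782  1.734398e-06     0.873       30
          8     0.5  4.782  1.734398e-06     0.873       30
```

The numbered scripts under `analysis/` run the remaining stages (descriptive
metrics across densities and time, joining behaviour toward existing
clusters, mixed-maternity scoring); each writes its tables under `results/`
and prints what it found. The same stages are available from the shell:

```bash
eggcluster synth social --seed 5 --outdir data/synth
eggcluster fit-k --observed data/synth/vials.csv --seed 2 --out curves.csv
eggcluster test-nonrandom --observed data/synth/vials.csv --seed 3
eggcluster run --seed 1 --outdir results   # full pipeline
```

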