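# ivmix

Mixture-model clustering of Mendelian-randomization ratio estimates, with a
null cluster, a heavy-tailed junk cluster, and BIC selection of the number of
clusters.

## The problem

In Mendelian randomization (MR), genetic variants serve as instrumental
variables for estimating the causal effect of an exposure (say, blood
pressure) on an outcome (say, coronary artery disease risk).  Each variant
*j* yields a Wald **ratio estimate**

```
theta_j = beta_Yj / beta_Xj,      se(theta_j) = se(beta_Yj) / |beta_Xj|   (first order)
```

from its associations with the outcome (`beta_Yj`) and the exposure
(`beta_Xj`).  If all variants act through one mechanism, the `theta_j`
scatter around a single value.  Often they do not: subsets of variants
converge on *distinct* values — clustered heterogeneity — because the
exposure is composite, can be intervened on in different ways, or because
variants act through pleiotropic pathways.  Identifying those clusters, and
the traits their members share, is a route to dissecting causal mechanisms.

## The model

For `J` variants with ratio estimates `theta_hat_j` and known standard
errors `sigma_hat_j`, the observations follow a `K + 2`-component mixture:

```
theta_hat_j ~ pi_0 N(0, sigma_hat_j^2)                       null cluster
            + sum_k pi_k N(theta_k, sigma_hat_j^2)           K substantive clusters
            + pi_{K+1} t_4((x - mu)/psi) / psi               junk cluster
```

Every observation keeps its own variance — precise estimates dominate — and
the M-step update for each `theta_k` is a responsibility-weighted
inverse-variance-weighted (IVW) average.  The null cluster (mean pinned at
0) absorbs variants with no causal signal; the junk cluster, a fixed
Student-t with `mu = mean(theta_hat)` and scale
`psi = range(theta_hat) + 2 max(sigma_hat)`, absorbs variants that fit
nowhere, so a substantive cluster is only reported when several variants
genuinely agree.  Estimation is by expectation-maximization from 25 random
initializations (k-means centres, random null/junk mass in (0.05, 0.4));
`K` is chosen by minimizing `BIC(K) = (2K + 1) log J - 2 log L`.

Two reporting conventions: version A assigns every variant to its
maximum-responsibility component; version B (recommended, the default)
additionally requires that probability to reach 0.8 and dissolves
substantive clusters with fewer than 4 confident members.

## Worked example

```python
import numpy as np
from ivmix import (RatioMixture, scenario_preset, simulate_summary_data,
                   build_ratio_dataset)

rng = np.random.default_rng(11)
sim = simulate_summary_data(scenario_preset(4, 5000), rng)   # 3 true clusters
data = build_ratio_dataset(sim.summaries, se_order="first")
X = np.c_[data.theta_hat, data.sigma_hat]

model = RatioMixture(k_max=5, random_state=0).fit(X)
print("selected K:", model.best_k_)
print("BIC by K:", {k: round(v, 1) for k, v in model.bic_.items()})
print("cluster means:", np.round(model.cluster_means_, 3))
```

prints

```
selected K: 3
BIC by K: {0: 447.0, 1: 418.5, 2: 183.2, 3: 146.9, 4: 152.1, 5: 150.7}
cluster means: [-0.4    0.447  0.819]
```

The data were generated with true clusters at -0.4, 0.4 and 0.8 (of 20, 10
and 40 variants) plus 10 null and 10 junk variants: BIC falls steeply until
`K = 3` and rises after, and the fitted means land on the truth.  Version-B
assignment reported clusters of 18, 8 and 33 confident members, 12 null, 6
junk and 13 unassigned.  `model.labels_` holds the integer assignment (0 =
null, `1..K` = clusters by ascending mean, `K+1` = junk, -1 = unassigned);
`model.cluster_summaries_` adds per-cluster means and IVW standard errors.

The same pipeline is available from the shell:

```
ivmix fit --input summary_stats.tsv --out results/ --seed 7
ivmix simulate --scenario 4 --N 5000 --reps 10 --seed 7 --out sim/
ivmix enrich --table assoc.tsv --cluster-members members.txt \
             --all-variants all.txt --out enrichment/
```

`fit` expects a TSV with columns
`variant_id, beta_exp, se_exp, beta_out, se_out` (pre-harmonized to a
consistent effect allele) and writes per-variant and per-cluster tables for
both reporting conventions; `enrich` scans a long-format
`variant_id, trait, p_value` table for traits over-represented in a cluster
(exact hypergeometric test; raw p-values — no multiplicity correction is
attempted).

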