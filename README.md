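# richclubnet

Weighted rich-club analysis of structural brain connectomes: global graph
metrics, normalized rich-club coefficients against degree- and
weight-preserving rewired null ensembles, rich/feeder/local edge-class
strengths, and covariate-adjusted group/sex inference with
permutation-adjusted p-values.

## Who this is for

Network-neuroscience analyses of diffusion-MRI cohorts — for example,
asking whether the hub core ("rich club") of the structural connectome is
differentially disrupted by diagnostic group and sex in an Alzheimer's
disease spectrum cohort. The package takes per-subject weighted 90×90
AAL-parcellation connectivity matrices plus a cohort metadata CSV and
produces curves, per-class strengths, z-scores and statistics tables. A
synthetic-cohort generator with planted multiplicative effects makes every
stage testable end to end without imaging data.

## The model in brief

For a weighted undirected network with binary degrees k, the weighted
rich-club coefficient at degree threshold κ is

    Φw(κ) = W(>κ) / Σ of the E(>κ) largest weights in the network,

where W(>κ) and E(>κ) are the total weight and edge count of the subgraph
of nodes with k > κ. Because hubs interconnect by chance, Φw is normalized
by the mean Φw of m random networks that preserve the degree sequence and
the edge-weight multiset exactly (Maslov–Sneppen double edge swaps plus
weight-multiset reassignment):

    Φnorm(κ) = Φw(κ) / ⟨Φw,rand(κ)⟩ ,

with Φnorm > 1 over a κ range indicating rich-club organization; an AUC
permutation test against the null ensemble makes this inferential. Edges
are classified by their endpoints' membership in a fixed 12-node club
(bilateral superior frontal, superior parietal, precuneus, hippocampus,
putamen, thalamus) as rich-club, feeder or local; per-class strengths are
analyzed with a Type-III GLM (sum-to-zero coding) adjusting for age and
education, with partial η², permutation-adjusted p-values (label
permutation for main effects, Freedman–Lane for interactions) and
max-statistic family-wise control. See `docs/methods.md` for every
convention and its rationale.

## Worked example

```python
import richclubnet as rc

# cohort of 60 synthetic subjects with a planted pattern: women-only 0.8x
# deficit on rich and feeder strength in the dementia cell, 0.85x local
# deficit in both sexes of that cell
cfg = rc.SyntheticConfig(n_per_cell=10, master_seed=7,
                         effects=rc.fig_pattern_effects())
cohort = rc.simulate_cohort(cfg)

run = rc.RunConfig(m=50, n_perm=500, master_seed=11)
bundle = rc.run_full_analysis(run, cohort=cohort)

print(bundle["richclub_tests"]["cohort_mean"])
s = bundle["stats"]
print(s[(s.term == "sex") & (s.subset == "ADdementia")]
      [["outcome", "F", "eta_p2", "p_perm"]])
print(s[s.term == "group:sex"][["outcome", "F", "eta_p2", "p_perm"]])
```

prints (abridged):

```
{'observed_auc': 41.3874, 'p_value': 0.004, ..., 'decision': True}
   outcome         F  eta_p2  p_perm
      rich  304.9288  0.9501  0.0020
    feeder 1921.3522  0.9917  0.0020
     local    3.1006  0.1623  0.5768
outcome        F  eta_p2  p_perm
   rich 100.1881  0.7940   0.002
 feeder 576.5955  0.9569   0.002
  local   0.7133  0.0267   0.493
```

Reading it: the cohort-mean network's rich-club AUC is far outside its
rewired-null distribution (`decision: True` — rich-club organization is
present); within the dementia group women differ from men on rich and
feeder strength (family-adjusted permutation p = 0.002, the floor at 500
permutations) but not on local strength; and the group×sex interaction is
detected on rich and feeder, exactly the planted truth. Per-subject global
metrics land on the scale familiar from normalized streamline networks
(strength ≈ 5.0, global efficiency ≈ 0.20).

The same analyses are available from the shell:

```bash
richclub simulate --out cohort/ --seed 3 --planted
richclub curve --matrix cohort/sub-CU-F-000.csv --m 200 --n-perm 500 \
    --seed 1 --out sub0
richclub run --config run.yaml          # full pipeline, writes CSVs + manifest
richclub stats --strengths results/strengths.csv --cohort cohort/cohort.csv \
    --n-perm 1000 --seed 0 --out stats.csv
```

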