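# dytidriver

Tissue-aware network prioritization of cancer driver genes.

Somatic mutation calls from a tumor cohort contain far more passenger than
driver genes, and recurrence alone misses drivers mutated at low frequency.
`dytidriver` ranks mutated genes by combining three signals on a gene
functional interaction network: drivers dysregulate the expression of their
network neighbors, they cluster into functional modules whose members are
co-expressed in the tumor's tissue of origin, and they recur across
patients. The package is aimed at computational cancer-genomics groups who
have a patient × gene mutation matrix (MAF or binary TSV), tumor expression,
one or more tissue expression matrices, and an interaction network, and want
a ranked candidate-driver list plus top-K benchmark evaluation. A synthetic
cohort generator with planted drivers makes the whole pipeline testable
without any external downloads.

## Method

1. **Dysregulation filter.** Per-gene expression z-scores are computed
   across the cohort (sample sd, ddof = 1); gene *g* is *outlying* in
   patient *p* if |z(p, g)| > 2.0 (strict). A mutated gene is retained iff
   in at least one patient carrying the mutation, at least one of its
   network neighbors is outlying in that same patient. Retained genes
   induce the binary mutated-gene adjacency matrix.
2. **Tissue co-expression weighting.** Per tissue, gene–gene Pearson
   correlations are thresholded (|r| > 0.3 strict, stored as |r|) and the
   per-tissue matrices averaged; the result is masked onto the adjacency,
   giving the weighted mutated graph *W*.
3. **Scoring.** For every edge of *W* the edge clustering coefficient is

   ```
   ECC(i,j) = Σ_{k ∈ N_i ∩ N_j} (W_ik + W_jk) / min(d_i, d_j)
   ```

   with N_i the nonzero-weight neighbors of *i* and d_i = |N_i|. The module
   score M_i = Σ_{j ∈ N_i} ECC(i, j) measures how deeply *i* sits in a
   co-expressed mutated module; the variation frequency V_i is the fraction
   of patients in which *i* is mutated; genes are ranked by F_i = V_i · M_i
   descending (ties: V descending, then symbol).
4. **Evaluation.** Against a benchmark driver list, top-K precision, recall
   and F-score curves for K = 1..200.

## Worked example

```python
from dytidriver import DyTidriver, SyntheticConfig, simulate_cohort

cohort = simulate_cohort(SyntheticConfig(seed=1))   # 500 genes, 100 patients,
results = DyTidriver(cohort.mutations,              # 10 planted drivers
                     cohort.tumor_expr,
                     cohort.network,
                     cohort.tissue_expr).fit()
print(results.summary(n_top=5))
```

```
DyTidriver ranking summary
============================================================
patients: 100   mutated genes: 423
retained after dysregulation filter: 202 (dropped 221)
mutated-gene subnetwork edges: 330 (co-expression weighted: 87)
cutoffs: |z| > 2.0, |r| > 0.3 over 1 tissue(s)
------------------------------------------------------------
rank gene                V          M          F
   1 G0001          0.3400     7.3210     2.4891
   2 G0000          0.3300     5.9002     1.9471
   3 G0021          0.2500     6.6305     1.6576
   4 G0020          0.2900     5.4411     1.5779
   5 G0011          0.2700     5.6336     1.5211
```

Of the 423 mutated genes, 202 survive the dysregulation filter; the top
ranks are dominated by the planted drivers (G0000/G0001, G0010/G0011, …
are the two drivers of each module), which combine a ~0.3 mutation
frequency with large module scores from their co-expressed neighborhoods.
All 10 planted drivers land in the top 20:

```python
curve = results.evaluate(cohort.truth, k_max=20)
print(curve[curve["K"].isin([5, 10, 20])].to_string(index=False))
```

```
 K  TP  FP  FN  precision  recall   fscore
 5   5   0   5        1.0     0.5 0.666667
10  10   0   0        1.0     1.0 1.000000
20  10  10   0        0.5     1.0 0.666667
```

The same pipeline is available from the shell:

```bash
dytidriver simulate --seed 1 --outdir cohort/
dytidriver rank --mutations cohort/mutations.tsv \
    --expression cohort/tumor_expression.tsv \
    --network cohort/network.tsv --tissue cohort/tissue_expression.tsv \
    --benchmark cohort/planted_drivers.txt --out ranked.tsv
dytidriver evaluate --ranking ranked.tsv \
    --benchmark cohort/planted_drivers.txt --kmax 200 --out curves.tsv
```

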