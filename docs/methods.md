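# Methods

## Model

`dytidriver` scores somatically mutated genes on an undirected gene
functional interaction network using three assumptions: (i) driver
mutations perturb the expression of the mutated gene's network neighbors;
(ii) drivers act together in functional modules whose members are
co-expressed in the tumor's tissue of origin; (iii) drivers recur across
patients more often than passengers. The pipeline is deterministic — there
is no stochastic fitting step — so a "fit" is a single pass:

1. *Outlier calling.* z(p, g) = (x(p, g) − mean_g) / sd_g with per-gene
   mean and sample standard deviation (ddof = 1) over all tumor samples of
   the cohort. Gene g is outlying in patient p iff |z(p, g)| strictly
   exceeds the cutoff.
2. *Dysregulation filter.* Mutated gene g is retained iff some patient
   both carries the mutation and has at least one network neighbor of g
   outlying. The retained genes induce the binary mutated-gene adjacency.
3. *Tissue weighting.* Per tissue, all gene–gene Pearson correlations are
   computed, |r| strictly greater than the cutoff kept as |r| (else 0),
   the per-tissue matrices averaged elementwise, and the average masked
   onto the adjacency to give the weighted mutated graph W.
4. *Scoring.* ECC(i,j) = Σ_{k∈N_i∩N_j}(W_ik + W_jk) / min(d_i, d_j) on
   edges of W; M_i sums a gene's incident ECC values; V_i is its mutation
   frequency over the cohort; genes are ranked by F_i = V_i·M_i.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `zscore_cutoff` | 2.0 | outlying-gene threshold, in sd units of the cohort reference; strict inequality |
| `pcc_cutoff` | 0.3 | minimum single-tissue \|r\| for an edge to carry weight; strict inequality |
| `per_patient` | True | mutation and neighbor dysregulation must co-occur in the same patient; `False` pools outliers across patients (sensitivity mode) |
| `classic_ecc` | False | use min(d_i−1, d_j−1), guarded by max(·, 1), instead of min(d_i, d_j) |
| `log2_transform` | False | apply log2(x+1) to tumor expression before z-scoring |
| `tumor_samples` | None | explicit tumor annotation; by default every sample is treated as a tumor — tumor/normal status is never inferred silently |

Both cutoffs are unitless; 2 sd is the conventional expression-outlier
call and 0.3 a conventional floor for "co-expressed" on microarray data.

## Design choices at genuinely open points

- **z-score reference population.** Per-gene statistics over all tumor
  samples of the cohort. An alternative (normals-only reference) would
  need matched normals, which many cohorts lack; the cohort-wide tumor
  reference is the convention of dysregulation-based driver methods.
- **Per-patient filtering** is the default because the filter's rationale
  is causal: the mutation in *this* patient should explain the neighbor's
  dysregulation in *this* patient. The pooled mode exists only for
  sensitivity analysis.
- **Stored weights are |r|, not signed r.** Strong negative co-expression
  is still evidence of functional coupling, and nonnegative weights keep
  ECC, module scores and final scores nonnegative and monotone in the
  weights. `threshold_correlations(..., signed=True)` exposes signed
  matrices for inspection, but edge weighting always uses magnitudes.
- **Degrees count nonzero-weight neighbors of W**, not neighbors in the
  binary adjacency: an edge whose co-expression fell below the cutoff is
  treated as absent everywhere (neighborhood, degree, ECC support).
- **ECC denominator.** The printed definition min(d_i, d_j) is used as-is
  even though the classical edge-clustering denominator is
  min(d_i−1, d_j−1); the classical variant is available behind
  `classic_ecc` and agrees with an independent enumeration in the tests.
  Since d ≥ 1 on any edge, the printed form needs no zero guard.
- **V_i uses all mutation calls** of a gene over the full tumor cohort,
  including patients where the per-patient filter found no dysregulated
  neighbor: the filter decides membership, not frequency.
- **Cross-tissue averaging averages already-thresholded matrices** (the
  per-tissue threshold is applied first), so averaged entries may fall
  below the single-tissue cutoff and are kept. Averaging is over the gene
  union with absent pairs contributing 0.
- **Multi-probe expression columns** mapping to one symbol are collapsed
  by arithmetic mean. Gene identifiers match exactly after trim+uppercase;
  genes missing from one input are dropped from joint computations with
  counts logged, never remapped via external services.
- **False-negative universe.** Recall counts benchmark genes present in
  the ranking universe (genes never scored cannot be retrieved at any K);
  the unrestricted benchmark size is reported alongside in the curve's
  attrs. F-score at precision = recall = 0 is defined as 0.
- **Tie-breaking** is total and documented (F desc, V desc, symbol asc),
  so rankings and all written TSVs are byte-stable across runs.

## Numerical notes and degenerate inputs

Pearson correlations use pairwise-complete samples with a minimum of 3;
pairs below the minimum, or with zero variance in either gene, get weight
0. Zero-variance genes get z = 0 everywhere (never outlying), as do genes
with fewer than two finite values (logged). An empty retained set after
the filter raises a diagnostic error rather than producing an empty
ranking. Floats in output TSVs carry 12 significant digits, so a
write/read round trip reproduces scores to well below 1e-9.

## Synthetic cohorts

The generator plants exactly the three signals the method exploits and
nothing else, so recovery attributes performance to the implemented
mechanics: dense network modules (within-module edge probability 0.9 over
an Erdős–Rényi background of 0.01), module genes loading on a shared
latent factor in tissue expression (within-module correlation
λ²/(λ²+σ²) ≈ 0.72 at the defaults λ = 0.8, σ = 0.5), drivers mutated at
0.3 per patient against a 0.02 passenger rate, and a ±3 z-unit expression
shift applied to a mutated driver's neighbors in exactly the affected
patients, with the sign fixed per (driver, neighbor) pair. All draws come
from one seeded stream in a fixed order (network → tissue → mutations and
tumor expression), so every artifact is byte-reproducible. Default sizes
(500 genes, 100 patients, 80 tissue samples, five 10-gene modules with two
drivers each) keep a 20-cohort experiment under a few seconds while
leaving per-stage counts (≈400 mutated, ≈200 retained) large enough to be
non-trivial; the committed unit-test preset is 50 genes × 20 patients.

What the simulation does **not** emulate: mutational signatures and
hotspots, copy-number effects, probe-level microarray artifacts,
tumor/normal mixtures, batch effects, or correlated passenger mutation.
Passing recovery tests therefore demonstrate that the implementation
extracts the intended signals, not that the method succeeds on real
cohorts.

Two consequences of the default conditions are worth knowing. First,
cohort-wide z-scoring is self-diluting: when a fraction q of patients
carries a driver's shift s, the reference distribution of a neighbor gene
has mean q·s and variance 1 + s²q(1−q), so the outlying rate among shifted
cells is well below the naive N(s, 1) tail unless q is small; the tests
assert the dilution-aware closed form. Second, the 15-fold gap between
driver and passenger mutation rates makes raw frequency a perfect
separator at these sample sizes: the frequency-only baseline saturates
top-20 recovery, so the defaults exercise the pipeline's mechanics but
cannot show an advantage *over* frequency — demonstrating that advantage
would require a regime with rare drivers or frequent passengers, which is
outside the stated study conditions.

## Known limitations

- Disease → tissue selection is user input; the package does not mine
  disease–tissue associations.
- No statistical significance is attached to scores (no p-values/FDR),
  and no network propagation/diffusion is performed.
- MAF parsing requires only the gene-symbol and sample-barcode columns;
  variant-class filtering (e.g. dropping silent mutations) is available
  but off by default.
- Identifier harmonization is purely syntactic (trim + uppercase).
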