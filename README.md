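# tmrmr — temporal minimum-redundancy maximum-relevance gene selection

`tmrmr` is a filter feature-selection toolkit for **multivariate temporal
gene-expression data**: studies that measure G genes in N subjects at T time
points and attach one class label per subject (the motivating case is human
viral-challenge cohorts labelled symptomatic vs asymptomatic). Classical
filter methods flatten each subject's G×T measurements into one long vector
and discard the temporal structure; `tmrmr` keeps trajectories intact.

## The method

For gene *j*, **relevance** is the one-way ANOVA F-statistic of its
expression slice against the class label, computed per time point and
averaged across time (median, geometric mean and maximum are available
aggregators):

    F(g_j, c) = (1/T) Σ_t F(g_j^(t), c)

**Redundancy** between genes *i* and *j* compares per-subject trajectories
after z-scoring each trajectory (so only *shape* matters — offsets and
amplitudes are removed), using exact dynamic-time-warping distances
D_pq = dtw(g_i,p , g_j,q). Two reductions of the N×N matrix D give the two
variants:

    R_c(g_i, g_j) = 1 / ( (1/N²) Σ_pq D_pq )     (all subject pairs,   TMRMR-C)
    R_m(g_i, g_j) = 1 / ( (1/N)  Σ_p  D_pp )     (matched subjects,    TMRMR-M)

Selection is greedy under the MIQ quotient: restrict candidates to the
**α-pool** (the top round(α·G) genes by relevance, α = 0.3 by default), seed
with the most relevant gene, then repeatedly add the candidate g_k
maximizing V_F / W_dtw, where V_F is the mean relevance of S ∪ {g_k} and
W_dtw the mean pairwise redundancy over its off-diagonal pairs. TMRMR-M
needs only the N diagonal DTW distances per gene pair (O(N) versus O(N²)
for TMRMR-C).

The package also ships the classical flattened mRMR baseline (per-column F
relevance, |Pearson| redundancy, MIQ or MID), a synthetic-data generator
with planted relevant genes and planted redundancy clusters, a
leakage-free cross-validation harness, and selection-stability metrics
(shared-gene count, Tanimoto similarity, Spearman ρ across folds).

## A worked example

`tmrmr.worked_example()` is a 4-subject, 6-gene, 5-time-point instance whose
every number is derived by hand in `docs/worked_example.md`. Running
`python examples/worked_example.py` prints:

```
Relevance (one-way F per time point, and the mean across time):
  gUP     [  81.0    9.0    0.0    9.0   81.0 ]  mean F = 36.00
  gUPs    [  49.0    9.0    1.0    9.0   49.0 ]  mean F = 23.40
  gBUMP   [   1.0    1.0    8.0    1.0    9.0 ]  mean F =  4.00
  gZIG    [   0.0    0.0    0.0    0.0    0.0 ]  mean F =  0.00
  gNOISE  [   0.0    0.0    0.0    0.0    0.2 ]  mean F =  0.04
  gFLAT   [   0.0    0.0    0.0    0.0    0.0 ]  mean F =  0.00

Redundancy of the two key pairs (z-scored trajectories, DTW):
  gUP-gUPs: R_c = 0.213 (all subject pairs), R_m = 0.966 (matched subjects)
  gUP-gBUMP: R_c = 0.200 (all subject pairs), R_m = 0.173 (matched subjects)

TMRMR_C greedy selection: gUP (obj 36.0), gUPs (obj 139.7), gZIG (obj 104.4)
TMRMR_M greedy selection: gUP (obj 36.0), gBUMP (obj 115.9), gZIG (obj 71.2)
```

`gUPs` is `gUP` lagged by one time step. The matched-subject redundancy
(R_m ≈ 0.97 against a ≈ 0.18 background) flags the duplicate, so TMRMR-M
spends its second slot on the independent signal `gBUMP`. On larger
synthetic studies (`examples/select_genes.py`) the roles flip: there
TMRMR-C reliably keeps at most one gene per planted co-expression cluster
while a pure F-ranking picks several interchangeable members.

From a shell, the same operations are available as a thin CLI:

```sh
tmrmr simulate --seed 1 --out-dir study/
tmrmr select --expression study/expression.csv --labels study/labels.csv \
      --variant tmrmr-c --alpha 0.3 --top 8 --out ranked.csv
tmrmr evaluate --expression study/expression.csv --labels study/labels.csv \
      --top 8 --out accuracy.csv
```

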