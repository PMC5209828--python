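# Methods

## Model and procedure

The selection problem: given expression trajectories x_{p,j,t} for subjects
p = 1..N, genes j = 1..G, time points t = 1..T, and a class label c_p ∈
{1..K} per subject, rank a small set of m genes that separate the classes
without duplicating each other's information.

**Relevance.** Per time point, the one-way ANOVA F-statistic

F(g_j^(t), c) = [Σ_k n_k (ḡ_{j,(k)}^(t) − ḡ_j^(t))² / (K−1)] /
[Σ_k Σ_l (g_{j,l,(k)}^(t) − ḡ_{j,(k)}^(t))² / (N−K)]

is aggregated across the T time points, by default with the arithmetic
mean. Median, geometric mean and maximum are exposed because they weight
the time axis differently: the maximum favours genes that separate classes
strongly in a short window; mean and median reward sustained separation;
the geometric mean (defined as 0 whenever any per-time F is 0) demands
separation at *every* time point. The mean is the default and the only
aggregator used by the shipped analyses.

**Redundancy.** Each per-subject trajectory is z-scored (population σ,
divide by T), mapping a constant trajectory to the zero vector — a flat
trajectory has no shape, and zero is the natural fixed point. Dynamic time
warping then measures shape dissimilarity: the exact dynamic program with
local cost |a_u − b_v|, unit-weighted steps (1,0), (0,1), (1,1),
boundary-matched paths and no warping window. Redundancy is the reciprocal
of a mean DTW distance: over all N² cross-subject pairs (R_c, variant
TMRMR-C) or over the N matched-subject pairs (R_m, variant TMRMR-M).
The mean distance is floored at ε = 1e−12 before the reciprocal so
duplicate genes produce a very large finite redundancy rather than an
infinity that would poison the objective.

**Greedy MIQ selection.** Candidates are restricted to the α-pool — the
top round(α·G) genes by aggregate relevance (round half away from zero,
clamped to [1, G]); the pool exists because the bare quotient criterion can
admit an irrelevant feature purely for being unlike the selected ones. The
set S is seeded with the single most relevant gene and grown greedily:
each step adds the candidate maximizing V_F / W_dtw over S ∪ {g_k}, with
V_F the mean aggregate relevance and W_dtw the mean pairwise redundancy.

Two conventions fix corner cases the formulas leave open:

* **W_dtw averages off-diagonal ordered pairs only**, and W_dtw ≡ 1 when
  |S| = 1. A literal double sum over i, j ∈ S would include i = j terms,
  and under R_m a gene's self-redundancy is 1/0 (a trajectory is at DTW
  distance zero from itself). Excluding the diagonal keeps both variants
  on the same footing and reduces the seed step to pure maximum relevance.
  This is the one deliberate deviation from the literal objective and the
  most consequential convention in the package.
* **Infinite relevance** (zero within-class variance with separated class
  means, possible on noiseless synthetic data) is represented as an `inf`
  sentinel that outranks every finite score; inside the objective it is
  replaced by 10× the largest finite pool relevance, with a warning, so
  quotients stay finite and ordered. A fully constant slice scores 0.

Ties everywhere break toward the smaller gene index, so runs are
bit-reproducible. Candidate evaluation uses the full-set objective rather
than the incremental mRMR recursion; with pairwise sums maintained
incrementally each step still costs O(pool) objective evaluations, and
memoization keeps distinct redundancy computations ≤ pool·m (instrumented
counters verify both bounds in the tests).

**Flattened baseline.** Classical mRMR on the N×(G·T) gene-major flattened
matrix: per-column F relevance, |Pearson| redundancy (anti-correlated
columns are equally redundant for classification; a constant column
correlates 0 by convention), MIQ or MID criterion, same α-pool and
tie-break rules.

## Preprocessing

Missing cells are filled per (subject, gene) trajectory by linear
interpolation against the numeric time index; leading/trailing gaps take
the nearest observed value, since interpolation is undefined outside the
observed range. Each gene is then min-max normalized to [0, 1] over all its
N·T values (constant genes map to 0). Inside cross-validation the min/max
are refit on training subjects only and held-out values are clipped to
[0, 1] — whether normalization should be refit per fold is genuinely open;
refitting is the leakage-safe choice and is our convention.

## Cross-validation harness and stability

Folds are stratified by class and seeded. All selection happens on training
subjects; the classifier (anything with `fit`/`predict`) consumes the
selected genes' trajectories flattened per subject (an m·T vector — the
only representation compatible with generic KNN/NB/SVM-style classifiers).
Genes are selected once per fold at max(m) and smaller m values take
prefixes, which the greedy's prefix property makes exact. Accuracy is
reported per fold and pooled per subject (the two can differ when folds
differ in size; both are emitted). An optional time-point reduction keeps
the first, last and equally spaced interior time points.

Stability across folds of the top-m lists: the count of genes selected in
all folds; the mean Tanimoto similarity |A∩B|/|A∪B| over fold pairs
(reported as a similarity — larger is more stable); and the mean Spearman
rank correlation over fold pairs, computed on the union of each pair's
lists with absent genes placed at tied rank m+1. The union-with-tied-rank
convention for partially overlapping lists is ours.

## The synthetic generator

The generator emulates a two-class challenge study at the scale the
analyses use by default: N = 20 subjects in balanced classes, G = 200
genes, T = 10 time points; 8 independent relevant genes plus 3 redundancy
clusters of 4 genes (20 planted genes), the remaining 180 pure noise.
Parameter choices, all in normalized expression units:

* **effect = 1.5, noise_sd = 0.3** — the full between-class trajectory
  difference of a relevant gene versus per-timepoint measurement noise
  (SNR up to 5 at the trajectory extremes). Relevant genes draw one of
  three shape families: rising trend, falling trend (classes get opposite
  signs, ±effect/2), or an early transient bump — sustained versus
  short-window separation.
* **Clusters** share one latent single-cycle sinusoid per cluster (one
  response-and-return cycle over the study window, random phase). Members
  are phase-shifted by at most one time step, amplitude-rescaled by
  0.7–1.4× and offset by ±1 — exactly the distortions z-scored DTW is
  designed to see through. Classes express the latent at different
  same-sign amplitudes (effect·3.0 vs effect·2.25 for K = 2): amplitude
  modulation keeps every member shape-correlated with every other across
  *all* subjects (z-scoring removes amplitude), while the contrast Δamp is
  sized so a member's expected per-time F matches an independent relevant
  gene's — making the clusters a genuine confound for relevance-only
  ranking. Both classes sit far above noise, as the strongest co-expression
  modules in real challenge data do.
* **Noise genes** are iid Gaussian around a flat random baseline.
* Optional uniform missingness (every trajectory keeps ≥ 1 observation);
  a single integer seed drives one generator stream.

What the generator does **not** emulate: probe/batch effects, heavy-tailed
or heteroscedastic noise, correlated noise across genes, class imbalance,
irregular per-subject sampling, and modules whose members respond in
opposite directions. Passing the recovery tests therefore shows the
selection machinery behaves as designed under its own assumptions, not
that it will match any particular accuracy on real cohorts.

## Numerical choices

* DTW is O(T²) exact; the per-gene-pair distance matrix is computed with
  the dynamic program vectorized across all subject pairs. No
  approximate/linear-time DTW and no warping window.
* z-score uses the population σ; ε = 1e−12 floors both the redundancy
  denominator and the objective's W.
* pool_size rounds half away from zero. At α = 0.3 and G = 12023 this
  gives 3607 (0.3·12023 = 3606.9); published descriptions of comparable
  analyses quote 3610 for the same arithmetic, a discrepancy whose
  rounding rule is unknown — we keep plain nearest-integer rounding rather
  than reverse-engineering the printed figure.
* Degenerate inputs: empty sequences are rejected by DTW; a single class
  is rejected by the F-statistic; m larger than the pool is a config
  error; duplicate gene/subject ids are rejected at construction.

## Problem sizes in the shipped analyses

The default synthetic study (N = 20, G = 200, T = 10, α-pool 60, m = 8,
20 seeds) is the scale at which the recovery properties are asserted; the
oracle comparisons use 500 random sequence pairs (length ≤ 5, where
exhaustive path enumeration is cheap) and 500 random ANOVA slices; the
greedy audit re-evaluates every step from scratch on 50 instances with
G ≤ 12, N ≤ 6, T ≤ 6. These sizes keep the full test suite and the
acceptance script in the tens of seconds while exercising every code path
at the dimensionalities the method targets (m ≪ pool ≪ G, T small).

## Known limitations

* **R_c dilution under anti-symmetric classes.** When the two classes'
  trajectories of the *same* gene have opposite shapes (rising vs
  falling), cross-class subject pairs are far apart after z-scoring, so
  the all-pairs mean in R_c mixes aligned and anti-phase pairs and the
  redundancy contrast of a true duplicate shrinks (the worked example
  shows TMRMR-C keeping a lagged duplicate that TMRMR-M rejects). R_m is
  immune because matched subjects share a class.
* **Boundary-matched DTW cannot absorb large phase shifts.** A shifted
  periodic trajectory retains an O(amplitude) residual at the boundaries;
  members of a module must lead/lag by a small fraction of the response
  period for DTW redundancy to recognize them.
* **Late-stage dilution of the redundancy penalty.** W_dtw averages over
  |S|(|S|−1) pairs, so one high-redundancy pair weighs less as S grows;
  occasionally a cluster contributes a second member at a late greedy
  step. This is the criterion's honest behaviour, visible in the planted
  recovery study as a small fraction of seeds with a duplicated cluster.
* Greedy search only — no look-ahead or global optimizer; the quotient
  criterion (MIQ) is the only temporal objective, as the difference form
  has no natural scale between mean-F relevance and reciprocal-distance
  redundancy.
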