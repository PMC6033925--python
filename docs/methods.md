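# Methods

## The model

`colocnet` infers gene co-expression networks as Gaussian graphical models
(GGMs).  Expression profiles of p genes across n samples are modelled as
multivariate normal with precision matrix Ω; gene pairs (i, j) are
conditionally independent given all other genes exactly when ω_ij = 0, so
the network is the off-diagonal support of Ω and edge weights are the
partial correlations −ω_ij/√(ω_ii ω_jj).  Because the regime of interest is
p ≫ n (hundreds of candidate genes, ~61 arrays), Ω is estimated by
ℓ1-penalized maximum likelihood (graphical lasso):

    maximize  log det Θ − tr(SΘ) − Σ_ij P_ij |Θ_ij|

over positive-definite Θ, where S is the sample correlation matrix.

The distinguishing feature is that the penalty P is a **matrix**, carrying
edge-level prior evidence from 3D DNA FISH measurements of nuclear
co-localization:

* unconstrained pairs: P_ij = λ (the base sparsity level);
* **must-present** pairs (observed co-localized): P_ij = ρ·λ with ρ ∈ [0, 1];
* **forbidden** pairs (observed not co-localized): P_ij = +∞, which the
  soft-threshold step turns into an exact structural zero — the constraint
  holds for every λ, ρ and dataset;
* the diagonal is unpenalized (the convention scikit-learn's graphical
  lasso uses, which serves as the uniform-penalty cross-check in the tests).

Since an ℓ1 penalty, however small, cannot *guarantee* selection,
must-present pairs are additionally unioned into the reported edge set when
`enforce_must` is on (the default): the iterative design treats
FISH-validated pairs as known associations.

The solver is the block coordinate-descent graphical lasso generalized to
elementwise penalties; each column's lasso subproblem is solved by
coordinate descent (numba-compiled).  Convergence is declared when the
working covariance changes by less than `tol` (default 1e-6, relative to
the off-diagonal scale of S); support is read off the estimate with an AND
rule at 1e-8 (both Θ_ij and Θ_ji must be selected), which is conservative.

### Choice of ρ (default 0.5)

ρ = 0 removes the penalty on prior pairs entirely.  Experiments on modular
synthetic data show this lets the corresponding precision entries absorb
neighbouring partial-correlation structure and restructure the support
around the prior pairs — occasionally *removing* correct edges elsewhere.
That contradicts the premise of the iterative design, namely that a handful
of validated priors should refine, not disturb, the network (the study
setting reports >80% edge conservation across iterations).  Halving the
penalty (ρ = 0.5) reinforces the validated pairs while leaving the
surrounding estimate stable; in the test suite's 20-replicate recovery
experiment, adding 10 correct must-priors never lowers edge recall at this
default.  ρ remains exposed for sensitivity analyses; strict monotonicity
of recall is not a theorem for any ρ < 1, since refitting can always drop a
borderline edge.

### Sparsity selection

The base λ is chosen by bisection so that the inferred network's density
(100·E/(p(p−1)/2)) matches a target percentage within ±0.5 points —
mirroring the observable trace of the original analysis, whose networks sit
at 3.25–3.55% density.  λ_max = max |off-diagonal sample correlation|
empties the unconstrained support and brackets the search from above; the
lower bracket stays strictly positive when p ≥ n.  If the target is
unattainable (density is only piecewise monotone in λ), the closest
achieved λ is returned with a warning.  Per-iteration re-selection is the
default; a fixed λ can be given instead.

## Preprocessing

Probe-level log2 matrices are imputed with k-NN (k = 3, nan-Euclidean
distances over co-observed columns — scikit-learn's `KNNImputer`), collapsed
to one probe per gene (the probe with the highest mean Pearson correlation
with its siblings; ties break to the smallest probe id), and restricted to
genes whose |Pearson r| with at least one anchor gene (IGF2, DLK1, MEG3)
reaches 0.84.  An r² mode is provided because the source analyses state the
threshold both ways; |r| is the default.  Imputation precedes probe
collapse.

## FISH distance analysis

Confocal stacks have anisotropic voxels (0.077 × 0.077 × 0.284 µm default);
coordinates flagged as voxels are rescaled axis-wise before any distance is
computed.  A nucleus is analysed for a pair only when it shows exactly four
signals (two alleles per gene).  Its inter-gene distance is the minimum 3D
centre-to-centre distance over the 2×2 cross-gene allele pairs — a nucleus
is "associated" as soon as one allele pair is close, matching per-nucleus
binary counting.  Distance classes: co-localized d ≤ 0.5 µm, close
0.5 < d ≤ 1 µm, distant d > 1 µm.  The 1 µm cut-off reflects the axial
resolution limit (3 voxels ≈ 0.852 µm); the co-localized boundary is
inclusive by default and configurable, since published tables print it both
ways.

Percentages are reported rounded half-away-from-zero to integers, as in
published association tables, and the association decision applies the
strict rule *reported associated % > 10* — the threshold sits at the
sporadic association level (~8%) of negative-control pairs, and a tested
pair printed at exactly 10% was classified not co-localized, which fixes
both the strictness and the use of the rounded value.  Associated pairs
contribute the cross-product of their constituent genes (composite loci
such as DLK1/MEG3 expand to both symbols) to the must-present set;
non-associated tested pairs to the forbidden set; a pair receiving both
labels is an error.

## Network mining and clustering

Density is reported to two decimals.  Degree and betweenness (raw
fractional shortest-path counts, unnormalized, endpoints excluded;
disconnected graphs count only existing paths) come from networkx.
Cross-iteration reports give per-gene percentage changes (zero baselines
are flagged undefined rather than infinite) and the percentage of baseline
edges conserved.

Clustering is Louvain modularity optimization (networkx, seeded; cluster
ids are renumbered contiguously by smallest member for determinism;
isolated nodes become singletons).  Modularity is the Newman–Girvan
Q = Σ_c (e_c/m − (d_c/2m)²), implemented directly and cross-checked against
networkx in the tests.

Significance uses a degree-preserving permutation test: B (default 500)
null graphs are produced by double-edge swaps — 10·E swap *attempts* each,
rejecting self-loops and multi-edges, so every null has exactly the
original degree sequence — each null is clustered with Louvain, and the
add-one p-value (1 + #{Q_null ≥ Q_obs})/(1 + B) is reported.  With B = 500
and an observed modularity exceeding every null this gives 1/501 ≈ 0.002,
the smallest value the test can produce.  Graphs admitting no swap (stars)
yield p = 1 with a warning.

Partitions are compared by contingency tables, per-cluster best-match
shares, and NMI with arithmetic-mean normalization 2I/(H_a + H_b)
(max- and sqrt-normalizations available, since published NMI values do not
pin the variant down).

## Synthetic data

`simulate_expression` plants a block-modular precision matrix: genes are
split into equal modules, within-module pairs receive ±magnitude entries
with a given probability (signs random), and the off-diagonal block is
shrunk just enough to keep the smallest eigenvalue at 0.05, so the realized
partial-correlation magnitude (reported as `attenuation` × magnitude) is
exact and the support is known.  Samples are multivariate normal via a
Cholesky factor with a seeded generator.  Defaults — p = 120 in 6 modules,
n = 61, edge probability 0.25, magnitude 0.3 — emulate the study regime: a
few hundred candidate genes on 61 arrays with a true density of a few
percent.  What the generator does *not* emulate: probe-level noise and
probe multiplicity, batch/genotype structure, non-normal intensity
distributions, and negative or hub-dominated dependence beyond what random
signed modules produce.  Passing recovery tests therefore demonstrate
correctness of the estimator under its own model assumptions, not
performance on microarray data.

`simulate_fish` plants a per-nucleus association rate: with probability ρ*
the minimum cross-gene allele distance is drawn uniformly from (0, 1) µm,
otherwise from (1.2, 5) µm — the margins around the 1 µm cut-off keep
classification noise from blurring the planted rate.  Remaining alleles are
placed uniformly in a 3 µm-radius nucleus sphere, rejected only if they
undercut the intended class floor.  `simulate_fish_composition` realizes an
exact distant/close/co-localized count composition (distances drawn with
0.05 µm safety margins inside each class), which is how published
association-table rows are reconstructed as nucleus sets.

## Numerical and degenerate-input choices

* Constant genes are dropped with a warning before inference (their
  correlation is undefined); a variance tolerance absorbs float roundoff.
* Probe-collapse correlations involving a constant probe contribute 0.
* Sample partial correlations via direct inversion require n > p and a
  condition number below 1e12; otherwise the penalized path is suggested.
* Percentage deltas with zero baselines are NaN with an explicit flag.
* All randomness (Louvain, rewiring, simulation) flows from integer seeds;
  pipeline reruns are bit-stable for edge sets and cluster assignments.

## Problem sizes used in validation

The automated checks run entirely on synthetic or reconstructed desk-scale
inputs: support recovery on p = 40, n = 200 with 20 replicates (median F1
≥ 0.7 at density-matched λ); the permutation test on a 40-node two-block
graph with B = 500; FISH rate recovery on 200-nucleus batches across 20
seeds; association-table reconstruction on the published 58–103-nucleus
compositions.  These sizes exercise every code path at full statistical
fidelity while keeping a complete run in minutes on one CPU.

## Known limitations

* The exact prior-weighting and λ-tuning scheme of the original analysis is
  not public; the penalty-factor matrix and density-targeted bisection are
  this package's own design, so published edge counts are reproduced only
  property-wise (density arithmetic, constraint satisfaction, stability).
* Louvain is a heuristic; partitions depend on the seed (a restart option
  reports the best of several seeds).
* The estimator assumes i.i.d. samples; the study's genotype × age design
  is not modelled.
* FISH nuclei are treated as exchangeable; allele-level effects (e.g.
  imprinted monoallelic expression) are not modelled beyond the
  minimum-distance rule.
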