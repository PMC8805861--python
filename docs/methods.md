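# Methods

This note documents the models, numerical choices and validation design of
`dirconn`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, which
knobs matter, and what the synthetic validation does and does not show.

## Lagged correlation and its decomposition

The core quantity is the lagged Pearson correlation ρ_{j→k}(d): the
correlation of the first N−d samples of the source series x_j with the last
N−d samples of the target series x_k, normalized by 1/(N−d−1) with the
means and sample standard deviations of the two *segments* (not of the full
series). At d=0 this is exactly the classical Pearson correlation matrix;
`ZeroLagCorrelation` is computed through the same z-scoring code path so
that the identity holds bit-for-bit, which in turn makes the binarized
symmetric(d=0) network identical to the binarized zero-lag network at every
density (S = 2·zero-lag there, and thresholding is scale-invariant with a
deterministic tie-break). Because the segment normalization is not the
global one, |ρ| can marginally exceed 1 in edge cases; values are clamped
to [−1, 1] with a logged warning.

The lagged matrix L decomposes uniquely as 2L = A + S with A = L − L^T
antisymmetric and S = L + L^T symmetric. The decomposition is applied to
the *signed* L; negative entries and the diagonal are zeroed afterwards
("clipping"), treating anti-correlations and self-connections as absent.
Clipped antisymmetric entries live in [0, 2]; no rescaling by 1/2 is
applied since every downstream step is rank- or threshold-based.
Zero-variance segments produce zeroed connections with a warning rather
than NaN.

## Granger reference method

The comparison network fits, for every ordered region pair, a bivariate
AR(p) model by ordinary least squares and reports
F_{source→target} = ln(var(ε_R)/var(ε_U)), the log-ratio of restricted
(own-history) to unrestricted residual variances. Series are demeaned and
linearly detrended first; if a series still has lag-1 autocorrelation above
0.99 (unit-root heuristic) all series are first-differenced together,
preserving temporal alignment across the pair. Residual variances are
floored at 1e-12 so that noiseless deterministic couplings yield a large
finite F rather than overflowing. Rank-deficient designs yield F = 0 with
a warning. Default order p = 1; p must satisfy p < T/4.

## Networks and graph measures

Thresholding keeps the top ⌊D·n(n−1)⌋ off-diagonal weights at each density
D of the grid (default 1%–50% in 1% steps; the antisymmetric matrix has at
most 50% positive entries, which motivates the 50% cap). Ties are broken
deterministically by (weight descending, row, column). Requesting a density
beyond the fraction of positive entries raises an error naming the
attainable maximum; the study driver caps the grid at the cohort-wide
attainable maximum so all subjects share one grid.

Binary measures: in/out degree; directed shortest-path distances (hop
counts; unreachable pairs contribute distance ∞, i.e. 0 to efficiency, and
the diameter is the largest finite distance with a disconnection flag);
nodal in/out global efficiency (mean inverse distance to/from a node);
in/out local efficiency (global efficiency of the subgraph induced by a
node's neighbors, where "neighbors" is the union of in- and out-neighbors
and nodes with fewer than two neighbors contribute 0); directed clustering
C_i = (A³)_ii / (d_in d_out − d↔) with d↔ = (A²)_ii, counting a triangle
only when its edges form a directed cycle; transitivity
T = trace(A³) / Σ_i [d_i(d_i−1) − 2(A²)_ii], where the denominator is
summed over nodes (the only reading that keeps T dimensionless and ≤ 1 —
verified exhaustively on small digraphs); and Louvain modularity under the
directed (Leicht–Newman) quality function at γ = 1 with 100 seeded restarts
keeping the best Q. Degenerate clustering/transitivity denominators (≤ 0)
return 0.

Weighted generalizations follow the standard conventions: strengths for
degree; inverse-weight edge lengths for distances/efficiency; cube-root
weights normalized by the network maximum for clustering and transitivity;
edge weights in the modularity quality. Nodal curves are integrated over
the density grid by the trapezoid rule (AUC), giving one threshold-robust
value per measure and region; the integration error is O(h²) in the grid
step, so refining the grid by 2 reduces it by 4.

## Group inference

Group differences are tested nonparametrically: the dependent values are
first residualized on covariates (OLS with intercept; the study covariates
are age, sex and six motion summaries — per-volume motion parameters
collapse to one mean-absolute scalar each), then group labels are permuted
(a simplified Freedman–Lane scheme). Two-tailed p-values use the add-one
rule p = (1 + #{|null| ≥ |obs|})/(n_perm + 1); the default is 10 000
permutations. Global measures are tested per density with a 2.5/97.5
percentile null envelope; nodal tests run on AUC values (residualizing the
AUC rather than per-density values — a documented choice) and are corrected
across regions with Benjamini–Hochberg FDR at q = 0.05. Results at
different temporal lags are deliberately *not* corrected across lags by
default, mirroring the exploratory design; a flag enables pooling.
Clinical correlations (Pearson r of residualized network value vs
residualized score, permutation p) are computed only for regions surviving
the group comparison. Permutation p-values are reproducible under a fixed
seed and invariant to subject ordering up to Monte-Carlo error.

## Synthetic ground truth

The generator emulates what the method needs from real data — multivariate
series whose directed interactions arise from lagged propagation — with a
stable VAR(1): x(t) = B x(t−1) + ε, white Gaussian innovations, burn-in of
500 samples discarded. Nonzero off-diagonal coefficients are the true
directed edges. Defaults (the validation conditions): 20 regions (scaled
down from the 200-region atlas scale for runtime; the network-size-dependent
monotonicity check runs at n = 200 separately), T = 207 time points,
15 controls vs 95 patients, Erdős–Rényi support of density 0.10 with
couplings ±0.20, per-subject coefficient jitter of SD 0.05 on nonzero
coefficients, stability enforced via the companion-matrix spectral radius.
Covariates echo the study sample (controls older and more often male;
motion summaries folded-normal). A planted group effect is a named set of
coefficient deltas applied to patients only.

The self-lag default is 0.20. Rationale: the generator does not convolve
with a hemodynamic response (a smoothing option exists but defaults off),
and in real BOLD data most of the temporal autocorrelation is imposed by
that hemodynamic filter; the self-lag therefore represents only residual
neuronal-level autocorrelation. This matters for interpretation: target
autocorrelation converts a lagged coupling into an instantaneous
correlation (corr(x_j(t), x_k(t)) ≈ b·ρ_j(1) for a coupling b), so a
generator with strong self-lags leaks directed effects into the zero-lag
method. With the propagation-dominated default, the planted-direction
experiments show the intended contrast: the antisymmetric pipeline detects
planted couplings significantly more often than the zero-lag pipeline.
Detection is not near-certain even for a 0.8 coupling, for two reasons
inherent to the conditions: the 15-subject control group bounds the power
of the nodal test, and the coupling raises the target's variance, which
weakens the target's *other* incoming correlations and partially cancels
the planted edge's contribution to rank-thresholded in-measures.

What passing the synthetic validation does *not* show about real data: no
hemodynamic variability or regional HRF differences, no physiological or
scanner noise spectra, no spatial correlation of parcel time series, linear
interactions only, and Gaussian innovations. The validation establishes
correctness and calibration of the machinery, not expected effect sizes in
fMRI cohorts.

## Validation design and problem sizes

- Decomposition identity and lag-0 equivalences: exact (≤ 1e-12) on random
  series at the study's T = 207 scale.
- Oracle equivalence: every binary measure equals independent pure-Python
  enumeration oracles (BFS distances, explicit neighbor subgraphs, ordered
  triple counts) exhaustively over all 4 164 labelled digraphs on ≤ 4
  nodes, a seeded 3 000-graph sample of 5-node digraphs, and 200 random
  10-node digraphs; Louvain Q is checked against exhaustive partition
  enumeration on small fixtures (two bidirectional 3-cliques: Q = 0.5).
- Monotonicity in density: global efficiency is provably nondecreasing for
  nested thresholds; local efficiency, mean clustering and transitivity are
  not (adding an edge can grow a denominator without closing cycles), but
  become empirically monotone at the 200-node network scale by
  self-averaging. The check therefore runs at n = 200: E, clustering and
  transitivity on a 2%-step grid, local efficiency on a coarser nested grid
  (0.05–0.45) for runtime.
- Statistical calibration: type-I error of the covariate-adjusted
  permutation test over 200 null cohorts with group-correlated covariates
  (15/95 design, 1 000 permutations), and empirical FDR of BH over 200
  datasets with 10% planted effects across 50 regions.
- Direction recovery: 50 replicate cohorts with a planted j→k lag-1
  coupling of 0.8 in patients; a replicate counts as detected when either
  of the study driver's nodal in-measures (in-degree or
  in-global-efficiency AUC) at the target region reaches p < 0.05 before
  FDR. The same rule is applied to the zero-lag pipeline and the rates are
  compared with a one-sided Fisher exact test.
- Granger: null F magnitudes from independent series (the 95th percentile
  scales as χ²₁/T) and direction accuracy for a planted 0.9 lag-1 coupling
  at T = 207.

## Known limitations

- The lagged correlation is a functional, not effective, connectivity
  measure: it orders regions by temporal precedence and does not identify
  causal mechanisms or rule out common drivers.
- Bivariate Granger ignores the rest of the network (no conditional/
  multivariate variant).
- The weighted clustering/transitivity normalization (by the network
  maximum weight) makes those values scale-free but not comparable across
  networks with very different weight ranges.
- Louvain is a stochastic heuristic; Q is a best-of-restarts value and the
  partition is not guaranteed optimal beyond the small brute-forced
  fixtures.
- AUC integrates nodal curves over the full density range, which dilutes
  effects that live only at sparse densities; this mirrors the analysis
  design rather than a numerical choice.
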