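# Methods

`covnet` implements group-level structural covariance network analysis of
regional gray-matter (GM) volumes: two groups of subjects, each described
by 90 regional volumes (AAL-90 parcellation, cerebellum excluded), are
compared through the topology of their across-subject correlation
networks.

## The model and pipeline

**Covariance networks are group-level objects.** For each group, entry
r_ij of the 90×90 association matrix R is the Pearson correlation between
the confound-corrected volumes of ROIs i and j *across subjects*. No
subject-level network exists; consequently all inference is by subject
relabeling (below).

**Quality control.** Each subject's volume vector is correlated with every
other subject's; subject i's homogeneity score is the mean of those
correlations, and subjects scoring more than 2 SD below the cohort mean
are excluded before any model fitting. This is a volume-table re-expression
of the covariance-based sample homogeneity screen used in VBM practice,
which operates on images that this pipeline never sees.

**Confound correction.** Per ROI, ordinary least squares of volume on an
intercept, age, and total brain volume; the residuals are the corrected
volumes. The default fits one pooled model across all retained subjects
(one correction model for the whole sample, the common practice in
covariance-network toolboxes); a per-group mode is available since the
field is not unanimous. Residuals are exactly orthogonal to the covariates
(checked to 1e-10) and zero-mean within the regression sample.

**Thresholding.** Comparing graphs of different density confounds
topology with connection cost, so R is binarized at matched densities
D = E / [N(N−1)/2]: the E = round(D·N(N−1)/2) largest off-diagonal
correlations (round half away from zero) become edges, and the sweep
D = 0.10–0.50 in steps of 0.02 (21 graphs) is analyzed as a family.
Ranking uses *signed* correlations by default — an edge exists where r
exceeds the implied threshold, so strong negative correlations are never
edges; an absolute-value mode exists. At D = 0.50 some retained edges can
have negative r; they are retained, not hidden. Ties are broken by
(row, column) index, which makes edge sets deterministic and nested along
the grid. The minimum density at which a group's graph forms a single
connected component is reported; below it, graphs are analyzed per
component rather than rejected.

**Global measures.** Clustering coefficient C (mean over nodes of realized
neighbor-pair links; degree < 2 contributes 0), characteristic path length
L (mean shortest-path distance over *connected* pairs, with the number of
unreachable pairs reported; a harmonic-mean variant is available),
normalized ratios gamma = C/C_null and lambda = L/L_null against the mean
of an ensemble of degree-preserving rewired null graphs, the small-world
index sigma = gamma/lambda, and Newman modularity
Q = Σ_m [e_mm/E − a_m²] of the detected partition.

**Null model.** Maslov–Sneppen double-edge-swap rewiring preserving every
node's degree exactly, 10·E attempted swaps per null graph, ensemble size
20 by default (both config-exposed). Graphs admitting no swap (e.g.
complete graphs) yield copies with a warning. On Erdős–Rényi graphs at the
90-node scale this calibrates to sigma ≈ 1 and C_null ≈ D (tested); ring
lattices give sigma > 1.

**Community detection.** Leiden local-moving modularity maximization
(igraph implementation) with the RNG seeded immediately before every call,
so detected partitions and Q values are reproducible. This was chosen over
CNM greedy agglomeration after simulation showed CNM recovers a planted
4-module partition at loading 0.75 with adjusted Rand ≈ 0.72 on average,
versus ≈ 0.94 for Leiden at equal cost (~1 ms on 90-node graphs — the
binding constraint, since community detection runs inside every
permutation). CNM (`method="greedy"`) and an exhaustive partition search
(`method="exhaustive"`, ≤ 12 nodes; the test oracle) remain available.

**Nodal measures and hubs.** Betweenness centrality (raw pair-count form)
and degree, each also reported normalized by the network-wide mean of the
measure (the literal reading of "normalized by the mean of the network";
raw values are always retained). A node is a hub when its betweenness is
at least 2 SD (sample SD) above the network mean; zero-variance
centrality yields an empty hub set rather than an error.

**Permutation inference.** In each of 1,000 repetitions (default) the
residual vectors are reassigned to two pseudo-groups of the original
sizes; both association matrices are rebuilt, thresholded across the grid,
and the measures recomputed — the full pipeline re-runs from residuals,
because the network is a group-level statistic. The two-tailed p-value is
the percentile position of the observed difference with a +1 correction,

    p = 2·min[(1 + #{null ≥ obs})/(n+1), (1 + #{null ≤ obs})/(n+1)],

capped at 1, so p is never exactly 0. The 2.5th/97.5th percentiles of the
null differences form the per-density 95% CI band. Density-sweep summaries:
AUC (trapezoidal integral of the difference curve over the grid) and an
FDA-style functional statistic (sum of the difference over grid points),
each located in the permutation null of the same statistic. Both groups'
community detection inside a permutation uses the same seed, so detection
noise is paired and identical groups give exactly zero difference. No
multiplicity correction is added beyond the permutation scheme itself,
whose maximal-statistic-free per-density/per-node form is reported openly
(per-density flags and raw p-values are both emitted). Nodal comparison
uses normalized betweenness at a reference density — by default the
smallest grid density at which both observed group networks are connected.

**Default measure set for permutation.** Modularity (Q) only. Permutation
inference on gamma/lambda/sigma requires a fresh rewiring ensemble inside
every permutation (21 densities × 2 groups × n_null graphs × 1,000
permutations) and is supported via `measures=("gamma","lambda","sigma")`
but is deliberately not the default; descriptive gamma/lambda/sigma curves
with a 20-null ensemble are always computed per group. Raw C and L are
cheap and can be added to the permutation set freely.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with ground truth for recovery tests. Per subject i in group g and ROI j
with module m(j):

    v_ij = mu_j + w_g·f_{i,m(j)} + beta_age·age_i + beta_tbv·tbv_i + eps_ij

with f i.i.d. standard normal latent module factors (one draw per subject
per module), eps ~ N(0, noise_sd²), and volumes floored at 0. After
residualization, same-module ROIs correlate at w_g²/(w_g² + noise_sd²) in
expectation and different-module ROIs at 0 — the simplest model with a
planted partition, and exactly the block structure a covariance network
detects. Larger w_g means stronger within-module correlation and higher
expected modularity (tested over three loading levels).

Defaults (the simulated study conditions): 30 subjects/group, 90 ROIs
named per the AAL-90 atlas, 4 equal contiguous modules, loadings (0.45,
0.75) so group B is the more modular "patient-like" group, noise SD 1,
ages U(55, 82) years, total brain volume U(1100, 1600) ml with slopes
−0.02 volume-units/year and +0.005 per ml, per-ROI baselines
mu_j ~ U(4, 16) volume units drawn once per cohort and shared by groups.
The baseline *profile* matters: regional volumes differing across ROIs is
what makes subjects' volume vectors mutually correlated (here ≈ 0.9),
so the homogeneity score separates genuine outliers; with a flat profile
the score would be uninformative. Injected outliers add
`magnitude` cohort-SDs of a random-sign pattern fixed by the subject's
row index (deterministic; two outliers get uncorrelated patterns).

What the generator does *not* emulate: non-Gaussian marginals of real GM
volumes, spatially structured (distance- or homotopy-dependent)
correlation, hemispheric symmetry, group differences in means or
variances, and site/scanner effects. Passing tests therefore demonstrate
correctness of the machinery and calibration under the latent-factor
model, not robustness to those features of real data.

## Numerical choices and edge cases

- Exactly one RNG stream per generator call, seeded explicitly; all
  derived seeds stay below 2³¹.
- Density→edge count: round half away from zero (e.g. D=0.16 on 90 nodes
  gives exactly 641 edges; D=0.50 gives 2003).
- Correlation of a constant ROI or subject vector is undefined and raises
  an error naming the offender; rank-deficient regression designs raise
  an error naming the offending covariate.
- p-values on degenerate single-density grids: AUC is undefined (needs ≥ 2
  points) and reported as NaN; the FDA statistic reduces to the pointwise
  difference.
- Fragmented graphs: L averages over connected pairs (count reported);
  measures undefined at a density are recorded as missing in permutation
  results, never fatal.

## Problem sizes in the test suite

Monte-Carlo checks use the smallest sizes at which the tested property is
meaningful: type-I error with 200 replicates × 500 permutations at a
single density (D = 0.30); power with 50 replicates × 200 permutations on
a reduced 6-density grid (0.10–0.50, step 0.08); oracle equivalence on
every labeled connected graph with ≤ 5 nodes plus seeded random graphs up
to 30 nodes; small-world calibration with 20 replicates × 20 nulls. The
acceptance script runs the full default configuration (21 densities,
1,000 permutations) once on the default synthetic cohort.

## Known limitations

- The homogeneity screen is a table-level stand-in for an image-space QC
  step; on real data both should be used.
- Betweenness-based nodal permutation tests are noisy on small dense
  graphs; single-node effects need a graded betweenness landscape (several
  alternative paths) to be detectable, as the bridge-recovery test
  illustrates.
- Whether pooled or per-group confound correction is "correct" is
  unsettled; both are provided and the choice is recorded in provenance.
- Weighted and directed variants, efficiency/assortativity/rich-club
  measures, and correlation-matrix-randomization (as opposed to topology-
  randomization) null models are out of scope.
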