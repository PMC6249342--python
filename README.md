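# covnet

Structural covariance network analysis of regional gray-matter volumes.

Many neurological conditions — normal pressure hydrocephalus, Alzheimer's
disease, multiple sclerosis — alter not just individual brain regions but
the *coordination* between regions. Structural covariance networks capture
this at the group level: nodes are the 90 cerebral regions of the AAL
atlas, and an edge connects regions whose gray-matter volumes correlate
across the subjects of a group. `covnet` is for researchers who already
have a subject × ROI volume table (e.g. from a VBM pipeline) and want to
build the group networks, characterize their topology, and test whether
two groups (say patients vs. controls) differ.

## What it computes

For each group, the association matrix **R** with entries
r_ij = Pearson correlation of confound-corrected volumes of ROIs i and j
across subjects, binarized at matched connection densities
D = E/[N(N−1)/2] over the sweep D = 0.10–0.50 in 0.02 steps. On each
binary graph:

- clustering coefficient **C** and characteristic path length **L**;
- **γ** = C/C_null, **λ** = L/L_null and the small-world index
  **σ** = γ/λ, against degree-preserving (Maslov–Sneppen rewired) null
  graphs;
- Newman modularity **Q** = Σ_m [e_mm/E − a_m²] of the detected partition
  (seeded Leiden);
- nodal betweenness and degree (raw and mean-normalized), and hubs
  (betweenness ≥ mean + 2 SD).

Group differences are tested by subject-relabeling permutation (default
1,000 repetitions): residual volume vectors are reassigned to pseudo-groups
of the original sizes and the whole network construction re-runs, giving
per-density two-tailed percentile p-values with 95% CI bands plus AUC and
FDA summaries across the density sweep. A synthetic-cohort generator with
a planted module structure provides ground truth for calibration and
recovery testing. Details: [docs/methods.md](docs/methods.md).

## Worked example

```python
import covnet

# two groups x 30 subjects x 90 ROIs; group B has stronger within-module
# covariance (loadings 0.45 vs 0.75)
cohort, truth = covnet.generate_cohort(covnet.CohortSpec(seed=1))

report = covnet.homogeneity_check(cohort)        # outlier screen
cohort = covnet.drop_flagged(cohort, report)
resid = covnet.residualize(cohort, ("age", "tbv"))

R_b = covnet.association_matrix(resid, "B")
grid = covnet.default_density_grid()
print("min connected density B:", covnet.min_connected_density(R_b, grid))

G = covnet.threshold_at_density(R_b, 0.16)
Q, membership = covnet.modularity(G)
print("Q at D=0.16:", round(Q, 3))

cfg = covnet.PermutationConfig(n_permutations=200,
                               densities=grid[::4], measures=("Q",), seed=0)
res = covnet.permutation_test_global(resid, cfg)["Q"]
print("modularity FDA p:", round(res.fda_p, 3))
```

Output:

```
min connected density B: 0.12
Q at D=0.16: 0.526
modularity FDA p: 0.01
```

Group B's network fragments below density 0.12 (below it some node pairs
have no connecting path). Its modularity at D = 0.16, Q ≈ 0.53,
reflects the four planted modules, and the permutation FDA summary
(p = 0.01, the smallest value 200 permutations can resolve) correctly
detects that group B is more modular than group A.

The same analysis end-to-end, from the shell:

```bash
covnet simulate --out sim --seed 1
covnet run --cohort sim/cohort.csv --out results --seed 1
```

writes QC report, residuals, association matrices, per-density global
metrics, permutation comparison (JSON + TSV), nodal comparison, and hub
reports, each embedding the full configuration, its hash, seeds and
package version.

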