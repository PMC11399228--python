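# guidecall

Guide assignment for low-MOI single-cell CRISPR screens: ten assignment
strategies behind one interface, an evaluation framework to compare them,
and a seeded synthetic-screen generator with ground truth.

## The problem

In a pooled single-cell CRISPR screen, each cell receives guide RNAs
(gRNAs) that direct a Cas protein to a target gene; sequencing yields a
sparse gRNA-by-cell UMI count matrix alongside the gene-expression
read-out.  Before any downstream analysis, each cell must be *assigned*
the gRNA(s) it truly carries.  This is harder than it sounds: ambient
gRNA molecules (e.g. from lysed cells) contaminate every cell with
low-count noise, capture is overdispersed, and sequencing depth varies
per cell.  At low multiplicity of infection (MOI) most transduced cells
carry a single guide, and the analysis unit is the *uniquely assigned*
cell.  The choice of assignment strategy changes the number of usable
cells, the apparent strength of target-gene knockdown, and ultimately the
number of discoveries a screen yields.

## Assignment strategies

For a cell c with counts k_cg over guides g, library size
L_c = Σ_g k_cg and top-guide fraction f_c = max_g k_cg / L_c:

| family | method | rule |
| --- | --- | --- |
| independent | `umi_threshold` | call (c,g) iff k_cg ≥ t |
| across gRNAs | `maximum` | call the unique argmax_g k_cg |
| across gRNAs | `ratio` | call the unique argmax iff f_c ≥ r |
| across cells | `gauss` | per-guide 2-component Gaussian mixture on log2(k+1), zeros included (the Cell Ranger model) |
| across cells | `gauss_nonzero` | the same fitted on nonzero counts only |
| across cells | `pois_gauss` | Poisson background + discretized log-normal signal on raw counts |
| across cells | `nb_gauss` | negative-binomial background + log-normal signal |
| cells and gRNAs | `glm` | k_cg ~ Poisson(exp(β₀ + β₁ z_c + log L_c)), latent perturbation indicator z_c |
| cells and gRNAs | `beta_2`, `beta_3` | Beta mixtures on f_c per batch; calls above a learnt per-batch frequency threshold |

All model-based methods are fitted by expectation–maximization with
closed-form (or exactly profiled) M-steps and call a (cell, guide) pair
when the posterior signal probability exceeds a cutoff (default 0.5).

Evaluation follows four criteria: numbers of total and uniquely assigned
cells, pairwise Jaccard concordance of assignments, target-gene
downregulation in assigned cells (median −log2 fold change vs cells
assigned to non-targeting controls), and discovery / false-discovery
counts from a rank-sum + Benjamini–Hochberg differential-expression
screen (simple built-in plumbing, not a substitute for dedicated DE
engines such as SCEPTRE).

## Worked example

```python
import guidecall as gc

cfg = gc.scenario_config("separated", seed=11)      # easy, well-separated screen
matrix, ctx, truth = gc.simulate_screen(cfg)
print(f"{matrix.n_cells} cells x {matrix.n_guides} guides, "
      f"{matrix.counts.nnz} nonzero entries")

tables = [
    gc.assign_umi_threshold(matrix, t=5),
    gc.assign_from_mixture(matrix, "pois_gauss"),
    gc.assign_beta(matrix, n_components=2),
]
report = gc.build_report(tables, ctx=ctx, truth=truth, run_de=False)
print(report.summary[["n_calls", "n_uniquely_assigned_cells"]])
print(report.truth_scores.round(3))
print("median -log2FC (umi_threshold):",
      round(gc.median_target_downregulation(tables[0], ctx), 2))
```

prints

```
2000 cells x 26 guides, 2064 nonzero entries
               n_calls  n_uniquely_assigned_cells
method
umi_threshold     2042                       1959
pois_gauss        2042                       1959
beta_2            1938                       1938
               precision  recall     f1
method
umi_threshold        1.0   1.000  1.000
pois_gauss           1.0   1.000  1.000
beta_2               1.0   0.949  0.974
median -log2FC (umi_threshold): 1.99
```

On this well-separated screen the threshold and mixture methods recover
the simulated infections exactly; the 2-Beta method, which emits at most
one call per cell, misses only the multi-infected cells.  The median
−log2 fold change of 1.99 recovers the simulated 4-fold (2²) knockdown,
confirming that the assigned cells really carry their guides.

The same pipeline is available from the shell:

```bash
guidecall simulate --scenario separated --seed 11 --out screen/
guidecall assign mixture --model pois_gauss --input screen/guide_counts --out calls.csv
guidecall assign umi-threshold --t 5 --input screen/guide_counts --out calls_umi.csv
guidecall evaluate compare --assignments calls.csv --assignments calls_umi.csv \
    --expression screen/expression.csv --guide-map screen/guide_map.csv \
    --truth screen/truth.csv --out report/
```

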