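# hoxpos

Position inference and homeodomain-code analysis for single-cell RNA-seq of
*Drosophila* embryonic motoneurons.

Motoneurons of the embryonic ventral nerve cord express the seven Hox
transcription factors (lab, Dfd, Scr, Antp, Ubx, abd-A, Abd-B) in consecutive
anterior→posterior (AP) domains. Because those domains are known from
immunofluorescence, the Hox read counts of a single cell carry information
about where along the body axis the cell sat. `hoxpos` turns that idea into a
tested pipeline:

1. **QC** — keep cells with ≥ 10 reads in each of ≥ 500 genes, and genes with
   ≥ 10 reads in each of ≥ 5 cells.
2. **Variable genes** — fit the technical trend CV² = a₁/μ + a₀ across genes
   and call genes whose variance significantly exceeds it (χ² test, BH
   adjustment).
3. **Near-binary normalization** — per gene, N_i = log_k(1 + k·s_i) with
   s_i the cell's share of the gene's total normalized counts and k = 10⁶;
   approaches a presence/absence code for large k while keeping quantitative
   differences for highly expressed genes.
4. **AP reference map** — per-Hox-protein intensity curves Y_g(x) ∈ [0, 1] on
   a normalized axis, built from immunofluorescence traces (or synthetic
   stripe specifications).
5. **Position mapping** — per cell, maximize over grid positions x the
   Poisson log-likelihood

       log p(D | x) = Σ_g log Pois(D_g | r_g·Y_g(x))   where Y_g(x) > 0
                    = Σ_g log Pois(D_g | λ)            where Y_g(x) = 0

   with background rate λ = 0.1 and r_g = (total counts of g) / (number of
   expressing cells). A Latin-hypercube scan over (λ, global r multiplier)
   verifies the estimates are insensitive to these choices.
6. **Spatially variable genes** — per gene, a cubic B-spline model of
   expression on inferred position (3 df) versus an intercept-only null,
   compared by BIC; selected profiles are smoothed with an absolute
   exponential kernel (decay 10 per unit axis) and grouped into pattern
   modules.
7. **Clustering** — ward/Euclidean hierarchical clustering: 3 major clusters
   on the 20 most variable genes, and homeodomain-code clusters (default 60)
   on near-binary values of the variable homeobox genes, with Hox-negative
   cells excluded.
8. **Association** — per-gene one-way ANOVA F-test of expression on cluster
   identity; Fisher and rank-sum tests for gene-class enrichment (notably
   immunoglobulin-domain genes) among cluster-associated genes; a
   hypergeometric overlap test against a 13,920-gene universe for external
   gene sets.

A first-class synthetic-data module generates datasets with exactly the
generative structure the mapping model assumes (stripe references, Poisson
counts with background, planted spatial genes, planted homeodomain codes with
linked Ig programs), so every stage runs and is tested without downloads.

## Worked example

```python
import numpy as np
from hoxpos import (make_reference, simulate_cells, estimate_rg,
                    MappingParams, map_cells, robustness_lhs)
from hoxpos.synthetic import DEFAULT_HOX_SPECS

ref = make_reference(DEFAULT_HOX_SPECS, grid_size=201)
counts, truth = simulate_cells(ref, n_cells=500, r=20.0, lambda_bg=0.1, seed=1)

r = estimate_rg(counts, ref.gene_ids)
print("r_g:", {g: round(v, 1) for g, v in r.items()})

pos = map_cells(counts, ref, MappingParams(r=r.to_numpy(), lambda_bg=0.1))
mapped = pos["mapped"]
err = np.abs(pos.loc[mapped, "x_hat"].to_numpy() - truth.positions[mapped.to_numpy()])
print(f"mapped {mapped.sum()}/500 cells; median |error| = {np.median(err):.3f} axis fraction")

corr, _ = robustness_lhs(counts, ref, n_draws=20, seed=1)
print(f"min pairwise Spearman across the parameter scan: {corr.min():.3f}")
```

Output:

```
r_g: {'lab': 10.3, 'Dfd': 10.9, 'Scr': 10.7, 'Antp': 9.0, 'Ubx': 8.6, 'abd-A': 9.4, 'Abd-B': 13.5}
mapped 494/500 cells; median |error| = 0.023 axis fraction
min pairwise Spearman across the parameter scan: 0.929
```

`r_g` lands near 10 rather than the simulated 20 because it averages over all
expressing cells, not only cells at full reference intensity — exactly why the
robustness scan matters: the position estimates barely move when λ and r are
varied over wide ranges (minimum pairwise Spearman 0.93 here). The median
mapping error of 0.023 corresponds to ≈ 46 units on the 0–2000 nerve-cord
scale. Six cells had no Hox reads and were excluded from mapping.

The same stages are available from the shell:

```bash
hoxpos simulate --scenario mapping --seed 1 --out sim/
hoxpos qc --in sim/ --min-genes 1 --min-reads 1 --out qc/
hoxpos map --counts qc/ --reference sim/reference.tsv --out positions.tsv
hoxpos run --config cfg.yaml          # full pipeline with a manifest
```

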