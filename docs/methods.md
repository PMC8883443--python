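# Methods

## The observation model

A cell c at axis position x ∈ [0, 1] yields read counts for each Hox gene g:

    D_g ~ Pois(r_g · Y_g(x))   if Y_g(x) > 0
    D_g ~ Pois(λ)              if Y_g(x) = 0

Y_g is the immunofluorescence-derived reference intensity, scaled so each
gene attains 1 somewhere; r_g is the expected read count at full intensity;
λ is a small background rate for reads observed where the reference says the
gene is off. The position estimate is the grid argmax of the summed
log-likelihood. Assumptions worth stating explicitly:

- **Conditional independence across genes given position.** Shared technical
  depth violates this mildly; the Latin-hypercube robustness scan
  (`robustness_lhs`) is the check that conclusions do not hinge on it or on
  the exact (λ, r) values.
- **Protein intensity ∝ expected RNA counts.** The reference is a protein
  measurement while counts are RNA; r_g absorbs the scale but not shape
  distortions between the two.
- **All profiles share one axis.** No left/right or dorsoventral structure;
  the model is strictly 1-D.

`r_g` is estimated as total counts over the number of expressing cells. On a
reference whose mean intensity over its territory is below 1 this
underestimates the full-intensity rate (a boxcar at Y ≡ 1 recovers it
exactly; a Gaussian domain averages Y < 1). That bias is deliberately left
uncorrected — it rescales likelihood terms jointly and the robustness scan
shows position calls are insensitive to a global r multiplier between 0.2
and 5.

Numerical choices: everything is computed in log space (the likelihood
product under/overflows); `xlogy` keeps λ = 0 legal (−∞ at impossible
positions, never NaN); argmax ties — exact on flat boxcar plateaus — resolve
to the median tied grid index, which is symmetric and deterministic.
Positions are grid points; the default 201-point grid on [0, 1] matches a
10-unit step on the 0–2000 nerve-cord scale and keeps the whole 500-cell
mapping under a second.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| λ | 0.1 | counts | background read rate in non-expressing territory |
| r_g | estimated | counts | mean expression over expressing cells |
| grid_size | 201 | points | 10-unit resolution on the 0–2000 scale |
| k | 10⁶ | — | near-binary gain; lowly expressed genes binarize, highly expressed keep quantitative structure |
| QC thresholds | 500 genes × 10 reads; 5 cells × 10 reads | — | standard Smart-seq2 quality rules for this dataset class |
| HVG FDR | 0.1 | — | the conventional level for the CV²-trend test |
| spline df | 3 | basis columns | cubic B-spline with no internal knots (Bernstein basis) |
| kernel decay | 10 | per unit axis | half-width ≈ 0.07 axis fraction |
| n_homeo | 60 | clusters | matches the estimated number of twit-low cells |
| overlap universe | 13,920 | genes | protein-coding gene count used for set-overlap tests |

Decisions where the protocol was genuinely open, and the choice made here:

- **Near-binary formula.** The transform is implemented as
  N_i = log_k(1 + k·s_i). The alternative reading log_k(1 + s_i) tends to 0
  for every input as k grows and cannot binarize, so it is kept only as
  `variant="plain"` for comparison.
- **"Expressed"** means ≥ 1 read, both for Hox positivity and marker
  observation in the subtype scores; configurable.
- **Filter order** is cells first, then genes; both orders are supported and
  the order is logged. On data where the two interact the results differ
  slightly; determinism and logging were preferred over guessing.
- **Kernel decay scale.** The decay rate of 10 is interpreted per unit of
  the [0, 1] axis. Reinterpreting it on the 0–2000 scale would make the
  kernel ~200× narrower and essentially a nearest-cell lookup.
- **Spline df.** "3 degrees of freedom" is taken as 3 basis columns (plus an
  explicit intercept), i.e. R's `bs(x, df=3)`; not 3 internal knots.
- **BIC, not a p-value, selects spatial genes.** No multiplicity correction
  is applied on top of the BIC comparison; BIC's complexity penalty is the
  selection rule.
- **scale_expression recipe.** Size-factor normalization, log1p, then
  per-gene standardization by the fitted total variance on the log scale
  (observed, floored at the delta-method image of the technical variance).
  The recipe is isolated in one function so it can be swapped.
- **Background threshold for reference traces** is a per-gene intensity
  quantile (default 0.1) since only "thresholds were set" is known upstream;
  the value is logged on every build.
- **Fisher significance column.** The class-association 2×2 table uses
  BH-adjusted p-values at α = 0.05 by default; raw p-values are one flag
  away, and both are reported per gene.
- **Ward tie behaviour.** scipy's ward linkage is deterministic for a given
  input ordering; cluster *content* is additionally verified order-invariant
  in the tests via the adjusted Rand index.

## The synthetic data

The generators produce data from exactly the generative dual of the
observation model, plus the structures the downstream stages look for:

- `make_reference` — seven default stripe specs: three anterior hard-edged,
  non-overlapping boxcar stripes and four posterior overlapping domains
  (Gaussians truncated at 3σ, and one saturating posterior tail). Compact
  support is enforced so the λ branch of the model is exercised.
- `simulate_cells` — uniform positions, Poisson counts, optional lognormal
  per-cell depth factors. Uniform placement is a neutral testing choice;
  the real spatial density of motoneurons along the cord is not modeled.
- `add_spatial_genes` — planted genes whose mean follows a sigmoid or bump
  of true position with a stated fold-change; flat genes as negatives.
- `simulate_homeo_population` — clusters defined by distinct random binary
  homeobox codes (on ≈ 20 counts, off ≈ λ), each with a cluster-specific
  Ig-gene subset boosted by a stated fold-change, plus optional unlinked
  background genes; clusters are laid out in order along the axis.

What passing tests on these data do **not** show: robustness to doublets,
ambient RNA, zero inflation beyond Poisson, segment-level position structure,
protein/RNA shape discordance, or batch effects — none of which the
generators emulate. They certify the inference machinery: that each stage
recovers precisely the structure its model assumes, at realistic depths and
effect sizes, and that its null calibration holds.

## Degenerate inputs

All-zero genes pass through the near-binary transform as zeros; constant
genes scale to 0 and get F = 0, p = 1 in the association test; cells with no
Hox reads are excluded from mapping with an explicit reason; constant-depth
covariate checks return p = 1; intensity traces without dynamic range after
background removal are an error rather than a silent flat curve.

## Problem sizes

Tests and the acceptance script run at 500 cells for mapping and
spatial-gene analyses, 1,000 genes × 120–200 cells for variable-gene
calibration (20 replicates under the null), 6 × 40 cells for
homeodomain-code recovery, and 50 random 5-gene × 21-grid fixtures for the
likelihood oracle — sizes chosen so the full suite completes in seconds
while keeping every statistical check comfortably powered.

## Known limitations

- The hook for factor-analysis models that separate known from unknown
  covariates (e.g. ZINB-WaVE) is documentation-only; no embedding or factor
  model is implemented here.
- Position estimates are grid-restricted MLEs; no posterior uncertainty
  beyond the stored log-likelihood profile.
- The subtype scores assume marker observation is informative at a 1-read
  threshold; with deeper per-cell coverage the threshold should rise.
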