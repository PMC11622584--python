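# Methods

## Data model and ingestion

Input methylation calls are CGmap lines (chrom, C/G nucleotide, 1-based
position, context, sub-context, methylation ratio, methylated reads, total
reads). Only CpG-context lines are kept. Calls on the G strand are mapped
to the C-strand coordinate (position − 1) and read counts from the two
strands are summed per CpG dinucleotide before filtering, on the grounds
that CpG methylation is symmetric; levels are recomputed from counts, and
the stored ratio column is used only as a consistency check (warning beyond
1e-3). An entry enters the matrix when its summed depth reaches
`min_coverage` (default 40×, the depth at which a binomial level estimate
has standard error ≤ 0.08); lower-coverage entries are *missing*, not zero
— zeros would bias toward hypomethylation. Sites missing in every sample
are dropped. Rows (samples) and columns (sites, by natural chromosome
order then position) are sorted so all downstream fits are deterministic.

Missing entries are imputed across samples with k nearest neighbours
(default `k = 5`): the fill value is the mean of the k nearest samples'
levels at that site, with nearness measured on mutually observed sites
(scikit-learn's `KNNImputer` with samples as rows). Imputation never
changes observed entries and is idempotent. `k` must be below the sample
count; downstream results should be insensitive to `k` in roughly 3–10 at
typical missingness.

## Cell-type deconvolution

A bulk profile `m` is decomposed against a reference methylome `R`
(sites × cell types, each column the unweighted mean of its replicate
WGBS profiles restricted to the common panel sites) by non-negative least
squares, `ŵ = argmin_{w≥0} ‖Rw − m‖₂`, computed with `scipy.optimize.nnls`
on the sites shared between the sample (non-missing) and the reference
(at least 50 required). With `normalize=True` (default) the weights are
rescaled to sum to one; raw weights and the residual norm are retained.
An all-zero solution raises rather than silently renormalising.

Because sperm are haploid and somatic cells diploid, the weights estimate
DNA proportions, not cell fractions; all recovery tests compare against
DNA-mixing ground truth. No site weighting or automatic unknown-component
estimation is performed — an extra "unknown" column can simply be added to
the reference.

## The multifactor model

The design matrix holds a constant column, a 0/1 batch indicator, and the
substantive factors (age, compositions) min-max scaled to [0,1] so their
coefficients are comparable; the (min, max) pairs are stored for inverse
transformation. Two collinearity guards run before fitting:

- **Simplex completeness.** Normalised compositions sum to one, so a
  complete set of composition factors is exactly collinear with the
  constant. When detected (sum ≈ 1 for every sample), the last-requested
  unpinned composition is dropped, as a leave-one-out encoding.
- **Pairwise pruning.** While any pair of substantive factors has
  |Pearson r| above `prune_threshold` (default 0.7), the unpinned factor
  in a violating pair with the largest mean absolute correlation is
  dropped. Age is always pinned; the built-in tissue profiles also pin
  the composition of interest (sperm for semen, epithelial for buccal),
  so collinear nuisance compositions are the ones removed — matching the
  practice of keeping the factor the analysis is about.

The fit is `β̂ = X⁺M` with SVD cutoff `max(n, p)·ε` relative to the largest
singular value (configurable). This equals per-site OLS when X has full
column rank and is the minimum-Frobenius-norm least-squares solution
otherwise. Factor prediction inverts through the coefficient matrix:
`X_pred = M β̂⁺`. LOOCV refits β on each leave-one-out subset and predicts
the held-out sample's factor row; per-factor Pearson r with a two-sided
t-test p-value (n − 2 df) and MAE in original units (years, fractions) are
reported. The constant and batch columns participate in fitting but are
excluded from reports and from site assignment: they are nuisance terms.
In-sample (`evaluate_fullfit`) and LOOCV statistics are both available;
LOOCV is the honest generalisation estimate, and in-sample r is optimistic
by construction.

A caution from the null simulations: with many more sites than samples,
the LOOCV correlation of a truly unassociated factor is *not* tightly
concentrated at zero — across pure-noise cohorts (n = 80, 2,000 sites) it
has a standard deviation near 0.12 with occasional excursions past 0.3,
and structured noise (shared per-site baselines with small jitter) widens
it further through near-singular coefficient matrices. Observed LOOCV
correlations should therefore be compared against this null spread, not
against zero.

## Site selection

Per-site statistics use the same design matrix: `r_site` is the Pearson
correlation between observed and model-predicted methylation across
samples (undefined for zero-variance sites, which therefore fail the
correlation filter), and per-factor p-values come from vectorised OLS
t-tests sharing one `(XᵀX)⁻¹` across sites (cross-checked against
statsmodels in the test suite), BH-adjusted per factor across all sites.
Adjusting per factor rather than pooled keeps unrelated factors from
influencing each other's thresholds.

Selection for a factor keeps sites passing all three conjunctive filters
(`|r_site| ≥ 0.5`, `q ≤ 0.05`, largest |coefficient| among substantive
factors — making per-factor site sets disjoint), ranks by adjusted p
ascending with ties broken by |coefficient| descending then site id,
truncates to `cap = 200`, and splits by coefficient sign. A coefficient of
exactly zero lands in the positive group and is flagged. Both pre-cap and
post-cap counts are reported, since a binding cap changes interpretation.
The intercept and batch coefficients are excluded from the argmax filter:
the intercept would otherwise absorb nearly every site.

## Synthetic cohorts

The generator draws, per config seed: a reference methylome; compositions
`w_i ~ Dirichlet(α)` (semen profile: sperm-dominant α = (10, 3, 1.5, 1.5)
over sperm/prostate/T/granulocyte; buccal: epithelial-dominant
(12, 2, 2)); ages uniform on 27–61.5 y; a balanced two-batch split. Site
means are `W Rᵀ` plus a linear age drift of magnitude `age_slope` (default
0.1 methylation across the age range, 80% negative slopes by default,
reflecting the predominance of demethylation with age) at
`n_age_sites = 200` planted sites, plus an additive `batch_shift = 0.05`
at 100 batch sites, clamped to [0,1]. Observed reads are
`c ~ Poisson(74)` and `m ~ Binomial(c, μ)` — count noise matching
bisulfite data at the panel's typical depth — with entries below the 40×
floor missing; a Gaussian-jitter noise model is available for stress
tests where an explicit noise sd is wanted.

Reference columns share a background — half bimodal Beta(0.4, 0.4) CpGs,
half intermediate U(0.2, 0.8) "dynamic" CpGs, emulating a targeted panel
enriched for variable EWAS/clock probes — and differ in per-type
discriminating blocks where one type sits at the opposite methylation
extreme (|Δ| ∈ [0.84, 0.96]); block size is chosen so every column pair
differs by at least δ (default 0.3) on average, verified at generation.
Effects are planted outside the discriminating blocks, preferentially at
intermediate-methylation sites where the full drift can be expressed
without clamping — without this, large slopes saturate against the [0,1]
bounds and detectability stops growing with effect size. "Slope-to-noise
≥ 3" in the recovery guarantees means the planted signal's standard
deviation across samples exceeds three times the noise sd.

What passing tests show — and don't. The generator reproduces the
*assumptions* of the analysis (linear factor effects, additive batch
shift, binomial counts, independent sites). Recovery on it validates the
algebra and the selection logic, not robustness to what real methylomes
add: correlated neighbouring CpGs, nonlinear age trajectories,
reference/sample domain shift, bisulfite conversion error, or unmodelled
cell types.

## Numerical and design choices

- Pseudoinverse cutoff `max(n, p)·ε·σ_max`; passed as a relative
  tolerance, with a fallback for numpy versions lacking the `rtol`
  keyword.
- Coverage ties: depth exactly at the floor is retained (≥, not >).
- Undefined correlations (zero variance) are reported as NaN, never
  silently zero; such sites simply fail the correlation filter.
- BH adjustment delegates to statsmodels (`fdr_bh`); the test suite keeps
  an independent hand-written step-up oracle.
- The two batch levels are encoded 0/1 in sorted label order;
  single-batch cohorts get no batch column (it would be collinear with
  the constant), more than two levels are rejected.
- Problem sizes in the test and acceptance runs (cohorts of 40–80 samples
  and 400–2,000 sites, 10-seed null batteries) were chosen as the
  smallest at which the recovery properties are stable and well separated
  from their thresholds.

## Known limitations

- The deconvolution assumes the reference spans the sample's cell types;
  material from absent types is distributed over the available columns.
- Factor pruning is pairwise; more diffuse multicollinearity (beyond the
  simplex-completeness case, which is handled exactly) is reflected only
  in inflated coefficient variance.
- With p ≫ n the pseudoinverse fit interpolates; all generalisation
  claims rest on LOOCV, and its null spread (above) must be kept in mind
  for weakly identified factors.
- The 40× floor is applied to strand-merged CpG depth; panels counted
  per strand will retain slightly different site sets.
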