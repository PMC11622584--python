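# semenmeth

Tools for analysing targeted bisulfite sequencing of semen and buccal-swab
DNA: assembling methylation matrices from per-cytosine calls, estimating
cell-type composition by reference-based deconvolution, modelling the joint
effect of age, batch, and cell composition on CpG methylation, and selecting
the CpG sites most associated with each factor.

Bulk semen methylomes mix signals from sperm, prostate epithelium, and
immune cells, and shift with donor age; any per-site association analysis
must disentangle these factors. This package implements that analysis as a
reusable pipeline, aimed at epigenomics researchers working with
CGmap-format methylation calls from capture panels.

## The model

For `n` samples and `m` CpG sites, the observed methylation matrix
`M ∈ [0,1]^{n×m}` is modelled as a multivariate multiple regression on a
factor matrix `X ∈ R^{n×p}` (a constant column, a 0/1 batch indicator, and
age and cell-composition factors min-max scaled to `[0,1]`):

```
M = X β,        β̂ = X⁺ M        (Moore–Penrose pseudoinverse)
M_pred = X β̂,   X_pred = M β̂⁺
```

Upstream, per-sample cell compositions are estimated by non-negative least
squares against a reference methylome `R` (sites × cell types):
`ŵ = argmin_{w≥0} ‖R w − m‖₂`, optionally renormalised to sum to one. The
weights are DNA proportions, not cell counts (sperm are haploid).
Generalisation of the factor model is assessed by leave-one-out
cross-validation: each sample's factor row is predicted from a coefficient
matrix fitted without it, and predicted vs observed factors are compared by
Pearson correlation and mean absolute error in original units.

Sites associated with a factor pass three filters: (1) observed vs
predicted methylation correlate with `|r| ≥ 0.5` across samples; (2) the
factor's per-site OLS t-test, Benjamini–Hochberg adjusted per factor, has
`q ≤ 0.05`; (3) the factor holds the largest absolute coefficient at that
site among substantive factors. At most 200 sites per factor are kept
(smallest `q` first) and split into positive- and negative-coefficient
groups — negative meaning methylation loss as the factor increases.

The estimators follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, trailing-underscore fitted attributes):
`KNNSampleImputer`, `NNLSDeconvolver`, `MultifactorModel`, `SiteSelector`.

## Worked example

A fully synthetic cohort with known ground truth — 80 samples, 2,000 panel
sites, four semen cell types, and 200 planted CpGs that demethylate with
age (slope 0.1 across the 27–61.5 y age range, Gaussian noise sd 0.03):

```python
from semenmeth import (SimulationConfig, simulate_cohort, deconvolve_all,
                       build_factor_matrix, MultifactorModel, SiteSelector)

cfg = SimulationConfig(n_samples=80, seed=7, noise_model="gaussian",
                       gaussian_sd=0.03, age_frac_negative=1.0)
cohort = simulate_cohort(cfg)

comp = deconvolve_all(cohort.matrix, cohort.reference)
X, pruned = build_factor_matrix(
    cohort.truth.phenotypes, comp,
    ["age", "sperm", "prostate_epithelium", "T_lymphocyte", "granulocyte"],
    pinned=["age", "sperm"])
print("factors:", X.factor_names)

model = MultifactorModel().fit(X, cohort.matrix.values)
print(model.loocv(X, cohort.matrix.values).stats.round(3))

res = SiteSelector().fit(X, cohort.matrix.values, model=model).select("age")
print(f"age sites: {len(res.selected)} selected "
      f"({len(res.negative)} negative, {len(res.positive)} positive)")
```

Output:

```
factors: ['constant', 'batch', 'age', 'sperm', 'prostate_epithelium', 'T_lymphocyte']
                         r    p    mae   n
age                  0.994  0.0  1.311  80
sperm                1.000  0.0  0.001  80
prostate_epithelium  1.000  0.0  0.001  80
T_lymphocyte         1.000  0.0  0.001  80
age sites: 199 selected (198 negative, 1 positive)
```

The granulocyte composition is dropped automatically because a complete
set of simplex-normalised compositions is collinear with the constant term.
LOOCV predicts age with `r = 0.994` and a mean absolute error of 1.3 years
on this cohort, and the site selector recovers the planted age sites with
the correct (negative) coefficient sign for all but one boundary case.

The same analysis runs from the shell:

```bash
semenmeth simulate --profile semen --seed 7 --out fixtures/
semenmeth run --config run.yaml --out results/
semenmeth select --matrix m.tsv --factors f.tsv --out sel/
```

where `run.yaml` points at a CGmap directory, a phenotype table, a
reference methylome, and an optional panel BED (see
`semenmeth.pipeline.RunConfig` for all parameters).

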