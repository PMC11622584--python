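"""Synthetic cohorts for end-to-end verification of the pipeline.

Generates reference cell-type methylomes, mixed bulk samples with known
compositions, ages, and batch labels, planted linear age and batch effects,
and binomial read-sampling noise at targeted-bisulfite coverage — together
with the ground truth needed for parameter-recovery tests.

Generative model, per sample i and site j:

    mu_ij = sum_t w_it * R_jt  +  s_j * a_i * [j planted for age]
                              +  d   * b_i * [j planted for batch]

with compositions w_i ~ Dirichlet(alpha), scaled age a_i in [0, 1], batch
indicator b_i, per-site slope s_j (sign and magnitude recorded in the
truth tables), and mu clamped to [0, 1]. Observed reads are
c_ij ~ Poisson(mean coverage) and  m_ij ~ Binomial(c_ij, mu_ij); the level
is m/c, and entries with c below the coverage floor are missing. A Gaussian
jitter on mu is available for noise-model stress tests. Every draw is
controlled by the config seed.

What this emulates: mixtures of distinct cell-type methylomes, age-linked
linear drift, a two-batch additive shift, count noise at ~74x coverage, and
dropout below 40x. What it does not: read alignment, bisulfite conversion
error, genomic correlation between neighbouring CpGs, or realistic
coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deconvolution import write_reference
from .io import ConfigurationError, CpGSite, MethylationMatrix, write_sites_bed

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "simulate_reference",
    "simulate_cohort",
    "export_fixtures",
]

SEMEN_CELL_TYPES = ("sperm", "prostate_epithelium", "T_lymphocyte", "granulocyte")
BUCCAL_CELL_TYPES = ("epithelial", "T_lymphocyte", "granulocyte")
# sperm-dominant vs epithelial-dominant mixing priors
SEMEN_ALPHA = (10.0, 3.0, 1.5, 1.5)
BUCCAL_ALPHA = (12.0, 2.0, 2.0)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; the seed fully determines output."""

    n_samples: int = 40
    n_sites: int = 2000
    cell_types: tuple[str, ...] = SEMEN_CELL_TYPES
    delta: float = 0.3  # required pairwise mean |Δmethylation| between references
    composition_alpha: tuple[float, ...] = SEMEN_ALPHA
    n_zero_sperm: int = 0  # azoospermia-like samples (first cell type zeroed)
    age_range: tuple[float, float] = (27.0, 61.5)
    n_age_sites: int = 200
    age_slope: float = 0.1  # |Δmethylation| across the full age range
    age_frac_negative: float = 0.8  # demethylation with age predominates
    n_batch_sites: int = 100
    batch_shift: float = 0.05
    mean_coverage: float = 74.0
    coverage_floor: int = 40
    noise_model: str = "binomial"  # "binomial" | "gaussian" | "none"
    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ConfigurationError("need at least two cell types")
        if len(self.composition_alpha) != len(self.cell_types):
            raise ConfigurationError(
                "composition_alpha must match cell_types in length"
            )
        if not 0 < self.delta <= 1:
            raise ConfigurationError("delta must be in (0, 1]")
        if self.noise_model not in ("binomial", "gaussian", "none"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if self.age_range[1] <= self.age_range[0]:
            raise ConfigurationError("age_range must be increasing")
        if self.n_age_sites + self.n_batch_sites > self.n_sites:
            raise ConfigurationError("more planted sites than panel sites")

    @classmethod
    def semen(cls, **overrides) -> "SimulationConfig":
        return cls(**overrides)

    @classmethod
    def buccal(cls, **overrides) -> "SimulationConfig":
        overrides.setdefault("cell_types", BUCCAL_CELL_TYPES)
        overrides.setdefault("composition_alpha", BUCCAL_ALPHA)
        return cls(**overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cell_types"] = list(self.cell_types)
        d["composition_alpha"] = list(self.composition_alpha)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("cell_types", "composition_alpha", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth: DNA-proportion compositions, phenotypes, planted sites."""

    compositions: pd.DataFrame  # samples x cell types, rows sum to 1
    phenotypes: pd.DataFrame  # sample-indexed: age, batch
    planted_sites: pd.DataFrame  # site-indexed: factor, sign, slope


@dataclass
class SyntheticCohort:
    matrix: MethylationMatrix  # observed levels; NaN below the coverage floor
    meth_counts: pd.DataFrame  # methylated read counts (binomial model)
    reference: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig

    @property
    def sites(self) -> list[CpGSite]:
        return self.matrix.sites()


def _site_ids(n_sites: int) -> list[str]:
    # synthetic coordinates: 1000 sites per chromosome, 10 bp apart
    return [f"chr{j // 1000 + 1}:{1000 + 10 * (j % 1000)}" for j in range(n_sites)]


def _block_size(config: SimulationConfig) -> int:
    # discriminating sites differ by 0.84-0.96 (mean 0.90) between the
    # flipped type and the rest; a pair of columns differs at both types'
    # blocks, so 2 * block * 0.90 / n_sites >= delta, plus 5% headroom
    return int(np.ceil(1.05 * config.delta * config.n_sites / 1.8))


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a reference methylome with pairwise mean |Δ| >= delta.

    Sites share a bimodal background level across cell types except in
    per-type discriminating blocks, where one type sits at the opposite
    methylation extreme. Block size is chosen so every pair of columns
    differs by at least delta on average, which is verified before return.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    n_types = len(config.cell_types)
    n = config.n_sites
    block = _block_size(config)
    if n_types * block > n:
        raise ConfigurationError(
            f"delta={config.delta} needs {n_types * block} discriminating "
            f"sites but the panel has only {n}"
        )
    # background: half bimodal CpGs, half intermediate "dynamic" CpGs, the
    # latter emulating the EWAS/clock probes a targeted panel is enriched for
    base = np.where(
        rng.random(n) < 0.5,
        rng.uniform(0.2, 0.8, size=n),
        rng.beta(0.4, 0.4, size=n),
    )
    values = np.tile(base[:, None], (1, n_types))
    for t in range(n_types):
        lo, hi = t * block, (t + 1) * block
        extreme = rng.uniform(0.02, 0.08, size=block)
        flip = rng.random(block) < 0.5
        others = np.where(flip, extreme, 1 - extreme)
        values[lo:hi, :] = others[:, None]
        values[lo:hi, t] = 1 - others
    ref = pd.DataFrame(
        values, index=_site_ids(n), columns=list(config.cell_types)
    )
    for a in range(n_types):
        for b in range(a + 1, n_types):
            gap = float(np.abs(values[:, a] - values[:, b]).mean())
            if gap < config.delta:
                raise ConfigurationError(
                    f"reference columns {a},{b} separated by only {gap:.3f} "
                    f"< delta={config.delta}"
                )
    return ref


def simulate_cohort(
    config: SimulationConfig, reference: pd.DataFrame | None = None
) -> SyntheticCohort:
    """Generate the observed cohort and its ground truth."""
    if reference is None:
        reference = simulate_reference(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    n, n_sites = config.n_samples, config.n_sites
    site_ids = list(reference.index)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    types = list(config.cell_types)

    W = rng.dirichlet(config.composition_alpha, size=n)
    for i in range(min(config.n_zero_sperm, n)):
        W[i, 0] = 0.0
        W[i] /= W[i].sum()
    ages = rng.uniform(*config.age_range, size=n)
    batch = np.zeros(n, dtype=int)
    batch[rng.permutation(n)[: n // 2]] = 1

    mu = W @ reference.to_numpy().T  # samples x sites mixture means

    # plant effects outside the reference's discriminating blocks so the
    # age signal is orthogonal to the cell-type signal, preferring
    # intermediate-methylation sites where a drift of the full slope can be
    # expressed without clamping at 0 or 1
    blocked = _block_size(config) * len(types)
    free = np.arange(blocked, n_sites)
    n_planted = config.n_age_sites + config.n_batch_sites
    ref0 = reference.to_numpy()[:, 0]
    mid = free[(ref0[free] >= 0.2) & (ref0[free] <= 0.8)] if len(free) else free
    if len(mid) >= n_planted:
        pool = mid
    elif len(free) >= n_planted:
        pool = free
    else:
        pool = np.arange(n_sites)
    chosen = rng.choice(pool, size=n_planted, replace=False)
    age_idx = np.sort(chosen[: config.n_age_sites])
    batch_idx = np.sort(chosen[config.n_age_sites :])

    signs = np.where(
        rng.random(config.n_age_sites) < config.age_frac_negative, -1.0, 1.0
    )
    scaled_age = (ages - config.age_range[0]) / (
        config.age_range[1] - config.age_range[0]
    )
    mu[:, age_idx] += scaled_age[:, None] * (signs * config.age_slope)[None, :]
    mu[:, batch_idx] += batch[:, None] * config.batch_shift
    if config.gaussian_sd > 0:
        mu += rng.normal(0.0, config.gaussian_sd, size=mu.shape)
    mu = np.clip(mu, 0.0, 1.0)

    if config.noise_model == "binomial":
        coverage = rng.poisson(config.mean_coverage, size=mu.shape)
        meth = rng.binomial(coverage, mu)
        with np.errstate(invalid="ignore"):
            levels = np.where(coverage > 0, meth / np.maximum(coverage, 1), np.nan)
        levels = np.where(coverage >= config.coverage_floor, levels, np.nan)
    else:
        coverage = np.full(mu.shape, int(round(config.mean_coverage)), dtype=int)
        levels = mu
        meth = np.rint(mu * coverage).astype(int)

    values = pd.DataFrame(levels, index=sample_ids, columns=site_ids)
    cov_df = pd.DataFrame(coverage, index=sample_ids, columns=site_ids)
    planted = pd.DataFrame(
        {
            "factor": ["age"] * len(age_idx) + ["batch"] * len(batch_idx),
            "sign": [("neg" if s < 0 else "pos") for s in signs]
            + ["pos"] * len(batch_idx),
            "slope": list(signs * config.age_slope)
            + [config.batch_shift] * len(batch_idx),
        },
        index=[site_ids[j] for j in np.concatenate([age_idx, batch_idx])],
    )
    truth = SyntheticTruth(
        compositions=pd.DataFrame(W, index=sample_ids, columns=types),
        phenotypes=pd.DataFrame(
            {"age": ages, "batch": batch, "tissue": "synthetic"},
            index=pd.Index(sample_ids, name="sample"),
        ),
        planted_sites=planted.rename_axis("site"),
    )
    return SyntheticCohort(
        matrix=MethylationMatrix(values, cov_df),
        meth_counts=pd.DataFrame(meth, index=sample_ids, columns=site_ids),
        reference=reference,
        truth=truth,
        config=config,
    )


def export_fixtures(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Write CGmap files, phenotypes, reference, truth tables, and manifest.

    CGmap lines are emitted only for entries at or above the coverage floor,
    mirroring what the matrix retains; re-reading the files and aggregating
    reproduces the cohort matrix exactly at those entries.
    """
    directory = Path(directory)
    cgmap_dir = directory / "cgmaps"
    cgmap_dir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    values = cohort.matrix.values
    coverage = cohort.matrix.coverage
    meth = cohort.meth_counts
    for sample in values.index:
        with (cgmap_dir / f"{sample}.cgmap").open("w") as fh:
            for sid in values.columns:
                cov = int(coverage.loc[sample, sid])
                if cov < cfg.coverage_floor:
                    continue
                m = int(meth.loc[sample, sid])
                chrom, _, pos = sid.rpartition(":")
                fh.write(
                    f"{chrom}\tC\t{pos}\tCG\tCG\t{m / cov:.6f}\t{m}\t{cov}\n"
                )
    cohort.truth.phenotypes.to_csv(directory / "phenotypes.tsv", sep="\t")
    write_reference(cohort.reference, directory / "reference.tsv")
    cohort.truth.compositions.to_csv(
        directory / "truth_compositions.tsv", sep="\t", index_label="sample"
    )
    cohort.truth.planted_sites.to_csv(directory / "truth_sites.tsv", sep="\t")
    write_sites_bed(cohort.sites, None, directory / "panel.bed")
    manifest = {"simulation": cfg.to_dict()}
    with (directory / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return directory
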