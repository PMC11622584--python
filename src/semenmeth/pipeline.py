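"""Config-driven orchestration of the full methylome analysis.

Stages: ingest CGmap files -> coverage filter + kNN imputation -> NNLS
cell-type deconvolution -> factor-matrix assembly with collinearity
pruning -> pseudoinverse multifactor fit with LOOCV -> per-site scoring and
three-filter site selection -> exports (tables, per-factor/sign BED files,
run log). Two built-in tissue profiles encode the semen and buccal factor
sets; arbitrary factor lists can be given in the config.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deconvolution import (
    NNLSDeconvolver,
    read_reference,
    write_composition,
)
from .io import (
    ConfigurationError,
    CpGSite,
    aggregate_matrix,
    knn_impute,
    read_cgmap,
    read_panel_bed,
    write_matrix,
    write_sites_bed,
)
from .multifactor import MultifactorModel, build_factor_matrix
from .selection import SiteSelector

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "TISSUE_PROFILES"]

logger = logging.getLogger("semenmeth")

#: per-tissue factor sets; the composition factor of interest is pinned
#: alongside age so collinear nuisance compositions are the ones pruned
TISSUE_PROFILES: dict[str, dict] = {
    "semen": {
        "factors": [
            "age",
            "sperm",
            "prostate_epithelium",
            "T_lymphocyte",
            "granulocyte",
        ],
        "pinned": ["age", "sperm"],
    },
    "buccal": {
        "factors": ["age", "epithelial", "T_lymphocyte", "granulocyte"],
        "pinned": ["age", "epithelial"],
    },
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and exit code."""

    def __init__(self, stage: str, exit_code: int, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = exit_code
        self.cause = cause


STAGES = ("ingest", "deconvolve", "factors", "model", "select", "export")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    tissue: str = "semen"
    cgmap_dir: str | Path = ""
    phenotypes: str | Path = ""
    reference: str | Path = ""
    panel_bed: str | Path | None = None
    out_dir: str | Path = "run"
    min_coverage: int = 40
    k: int = 5
    prune_threshold: float = 0.7
    r_min: float = 0.5
    q_max: float = 0.05
    cap: int = 200
    normalize: bool = True
    factors: list[str] | None = None
    pinned: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_PROFILES:
            raise ConfigurationError(
                f"unknown tissue profile {self.tissue!r}; "
                f"choose from {sorted(TISSUE_PROFILES)}"
            )
        for name, lo, hi in (
            ("min_coverage", 1, None),
            ("k", 1, None),
            ("prune_threshold", 0.0, 1.0),
            ("r_min", 0.0, 1.0),
            ("q_max", 0.0, 1.0),
            ("cap", 1, None),
        ):
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ConfigurationError(f"{name}={v} out of range")

    def validate_paths(self) -> None:
        for name in ("cgmap_dir", "phenotypes", "reference"):
            p = Path(getattr(self, name))
            if not str(p) or not p.exists():
                raise ConfigurationError(f"{name} path {p} does not exist")
        if self.panel_bed is not None and not Path(self.panel_bed).exists():
            raise ConfigurationError(f"panel_bed path {self.panel_bed} missing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def profile(self) -> dict:
        prof = TISSUE_PROFILES[self.tissue]
        return {
            "factors": self.factors or prof["factors"],
            "pinned": self.pinned or prof["pinned"],
        }


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    On failure the partial outputs are retained next to a FAILED marker file
    naming the stage, and a :class:`PipelineError` is raised.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out)
    stage = STAGES[0]
    try:
        logger.info(
            "semenmeth %s | tissue=%s seed=%d | %s",
            __version__,
            config.tissue,
            config.seed,
            {k: v for k, v in dataclasses.asdict(config).items()},
        )

        stage = "ingest"
        cgmap_dir = Path(config.cgmap_dir)
        files = sorted(cgmap_dir.glob("*.cgmap")) + sorted(
            cgmap_dir.glob("*.CGmap")
        )
        if not files:
            raise ConfigurationError(f"no CGmap files under {cgmap_dir}")
        records = {f.stem: read_cgmap(f) for f in files}
        panel = read_panel_bed(config.panel_bed) if config.panel_bed else None
        matrix = aggregate_matrix(records, config.min_coverage, panel)
        logger.info(
            "ingest: %d samples x %d sites (min_coverage=%d)",
            len(matrix.sample_ids),
            len(matrix.site_ids),
            config.min_coverage,
        )
        matrix = knn_impute(matrix, k=config.k)
        write_matrix(matrix, out / "methylation_matrix.tsv")

        stage = "deconvolve"
        reference = read_reference(config.reference)
        deconvolver = NNLSDeconvolver(normalize=config.normalize).fit(reference)
        composition = deconvolver.deconvolve(matrix)
        write_composition(composition, out / "composition.tsv")
        logger.info("deconvolve: cell types %s", composition.cell_types)

        stage = "factors"
        phenotypes = pd.read_csv(
            config.phenotypes, sep="\t", index_col="sample"
        )
        phenotypes.index = phenotypes.index.astype(str)
        prof = config.profile()
        available = set(phenotypes.columns) | set(composition.cell_types)
        requested = [f for f in prof["factors"] if f in available]
        missing = [f for f in prof["factors"] if f not in available]
        if missing:
            logger.info("factors: skipping unavailable factors %s", missing)
        X, pruning = build_factor_matrix(
            phenotypes.loc[matrix.sample_ids],
            composition,
            requested,
            prune_threshold=config.prune_threshold,
            pinned=prof["pinned"],
        )
        X.values.to_csv(out / "factor_matrix.tsv", sep="\t", index_label="sample")
        pd.DataFrame(pruning).to_csv(
            out / "pruning_report.tsv", sep="\t", index=False
        )
        logger.info(
            "factors: retained %s; pruned %s",
            X.factor_names,
            [p["dropped"] for p in pruning],
        )

        stage = "model"
        model = MultifactorModel().fit(X, matrix)
        fullfit = model.evaluate_fullfit(X)
        fullfit.to_csv(out / "fullfit_report.tsv", sep="\t", index_label="factor")
        report = model.loocv(X, matrix)
        report.stats.to_csv(out / "loocv_report.tsv", sep="\t", index_label="factor")
        report.predictions.to_csv(
            out / "loocv_predictions.tsv", sep="\t", index_label="sample"
        )
        logger.info("model: LOOCV stats\n%s", report.stats.to_string())

        stage = "select"
        selector = SiteSelector(
            r_min=config.r_min, q_max=config.q_max, cap=config.cap
        ).fit(X, matrix, model=model)
        results = selector.select_all()

        stage = "export"
        for factor, res in results.items():
            res.table.to_csv(
                out / f"sites_{factor}.tsv", sep="\t", index_label="site"
            )
            logger.info(
                "select: %s -> %d sites (%d pre-cap; cap=%d; +%d/-%d)",
                factor,
                len(res.selected),
                res.pre_cap_count,
                config.cap,
                len(res.positive),
                len(res.negative),
            )
            for sign, ids in (("pos", res.positive), ("neg", res.negative)):
                if not ids:
                    continue
                sites = [
                    CpGSite(sid.rpartition(":")[0], int(sid.rpartition(":")[2]))
                    for sid in ids
                ]
                write_sites_bed(
                    sites, [sign] * len(sites), out / f"sites_{factor}_{sign}.bed"
                )
        logger.info("run complete: %s", out)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, 10 + STAGES.index(stage), exc) from exc
    finally:
        handler.close()
        logger.removeHandler(handler)
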