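"""CGmap ingestion and methylation-matrix assembly.

Reads per-cytosine methylation calls in the CGmap dialect emitted by
BSBolt/BS-Seeker2 (chrom, C/G nucleotide, 1-based position, context,
sub-context, methylation ratio, methylated reads, total reads), merges
strand-symmetric CpG calls onto the C-strand coordinate, applies a minimum
read-depth filter, and assembles a samples x sites methylation matrix with
missing entries imputed across samples by k nearest neighbours.

Matrices are plain pandas DataFrames: rows are sample ids, columns are site
ids of the form ``"chrom:pos"``, values are methylation fractions in [0, 1].
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer

__all__ = [
    "CpGSite",
    "MethylationRecord",
    "MethylationMatrix",
    "CGmapParseError",
    "ConfigurationError",
    "MethylationDataError",
    "read_cgmap",
    "aggregate_matrix",
    "knn_impute",
    "KNNSampleImputer",
    "write_sites_bed",
    "write_matrix",
    "read_matrix",
    "read_panel_bed",
    "natural_site_key",
]


class CGmapParseError(ValueError):
    """A CGmap line could not be parsed."""


class ConfigurationError(ValueError):
    """A parameter or configuration value is invalid."""


class MethylationDataError(ValueError):
    """Input data violates a methylation-domain invariant."""


_CHROM_CHUNKS = re.compile(r"(\d+)")


def natural_site_key(site_id: str) -> tuple:
    """Sort key ordering sites by (chromosome natural order, position).

    "chr2:5" sorts before "chr10:1"; position is compared numerically.
    """
    chrom, _, pos = site_id.rpartition(":")
    chrom_key = tuple(
        int(c) if c.isdigit() else c for c in _CHROM_CHUNKS.split(chrom)
    )
    return (chrom_key, int(pos))


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide addressed by its C-strand cytosine coordinate."""

    chrom: str
    pos: int  # 1-based

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def sort_key(self) -> tuple:
        return natural_site_key(self.id)


@dataclass(frozen=True)
class MethylationRecord:
    """One CpG methylation call: counts and the derived level."""

    site: CpGSite
    meth_reads: int
    total_reads: int
    level: float

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise MethylationDataError(
                f"{self.site.id}: total_reads must be positive"
            )
        if self.meth_reads < 0 or self.meth_reads > self.total_reads:
            raise MethylationDataError(
                f"{self.site.id}: meth_reads {self.meth_reads} outside "
                f"[0, {self.total_reads}]"
            )
        if abs(self.level - self.meth_reads / self.total_reads) > 1e-6:
            raise MethylationDataError(
                f"{self.site.id}: level inconsistent with counts"
            )


@dataclass
class MethylationMatrix:
    """Samples x sites methylation fractions with optional per-entry coverage.

    ``values``: DataFrame indexed by sample id, columns are site ids; NaN
    marks entries below the coverage threshold (before imputation).
    ``coverage``: same shape, integer read depth (0 where unobserved); may be
    None after imputation or when loaded from disk.
    """

    values: pd.DataFrame
    coverage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise MethylationDataError("methylation values outside [0, 1]")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise MethylationDataError("duplicate sample or site labels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.columns)

    def sites(self) -> list[CpGSite]:
        out = []
        for sid in self.values.columns:
            chrom, _, pos = sid.rpartition(":")
            out.append(CpGSite(chrom, int(pos)))
        return out


def read_cgmap(
    path: str | Path, context_filter: str = "CG"
) -> list[MethylationRecord]:
    """Parse a CGmap file, keeping calls in the requested context.

    G-strand calls (column 2 == "G") are mapped to the C-strand coordinate
    (pos - 1) so that both strands of a CpG share one site id. The stored
    methylation ratio column is ignored in favour of the read counts; a
    discrepancy beyond 1e-3 triggers a warning.
    """
    records: list[MethylationRecord] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (7, 8):
                raise CGmapParseError(
                    f"{path.name}:{lineno}: expected 7-8 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, nuc, pos_s, context = fields[0], fields[1], fields[2], fields[3]
            ratio_s, meth_s, total_s = fields[-3], fields[-2], fields[-1]
            if context != context_filter:
                continue
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                total = int(total_s)
                ratio = float(ratio_s)
            except ValueError as exc:
                raise CGmapParseError(
                    f"{path.name}:{lineno}: non-numeric field ({exc})"
                ) from exc
            if meth > total:
                raise MethylationDataError(
                    f"{path.name}:{lineno}: methylated reads ({meth}) exceed "
                    f"total reads ({total})"
                )
            if total <= 0:
                raise MethylationDataError(
                    f"{path.name}:{lineno}: non-positive total read count"
                )
            if nuc == "G":
                pos -= 1  # symmetric CpG: report on the C strand
            level = meth / total
            if abs(level - ratio) > 1e-3:
                warnings.warn(
                    f"{path.name}:{lineno}: stored ratio {ratio} disagrees "
                    f"with counts {meth}/{total}; using counts",
                    stacklevel=2,
                )
            records.append(
                MethylationRecord(CpGSite(chrom, pos), meth, total, level)
            )
    return records


def aggregate_matrix(
    records_by_sample: Mapping[str, Iterable[MethylationRecord]],
    min_coverage: int = 40,
    panel: Sequence[CpGSite] | None = None,
) -> MethylationMatrix:
    """Assemble the coverage-filtered methylation matrix.

    Counts of records sharing a site within a sample (the two CpG strands)
    are summed before filtering. An entry is the methylation level when the
    summed depth reaches ``min_coverage``, else missing. Sites outside the
    panel are dropped, as are sites missing in every sample. Rows and columns
    are sorted (samples by id, sites by chromosome natural order then
    position) so downstream fits are deterministic.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    panel_ids = None
    if panel is not None:
        if not panel:
            raise ValueError("panel must be non-empty")
        panel_ids = {s.id for s in panel}

    meth_counts: dict[str, dict[str, int]] = {}
    total_counts: dict[str, dict[str, int]] = {}
    for sample, records in records_by_sample.items():
        m = meth_counts.setdefault(sample, {})
        t = total_counts.setdefault(sample, {})
        for rec in records:
            sid = rec.site.id
            if panel_ids is not None and sid not in panel_ids:
                continue
            m[sid] = m.get(sid, 0) + rec.meth_reads
            t[sid] = t.get(sid, 0) + rec.total_reads

    observed_sites = set().union(*total_counts.values()) if total_counts else set()
    if panel_ids is not None and not observed_sites:
        raise MethylationDataError(
            "no observed sites intersect the target panel"
        )
    site_order = sorted(observed_sites, key=natural_site_key)
    sample_order = sorted(records_by_sample)

    values = np.full((len(sample_order), len(site_order)), np.nan)
    coverage = np.zeros((len(sample_order), len(site_order)), dtype=int)
    col = {sid: j for j, sid in enumerate(site_order)}
    for i, sample in enumerate(sample_order):
        t = total_counts[sample]
        m = meth_counts[sample]
        for sid, tot in t.items():
            j = col[sid]
            coverage[i, j] = tot
            if tot >= min_coverage:
                values[i, j] = m[sid] / tot

    vdf = pd.DataFrame(values, index=sample_order, columns=site_order)
    cdf = pd.DataFrame(coverage, index=sample_order, columns=site_order)
    keep = vdf.notna().any(axis=0)
    if not keep.any():
        raise MethylationDataError(
            "no site passes the coverage filter in any sample"
        )
    return MethylationMatrix(vdf.loc[:, keep], cdf.loc[:, keep])


class KNNSampleImputer(BaseEstimator, TransformerMixin):
    """Impute missing methylation entries from the k nearest samples.

    Neighbours are other samples (rows); a missing entry (s, j) is filled
    with the mean of the k nearest samples' values at site j, with distances
    computed over mutually observed sites. Imputed values stay in [0, 1]
    because they are means of values in [0, 1].

    Parameters
    ----------
    k : int, default 5
        Number of neighbouring samples averaged per missing entry.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y=None):
        values = X.values if isinstance(X, MethylationMatrix) else X
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.k >= values.shape[0]:
            raise ConfigurationError(
                f"k={self.k} must be smaller than the number of samples "
                f"({values.shape[0]})"
            )
        if values.isna().all(axis=0).any():
            raise MethylationDataError(
                "cannot impute a site that is missing in every sample"
            )
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        values = X.values if isinstance(X, MethylationMatrix) else X
        if not values.isna().to_numpy().any():
            return values.copy()
        imputer = KNNImputer(n_neighbors=self.k, weights="uniform")
        out = imputer.fit_transform(values.to_numpy(dtype=float))
        return pd.DataFrame(out, index=values.index, columns=values.columns)


def knn_impute(matrix: MethylationMatrix, k: int = 5) -> MethylationMatrix:
    """Functional wrapper over :class:`KNNSampleImputer`."""
    imputer = KNNSampleImputer(k=k).fit(matrix)
    return MethylationMatrix(imputer.transform(matrix), matrix.coverage)


def write_sites_bed(
    sites: Sequence[CpGSite],
    signs: Sequence[str] | None,
    path: str | Path,
) -> None:
    """Write CpG sites as a sorted BED3+1 file.

    Intervals are 0-based half-open of length 2, covering the CpG
    dinucleotide; the fourth column carries the sign label ("pos"/"neg").
    """
    if not sites:
        raise ValueError("cannot write an empty site list")
    if signs is None:
        signs = ["."] * len(sites)
    if len(signs) != len(sites):
        raise ValueError("signs must match sites in length")
    rows = sorted(zip(sites, signs), key=lambda r: r[0].sort_key())
    with Path(path).open("w") as fh:
        for site, sign in rows:
            fh.write(f"{site.chrom}\t{site.pos - 1}\t{site.pos + 1}\t{sign}\n")


def read_panel_bed(path: str | Path) -> list[CpGSite]:
    """Read a target-panel BED file into CpG sites.

    Each interval's first base is taken as the cytosine: a BED line
    ``chrom  99  101`` denotes the CpG at 1-based position 100.
    """
    sites = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            sites.append(CpGSite(fields[0], int(fields[1]) + 1))
    return sorted(set(sites), key=lambda s: s.sort_key())


def write_matrix(matrix: MethylationMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write a methylation matrix as TSV: sites as rows, samples as columns."""
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    values.T.to_csv(path, sep="\t", index_label="site", na_rep="NA")


def read_matrix(path: str | Path) -> MethylationMatrix:
    """Read a TSV matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="site", na_values="NA")
    return MethylationMatrix(df.T.rename_axis(index=None, columns=None))
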