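"""Reference-based cell-type deconvolution by non-negative least squares.

A bulk methylation profile is modelled as a non-negative mixture of
reference cell-type methylomes: for sample vector m over the shared sites
and reference matrix R (sites x cell types), the composition estimate is

    w_hat = argmin_{w >= 0} || R w - m ||_2

optionally renormalised to sum to one. The weights are DNA-proportion
estimates, not cell-count fractions: haploid sperm contribute half as much
DNA per cell as diploid somatic cells, so a sperm DNA fraction understates
the sperm cell fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .io import MethylationDataError, MethylationMatrix, natural_site_key

__all__ = [
    "CellComposition",
    "NNLSDeconvolver",
    "build_reference",
    "deconvolve_sample",
    "deconvolve_all",
    "write_composition",
    "read_reference",
    "write_reference",
]

MIN_SHARED_SITES = 50


@dataclass
class CellComposition:
    """Per-sample cell-type fractions with the NNLS residual norm.

    ``fractions``: samples x cell types; non-negative, summing to one per
    sample when normalisation was enabled. ``residual_norm``: per-sample
    Euclidean norm of the NNLS residual. ``raw_weights`` retains the
    unnormalised NNLS solution.
    """

    fractions: pd.DataFrame
    residual_norm: pd.Series
    raw_weights: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)


def build_reference(
    replicate_profiles: Mapping[str, Sequence[pd.Series]],
    panel: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average replicate methylomes into one reference column per cell type.

    Each cell type's profile is the unweighted mean of its replicates,
    restricted to the sites present in all replicates of all types and, if
    given, in the panel. Returns a sites x cell-types DataFrame.
    """
    if not replicate_profiles:
        raise ValueError("no replicate profiles supplied")
    common: set[str] | None = None
    for reps in replicate_profiles.values():
        if not reps:
            raise ValueError("each cell type needs at least one replicate")
        for rep in reps:
            idx = set(rep.dropna().index)
            common = idx if common is None else common & idx
    if panel is not None:
        common &= set(panel)
    if common is None or len(common) < MIN_SHARED_SITES:
        raise MethylationDataError(
            f"only {0 if common is None else len(common)} sites shared across "
            f"reference replicates; need >= {MIN_SHARED_SITES} to deconvolve"
        )
    sites = sorted(common, key=natural_site_key)
    cols = {}
    for cell_type, reps in replicate_profiles.items():
        stacked = pd.concat([rep.loc[sites] for rep in reps], axis=1)
        cols[cell_type] = stacked.mean(axis=1)
    ref = pd.DataFrame(cols, index=sites)
    if (ref.to_numpy() < -1e-12).any() or (ref.to_numpy() > 1 + 1e-12).any():
        raise MethylationDataError("reference methylation outside [0, 1]")
    return ref


class NNLSDeconvolver(BaseEstimator, TransformerMixin):
    """Estimate cell-type compositions by NNLS against a reference methylome.

    Parameters
    ----------
    normalize : bool, default True
        Rescale each sample's non-negative weights to sum to one. The raw
        weights are kept in the returned :class:`CellComposition`.
    min_shared_sites : int, default 50
        Minimum number of sites shared between a sample (non-missing) and
        the reference; below this the fit is refused as underdetermined.

    Attributes
    ----------
    reference_ : pd.DataFrame
        Sites x cell types reference methylome the transformer was fit on.
    cell_types_ : list of str
    """

    def __init__(self, normalize: bool = True, min_shared_sites: int = MIN_SHARED_SITES):
        self.normalize = normalize
        self.min_shared_sites = min_shared_sites

    def fit(self, reference: pd.DataFrame, y=None):
        ref = reference.astype(float)
        arr = ref.to_numpy()
        if np.isnan(arr).any():
            raise MethylationDataError("reference contains missing values")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise MethylationDataError("reference methylation outside [0, 1]")
        for a in range(ref.shape[1]):
            for b in range(a + 1, ref.shape[1]):
                if np.allclose(arr[:, a], arr[:, b]):
                    raise MethylationDataError(
                        f"reference columns {ref.columns[a]!r} and "
                        f"{ref.columns[b]!r} are identical"
                    )
        self.reference_ = ref
        self.cell_types_ = list(ref.columns)
        return self

    def deconvolve_sample(self, levels: pd.Series) -> tuple[np.ndarray, np.ndarray, float]:
        """NNLS fit of one sample; returns (weights, fractions, residual norm)."""
        shared = self.reference_.index.intersection(levels.dropna().index)
        if len(shared) < self.min_shared_sites:
            raise MethylationDataError(
                f"only {len(shared)} sites shared with the reference; "
                f"need >= {self.min_shared_sites}"
            )
        R = self.reference_.loc[shared].to_numpy()
        m = levels.loc[shared].to_numpy(dtype=float)
        w, rnorm = nnls(R, m)
        if self.normalize:
            total = w.sum()
            if total <= 0:
                raise MethylationDataError(
                    "degenerate NNLS fit: all cell-type weights are zero"
                )
            fractions = w / total
        else:
            fractions = w.copy()
        return w, fractions, rnorm

    def transform(self, X) -> pd.DataFrame:
        """Deconvolve every sample; returns the fractions DataFrame."""
        return self.deconvolve(X).fractions

    def deconvolve(self, X) -> CellComposition:
        """Row-wise deconvolution of a methylation matrix."""
        values = X.values if isinstance(X, MethylationMatrix) else X
        raws, fracs, rnorms = [], [], []
        for sample_id, row in values.iterrows():
            try:
                w, f, rnorm = self.deconvolve_sample(row)
            except MethylationDataError as exc:
                raise MethylationDataError(f"sample {sample_id!r}: {exc}") from exc
            raws.append(w)
            fracs.append(f)
            rnorms.append(rnorm)
        idx = values.index
        return CellComposition(
            fractions=pd.DataFrame(fracs, index=idx, columns=self.cell_types_),
            residual_norm=pd.Series(rnorms, index=idx, name="residual_norm"),
            raw_weights=pd.DataFrame(raws, index=idx, columns=self.cell_types_),
        )


def deconvolve_sample(
    sample_levels: pd.Series,
    reference: pd.DataFrame,
    normalize: bool = True,
) -> tuple[pd.Series, float]:
    """Deconvolve one sample; returns (per-cell-type fractions, residual norm)."""
    dec = NNLSDeconvolver(normalize=normalize).fit(reference)
    _, fractions, rnorm = dec.deconvolve_sample(sample_levels)
    return pd.Series(fractions, index=dec.cell_types_), rnorm


def deconvolve_all(
    matrix: MethylationMatrix | pd.DataFrame,
    reference: pd.DataFrame,
    normalize: bool = True,
) -> CellComposition:
    """Deconvolve every sample of a methylation matrix."""
    return NNLSDeconvolver(normalize=normalize).fit(reference).deconvolve(matrix)


def write_composition(composition: CellComposition, path) -> None:
    out = composition.fractions.copy()
    out["residual_norm"] = composition.residual_norm
    out.to_csv(path, sep="\t", index_label="sample")


def write_reference(reference: pd.DataFrame, path) -> None:
    reference.to_csv(path, sep="\t", index_label="site")


def read_reference(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")
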