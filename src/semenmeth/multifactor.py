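"""Pseudoinverse multivariate multiple regression (the multifactor model).

The model links a phenotype factor matrix X (samples x factors: constant,
batch indicator, age, cell-type compositions, each scaled to [0, 1]) to the
observed methylation matrix M (samples x sites):

    M = X . beta

The least-squares, minimum-norm coefficient matrix is obtained through the
Moore-Penrose pseudoinverse, beta = X+ . M. The model predicts in both
directions: methylation from factors, M_pred = X . beta, and factors from
methylation, X_pred = M . beta+, where beta+ is the pseudoinverse of beta.
Generalisation is assessed by leave-one-out cross-validation: each sample's
factor row is predicted from a coefficient matrix fitted on the remaining
samples, and predicted vs observed factors are compared by Pearson
correlation and by mean absolute error on the original (unscaled) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .deconvolution import CellComposition
from .io import ConfigurationError, MethylationDataError, MethylationMatrix

__all__ = [
    "FactorMatrix",
    "LoocvReport",
    "MultifactorModel",
    "build_factor_matrix",
    "fit",
    "loocv",
    "evaluate_fullfit",
]

CONSTANT = "constant"
BATCH = "batch"
#: factors never pruned, never reported on, never eligible for site assignment
NUISANCE_FACTORS = (CONSTANT, BATCH)


def default_pinv_cutoff(shape: tuple[int, int]) -> float:
    """SVD cutoff max(n, p) * machine epsilon, relative to the largest
    singular value."""
    return max(shape) * np.finfo(float).eps


def _pinv(a: np.ndarray, cutoff: float) -> np.ndarray:
    try:
        return np.linalg.pinv(a, rtol=cutoff)
    except TypeError:  # older numpy without the rtol keyword
        return np.linalg.pinv(a, rcond=cutoff)


@dataclass
class FactorMatrix:
    """Samples x factors design matrix with min-max scaling metadata.

    ``values`` holds a constant column of ones, a 0/1 batch column, and the
    substantive factors scaled into [0, 1]. ``scaling`` maps each factor to
    the (min, max) used, enabling inverse transformation to original units.
    """

    values: pd.DataFrame
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    pinned: tuple[str, ...] = ()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def substantive_factors(self) -> list[str]:
        return [f for f in self.values.columns if f not in NUISANCE_FACTORS]

    def unscale(self, factor: str, scaled: np.ndarray) -> np.ndarray:
        """Map [0, 1]-scaled values of a factor back to original units."""
        lo, hi = self.scaling.get(factor, (0.0, 1.0))
        return np.asarray(scaled) * (hi - lo) + lo


def _as_design(X) -> pd.DataFrame:
    return X.values if isinstance(X, FactorMatrix) else X


def _as_matrix(M) -> pd.DataFrame:
    return M.values if isinstance(M, MethylationMatrix) else M


def build_factor_matrix(
    phenotypes: pd.DataFrame,
    composition: CellComposition | pd.DataFrame | None,
    factors: Sequence[str],
    prune_threshold: float = 0.7,
    pinned: Sequence[str] = ("age",),
) -> tuple[FactorMatrix, list[dict]]:
    """Assemble, scale, and prune the multifactor design matrix.

    Factors are looked up first in ``phenotypes`` then in the cell-type
    ``composition``; each is min-max scaled to [0, 1]. To avoid
    multicollinearity, while any pair of substantive factors has
    |Pearson r| > ``prune_threshold``, the unpinned factor of a violating
    pair with the largest mean absolute correlation to the other factors is
    dropped; dropped factors are listed in the returned pruning report.
    A constant column and a 0/1 batch column (from the phenotype table's
    ``batch`` column) are appended after pruning.
    """
    if not factors:
        raise ConfigurationError("factor list must be non-empty")
    comp = composition.fractions if isinstance(composition, CellComposition) else composition
    sample_ids = list(phenotypes.index)
    if comp is not None:
        if set(comp.index) != set(sample_ids):
            raise MethylationDataError(
                "phenotype table and composition cover different samples"
            )
        comp = comp.loc[sample_ids]

    raw_cols: dict[str, np.ndarray] = {}
    comp_factors: list[str] = []
    for name in factors:
        if name in phenotypes.columns:
            raw_cols[name] = phenotypes[name].to_numpy(dtype=float)
        elif comp is not None and name in comp.columns:
            raw_cols[name] = comp[name].to_numpy(dtype=float)
            comp_factors.append(name)
        else:
            raise ConfigurationError(f"unknown factor {name!r}")

    report: list[dict] = []
    # A complete set of simplex-normalised compositions sums to one and is
    # exactly collinear with the constant column; drop the last-requested
    # composition (the least factor of interest) as a leave-one-out encoding.
    if len(comp_factors) >= 2:
        total = np.sum([raw_cols[f] for f in comp_factors], axis=0)
        if np.allclose(total, 1.0, atol=1e-6):
            droppable = [f for f in comp_factors if f not in pinned]
            drop = (droppable or comp_factors)[-1]
            del raw_cols[drop]
            report.append(
                {
                    "dropped": drop,
                    "with": "constant",
                    "max_abs_r": 1.0,
                    "mean_abs_r": np.nan,
                    "reason": "compositions complete the simplex",
                }
            )

    columns: dict[str, np.ndarray] = {}
    scaling: dict[str, tuple[float, float]] = {}
    for name, raw in raw_cols.items():
        lo, hi = float(np.min(raw)), float(np.max(raw))
        if hi - lo <= 0:
            raise ConfigurationError(
                f"factor {name!r} is constant; cannot scale or fit it"
            )
        columns[name] = (raw - lo) / (hi - lo)
        scaling[name] = (lo, hi)

    design = pd.DataFrame(columns, index=sample_ids)
    pinned = tuple(p for p in pinned if p in design.columns)
    while design.shape[1] > 1:
        corr = design.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.to_numpy().max() <= prune_threshold:
            break
        violating = {
            f
            for f in design.columns
            if corr.loc[f].max() > prune_threshold and f not in pinned
        }
        if not violating:
            break  # remaining collinearity is between pinned factors
        mean_abs = corr.mean(axis=1)
        drop = max(sorted(violating), key=lambda f: mean_abs[f])
        partner = corr.loc[drop].idxmax()
        report.append(
            {
                "dropped": drop,
                "with": partner,
                "max_abs_r": float(corr.loc[drop, partner]),
                "mean_abs_r": float(mean_abs[drop]),
                "reason": "pairwise correlation",
            }
        )
        design = design.drop(columns=[drop])

    out = pd.DataFrame(index=sample_ids)
    out[CONSTANT] = 1.0
    if "batch" in phenotypes.columns:
        labels = phenotypes["batch"]
        levels = sorted(pd.unique(labels))
        if len(levels) > 2:
            raise ConfigurationError(
                f"batch must have at most two levels, got {levels}"
            )
        if len(levels) == 2:  # single-batch cohorts get no indicator column
            out[BATCH] = labels.map(
                {lv: i for i, lv in enumerate(levels)}
            ).to_numpy(float)
    for name in design.columns:
        out[name] = design[name]
    return FactorMatrix(out, scaling, pinned), report


@dataclass
class LoocvReport:
    """Held-out factor predictions and per-factor accuracy statistics.

    ``predictions``: samples x factors, on the [0, 1] model scale.
    ``stats``: per substantive factor — Pearson r between predicted and
    observed (NaN when either side has zero variance), two-sided p-value
    (t-distribution, n - 2 df), and MAE on original units.
    """

    predictions: pd.DataFrame
    stats: pd.DataFrame


def _factor_stats(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    X: FactorMatrix | pd.DataFrame,
    factors: Sequence[str],
) -> pd.DataFrame:
    rows = {}
    for f in factors:
        obs = observed[f].to_numpy(dtype=float)
        pred = predicted[f].to_numpy(dtype=float)
        if np.std(obs) == 0 or np.std(pred) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(obs, pred)
        if isinstance(X, FactorMatrix):
            mae = float(np.mean(np.abs(X.unscale(f, pred) - X.unscale(f, obs))))
        else:
            mae = float(np.mean(np.abs(pred - obs)))
        rows[f] = {"r": float(r), "p": float(p), "mae": mae, "n": len(obs)}
    return pd.DataFrame(rows).T.astype({"n": int}, errors="ignore")


class MultifactorModel(BaseEstimator):
    """Multivariate multiple regression solved by Moore-Penrose pseudoinverse.

    Parameters
    ----------
    pinv_tolerance : float or None, default None
        Relative SVD cutoff for the pseudoinverse. None uses
        max(n, p) * machine epsilon.

    Attributes
    ----------
    beta_ : pd.DataFrame
        Coefficient matrix, factors x sites.
    beta_pinv_ : np.ndarray
        Pseudoinverse of beta (sites x factors), for factor prediction.
    M_pred_ : pd.DataFrame
        In-sample methylation prediction X . beta.
    X_pred_ : pd.DataFrame
        In-sample factor prediction M . beta+.
    """

    def __init__(self, pinv_tolerance: float | None = None):
        self.pinv_tolerance = pinv_tolerance

    # ------------------------------------------------------------------ fit
    def fit(self, X, M):
        Xdf = _as_design(X)
        Mdf = _as_matrix(M)
        Xv = Xdf.to_numpy(dtype=float)
        Mv = Mdf.to_numpy(dtype=float)
        if np.isnan(Mv).any():
            raise MethylationDataError(
                "methylation matrix contains missing values; impute first"
            )
        if np.isnan(Xv).any():
            raise MethylationDataError("factor matrix contains missing values")
        n, p = Xv.shape
        if n <= p:
            raise ConfigurationError(
                f"need more samples ({n}) than factors ({p})"
            )
        if np.linalg.matrix_rank(Xv) < 2:
            raise ConfigurationError("design matrix has rank < 2")
        cutoff = (
            self.pinv_tolerance
            if self.pinv_tolerance is not None
            else default_pinv_cutoff(Xv.shape)
        )
        self.pinv_tolerance_ = float(cutoff)
        self.X_pinv_ = _pinv(Xv, cutoff)
        beta = self.X_pinv_ @ Mv
        self.beta_ = pd.DataFrame(beta, index=Xdf.columns, columns=Mdf.columns)
        self.beta_pinv_ = _pinv(beta, default_pinv_cutoff(beta.shape))
        self.factor_names_ = list(Xdf.columns)
        self.site_ids_ = list(Mdf.columns)
        self.M_pred_ = pd.DataFrame(
            Xv @ beta, index=Xdf.index, columns=Mdf.columns
        )
        self.X_pred_ = pd.DataFrame(
            Mv @ self.beta_pinv_, index=Mdf.index, columns=Xdf.columns
        )
        return self

    def predict(self, X) -> pd.DataFrame:
        """Predict methylation from factors: M_pred = X . beta."""
        Xdf = _as_design(X)
        return pd.DataFrame(
            Xdf.to_numpy(dtype=float) @ self.beta_.to_numpy(),
            index=Xdf.index,
            columns=self.site_ids_,
        )

    def predict_factors(self, M) -> pd.DataFrame:
        """Predict factors from methylation: X_pred = M . beta+."""
        Mdf = _as_matrix(M)
        return pd.DataFrame(
            Mdf.to_numpy(dtype=float) @ self.beta_pinv_,
            index=Mdf.index,
            columns=self.factor_names_,
        )

    # ---------------------------------------------------------- evaluation
    def loocv(self, X, M) -> LoocvReport:
        """Leave-one-out cross-validated factor prediction.

        For each sample i the coefficient matrix is refitted on the other
        n - 1 samples and sample i's factor row is predicted as
        M[i] . beta_i+. The constant and batch columns are fitted but not
        reported: they are nuisance terms.
        """
        Xdf = _as_design(X)
        Mdf = _as_matrix(M)
        n = Xdf.shape[0]
        if n < 3 + Xdf.shape[1]:
            raise ConfigurationError(
                f"LOOCV needs at least {3 + Xdf.shape[1]} samples, got {n}"
            )
        preds = np.empty_like(Xdf.to_numpy(dtype=float))
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            sub = MultifactorModel(self.pinv_tolerance).fit(
                Xdf.iloc[mask], Mdf.iloc[mask]
            )
            preds[i] = sub.predict_factors(Mdf.iloc[[i]]).to_numpy()[0]
            mask[i] = True
        predictions = pd.DataFrame(preds, index=Xdf.index, columns=Xdf.columns)
        factors = (
            X.substantive_factors
            if isinstance(X, FactorMatrix)
            else [f for f in Xdf.columns if f not in NUISANCE_FACTORS]
        )
        return LoocvReport(predictions, _factor_stats(Xdf, predictions, X, factors))

    def evaluate_fullfit(self, X) -> pd.DataFrame:
        """In-sample per-factor (r, p, MAE) from the fitted X_pred_."""
        Xdf = _as_design(X)
        factors = (
            X.substantive_factors
            if isinstance(X, FactorMatrix)
            else [f for f in Xdf.columns if f not in NUISANCE_FACTORS]
        )
        return _factor_stats(Xdf, self.X_pred_, X, factors)


def fit(M_obs, X, pinv_tolerance: float | None = None) -> MultifactorModel:
    """Fit the multifactor model; functional wrapper over the estimator."""
    return MultifactorModel(pinv_tolerance=pinv_tolerance).fit(X, M_obs)


def loocv(M_obs, X, pinv_tolerance: float | None = None) -> LoocvReport:
    return MultifactorModel(pinv_tolerance=pinv_tolerance).loocv(X, M_obs)


def evaluate_fullfit(model: MultifactorModel, X) -> pd.DataFrame:
    return model.evaluate_fullfit(X)
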