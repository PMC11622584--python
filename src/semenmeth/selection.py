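"""Three-filter selection of factor-associated CpG sites.

Sites associated with a factor (age, a cell-type composition) are chosen by
three filters applied to the multifactor regression:

1. High correlation — the site's observed methylation correlates with its
   model prediction across samples, |r| >= r_min (default 0.5).
2. Statistical significance — the factor's per-site OLS t-test p-value,
   Benjamini-Hochberg adjusted per factor across all sites, is <= q_max
   (default 0.05).
3. Highest coefficient — among the substantive factors, the site's largest
   absolute coefficient belongs to this factor (making per-factor site sets
   disjoint).

If more than ``cap`` (default 200) sites survive, the sites with the
smallest adjusted p-values are kept. Selected sites are split into
positive- and negative-coefficient groups: a negative coefficient means
methylation loss as the factor increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import ConfigurationError, MethylationDataError
from .multifactor import (
    NUISANCE_FACTORS,
    MultifactorModel,
    _as_design,
    _as_matrix,
)

__all__ = [
    "SelectionResult",
    "SiteSelector",
    "bh_adjust",
    "score_sites",
    "select_sites",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SelectionResult:
    """Sites selected for one factor, split by coefficient sign."""

    factor: str
    table: pd.DataFrame  # selected sites: coefficient, p, q, r_site, sign
    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)
    pre_cap_count: int = 0
    zero_coefficient_sites: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index)


def score_sites(M_obs, X, model: MultifactorModel) -> pd.DataFrame:
    """Per-site regression statistics for every substantive factor.

    Returns a DataFrame indexed by site id with columns ``r_site`` (Pearson
    correlation across samples between observed and model-predicted
    methylation; NaN for zero-variance sites) and, per substantive factor f,
    ``coef_f`` (regression coefficient), ``p_f`` (two-sided OLS t-test
    p-value) and ``q_f`` (BH-adjusted within factor f across all sites).
    """
    Xdf = _as_design(X)
    Mdf = _as_matrix(M_obs)
    Xv = Xdf.to_numpy(dtype=float)
    Mv = Mdf.to_numpy(dtype=float)
    beta = model.beta_.to_numpy()
    if list(model.beta_.columns) != list(Mdf.columns) or list(
        model.beta_.index
    ) != list(Xdf.columns):
        raise MethylationDataError("model fit inconsistent with M_obs / X")
    n, p = Xv.shape

    # observed-vs-predicted correlation per site
    M_pred = Xv @ beta
    a = Mv - Mv.mean(axis=0)
    b = M_pred - M_pred.mean(axis=0)
    na = np.sqrt((a**2).sum(axis=0))
    nb = np.sqrt((b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_site = (a * b).sum(axis=0) / (na * nb)
    r_site[(na == 0) | (nb == 0)] = np.nan

    # per-site OLS t-tests sharing the design matrix across sites
    rank = np.linalg.matrix_rank(Xv)
    dof = n - rank
    if dof <= 0:
        raise ConfigurationError("no residual degrees of freedom for t-tests")
    resid = Mv - M_pred
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv_diag = np.diag(np.linalg.pinv(Xv.T @ Xv))

    out = pd.DataFrame({"r_site": r_site}, index=Mdf.columns)
    factors = [f for f in Xdf.columns if f not in NUISANCE_FACTORS]
    for f in factors:
        k = list(Xdf.columns).index(f)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(sigma2 * xtx_inv_diag[k])
            t = beta[k] / se
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
        pvals = np.where(np.isnan(t), 1.0, pvals)
        out[f"coef_{f}"] = beta[k]
        out[f"p_{f}"] = pvals
        out[f"q_{f}"] = bh_adjust(pvals)
    out.attrs["factors"] = factors
    return out


def select_sites(
    scores: pd.DataFrame,
    factor: str,
    r_min: float = 0.5,
    q_max: float = 0.05,
    cap: int = 200,
) -> SelectionResult:
    """Apply the three filters for one factor and split by coefficient sign.

    The filters are conjunctive, so their application order is irrelevant.
    Surviving sites are ranked by adjusted p ascending, ties broken by
    |coefficient| descending then site id, and truncated to ``cap``.
    Zero coefficients land in the positive group and are flagged.
    """
    factors = scores.attrs.get("factors") or [
        c[5:] for c in scores.columns if c.startswith("coef_")
    ]
    if factor not in factors:
        raise ConfigurationError(
            f"unknown factor {factor!r}; scored factors: {factors}"
        )
    coef_cols = [f"coef_{f}" for f in factors]
    abs_coefs = scores[coef_cols].abs()
    # filter 3: argmax of |coefficient| over substantive factors
    is_top = abs_coefs.idxmax(axis=1) == f"coef_{factor}"
    # filter 1: observed-vs-predicted correlation (NaN r fails)
    high_r = scores["r_site"].abs() >= r_min
    high_r &= scores["r_site"].notna()
    # filter 2: BH-adjusted significance of this factor's coefficient
    signif = scores[f"q_{factor}"] <= q_max

    passed = scores.loc[high_r & signif & is_top]
    pre_cap = len(passed)
    q = passed[f"q_{factor}"]
    c = passed[f"coef_{factor}"].abs()
    rank_order = sorted(passed.index, key=lambda s: (q[s], -c[s], s))
    selected = passed.loc[rank_order[:cap]]

    coef = selected[f"coef_{factor}"]
    table = pd.DataFrame(
        {
            "factor": factor,
            "coefficient": coef,
            "p": selected[f"p_{factor}"],
            "q": selected[f"q_{factor}"],
            "r_site": selected["r_site"],
            "sign": np.where(coef < 0, "neg", "pos"),
        },
        index=selected.index,
    )
    return SelectionResult(
        factor=factor,
        table=table,
        positive=list(table.index[table["sign"] == "pos"]),
        negative=list(table.index[table["sign"] == "neg"]),
        pre_cap_count=pre_cap,
        zero_coefficient_sites=list(table.index[coef == 0]),
        thresholds={"r_min": r_min, "q_max": q_max, "cap": cap},
    )


class SiteSelector(BaseEstimator):
    """Score all sites against the multifactor model and select per factor.

    Parameters
    ----------
    r_min : float, default 0.5
        Minimum |observed-vs-predicted correlation| per site (filter 1).
    q_max : float, default 0.05
        Maximum BH-adjusted p-value for the factor coefficient (filter 2).
    cap : int, default 200
        Maximum number of sites retained per factor, keeping the smallest
        adjusted p-values.
    pinv_tolerance : float or None
        Passed through to the internal :class:`MultifactorModel` when one is
        not supplied to :meth:`fit`.
    """

    def __init__(
        self,
        r_min: float = 0.5,
        q_max: float = 0.05,
        cap: int = 200,
        pinv_tolerance: float | None = None,
    ):
        self.r_min = r_min
        self.q_max = q_max
        self.cap = cap
        self.pinv_tolerance = pinv_tolerance

    def fit(self, X, M, model: MultifactorModel | None = None):
        if model is None:
            model = MultifactorModel(self.pinv_tolerance).fit(X, M)
        self.model_ = model
        self.scores_ = score_sites(M, X, model)
        self.factors_ = list(self.scores_.attrs["factors"])
        return self

    def select(self, factor: str) -> SelectionResult:
        return select_sites(
            self.scores_, factor, r_min=self.r_min, q_max=self.q_max, cap=self.cap
        )

    def select_all(self) -> dict[str, SelectionResult]:
        return {f: self.select(f) for f in self.factors_}
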