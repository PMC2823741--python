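"""Composite socioeconomic indicator: the PCA-based asset index.

The index follows the standard Filmer-Pritchett construction.  Binary
asset-ownership indicators are screened (a variable is kept only if it has
at least one pairwise Spearman rank correlation with another variable
significant at the chosen level; constant columns are always dropped), the
first principal component of the correlation matrix of the retained
variables is extracted, and a household's index is

    A_i = sum_k f_k * (a_ik - mean_k) / sd_k

where ``a_ik`` is household ``i``'s value for asset ``k``, ``mean_k`` and
``sd_k`` are the sample mean and standard deviation, and the scoring weight
``f_k`` is the PC1 eigenvector loading (unit norm: the squared weights sum
to one).  Household indices are averaged within each district and the
district averages are shifted so the least deprived district sits at
exactly 1, making the normalized index usable as a population-weighting
multiplier.

The sign of a principal component is arbitrary; the component is oriented
so that a configurable set of wealth markers (car, refrigerator, flush
toilet, electric/gas cooking by default) loads positively, i.e. higher raw
index = better off.  District means are normalized on that same
orientation — the minimum district is shifted to exactly 1 — reproducing
the published convention in which the urban districts carry the largest
normalized indices and the normalized index correlates negatively with the
stunting rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import DISTRICT_COLUMN

DEFAULT_WEALTH_MARKERS = (
    "car_truck",
    "refrigerator",
    "toilet_flush",
    "fuel_electricity_gas",
)

ZERO_VARIANCE = "zero variance"


def _indicator_frame(survey: pd.DataFrame) -> pd.DataFrame:
    """Drop the district label column if present."""
    if DISTRICT_COLUMN in survey.columns:
        return survey.drop(columns=[DISTRICT_COLUMN])
    return survey


def screen_variables(
    survey: pd.DataFrame, alpha: float = 0.01
) -> tuple[list[str], list[tuple[str, str]]]:
    """Screen indicator variables by pairwise Spearman significance.

    A variable is retained iff it has at least one pairwise Spearman rank
    correlation with another variable that is significant at ``alpha``
    (two-sided).  Constant columns are screened out with reason
    ``"zero variance"``.

    Returns ``(retained, screened_out)`` where ``screened_out`` is a list
    of ``(variable, reason)`` pairs.

    Raises
    ------
    ValueError
        If fewer than 2 variables or 10 households are supplied, or if
        every variable ends up screened out.
    """
    X = _indicator_frame(survey)
    if X.shape[1] < 2:
        raise ValueError("screening needs at least 2 variables")
    if X.shape[0] < 10:
        raise ValueError("screening needs at least 10 households")

    screened: list[tuple[str, str]] = []
    varying = []
    for col in X.columns:
        if X[col].nunique() <= 1:
            screened.append((col, ZERO_VARIANCE))
        else:
            varying.append(col)

    retained: list[str] = []
    if len(varying) == 1:
        screened.append((varying[0], "no co-varying variable to test against"))
    elif varying:
        _, pvals = stats.spearmanr(X[varying].to_numpy())
        pvals = np.atleast_2d(pvals)
        if pvals.shape == (1, 1):  # scipy collapses the 2-variable case
            p = float(pvals[0, 0])
            pvals = np.array([[0.0, p], [p, 0.0]])
        np.fill_diagonal(pvals, np.inf)
        for j, col in enumerate(varying):
            if np.min(pvals[j]) < alpha:
                retained.append(col)
            else:
                screened.append(
                    (col, f"no significant pairwise correlation at alpha={alpha}")
                )
    if not retained:
        raise ValueError("all variables screened out; cannot build an index")
    return retained, screened


class AssetIndex(BaseEstimator, TransformerMixin):
    """First-principal-component asset index over binary indicators.

    Parameters
    ----------
    alpha:
        Significance level for the Spearman screening step.
    screen:
        If False, skip screening and retain every non-constant column.
    wealth_markers:
        Variables whose summed loading fixes the sign of the component
        (positive = higher SES).  If none of them survive screening, the
        component is oriented so the index correlates positively with the
        household's total count of owned assets.

    Attributes
    ----------
    retained_variables_ : list of str
    screened_out_ : list of (variable, reason)
    means_, stds_ : ndarray, sample mean / SD (denominator n) per retained variable
    loadings_ : ndarray, unit-norm PC1 eigenvector (the scoring weights f_k)
    factor_scores_ : ndarray, alias of ``loadings_``
    explained_variance_ratio_ : float, leading eigenvalue / number retained
    """

    def __init__(
        self,
        alpha: float = 0.01,
        screen: bool = True,
        wealth_markers: tuple[str, ...] = DEFAULT_WEALTH_MARKERS,
    ):
        self.alpha = alpha
        self.screen = screen
        self.wealth_markers = wealth_markers

    def fit(self, X: pd.DataFrame, y=None) -> "AssetIndex":
        X = _indicator_frame(pd.DataFrame(X))
        if X.shape[0] <= 1:
            raise ValueError("correlation matrix needs more than one household")
        if self.screen:
            retained, screened = screen_variables(X, alpha=self.alpha)
        else:
            retained = [c for c in X.columns if X[c].nunique() > 1]
            screened = [
                (c, ZERO_VARIANCE) for c in X.columns if c not in retained
            ]
            if not retained:
                raise ValueError("no non-constant variables to fit")
        Z = X[retained].to_numpy(dtype=float)
        means = Z.mean(axis=0)
        stds = Z.std(axis=0)  # population (denominator n) convention
        corr = np.corrcoef(Z, rowvar=False)
        corr = np.atleast_2d(corr)
        eigvals, eigvecs = np.linalg.eigh(corr)
        pc1 = eigvecs[:, -1]
        pc1 = self._orient(pc1, retained, (Z - means) / stds)
        self.retained_variables_ = retained
        self.screened_out_ = screened
        self.means_ = means
        self.stds_ = stds
        self.loadings_ = pc1
        self.factor_scores_ = pc1
        self.explained_variance_ratio_ = float(eigvals[-1] / len(retained))
        return self

    def _orient(
        self, pc1: np.ndarray, retained: list[str], Z_std: np.ndarray
    ) -> np.ndarray:
        marker_idx = [retained.index(m) for m in self.wealth_markers if m in retained]
        s = pc1[marker_idx].sum() if marker_idx else 0.0
        if s == 0.0:
            # fall back: index should rise with the count of owned assets
            s = float(np.corrcoef(Z_std @ pc1, Z_std.sum(axis=1))[0, 1])
        return -pc1 if s < 0 else pc1

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Score households: ``A_i = sum_k f_k (a_ik - mean_k) / sd_k``."""
        check_is_fitted(self, "loadings_")
        X = _indicator_frame(pd.DataFrame(X))
        missing = [c for c in self.retained_variables_ if c not in X.columns]
        if missing:
            raise ValueError(f"household data missing retained variables: {missing}")
        Z = X[self.retained_variables_].to_numpy(dtype=float)
        return (Z - self.means_) / self.stds_ @ self.loadings_


def fit_pc1(survey: pd.DataFrame, retained: list[str]) -> AssetIndex:
    """Fit the PC1 scoring model on an explicit retained-variable list."""
    X = _indicator_frame(survey)[retained]
    return AssetIndex(screen=False).fit(X)


def score_household(household, model: AssetIndex) -> float:
    """Raw asset index of a single household (mapping variable -> value)."""
    missing = [k for k in model.retained_variables_ if k not in household]
    if missing:
        raise ValueError(f"household missing retained variables: {missing}")
    a = np.array([float(household[k]) for k in model.retained_variables_])
    return float((a - model.means_) / model.stds_ @ model.loadings_)


def score_households(survey: pd.DataFrame, model: AssetIndex) -> pd.Series:
    """Raw asset index for every household, keeping district labels aligned."""
    return pd.Series(model.transform(survey), index=survey.index, name="asset_index")


def aggregate_to_districts(
    scores: pd.Series,
    districts: pd.Series,
    weights: pd.Series | None = None,
) -> pd.Series:
    """District raw index = (optionally weighted) mean of household indices.

    The unweighted arithmetic mean is the default and the standard
    practice; pass per-household ``weights`` for a weighted aggregation.
    """
    if len(scores) != len(districts):
        raise ValueError("scores and districts have different lengths")
    df = pd.DataFrame({"score": scores.to_numpy(), "d": districts.to_numpy()})
    if weights is None:
        out = df.groupby("d", sort=True)["score"].mean()
    else:
        df["w"] = np.asarray(weights, dtype=float)
        g = df.groupby("d", sort=True)
        out = g.apply(
            lambda s: np.average(s["score"], weights=s["w"]),
            include_groups=False,
        )
    out.index.name = DISTRICT_COLUMN
    out.name = "raw_index"
    return out


@dataclass(frozen=True)
class DistrictIndexSet:
    """Per-district raw and normalized indices plus the shift applied."""

    raw_index: pd.Series
    normalized_index: pd.Series
    shift_constant: float


def normalize_indices(raw: pd.Series) -> DistrictIndexSet:
    """Shift raw district indices so the minimum district is exactly 1.

    ``shift_constant = 1 - min(raw)``; the minimum district is set to 1.0
    exactly (not merely up to rounding), so the normalized index is a
    well-defined population multiplier >= 1.
    """
    if len(raw) < 1:
        raise ValueError("need at least one district")
    shift = 1.0 - float(raw.min())
    normalized = raw + shift
    normalized.loc[raw.idxmin()] = 1.0
    normalized.name = "normalized_asset_index"
    return DistrictIndexSet(
        raw_index=raw, normalized_index=normalized, shift_constant=shift
    )
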