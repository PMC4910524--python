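"""Phenotype corrections applied before twin-model fitting.

Achievement scores are regressed on age and sex (pooled across both
members of each pair — age is pair-constant, so per-twin fits would be
rank-deficient), standardized, and normalized with the rank-based van
der Waerden transform. Uncorrected mean effects of age or sex would
masquerade as shared environment, since both are perfectly correlated
within a pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrectionRecipe",
    "DegenerateInputError",
    "residualize_age_sex",
    "van_der_waerden",
    "apply_recipe",
]


class DegenerateInputError(ValueError):
    """Design matrix or input vector does not support the requested correction."""


@dataclass(frozen=True)
class CorrectionRecipe:
    """Which corrections to apply, in order: residualize -> transform -> standardize."""

    residualize: bool = True
    van_der_waerden: bool = True
    standardize: bool = True


def _as_float(values) -> np.ndarray:
    return np.asarray(values, dtype=float)


def residualize_age_sex(values, age, sex) -> np.ndarray:
    """OLS residuals of phenotype on age and sex, scaled to unit variance.

    ``sex`` is any 0/1 coding (or M/F strings). Missing phenotypes (NaN)
    are ignored in the fit and stay NaN in the output. Residuals have
    sample mean 0 and SD 1 over the non-missing entries; if the fit is
    exact (zero residual variance) the residuals are returned as zeros.
    """
    y = _as_float(values)
    age = _as_float(age)
    sex = np.asarray(sex)
    if sex.dtype.kind in "UOS":
        sex = (sex == "F").astype(float)
    sex = _as_float(sex)
    if not (len(y) == len(age) == len(sex)):
        raise ValueError("values, age and sex must be aligned")
    mask = ~np.isnan(y)
    n = int(mask.sum())
    if n < 3:
        raise DegenerateInputError(f"need >= 3 non-missing values, have {n}")
    X = np.column_stack([np.ones(n), age[mask], sex[mask]])
    # drop covariates that are constant (collinear with the intercept)
    keep = [0] + [j for j in (1, 2) if np.ptp(X[:, j]) > 0]
    if len(keep) == 1 and np.ptp(y[mask]) == 0:
        raise DegenerateInputError("constant phenotype with constant covariates")
    X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y[mask], rcond=None)
    resid = y[mask] - X @ beta
    sd = resid.std(ddof=0)
    out = np.full_like(y, np.nan)
    # an exact fit leaves numerical dust; don't standardize it into noise
    tiny = 1e-10 * max(1.0, float(np.std(y[mask])))
    out[mask] = resid / sd if sd > tiny else 0.0
    return out


def van_der_waerden(values) -> np.ndarray:
    """Rank-based inverse-normal scores.

    The value with rank r among n non-missing entries maps to the
    standard-normal quantile at r/(n+1); ties take the quantile of their
    average rank. Order is preserved and missing entries stay missing.
    """
    y = _as_float(values)
    mask = ~np.isnan(y)
    obs = y[mask]
    if len(np.unique(obs)) < 2:
        raise DegenerateInputError("need >= 2 distinct non-missing values")
    ranks = stats.rankdata(obs, method="average")
    scores = stats.norm.ppf(ranks / (len(obs) + 1.0))
    out = np.full_like(y, np.nan)
    out[mask] = scores
    return out


def apply_recipe(values, age, sex, recipe: CorrectionRecipe = CorrectionRecipe()) -> np.ndarray:
    """Run the full correction chain on one phenotype vector."""
    y = _as_float(values).copy()
    if recipe.residualize:
        y = residualize_age_sex(y, age, sex)
    if recipe.van_der_waerden:
        y = van_der_waerden(y)
    if recipe.standardize:
        mask = ~np.isnan(y)
        mu = y[mask].mean()
        sd = y[mask].std(ddof=0)
        if sd > 0:
            y[mask] = (y[mask] - mu) / sd
        else:
            y[mask] = 0.0
    return y
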