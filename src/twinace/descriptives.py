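"""Descriptive statistics on one randomly selected twin per pair.

Twins within a pair are not independent observations, so sample-level
descriptives (sex-difference chi-square for choices, sex x zygosity
ANOVA for grades) are computed on one twin per pair, drawn uniformly
under a caller-supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .twin_data import TwinPairRecord

__all__ = [
    "AnovaReport",
    "UndefinedStatisticError",
    "select_one_per_pair",
    "chisq_one_per_pair",
    "anova_sex_zygosity",
]


class UndefinedStatisticError(ValueError):
    """A margin of the contingency table is zero; the statistic is undefined."""


@dataclass(frozen=True)
class AnovaReport:
    f_sex: float
    f_zygosity: float
    f_interaction: float
    p_sex: float
    p_zygosity: float
    p_interaction: float
    r_squared: float
    n: int
    interaction_dropped: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"R^2 = {self.r_squared} outside [0, 1]")


def select_one_per_pair(
    records: Sequence[TwinPairRecord], seed: int
) -> pd.DataFrame:
    """One uniformly sampled individual per pair, as a DataFrame."""
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, 2, size=len(records))
    rows = []
    for rec, k in zip(records, picks):
        member = rec.twin1 if k == 0 else rec.twin2
        row = {"family_id": rec.family_id, "zygosity": rec.group.value,
               "sex": member.sex, "age": rec.age}
        for t, v in member.choices.items():
            row[f"choice_{t}"] = v
        for t, v in member.grades.items():
            row[f"grade_{t}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def chisq_one_per_pair(
    records: Sequence[TwinPairRecord], trait: str, seed: int
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) of sex vs choice.

    Returns ``(statistic, df, p)`` with df = 1, on the 2x2 table built
    from one randomly selected twin per pair.
    """
    df = select_one_per_pair(records, seed)
    col = f"choice_{trait}"
    if col not in df.columns:
        raise KeyError(f"trait {trait!r} not present")
    sub = df.dropna(subset=[col])
    table = pd.crosstab(sub["sex"], sub[col].astype(int))
    if table.shape != (2, 2) or (table.values.sum(axis=0) == 0).any() \
            or (table.values.sum(axis=1) == 0).any():
        raise UndefinedStatisticError(
            f"sex-by-choice table for {trait!r} has an empty margin"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table.values, correction=False)
    return float(chi2), int(dof), float(p)


def anova_sex_zygosity(
    records: Sequence[TwinPairRecord], trait: str, seed: int
) -> AnovaReport:
    """Two-factor fixed-effects ANOVA of a grade on sex, zygosity and their
    interaction, with sequential (type-I) sums of squares.

    R^2 is the proportion of total variance explained jointly by the
    three terms. With an empty sex x zygosity cell the interaction is
    dropped (reduced model) and flagged.
    """
    df = select_one_per_pair(records, seed)
    col = f"grade_{trait}"
    if col not in df.columns:
        raise KeyError(f"trait {trait!r} not present")
    sub = df.dropna(subset=[col]).rename(columns={col: "y"})
    if sub.empty:
        raise ValueError(f"no non-missing grades for {trait!r}")
    # zygosity enters as MZ vs DZ: the five-group labels are sex-determined
    # (MZm is all male), so the full crossing would be structurally empty
    sub = sub.assign(
        zygosity=np.where(sub["zygosity"].str.startswith("MZ"), "MZ", "DZ")
    )
    cells = sub.groupby(["sex", "zygosity"]).size()
    n_sex = sub["sex"].nunique()
    n_zyg = sub["zygosity"].nunique()
    dropped = len(cells) < n_sex * n_zyg
    formula = "y ~ C(sex) + C(zygosity)"
    if not dropped:
        formula += " + C(sex):C(zygosity)"
    fit = smf.ols(formula, data=sub).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    ss_total = float(table["sum_sq"].sum())
    effect_rows = [i for i in table.index if i != "Residual"]
    ss_model = float(table.loc[effect_rows, "sum_sq"].sum())

    def get(row_frag: str) -> tuple[float, float]:
        for i in effect_rows:
            if i == row_frag:
                return float(table.loc[i, "F"]), float(table.loc[i, "PR(>F)"])
        return float("nan"), float("nan")

    f_int, p_int = get("C(sex):C(zygosity)")
    return AnovaReport(
        f_sex=get("C(sex)")[0], f_zygosity=get("C(zygosity)")[0],
        f_interaction=f_int,
        p_sex=get("C(sex)")[1], p_zygosity=get("C(zygosity)")[1],
        p_interaction=p_int,
        r_squared=ss_model / ss_total if ss_total > 0 else float("nan"),
        n=len(sub), interaction_dropped=dropped,
    )
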