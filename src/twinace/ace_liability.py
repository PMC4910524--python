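"""ACE decomposition of binary choice traits on the liability scale.

A binary trait is modelled as a thresholded standard-normal liability;
within a zygosity group the pair's liabilities are bivariate normal with
correlation ``gamma * a2 + c2``. The joint multinomial likelihood over
all groups' 2x2 concordance tables is maximized over the threshold and
the standardized components (a2 + c2 + e2 = 1), with profile-likelihood
CIs. The threshold is equated across zygosity groups: zygosity should
not shift prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .ace_continuous import _FREE, _n_free  # same model family
from .tetrachoric import Concordance2x2, bvn_cell_probabilities
from .twin_data import FitReport, TwinPairRecord, ZygosityGroup

__all__ = [
    "LiabilityFit",
    "DegeneratePrevalenceError",
    "concordance_summary",
    "concordance_tables",
    "fit_liability_ace",
    "fit_liability_tables",
]

_CHI2_95 = stats.chi2.ppf(0.95, 1)
_MODELS = ("ACE", "AE", "CE", "E")


class DegeneratePrevalenceError(ValueError):
    """A required margin has no choosers or no non-choosers."""


@dataclass
class LiabilityFit:
    """Threshold plus standardized liability-scale variance components."""

    threshold: float
    a2: float
    c2: float
    e2: float
    loglik: float
    model: str
    implied_r: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_pairs: dict[str, int]
    converged: bool

    def report(self) -> FitReport:
        params = {
            "threshold": (self.threshold, float("nan"), float("nan")),
        }
        for name in ("a2", "c2", "e2"):
            lo, hi = self.ci.get(name, (float("nan"), float("nan")))
            params[name] = (getattr(self, name), lo, hi)
        return FitReport(
            model=self.model, loglik=self.loglik,
            n_params=1 + _liab_free(self.model),
            n_pairs=self.n_pairs, converged=self.converged, params=params,
            extras={"free": sorted(_FREE[self.model]), "implied_r": self.implied_r},
        )


def _liab_free(model: str) -> int:
    # unit liability variance: one fewer free parameter than the
    # continuous paths, with a floor of 0 for the pure-E model
    return {"ACE": 2, "AE": 1, "CE": 1, "E": 0}[model]


def concordance_tables(
    records: Sequence[TwinPairRecord], trait: str, pool: bool = True
) -> dict[str, Concordance2x2]:
    """2x2 pair-concordance counts for a binary trait.

    ``pool=True`` gives the combined-sex strata 'MZ' and 'DZ' (DZos
    included); ``pool=False`` keeps the five zygosity groups.
    """
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        c1 = rec.twin1.choices.get(trait)
        c2 = rec.twin2.choices.get(trait)
        if c1 is None or c2 is None:
            continue
        key = ("MZ" if rec.group.is_mz else "DZ") if pool else rec.group.value
        cell = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(c1, c2)]
        counts.setdefault(key, np.zeros(4))[cell] += 1
    return {
        k: Concordance2x2(*v, label=k) for k, v in counts.items()
    }


def concordance_summary(
    records: Sequence[TwinPairRecord], trait: str
) -> dict[str, dict]:
    """Per-group counts plus probandwise concordance 2 n11 / (2 n11 + n10 + n01)."""
    out = {}
    for key, tab in concordance_tables(records, trait, pool=False).items():
        out[key] = {
            "n11": tab.n11, "n10": tab.n10, "n01": tab.n01, "n00": tab.n00,
            "probandwise": tab.probandwise_concordance,
        }
    for key, tab in concordance_tables(records, trait, pool=True).items():
        out[key] = {
            "n11": tab.n11, "n10": tab.n10, "n01": tab.n01, "n00": tab.n00,
            "probandwise": tab.probandwise_concordance,
        }
    return out


def _check_tables(tables: Mapping[float, Concordance2x2]) -> None:
    for gamma, tab in tables.items():
        pos = 2 * tab.n11 + tab.n10 + tab.n01
        neg = 2 * tab.n00 + tab.n10 + tab.n01
        if pos <= 0 or neg <= 0:
            raise DegeneratePrevalenceError(
                f"stratum gamma={gamma:g}: all choosers or no choosers"
            )


def _components(theta: np.ndarray, model: str) -> tuple[float, float]:
    """(a2, c2) from the free parameter vector (threshold excluded)."""
    if model == "ACE":
        return float(theta[0]), float(theta[1])
    if model == "AE":
        return float(theta[0]), 0.0
    if model == "CE":
        return 0.0, float(theta[0])
    return 0.0, 0.0


def _nll_tables(
    t: float, a2: float, c2: float, tables: Mapping[float, Concordance2x2]
) -> float:
    if a2 < 0 or c2 < 0 or a2 + c2 > 1.0:
        return float("inf")
    total = 0.0
    for gamma, tab in tables.items():
        r = gamma * a2 + c2
        p = np.maximum(bvn_cell_probabilities(r, t, t), 1e-300)
        total -= float(tab.counts @ np.log(p))
    return total


_STARTS = [(0.6, 0.2), (0.2, 0.6), (0.3, 0.3), (0.05, 0.05)]


def fit_liability_tables(
    tables: Mapping[float, Concordance2x2],
    model: str = "ACE",
    ci_components: Sequence[str] = (),
) -> LiabilityFit:
    """ML liability-threshold fit from ``{gamma: Concordance2x2}`` tables."""
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    _check_tables(tables)
    if model in ("ACE", "AE") and len(set(tables)) < 2:
        raise ValueError("need MZ-type and DZ-type tables to separate A from C")
    n_total = sum(tab.total for tab in tables.values())
    n_pos = sum(2 * tab.n11 + tab.n10 + tab.n01 for tab in tables.values())
    prev = min(max(n_pos / (2.0 * n_total), 1e-6), 1 - 1e-6)
    t0 = float(stats.norm.isf(prev))
    k = _liab_free(model)

    def nll(theta: np.ndarray) -> float:
        a2, c2 = _components(theta[1:], model)
        return _nll_tables(theta[0], a2, c2, tables)

    best_x, best_f = None, float("inf")
    if k == 0:
        res = optimize.minimize(
            nll, np.array([t0]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10},
        )
        best_x, best_f = res.x, float(res.fun)
    else:
        cons = []
        if model == "ACE":
            cons = [{"type": "ineq",
                     "fun": lambda th: 1.0 - th[1] - th[2]}]
        bounds = [(-6.0, 6.0)] + [(0.0, 1.0)] * k
        for a2s, c2s in _STARTS:
            if model == "ACE":
                x0 = np.array([t0, a2s, c2s])
            elif model == "AE":
                x0 = np.array([t0, a2s + c2s])
            else:
                x0 = np.array([t0, a2s + c2s])
            res = optimize.minimize(
                nll, x0, method="SLSQP", bounds=bounds, constraints=cons,
                options={"maxiter": 300, "ftol": 1e-12},
            )
            f = float(res.fun)
            if f < best_f - 1e-9:
                best_x, best_f = res.x, f
            elif best_x is not None and abs(f - best_f) <= 1e-9:
                if _components(res.x[1:], model)[0] < _components(best_x[1:], model)[0]:
                    best_x = res.x
    assert best_x is not None
    if not np.isfinite(best_f):
        raise RuntimeError(f"liability {model} fit failed to converge")
    t_hat = float(best_x[0])
    a2, c2 = _components(best_x[1:], model)
    e2 = 1.0 - a2 - c2
    ci: dict[str, tuple[float, float]] = {}
    for comp in ci_components:
        ci[comp] = _profile_ci(comp, {"a2": a2, "c2": c2, "e2": e2}[comp],
                               best_f, tables)
    implied = {f"gamma={g:g}": g * a2 + c2 for g in tables}
    return LiabilityFit(
        threshold=t_hat, a2=a2, c2=c2, e2=max(0.0, e2), loglik=-best_f,
        model=model, implied_r=implied, ci=ci,
        n_pairs={f"gamma={g:g}": int(tab.total) for g, tab in tables.items()},
        converged=True,
    )


def _profile_nll(q: float, comp: str,
                 tables: Mapping[float, Concordance2x2]) -> float:
    """Min NLL with one standardized component fixed at q."""
    def nll(theta: np.ndarray) -> float:
        t, phi = theta
        if comp == "a2":
            a2, c2 = q, phi * (1.0 - q)
        elif comp == "c2":
            a2, c2 = phi * (1.0 - q), q
        else:  # e2 fixed at q
            a2, c2 = phi * (1.0 - q), (1.0 - phi) * (1.0 - q)
        return _nll_tables(t, a2, c2, tables)

    n_total = sum(tab.total for tab in tables.values())
    n_pos = sum(2 * tab.n11 + tab.n10 + tab.n01 for tab in tables.values())
    prev = min(max(n_pos / (2.0 * n_total), 1e-6), 1 - 1e-6)
    t0 = float(stats.norm.isf(prev))
    best = float("inf")
    for phi0 in (0.2, 0.5, 0.8):
        res = optimize.minimize(
            nll, np.array([t0, phi0]), method="L-BFGS-B",
            bounds=[(-6.0, 6.0), (0.0, 1.0)],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        best = min(best, float(res.fun))
    return best


def _profile_ci(comp: str, hat: float, nll_hat: float,
                tables: Mapping[float, Concordance2x2]) -> tuple[float, float]:
    crit = nll_hat + 0.5 * _CHI2_95

    def dev(q: float) -> float:
        return _profile_nll(q, comp, tables) - crit

    def solve(lo: float, hi: float, boundary_is_hi: bool) -> float:
        target = hi if boundary_is_hi else lo
        if dev(target) <= 0:
            return target
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            inside = dev(mid) <= 0
            if boundary_is_hi:
                lo, hi = (mid, hi) if inside else (lo, mid)
            else:
                lo, hi = (lo, mid) if inside else (mid, hi)
            if hi - lo < 5e-4:
                break
        return 0.5 * (lo + hi)

    eps = 1e-6
    hat = min(max(hat, eps), 1 - eps)
    lo = solve(eps, hat, boundary_is_hi=False)
    hi = solve(hat, 1 - eps, boundary_is_hi=True)
    return min(lo, hat), max(hi, hat)


def fit_liability_ace(
    records: Sequence[TwinPairRecord],
    trait: str,
    model: str = "ACE",
    ci_components: Sequence[str] = ("a2", "c2", "e2"),
) -> LiabilityFit:
    """Joint liability-threshold ACE fit for a binary trait.

    MZ strata pool at gamma = 1, all DZ strata (same- and opposite-sex)
    at gamma = 0.5, sharing one threshold.
    """
    tabs = concordance_tables(records, trait, pool=True)
    if not tabs:
        raise ValueError(f"no complete pairs with choices for trait {trait!r}")
    gamma_map = {"MZ": 1.0, "DZ": 0.5}
    return fit_liability_tables(
        {gamma_map[k]: v for k, v in tabs.items()},
        model=model, ci_components=ci_components,
    )
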