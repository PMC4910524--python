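"""Univariate ACE decomposition for continuous traits.

The classical twin design partitions phenotypic variance into additive
genetic (A), shared environmental (C) and non-shared environmental (E)
parts by exploiting the known genetic relatedness of MZ (gamma = 1) and
DZ (gamma = 0.5) pairs: the expected cross-twin covariance in group g is
``gamma_g * a^2 + c^2`` while the phenotypic variance is
``a^2 + c^2 + e^2``. Two estimators are provided:

* :func:`falconer_decomposition` -- the moment estimator
  a2 = 2 (rMZ - rDZ), c2 = rMZ - a2, e2 = 1 - rMZ;
* :func:`fit_ace_ml` -- full maximum likelihood over per-group bivariate
  normals with nonnegative path coefficients, nested submodels (AE, CE,
  E), likelihood-ratio tests with the chi-square boundary mixture, and
  profile-likelihood confidence intervals for the standardized
  components.

Opposite-sex DZ pairs are pooled with same-sex DZ pairs at gamma = 0.5
in combined-sex analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .twin_data import FitReport, TwinPairRecord, ZygosityGroup

__all__ = [
    "VarianceComponents",
    "GroupCorrelation",
    "LRTResult",
    "falconer_decomposition",
    "group_correlations",
    "fit_ace_ml",
    "fit_ace_arrays",
    "likelihood_ratio_test",
    "PairStats",
    "pair_stats",
    "variance_components",
]

_CHI2_95 = stats.chi2.ppf(0.95, 1)
MODELS = ("ACE", "AE", "CE", "E")
_FREE = {"ACE": frozenset("ace"), "AE": frozenset("ae"),
         "CE": frozenset("ce"), "E": frozenset("e")}


@dataclass(frozen=True)
class VarianceComponents:
    """Standardized proportions with their (nonnegative) path coefficients."""

    a2: float
    c2: float
    e2: float
    out_of_bounds: bool = False

    @property
    def paths(self) -> tuple[float, float, float]:
        return tuple(math.sqrt(max(0.0, v)) for v in (self.a2, self.c2, self.e2))


@dataclass(frozen=True)
class GroupCorrelation:
    label: str
    r: float
    n: int
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    p_value_boundary: float
    preferred: str


@dataclass(frozen=True)
class PairStats:
    """Sufficient statistics of one zygosity stratum for the bivariate-normal
    likelihood: counts, per-twin sums, sums of squares and cross-products."""

    gamma: float
    n: int
    s1: float
    s2: float
    q1: float
    q2: float
    x12: float

    @classmethod
    def from_arrays(cls, gamma: float, x1: np.ndarray, x2: np.ndarray) -> "PairStats":
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        return cls(
            gamma=gamma, n=len(x1),
            s1=float(x1.sum()), s2=float(x2.sum()),
            q1=float(x1 @ x1), q2=float(x2 @ x2), x12=float(x1 @ x2),
        )


def pair_stats(
    groups: Mapping[float, tuple[np.ndarray, np.ndarray]]
) -> list[PairStats]:
    """Build sufficient statistics from ``{gamma: (twin1, twin2)}`` arrays."""
    return [PairStats.from_arrays(g, x1, x2) for g, (x1, x2) in groups.items()]


def falconer_decomposition(rMZ: float, rDZ: float) -> VarianceComponents:
    """Moment estimator: double the MZ-DZ correlation difference.

    Values outside [0, 1] (e.g. when rDZ < rMZ / 2 forces a negative
    shared-environment estimate) are returned as-is with the
    ``out_of_bounds`` flag set; nothing is truncated silently.
    """
    if not (-1.0 <= rMZ <= 1.0 and -1.0 <= rDZ <= 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (rMZ - rDZ)
    c2 = rMZ - a2
    e2 = 1.0 - rMZ
    oob = any(not 0.0 <= v <= 1.0 for v in (a2, c2, e2))
    return VarianceComponents(a2=a2, c2=c2, e2=e2, out_of_bounds=oob)


def _extract_pairs(
    records: Sequence[TwinPairRecord], trait: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Complete-pair grade arrays keyed by 'MZ'/'DZ' (DZos pooled into DZ)."""
    buckets: dict[str, tuple[list[float], list[float]]] = {
        "MZ": ([], []), "DZ": ([], [])
    }
    for rec in records:
        g1 = rec.twin1.grades.get(trait)
        g2 = rec.twin2.grades.get(trait)
        if g1 is None or g2 is None:
            continue
        key = "MZ" if rec.group.is_mz else "DZ"
        buckets[key][0].append(g1)
        buckets[key][1].append(g2)
    return {
        k: (np.asarray(v[0]), np.asarray(v[1]))
        for k, v in buckets.items() if v[0]
    }


def group_correlations(
    records: Sequence[TwinPairRecord], trait: str
) -> list[GroupCorrelation]:
    """Pearson twin correlations for the pooled MZ and DZ strata with
    Fisher-z 95% CIs. Pair order is symmetrized (double entry) only in the
    sense that correlations use the raw twin-1/twin-2 pairing."""
    out = []
    for label, (x1, x2) in _extract_pairs(records, trait).items():
        n = len(x1)
        r = float(np.corrcoef(x1, x2)[0, 1]) if n > 1 else float("nan")
        if n > 3 and abs(r) < 1:
            z = math.atanh(r)
            half = 1.959964 / math.sqrt(n - 3)
            lo, hi = math.tanh(z - half), math.tanh(z + half)
        else:
            lo = hi = float("nan")
        out.append(GroupCorrelation(label=label, r=r, n=n, ci_low=lo, ci_high=hi))
    return out


# --- likelihood ---------------------------------------------------------

def _nll_suff(mu: float, v: float, covs: Iterable[float],
              stats_list: Sequence[PairStats]) -> float:
    """Negative log-likelihood with common mean/variance and per-group covariance."""
    total = 0.0
    for st, cv in zip(stats_list, covs):
        det = v * v - cv * cv
        if det <= 0 or v <= 0:
            return float("inf")
        ss1 = st.q1 - 2.0 * mu * st.s1 + st.n * mu * mu
        ss2 = st.q2 - 2.0 * mu * st.s2 + st.n * mu * mu
        sx = st.x12 - mu * st.s2 - mu * st.s1 + st.n * mu * mu
        quad = (v * (ss1 + ss2) - 2.0 * cv * sx) / det
        total += st.n * math.log(2.0 * math.pi) + 0.5 * st.n * math.log(det) + 0.5 * quad
    return total


def _nll_paths(theta: np.ndarray, stats_list: Sequence[PairStats],
               model: str) -> float:
    mu = theta[0]
    a, c, e = _expand_paths(theta[1:], model)
    v = a * a + c * c + e * e
    covs = [st.gamma * a * a + c * c for st in stats_list]
    return _nll_suff(mu, v, covs, stats_list)


def _expand_paths(free: np.ndarray, model: str) -> tuple[float, float, float]:
    if model == "ACE":
        return free[0], free[1], free[2]
    if model == "AE":
        return free[0], 0.0, free[1]
    if model == "CE":
        return 0.0, free[0], free[1]
    if model == "E":
        return 0.0, 0.0, free[0]
    raise ValueError(f"unknown model {model!r}")


def _n_free(model: str) -> int:
    return {"ACE": 3, "AE": 2, "CE": 2, "E": 1}[model]


# five deterministic starts spanning the (a2, c2) simplex
_STARTS = [(0.6, 0.2), (0.2, 0.6), (0.33, 0.33), (0.05, 0.05), (0.45, 0.10)]


def _fit_ml(stats_list: Sequence[PairStats], model: str) -> tuple[np.ndarray, float]:
    n_tot = sum(st.n for st in stats_list)
    mu0 = sum(st.s1 + st.s2 for st in stats_list) / (2 * n_tot)
    v0 = max(
        1e-8,
        sum(st.q1 + st.q2 for st in stats_list) / (2 * n_tot) - mu0 * mu0,
    )
    k = _n_free(model)
    best_x, best_f = None, float("inf")
    for a2s, c2s in _STARTS:
        e2s = max(1e-3, 1.0 - a2s - c2s)
        full = (math.sqrt(a2s * v0), math.sqrt(c2s * v0), math.sqrt(e2s * v0))
        if model == "ACE":
            start = full
        elif model == "AE":
            start = (full[0], full[2])
        elif model == "CE":
            start = (full[1], full[2])
        else:
            start = (math.sqrt(v0),)
        x0 = np.array([mu0, *start])
        bounds = [(None, None)] + [(0.0, None)] * k
        bounds[-1] = (1e-8, None)  # e > 0 keeps the likelihood proper
        res = optimize.minimize(
            _nll_paths, x0, args=(stats_list, model), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        f = float(res.fun)
        if f < best_f - 1e-9:
            best_x, best_f = res.x, f
        elif best_x is not None and abs(f - best_f) <= 1e-9:
            # tie-break on lowest a2 for reproducibility
            a_new = _expand_paths(res.x[1:], model)[0]
            a_old = _expand_paths(best_x[1:], model)[0]
            if a_new < a_old:
                best_x = res.x
        if model == "E":
            break  # closed-form-like; one start suffices
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError(f"{model} fit failed to converge from all starts")
    return best_x, best_f


# --- profile CIs on standardized components -----------------------------

_COMP_INDEX = {"a2": 0, "c2": 1, "e2": 2}


def _profile_nll_component(
    q: float, comp: str, stats_list: Sequence[PairStats]
) -> float:
    """Min NLL subject to (component proportion) = q.

    Parameterization: total variance v and split fraction phi of the
    remaining (1 - q) v between the other two components.
    """
    idx = _COMP_INDEX[comp]

    def nll(theta: np.ndarray) -> float:
        mu, logv, phi = theta
        v = math.exp(min(max(logv, -30.0), 30.0))
        main = q * v
        rest1 = phi * (1.0 - q) * v
        rest2 = (1.0 - phi) * (1.0 - q) * v
        if comp == "a2":
            a2, c2 = main, rest1
        elif comp == "c2":
            a2, c2 = rest1, main
        else:
            a2, c2 = rest1, rest2  # e2 fixed; split A/C
        covs = [st.gamma * a2 + c2 for st in stats_list]
        return _nll_suff(mu, v, covs, stats_list)

    n_tot = sum(st.n for st in stats_list)
    mu0 = sum(st.s1 + st.s2 for st in stats_list) / (2 * n_tot)
    v0 = max(1e-8, sum(st.q1 + st.q2 for st in stats_list) / (2 * n_tot) - mu0 * mu0)
    best = float("inf")
    for phi0 in (0.2, 0.5, 0.8):
        res = optimize.minimize(
            nll, np.array([mu0, math.log(v0), phi0]), method="L-BFGS-B",
            bounds=[(None, None), (-30.0, 30.0), (1e-9, 1.0 - 1e-9)],
            options={"maxiter": 300, "ftol": 1e-12},
        )
        best = min(best, float(res.fun))
    return best


def _profile_ci(
    comp: str, hat: float, nll_hat: float, stats_list: Sequence[PairStats]
) -> tuple[float, float]:
    crit = nll_hat + 0.5 * _CHI2_95

    def dev(q: float) -> float:
        return _profile_nll_component(q, comp, stats_list) - crit

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
    return (
        solve(eps, hat, boundary_is_hi=False),
        solve(hat, 1 - eps, boundary_is_hi=True),
    )


def fit_ace_arrays(
    groups: Mapping[float, tuple[np.ndarray, np.ndarray]] | Sequence[PairStats],
    model: str = "ACE",
    ci_components: Sequence[str] = (),
    n_pairs_labels: Mapping[str, int] | None = None,
) -> FitReport:
    """ML fit from per-gamma pair arrays (or precomputed sufficient stats)."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if isinstance(groups, Mapping):
        stats_list = pair_stats(groups)
    else:
        stats_list = list(groups)
    if not stats_list:
        raise ValueError("no complete pairs available")
    gammas = {st.gamma for st in stats_list}
    if model in ("ACE", "AE") and len(gammas) < 2:
        raise ValueError(
            "need both MZ-type and DZ-type strata to separate A from C"
        )
    for st in stats_list:
        if st.n < 20:
            warnings.warn(
                f"stratum gamma={st.gamma} has only {st.n} pairs; "
                "estimates will be unstable", stacklevel=2,
            )
    x, nll = _fit_ml(stats_list, model)
    mu = float(x[0])
    a, c, e = _expand_paths(x[1:], model)
    v = a * a + c * c + e * e
    comps = {"a2": a * a / v, "c2": c * c / v, "e2": e * e / v}
    params: dict[str, tuple[float, float, float]] = {
        "mu": (mu, float("nan"), float("nan")),
        "var": (v, float("nan"), float("nan")),
    }
    for name in ("a2", "c2", "e2"):
        lo = hi = float("nan")
        if name in ci_components:
            lo, hi = _profile_ci(name, comps[name], nll, stats_list)
            lo, hi = min(lo, comps[name]), max(hi, comps[name])
        params[name] = (comps[name], lo, hi)
    n_pairs = n_pairs_labels or {
        f"gamma={st.gamma:g}": st.n for st in stats_list
    }
    return FitReport(
        model=model, loglik=-nll, n_params=1 + _n_free(model),
        n_pairs=dict(n_pairs), converged=True, params=params,
        extras={"paths": (a, c, e), "free": sorted(_FREE[model])},
    )


def fit_ace_ml(
    records: Sequence[TwinPairRecord],
    trait: str,
    model: str = "ACE",
    ci_components: Sequence[str] = ("a2", "c2", "e2"),
) -> FitReport:
    """Fit an ACE-family model to a continuous trait from pair records.

    Uses complete pairs only; MZ strata enter at gamma = 1 and all DZ
    strata (same- and opposite-sex) at gamma = 0.5.
    """
    buckets = _extract_pairs(records, trait)
    if not buckets:
        raise ValueError(f"no complete pairs with grades for trait {trait!r}")
    gamma_map = {"MZ": 1.0, "DZ": 0.5}
    groups = {gamma_map[k]: v for k, v in buckets.items()}
    labels = {k: len(v[0]) for k, v in buckets.items()}
    return fit_ace_arrays(
        groups, model=model, ci_components=ci_components, n_pairs_labels=labels
    )


def variance_components(report: FitReport) -> VarianceComponents:
    return VarianceComponents(
        a2=report.estimate("a2"), c2=report.estimate("c2"),
        e2=report.estimate("e2"),
    )


def likelihood_ratio_test(full: FitReport, reduced: FitReport) -> LRTResult:
    """Compare nested ML fits.

    ``p_value`` is the naive chi-square tail; ``p_value_boundary`` uses
    the 50:50 mixture of chi-square(df) and chi-square(df-1) appropriate
    when the reduced model pins a variance component at its zero
    boundary. The preferred model is the reduced one when the boundary
    test fails to reject at the 5% level.
    """
    free_full = set(full.extras.get("free", ()))
    free_red = set(reduced.extras.get("free", ()))
    if not free_red <= free_full:
        raise ValueError(
            f"models not nested: {sorted(free_red)} vs {sorted(free_full)}"
        )
    if full.n_pairs != reduced.n_pairs:
        raise ValueError("fits use different data")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise RuntimeError("reduced model outperforms full model: non-convergence")
    stat = max(0.0, stat)
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(stat, df)) if stat > 0 and df > 0 else 1.0
    if stat <= 0 or df == 0:
        p_b = 1.0
    elif df == 1:
        p_b = 0.5 * float(stats.chi2.sf(stat, 1))
    else:
        p_b = 0.5 * float(stats.chi2.sf(stat, df)) + 0.5 * float(
            stats.chi2.sf(stat, df - 1)
        )
    preferred = full.model if p_b < 0.05 else reduced.model
    return LRTResult(statistic=stat, df=df, p_value=p,
                     p_value_boundary=p_b, preferred=preferred)
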