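"""Five-group sex-limitation models.

Comparing MZ male, MZ female, DZ male, DZ female and DZ opposite-sex
pairs separates two kinds of sex difference:

* *quantitative* -- the same genetic and environmental factors operate in
  both sexes but with different magnitudes (sex-specific a, c, e);
* *qualitative* -- partially different factors operate, detected through
  the DZ opposite-sex cross-twin correlation. The opposite-sex additive
  cross-covariance is ``0.5 * rg * a_m * a_f`` and the shared-environment
  part ``rc * c_m * c_f``; rg and rc are not jointly identified from twin
  data, so exactly one is freed (default rg, with rc fixed at 1).

Nested model chain (each a restriction of the previous):

  full > qualitative_constrained (rg = 0.5, or rc = 1)
       > quantitative_equal (male/female paths equated)
       > homogeneous (means/variances equated too)

Works for continuous traits (per-group bivariate-normal likelihood) and
binary traits (liability-threshold likelihood with sex-specific
thresholds; the homogeneous model equates the threshold as well).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .ace_continuous import LRTResult, PairStats
from .tetrachoric import Concordance2x2, bvn_cell_probabilities, bvn_upper
from .twin_data import TwinPairRecord, ZygosityGroup

__all__ = [
    "SexLimSpec",
    "SexLimFit",
    "MODEL_CHAIN",
    "fit_sex_limitation",
    "fit_sex_limitation_chain",
]

MODEL_CHAIN = ("full", "qualitative_constrained", "quantitative_equal", "homogeneous")

_GROUPS = ("MZm", "MZf", "DZm", "DZf", "DZos")


@dataclass(frozen=True)
class SexLimSpec:
    """Which model of the chain to fit and which cross-sex correlation is free."""

    model: str = "full"
    free: str = "rg"  # "rg" (rc fixed at 1) or "rc" (rg fixed at 0.5)

    def __post_init__(self) -> None:
        if self.model not in MODEL_CHAIN:
            raise ValueError(f"model must be one of {MODEL_CHAIN}")
        if self.free not in ("rg", "rc"):
            raise ValueError("free must be 'rg' or 'rc'")


@dataclass
class SexLimFit:
    model: str
    kind: str  # "continuous" or "liability"
    male: dict[str, float]
    female: dict[str, float]
    rg: float
    rc: float
    loglik: float
    n_params: int
    n_pairs: dict[str, int]
    converged: bool
    extras: dict = field(default_factory=dict)


# --- data extraction ----------------------------------------------------

def _continuous_groups(
    records: Sequence[TwinPairRecord], trait: str
) -> dict[str, PairStats]:
    buckets: dict[str, tuple[list, list]] = {g: ([], []) for g in _GROUPS}
    for rec in records:
        g1 = rec.twin1.grades.get(trait)
        g2 = rec.twin2.grades.get(trait)
        if g1 is None or g2 is None:
            continue
        # orient opposite-sex pairs male-first
        if rec.group is ZygosityGroup.DZos and rec.twin1.sex == "F":
            g1, g2 = g2, g1
        b = buckets[rec.group.value]
        b[0].append(g1)
        b[1].append(g2)
    out = {}
    for g, (x1, x2) in buckets.items():
        if x1:
            gamma = 1.0 if g.startswith("MZ") else 0.5
            out[g] = PairStats.from_arrays(gamma, np.array(x1), np.array(x2))
    return out


def _binary_tables(
    records: Sequence[TwinPairRecord], trait: str
) -> dict[str, Concordance2x2]:
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        c1 = rec.twin1.choices.get(trait)
        c2 = rec.twin2.choices.get(trait)
        if c1 is None or c2 is None:
            continue
        if rec.group is ZygosityGroup.DZos and rec.twin1.sex == "F":
            c1, c2 = c2, c1
        cell = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(c1, c2)]
        counts.setdefault(rec.group.value, np.zeros(4))[cell] += 1
    return {k: Concordance2x2(*v, label=k) for k, v in counts.items()}


def _check_groups(n_pairs: Mapping[str, int]) -> None:
    if "DZos" not in n_pairs or n_pairs["DZos"] == 0:
        raise ValueError(
            "sex-limitation model requires opposite-sex DZ pairs; "
            "the qualitative test is undefined without them"
        )
    for g in _GROUPS:
        n = n_pairs.get(g, 0)
        if n < 20:
            warnings.warn(
                f"group {g} has only {n} pairs; the sex-limitation fit is "
                "underpowered", stacklevel=3,
            )


# --- continuous likelihood ---------------------------------------------

def _nll_bvn(mu1, mu2, v1, v2, cv, st: PairStats) -> float:
    det = v1 * v2 - cv * cv
    if det <= 0 or v1 <= 0 or v2 <= 0:
        return float("inf")
    ss1 = st.q1 - 2.0 * mu1 * st.s1 + st.n * mu1 * mu1
    ss2 = st.q2 - 2.0 * mu2 * st.s2 + st.n * mu2 * mu2
    sx = st.x12 - mu1 * st.s2 - mu2 * st.s1 + st.n * mu1 * mu2
    quad = (v2 * ss1 + v1 * ss2 - 2.0 * cv * sx) / det
    return st.n * math.log(2.0 * math.pi) + 0.5 * st.n * math.log(det) + 0.5 * quad


def _unpack_continuous(theta: np.ndarray, model: str, free: str):
    """-> (mum, muf, paths_m, paths_f, rg, rc)"""
    if model == "full":
        mum, muf, am, cm, em, af, cf, ef, x = theta
        rg, rc = (x, 1.0) if free == "rg" else (0.5, x)
    elif model == "qualitative_constrained":
        mum, muf, am, cm, em, af, cf, ef = theta
        rg, rc = 0.5, 1.0
    elif model == "quantitative_equal":
        mum, muf, a, c, e = theta
        am = af = a
        cm = cf = c
        em = ef = e
        rg, rc = 0.5, 1.0
    else:  # homogeneous
        mu, a, c, e = theta
        mum = muf = mu
        am = af = a
        cm = cf = c
        em = ef = e
        rg, rc = 0.5, 1.0
    return mum, muf, (am, cm, em), (af, cf, ef), rg, rc


def _nll_continuous(theta, groups: Mapping[str, PairStats], model, free) -> float:
    mum, muf, (am, cm, em), (af, cf, ef), rg, rc = _unpack_continuous(
        theta, model, free
    )
    vm = am * am + cm * cm + em * em
    vf = af * af + cf * cf + ef * ef
    total = 0.0
    for g, st in groups.items():
        if g == "MZm":
            total += _nll_bvn(mum, mum, vm, vm, am * am + cm * cm, st)
        elif g == "DZm":
            total += _nll_bvn(mum, mum, vm, vm, 0.5 * am * am + cm * cm, st)
        elif g == "MZf":
            total += _nll_bvn(muf, muf, vf, vf, af * af + cf * cf, st)
        elif g == "DZf":
            total += _nll_bvn(muf, muf, vf, vf, 0.5 * af * af + cf * cf, st)
        else:  # DZos, male-first
            cv = 0.5 * rg * am * af + rc * cm * cf
            total += _nll_bvn(mum, muf, vm, vf, cv, st)
    return total


_N_PARAMS_CONT = {"full": 9, "qualitative_constrained": 8,
                  "quantitative_equal": 5, "homogeneous": 4}
_N_PARAMS_LIAB = {"full": 7, "qualitative_constrained": 6,
                  "quantitative_equal": 4, "homogeneous": 3}


def _fit_continuous(groups: Mapping[str, PairStats], spec: SexLimSpec) -> SexLimFit:
    n_tot = sum(st.n for st in groups.values())
    mu0 = sum(st.s1 + st.s2 for st in groups.values()) / (2 * n_tot)
    v0 = max(
        1e-8, sum(st.q1 + st.q2 for st in groups.values()) / (2 * n_tot) - mu0 ** 2
    )
    model, free = spec.model, spec.free
    starts = []
    for a2s, c2s in ((0.5, 0.2), (0.2, 0.5), (0.1, 0.1), (0.35, 0.35)):
        e2s = 1.0 - a2s - c2s
        p = (math.sqrt(a2s * v0), math.sqrt(c2s * v0), math.sqrt(e2s * v0))
        if model == "full":
            x_free = 0.5 if free == "rg" else 1.0
            starts.append([mu0, mu0, *p, *p, x_free])
        elif model == "qualitative_constrained":
            starts.append([mu0, mu0, *p, *p])
        elif model == "quantitative_equal":
            starts.append([mu0, mu0, *p])
        else:
            starts.append([mu0, *p])
    n_theta = len(starts[0])
    bounds: list[tuple] = []
    if model in ("full", "qualitative_constrained", "quantitative_equal"):
        bounds += [(None, None), (None, None)]
    else:
        bounds += [(None, None)]
    n_paths = n_theta - len(bounds) - (1 if model == "full" else 0)
    path_bounds = [(0.0, None)] * n_paths
    # e paths strictly positive
    if n_paths == 6:
        path_bounds[2] = path_bounds[5] = (1e-8, None)
    else:
        path_bounds[-1] = (1e-8, None)
    bounds += path_bounds
    if model == "full":
        bounds.append((0.0, 1.0))
    best_x, best_f = None, float("inf")
    for x0 in starts:
        res = optimize.minimize(
            _nll_continuous, np.array(x0), args=(groups, model, free),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-10},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    assert best_x is not None
    mum, muf, pm, pf, rg, rc = _unpack_continuous(best_x, model, free)
    vm = sum(x * x for x in pm)
    vf = sum(x * x for x in pf)
    male = {"mu": mum, "var": vm, "a2": pm[0] ** 2 / vm,
            "c2": pm[1] ** 2 / vm, "e2": pm[2] ** 2 / vm}
    female = {"mu": muf, "var": vf, "a2": pf[0] ** 2 / vf,
              "c2": pf[1] ** 2 / vf, "e2": pf[2] ** 2 / vf}
    return SexLimFit(
        model=model, kind="continuous", male=male, female=female,
        rg=rg, rc=rc, loglik=-best_f, n_params=_N_PARAMS_CONT[model],
        n_pairs={g: st.n for g, st in groups.items()}, converged=True,
        extras={"free": spec.free},
    )


# --- liability likelihood ----------------------------------------------

def _unpack_liability(theta: np.ndarray, model: str, free: str):
    """-> (tm, tf, (a2m, c2m), (a2f, c2f), rg, rc)"""
    if model == "full":
        tm, tf, a2m, c2m, a2f, c2f, x = theta
        rg, rc = (x, 1.0) if free == "rg" else (0.5, x)
    elif model == "qualitative_constrained":
        tm, tf, a2m, c2m, a2f, c2f = theta
        rg, rc = 0.5, 1.0
    elif model == "quantitative_equal":
        tm, tf, a2, c2 = theta
        a2m = a2f = a2
        c2m = c2f = c2
        rg, rc = 0.5, 1.0
    else:
        t, a2, c2 = theta
        tm = tf = t
        a2m = a2f = a2
        c2m = c2f = c2
        rg, rc = 0.5, 1.0
    return tm, tf, (a2m, c2m), (a2f, c2f), rg, rc


def _nll_liability(theta, tables: Mapping[str, Concordance2x2],
                   model, free) -> float:
    tm, tf, (a2m, c2m), (a2f, c2f), rg, rc = _unpack_liability(theta, model, free)
    for a2, c2 in ((a2m, c2m), (a2f, c2f)):
        if a2 < 0 or c2 < 0 or a2 + c2 > 1.0:
            return float("inf")
    r_by_group = {
        "MZm": a2m + c2m,
        "DZm": 0.5 * a2m + c2m,
        "MZf": a2f + c2f,
        "DZf": 0.5 * a2f + c2f,
        "DZos": 0.5 * rg * math.sqrt(a2m * a2f) + rc * math.sqrt(c2m * c2f),
    }
    t_by_group = {"MZm": (tm, tm), "DZm": (tm, tm), "MZf": (tf, tf),
                  "DZf": (tf, tf), "DZos": (tm, tf)}
    total = 0.0
    for g, tab in tables.items():
        t1, t2 = t_by_group[g]
        p = np.maximum(
            bvn_cell_probabilities(min(r_by_group[g], 1.0), t1, t2), 1e-300
        )
        total -= float(tab.counts @ np.log(p))
    return total


def _fit_liability(tables: Mapping[str, Concordance2x2],
                   spec: SexLimSpec) -> SexLimFit:
    model, free = spec.model, spec.free
    n_total = sum(t.total for t in tables.values())
    n_pos = sum(2 * t.n11 + t.n10 + t.n01 for t in tables.values())
    prev = min(max(n_pos / (2.0 * n_total), 1e-6), 1 - 1e-6)
    t0 = float(stats.norm.isf(prev))
    starts = []
    for a2s, c2s in ((0.5, 0.2), (0.2, 0.5), (0.1, 0.1), (0.3, 0.3)):
        if model == "full":
            x_free = 0.5 if free == "rg" else 1.0
            starts.append([t0, t0, a2s, c2s, a2s, c2s, x_free])
        elif model == "qualitative_constrained":
            starts.append([t0, t0, a2s, c2s, a2s, c2s])
        elif model == "quantitative_equal":
            starts.append([t0, t0, a2s, c2s])
        else:
            starts.append([t0, a2s, c2s])
    if model in ("full", "qualitative_constrained"):
        bounds = [(-6, 6), (-6, 6)] + [(0.0, 1.0)] * (len(starts[0]) - 2)
        cons = [
            {"type": "ineq", "fun": lambda th: 1.0 - th[2] - th[3]},
            {"type": "ineq", "fun": lambda th: 1.0 - th[4] - th[5]},
        ]
    elif model == "quantitative_equal":
        bounds = [(-6, 6), (-6, 6), (0.0, 1.0), (0.0, 1.0)]
        cons = [{"type": "ineq", "fun": lambda th: 1.0 - th[2] - th[3]}]
    else:
        bounds = [(-6, 6), (0.0, 1.0), (0.0, 1.0)]
        cons = [{"type": "ineq", "fun": lambda th: 1.0 - th[1] - th[2]}]
    best_x, best_f = None, float("inf")
    for x0 in starts:
        res = optimize.minimize(
            _nll_liability, np.array(x0), args=(tables, model, free),
            method="SLSQP", bounds=bounds, constraints=cons,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    assert best_x is not None
    tm, tf, (a2m, c2m), (a2f, c2f), rg, rc = _unpack_liability(best_x, model, free)
    male = {"threshold": tm, "a2": a2m, "c2": c2m, "e2": 1.0 - a2m - c2m}
    female = {"threshold": tf, "a2": a2f, "c2": c2f, "e2": 1.0 - a2f - c2f}
    return SexLimFit(
        model=model, kind="liability", male=male, female=female,
        rg=rg, rc=rc, loglik=-best_f, n_params=_N_PARAMS_LIAB[model],
        n_pairs={g: int(t.total) for g, t in tables.items()}, converged=True,
        extras={"free": spec.free},
    )


def fit_sex_limitation(
    records: Sequence[TwinPairRecord],
    trait: str,
    spec: SexLimSpec = SexLimSpec(),
    kind: str = "auto",
) -> SexLimFit:
    """Fit one sex-limitation model to a continuous or binary trait.

    ``kind='auto'`` fits the liability model when the trait appears in the
    choice maps, otherwise the continuous model on the grade maps.
    """
    if kind == "auto":
        has_choice = any(trait in r.twin1.choices for r in records)
        has_grade = any(
            r.twin1.grades.get(trait) is not None for r in records
        )
        kind = "continuous" if has_grade else ("liability" if has_choice else "")
        if not kind:
            raise ValueError(f"trait {trait!r} not found in records")
    if kind == "continuous":
        groups = _continuous_groups(records, trait)
        _check_groups({g: st.n for g, st in groups.items()})
        return _fit_continuous(groups, spec)
    if kind == "liability":
        tables = _binary_tables(records, trait)
        _check_groups({g: int(t.total) for g, t in tables.items()})
        return _fit_liability(tables, spec)
    raise ValueError(f"unknown kind {kind!r}")


def fit_sex_limitation_chain(
    records: Sequence[TwinPairRecord],
    trait: str,
    free: str = "rg",
    kind: str = "auto",
) -> tuple[dict[str, SexLimFit], dict[str, LRTResult]]:
    """Fit the full nested chain and LRT each reduced model against the full.

    Returns ``(fits, tests)`` keyed by model label; tests compare each
    restricted model with the full model (naive chi-square p-values; the
    restrictions are interior equality constraints, not boundary ones).
    """
    fits = {
        m: fit_sex_limitation(records, trait, SexLimSpec(model=m, free=free), kind)
        for m in MODEL_CHAIN
    }
    full = fits["full"]
    tests = {}
    for m in MODEL_CHAIN[1:]:
        red = fits[m]
        stat = max(0.0, 2.0 * (full.loglik - red.loglik))
        df = full.n_params - red.n_params
        p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
        tests[m] = LRTResult(
            statistic=stat, df=df, p_value=p, p_value_boundary=p,
            preferred="full" if p < 0.05 else m,
        )
    return fits, tests
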