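"""Synthetic twin cohorts with known ACE structure.

The generator draws latent additive-genetic (A), shared-environment (C)
and non-shared (E) components per twin with the cross-twin correlations
the classical twin design assumes: A correlates 1 within MZ pairs and
0.5 within DZ pairs (``0.5 * rg`` for opposite-sex pairs), C correlates 1
(``rc`` for opposite-sex pairs), E is independent. A standardized
phenotype is ``a*A + c*C + e*E``; a binary choice is the indicator that
the same kind of liability exceeds the standard-normal threshold at the
configured prevalence.

:func:`simulate_teds_like` reproduces the structure of a UK twin-register
educational cohort: 6584 pairs (2318 MZ / 2146 DZ same-sex / 2120 DZ
opposite-sex), a binary A-level choice for everyone and a 1-6 scale
achievement grade observed only in choosers. Selection into achievement
is driven by the choice itself, and the achievement liability shares a
configurable fraction of its latent components with the choice liability,
so the restriction of range is genetically informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy import stats

from .twin_data import GROUP_ORDER, TwinMember, TwinPairRecord, ZygosityGroup

__all__ = [
    "ACEParams",
    "SimulationConfig",
    "ConfigError",
    "teds_default_config",
    "simulate_continuous",
    "simulate_binary_choice",
    "simulate_teds_like",
    "simulate_pair_arrays",
    "simulate_choice_arrays",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ACEParams:
    """Standardized variance proportions a², c², e² (must sum to 1)."""

    a2: float
    c2: float
    e2: float

    def validate(self) -> None:
        for name, v in (("a2", self.a2), ("c2", self.c2), ("e2", self.e2)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-8:
            raise ConfigError(
                f"a2 + c2 + e2 = {self.a2 + self.c2 + self.e2} != 1"
            )

    @property
    def paths(self) -> tuple[float, float, float]:
        return (math.sqrt(self.a2), math.sqrt(self.c2), math.sqrt(self.e2))


# sexes of twin 1 and twin 2 per zygosity group (DZos is male-first by
# construction; analyses orient by the sex column, not by twin index)
GROUP_SEXES: dict[ZygosityGroup, tuple[str, str]] = {
    ZygosityGroup.MZm: ("M", "M"),
    ZygosityGroup.MZf: ("F", "F"),
    ZygosityGroup.DZm: ("M", "M"),
    ZygosityGroup.DZf: ("F", "F"),
    ZygosityGroup.DZos: ("M", "F"),
}


@dataclass
class SimulationConfig:
    """Generating model and cohort layout for one simulated twin study.

    Defaults mirror the emulated cohort: 6584 pairs in five zygosity
    groups (MZ and DZ same-sex pairs split evenly by sex), choice
    prevalence 0.5, grades centred at 3.90 with SD 1.16 on the 1-6 scale.
    ``ace`` drives the primary phenotype (the choice liability in
    :func:`simulate_teds_like`); ``grade_ace`` drives the achievement
    grade, whose latents overlap the choice latents with weight
    ``choice_grade_overlap`` (0 = independent, 1 = identical liability).
    """

    n_mzm: int = 1159
    n_mzf: int = 1159
    n_dzm: int = 1073
    n_dzf: int = 1073
    n_dzos: int = 2120
    ace: ACEParams | None = None
    ace_male: ACEParams | None = None
    ace_female: ACEParams | None = None
    grade_ace: ACEParams | None = None
    rg: float = 1.0
    rc: float = 1.0
    prevalence: float = 0.5
    grade_mean: float = 3.90
    grade_sd: float = 1.16
    grade_discretize: str = "continuous"  # or "integer"
    age_min: float = 18.0
    age_max: float = 19.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    choice_grade_overlap: float = 0.5
    seed: int | None = None

    def validate(self) -> None:
        for name in ("n_mzm", "n_mzf", "n_dzm", "n_dzf", "n_dzos"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.ace is None and (self.ace_male is None or self.ace_female is None):
            raise ConfigError("either common 'ace' or both sex-specific sets required")
        for p in (self.ace, self.ace_male, self.ace_female, self.grade_ace):
            if p is not None:
                p.validate()
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence {self.prevalence} must lie strictly in (0, 1)")
        for name in ("rg", "rc", "choice_grade_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.grade_sd <= 0:
            raise ConfigError("grade_sd must be positive")
        if self.grade_discretize not in ("continuous", "integer"):
            raise ConfigError(f"unknown grade_discretize {self.grade_discretize!r}")
        if self.age_max < self.age_min:
            raise ConfigError("age_max < age_min")

    def params_for_sex(self, sex: str) -> ACEParams:
        if self.ace_male is not None and self.ace_female is not None:
            return self.ace_male if sex == "M" else self.ace_female
        assert self.ace is not None
        return self.ace

    def group_sizes(self) -> dict[ZygosityGroup, int]:
        return {
            ZygosityGroup.MZm: self.n_mzm,
            ZygosityGroup.MZf: self.n_mzf,
            ZygosityGroup.DZm: self.n_dzm,
            ZygosityGroup.DZf: self.n_dzf,
            ZygosityGroup.DZos: self.n_dzos,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("ace", "ace_male", "ace_female", "grade_ace"):
            if d[k] is not None:
                d[k] = dict(d[k])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for k in ("ace", "ace_male", "ace_female", "grade_ace"):
            if d.get(k) is not None:
                d[k] = ACEParams(**d[k])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def teds_default_config(seed: int | None = None) -> SimulationConfig:
    """Cohort configured at the study's headline generating values.

    Choice liability (0.44, 0.47, 0.09); achievement (0.59, 0.07, 0.34);
    prevalence 0.5; grade scale mean 3.90, SD 1.16.
    """
    return SimulationConfig(
        ace=ACEParams(0.44, 0.47, 0.09),
        grade_ace=ACEParams(0.59, 0.07, 0.34),
        seed=seed,
    )


def _correlation_structure(
    group: ZygosityGroup, rg: float, rc: float
) -> tuple[float, float]:
    """Cross-twin correlations (A-correlation, C-correlation) for a group."""
    if group.is_mz:
        a_corr = 1.0
    elif group.is_opposite_sex:
        a_corr = 0.5 * rg
    else:
        a_corr = 0.5
    c_corr = rc if group.is_opposite_sex else 1.0
    return a_corr, c_corr


def _draw_latents(
    rng: np.random.Generator, n: int, a_corr: float, c_corr: float
) -> tuple[np.ndarray, ...]:
    """Six standard-normal latent vectors (A1, A2, C1, C2, E1, E2)."""
    def pair(corr: float) -> tuple[np.ndarray, np.ndarray]:
        shared = rng.standard_normal(n)
        w, u = math.sqrt(corr), math.sqrt(1.0 - corr)
        return (
            w * shared + u * rng.standard_normal(n),
            w * shared + u * rng.standard_normal(n),
        )

    a1, a2 = pair(a_corr)
    c1, c2 = pair(c_corr)
    return a1, a2, c1, c2, rng.standard_normal(n), rng.standard_normal(n)


def _combine(
    latents: tuple[np.ndarray, ...], p1: ACEParams, p2: ACEParams
) -> tuple[np.ndarray, np.ndarray]:
    a1, a2, c1, c2, e1, e2 = latents
    pa1, pc1, pe1 = p1.paths
    pa2, pc2, pe2 = p2.paths
    return pa1 * a1 + pc1 * c1 + pe1 * e1, pa2 * a2 + pc2 * c2 + pe2 * e2


def simulate_pair_arrays(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[ZygosityGroup, tuple[np.ndarray, np.ndarray]]:
    """Standardized continuous phenotypes per group, as ``(twin1, twin2)`` arrays.

    Low-level path used by power and coverage simulations where building
    full records would dominate the run time.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = {}
    for group, n in config.group_sizes().items():
        if n == 0:
            continue
        a_corr, c_corr = _correlation_structure(group, config.rg, config.rc)
        s1, s2 = GROUP_SEXES[group]
        lat = _draw_latents(rng, n, a_corr, c_corr)
        y1, y2 = _combine(lat, config.params_for_sex(s1), config.params_for_sex(s2))
        if config.sex_effect != 0.0:
            if s1 == "F":
                y1 = y1 + config.sex_effect
            if s2 == "F":
                y2 = y2 + config.sex_effect
        out[group] = (y1, y2)
    return out


def simulate_choice_arrays(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[ZygosityGroup, tuple[np.ndarray, np.ndarray]]:
    """Binary choice indicators per group (liability above the prevalence threshold)."""
    t = stats.norm.isf(config.prevalence)
    return {
        g: ((y1 > t).astype(np.int64), (y2 > t).astype(np.int64))
        for g, (y1, y2) in simulate_pair_arrays(config, rng).items()
    }


def _grade_from_latent(config: SimulationConfig, y: np.ndarray) -> np.ndarray:
    g = config.grade_mean + config.grade_sd * y
    if config.grade_discretize == "integer":
        g = np.rint(g)
    return np.clip(g, 1.0, 6.0)


def _build_records(
    config: SimulationConfig,
    rng: np.random.Generator,
    per_group: dict[ZygosityGroup, dict[str, tuple[np.ndarray, np.ndarray]]],
    choice_traits: set[str],
) -> list[TwinPairRecord]:
    records: list[TwinPairRecord] = []
    fid = 0
    for group in GROUP_ORDER:
        if group not in per_group:
            continue
        data = per_group[group]
        n = len(next(iter(data.values()))[0])
        ages = rng.uniform(config.age_min, config.age_max, size=n)
        s1, s2 = GROUP_SEXES[group]
        for i in range(n):
            members = []
            for j, sex in ((0, s1), (1, s2)):
                choices: dict[str, int | None] = {}
                grades: dict[str, float | None] = {}
                for name, arrs in data.items():
                    v = arrs[j][i]
                    if name in choice_traits:
                        choices[name.removeprefix("choice:")] = (
                            None if np.isnan(v) else int(v)
                        )
                    else:
                        grades[name.removeprefix("grade:")] = (
                            None if np.isnan(v) else float(v)
                        )
                members.append(TwinMember(sex=sex, choices=choices, grades=grades))
            fid += 1
            records.append(
                TwinPairRecord(
                    family_id=f"F{fid:06d}",
                    group=group,
                    age=round(float(ages[i]), 2),
                    twin1=members[0],
                    twin2=members[1],
                )
            )
    return records


def simulate_continuous(
    config: SimulationConfig, trait: str = "trait"
) -> list[TwinPairRecord]:
    """Cohort with one continuous phenotype on the 1-6 grade scale.

    The standardized ACE phenotype is mapped through
    ``grade_mean + grade_sd * y`` and clipped to [1, 6]; the matching
    choice flag is 1 for everyone (no selection). Optional age and sex
    mean effects are added before scaling.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    per_group: dict[ZygosityGroup, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    ages_cache: dict[ZygosityGroup, np.ndarray] = {}
    for group, n in config.group_sizes().items():
        if n == 0:
            continue
        a_corr, c_corr = _correlation_structure(group, config.rg, config.rc)
        s1, s2 = GROUP_SEXES[group]
        lat = _draw_latents(rng, n, a_corr, c_corr)
        y1, y2 = _combine(lat, config.params_for_sex(s1), config.params_for_sex(s2))
        age = rng.uniform(config.age_min, config.age_max, size=n)
        mid = 0.5 * (config.age_min + config.age_max)
        for y, sex in ((y1, s1), (y2, s2)):
            y += config.age_effect * (age - mid)
            if sex == "F":
                y += config.sex_effect
        g1, g2 = _grade_from_latent(config, y1), _grade_from_latent(config, y2)
        per_group[group] = {
            f"choice:{trait}": (np.ones(n), np.ones(n)),
            f"grade:{trait}": (g1, g2),
        }
        ages_cache[group] = age
    # ages must match those used for the age effect, so rebuild with a
    # dedicated rng whose draws we override below
    records = _build_records(
        config, np.random.default_rng(0), per_group, {f"choice:{trait}"}
    )
    flat_ages = np.concatenate([ages_cache[g] for g in GROUP_ORDER if g in ages_cache])
    for rec, a in zip(records, flat_ages):
        rec.age = round(float(a), 2)
    return records


def simulate_binary_choice(
    config: SimulationConfig, trait: str = "choice"
) -> list[TwinPairRecord]:
    """Cohort with one binary choice trait thresholded at prevalence K."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = stats.norm.isf(config.prevalence)
    per_group = {}
    for group, (y1, y2) in simulate_pair_arrays(config, rng).items():
        per_group[group] = {
            f"choice:{trait}": (
                (y1 > t).astype(float), (y2 > t).astype(float)
            )
        }
    return _build_records(config, rng, per_group, {f"choice:{trait}"})


def simulate_teds_like(
    config: SimulationConfig | None = None, trait: str = "alevel"
) -> list[TwinPairRecord]:
    """Full study-shaped cohort: choice for all, grades only for choosers.

    The choice liability follows ``config.ace`` (per sex if set); the
    achievement phenotype follows ``config.grade_ace`` (defaults to
    ``config.ace``) with each of its latent components mixing the choice
    component (weight ``choice_grade_overlap``) with a fresh draw, so both
    phenotypes keep exact marginal ACE proportions while choosers are a
    non-random, genetically informative subset. Grades of non-choosers
    are missing.
    """
    if config is None:
        config = teds_default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = stats.norm.isf(config.prevalence)
    grade_ace = config.grade_ace or config.ace or config.ace_male
    assert grade_ace is not None
    alpha = config.choice_grade_overlap
    beta = math.sqrt(1.0 - alpha * alpha)

    per_group = {}
    ages_cache = {}
    mid = 0.5 * (config.age_min + config.age_max)
    for group, n in config.group_sizes().items():
        if n == 0:
            continue
        a_corr, c_corr = _correlation_structure(group, config.rg, config.rc)
        s1, s2 = GROUP_SEXES[group]
        base = _draw_latents(rng, n, a_corr, c_corr)
        fresh = _draw_latents(rng, n, a_corr, c_corr)
        mixed = tuple(alpha * b + beta * f for b, f in zip(base, fresh))
        l1, l2 = _combine(base, config.params_for_sex(s1), config.params_for_sex(s2))
        g1, g2 = _combine(mixed, grade_ace, grade_ace)
        age = rng.uniform(config.age_min, config.age_max, size=n)
        for g, sex in ((g1, s1), (g2, s2)):
            g += config.age_effect * (age - mid)
            if sex == "F":
                g += config.sex_effect
        ch1, ch2 = (l1 > t).astype(float), (l2 > t).astype(float)
        gr1, gr2 = _grade_from_latent(config, g1), _grade_from_latent(config, g2)
        gr1 = np.where(ch1 == 1, gr1, np.nan)
        gr2 = np.where(ch2 == 1, gr2, np.nan)
        per_group[group] = {
            f"choice:{trait}": (ch1, ch2),
            f"grade:{trait}": (gr1, gr2),
        }
        ages_cache[group] = age
    records = _build_records(
        config, np.random.default_rng(0), per_group, {f"choice:{trait}"}
    )
    flat_ages = np.concatenate([ages_cache[g] for g in GROUP_ORDER if g in ages_cache])
    for rec, a in zip(records, flat_ages):
        rec.age = round(float(a), 2)
    return records
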