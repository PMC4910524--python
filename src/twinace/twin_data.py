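"""Domain types and I/O for twin-pair tables.

The tabular interchange format is long CSV: one row per individual with
columns ``family_id, twin, zygosity, sex, age`` followed by phenotype
columns ``choice_<trait>`` (binary) and ``grade_<trait>`` (1-6 scale).
Missing cells may be empty or the sentinel string ``NA``; ``NA`` is
written on output.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ZygosityGroup",
    "TwinMember",
    "TwinPairRecord",
    "FitReport",
    "MalformedPairError",
    "InvariantViolationError",
    "read_twin_table",
    "write_twin_table",
    "records_to_frame",
    "frame_to_records",
    "summarize_counts",
    "GROUP_ORDER",
]


class MalformedPairError(ValueError):
    """A family does not form a valid twin pair."""


class InvariantViolationError(ValueError):
    """A record violates a structural invariant (e.g. sex-discordant MZ pair)."""


class ZygosityGroup(enum.Enum):
    """Five-group zygosity classification used throughout the twin design.

    ``gamma`` is the additive-genetic relatedness coefficient: monozygotic
    pairs share all segregating genes (gamma = 1), dizygotic pairs share
    half on average (gamma = 0.5).
    """

    MZm = "MZm"
    MZf = "MZf"
    DZm = "DZm"
    DZf = "DZf"
    DZos = "DZos"

    @property
    def gamma(self) -> float:
        return 1.0 if self.is_mz else 0.5

    @property
    def is_mz(self) -> bool:
        return self.name.startswith("MZ")

    @property
    def is_opposite_sex(self) -> bool:
        return self is ZygosityGroup.DZos


GROUP_ORDER: tuple[ZygosityGroup, ...] = (
    ZygosityGroup.MZm,
    ZygosityGroup.MZf,
    ZygosityGroup.DZm,
    ZygosityGroup.DZf,
    ZygosityGroup.DZos,
)


@dataclass
class TwinMember:
    """One individual of a pair: sex plus per-trait choice flags and grades."""

    sex: str
    choices: dict[str, int | None] = field(default_factory=dict)
    grades: dict[str, float | None] = field(default_factory=dict)


@dataclass
class TwinPairRecord:
    """One family's twin pair.

    Invariants (enforced by :meth:`validate`):

    * same-sex groups have concordant sexes; DZos pairs have discordant sexes
    * a grade is present for a trait only if the matching choice flag is 1
    * grades lie on the 1-6 scale
    """

    family_id: str
    group: ZygosityGroup
    age: float
    twin1: TwinMember
    twin2: TwinMember

    def validate(self) -> None:
        sexes = {self.twin1.sex, self.twin2.sex}
        if not sexes <= {"M", "F"}:
            raise InvariantViolationError(
                f"family {self.family_id}: sexes must be 'M'/'F', got {sorted(sexes)}"
            )
        if self.group.is_opposite_sex:
            if len(sexes) != 2:
                raise InvariantViolationError(
                    f"family {self.family_id}: DZos pair must be opposite-sex"
                )
        elif len(sexes) != 1:
            raise InvariantViolationError(
                f"family {self.family_id}: same-sex group {self.group.value} "
                f"with discordant sexes"
            )
        else:
            expected = "M" if self.group.value.endswith("m") else "F"
            if self.twin1.sex != expected:
                raise InvariantViolationError(
                    f"family {self.family_id}: group {self.group.value} but sex "
                    f"{self.twin1.sex}"
                )
        for member in (self.twin1, self.twin2):
            for trait, grade in member.grades.items():
                if grade is None:
                    continue
                if not (1.0 <= grade <= 6.0):
                    raise InvariantViolationError(
                        f"family {self.family_id}: grade {grade!r} for {trait!r} "
                        f"outside [1, 6]"
                    )
                if member.choices.get(trait) != 1:
                    raise InvariantViolationError(
                        f"family {self.family_id}: grade present for {trait!r} "
                        f"without choice = 1"
                    )


@dataclass
class FitReport:
    """Generic carrier for a maximum-likelihood fit.

    ``params`` maps parameter name to ``(estimate, ci_low, ci_high)``; CI
    bounds may be NaN when not requested.
    """

    model: str
    loglik: float
    n_params: int
    n_pairs: dict[str, int]
    converged: bool
    params: dict[str, tuple[float, float, float]]
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (est, lo, hi) in self.params.items():
            if not (math.isnan(lo) or math.isnan(hi)) and not (
                lo <= est + 1e-9 and est <= hi + 1e-9
            ):
                raise ValueError(f"parameter {name}: CI [{lo}, {hi}] excludes {est}")

    def estimate(self, name: str) -> float:
        return self.params[name][0]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_pairs": self.n_pairs,
            "converged": self.converged,
            "params": {
                k: {"estimate": v[0], "ci_low": v[1], "ci_high": v[2]}
                for k, v in self.params.items()
            },
        }


_BASE_COLUMNS = ["family_id", "twin", "zygosity", "sex", "age"]


def _trait_columns(columns: Iterable[str]) -> tuple[list[str], list[str]]:
    choice = [c for c in columns if c.startswith("choice_")]
    grade = [c for c in columns if c.startswith("grade_")]
    return choice, grade


def read_twin_table(
    source, schema: Mapping[str, str] | None = None
) -> list[TwinPairRecord]:
    """Read a long-format twin CSV into validated pair records.

    ``schema`` optionally renames columns (map from file column name to the
    canonical name). Every ``family_id`` must appear exactly twice; pairs
    are assembled in twin-index order and all record invariants are checked.
    """
    df = pd.read_csv(source, dtype={"family_id": str}, na_values=["NA"], keep_default_na=True)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedPairError(f"missing required columns: {missing}")
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[TwinPairRecord]:
    """Assemble a long-format DataFrame (one row per individual) into records."""
    choice_cols, grade_cols = _trait_columns(df.columns)
    records: list[TwinPairRecord] = []
    for fid, rows in df.groupby("family_id", sort=False):
        if len(rows) != 2:
            raise MalformedPairError(
                f"family {fid}: expected 2 rows, found {len(rows)}"
            )
        rows = rows.sort_values("twin")
        r1, r2 = rows.iloc[0], rows.iloc[1]
        zyg = str(r1["zygosity"])
        try:
            group = ZygosityGroup(zyg)
        except ValueError:
            raise MalformedPairError(
                f"family {fid}: unknown zygosity code {zyg!r}"
            ) from None
        if str(r2["zygosity"]) != zyg:
            raise MalformedPairError(f"family {fid}: zygosity differs within pair")
        if not np.isclose(float(r1["age"]), float(r2["age"])):
            raise InvariantViolationError(f"family {fid}: ages differ within pair")
        members = []
        for r in (r1, r2):
            choices = {
                c[len("choice_"):]: (None if pd.isna(r[c]) else int(r[c]))
                for c in choice_cols
            }
            grades = {
                g[len("grade_"):]: (None if pd.isna(r[g]) else float(r[g]))
                for g in grade_cols
            }
            members.append(TwinMember(sex=str(r["sex"]), choices=choices, grades=grades))
        rec = TwinPairRecord(
            family_id=str(fid),
            group=group,
            age=float(r1["age"]),
            twin1=members[0],
            twin2=members[1],
        )
        rec.validate()
        records.append(rec)
    return records


def records_to_frame(records: Sequence[TwinPairRecord]) -> pd.DataFrame:
    """Flatten records to the long one-row-per-individual layout."""
    traits_c: list[str] = []
    traits_g: list[str] = []
    for rec in records:
        for t in rec.twin1.choices:
            if t not in traits_c:
                traits_c.append(t)
        for t in rec.twin1.grades:
            if t not in traits_g:
                traits_g.append(t)
    rows = []
    for rec in records:
        for idx, member in ((1, rec.twin1), (2, rec.twin2)):
            row: dict = {
                "family_id": rec.family_id,
                "twin": idx,
                "zygosity": rec.group.value,
                "sex": member.sex,
                "age": rec.age,
            }
            for t in traits_c:
                row[f"choice_{t}"] = member.choices.get(t)
            for t in traits_g:
                row[f"grade_{t}"] = member.grades.get(t)
            rows.append(row)
    cols = _BASE_COLUMNS + [f"choice_{t}" for t in traits_c] + [f"grade_{t}" for t in traits_g]
    return pd.DataFrame(rows, columns=cols)


def write_twin_table(records: Sequence[TwinPairRecord], dest) -> None:
    """Write records as long CSV; missing cells become the sentinel ``NA``."""
    df = records_to_frame(records)
    # choice columns as nullable ints so "1" round-trips, not "1.0"
    for c in df.columns:
        if c.startswith("choice_"):
            df[c] = df[c].astype("Int64")
    df.to_csv(dest, index=False, na_rep="NA")


def summarize_counts(
    records: Sequence[TwinPairRecord], trait: str
) -> pd.DataFrame:
    """Chooser counts and shares for one binary trait.

    One row per category. The ``percent`` column uses an explicit
    denominator per row: the whole non-missing sample for the overall
    choosing rate, and the chooser count for sex and zygosity-group shares
    (shares of *who* chose, not of the population). Percentages carry one
    decimal; round at presentation time.
    """
    known = False
    n_choosers = 0
    n_total = 0
    by_sex: dict[str, int] = {"M": 0, "F": 0}
    by_group: dict[str, int] = {g.value: 0 for g in GROUP_ORDER}
    for rec in records:
        for member in (rec.twin1, rec.twin2):
            if trait not in member.choices:
                continue
            known = True
            flag = member.choices[trait]
            if flag is None:
                continue
            n_total += 1
            if flag == 1:
                n_choosers += 1
                by_sex[member.sex] += 1
                by_group[rec.group.value] += 1
    if not known:
        raise KeyError(f"trait {trait!r} not present in any record")

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 1) if den else 0.0

    rows = [
        {"category": "choosers", "count": n_choosers, "denominator": n_total,
         "percent": pct(n_choosers, n_total)},
        {"category": "male", "count": by_sex["M"], "denominator": n_choosers,
         "percent": pct(by_sex["M"], n_choosers)},
        {"category": "female", "count": by_sex["F"], "denominator": n_choosers,
         "percent": pct(by_sex["F"], n_choosers)},
    ]
    for g in GROUP_ORDER:
        rows.append(
            {"category": g.value, "count": by_group[g.value],
             "denominator": n_choosers, "percent": pct(by_group[g.value], n_choosers)}
        )
    return pd.DataFrame(rows).set_index("category")
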