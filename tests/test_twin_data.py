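import io
import math

import pytest

from twinace.synthetic_twins import ACEParams, SimulationConfig, simulate_teds_like
from twinace.twin_data import (
    FitReport,
    InvariantViolationError,
    MalformedPairError,
    TwinMember,
    TwinPairRecord,
    ZygosityGroup,
    read_twin_table,
    summarize_counts,
    write_twin_table,
)

HEADER = "family_id,twin,zygosity,sex,age,choice_alevel,grade_alevel\n"


def make_record(group="MZf", sexes=("F", "F"), choice=(1, 1), grade=(4.0, 5.0),
                fid="fam1"):
    members = [
        TwinMember(sex=s, choices={"alevel": c},
                   grades={"alevel": g if c == 1 else None})
        for s, c, g in zip(sexes, choice, grade)
    ]
    return TwinPairRecord(family_id=fid, group=ZygosityGroup(group), age=18.5,
                          twin1=members[0], twin2=members[1])


class TestReadTwinTable:
    def test_minimal_mzf_pair(self):
        csv = HEADER + "f1,1,MZf,F,18.2,1,4\nf1,2,MZf,F,18.2,1,5\n"
        records = read_twin_table(io.StringIO(csv))
        assert len(records) == 1
        rec = records[0]
        assert rec.group is ZygosityGroup.MZf
        assert rec.twin1.choices["alevel"] == 1
        assert rec.twin2.grades["alevel"] == 5.0

    def test_mz_pair_with_discordant_sex_rejected(self):
        csv = HEADER + "f1,1,MZm,M,18.2,1,4\nf1,2,MZm,F,18.2,1,5\n"
        with pytest.raises(InvariantViolationError):
            read_twin_table(io.StringIO(csv))

    def test_family_with_wrong_row_count(self):
        csv = HEADER + "f1,1,MZf,F,18.2,1,4\n"
        with pytest.raises(MalformedPairError, match="f1"):
            read_twin_table(io.StringIO(csv))

    def test_unknown_zygosity_code(self):
        csv = HEADER + "f1,1,XX,F,18.2,1,4\nf1,2,XX,F,18.2,1,5\n"
        with pytest.raises(MalformedPairError, match="zygosity"):
            read_twin_table(io.StringIO(csv))

    def test_dzos_must_be_opposite_sex(self):
        csv = HEADER + "f1,1,DZos,M,18.2,1,4\nf1,2,DZos,M,18.2,1,5\n"
        with pytest.raises(InvariantViolationError):
            read_twin_table(io.StringIO(csv))

    def test_grade_requires_choice(self):
        csv = HEADER + "f1,1,MZf,F,18.2,0,4\nf1,2,MZf,F,18.2,1,5\n"
        with pytest.raises(InvariantViolationError, match="choice"):
            read_twin_table(io.StringIO(csv))


def test_round_trip_preserves_records_and_missingness():
    cfg = SimulationConfig(
        n_mzm=2, n_mzf=2, n_dzm=2, n_dzf=2, n_dzos=2,
        ace=ACEParams(0.44, 0.47, 0.09), grade_ace=ACEParams(0.59, 0.07, 0.34),
        seed=5,
    )
    records = simulate_teds_like(cfg)
    buf = io.StringIO()
    write_twin_table(records, buf)
    buf.seek(0)
    back = read_twin_table(buf)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert a.family_id == b.family_id
        assert a.group is b.group
        assert math.isclose(a.age, b.age)
        for ma, mb in ((a.twin1, b.twin1), (a.twin2, b.twin2)):
            assert ma.sex == mb.sex
            assert ma.choices == mb.choices
            for t in ma.grades:
                ga, gb = ma.grades[t], mb.grades[t]
                assert (ga is None) == (gb is None)
                if ga is not None:
                    assert math.isclose(ga, gb, rel_tol=1e-9)


class TestZygosityGroup:
    def test_gamma_is_one_exactly_for_mz(self):
        for g in ZygosityGroup:
            assert (g.gamma == 1.0) == g.name.startswith("MZ")

    def test_dzos_is_the_only_mixed_sex_group(self):
        assert [g for g in ZygosityGroup if g.is_opposite_sex] == [ZygosityGroup.DZos]


class TestSummarizeCounts:
    def records(self):
        recs = []
        # 3 female chooser pairs (MZf), 2 male chooser pairs (MZm),
        # 2 male non-chooser pairs (DZm)
        for i in range(3):
            recs.append(make_record("MZf", ("F", "F"), (1, 1), fid=f"f{i}"))
        for i in range(2):
            recs.append(make_record("MZm", ("M", "M"), (1, 1), fid=f"m{i}"))
        for i in range(2):
            recs.append(make_record("DZm", ("M", "M"), (0, 0), grade=(None, None),
                                    fid=f"d{i}"))
        return recs

    def test_counts_and_shares(self):
        table = summarize_counts(self.records(), "alevel")
        assert table.loc["choosers", "count"] == 10
        assert table.loc["choosers", "denominator"] == 14
        assert table.loc["choosers", "percent"] == pytest.approx(71.4)
        # sex shares are of the choosers, not of the sample
        assert table.loc["female", "percent"] == pytest.approx(60.0)
        assert table.loc["male", "percent"] == pytest.approx(40.0)

    def test_group_shares_partition_choosers(self):
        table = summarize_counts(self.records(), "alevel")
        groups = ["MZm", "MZf", "DZm", "DZf", "DZos"]
        assert table.loc[groups, "count"].sum() == table.loc["choosers", "count"]
        assert table.loc[groups, "percent"].sum() == pytest.approx(100.0, abs=0.5)

    def test_zero_choosers_no_division_error(self):
        recs = [make_record("MZf", ("F", "F"), (0, 0), grade=(None, None))]
        table = summarize_counts(recs, "alevel")
        assert table.loc["choosers", "percent"] == 0.0
        assert table.loc["female", "percent"] == 0.0

    def test_unknown_trait(self):
        with pytest.raises(KeyError):
            summarize_counts(self.records(), "nope")


def test_fit_report_rejects_ci_excluding_estimate():
    with pytest.raises(ValueError, match="CI"):
        FitReport(model="ACE", loglik=0.0, n_params=4, n_pairs={}, converged=True,
                  params={"a2": (0.5, 0.6, 0.9)})
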