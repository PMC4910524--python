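import numpy as np
import pytest

from twinace.synthetic_twins import (
    ACEParams,
    ConfigError,
    SimulationConfig,
    simulate_binary_choice,
    simulate_choice_arrays,
    simulate_continuous,
    simulate_pair_arrays,
    simulate_teds_like,
    teds_default_config,
)
from twinace.twin_data import ZygosityGroup, records_to_frame


def corr(xy):
    return float(np.corrcoef(xy[0], xy[1])[0, 1])


class TestConfigValidation:
    def test_prevalence_must_be_interior(self):
        cfg = SimulationConfig(ace=ACEParams(0.5, 0.2, 0.3), prevalence=1.0)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_components_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(ace=ACEParams(0.5, 0.2, 0.2)).validate()

    def test_roundtrip_through_dict(self):
        cfg = teds_default_config(seed=3)
        back = SimulationConfig.from_dict(cfg.to_dict())
        assert back == cfg


class TestContinuousStructure:
    def test_pure_noise_has_no_twin_correlation(self):
        cfg = SimulationConfig(n_mzm=10_000, n_mzf=0, n_dzm=0, n_dzf=0, n_dzos=0,
                               ace=ACEParams(0.0, 0.0, 1.0), seed=1)
        arrays = simulate_pair_arrays(cfg)
        assert abs(corr(arrays[ZygosityGroup.MZm])) < 0.03

    def test_twin_correlations_match_ace_expectations(self):
        cfg = SimulationConfig(n_mzm=50_000, n_mzf=0, n_dzm=50_000, n_dzf=0,
                               n_dzos=0, ace=ACEParams(0.6, 0.2, 0.2), seed=2)
        arrays = simulate_pair_arrays(cfg)
        assert corr(arrays[ZygosityGroup.MZm]) == pytest.approx(0.8, abs=0.01)
        assert corr(arrays[ZygosityGroup.DZm]) == pytest.approx(0.5, abs=0.01)

    def test_marginal_variance_is_one(self):
        cfg = SimulationConfig(n_mzm=50_000, n_mzf=0, n_dzm=0, n_dzf=0, n_dzos=0,
                               ace=ACEParams(0.3, 0.4, 0.3), seed=3)
        y1, y2 = simulate_pair_arrays(cfg)[ZygosityGroup.MZm]
        assert np.var(np.concatenate([y1, y2])) == pytest.approx(1.0, abs=0.02)

    def test_dzos_genetic_correlation_scales_with_rg(self):
        cfg = SimulationConfig(n_mzm=0, n_mzf=0, n_dzm=0, n_dzf=0, n_dzos=80_000,
                               ace=ACEParams(0.8, 0.0, 0.2), rg=0.2, seed=4)
        # expected cross-twin correlation: 0.5 * rg * a2 = 0.08
        assert corr(simulate_pair_arrays(cfg)[ZygosityGroup.DZos]) == pytest.approx(
            0.08, abs=0.015
        )

    def test_dzos_shared_environment_scales_with_rc(self):
        cfg = SimulationConfig(n_mzm=0, n_mzf=0, n_dzm=0, n_dzf=0, n_dzos=80_000,
                               ace=ACEParams(0.0, 0.8, 0.2), rc=0.5, seed=5)
        assert corr(simulate_pair_arrays(cfg)[ZygosityGroup.DZos]) == pytest.approx(
            0.4, abs=0.015
        )

    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(n_mzm=50, n_mzf=50, n_dzm=50, n_dzf=50, n_dzos=50,
                               ace=ACEParams(0.5, 0.3, 0.2), seed=9)
        a = records_to_frame(simulate_continuous(cfg, "t"))
        b = records_to_frame(simulate_continuous(cfg, "t"))
        assert a.equals(b)


class TestBinaryChoice:
    def test_median_threshold_gives_half_prevalence(self):
        cfg = SimulationConfig(n_mzm=10_000, n_mzf=0, n_dzm=0, n_dzf=0, n_dzos=0,
                               ace=ACEParams(0.4, 0.3, 0.3), prevalence=0.5, seed=6)
        b1, b2 = simulate_choice_arrays(cfg)[ZygosityGroup.MZm]
        assert np.mean(np.concatenate([b1, b2])) == pytest.approx(0.5, abs=0.02)

    def test_low_prevalence(self):
        cfg = SimulationConfig(n_mzm=50_000, n_mzf=0, n_dzm=0, n_dzf=0, n_dzos=0,
                               ace=ACEParams(0.4, 0.3, 0.3), prevalence=0.1, seed=7)
        b1, b2 = simulate_choice_arrays(cfg)[ZygosityGroup.MZm]
        assert np.mean(np.concatenate([b1, b2])) == pytest.approx(0.1, abs=0.01)

    def test_records_carry_choice_flags(self):
        cfg = SimulationConfig(n_mzm=20, n_mzf=0, n_dzm=20, n_dzf=0, n_dzos=0,
                               ace=ACEParams(0.4, 0.3, 0.3), seed=8)
        recs = simulate_binary_choice(cfg, "stem")
        assert all(r.twin1.choices["stem"] in (0, 1) for r in recs)
        assert all(not r.twin1.grades for r in recs)


class TestTedsLike:
    def test_default_group_sizes_match_study_design(self, teds_cohort):
        by_top = {"MZ": 0, "DZss": 0, "DZos": 0}
        for rec in teds_cohort:
            if rec.group.is_mz:
                by_top["MZ"] += 1
            elif rec.group.is_opposite_sex:
                by_top["DZos"] += 1
            else:
                by_top["DZss"] += 1
        assert by_top == {"MZ": 2318, "DZss": 2146, "DZos": 2120}

    def test_grades_only_for_choosers(self, teds_cohort):
        for rec in teds_cohort[::7]:
            for m in (rec.twin1, rec.twin2):
                if m.grades.get("alevel") is not None:
                    assert m.choices["alevel"] == 1
                else:
                    assert m.choices["alevel"] == 0

    def test_grades_on_scale(self, teds_cohort):
        for rec in teds_cohort[::13]:
            for m in (rec.twin1, rec.twin2):
                g = m.grades.get("alevel")
                if g is not None:
                    assert 1.0 <= g <= 6.0

    def test_choice_prevalence_near_half(self, teds_cohort):
        flags = [m.choices["alevel"] for r in teds_cohort for m in (r.twin1, r.twin2)]
        assert np.mean(flags) == pytest.approx(0.5, abs=0.02)

    def test_chooser_grades_correlate_with_choice_liability_selection(self):
        # with zero overlap the chooser subset is a random draw for grades:
        # MZ grade correlation equals the unconditional one; with overlap 1
        # the double truncation attenuates it
        base = dict(n_mzm=20_000, n_mzf=0, n_dzm=0, n_dzf=0, n_dzos=0,
                    ace=ACEParams(0.44, 0.47, 0.09),
                    grade_ace=ACEParams(0.59, 0.07, 0.34), seed=10)
        out = {}
        for alpha in (0.0, 1.0):
            recs = simulate_teds_like(
                SimulationConfig(choice_grade_overlap=alpha, **base)
            )
            g1 = np.array([r.twin1.grades["alevel"] or np.nan for r in recs], float)
            g2 = np.array([r.twin2.grades["alevel"] or np.nan for r in recs], float)
            ok = ~np.isnan(g1) & ~np.isnan(g2)
            out[alpha] = np.corrcoef(g1[ok], g2[ok])[0, 1]
        assert out[0.0] == pytest.approx(0.66, abs=0.03)
        assert out[1.0] < out[0.0] - 0.05
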