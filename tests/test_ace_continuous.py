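import warnings

import numpy as np
import pytest

from twinace.ace_continuous import (
    falconer_decomposition,
    fit_ace_arrays,
    fit_ace_ml,
    group_correlations,
    likelihood_ratio_test,
    pair_stats,
)
from twinace.synthetic_twins import (
    ACEParams,
    SimulationConfig,
    simulate_continuous,
    simulate_pair_arrays,
)
from twinace.twin_data import ZygosityGroup


def two_group_arrays(a2, c2, e2, n, seed):
    cfg = SimulationConfig(n_mzm=n, n_mzf=0, n_dzm=n, n_dzf=0, n_dzos=0,
                           ace=ACEParams(a2, c2, e2), seed=seed)
    return {g.gamma: xy for g, xy in simulate_pair_arrays(cfg).items()}


class TestFalconer:
    @pytest.mark.parametrize("rmz,rdz,expected", [
        ((0.8), 0.5, (0.6, 0.2, 0.2)),
        (0.5, 0.25, (0.5, 0.0, 0.5)),
    ])
    def test_direct_formula(self, rmz, rdz, expected):
        vc = falconer_decomposition(rmz, rdz)
        assert (vc.a2, vc.c2, vc.e2) == pytest.approx(expected)
        assert not vc.out_of_bounds

    def test_out_of_bounds_flag_not_truncated(self):
        vc = falconer_decomposition(0.8, 0.3)
        assert (vc.a2, vc.c2, vc.e2) == pytest.approx((1.0, -0.2, 0.2))
        assert vc.out_of_bounds

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            falconer_decomposition(1.2, 0.5)


class TestMLFit:
    def test_recovery_and_falconer_agreement(self, balanced_continuous_groups):
        groups = balanced_continuous_groups
        rep = fit_ace_arrays(groups, model="ACE")
        assert rep.estimate("a2") == pytest.approx(0.6, abs=0.03)
        assert rep.estimate("c2") == pytest.approx(0.2, abs=0.03)
        assert rep.estimate("e2") == pytest.approx(0.2, abs=0.03)
        rmz = np.corrcoef(*groups[1.0])[0, 1]
        rdz = np.corrcoef(*groups[0.5])[0, 1]
        falc = falconer_decomposition(rmz, rdz)
        assert rep.estimate("a2") == pytest.approx(falc.a2, abs=0.02)
        assert rep.estimate("c2") == pytest.approx(falc.c2, abs=0.02)

    def test_components_sum_to_one_and_are_proportions(self, balanced_continuous_groups):
        for model in ("ACE", "AE", "CE", "E"):
            rep = fit_ace_arrays(balanced_continuous_groups, model=model)
            comps = [rep.estimate(k) for k in ("a2", "c2", "e2")]
            assert sum(comps) == pytest.approx(1.0, abs=1e-8)
            assert all(0.0 <= v <= 1.0 for v in comps)

    def test_pure_noise_limit(self):
        groups = two_group_arrays(0.0, 0.0, 1.0, 20_000, seed=11)
        rep = fit_ace_arrays(groups)
        assert rep.estimate("e2") == pytest.approx(1.0, abs=0.02)

    def test_profile_ci_brackets_estimate(self, balanced_continuous_groups):
        rep = fit_ace_arrays(balanced_continuous_groups,
                             ci_components=("a2", "c2", "e2"))
        for k in ("a2", "c2", "e2"):
            est, lo, hi = rep.params[k]
            assert lo <= est <= hi
            assert hi - lo < 0.2  # informative at 5000+5000 pairs

    def test_records_interface_pools_dz_groups(self):
        cfg = SimulationConfig(n_mzm=400, n_mzf=400, n_dzm=300, n_dzf=300,
                               n_dzos=600, ace=ACEParams(0.5, 0.25, 0.25), seed=12)
        recs = simulate_continuous(cfg, "g")
        rep = fit_ace_ml(recs, "g", ci_components=())
        assert rep.n_pairs == {"MZ": 800, "DZ": 1200}
        corrs = {c.label: c for c in group_correlations(recs, "g")}
        assert corrs["MZ"].n == 800
        assert corrs["MZ"].ci_low < corrs["MZ"].r < corrs["MZ"].ci_high

    def test_small_stratum_warns(self):
        groups = two_group_arrays(0.5, 0.2, 0.3, 10, seed=13)
        with pytest.warns(UserWarning, match="pairs"):
            fit_ace_arrays(groups)

    def test_single_stratum_rejected_for_ace(self):
        groups = two_group_arrays(0.5, 0.2, 0.3, 100, seed=14)
        with pytest.raises(ValueError, match="strata"):
            fit_ace_arrays({1.0: groups[1.0]})


class TestLRT:
    def test_model_against_itself_is_null(self, balanced_continuous_groups):
        rep = fit_ace_arrays(balanced_continuous_groups)
        res = likelihood_ratio_test(rep, rep)
        assert res.statistic == 0.0
        assert res.df == 0
        assert res.p_value == 1.0

    def test_statistic_nonnegative_for_nested_pairs(self, balanced_continuous_groups):
        full = fit_ace_arrays(balanced_continuous_groups, model="ACE")
        for reduced_model in ("AE", "CE", "E"):
            red = fit_ace_arrays(balanced_continuous_groups, model=reduced_model)
            assert likelihood_ratio_test(full, red).statistic >= 0.0

    def test_non_nested_rejected(self, balanced_continuous_groups):
        ae = fit_ace_arrays(balanced_continuous_groups, model="AE")
        ce = fit_ace_arrays(balanced_continuous_groups, model="CE")
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(ae, ce)

    def test_detects_simulated_c(self):
        groups = two_group_arrays(0.4, 0.35, 0.25, 3000, seed=15)
        full = fit_ace_arrays(groups)
        red = fit_ace_arrays(groups, model="AE")
        res = likelihood_ratio_test(full, red)
        assert res.p_value_boundary < 1e-6
        assert res.preferred == "ACE"
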