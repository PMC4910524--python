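import numpy as np
import pytest

from twinace.ace_continuous import fit_ace_arrays
from twinace.sex_limitation import (
    MODEL_CHAIN,
    SexLimSpec,
    fit_sex_limitation,
    fit_sex_limitation_chain,
)
from twinace.synthetic_twins import (
    ACEParams,
    SimulationConfig,
    simulate_binary_choice,
    simulate_continuous,
    simulate_pair_arrays,
)


def five_group_cfg(n, seed, **kwargs):
    defaults = dict(n_mzm=n, n_mzf=n, n_dzm=n, n_dzf=n, n_dzos=n,
                    ace=ACEParams(0.5, 0.2, 0.3), seed=seed)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="module")
def homogeneous_cohort():
    return simulate_continuous(five_group_cfg(2000, seed=31), "g")


class TestSpec:
    def test_invalid_model_label(self):
        with pytest.raises(ValueError):
            SexLimSpec(model="bogus")

    def test_missing_dzos_rejected(self):
        recs = simulate_continuous(five_group_cfg(100, seed=32, n_dzos=0), "g")
        with pytest.raises(ValueError, match="opposite-sex"):
            fit_sex_limitation(recs, "g")


class TestContinuous:
    def test_homogeneous_truth_matches_pooled_ace(self, homogeneous_cohort):
        full = fit_sex_limitation(homogeneous_cohort, "g", SexLimSpec("full"))
        pooled = fit_ace_arrays(_pooled_groups(homogeneous_cohort, "g"))
        for k in ("a2", "c2", "e2"):
            assert full.male[k] == pytest.approx(full.female[k], abs=0.06)
            assert full.male[k] == pytest.approx(pooled.estimate(k), abs=0.03)

    def test_loglik_ordering_along_chain(self, homogeneous_cohort):
        fits, _ = fit_sex_limitation_chain(homogeneous_cohort, "g")
        lls = [fits[m].loglik for m in MODEL_CHAIN]
        for a, b in zip(lls, lls[1:]):
            assert a >= b - 1e-6

    def test_low_rg_pulls_estimate_below_half(self):
        cfg = five_group_cfg(5000, seed=33, ace=ACEParams(0.6, 0.1, 0.3), rg=0.2)
        recs = simulate_continuous(cfg, "g")
        full = fit_sex_limitation(recs, "g", SexLimSpec("full", free="rg"))
        assert full.rg < 0.4
        _, tests = fit_sex_limitation_chain(recs, "g")
        assert tests["qualitative_constrained"].p_value < 0.05

    def test_free_rc_variant(self):
        cfg = five_group_cfg(3000, seed=34, ace=ACEParams(0.2, 0.5, 0.3), rc=0.6)
        recs = simulate_continuous(cfg, "g")
        full = fit_sex_limitation(recs, "g", SexLimSpec("full", free="rc"))
        assert full.rg == 0.5
        assert full.rc < 0.85


class TestLiability:
    def test_chain_runs_and_orders(self):
        cfg = five_group_cfg(1500, seed=35, ace=ACEParams(0.44, 0.47, 0.09))
        recs = simulate_binary_choice(cfg, "choice")
        fits, tests = fit_sex_limitation_chain(recs, "choice")
        lls = [fits[m].loglik for m in MODEL_CHAIN]
        for a, b in zip(lls, lls[1:]):
            assert a >= b - 1e-6
        hom = fits["homogeneous"]
        assert hom.male["a2"] == pytest.approx(0.44, abs=0.09)
        assert hom.male["threshold"] == pytest.approx(0.0, abs=0.05)

    def test_sex_specific_thresholds(self):
        # females choose more often: emulated by a mean shift on the liability
        cfg = five_group_cfg(2000, seed=36, sex_effect=0.35)
        recs = simulate_binary_choice(cfg, "choice")
        full = fit_sex_limitation(recs, "choice", SexLimSpec("full"))
        assert full.female["threshold"] < full.male["threshold"] - 0.15


def test_underpowered_subsample_gives_overlapping_cis():
    """Sex-specific heritabilities fitted on study-subsample-sized groups
    (a 15%-choice trait) have CIs too wide to separate a 0.51 vs 0.70
    contrast."""
    cfg = SimulationConfig(
        n_mzm=370, n_mzf=344, n_dzm=371, n_dzf=260, n_dzos=0,
        ace_male=ACEParams(0.51, 0.2, 0.29), ace_female=ACEParams(0.70, 0.1, 0.20),
        seed=37,
    )
    arrays = simulate_pair_arrays(cfg)
    from twinace.twin_data import ZygosityGroup as Z
    males = {1.0: arrays[Z.MZm], 0.5: arrays[Z.DZm]}
    females = {1.0: arrays[Z.MZf], 0.5: arrays[Z.DZf]}
    fit_m = fit_ace_arrays(males, ci_components=("a2",))
    fit_f = fit_ace_arrays(females, ci_components=("a2",))
    lo_m, hi_m = fit_m.params["a2"][1:]
    lo_f, hi_f = fit_f.params["a2"][1:]
    assert max(lo_m, lo_f) < min(hi_m, hi_f)  # intervals overlap


def _pooled_groups(records, trait):
    g1 = {"MZ": ([], []), "DZ": ([], [])}
    for rec in records:
        a, b = rec.twin1.grades.get(trait), rec.twin2.grades.get(trait)
        if a is None or b is None:
            continue
        key = "MZ" if rec.group.is_mz else "DZ"
        g1[key][0].append(a)
        g1[key][1].append(b)
    return {(1.0 if k == "MZ" else 0.5): (np.array(v[0]), np.array(v[1]))
            for k, v in g1.items()}
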