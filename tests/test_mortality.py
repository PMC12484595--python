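"""Rank tests against enumeration oracles; bag GLM coefficient recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats

from seiszoo import mortality as mort
from seiszoo.synthetic import (
    MortalityScenario,
    TreatmentArm,
    default_mortality_scenario,
    gen_bag_trials,
    gen_net_samples,
)


def nets_frame(props, dists, phases=None, n=100):
    dead = (np.asarray(props) * n).round().astype(int)
    return pd.DataFrame({
        "haul_id": [f"h{i}" for i in range(len(dead))],
        "approach": 1,
        "distance_m": dists,
        "phase": phases if phases is not None else ["during"] * len(dead),
        "n_live": n - dead,
        "n_dead": dead,
    })


# independent oracles, deliberately written differently from the implementation

def oracle_spearman_p(x, y):
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    def rho_of(perm):
        r = np.corrcoef(rx, perm)[0, 1]
        return r
    obs = abs(rho_of(ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        hits += abs(rho_of(np.array(perm))) >= obs - 1e-12
    return hits / total


def oracle_mw_p(x, y):
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2
    obs = abs(ranks[:n1].sum() - n1 * (n1 + 1) / 2 - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        hits += abs(u - mu) >= obs - 1e-9
    return hits / total


class TestProportion:
    def test_examples(self):
        assert mort.proportion_dead(36, 100) == 0.36
        assert mort.proportion_dead(0, 50) == 0.0
        assert mort.proportion_dead(10, 10) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            mort.proportion_dead(0, 0)


class TestSpearman:
    def test_monotone_gives_plus_minus_one(self):
        d = np.linspace(100, 9000, 6)
        up = mort.spearman_mortality_distance(nets_frame([.1, .15, .2, .25, .3, .35], d))
        dn = mort.spearman_mortality_distance(nets_frame([.35, .3, .25, .2, .15, .1], d))
        assert up["rho"] == 1.0 and dn["rho"] == -1.0
        assert up["method"] == "exact permutation"

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        x, y = rng.normal(size=n), rng.normal(size=n)
        _, p = mort.exact_spearman_p(x, y)
        assert p == pytest.approx(oracle_spearman_p(x, y), abs=1e-12)

    def test_large_sample_approximation_close_to_exact(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=7), rng.normal(size=7)
            _, pe = mort.exact_spearman_p(x, y)
            errs.append(abs(stats.spearmanr(x, y).pvalue - pe))
        assert np.mean(errs) < 0.02 and max(errs) < 0.05

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            out = mort.spearman_mortality_distance(
                nets_frame([.2, .2, .2, .2], [1, 2, 3, 4]))
        assert np.isnan(out["rho"])

    def test_phase_filter_and_min_n(self):
        df = nets_frame([.1, .2], [1, 2])
        with pytest.raises(ValueError):
            mort.spearman_mortality_distance(df)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        df = nets_frame([.2, .3, .2, .3], [1, 2, 3, 4],
                        phases=["during", "during", "after", "after"])
        assert mort.mann_whitney_during_after(df)["p"] == 1.0

    def test_separated_4v4_exact_p(self):
        df = nets_frame([.1, .12, .14, .16, .5, .52, .54, .56], range(8),
                        phases=["during"] * 4 + ["after"] * 4)
        out = mort.mann_whitney_during_after(df)
        assert out["p"] == pytest.approx(2 / 70, abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        props = rng.uniform(0, 0.5, 9)
        phases = ["during"] * 5 + ["after"] * 4
        df = nets_frame(props, range(9), phases=phases)
        swapped = df.copy()
        swapped["phase"] = ["after" if p == "during" else "during" for p in phases]
        assert mort.mann_whitney_during_after(df)["p"] == pytest.approx(
            mort.mann_whitney_during_after(swapped)["p"])

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed + 10)
        n1, n2 = rng.integers(3, 8, size=2)
        # integer values force ties, exercising the mid-rank path
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 4, n2).astype(float)
        _, p = mort.exact_mann_whitney(x, y)
        assert p == pytest.approx(oracle_mw_p(x, y), abs=1e-12)

    def test_empty_phase_rejected(self):
        df = nets_frame([.1, .2, .3], [1, 2, 3])
        with pytest.raises(ValueError):
            mort.mann_whitney_during_after(df)


class TestCumulativeCurve:
    def test_bookkeeping_example(self):
        trials = pd.DataFrame([{"bag_id": "b0", "treatment": "x", "n0": 10,
                                **{f"dead_day{d}": v for d, v in
                                   zip(range(8), [1, 1, 1, 2, 2, 2, 2, 2])}}])
        curve = mort.cumulative_mortality_curve(trials, "x")
        assert list(curve["mean"]) == [0.1, 0.1, 0.1, 0.2, 0.2, 0.2, 0.2, 0.2]

    def test_all_zero_bags_flat(self):
        sc = MortalityScenario([TreatmentArm("x", 4, 10, 0.0, 0.0)], seed=0)
        curve = mort.cumulative_mortality_curve(gen_bag_trials(sc), "x")
        assert (curve["mean"] == 0.0).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_means_nondecreasing_for_any_seed(self, seed):
        trials = gen_bag_trials(default_mortality_scenario(seed=seed))
        for t in trials["treatment"].unique():
            curve = mort.cumulative_mortality_curve(trials, t)
            assert (np.diff(curve["mean"]) >= -1e-12).all()

    def test_day_outside_follow_up(self):
        trials = gen_bag_trials(default_mortality_scenario(seed=1))
        with pytest.raises(ValueError):
            mort.bags_to_long(trials, days=range(9))


class TestBagGlm:
    def test_logodds_contrast_recovery(self):
        # planted immediate proportions 0.1 vs 0.3, 200 bags of 50 per arm
        arms = [TreatmentArm("control", 200, 50, 0.1, 0.0),
                TreatmentArm("exposure_close", 200, 50, 0.3, 0.0)]
        trials = gen_bag_trials(MortalityScenario(arms, follow_up_days=0, seed=5))
        res = mort.fit_bag_glm(trials, immediate=True)
        c = res.treatment_contrast("exposure_close")
        target = np.log((0.3 / 0.7) / (0.1 / 0.9))
        assert abs(c["estimate"] - target) < 3 * c["se"]

    def test_cumulative_model_detects_planted_difference(self):
        trials = gen_bag_trials(default_mortality_scenario(seed=2))
        res = mort.fit_bag_glm(trials)
        assert res.lrt_treatment["p"] < 0.05
        assert res.n == len(trials) * 8
        assert "treatment" in res.model.formula

    def test_separation_flagged_and_penalized(self):
        arms = [TreatmentArm("control", 10, 10, 0.3, 0.1),
                TreatmentArm("exposed", 10, 10, 0.0, 0.0)]
        trials = gen_bag_trials(MortalityScenario(arms, seed=0))
        with pytest.warns(UserWarning, match="separation"):
            res = mort.fit_bag_glm(trials, reference="control")
        assert res.penalized and res.separated_treatments == ["exposed"]
        assert np.isfinite(res.treatment_contrast("exposed")["estimate"])

    def test_day_factor_coding_available(self):
        trials = gen_bag_trials(default_mortality_scenario(seed=3))
        res = mort.fit_bag_glm(trials, day_as_factor=True)
        assert any("C(day)" in name for name in res.params.index)

    def test_needs_two_treatments(self):
        sc = MortalityScenario([TreatmentArm("only", 5, 10, 0.1, 0.1)], seed=0)
        with pytest.raises(ValueError):
            mort.fit_bag_glm(gen_bag_trials(sc), reference="only")

    def test_row_order_invariance(self):
        trials = gen_bag_trials(default_mortality_scenario(seed=6))
        shuffled = trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = mort.fit_bag_glm(trials).lrt_treatment
        b = mort.fit_bag_glm(shuffled).lrt_treatment
        assert a["statistic"] == pytest.approx(b["statistic"], rel=1e-9)

    def test_summary_mentions_caveat(self):
        trials = gen_bag_trials(default_mortality_scenario(seed=7))
        assert "within-bag correlation" in mort.fit_bag_glm(trials).summary()


class TestPowerAnalysis:
    def test_huge_effect_saturates(self):
        arms = [TreatmentArm("control", 12, 10, 0.05, 0.0),
                TreatmentArm("exposure_close", 36, 10, 0.9, 0.0)]
        sc = MortalityScenario(arms, seed=0)
        out = mort.power_analysis(sc, n_reps=100, model="immediate", seed=1)
        assert out["power"] > 0.99

    def test_zero_effect_power_near_alpha(self):
        arms = [TreatmentArm("control", 12, 10, 0.1, 0.0),
                TreatmentArm("exposure_close", 36, 10, 0.1, 0.0)]
        sc = MortalityScenario(arms, seed=0)
        out = mort.power_analysis(sc, n_reps=150, model="immediate",
                                  use_lrt=False, seed=2)
        assert out["power"] < 0.15

    def test_degenerate_scenario_rejected(self):
        arms = [TreatmentArm("a", 5, 10, 0.0, 0.0),
                TreatmentArm("b", 5, 10, 1.0, 0.0)]
        with pytest.raises(ValueError):
            mort.power_analysis(MortalityScenario(arms, seed=0), n_reps=100)


class TestRowOrderInvariance:
    def test_rank_tests_permutation_invariant(self):
        rng = np.random.default_rng(4)
        df = gen_net_samples(default_mortality_scenario(seed=4),
                             rng.uniform(100, 9000, 12),
                             phases=["during"] * 8 + ["after"] * 4)
        shuffled = df.sample(frac=1.0, random_state=2).reset_index(drop=True)
        a = mort.spearman_mortality_distance(df)
        b = mort.spearman_mortality_distance(shuffled)
        assert a["rho"] == pytest.approx(b["rho"]) and a["p"] == pytest.approx(b["p"])
        assert (mort.mann_whitney_during_after(df)["p"]
                == pytest.approx(mort.mann_whitney_during_after(shuffled)["p"]))
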