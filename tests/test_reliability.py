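import numpy as np
import pytest
from scipy import stats

from erpconsensus.datamodel import PipelineConfig
from erpconsensus.pipeline import cluster_trials
from erpconsensus.reliability import (aggregate_reliability, condition_test,
                                      cronbach_alpha, monte_carlo, sem,
                                      standard_error)
from erpconsensus.simulate import ground_truth_template, simulate_study


class TestStandardError:
    def test_closed_form(self):
        assert standard_error([1.0, 2.0, 3.0]) == pytest.approx(1 / np.sqrt(3))

    def test_constant_vector(self):
        assert standard_error([4.0] * 10) == 0.0

    def test_matches_two_pass_oracle(self, rng):
        v = rng.normal(size=57)
        mean = v.sum() / v.size
        var = ((v - mean) ** 2).sum() / (v.size - 1)
        assert standard_error(v) == pytest.approx(np.sqrt(var / v.size))

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            standard_error([1.0])


class TestAggregateReliability:
    def test_zero_error_gives_reliability_one(self, rng):
        scores = rng.normal(size=10)
        out = aggregate_reliability(np.zeros(10), scores)
        assert out["reliability"] == pytest.approx(1.0)

    def test_zero_subject_variance_gives_zero(self):
        out = aggregate_reliability(np.full(6, 0.5), np.full(6, 2.0))
        assert out["reliability"] == pytest.approx(0.0)

    def test_total_variance_identity_to_machine_precision(self, rng):
        ses = np.abs(rng.normal(size=12))
        scores = rng.normal(size=12)
        out = aggregate_reliability(ses, scores)
        resid = out["Var_all"] - out["Var_par"] - out["MS_SE"]
        assert abs(resid) <= 4 * np.finfo(float).eps * out["Var_all"]

    def test_recovers_known_variance_components(self, rng):
        # subjects' true scores vary with sd_par; each observed with error
        sd_par, sd_err, n, m = 2.0, 0.7, 400, 50
        truth = rng.normal(0, sd_par, size=n)
        ses, observed = [], []
        for t in truth:
            reps = t + rng.normal(0, sd_err, size=m)
            observed.append(reps.mean())
            ses.append(reps.std(ddof=1) / np.sqrt(m))
        out = aggregate_reliability(np.array(ses), np.array(observed))
        expected = sd_par**2 / (sd_par**2 + sd_err**2 / m)
        assert out["reliability"] == pytest.approx(expected, abs=0.02)


class TestCronbachAlpha:
    def test_identical_items(self, rng):
        col = rng.normal(size=20)
        assert cronbach_alpha(np.column_stack([col] * 4)) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        X = rng.normal(size=(10_000, 3))
        assert abs(cronbach_alpha(X)) < 0.1

    def test_two_item_hand_oracle(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 5.0], [4.0, 9.0]])
        q = 2
        item_vars = X.var(axis=0, ddof=1)
        tot = X.sum(axis=1).var(ddof=1)
        expected = q / (q - 1) * (1 - item_vars.sum() / tot)
        assert cronbach_alpha(X) == pytest.approx(expected)

    def test_invariant_to_item_constants(self, rng):
        X = rng.normal(size=(30, 4))
        shifted = X + np.array([10.0, -3.0, 0.5, 100.0])
        assert cronbach_alpha(shifted) == pytest.approx(cronbach_alpha(X))

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        X = rng.normal(size=(25, 3)) + rng.normal(size=(25, 1))
        a, _ = pingouin.cronbach_alpha(data=pd.DataFrame(X))
        assert cronbach_alpha(X) == pytest.approx(a, abs=1e-9)


class TestSem:
    @pytest.mark.parametrize("sd, alpha, expected", [
        (3.0, 1.0, 0.0),
        (3.0, 0.0, 3.0),
        (2.0, 0.75, 1.0),
    ])
    def test_arithmetic(self, sd, alpha, expected):
        assert sem(sd, alpha) == pytest.approx(expected)

    def test_alpha_above_one_rejected(self):
        with pytest.raises(ValueError):
            sem(1.0, 1.2)


class TestConditionTest:
    def test_identical_conditions(self, rng):
        x = rng.normal(size=15)
        res = condition_test(np.column_stack([x, x]))
        assert res.F == 0.0 and res.eta_p2 == 0.0 and res.p == 1.0

    def test_equals_squared_paired_t(self, rng):
        X = rng.normal(size=(20, 2)) + [0.5, 0.0]
        res = condition_test(X)
        t, p = stats.ttest_rel(X[:, 0], X[:, 1])
        assert res.F == pytest.approx(t**2)
        assert res.p == pytest.approx(p)
        assert res.df == (1, 19)
        assert res.eta_p2 == pytest.approx(res.F / (res.F + 19))

    def test_matches_pingouin_rm_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        X = rng.normal(size=(12, 2)) + [1.0, 0.0]
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "condition": np.tile(["a", "b"], 12),
            "score": X.ravel(),
        })
        aov = pingouin.rm_anova(data=long, dv="score", within="condition",
                                subject="subject", effsize="np2")
        res = condition_test(X)
        assert res.F == pytest.approx(float(aov["F"].iloc[0]))
        assert res.eta_p2 == pytest.approx(float(aov["np2"].iloc[0]))

    def test_constant_nonzero_difference_capped(self):
        X = np.column_stack([np.arange(5.0) + 1.0, np.arange(5.0)])
        res = condition_test(X)
        assert res.capped and np.isinf(res.F) and res.eta_p2 == 1.0


@pytest.fixture(scope="module")
def mc_setup():
    from erpconsensus.simulate import ComponentSpec, StudySpec
    comp = ComponentSpec("P3", "Pz", 0.6, +1, (300, 320), (200, 220),
                         (5.0, 6.0), (10, 1, 10))
    spec = StudySpec(n_subjects=1, n_conditions=1, n_trials=12, noise_sd=0.5,
                     components=[comp], condition_scale={}, seed=33)
    epochsets, _ = simulate_study(spec)
    e = epochsets[0]
    cfg = PipelineConfig(seed=33)
    labs = cluster_trials(e, ["KM", "HC", "MKM"], cfg, 33)
    tpl = ground_truth_template("P3", spec)
    return e, labs, tpl, cfg


class TestMonteCarlo:
    def test_identical_pool_gives_zero_iteration_variance(self, mc_setup):
        e, labs, tpl, cfg = mc_setup
        one = {0: labs[0]}
        pool = {i: labs[0] for i in range(8)}
        mc = monte_carlo(e, pool, tpl, cfg, R=10, seed=1)
        # every iteration draws the same labeling: subject-level scores are
        # determined by which trials were drawn, but windows are identical
        assert mc.iteration_scores["tw_start"].nunique() == 1

    def test_eq7_identity_when_all_se_equal(self, mc_setup):
        e, labs, tpl, cfg = mc_setup
        mc = monte_carlo(e, labs, tpl, cfg, R=20, seed=2)
        manual = np.sqrt(np.mean(mc.se_r["amplitude"] ** 2))
        assert mc.mc_se["amplitude"] == pytest.approx(manual)

    def test_mcse_shrinks_with_n_draw(self, mc_setup):
        e, labs, tpl, cfg = mc_setup
        vals = []
        for n_draw in (4, 8, 16, 32):
            mc = monte_carlo(e, labs, tpl, cfg, n_draw=n_draw, R=40, seed=3)
            vals.append(mc.mc_se["amplitude"])
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_bit_reproducible_with_seed(self, mc_setup):
        e, labs, tpl, cfg = mc_setup
        a = monte_carlo(e, labs, tpl, cfg, R=15, seed=9)
        b = monte_carlo(e, labs, tpl, cfg, R=15, seed=9)
        assert a.mc_se == b.mc_se
        assert a.iteration_scores.equals(b.iteration_scores)
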