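"""Rejection, model choice, parameter adjustment and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from serialabc.abc import (
    ABCParameterAdjuster,
    ABCScenarioClassifier,
    ReferenceTable,
    _rejection_core,
    adjust_parameters,
    build_reference_table,
    infer,
    percent_change,
    posterior_summary,
    rejection,
    scenario_posteriors,
    weighted_quantile,
)
from serialabc.coalescent import SampleConfig, dataset_summaries, summary_names
from serialabc.scenarios import ParameterDraw, PriorSpec, make_scenario
from serialabc.stats import SummaryVector


@pytest.fixture(scope="module")
def small_table():
    """Constant + bottleneck reference table at a tiny temporal design."""
    cfg = SampleConfig(samples=((30, 12), (0, 10)), n_loci=6)
    scens = [make_scenario("constant"), make_scenario("bottleneck")]
    rng = np.random.default_rng(123)
    return build_reference_table(scens, 300, cfg, rng)


def toy_table(summaries, labels=None, params=None, stat_names=None):
    """Hand-built reference table around explicit summary rows."""
    summaries = np.asarray(summaries, dtype=float)
    n, d = summaries.shape
    labels = np.asarray(
        labels if labels is not None else ["constant"] * n, dtype=object
    )
    names = tuple(stat_names or [f"s{i}" for i in range(d)])
    scen = {
        name: make_scenario(name)
        for name in np.unique(labels)
    }
    if params is None:
        params = pd.DataFrame({"N": np.arange(n, dtype=float) + 10})
    return ReferenceTable(
        scenario=labels, params=params, summaries=summaries,
        stat_names=names, scale=np.ones(d), scenarios=scen,
        sample_config=SampleConfig(samples=((0, 5),), n_loci=2),
    )


class TestReferenceTable:
    def test_balanced_rows(self, small_table):
        labs, cnts = np.unique(small_table.scenario, return_counts=True)
        assert sorted(labs) == ["bottleneck", "constant"]
        assert (cnts == 300).all()

    def test_scale_factors_positive(self, small_table):
        assert (small_table.scale > 0).all()

    def test_renormalization_idempotent(self, small_table):
        """After dividing by the stored scale, per-statistic MADs are 1."""
        Z = small_table.summaries / small_table.scale
        med = np.median(Z, axis=0)
        mad = np.median(np.abs(Z - med), axis=0)
        assert np.allclose(mad, 1.0, atol=1e-9)

    def test_too_few_simulations_rejected(self):
        cfg = SampleConfig(samples=((0, 5),), n_loci=2)
        with pytest.raises(ValueError, match="at least 100"):
            build_reference_table(
                [make_scenario("constant")], 50, cfg, np.random.default_rng(0)
            )

    def test_save_load_roundtrip(self, small_table, tmp_path):
        path = str(tmp_path / "table.tsv")
        small_table.save(path)
        back = ReferenceTable.load(path)
        assert back.stat_names == small_table.stat_names
        assert np.allclose(back.summaries, small_table.summaries)
        assert np.allclose(back.scale, small_table.scale)
        assert list(back.scenario) == list(small_table.scenario)
        assert back.sample_config == small_table.sample_config


class TestRejection:
    def test_tolerance_one_retains_everything(self, small_table):
        obs = small_table.summaries[0]
        rej = rejection(small_table, obs, tolerance=1.0)
        assert rej.n_retained == small_table.n_rows

    def test_exact_row_has_zero_distance(self, small_table):
        obs = small_table.summaries[17]
        rej = rejection(small_table, obs, tolerance=0.05)
        assert rej.indices[0] == 17
        assert rej.distances[0] == 0.0

    def test_matches_brute_force_on_random_table(self, rng):
        X = rng.normal(size=(200, 5))
        scale = np.abs(rng.normal(size=5)) + 0.5
        obs = rng.normal(size=5)
        tol = 0.07
        got = _rejection_core(X, scale, obs, tol)
        d = np.array(
            [np.sqrt((((row - obs) / scale) ** 2).sum()) for row in X]
        )
        m = int(np.ceil(tol * 200))
        expected = np.argsort(d, kind="stable")[:m]
        assert np.array_equal(got.indices, expected)
        assert np.allclose(got.distances, d[expected])

    def test_ties_broken_by_row_index(self):
        X = np.zeros((10, 2))  # all rows identical
        got = _rejection_core(X, np.ones(2), np.ones(2), 0.3)
        assert np.array_equal(got.indices, [0, 1, 2])

    def test_invariant_to_common_rescaling(self, rng):
        X = rng.normal(size=(100, 3))
        scale = np.ones(3)
        obs = rng.normal(size=3)
        base = _rejection_core(X, scale, obs, 0.1)
        X2, s2, o2 = X.copy(), scale.copy(), obs.copy()
        X2[:, 1] *= 37.0
        s2[1] *= 37.0
        o2[1] *= 37.0
        again = _rejection_core(X2, s2, o2, 0.1)
        assert np.array_equal(base.indices, again.indices)

    def test_name_mismatch_rejected(self, small_table):
        sv = SummaryVector(
            names=("wrong",) * len(small_table.stat_names),
            values=np.zeros(len(small_table.stat_names)),
        )
        with pytest.raises(ValueError, match="do not match"):
            rejection(small_table, sv, 0.1)

    def test_bad_tolerance_rejected(self, small_table):
        with pytest.raises(ValueError, match="tolerance"):
            rejection(small_table, small_table.summaries[0], 0.0)


class TestScenarioPosteriors:
    def test_single_scenario_degenerate(self):
        # constant rows cluster at 0, bottleneck rows far away at 100
        X = np.r_[np.zeros((50, 2)), np.full((50, 2), 100.0)]
        labels = np.array(["constant"] * 50 + ["bottleneck"] * 50, dtype=object)
        table = toy_table(X, labels)
        post = scenario_posteriors(table, np.zeros(2), tolerance=0.2)
        assert "degenerate_single_scenario" in post.flags
        assert post.direct["constant"] == 1.0

    def test_probabilities_sum_to_one(self, small_table):
        obs = small_table.summaries[5]
        post = scenario_posteriors(small_table, obs, tolerance=0.1)
        assert sum(post.direct.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(post.logistic.values()) == pytest.approx(1.0, abs=1e-9)

    def test_indistinguishable_scenarios_near_half(self, rng):
        """Two labels over the same summary distribution: averaged over
        observed points the posterior is ~1/2 each."""
        clf = ABCScenarioClassifier(tolerance=0.2)
        X = rng.normal(size=(2000, 3))
        y = np.array(["a", "b"] * 1000, dtype=object)
        clf.fit(X, y)
        probs = clf.predict_proba(rng.normal(size=(40, 3)))
        assert probs[:, 0].mean() == pytest.approx(0.5, abs=0.1)

    def test_separated_constant_sizes_recovered(self, rng):
        """Data simulated at N=10000 vs a N=100 alternative: the correct
        label wins decisively in nearly all replicates."""
        cfg = SampleConfig(samples=((0, 50),), n_loci=30)
        sims, labels = [], []
        for N, lab in ((100.0, "small"), (10000.0, "large")):
            for _ in range(400):
                d = ParameterDraw(
                    scenario="constant", params={"N": N},
                    mu_mean=5e-4, gsm_p=0.0,
                )
                sims.append(dataset_summaries(d, cfg, rng))
                labels.append(lab)
        clf = ABCScenarioClassifier(tolerance=0.05)
        clf.fit(np.array(sims), np.array(labels, dtype=object))
        wins = 0
        for _ in range(50):
            d = ParameterDraw(
                scenario="constant", params={"N": 10000.0},
                mu_mean=5e-4, gsm_p=0.0,
            )
            obs = dataset_summaries(d, cfg, rng)
            p = clf.predict_proba(obs)[0]
            wins += p[list(clf.classes_).index("large")] > 0.9
        assert wins >= 45

    def test_sklearn_estimator_contract(self, rng):
        clf = ABCScenarioClassifier(tolerance=0.3, ridge=1e-5)
        assert clone(clf).get_params() == clf.get_params()
        X = rng.normal(size=(100, 2))
        y = np.array(["a", "b"] * 50, dtype=object)
        clf.fit(X, y)
        assert clf.predict(X[:3]).shape == (3,)
        assert clf.predict_proba(X[:3]).shape == (3, 2)


class TestAdjustment:
    def test_zero_deviation_is_identity(self, rng):
        """When every retained simulation sits exactly at the observed
        summaries the regression has nothing to correct."""
        X = np.tile([1.0, 2.0], (40, 1))
        y = rng.uniform(10, 90, size=(40, 1))
        adj = ABCParameterAdjuster(bounds=[(0.0, 100.0)])
        adj.fit(X, y)
        out = adj.adjust(np.array([1.0, 2.0]), np.ones(40))
        assert np.allclose(out[:, 0], y[:, 0], rtol=1e-8)

    def test_adjusted_values_stay_in_bounds(self, rng):
        for _ in range(100):
            X = rng.normal(size=(60, 3))
            y = rng.uniform(5, 15, size=(60, 2))
            adj = ABCParameterAdjuster(bounds=[(5.0, 15.0), (5.0, 15.0)])
            adj.fit(X, y)
            out = adj.adjust(rng.normal(size=3), np.ones(60))
            assert (out >= 5.0).all() and (out <= 15.0).all()

    def test_conjugate_gaussian_toy(self, rng):
        """theta ~ N(0,1), summary = theta + noise: the adjusted posterior
        matches the conjugate Normal posterior closely."""
        n, sigma, x_obs = 100_000, 0.5, 0.3
        theta = rng.normal(0, 1, n)
        x = theta + rng.normal(0, sigma, n)
        scale = np.array([np.median(np.abs(x - np.median(x)))])
        rej = _rejection_core(x[:, None], scale, np.array([x_obs]), 0.01)
        w = rej.weights()
        adj = ABCParameterAdjuster(bounds=[(-8.0, 8.0)])
        adj.fit(x[rej.indices, None], theta[rej.indices, None])
        s = adj.adjust(np.array([x_obs]), w)[:, 0]
        mean = np.average(s, weights=w)
        var = np.average((s - mean) ** 2, weights=w)
        prec = 1 + 1 / sigma**2
        assert mean == pytest.approx(x_obs * (1 / sigma**2) / prec, rel=0.1, abs=0.02)
        assert var == pytest.approx(1 / prec, rel=0.12)

    def test_requires_enough_rows(self, small_table):
        obs = small_table.summaries[0]
        with pytest.raises(ValueError, match="at least 30"):
            adjust_parameters(small_table, obs, "constant", tolerance=0.01)

    def test_unknown_scenario_rejected(self, small_table):
        with pytest.raises(ValueError, match="not present"):
            adjust_parameters(
                small_table, small_table.summaries[0], "mystery", 0.2
            )

    def test_adjusted_within_prior_bounds(self, small_table):
        obs = small_table.summaries[3]
        adj = adjust_parameters(small_table, obs, "bottleneck", tolerance=0.2)
        prior = small_table.scenarios["bottleneck"].prior
        for p in adj.param_names:
            lo, hi = prior.bounds_for(p)
            assert (adj.samples[p] >= lo).all() and (adj.samples[p] <= hi).all()


class TestPosteriorSummaries:
    def test_single_sample(self):
        s = posterior_summary([42.0])
        assert s.median == s.q025 == s.q975 == 42.0

    def test_uniform_weights_match_linear_interpolation(self):
        vals = np.arange(1, 1001, dtype=float)
        q = weighted_quantile(vals, [0.025, 0.5, 0.975])
        assert np.allclose(q, [25.975, 500.5, 975.025])
        assert np.allclose(
            q, np.quantile(vals, [0.025, 0.5, 0.975])
        )

    def test_point_mass_weighting(self):
        q = weighted_quantile(
            np.array([1.0, 2.0, 3.0]), [0.5], np.array([1e-9, 1.0, 1e-9])
        )
        assert q[0] == pytest.approx(2.0, abs=0.01)

    def test_flat_posterior_flagged_not_estimable(self, rng):
        samples = rng.uniform(1, 5000, 5000)
        s = posterior_summary(samples, prior_bounds=(1, 5000))
        assert s.not_estimable
        assert s.q025 == pytest.approx(0.025 * 4999 + 1, rel=0.05)

    def test_concentrated_posterior_estimable(self, rng):
        s = posterior_summary(
            rng.normal(100, 5, 2000), prior_bounds=(1, 5000)
        )
        assert not s.not_estimable

    def test_quantile_ordering(self, rng):
        s = posterior_summary(rng.normal(size=500), rng.uniform(0.1, 1, 500))
        assert s.q025 <= s.median <= s.q975


class TestPercentChange:
    def test_decline_truncates_toward_zero(self):
        assert percent_change(15700, 3230) == 79
        assert percent_change(100, 100) == 0

    def test_increase_reports_ratio_percent(self):
        assert percent_change(1510, 17100) == 1132

    def test_nonpositive_before_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0, 5)


class TestInfer:
    def test_tolerance_one_direct_equals_proportions(self, small_table):
        obs = small_table.summaries[0]
        post = scenario_posteriors(small_table, obs, tolerance=1.0)
        assert post.direct["constant"] == pytest.approx(0.5)
        assert post.direct["bottleneck"] == pytest.approx(0.5)

    def test_full_inference_is_deterministic(self, small_table):
        obs = small_table.summaries[40]
        r1 = infer(small_table, obs, tolerance=0.2)
        r2 = infer(small_table, obs, tolerance=0.2)
        assert r1.best_scenario == r2.best_scenario
        assert r1.posteriors.logistic == r2.posteriors.logistic
        pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())

    def test_result_frame_and_change(self, small_table):
        obs = small_table.summaries[310]  # a bottleneck row
        res = infer(small_table, obs, tolerance=0.2)
        frame = res.to_frame()
        assert set(frame["parameter"]) == set(
            small_table.scenarios[res.best_scenario].param_names
        )
        change = res.ne_change()
        if res.best_scenario == "bottleneck":
            assert 0 <= change["change"] <= 100
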