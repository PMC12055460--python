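"""Weight estimation: reciprocals, stabilization, truncation, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quitline_ipw import (
    FittedProbabilityModel,
    WeightModelSpec,
    WeightSet,
    combine_weights,
    compute_ipcw,
    compute_iptw,
    fit_probability_model,
    stabilize,
    summarize_weights,
    truncate,
)
from quitline_ipw.ipw import DEFAULT_CENSORING_PREDICTORS, DEFAULT_TREATMENT_PREDICTORS

from conftest import make_cohort


def constant_cohort(n=10, n_resp=5, a_share=0.5):
    a = (np.arange(n) < a_share * n).astype(int)
    c = (np.arange(n) >= n_resp).astype(int)
    rng = np.random.default_rng(0)
    return make_cohort(a, c, rng.integers(0, 2, n), grp=np.repeat(["u", "v"], n // 2))


class TestProbabilityModel:
    def test_intercept_only_fits_bernoulli_mean(self):
        cohort = constant_cohort(n=10, n_resp=5)
        model = fit_probability_model(cohort, WeightModelSpec("censoring", ("1",)))
        np.testing.assert_allclose(model.probabilities, 0.5, atol=1e-8)

    def test_saturated_binary_covariate_recovers_stratum_proportion(self):
        # 8 of 10 uncensored in stratum u, 4 of 10 in stratum v
        grp = np.repeat(["u", "v"], 10)
        c = np.r_[np.zeros(8), np.ones(2), np.zeros(4), np.ones(6)].astype(int)
        cohort = make_cohort(np.tile([0, 1], 10), c, np.zeros(20), grp=grp)
        model = fit_probability_model(cohort, WeightModelSpec("censoring", ("grp",)))
        p = model.probabilities
        np.testing.assert_allclose(p[grp == "u"], 0.8, atol=1e-7)
        np.testing.assert_allclose(p[grp == "v"], 0.4, atol=1e-7)

    def test_single_class_outcome_rejected(self):
        cohort = make_cohort([0, 1, 0, 1], [0, 0, 0, 0], [1, 0, 1, 0])
        with pytest.raises(ValueError, match="single class"):
            fit_probability_model(cohort, WeightModelSpec("censoring", ("A",)))

    def test_treatment_model_cannot_use_A(self):
        with pytest.raises(ValueError, match="only predict censoring"):
            WeightModelSpec("treatment", ("A", "age"))

    def test_default_predictor_sets(self):
        assert DEFAULT_CENSORING_PREDICTORS == ("A", "age", "race_eth", "insurance", "geography")
        assert DEFAULT_TREATMENT_PREDICTORS == ("age", "insurance", "income")


def fake_model(cohort, target, probs):
    spec = WeightModelSpec(target, ("A",) if target == "censoring" else ("grp",))
    return FittedProbabilityModel(spec=spec, params=None,
                                  probabilities=np.asarray(probs, float),
                                  ids=cohort.data["id"].to_numpy(),
                                  converged=True, n_iter=1)


class TestWeights:
    def test_ipcw_is_reciprocal_of_response_probability(self):
        cohort = constant_cohort(n=6, n_resp=4)
        model = fake_model(cohort, "censoring", np.full(6, 0.5))
        ws = compute_ipcw(cohort, model)
        assert len(ws) == 4  # responders only
        np.testing.assert_allclose(ws.weights, 2.0)

    def test_ipcw_stratum_point_eight_gives_one_point_two_five(self):
        cohort = constant_cohort(n=4, n_resp=4)
        ws = compute_ipcw(cohort, fake_model(cohort, "censoring", np.full(4, 0.8)))
        np.testing.assert_allclose(ws.weights, 1.25)

    def test_iptw_reciprocals_by_received_arm(self):
        cohort = make_cohort([1, 0], [0, 0], [0, 0])
        ws = compute_iptw(cohort, fake_model(cohort, "treatment", [0.75, 0.75]))
        np.testing.assert_allclose(ws.weights, [4.0 / 3.0, 4.0])

    def test_randomized_half_half_gives_weight_two(self):
        cohort = make_cohort([1, 0, 1, 0], [0] * 4, [0] * 4)
        ws = compute_iptw(cohort, fake_model(cohort, "treatment", [0.5] * 4))
        np.testing.assert_allclose(ws.weights, 2.0)

    def test_combine_is_product_and_commutative(self):
        cohort = make_cohort([1, 0], [0, 0], [0, 0])
        ipcw = compute_ipcw(cohort, fake_model(cohort, "censoring", [0.5, 0.5]))
        iptw = compute_iptw(cohort, fake_model(cohort, "treatment", [2 / 3, 1 / 3]))
        both = combine_weights(ipcw, iptw)
        assert both.kind == "IPTCW"
        np.testing.assert_allclose(both.weights, [2 * 1.5, 2 * 1.5])
        flipped = combine_weights(iptw, ipcw)
        np.testing.assert_allclose(both.weights, flipped.weights)

    def test_combine_identity_when_ipcw_unity(self):
        cohort = make_cohort([1, 0, 1], [0, 0, 0], [0, 0, 0])
        ipcw = compute_ipcw(cohort, fake_model(cohort, "censoring", [1 - 1e-12] * 3))
        iptw = compute_iptw(cohort, fake_model(cohort, "treatment", [0.25, 0.5, 0.8]))
        both = combine_weights(ipcw, iptw)
        np.testing.assert_allclose(both.weights, iptw.weights, rtol=1e-9)

    def test_combine_rejects_wrong_kinds(self):
        cohort = make_cohort([1, 0], [0, 0], [0, 0])
        iptw = compute_iptw(cohort, fake_model(cohort, "treatment", [0.5, 0.5]))
        with pytest.raises(ValueError, match="IPCW"):
            combine_weights(iptw, iptw)


class TestStabilize:
    def test_intercept_only_propensity_gives_unit_stabilized_weights(self):
        a = np.r_[np.ones(6, int), np.zeros(4, int)]
        cohort = make_cohort(a, np.zeros(10, int), np.zeros(10))
        model = fit_probability_model(cohort, WeightModelSpec("treatment", ("1",)))
        sw = stabilize(compute_iptw(cohort, model), cohort)
        np.testing.assert_allclose(sw.weights, 1.0, atol=1e-10)

    def test_double_stabilization_rejected(self):
        cohort = make_cohort([1, 0], [0, 0], [0, 0])
        sw = stabilize(compute_iptw(cohort, fake_model(cohort, "treatment", [0.7, 0.7])), cohort)
        with pytest.raises(ValueError, match="already stabilized"):
            stabilize(sw, cohort)


class TestTruncate:
    def make(self, w):
        w = np.asarray(w, float)
        return WeightSet(ids=np.arange(len(w)), probabilities=1.0 / w, weights=w, kind="IPTW")

    def test_one_to_ten_clipped_at_interpolated_percentiles(self):
        out = truncate(self.make(np.arange(1.0, 11.0)), 10, 90)
        assert out.weights.min() == pytest.approx(1.9)
        assert out.weights.max() == pytest.approx(9.1)

    def test_full_range_unchanged(self):
        w = np.array([3.0, 1.0, 4.0, 1.5])
        out = truncate(self.make(w), 0, 100)
        np.testing.assert_allclose(out.weights, w)

    def test_all_equal_unchanged(self):
        out = truncate(self.make(np.full(5, 2.0)), 25, 75)
        np.testing.assert_allclose(out.weights, 2.0)

    def test_idempotent(self):
        first = truncate(self.make(np.arange(1.0, 11.0)), 10, 90)
        again = truncate(first, 10, 90)
        np.testing.assert_array_equal(first.weights, again.weights)

    @given(st.lists(st.floats(min_value=1.0, max_value=100.0), min_size=3, max_size=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_variance_nonincreasing(self, ws):
        before = self.make(np.asarray(ws))
        after = truncate(before, 5, 95)
        assert np.var(after.weights) <= np.var(before.weights) + 1e-12

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError):
            truncate(self.make(np.ones(3)), 90, 10)


class TestSummaries:
    def test_constant_weights(self):
        ws = WeightSet(ids=np.arange(4), probabilities=np.full(4, 0.25),
                       weights=np.full(4, 4.0), kind="IPTW")
        s = summarize_weights(ws)
        assert s["mean"] == 4.0 and s["sd"] == 0.0

    def test_two_point_summary(self):
        ws = WeightSet(ids=np.arange(2), probabilities=np.array([1.0, 1 / 3]),
                       weights=np.array([1.0, 3.0]), kind="IPCW")
        s = summarize_weights(ws)
        assert (s["mean"], s["min"], s["max"]) == (2.0, 1.0, 3.0)

    def test_matches_independent_two_pass_recomputation(self):
        rng = np.random.default_rng(8)
        w = rng.lognormal(0.2, 0.5, 500)
        ws = WeightSet(ids=np.arange(500), probabilities=1 / w, weights=w, kind="IPTW")
        s = summarize_weights(ws)
        # streaming oracle: two-pass mean/variance, independent of numpy stats
        total = 0.0
        for x in w:
            total += x
        mean = total / len(w)
        ssq = 0.0
        for x in w:
            ssq += (x - mean) ** 2
        assert s["mean"] == pytest.approx(mean, rel=1e-12)
        assert s["sd"] == pytest.approx(np.sqrt(ssq / (len(w) - 1)), rel=1e-12)

    def test_empty_rejected(self):
        ws = WeightSet(ids=np.array([]), probabilities=np.array([]),
                       weights=np.array([]), kind="IPTW")
        with pytest.raises(ValueError, match="empty"):
            summarize_weights(ws)


@pytest.fixture(scope="module")
def weights(confounded_50k):
    cohort, _ = confounded_50k
    cm = fit_probability_model(cohort, WeightModelSpec("censoring", DEFAULT_CENSORING_PREDICTORS))
    tm = fit_probability_model(cohort, WeightModelSpec("treatment", DEFAULT_TREATMENT_PREDICTORS))
    return cohort, compute_ipcw(cohort, cm), compute_iptw(cohort, tm)


class TestLargeSampleInvariants:
    """Weighted responders reconstruct the cohort; each arm reweights to n."""

    def test_unstabilized_weights_at_least_one(self, weights):
        _, ipcw, iptw = weights
        assert ipcw.weights.min() >= 1.0
        assert iptw.weights.min() >= 1.0

    def test_ipcw_sum_reconstructs_cohort_size(self, weights):
        cohort, ipcw, _ = weights
        assert abs(ipcw.weights.sum() - len(cohort)) < 0.01 * len(cohort)

    def test_iptw_sum_is_twice_cohort_size(self, weights):
        cohort, _, iptw = weights
        assert abs(iptw.weights.sum() - 2 * len(cohort)) < 0.01 * 2 * len(cohort)

    def test_mean_stabilized_iptw_near_one(self, weights):
        cohort, _, iptw = weights
        sw = stabilize(iptw, cohort)
        assert abs(sw.weights.mean() - 1.0) < 0.02
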