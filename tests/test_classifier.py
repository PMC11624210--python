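"""The statistical core: beta-binomial pmf and MLE, clipped log-ratio
scoring, cross-validation, confusion metrics and the PR curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import sjactiv as sj
from sjactiv.classifier import PARAM_CAP
from sjactiv.errors import FitError


class TestBetabinLogpmf:
    def test_empty_trial_has_probability_one(self):
        assert sj.betabin_logpmf(0, 0, 3.2, 0.7) == pytest.approx(0.0)

    def test_uniform_case(self):
        # alpha = beta = 1 makes every k equally likely: pmf = 1/(n+1)
        assert np.exp(sj.betabin_logpmf(2, 4, 1.0, 1.0)) == pytest.approx(1 / 5)

    @pytest.mark.parametrize(
        "k,n,a,b", [(3, 10, 2.0, 5.0), (0, 7, 0.5, 3.2), (12, 20, 8.1, 0.7), (25, 60, 30.0, 90.0)]
    )
    def test_quadrature_oracle(self, k, n, a, b):
        """The pmf must equal the Beta(a,b) mixture of Binomial(n,p) at k."""
        q, _ = integrate.quad(
            lambda p: stats.binom.pmf(k, n, p) * stats.beta.pdf(p, a, b), 0, 1
        )
        assert sj.betabin_logpmf(k, n, a, b) == pytest.approx(np.log(q), abs=1e-8)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            a, b = rng.uniform(0.05, 50, size=2)
            assert sj.betabin_logpmf(k, n, a, b) == pytest.approx(
                float(stats.betabinom.logpmf(k, n, a, b)), abs=1e-9
            )

    @pytest.mark.parametrize("n", [0, 1, 5, 30, 100])
    @pytest.mark.parametrize("a,b", [(1.0, 1.0), (0.3, 7.0), (50.0, 50.0), (2.0, 0.1)])
    def test_pmf_sums_to_one(self, n, a, b):
        total = np.exp(sj.betabin_logpmf(np.arange(n + 1), np.full(n + 1, n), a, b)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sj.betabin_logpmf(5, 3, 1.0, 1.0)
        with pytest.raises(ValueError):
            sj.betabin_logpmf(1, 3, 0.0, 1.0)


class TestFitBetabin:
    def test_recovers_mean_from_simulated_data(self):
        rng = np.random.default_rng(42)
        p = rng.beta(2.0, 18.0, 2000)
        k = rng.binomial(50, p)
        fit = sj.fit_betabin(k, np.full(2000, 50))
        assert fit.mean == pytest.approx(0.1, abs=0.01)
        assert fit.converged

    def test_binomial_data_drives_dispersion_to_cap(self):
        rng = np.random.default_rng(6)  # an (at most binomially) dispersed draw
        k = rng.binomial(50, 0.2, 2000)
        fit = sj.fit_betabin(k, np.full(2000, 50))
        assert fit.mean == pytest.approx(0.2, abs=0.01)
        assert fit.concentration >= PARAM_CAP * 0.99

    def test_all_zero_counts_floor_the_mean(self):
        fit = sj.fit_betabin(np.zeros(10), np.full(10, 20))
        assert fit.mean <= 1 / 21

    def test_error_without_informative_samples(self):
        with pytest.raises(FitError):
            sj.fit_betabin([0, 0], [0, 0])

    def test_estimation_error_shrinks_with_sample_size(self):
        errs = {}
        for nsamp in (200, 2000):
            rng = np.random.default_rng(5)
            p = rng.beta(2.0, 18.0, nsamp)
            k = rng.binomial(50, p)
            fit = sj.fit_betabin(k, np.full(nsamp, 50))
            errs[nsamp] = (abs(fit.mean - 0.1), abs(fit.concentration - 20.0))
        assert errs[2000][0] < errs[200][0]
        assert errs[2000][1] < errs[200][1]


def two_feature_model(clip=10.0, **kw):
    feats = [
        sj.SJPair("a0", "chr1", 10, 20, ("n0",)),
        sj.SJPair("a1", "chr1", 30, 40, ("n1",)),
    ]
    pa = [sj.BetaBinParams(3.0, 17.0), sj.BetaBinParams(6.0, 14.0)]
    pi = [sj.BetaBinParams(0.5, 49.5), sj.BetaBinParams(1.0, 99.0)]
    return sj.ClassifierModel(feats, pa, pi, clip_bound=clip, **kw)


class TestScoreSample:
    def test_symmetric_model_scores_zero(self):
        feats = [sj.SJPair("a", "chr1", 1, 2, ("n",))]
        params = [sj.BetaBinParams(2.0, 8.0)]
        m = sj.ClassifierModel(feats, params, list(params))
        rep = sj.score_sample(m, [3], [20])
        assert rep.nrf2_score == pytest.approx(0.0)
        assert rep.predicted == "Inactive"

    def test_uninformative_features_contribute_nothing(self):
        m = two_feature_model()
        rep = sj.score_sample(m, [0, 0], [0, 0])
        assert rep.nrf2_score == pytest.approx(m.prior_log_ratio)
        assert np.all(rep.per_feature_contributions == 0)
        assert rep.n_features_informative == 0

    def test_extreme_log_ratio_clipped_to_exactly_ten(self):
        m = sj.ClassifierModel(
            [sj.SJPair("a", "chr1", 1, 2, ("n",))],
            [sj.BetaBinParams(50.0, 50.0)],
            [sj.BetaBinParams(0.5, 500.0)],
        )
        rep = sj.score_sample(m, [40], [80])
        assert rep.per_feature_contributions[0] == pytest.approx(10.0)

    def test_two_feature_score_matches_quadrature_ratios(self):
        m = two_feature_model(clip=1e9)  # clip out of the way for the oracle
        k, n = [3, 7], [50, 60]
        expected = 0.0
        for i, (pa, pi) in enumerate(zip(m.params_active, m.params_inactive)):
            num, _ = integrate.quad(
                lambda p: stats.binom.pmf(k[i], n[i], p) * stats.beta.pdf(p, pa.alpha, pa.beta), 0, 1
            )
            den, _ = integrate.quad(
                lambda p: stats.binom.pmf(k[i], n[i], p) * stats.beta.pdf(p, pi.alpha, pi.beta), 0, 1
            )
            expected += np.log(num) - np.log(den)
        assert sj.score_sample(m, k, n).nrf2_score == pytest.approx(expected, abs=1e-6)

    def test_score_decomposition(self):
        m = two_feature_model(log_prior_active=np.log(0.2), log_prior_inactive=np.log(0.8))
        rep = sj.score_sample(m, [5, 2], [40, 30])
        assert rep.nrf2_score == pytest.approx(
            rep.per_feature_contributions.sum() + m.prior_log_ratio, abs=1e-12
        )

    def test_antisymmetry_under_class_swap(self):
        m = two_feature_model()
        swapped = sj.ClassifierModel(
            m.features, m.params_inactive, m.params_active, clip_bound=m.clip_bound
        )
        k, n = [5, 2], [40, 30]
        assert sj.score_sample(m, k, n).nrf2_score == pytest.approx(
            -sj.score_sample(swapped, k, n).nrf2_score
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        k=st.integers(0, 200),
        n_extra=st.integers(0, 400),
        loga1=st.floats(-5, 5),
        logb1=st.floats(-5, 5),
        loga2=st.floats(-5, 5),
        logb2=st.floats(-5, 5),
    )
    def test_clip_bound_never_exceeded(self, k, n_extra, loga1, logb1, loga2, logb2):
        m = sj.ClassifierModel(
            [sj.SJPair("a", "chr1", 1, 2, ("n",))],
            [sj.BetaBinParams(10.0**loga1, 10.0**logb1)],
            [sj.BetaBinParams(10.0**loga2, 10.0**logb2)],
        )
        rep = sj.score_sample(m, [k], [k + n_extra])
        assert abs(rep.per_feature_contributions[0]) <= m.clip_bound + 1e-12

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            sj.score_sample(two_feature_model(), [1], [2])


class TestFitModel:
    def test_one_params_pair_per_surviving_feature(self, sim_default):
        c = sim_default
        feats = sj.select_features(c.junctions, c.counts, c.labels, c.cohort_map)
        model = sj.fit_model(c.counts, c.labels, feats)
        assert len(model.params_active) == len(model.features) == len(model.params_inactive)
        assert len(model.features) > 0

    def test_single_class_labels_rejected(self, sim_default):
        c = sim_default
        labels = c.labels.copy()
        labels["label"] = "Active"
        feats = [sj.SJPair("abn0", "chr1", 10100, 10900, ("nrm0",))]
        with pytest.raises(FitError):
            sj.fit_model(c.counts, labels, feats)

    def test_empirical_priors_shift_scores_by_log_class_ratio(self, sim_default):
        c = sim_default
        feats = sj.select_features(c.junctions, c.counts, c.labels, c.cohort_map)
        m_eq = sj.fit_model(c.counts, c.labels, feats, priors_mode="equal")
        m_emp = sj.fit_model(c.counts, c.labels, feats, priors_mode="empirical")
        s_eq = sj.score_matrix(m_eq, c.counts)["nrf2_score"].to_numpy()
        s_emp = sj.score_matrix(m_emp, c.counts)["nrf2_score"].to_numpy()
        n_act = (c.labels["label"] == "Active").sum()
        n_inact = (c.labels["label"] == "Inactive").sum()
        assert s_emp - s_eq == pytest.approx(np.log(n_act / n_inact), abs=1e-12)

    def test_score_matrix_agrees_with_score_sample(self, sim_default):
        c = sim_default
        feats = sj.select_features(c.junctions, c.counts, c.labels, c.cohort_map)
        model = sj.fit_model(c.counts, c.labels, feats)
        df = sj.score_matrix(model, c.counts).set_index("sample_id")
        for sid in c.counts.sample_ids[:5]:
            ks = [f.counts(c.counts)[0][c.counts.sample_index(sid)] for f in model.features]
            ns = [f.counts(c.counts)[1][c.counts.sample_index(sid)] for f in model.features]
            rep = sj.score_sample(model, ks, ns, sid)
            assert rep.nrf2_score == pytest.approx(df.loc[sid, "nrf2_score"], abs=1e-9)


class TestMetrics:
    def test_cross_validation_confusion_arithmetic(self):
        c = sj.ConfusionCounts(tp=305, fp=273, tn=8534, fn=162)
        m = sj.compute_metrics(c)
        assert m["specificity_pct"] == 96.90
        assert m["precision_pct"] == 52.77
        assert m["recall_pct"] == 65.31

    def test_zero_denominators_are_nan_not_zero(self):
        c = sj.ConfusionCounts(tp=0, fp=0, tn=5, fn=0)
        assert np.isnan(c.precision) and np.isnan(c.recall)
        assert c.specificity == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sj.ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestPRCurve:
    def test_perfect_separation_has_unit_area(self):
        scores = [5.0, 4.0, 3.0, 1.0, 0.5]
        labels = ["Active", "Active", "Active", "Inactive", "Inactive"]
        _, auc = sj.pr_curve(scores, labels)
        assert auc == pytest.approx(1.0)

    def test_four_point_hand_example(self):
        # scores 4 > 3 > 2 > 1 with labels A, I, A, I. Between the operating
        # points (TP=1,FP=1) and (TP=2,FP=1) precision integrates to
        # 1 - ln(3/2); the first segment contributes 1. AUC = (2 - ln 1.5)/2.
        points, auc = sj.pr_curve([4, 3, 2, 1], ["Active", "Inactive", "Active", "Inactive"])
        assert auc == pytest.approx((2 - np.log(1.5)) / 2)
        assert points["precision"].tolist() == pytest.approx([1.0, 0.5, 2 / 3, 0.5])
        assert points["recall"].tolist() == pytest.approx([0.5, 0.5, 1.0, 1.0])

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(77)
        n = 4000
        labels = np.array(["Active"] * (n // 4) + ["Inactive"] * (3 * n // 4))
        scores = rng.normal(size=n)
        _, auc = sj.pr_curve(scores, labels)
        assert auc == pytest.approx(0.25, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sj.pr_curve([1.0, 2.0], ["Active", "Active"])


class TestCrossValidation:
    def test_same_seed_reproduces_scores(self, sim_default):
        c = sim_default
        r1 = sj.cross_validate(c.junctions, c.counts, c.labels, c.cohort_map, seed=3)
        r2 = sj.cross_validate(c.junctions, c.counts, c.labels, c.cohort_map, seed=3)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)

    def test_each_sample_scored_exactly_once(self, sim_default):
        c = sim_default
        r = sj.cross_validate(c.junctions, c.counts, c.labels, c.cohort_map, seed=3)
        eligible = c.labels[c.labels["label"].isin(["Active", "Inactive"])]["sample_id"]
        assert sorted(r.scores["sample_id"]) == sorted(eligible)

    def test_strong_effect_cohort_separates(self, sim_default):
        c = sim_default
        r = sj.cross_validate(c.junctions, c.counts, c.labels, c.cohort_map, seed=3)
        assert r.confusion.recall > 0.9
        act = r.scores.loc[r.scores["label"] == "Active", "nrf2_score"]
        inact = r.scores.loc[r.scores["label"] == "Inactive", "nrf2_score"]
        p = stats.mannwhitneyu(act, inact, alternative="greater").pvalue
        assert p < 1e-6

    def test_permuted_labels_give_prevalence_level_precision(self, sim_default):
        c = sim_default
        feats = sj.select_features(c.junctions, c.counts, c.labels, c.cohort_map)
        rng = np.random.default_rng(99)
        labels = c.labels.copy()
        mask = labels["label"].isin(["Active", "Inactive"])
        labels.loc[mask, "label"] = rng.permutation(labels.loc[mask, "label"].to_numpy())
        r = sj.cross_validate(
            c.junctions, c.counts, labels, c.cohort_map, seed=7, features=feats, threshold=0.0
        )
        prevalence = 60 / 660
        assert r.confusion.precision == pytest.approx(prevalence, abs=0.05)

    def test_too_few_samples_per_class_rejected(self):
        cm = sj.CountMatrix(["j"], ["s1", "s2", "s3"], np.array([[1, 2, 3]]))
        labels = pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3"], "label": ["Active", "Inactive", "Inactive"]}
        )
        with pytest.raises(FitError):
            sj.cross_validate([], cm, labels, {}, seed=0)
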