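import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cinsig.subtypes import (
    concordance_index,
    consensus_cluster,
    enrichment_tests,
    km_estimate,
    logrank,
    mann_whitney,
    median_split,
    patient_stability,
    presence_absence,
    summarize_per_patient,
    train_subtype_classifier,
    classify_samples,
)


def planted_exposures(n_clusters, per_cluster, seed, concentration=60.0):
    """Cluster-concentrated Dirichlet exposure profiles with known labels."""
    rng = np.random.default_rng(seed)
    k_dim = max(n_clusters + 1, 4)
    centers = []
    while len(centers) < n_clusters:
        c = rng.dirichlet(np.full(k_dim, 0.3))
        if all(
            (c @ o) / (np.linalg.norm(c) * np.linalg.norm(o)) < 0.5 for o in centers
        ):
            centers.append(c)
    rows, labels = [], []
    for ci, center in enumerate(centers):
        for _ in range(per_cluster):
            rows.append(rng.dirichlet(center * concentration + 1e-2))
            labels.append(ci)
    idx = [f"s{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), pd.Series(labels, index=idx)


class TestConsensusClustering:
    def test_recovers_planted_partition(self):
        E, truth = planted_exposures(3, 15, seed=0)
        result = consensus_cluster(E, k_range=(2, 5), n_resamples=120, seed=1)
        assert result.chosen_k == 3
        assert adjusted_rand_score(truth, result.labels) == 1.0

    def test_deterministic_under_seed(self):
        E, _ = planted_exposures(3, 10, seed=2)
        r1 = consensus_cluster(E, k_range=(2, 4), n_resamples=80, seed=9)
        r2 = consensus_cluster(E, k_range=(2, 4), n_resamples=80, seed=9)
        assert (r1.labels == r2.labels).all()
        assert np.array_equal(r1.consensus, r2.consensus)

    def test_identical_samples_all_ones(self):
        E = pd.DataFrame(np.tile([0.5, 0.3, 0.2], (12, 1)))
        result = consensus_cluster(E, k_range=(2, 2), n_resamples=50, seed=0)
        assert np.allclose(result.consensus, 1.0)

    def test_consensus_entries_in_unit_interval(self):
        E, _ = planted_exposures(2, 12, seed=3)
        result = consensus_cluster(E, k_range=(2, 3), n_resamples=60, seed=4)
        assert result.consensus.min() >= 0.0 and result.consensus.max() <= 1.0
        assert np.allclose(np.diag(result.consensus), 1.0)

    def test_order_invariant_labels(self):
        E, _ = planted_exposures(3, 10, seed=5)
        r1 = consensus_cluster(E, k_range=(3, 3), n_resamples=80, seed=6)
        perm = E.sample(frac=1.0, random_state=1)
        r2 = consensus_cluster(perm, k_range=(3, 3), n_resamples=80, seed=6)
        merged = pd.DataFrame({"a": r1.labels, "b": r2.labels.loc[r1.labels.index]})
        assert adjusted_rand_score(merged.a, merged.b) == 1.0

    def test_too_few_samples_rejected(self):
        E = pd.DataFrame(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValueError, match="samples"):
            consensus_cluster(E, k_range=(2, 4))


class TestPatientStability:
    def test_definition_example(self):
        labels = pd.Series({"a1": "A", "a2": "A", "b1": "A", "b2": "B"})
        mapping = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"}
        lab = patient_stability(labels, mapping)
        assert lab.stability_fraction == 0.5
        assert lab.patient_subtype["P2"] == "unstable"
        assert lab.patient_subtype["P1"] == "A"

    def test_singletons_trivially_stable(self):
        labels = pd.Series({"s1": 1, "s2": 2, "s3": 3})
        mapping = {"s1": "P1", "s2": "P2", "s3": "P3"}
        assert patient_stability(labels, mapping).stability_fraction == 1.0

    def test_ten_patient_hand_count(self):
        labels, mapping = {}, {}
        # patients 0-6 stable (2 samples same label), 7-9 unstable
        for p in range(10):
            for s in range(2):
                sid = f"P{p}_s{s}"
                labels[sid] = "X" if p < 7 or s == 0 else "Y"
                mapping[sid] = f"P{p}"
        lab = patient_stability(pd.Series(labels), mapping)
        assert lab.stability_fraction == pytest.approx(0.7)


class TestClassifier:
    def test_separable_cohort_high_accuracy(self):
        E, truth = planted_exposures(3, 20, seed=7)
        clf = train_subtype_classifier(E, truth, seed=0, n_estimators=200)
        labels, probs = classify_samples(clf, E)
        assert (labels == truth).mean() >= 0.95
        assert clf.oob_score_ >= 0.9
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_permuted_labels_near_chance(self):
        E, truth = planted_exposures(3, 20, seed=8)
        rng = np.random.default_rng(0)
        permuted = pd.Series(rng.permutation(truth.to_numpy()), index=truth.index)
        clf = train_subtype_classifier(E, permuted, seed=0, n_estimators=200)
        assert clf.oob_score_ < 0.55  # chance is 1/3

    def test_single_class_rejected(self):
        E, truth = planted_exposures(2, 10, seed=9)
        with pytest.raises(ValueError, match="two classes"):
            train_subtype_classifier(E, pd.Series(0, index=E.index), seed=0)

    def test_small_class_rejected(self):
        E, truth = planted_exposures(2, 10, seed=10)
        truth.iloc[:3] = 2
        with pytest.raises(ValueError, match="< 5 samples"):
            train_subtype_classifier(E, truth, seed=0)


class TestKaplanMeier:
    def test_closed_form_no_censoring(self):
        curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=50)
        curve = km_estimate(times, np.ones(50, dtype=bool))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert curve.at(t) == pytest.approx(np.mean(times > t))

    def test_all_censored_constant_one(self):
        curve = km_estimate(np.array([1.0, 2.0]), np.array([0, 0]))
        assert curve.at(5.0) == 1.0

    def test_against_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        times = rng.exponential(10, size=80)
        events = rng.random(80) < 0.7
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in [1.0, 5.0, 15.0]:
            assert curve.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.ones(5, dtype=bool)
        chi2, p = logrank([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_against_lifelines_two_groups(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(2)
        t1, t2 = rng.exponential(10, 40), rng.exponential(18, 35)
        e1 = rng.random(40) < 0.8
        e2 = rng.random(35) < 0.8
        chi2, p = logrank([(t1, e1), (t2, e2)])
        ll = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-6)
        assert p == pytest.approx(ll.p_value, rel=1e-6)

    def test_against_lifelines_three_groups(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(3)
        groups = [(rng.exponential(s, 30), rng.random(30) < 0.75)
                  for s in (8.0, 12.0, 20.0)]
        chi2, p = logrank(groups)
        df = pd.DataFrame(
            {
                "t": np.concatenate([t for t, _ in groups]),
                "e": np.concatenate([e for _, e in groups]),
                "g": np.repeat([0, 1, 2], 30),
            }
        )
        ll = multivariate_logrank_test(df.t, df.g, df.e)
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-6)
        assert p == pytest.approx(ll.p_value, rel=1e-6)

    def test_zero_event_group_contributes_expected_only(self):
        t1, e1 = np.array([1.0, 2, 3]), np.array([1, 1, 1])
        t2, e2 = np.array([4.0, 5, 6]), np.array([0, 0, 0])
        chi2, p = logrank([(t1, e1), (t2, e2)])
        assert np.isfinite(chi2) and 0 <= p <= 1


class TestConcordance:
    def test_perfectly_ordered(self):
        times = np.array([5.0, 4, 3, 2, 1])
        risk = np.array([1.0, 2, 3, 4, 5])
        assert concordance_index(risk, times, np.ones(5, dtype=bool)) == 1.0

    def test_anti_ordered(self):
        times = np.array([1.0, 2, 3, 4, 5])
        risk = np.array([1.0, 2, 3, 4, 5])
        assert concordance_index(risk, times, np.ones(5, dtype=bool)) == 0.0

    def test_random_risks_near_half(self):
        rng = np.random.default_rng(4)
        n = 400
        times = rng.exponential(10, n)
        events = rng.random(n) < 0.7
        c = concordance_index(rng.random(n), times, events)
        assert abs(c - 0.5) < 0.05

    def test_against_lifelines(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(5)
        times = rng.exponential(10, 60)
        events = rng.random(60) < 0.8
        risk = rng.random(60)
        ours = concordance_index(risk, times, events)
        # lifelines scores predicted survival time (low risk = long survival)
        theirs = ll_cindex(times, -risk, events)
        assert ours == pytest.approx(theirs)


class TestGroupingHelpers:
    def test_median_split_even(self):
        act = pd.Series({"p1": 1.0, "p2": 2.0, "p3": 3.0, "p4": 4.0})
        split = median_split(act)
        assert set(split[split == "high"].index) == {"p3", "p4"}

    def test_all_equal_all_low(self):
        act = pd.Series({"p1": 2.0, "p2": 2.0, "p3": 2.0})
        assert (median_split(act) == "low").all()

    def test_patient_at_median_goes_low(self):
        act = pd.Series({"p1": 1.0, "p2": 2.0, "p3": 3.0})
        assert median_split(act)["p2"] == "low"

    def test_per_patient_sample_median(self):
        values = pd.Series({"s1": 1.0, "s2": 3.0, "s3": 10.0})
        mapping = {"s1": "P1", "s2": "P1", "s3": "P2"}
        out = summarize_per_patient(values, mapping)
        assert out["P1"] == 2.0 and out["P2"] == 10.0

    def test_presence_absence(self):
        assert list(presence_absence(np.array([0, 2, 0, 1]))) == [0, 1, 0, 1]
        assert list(presence_absence(np.zeros(3))) == [0, 0, 0]
        with pytest.raises(ValueError):
            presence_absence(np.array([-1]))


class TestMannWhitney:
    def test_disjoint_supports_exact_small_n(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([10.0, 11, 12, 13, 14])
        u, p = mann_whitney(x, y)
        # the most extreme of the C(10,5)=252 rankings, two-sided
        assert p == pytest.approx(2 / 252)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney(np.array([]), np.array([1.0]))

    def test_enrichment_family_bh(self):
        rng = np.random.default_rng(6)
        E = pd.DataFrame(rng.random((30, 4)), columns=list("ABCD"))
        E.loc[:14, "A"] += 2.0
        ann = pd.Series([True] * 15 + [False] * 15, index=E.index)
        table = enrichment_tests(E, ann)
        assert (table.q >= table.p - 1e-12).all()
        assert table.set_index("signature").q["A"] < 0.01

    def test_enrichment_one_sided_class_rejected(self):
        E = pd.DataFrame(np.random.default_rng(0).random((4, 2)))
        ann = pd.Series([True] * 4, index=E.index)
        with pytest.raises(ValueError, match="both classes"):
            enrichment_tests(E, ann)
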