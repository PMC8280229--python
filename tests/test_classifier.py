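"""Classifier tests, checked against independent brute-force oracles.

The oracle functions restate the nearest-shrunken-centroids formulas
naively (per-sample, per-class, per-gene loops) with no code shared with
the implementation.
"""

import numpy as np
import pandas as pd
import pytest

from metacms.classifier import (
    CentroidModel,
    distill_random_forest,
    posteriors_from_discriminants,
    predict_nsc,
    solve_confidence_cutoff,
    train_nsc,
    tune_loocv,
)
from metacms.core_io import CMS_CLASSES, ExpressionMatrix
from metacms.features import FeatureSet


# ---------------------------------------------------------------------------
# independent oracles


def oracle_train(values, y, classes, t):
    """Naive restatement of the training equations. values: genes x samples."""
    p, n = values.shape
    xbar = np.array([np.mean(values[j]) for j in range(p)])
    centroids, counts = {}, {}
    for k in classes:
        cols = [i for i in range(n) if y[i] == k]
        counts[k] = len(cols)
        centroids[k] = np.array([np.mean(values[j, cols]) for j in range(p)])
    s = np.zeros(p)
    for j in range(p):
        ss = 0.0
        for k in classes:
            for i in range(n):
                if y[i] == k:
                    ss += (values[j, i] - centroids[k][j]) ** 2
        s[j] = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))
    shrunken = {}
    for k in classes:
        m_k = np.sqrt(1.0 / counts[k] - 1.0 / n)
        sh = np.empty(p)
        for j in range(p):
            d = (centroids[k][j] - xbar[j]) / (m_k * (s[j] + s0))
            d_prime = np.sign(d) * max(abs(d) - t, 0.0)
            sh[j] = xbar[j] + m_k * (s[j] + s0) * d_prime
        shrunken[k] = sh
    priors = {k: counts[k] / n for k in classes}
    return xbar, centroids, shrunken, s, s0, priors


def oracle_predict(values, classes, shrunken, s, s0, priors):
    """Brute-force discriminant and posterior per sample."""
    p, n = values.shape
    post = np.empty((n, len(classes)))
    for i in range(n):
        delta = []
        for k in classes:
            d = 0.0
            for j in range(p):
                d += (values[j, i] - shrunken[k][j]) ** 2 / (s[j] + s0) ** 2
            d -= 2.0 * np.log(priors[k])
            delta.append(d)
        delta = np.array(delta)
        w = np.exp(-0.5 * (delta - delta.min()))
        post[i] = w / w.sum()
    return post


def _random_instance(rng, n_genes=6, n_per_class=4, classes=("CMS1", "CMS2", "CMS3")):
    y = np.repeat(list(classes), n_per_class)
    values = rng.normal(0, 1, (n_genes, len(y)))
    for k, cls in enumerate(classes):
        values[k, y == cls] += rng.uniform(0.5, 2.0)
    x = ExpressionMatrix(
        [f"g{j}" for j in range(n_genes)],
        [f"s{i}" for i in range(len(y))],
        values,
    )
    labels = pd.Series(y, index=x.sample_ids)
    fs = FeatureSet(list(x.gene_ids), 0.0, 0.0)
    return x, labels, fs, list(classes)


# ---------------------------------------------------------------------------


class TestTrain:
    def test_t_zero_equals_raw_centroids(self):
        rng = np.random.default_rng(0)
        x, labels, fs, _ = _random_instance(rng)
        model = train_nsc(x, labels, fs, t=0.0)
        np.testing.assert_allclose(model.shrunken_centroids, model.raw_centroids)

    def test_t_infinite_equals_overall_centroid(self):
        rng = np.random.default_rng(1)
        x, labels, fs, _ = _random_instance(rng)
        model = train_nsc(x, labels, fs, t=1e12)
        for k in range(len(model.classes)):
            np.testing.assert_allclose(
                model.shrunken_centroids[k], model.overall_centroid
            )

    def test_two_class_toy_matches_hand_formulas(self):
        # 2 classes, 2 genes, n=4 per class; checked against the oracle
        values = np.array(
            [
                [1.0, 2.0, 1.5, 1.5, 3.0, 4.0, 3.5, 3.5],
                [0.0, 0.5, -0.5, 0.0, 0.2, -0.2, 0.1, -0.1],
            ]
        )
        y = ["CMS1"] * 4 + ["CMS2"] * 4
        x = ExpressionMatrix(["gA", "gB"], [f"s{i}" for i in range(8)], values)
        labels = pd.Series(y, index=x.sample_ids)
        fs = FeatureSet(["gA", "gB"], 0.0, 0.0)
        for t in (0.0, 0.5, 2.0, 10.0):
            model = train_nsc(x, labels, fs, t=t)
            xbar, _, shrunken, s, s0, priors = oracle_train(
                values, np.array(y), ["CMS1", "CMS2"], t
            )
            np.testing.assert_allclose(model.overall_centroid, xbar, atol=1e-12)
            np.testing.assert_allclose(model.pooled_sd, s, atol=1e-12)
            assert model.s0 == pytest.approx(s0)
            for i, k in enumerate(["CMS1", "CMS2"]):
                np.testing.assert_allclose(
                    model.shrunken_centroids[i], shrunken[k], atol=1e-12
                )

    def test_class_with_one_sample_rejected(self):
        x = ExpressionMatrix(
            ["g0"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]])
        )
        labels = pd.Series(["CMS1", "CMS1", "CMS2"], index=x.sample_ids)
        with pytest.raises(ValueError, match="CMS2"):
            train_nsc(x, labels, FeatureSet(["g0"], 0, 0), t=0.0)

    def test_missing_feature_gene_listed(self):
        rng = np.random.default_rng(2)
        x, labels, _, _ = _random_instance(rng)
        with pytest.raises(KeyError, match="ghost"):
            train_nsc(x, labels, FeatureSet(["g0", "ghost"], 0, 0), t=0.0)

    def test_na_label_rejected(self):
        rng = np.random.default_rng(3)
        x, labels, fs, _ = _random_instance(rng)
        labels.iloc[0] = "NA"
        with pytest.raises(ValueError, match="confident"):
            train_nsc(x, labels, fs, t=0.0)

    def test_negative_t_rejected(self):
        rng = np.random.default_rng(4)
        x, labels, fs, _ = _random_instance(rng)
        with pytest.raises(ValueError, match="non-negative"):
            train_nsc(x, labels, fs, t=-0.5)


class TestPredict:
    def test_oracle_equivalence_100_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x, labels, fs, classes = _random_instance(
                rng,
                n_genes=int(rng.integers(3, 8)),
                n_per_class=int(rng.integers(2, 5)),
            )
            t = float(rng.uniform(0, 2))
            model = train_nsc(x, labels, fs, t=t)
            *_, shrunken, s, s0, priors = oracle_train(
                x.values, labels.to_numpy(), classes, t
            )
            expected = oracle_predict(x.values, classes, shrunken, s, s0, priors)
            got = predict_nsc(model, x)[classes].to_numpy()
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_sample_at_centroid_with_equal_priors_wins(self):
        rng = np.random.default_rng(5)
        x, labels, fs, classes = _random_instance(rng, n_per_class=4)
        model = train_nsc(x, labels, fs, t=0.0)
        probe = ExpressionMatrix(
            x.gene_ids, ["probe"], model.shrunken_centroids[1][:, None]
        )
        calls = predict_nsc(model, probe)
        assert calls.loc["probe", "nearest"] == classes[1]

    def test_fully_shrunken_posteriors_equal_priors(self):
        rng = np.random.default_rng(6)
        y = ["CMS1"] * 6 + ["CMS2"] * 3  # unequal priors
        values = rng.normal(0, 1, (4, 9))
        x = ExpressionMatrix(
            [f"g{j}" for j in range(4)], [f"s{i}" for i in range(9)], values
        )
        labels = pd.Series(y, index=x.sample_ids)
        model = train_nsc(x, labels, FeatureSet(list(x.gene_ids), 0, 0), t=1e12)
        post = predict_nsc(model, x)[["CMS1", "CMS2"]].to_numpy()
        np.testing.assert_allclose(post, np.tile([2 / 3, 1 / 3], (9, 1)), atol=1e-12)

    def test_posteriors_sum_to_one(self, small_cohort):
        prim = small_cohort.primaries()
        fs = FeatureSet(list(prim.gene_ids)[:50], 0, 0)
        model = train_nsc(prim, small_cohort.true_labels(), fs, t=0.5)
        post = predict_nsc(model, prim)[list(model.classes)].to_numpy()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_posterior_invariant_to_delta_offset(self):
        rng = np.random.default_rng(7)
        delta = rng.uniform(0, 50, (5, 4))
        a = posteriors_from_discriminants(delta)
        b = posteriors_from_discriminants(delta + 123.4)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_raising_cutoff_never_unNAs(self):
        rng = np.random.default_rng(8)
        x, labels, fs, _ = _random_instance(rng, n_genes=5, n_per_class=5)
        model = train_nsc(x, labels, fs, t=0.5)
        lo = predict_nsc(model, x, cutoff=0.4)["call"]
        hi = predict_nsc(model, x, cutoff=0.9)["call"]
        for s in x.sample_ids:
            if lo[s] == "NA":
                assert hi[s] == "NA"

    def test_nonfinite_input_names_sample(self):
        rng = np.random.default_rng(9)
        x, labels, fs, _ = _random_instance(rng)
        model = train_nsc(x, labels, fs, t=0.0)
        bad_vals = x.values.copy()
        probe = ExpressionMatrix.__new__(ExpressionMatrix)
        probe.gene_ids = list(x.gene_ids)
        probe.sample_ids = list(x.sample_ids)
        bad_vals[0, 2] = np.inf
        probe.values = bad_vals
        with pytest.raises(ValueError, match="s2"):
            predict_nsc(model, probe)

    def test_missing_model_gene_errors(self):
        rng = np.random.default_rng(10)
        x, labels, fs, _ = _random_instance(rng)
        model = train_nsc(x, labels, fs, t=0.0)
        sub = x.subset_genes(x.gene_ids[1:])
        with pytest.raises(KeyError, match="g0"):
            predict_nsc(model, sub)


class TestTuning:
    def test_separable_data_reaches_accuracy_one(self, small_cohort):
        prim = small_cohort.primaries()
        labels = small_cohort.true_labels()
        fs = FeatureSet(list(prim.gene_ids)[:100], 0, 0)
        curve = tune_loocv(prim, labels, fs)
        assert curve.accuracies.max() == 1.0
        ties = curve.t_grid[curve.accuracies == curve.accuracies.max()]
        assert curve.chosen_t == ties.max()

    def test_tie_broken_toward_largest_t(self):
        rng = np.random.default_rng(11)
        x, labels, fs, _ = _random_instance(rng, n_genes=4, n_per_class=6)
        curve = tune_loocv(x, labels, fs, t_grid=[0.0, 0.1, 0.2])
        ties = curve.t_grid[curve.accuracies == curve.accuracies.max()]
        assert curve.chosen_t == ties.max()

    def test_permuted_labels_near_majority_rate(self, small_cohort):
        prim = small_cohort.primaries()
        labels = small_cohort.true_labels().loc[list(prim.sample_ids)]
        rng = np.random.default_rng(123)
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        fs = FeatureSet(list(prim.gene_ids)[:60], 0, 0)
        curve = tune_loocv(prim, permuted, fs, t_grid=[0.5])
        n = prim.n_samples
        majority = labels.value_counts(normalize=True).max()
        # binomial noise around the chance rate
        bound = majority + 3 * np.sqrt(majority * (1 - majority) / n)
        assert curve.accuracies[0] <= bound

    def test_negative_grid_rejected(self, small_cohort):
        prim = small_cohort.primaries()
        fs = FeatureSet(list(prim.gene_ids)[:20], 0, 0)
        with pytest.raises(ValueError, match="negative"):
            tune_loocv(prim, small_cohort.true_labels(), fs, t_grid=[-1.0, 0.5])

    def test_empty_grid_rejected(self, small_cohort):
        prim = small_cohort.primaries()
        fs = FeatureSet(list(prim.gene_ids)[:20], 0, 0)
        with pytest.raises(ValueError, match="empty"):
            tune_loocv(prim, small_cohort.true_labels(), fs, t_grid=[])


class TestDefaults:
    def test_published_operating_point_is_default(self):
        # shrinkage 1.5 and posterior cutoff 0.5 are the published settings
        from metacms.classifier import DEFAULT_CUTOFF, DEFAULT_SHRINKAGE

        assert DEFAULT_SHRINKAGE == 1.5
        assert DEFAULT_CUTOFF == 0.5


class TestCutoffSolver:
    def test_solves_target_na_fraction(self, small_cohort):
        prim = small_cohort.primaries()
        fs = FeatureSet(list(prim.gene_ids)[:60], 0, 0)
        model = train_nsc(prim, small_cohort.true_labels(), fs, t=1.0)
        calls = predict_nsc(model, prim)
        for target in (0.0, 0.25, 0.5):
            c = solve_confidence_cutoff(calls, target)
            refreshed = predict_nsc(model, prim, cutoff=c)
            na_frac = (refreshed["call"] == "NA").mean()
            assert na_frac >= target
            assert na_frac - target <= 1.0 / len(calls) + 1e-12


@pytest.fixture(scope="module")
def distilled(small_cohort):
    prim = small_cohort.primaries()
    fs = FeatureSet(list(prim.gene_ids)[:80], 0, 0)
    model = train_nsc(prim, small_cohort.true_labels(), fs, t=0.5)
    calls = predict_nsc(model, prim)
    forest = distill_random_forest(calls, prim, fs, n_trees=100, seed=9)
    return prim, fs, model, calls, forest


class TestDistillation:
    def test_distillation_fidelity(self, distilled):
        prim, _, _, calls, forest = distilled
        confident = calls[calls["call"] != "NA"]
        fcalls = forest.predict(prim)
        agreement = (
            fcalls.loc[confident.index, "nearest"] == confident["call"]
        ).mean()
        assert agreement >= 0.95

    def test_deterministic_given_seed(self, distilled, small_cohort):
        prim, fs, model, calls, forest = distilled
        forest2 = distill_random_forest(calls, prim, fs, n_trees=100, seed=9)
        a = forest.predict(small_cohort.metastases())
        b = forest2.predict(small_cohort.metastases())
        assert (a == b).all().all()

    def test_single_tree_two_samples_exact(self):
        x = ExpressionMatrix(
            ["g0", "g1"], ["a", "b"], np.array([[0.0, 10.0], [10.0, 0.0]])
        )
        calls = pd.DataFrame(
            {"nearest": ["CMS1", "CMS2"], "call": ["CMS1", "CMS2"]},
            index=["a", "b"],
        )
        fs = FeatureSet(["g0", "g1"], 0, 0)
        forest = distill_random_forest(calls, x, fs, n_trees=1, seed=0)
        out = forest.predict(x)
        assert list(out["nearest"]) == ["CMS1", "CMS2"]

    def test_single_label_rejected(self):
        x = ExpressionMatrix(["g0"], ["a", "b"], np.array([[0.0, 1.0]]))
        calls = pd.DataFrame(
            {"nearest": ["CMS1", "CMS1"], "call": ["CMS1", "CMS1"]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="distinct"):
            distill_random_forest(calls, x, FeatureSet(["g0"], 0, 0), seed=0)

    def test_na_samples_excluded_from_training(self):
        x = ExpressionMatrix(
            ["g0"], ["a", "b", "c"], np.array([[0.0, 10.0, 5.0]])
        )
        calls = pd.DataFrame(
            {"nearest": ["CMS1", "CMS2", "CMS3"], "call": ["CMS1", "CMS2", "NA"]},
            index=["a", "b", "c"],
        )
        forest = distill_random_forest(
            calls, x, FeatureSet(["g0"], 0, 0), n_trees=10, seed=0
        )
        assert set(forest.classes) == {"CMS1", "CMS2"}
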