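import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from mirpanel import panel
from mirpanel.config import table1_sources
from mirpanel.errors import InsufficientGroupError

from _oracles import (criterion, exhaustive_best, greedy_forward,
                      latent_pair_instance, random_instance)


def sample_frame(counts):
    """counts: list of (source_id, n_cases, n_controls)."""
    rows = []
    i = 0
    for src, nc, nn in counts:
        for cls, n in (("cancer", nc), ("non_cancer", nn)):
            for _ in range(n):
                i += 1
                rows.append((f"s{i:04d}", src, cls))
    return pd.DataFrame(rows, columns=["sample_id", "source_id", "class"])


class TestStratifiedPartition:
    def check_invariants(self, samples, part):
        a, b = set(part.group_a), set(part.group_b)
        assert not a & b
        assert a | b == set(samples["sample_id"])
        tagged = samples.set_index("sample_id")
        for (src, cls), cell in samples.groupby(["source_id", "class"]):
            na = len(a & set(cell["sample_id"]))
            nb = len(b & set(cell["sample_id"]))
            assert abs(na - nb) <= 1
        for src, grp in samples.groupby("source_id"):
            na = len(a & set(grp["sample_id"]))
            nb = len(b & set(grp["sample_id"]))
            assert abs(na - nb) <= 1
        return tagged

    def test_single_source_balanced(self):
        samples = sample_frame([("s1", 5, 5)])
        part = panel.stratified_partition(samples,
                                          np.random.default_rng(0))
        assert len(part.group_a) == len(part.group_b) == 5
        self.check_invariants(samples, part)

    def test_two_even_sources_split_exactly(self):
        samples = sample_frame([("s1", 20, 20), ("s2", 20, 20)])
        part = panel.stratified_partition(samples,
                                          np.random.default_rng(1))
        for src in ("s1", "s2"):
            ids = set(samples.loc[samples["source_id"] == src, "sample_id"])
            assert len(ids & set(part.group_a)) == 20

    def test_full_training_cohort_layout(self):
        # discovery + validation1 sources: 663 samples across 6 sources
        counts = {}
        for s in table1_sources():
            if s.cohort in ("discovery", "validation1"):
                nc, nn = counts.get(s.source_id, (0, 0))
                counts[s.source_id] = (nc + s.n_cases, nn + s.n_controls)
        samples = sample_frame([(k, *v) for k, v in sorted(counts.items())])
        assert len(samples) == 663
        for seed in range(5):
            part = panel.stratified_partition(
                samples, np.random.default_rng(seed))
            self.check_invariants(samples, part)

    def test_deterministic_given_seed(self):
        samples = sample_frame([("s1", 11, 9), ("s2", 4, 7)])
        p1 = panel.stratified_partition(samples, np.random.default_rng(5))
        p2 = panel.stratified_partition(samples, np.random.default_rng(5))
        assert p1.group_a == p2.group_a and p1.group_b == p2.group_b


class TestFitLogistic:
    def test_matches_sklearn_reference(self, rng):
        X = rng.normal(size=(200, 3))
        y = (rng.uniform(size=200) <
             1 / (1 + np.exp(-(X @ [1.0, -0.5, 0.2])))).astype(float)
        model = panel.fit_logistic(
            pd.DataFrame(np.exp2(X), columns=list("abc")).apply(np.log2),
            y)
        ref = LogisticRegression(penalty=None, tol=1e-10, max_iter=1000)
        ref.fit(X, y)
        assert np.allclose(model.coefficients, ref.coef_[0], atol=1e-4)
        assert model.intercept == pytest.approx(ref.intercept_[0],
                                                abs=1e-4)

    def test_null_features_give_prevalence_intercept(self):
        rng = np.random.default_rng(12)
        n = 10_000
        X = rng.normal(size=(n, 2))
        y = (rng.uniform(size=n) < 0.3).astype(float)
        model = panel.fit_logistic(X, y)
        prev = y.mean()
        se = np.sqrt(1.0 / (n * prev * (1 - prev)))
        assert np.all(np.abs(model.coefficients) < 4 * se)
        assert abs(model.intercept - np.log(prev / (1 - prev))) < 4 * se

    def test_two_by_two_closed_form(self):
        a, b, c, d = 20, 15, 12, 25  # (x=1,y=1), (1,0), (0,1), (0,0)
        x = np.r_[np.ones(a + b), np.zeros(c + d)][:, None]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        model = panel.fit_logistic(x, y)
        assert model.coefficients[0] == pytest.approx(
            np.log(a * d / (b * c)), abs=1e-6)

    def test_separable_data_stays_finite(self):
        x = np.r_[np.linspace(1, 2, 10), np.linspace(3, 4, 10)][:, None]
        y = np.r_[np.zeros(10), np.ones(10)]
        model = panel.fit_logistic(x, y)
        assert np.isfinite(model.coefficients).all()
        from mirpanel.diffexpr import mannwhitney_auc
        assert mannwhitney_auc(x[:, 0] * model.coefficients[0],
                               y.astype(bool)) == 1.0

    def test_one_class_raises(self):
        with pytest.raises(InsufficientGroupError):
            panel.fit_logistic(np.random.default_rng(0).normal(size=(4, 1)),
                               np.ones(4))


class TestScore:
    def test_zero_model_scores_half(self):
        m = panel.PanelModel(["a"], np.array([0.0]), 0.0)
        assert panel.score(m, {"a": 123.0}) == pytest.approx(0.5)

    def test_large_intercept_saturates(self):
        m = panel.PanelModel(["a"], np.array([0.0]), 50.0)
        assert panel.score(m, {"a": 1.0}) == pytest.approx(1.0, abs=1e-12)

    def test_opposing_coefficients_cancel(self):
        m = panel.PanelModel(["a", "b"], np.array([1.0, -1.0]), 0.0)
        assert panel.score(m, {"a": 8.0, "b": 8.0}) == pytest.approx(0.5)

    def test_missing_feature_raises(self):
        m = panel.PanelModel(["a", "b"], np.array([1.0, -1.0]), 0.0)
        with pytest.raises(KeyError):
            panel.score_samples(m, pd.DataFrame({"a": [1.0]}))


class TestSFFS:
    def ids(self, p):
        return [f"m{i:02d}" for i in range(p)]

    def test_dominates_greedy_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X, y = random_instance(rng, n=60, p=6)
            best = panel.sffs(self.ids(6), X, y, 4)
            greedy = greedy_forward(X, y, 4)
            for s in range(1, 5):
                assert best[s][1] >= greedy[s][1] - 1e-12

    def test_matches_exhaustive_on_small_pools(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(10):
            X, y = random_instance(rng, n=60, p=8)
            best = panel.sffs(self.ids(8), X, y, 3)
            ok = all(abs(best[s][1] - exhaustive_best(X, y, s)[1]) < 1e-9
                     for s in (1, 2, 3))
            hits += ok
        assert hits >= 8

    def test_duplicate_feature_never_selected_twice(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, n=80, p=5)
        X = np.column_stack([X, X[:, 0]])  # m05 duplicates m00
        best = panel.sffs(self.ids(6), X, y, 4)
        for s, (ids, _) in best.items():
            assert not ({"m00", "m05"} <= set(ids))

    def test_floating_recovers_jointly_informative_pair(self):
        rng = np.random.default_rng(21)
        X, y, pair = latent_pair_instance(rng)
        names = self.ids(X.shape[1])
        best = panel.sffs(names, X, y, 4)
        greedy = greedy_forward(X, y, 2)
        assert set(best[2][0]) == {names[pair[0]], names[pair[1]]}
        assert set(greedy[2][0]) != set(pair)


def toy_cv_inputs(rng, n_per=10, p=6, effect=1.0):
    samples = sample_frame([("s1", n_per, n_per)])
    y = (samples["class"] == "cancer").to_numpy().astype(float)
    X = rng.normal(size=(2 * n_per, p)) + y[:, None] * effect
    expr = pd.DataFrame(np.exp2(X), index=samples["sample_id"],
                        columns=[f"m{i:02d}" for i in range(p)])
    return expr, samples


class TestCrossValidation:
    def test_record_bookkeeping(self, rng):
        expr, samples = toy_cv_inputs(rng)
        cv = panel.crossvalidate_panels(expr, samples,
                                        list(expr.columns),
                                        n_iter=2, sizes=range(2, 4),
                                        seed=0)
        assert len(cv) == 2 * 2 * 2  # iterations x folds x sizes
        assert set(cv["fold"]) == {"A_train", "B_train"}

    def test_bitwise_reproducible_from_master_seed(self, rng):
        expr, samples = toy_cv_inputs(rng)
        cv1 = panel.crossvalidate_panels(expr, samples, list(expr.columns),
                                         n_iter=3, sizes=range(2, 4),
                                         seed=9)
        cv2 = panel.crossvalidate_panels(expr, samples, list(expr.columns),
                                         n_iter=3, sizes=range(2, 4),
                                         seed=9)
        pd.testing.assert_frame_equal(cv1, cv2)

    def test_train_auc_dominates_test_auc_on_average(self, rng):
        expr, samples = toy_cv_inputs(rng, n_per=25, p=8, effect=0.4)
        cv = panel.crossvalidate_panels(expr, samples, list(expr.columns),
                                        n_iter=13, sizes=range(2, 6),
                                        seed=2)
        assert len(cv) >= 100
        assert cv["train_auc"].mean() >= cv["test_auc"].mean()


class TestOptimalSize:
    def record_frame(self, dists):
        rows = []
        for size, values in dists.items():
            for i, v in enumerate(values):
                rows.append((i, "A_train", size, "x", v, v))
        return pd.DataFrame(rows, columns=["iteration", "fold",
                                           "panel_size", "mirna_ids",
                                           "train_auc", "test_auc"])

    def test_flat_distributions_choose_smallest(self):
        cv = self.record_frame({s: [0.8] * 50 for s in (2, 3, 4)})
        assert panel.optimal_size(cv) == 2

    def test_step_increase_detected(self):
        rng = np.random.default_rng(0)
        cv = self.record_frame({
            2: rng.normal(0.70, 0.01, 200),
            3: rng.normal(0.90, 0.01, 200),
            4: rng.normal(0.90, 0.01, 200),
            5: rng.normal(0.90, 0.01, 200),
        })
        assert panel.optimal_size(cv, alpha=0.001) == 3

    def test_all_significant_returns_max(self):
        rng = np.random.default_rng(1)
        cv = self.record_frame({
            s: rng.normal(0.5 + 0.08 * s, 0.005, 100) for s in (2, 3, 4)})
        assert panel.optimal_size(cv, alpha=0.001) == 4


class TestSelectFinalPanel:
    def test_single_candidate_returned(self, rng):
        expr, samples = toy_cv_inputs(rng, n_per=15, p=4)
        y = samples.set_index("sample_id")["class"]
        cv = pd.DataFrame([(0, "A_train", 2, "m00,m01", 0.9, 0.8)],
                          columns=["iteration", "fold", "panel_size",
                                   "mirna_ids", "train_auc", "test_auc"])
        model = panel.select_final_panel(cv, 2, expr, y, expr, y)
        assert model.mirna_ids == ["m00", "m01"]
        assert len(model.coefficients) == 2

    def test_dominating_candidate_wins(self):
        rng = np.random.default_rng(6)
        samples = sample_frame([("s1", 30, 30)])
        y = samples.set_index("sample_id")["class"]
        lab = (samples["class"] == "cancer").to_numpy().astype(float)
        X = rng.normal(size=(60, 4))
        X[:, 0] += lab * 3.0  # m00 strongly informative
        expr = pd.DataFrame(np.exp2(X), index=samples["sample_id"],
                            columns=["m00", "m01", "m02", "m03"])
        cv = pd.DataFrame([
            (0, "A_train", 2, "m00,m01", 0.9, 0.9),
            (0, "B_train", 2, "m02,m03", 0.6, 0.6),
        ], columns=["iteration", "fold", "panel_size", "mirna_ids",
                    "train_auc", "test_auc"])
        model = panel.select_final_panel(cv, 2, expr, y, expr, y)
        assert model.mirna_ids == ["m00", "m01"]
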