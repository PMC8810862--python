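import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpanel import normalize, quantify
from mirpanel.errors import (InsufficientCandidatesError,
                             InsufficientGroupError)
from mirpanel.synth import simulate_study

from conftest import small_config


def brute_force_genorm_m(log_expr: pd.DataFrame) -> pd.Series:
    """Independent double-loop implementation of the geNORM M value."""
    cols = list(log_expr.columns)
    out = {}
    for j in cols:
        sds = [np.std(log_expr[j] - log_expr[k], ddof=1)
               for k in cols if k != j]
        out[j] = float(np.mean(sds))
    return pd.Series(out)


def random_log_matrix(rng, n=10, k=20):
    return pd.DataFrame(rng.normal(10, 2, size=(n, k)),
                        columns=[f"g{i:02d}" for i in range(k)])


class TestGenormM:
    def test_pairwise_proportional_candidates_have_zero_m(self):
        base = np.linspace(1, 3, 6)
        log_expr = pd.DataFrame({"a": base, "b": base + 1.0,
                                 "c": base - 0.5})
        m = normalize.genorm_m(log_expr)
        assert np.allclose(m, 0.0, atol=1e-12)

    def test_two_candidates_share_the_ratio_sd(self, rng):
        log_expr = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        m = normalize.genorm_m(log_expr)
        want = np.std(log_expr["a"] - log_expr["b"], ddof=1)
        assert m["a"] == pytest.approx(want, rel=1e-12)
        assert m["b"] == pytest.approx(want, rel=1e-12)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(20):
            log_expr = random_log_matrix(rng, n=10, k=8)
            m = normalize.genorm_m(log_expr)
            want = brute_force_genorm_m(log_expr)
            assert np.allclose(m, want[m.index], atol=1e-12)

    def test_too_few_candidates(self):
        with pytest.raises(InsufficientCandidatesError):
            normalize.genorm_m(pd.DataFrame({"a": [1.0, 2.0]}))

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_to_constant_shift_of_one_candidate(self, shift):
        rng = np.random.default_rng(4)
        log_expr = random_log_matrix(rng, n=8, k=4)
        m0 = normalize.genorm_m(log_expr)
        shifted = log_expr.copy()
        shifted["g00"] = shifted["g00"] + shift
        m1 = normalize.genorm_m(shifted)
        assert np.allclose(m0, m1, atol=1e-9)


class TestGenormRank:
    def test_noisy_clone_excluded_first(self, rng):
        a = rng.normal(10, 0.1, 30)
        log_expr = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.1, 30),
                                 "c": a + rng.normal(0, 3.0, 30)})
        ranks, _ = normalize.genorm_rank(log_expr)
        assert ranks["c"] == 3  # least stable, excluded first

    def test_ranks_are_a_permutation(self, rng):
        log_expr = random_log_matrix(rng, n=12, k=7)
        ranks, v = normalize.genorm_rank(log_expr)
        assert sorted(ranks) == list(range(1, 8))
        assert len(v) == 5  # V(2,3) .. V(6,7)

    def test_column_permutation_invariance(self, rng):
        log_expr = random_log_matrix(rng, n=12, k=6)
        ranks1, _ = normalize.genorm_rank(log_expr)
        shuffled = log_expr[list(log_expr.columns[::-1])]
        ranks2, _ = normalize.genorm_rank(shuffled)
        pd.testing.assert_series_equal(ranks1.sort_index(),
                                       ranks2.sort_index())


class TestNormFinder:
    def test_identical_columns_give_zero_rho(self):
        base = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 3.5])
        log_expr = pd.DataFrame({"a": base, "b": base, "c": base})
        labels = np.array(["x", "x", "x", "y", "y", "y"])
        rho = normalize.normfinder_stability(log_expr, labels)
        assert np.allclose(rho, 0.0, atol=1e-12)

    def test_single_group_reduces_to_sqrt_w_over_n(self, rng):
        log_expr = random_log_matrix(rng, n=8, k=4)
        labels = np.repeat("x", 8)
        rho = normalize.normfinder_stability(log_expr, labels)
        X = log_expr.to_numpy()
        X = X - X.mean(axis=1, keepdims=True)
        want = np.sqrt(X.var(axis=0, ddof=1) / 8)
        assert np.allclose(rho, want, atol=1e-12)

    def test_matches_step_by_step_recomputation(self, rng):
        log_expr = random_log_matrix(rng, n=6, k=4)
        labels = np.array(["x", "x", "x", "y", "y", "y"])
        rho = normalize.normfinder_stability(log_expr, labels)
        # spreadsheet-style oracle
        X = log_expr.to_numpy() - log_expr.to_numpy().mean(1, keepdims=True)
        want = []
        for g in range(4):
            terms = []
            vs = {grp: X[labels == grp, g].mean() for grp in ("x", "y")}
            vbar = np.mean(list(vs.values()))
            for grp in ("x", "y"):
                w = X[labels == grp, g].var(ddof=1)
                n = (labels == grp).sum()
                terms.append(abs(vs[grp] - vbar) + np.sqrt(w / n))
            want.append(np.mean(terms))
        assert np.allclose(rho, want, atol=1e-12)

    def test_small_group_raises(self, rng):
        log_expr = random_log_matrix(rng, n=4, k=3)
        with pytest.raises(InsufficientGroupError):
            normalize.normfinder_stability(
                log_expr, np.array(["x", "x", "x", "y"]))


class TestSelectReferences:
    def test_agreeing_methods_return_their_top(self):
        stab = pd.DataFrame({
            "genorm_m": [0.1, 0.2, 0.3, 0.4],
            "genorm_rank": [1, 2, 3, 4],
            "normfinder_rho": [0.01, 0.02, 0.03, 0.04],
        }, index=["a", "b", "c", "d"])
        refs = normalize.select_references(stab, k=3)
        assert refs.mirna_ids == ["a", "b", "c"]

    def test_k_equal_to_pool_returns_all(self):
        stab = pd.DataFrame({"genorm_m": [0.1, 0.2],
                             "genorm_rank": [1, 2],
                             "normfinder_rho": [0.2, 0.1]},
                            index=["a", "b"])
        assert sorted(normalize.select_references(stab, 2).mirna_ids) == \
            ["a", "b"]

    def test_k_too_large_raises(self):
        stab = pd.DataFrame({"genorm_m": [0.1], "genorm_rank": [1],
                             "normfinder_rho": [0.1]}, index=["a"])
        with pytest.raises(InsufficientCandidatesError):
            normalize.select_references(stab, 2)


def as_matrix(values: pd.DataFrame) -> quantify.ExpressionMatrix:
    flags = pd.DataFrame("interpolated", index=values.index,
                         columns=values.columns)
    return quantify.ExpressionMatrix(values=values, flags=flags)


class TestNormalizeExpression:
    def test_per_sample_scale_invariance(self, rng):
        values = pd.DataFrame(np.exp2(rng.normal(10, 1, (5, 4))),
                              index=[f"s{i}" for i in range(5)],
                              columns=list("abcd"))
        refs = normalize.ReferenceSet(["a", "b"])
        n1 = normalize.normalize_expression(as_matrix(values), refs)
        scaled = values.copy()
        scaled.loc["s2"] *= 10.0
        n2 = normalize.normalize_expression(as_matrix(scaled), refs)
        pd.testing.assert_frame_equal(n1.values, n2.values)

    def test_unit_references_are_identity(self):
        values = pd.DataFrame({"ref": [1.0, 1.0], "x": [3.0, 5.0]},
                              index=["s1", "s2"])
        out = normalize.normalize_expression(
            as_matrix(values), normalize.ReferenceSet(["ref"]))
        pd.testing.assert_frame_equal(out.values, values)

    def test_toy_division_by_reference(self):
        values = pd.DataFrame({"A": [2.0, 4.0], "x": [8.0, 8.0],
                               "y": [2.0, 1.0]}, index=["s1", "s2"])
        out = normalize.normalize_expression(
            as_matrix(values), normalize.ReferenceSet(["A"]))
        assert out.values.loc["s1", "x"] == pytest.approx(4.0)
        assert out.values.loc["s2", "x"] == pytest.approx(2.0)
        assert out.values.loc["s2", "y"] == pytest.approx(0.25)

    def test_normalization_shrinks_null_marker_spread(self):
        # with per-sample content variation present, dividing by the
        # reference geometric mean reduces the spread of null markers
        cfg = small_config(seed=23, input_variation_sd=0.6)
        table, truth, ct = simulate_study(cfg)
        expr = quantify.quantify_dataset(ct, table, cfg.spikein_copies)
        null = truth.truth.index[~truth.truth["is_differential"]
                                 & ~truth.truth["is_reference"]]
        refs = normalize.ReferenceSet(
            sorted(truth.truth.index[truth.truth["is_reference"]]))
        norm = normalize.normalize_expression(expr, refs)
        sd_raw = np.log2(expr.values[null]).std().mean()
        sd_norm = np.log2(norm.values[null]).std().mean()
        assert sd_norm < sd_raw


class TestPlantedReferenceRecovery:
    def test_planted_references_most_stable(self):
        # references are generated with much lower biological variance, so
        # both stability methods should put them on top
        cfg = small_config(seed=31)
        table, truth, ct = simulate_study(cfg)
        expr = quantify.quantify_dataset(ct, table, cfg.spikein_copies)
        disc = table[table["cohort"] == "discovery"]
        ids = list(disc["sample_id"])
        pool = normalize.candidate_pool(quantify.ExpressionMatrix(
            values=expr.values.loc[ids], flags=expr.flags.loc[ids]))
        stab = normalize.stability_table(
            np.log2(expr.values.loc[ids, pool]),
            disc.set_index("sample_id").loc[ids, "class"])
        refs = normalize.select_references(stab, k=3)
        planted = sorted(truth.truth.index[truth.truth["is_reference"]])
        assert sorted(refs.mirna_ids) == planted
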