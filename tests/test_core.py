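"""Unit and property tests for the CTA score computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ctascore import (
    ClusterAssignment,
    ExpressionMatrix,
    InputError,
    build_cluster_profile,
    compute_cta_matrix,
    cta_score,
    gini_weight,
    row_normalize,
)
from ctascore.core import score_cell_type

from _oracle import oracle_cta
from conftest import random_instance


class TestRowNormalize:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([2.0, 2.0], [0.5, 0.5]),
            ([1.0, 3.0], [0.25, 0.75]),
            ([0.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3]),  # zero-row convention
        ],
    )
    def test_examples(self, row, expected):
        out = row_normalize(np.array([row]))
        np.testing.assert_allclose(out[0], expected, atol=1e-15)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            row_normalize(np.array([[1.0, -0.5]]))


class TestGiniWeight:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 1.25),  # uniform: minimal specificity 1 + 1/K
            ([1.0, 0.0, 0.0, 0.0], 2.0),       # one-hot: maximal specificity
            ([0.5, 0.3, 0.2], 1.38),           # 1 + 0.25 + 0.09 + 0.04
        ],
    )
    def test_examples(self, row, expected):
        w = gini_weight(np.array([row]))
        assert w[0] == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(InputError):
            gini_weight(np.array([[0.5, 0.2]]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        raw=arrays(
            float,
            st.tuples(st.integers(1, 6), st.integers(2, 40)),
            elements=st.floats(0, 100, allow_nan=False),
        )
    )
    def test_weight_bounds_property(self, raw):
        """Every weight lies in [1 + 1/K, 2] for any row-stochastic P."""
        p = row_normalize(raw)
        w = gini_weight(p)
        k = raw.shape[1]
        assert np.all(w >= 1 + 1 / k - 1e-12)
        assert np.all(w <= 2 + 1e-12)


class TestClusterProfile:
    def test_median_and_mean(self, toy_expr, toy_clusters):
        prof = build_cluster_profile(toy_expr, toy_clusters, ["ta"])
        # cluster "0" values of ta: {9, 8, 10} -> median 9, mean 9
        assert prof.median_raw[0, 0] == 9.0
        assert prof.mean_expr[0, 0] == pytest.approx(9.0)

    def test_even_count_median_is_midpoint(self):
        expr = ExpressionMatrix(["g"], ["a", "b"], np.array([[1.0, 3.0]]))
        clusters = ClusterAssignment({"a": "x", "b": "x"})
        prof = build_cluster_profile(expr, clusters, ["g"])
        assert prof.median_raw[0, 0] == 2.0

    def test_absent_marker_dropped_with_warning(self, toy_expr, toy_clusters):
        with pytest.warns(UserWarning, match="absent"):
            prof = build_cluster_profile(toy_expr, toy_clusters, ["ta", "nope"])
        assert prof.marker_ids == ["ta"]
        assert prof.dropped_markers == ["nope"]

    def test_all_markers_absent_is_error(self, toy_expr, toy_clusters):
        with pytest.raises(InputError, match="nope"):
            build_cluster_profile(toy_expr, toy_clusters, ["nope"])


class TestCtaScore:
    def test_hand_example_single_marker(self):
        """N=1, mean (2,0), one-hot profile: raw = (4, 0), normalized (1, 0)."""
        expr = ExpressionMatrix(
            ["g"], ["a", "b", "c", "d"], np.array([[2.0, 2.0, 0.0, 0.0]])
        )
        clusters = ClusterAssignment({"a": "k1", "b": "k1", "c": "k2", "d": "k2"})
        vec = score_cell_type(expr, clusters, ["g"])
        np.testing.assert_allclose(vec.raw, [4.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(vec.normalized, [1.0, 0.0], atol=1e-15)

    def test_all_zero_scores_fall_back_to_uniform(self):
        expr = ExpressionMatrix(["g", "h"], ["a", "b"], np.array([[0.0, 0.0], [1.0, 1.0]]))
        clusters = ClusterAssignment({"a": "x", "b": "y"})
        prof = build_cluster_profile(expr, clusters, ["g"])
        with pytest.warns(UserWarning, match="uniform"):
            vec = cta_score(prof, gini_weight(prof.P))
        np.testing.assert_allclose(vec.normalized, [0.5, 0.5])

    def test_dimension_mismatch(self, toy_expr, toy_clusters):
        prof = build_cluster_profile(toy_expr, toy_clusters, ["ta", "tb"])
        with pytest.raises(InputError):
            cta_score(prof, np.array([1.5]))


class TestCtaMatrix:
    def test_planted_markers_give_argmax_on_own_cluster(
        self, toy_expr, toy_clusters, toy_catalog
    ):
        m = compute_cta_matrix(toy_expr, toy_clusters, toy_catalog)
        assert m.cell_types == ["A", "B"]
        assert np.argmax(m.row("A")) == 0
        assert np.argmax(m.row("B")) == 1
        np.testing.assert_allclose(m.scores.sum(axis=1), 1.0, atol=1e-9)

    def test_shared_marker_used_by_both_types(self, toy_expr, toy_clusters):
        from ctascore import MarkerCatalog

        cat = MarkerCatalog({"A": ["ta", "bg1"], "B": ["tb", "bg1"]})
        m = compute_cta_matrix(toy_expr, toy_clusters, cat)
        assert np.argmax(m.row("A")) == 0
        assert np.argmax(m.row("B")) == 1

    def test_type_with_no_found_marker_is_excluded(self, toy_expr, toy_clusters):
        from ctascore import MarkerCatalog

        cat = MarkerCatalog({"A": ["ta"], "ghost": ["nope"]})
        with pytest.warns(UserWarning, match="excluded"):
            m = compute_cta_matrix(toy_expr, toy_clusters, cat)
        assert m.cell_types == ["A"]
        assert m.excluded == ["ghost"]

    def test_scale_invariance(self, toy_expr, toy_clusters, toy_catalog):
        base = compute_cta_matrix(toy_expr, toy_clusters, toy_catalog)
        for c in (0.01, 100.0):
            scaled = ExpressionMatrix(
                toy_expr.gene_ids, toy_expr.cell_ids, toy_expr.values * c
            )
            m = compute_cta_matrix(scaled, toy_clusters, toy_catalog)
            np.testing.assert_allclose(m.scores, base.scores, atol=1e-9)

    def test_cluster_permutation_equivariance(self, toy_expr, toy_catalog):
        fwd = ClusterAssignment(
            {"c1": "0", "c2": "0", "c3": "0", "c4": "1", "c5": "1", "c6": "1"},
            ["0", "1"],
        )
        rev = ClusterAssignment(fwd.cell_to_cluster, ["1", "0"])
        m_fwd = compute_cta_matrix(toy_expr, fwd, toy_catalog)
        m_rev = compute_cta_matrix(toy_expr, rev, toy_catalog)
        np.testing.assert_allclose(m_fwd.scores, m_rev.scores[:, ::-1], atol=1e-15)

    def test_determinism(self, toy_expr, toy_clusters, toy_catalog):
        a = compute_cta_matrix(toy_expr, toy_clusters, toy_catalog)
        b = compute_cta_matrix(toy_expr, toy_clusters, toy_catalog)
        assert np.array_equal(a.scores, b.scores)


class TestOracleEquivalence:
    def test_matches_loop_oracle_on_random_instances(self):
        """Vectorized scores equal the literal loop implementation at 1e-12."""
        rng = np.random.default_rng(20260921)
        for _ in range(200):
            expr, clusters, markers, rows, cluster_of_cell, marker_rows = random_instance(rng)
            raw_o, norm_o = oracle_cta(rows, cluster_of_cell, marker_rows)
            vec = score_cell_type(expr, clusters, markers)
            np.testing.assert_allclose(vec.raw, raw_o, atol=1e-12, rtol=1e-12)
            np.testing.assert_allclose(vec.normalized, norm_o, atol=1e-12, rtol=1e-12)

    def test_denominator_constant_cancels(self, toy_expr, toy_clusters, toy_catalog):
        """Replacing N**3 by 1 leaves normalized scores unchanged."""
        from ctascore.core import build_cluster_profile as bcp

        m = compute_cta_matrix(toy_expr, toy_clusters, toy_catalog)
        for i, ct in enumerate(m.cell_types):
            prof = bcp(toy_expr, toy_clusters, toy_catalog.entries[ct])
            w = gini_weight(prof.P)
            raw_no_denom = (prof.mean_expr * w[:, None]).sum(axis=0)  # denominator 1
            np.testing.assert_allclose(
                raw_no_denom / raw_no_denom.sum(), m.scores[i], atol=1e-9
            )
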