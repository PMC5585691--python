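import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gutlink.io import CountTable, SampleMetadata, TaxonomyTable
from gutlink.timeseries import (
    InteractionMatrix,
    LogAbundanceSeries,
    _bh_offdiag,
    build_interaction_matrix,
    classify_interactions,
    classify_pair,
    fit_pair,
    permutation_null,
    taxonomic_contrast,
    to_log_relative,
)


def fecal_metadata(days):
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"F{d}" for d in days],
                "sample_type": "fecal",
                "day": days,
            }
        )
    )


class TestLogRelative:
    def test_known_fraction(self):
        table = CountTable(
            np.array([[10.0, 10.0], [990.0, 990.0]]), ["a", "b"], ["F1", "F2"]
        )
        series = to_log_relative(table, fecal_metadata([1, 2]), pseudocount=0.0)
        assert series.x[0, 0] == pytest.approx(np.log(0.01))

    def test_pseudocount_keeps_zeros_finite(self):
        table = CountTable(
            np.array([[0.0, 5.0], [100.0, 95.0]]), ["a", "b"], ["F1", "F2"]
        )
        series = to_log_relative(table, fecal_metadata([1, 2]), pseudocount=0.5)
        assert np.isfinite(series.x).all()

    def test_preserves_within_sample_ordering(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 500, size=(10, 3)).astype(float)
        table = CountTable(vals, [f"t{i}" for i in range(10)], ["F1", "F2", "F3"])
        series = to_log_relative(table, fecal_metadata([1, 2, 3]))
        for j in range(3):
            assert (np.argsort(series.x[:, j]) == np.argsort(vals[:, j])).all()

    def test_duplicate_days_rejected(self):
        table = CountTable(np.ones((2, 2)), ["a", "b"], ["F1", "F2"])
        with pytest.raises(ValueError, match="duplicate"):
            to_log_relative(table, fecal_metadata([3, 3]))

    def test_calendar_gap_drops_transition(self):
        x = np.zeros((1, 5))
        series = LogAbundanceSeries(["a"], [1, 2, 3, 7, 8], x, 0.5)
        assert series.transitions().tolist() == [0, 1, 3]


class TestFitPair:
    def test_recovers_constructed_linear_map(self):
        # Δx_i,t = 0.5 − 0.2·x_j,t exactly
        rng = np.random.default_rng(1)
        T = 40
        x_j = rng.normal(size=T)
        x_i = np.zeros(T)
        for t in range(T - 1):
            x_i[t + 1] = x_i[t] + 0.5 - 0.2 * x_j[t]
        alpha, beta, p = fit_pair(x_i, x_j)
        assert alpha == pytest.approx(0.5, abs=1e-10)
        assert beta == pytest.approx(-0.2, abs=1e-10)
        assert p < 1e-12

    def test_constant_predictor_degenerate(self):
        x_i = np.random.default_rng(0).normal(size=20)
        alpha, beta, p = fit_pair(x_i, np.full(20, 3.0))
        assert beta == 0.0 and p == 1.0

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x_i, x_j = rng.normal(size=(2, 30))
            alpha, beta, p = fit_pair(x_i, x_j)
            X = sm.add_constant(x_j[:-1])
            ref = sm.OLS(np.diff(x_i), X).fit()
            assert beta == pytest.approx(ref.params[1], abs=1e-10)
            assert p == pytest.approx(ref.pvalues[1], abs=1e-10)


class TestInteractionMatrix:
    def _series(self, n, T, seed=0):
        rng = np.random.default_rng(seed)
        return LogAbundanceSeries(
            [f"t{i}" for i in range(n)],
            np.arange(1, T + 1),
            rng.normal(size=(n, T)),
            0.5,
        )

    def test_two_taxa_two_offdiagonal_models(self):
        imat = build_interaction_matrix(self._series(2, 20))
        assert np.isnan(imat.p_bh).sum() == 2  # diagonal excluded
        assert len(imat.to_frame()) == 2

    def test_vectorized_fits_equal_per_pair_fits(self):
        series = self._series(5, 25, seed=3)
        imat = build_interaction_matrix(series)
        for i in range(5):
            for j in range(5):
                a, b, p = fit_pair(series.x[i], series.x[j])
                assert imat.beta[i, j] == pytest.approx(b, abs=1e-10)
                assert imat.p_raw[i, j] == pytest.approx(p, abs=1e-10)

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng = np.random.default_rng(4)
        n = 5
        p = rng.uniform(size=(n, n))
        adj = _bh_offdiag(p)
        off = ~np.eye(n, dtype=bool)
        flat = p[off]
        m = flat.size
        order = np.argsort(flat)
        stepped = flat[order] * m / (np.arange(m) + 1)
        expected = np.minimum.accumulate(stepped[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(expected, 1.0)
        np.testing.assert_allclose(adj[off], out, rtol=1e-12)

    def test_bh_hand_case_all_equal(self):
        # p = (0.01, 0.02, 0.03, 0.04), m = 4 → every adjusted value 0.04
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.04)

    def test_equivariant_under_taxon_relabeling(self):
        series = self._series(6, 30, seed=5)
        perm = np.array([3, 1, 5, 0, 2, 4])
        permuted = LogAbundanceSeries(
            [series.taxa_ids[k] for k in perm], series.days, series.x[perm], 0.5
        )
        a = build_interaction_matrix(series)
        b = build_interaction_matrix(permuted)
        np.testing.assert_allclose(b.beta, a.beta[np.ix_(perm, perm)], atol=1e-12)
        np.testing.assert_allclose(b.p_raw, a.p_raw[np.ix_(perm, perm)], atol=1e-12)

    def test_too_few_transitions_rejected(self):
        with pytest.raises(ValueError, match="transitions"):
            build_interaction_matrix(self._series(3, 5))


class TestClassifyPair:
    @pytest.mark.parametrize(
        "b1,s1,b2,s2,expected",
        [
            (-0.3, True, -0.1, True, "competition"),
            (0.2, True, 0.0, False, "commensalism"),
            (0.2, True, -0.2, True, "parasitism"),
            (0.2, True, 0.3, True, "cooperation"),
            (-0.2, True, 0.1, False, "amensalism"),
            (0.5, False, -0.5, False, "none"),
        ],
    )
    def test_sign_pattern_mapping(self, b1, s1, b2, s2, expected):
        assert classify_pair(b1, s1, b2, s2) == expected
        assert classify_pair(b2, s2, b1, s1) == expected  # order-invariant

    def test_classification_table_covers_all_pairs(self):
        rng = np.random.default_rng(6)
        series = LogAbundanceSeries(
            ["a", "b", "c"], np.arange(1, 31), rng.normal(size=(3, 30)), 0.5
        )
        cats = classify_interactions(build_interaction_matrix(series))
        assert len(cats) == 3


class TestPermutationNull:
    def test_fixed_seed_reproduces_output(self):
        rng = np.random.default_rng(7)
        series = LogAbundanceSeries(
            [f"t{i}" for i in range(4)], np.arange(1, 41),
            rng.normal(size=(4, 40)), 0.5,
        )
        a = permutation_null(series, n_perm=5, seed=123)
        b = permutation_null(series, n_perm=5, seed=123)
        np.testing.assert_array_equal(a["pooled_p_raw"], b["pooled_p_raw"])
        np.testing.assert_array_equal(
            a["significant_per_replicate"], b["significant_per_replicate"]
        )


class TestTaxonomicContrast:
    def _matrix_with(self, beta_within, beta_between):
        # 4 taxa: first two share a phylum, last two are each their own
        n = 4
        beta = np.zeros((n, n))
        p_bh = np.ones((n, n))
        within = [(0, 1), (1, 0)]
        between = [(0, 2), (2, 0), (1, 3), (3, 1), (2, 3), (3, 2)]
        for k, (i, j) in enumerate(within):
            beta[i, j] = beta_within[k % len(beta_within)]
            p_bh[i, j] = 1e-6
        for k, (i, j) in enumerate(between):
            beta[i, j] = beta_between[k % len(beta_between)]
            p_bh[i, j] = 1e-6
        np.fill_diagonal(p_bh, np.nan)
        return InteractionMatrix(
            ["a", "b", "c", "d"], np.zeros((n, n)), beta, p_bh.copy(), p_bh
        )

    def _taxonomy(self):
        return TaxonomyTable(
            pd.DataFrame(
                {
                    "otu_id": ["a", "b", "c", "d"],
                    "phylum": ["P1", "P1", "P2", "P3"],
                }
            )
        )

    def test_constructed_within_more_negative(self):
        imat = self._matrix_with([-0.2], [0.1])
        res = taxonomic_contrast(imat, self._taxonomy(), "phylum")
        assert res["mean_within"] == pytest.approx(-0.2)
        assert res["mean_between"] == pytest.approx(0.1)
        assert res["p_one_sided"] < 0.05

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        imat = self._matrix_with(
            [-0.31, -0.17], [0.12, 0.05, -0.02, 0.21, -0.25, 0.08]
        )
        res = taxonomic_contrast(imat, self._taxonomy(), "phylum")
        within = [imat.beta[0, 1], imat.beta[1, 0]]
        between = [imat.beta[i, j] for i, j in
                   [(0, 2), (2, 0), (1, 3), (3, 1), (2, 3), (3, 2)]]
        pooled = np.array(within + between)
        nw = len(within)
        # scipy's U counts (within > between) pairs; 'less' is P(U ≤ U_obs)
        u_obs = sum(
            (a > b) + 0.5 * (a == b) for a in within for b in between
        )
        count = 0
        combos = list(itertools.combinations(range(len(pooled)), nw))
        for combo in combos:
            w = pooled[list(combo)]
            b = pooled[[k for k in range(len(pooled)) if k not in combo]]
            u = sum((x > y) + 0.5 * (x == y) for x in w for y in b)
            count += u <= u_obs
        # one-sided exact p: P(U ≤ U_obs) under random assignment
        assert res["p_one_sided"] == pytest.approx(count / len(combos), abs=1e-9)

    def test_empty_partition_errors(self):
        imat = self._matrix_with([-0.2], [0.1])
        imat.p_bh[0, 1] = imat.p_bh[1, 0] = 1.0  # no significant within-pairs
        with pytest.raises(ValueError, match="partition"):
            taxonomic_contrast(imat, self._taxonomy(), "phylum")
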