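"""Expression analysis: TPM, filtering, transform, clustering, ANOVA, Fisher."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster import hierarchy

from mycofly import (
    annotation_percentage,
    anova_pooled,
    filter_min_expression,
    fisher_enrichment,
    hcluster_complete,
    log_center,
    order_samples_by_titer,
    tpm_from_counts,
)


class TestTpm:
    def test_length_normalization_ratio(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["short", "long"])
        lengths = pd.Series({"short": 100, "long": 200})
        tpm = tpm_from_counts(counts, lengths)
        assert tpm.loc["short", "s"] / tpm.loc["long", "s"] == pytest.approx(2.0)

    def test_single_transcript_gets_everything(self):
        tpm = tpm_from_counts(pd.DataFrame({"s": [7]}, index=["t"]),
                              pd.Series({"t": 500}))
        assert tpm.loc["t", "s"] == pytest.approx(1e6)

    def test_columns_sum_to_a_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 5)))
        lengths = pd.Series(rng.integers(200, 2000, size=20), index=counts.index)
        tpm = tpm_from_counts(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-6)

    def test_all_zero_sample_stays_zero(self):
        counts = pd.DataFrame({"empty": [0, 0], "full": [5, 5]})
        tpm = tpm_from_counts(counts, pd.Series([100, 100], index=counts.index))
        assert (tpm["empty"] == 0).all()
        assert tpm["full"].sum() == pytest.approx(1e6)


class TestExpressionFilter:
    def test_inclusive_boundaries(self):
        matrix = pd.DataFrame(
            {"a": [10.0, 9.9], "b": [10.0, 9.9], "c": [10.0, 9.9], "d": [0.0, 9.9]},
            index=["at_threshold", "below"],
        )
        kept = filter_min_expression(matrix, min_tpm=10, min_samples=3)
        assert list(kept.index) == ["at_threshold"]

    def test_zero_thresholds_are_identity(self, rng):
        matrix = pd.DataFrame(rng.uniform(0, 5, size=(10, 4)))
        pd.testing.assert_frame_equal(filter_min_expression(matrix, 0, 0), matrix)

    def test_raising_min_tpm_is_monotone(self, rng):
        matrix = pd.DataFrame(rng.uniform(0, 20, size=(50, 6)))
        sizes = [len(filter_min_expression(matrix, t, 3)) for t in (0, 5, 10, 15)]
        assert sizes == sorted(sizes, reverse=True)


class TestLogCenter:
    def test_constant_row_centers_to_zero(self):
        out = log_center(pd.DataFrame([[4.0, 4.0, 4.0]]), pseudocount=0)
        assert np.allclose(out, 0.0)

    def test_hand_arithmetic(self):
        # log2(1+1)=1, log2(3+1)=2, mean 1.5
        out = log_center(pd.DataFrame([[1.0, 3.0]]), pseudocount=1)
        assert np.allclose(out.to_numpy(), [[-0.5, 0.5]])

    def test_row_means_are_zero(self, rng):
        matrix = pd.DataFrame(rng.uniform(0, 100, size=(30, 8)))
        out = log_center(matrix)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-9)

    def test_zero_pseudocount_with_zeros_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log_center(pd.DataFrame([[0.0, 1.0]]), pseudocount=0)


def brute_force_complete_linkage(values: np.ndarray):
    """Naive O(n^3) oracle: track member sets, inter-cluster max pairwise dist."""
    n = len(values)
    point_d = np.sqrt(((values[:, None, :] - values[None, :, :]) ** 2).sum(-1))
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(point_d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or (d, a, b) < best:
                best = (d, a, b)
        d, a, b = best
        clusters[n + step] = clusters.pop(a) | clusters.pop(b)
        merges.append((a, b, d))
    return merges


class TestCompleteLinkage:
    def test_identical_rows_merge_first_at_height_zero(self):
        matrix = pd.DataFrame([[1.0, 2.0], [5.0, 9.0], [1.0, 2.0], [7.0, 0.0]])
        result = hcluster_complete(matrix)
        a, b, h = result.merges[0]
        assert {a, b} == {0, 2} and h == 0.0

    def test_one_dimensional_example(self):
        result = hcluster_complete(pd.DataFrame({"x": [0.0, 1.0, 5.0, 6.0]}))
        assert result.merges[0] == (0, 1, 1.0)
        assert result.merges[1] == (2, 3, 1.0)
        assert result.merges[2][2] == 6.0  # complete linkage: max(|0-5|,|0-6|,|1-5|,|1-6|)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            matrix = pd.DataFrame(rng.normal(size=(9, 4)))
            mine = hcluster_complete(matrix).merges
            oracle = brute_force_complete_linkage(matrix.to_numpy())
            for (a1, b1, h1), (a2, b2, h2) in zip(mine, oracle):
                assert (a1, b1) == (a2, b2)
                assert h1 == pytest.approx(h2)

    def test_matches_scipy_heights_and_cuts(self, rng):
        from sklearn.metrics import adjusted_rand_score

        matrix = pd.DataFrame(rng.normal(size=(15, 5)))
        result = hcluster_complete(matrix)
        Z = hierarchy.linkage(matrix.to_numpy(), method="complete")
        assert np.allclose(sorted(h for *_, h in result.merges), sorted(Z[:, 2]))
        for k in (2, 3, 5):
            flat = hierarchy.fcluster(Z, k, criterion="maxclust")
            assert adjusted_rand_score(result.cut(k), flat) == 1.0

    def test_heights_monotone_nondecreasing(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(12, 3)))
        heights = [h for *_, h in hcluster_complete(matrix).merges]
        assert heights == sorted(heights)

    def test_pearson_centered_distance_mode(self):
        # rows 0 and 1 perfectly correlated -> distance 0, merge first
        matrix = pd.DataFrame([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [3.0, 1.0, 2.0]])
        result = hcluster_complete(matrix, distance="pearson_centered")
        a, b, h = result.merges[0]
        assert {a, b} == {0, 1} and h == pytest.approx(0.0, abs=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hcluster_complete(pd.DataFrame([[1.0, 2.0]]))


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
                              columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        de = anova_pooled(matrix, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert de["F"].iloc[0] == 0.0
        assert de["p"].iloc[0] == 1.0

    def test_f_equals_t_squared(self, rng):
        a_cols = [f"a{i}" for i in range(6)]
        b_cols = [f"b{i}" for i in range(8)]
        matrix = pd.DataFrame(
            np.c_[rng.normal(0, 1, size=(20, 6)), rng.normal(0.8, 1, size=(20, 8))],
            columns=a_cols + b_cols,
        )
        de = anova_pooled(matrix, a_cols, b_cols)
        t, p = stats.ttest_ind(matrix[a_cols], matrix[b_cols], axis=1)
        assert np.allclose(de["F"], t ** 2)
        assert np.allclose(de["p"], p)

    def test_null_type_one_error_near_nominal(self, rng):
        sigma = np.sqrt(np.log(1 + 0.2 ** 2))
        values = 100 * rng.lognormal(-sigma ** 2 / 2, sigma, size=(5000, 24))
        cols = [f"s{i}" for i in range(24)]
        matrix = pd.DataFrame(values, columns=cols)
        de = anova_pooled(matrix, cols[:12], cols[12:])
        rate = (de["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 5000)
        assert abs(rate - 0.05) < 3 * se

    def test_small_group_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a1", "b1", "b2"])
        with pytest.raises(ValueError, match="at least 2"):
            anova_pooled(matrix, ["a1"], ["b1", "b2"])

    def test_significance_flag_matches_threshold(self, rng):
        cols = [f"s{i}" for i in range(8)]
        matrix = pd.DataFrame(rng.normal(size=(50, 8)), columns=cols)
        de = anova_pooled(matrix, cols[:4], cols[4:], p_threshold=0.5)
        assert (de["significant"] == (de["p"] < 0.5)).all()


def hypergeometric_two_sided(a, b, c, d):
    """Exhaustive enumeration oracle for the two-sided Fisher exact p."""
    from math import comb

    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)
    probs = {}
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        probs[x] = comb(row1, x) * comb(row2, col1 - x) / denom
    observed = probs[a]
    return sum(p for p in probs.values() if p <= observed * (1 + 1e-12))


class TestFisher:
    def _run(self, a, b, c, d):
        study = {f"s{i}" for i in range(a + b)}
        rest = {f"r{i}" for i in range(c + d)}
        term = set(list(study)[:a] + list(rest)[:c])
        return fisher_enrichment(study, study | rest, {"T": term})

    def test_balanced_table_no_association(self):
        row = self._run(5, 5, 5, 5).iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_enumeration_oracle_on_diagonal_table(self):
        row = self._run(3, 0, 0, 3).iloc[0]
        assert row["p"] == pytest.approx(0.1)  # 2/20 of the 6-choose-3 support
        assert row["p"] == pytest.approx(hypergeometric_two_sided(3, 0, 0, 3))

    def test_bh_adjustment_never_below_raw(self, rng):
        genes = {f"g{i}" for i in range(40)}
        study = set(list(genes)[:12])
        annotation = {
            f"T{j}": set(rng.choice(sorted(genes), size=10, replace=False))
            for j in range(8)
        }
        result = fisher_enrichment(study, genes, annotation)
        assert (result["p_adjusted"] >= result["p"] - 1e-12).all()

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(set(), {"g"}, {"T": {"g"}})


class TestSampleOrdering:
    def _meta(self, titers, ids=None):
        ids = ids or [f"s{i}" for i in range(len(titers))]
        return pd.DataFrame({"sample_id": ids, "titer_fraction": titers})

    def test_ascending_by_titer(self):
        assert order_samples_by_titer(self._meta([0.5, 0.1, 0.9])) == [1, 0, 2]

    def test_equal_titers_preserve_id_order(self):
        assert order_samples_by_titer(self._meta([0.3, 0.3, 0.3])) == [0, 1, 2]

    def test_permutation_inverts_to_identity(self, rng):
        meta = self._meta(list(rng.uniform(size=8)))
        perm = order_samples_by_titer(meta)
        inverse = np.argsort(perm)
        assert list(np.array(perm)[inverse]) == list(range(8))

    def test_missing_titer_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            order_samples_by_titer(self._meta([0.1, np.nan]))


@pytest.mark.parametrize(
    "num,den,expected",
    [(1545, 3678, 42.0), (135, 508, 26.6), (44, 407, 10.8), (1419, 3500, 40.5)],
)
def test_annotation_percentage_printed_precision(num, den, expected):
    assert annotation_percentage(num, den) == expected
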