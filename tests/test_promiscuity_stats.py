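"""Correlation, KS, regression and drug-centric summary statistics."""

import numpy as np
import pandas as pd
import pytest
from oracles import permutation_pvalue_counts
from scipy import stats as sps

from ligandrmsd.promiscuity_stats import (
    build_table,
    correlate,
    ks_compare,
    regress_combined,
    summarize_drugs,
)


def _descriptors(drugs):
    return pd.DataFrame(
        {
            "mw": np.linspace(100, 500, len(drugs)),
            "logp": np.linspace(-2, 5, len(drugs)),
            "rotatable_abs": np.arange(len(drugs)),
            "rotatable_rel": np.linspace(0, 0.8, len(drugs)),
        },
        index=pd.Index(drugs, name="drug"),
    )


class TestBuildTable:
    def test_full_similarity_pair_count(self):
        drugs = ["AAA"]
        df = build_table(
            degrees={"AAA": 4},
            similar_pair_counts={"AAA": 6},
            conformer_counts={"AAA": 1},
            descriptors=_descriptors(drugs),
        )
        assert df.iloc[0]["similar_pair_count"] == 6  # 4*3/2

    def test_low_degree_drugs_excluded(self):
        df = build_table(
            degrees={"AAA": 2, "BBB": 3},
            similar_pair_counts={},
            conformer_counts={},
            descriptors=_descriptors(["AAA", "BBB"]),
        )
        assert list(df["drug"]) == ["BBB"]

    def test_missing_logp_kept_as_nan(self):
        desc = _descriptors(["AAA"]).drop(columns=["logp"])
        df = build_table(
            degrees={"AAA": 3},
            similar_pair_counts={"AAA": 1},
            conformer_counts={"AAA": 2},
            descriptors=desc,
        )
        assert np.isnan(df.iloc[0]["logp"])
        assert df.iloc[0]["target_count"] == 3

    def test_orphan_identifiers_error(self):
        with pytest.raises(ValueError, match="ZZZ"):
            build_table(
                degrees={"AAA": 3},
                similar_pair_counts={"ZZZ": 1},
                conformer_counts={},
                descriptors=_descriptors(["AAA"]),
            )

    def test_impossible_pair_count_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_table(
                degrees={"AAA": 3},
                similar_pair_counts={"AAA": 4},
                conformer_counts={},
                descriptors=_descriptors(["AAA"]),
            )


class TestCorrelate:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        rep = correlate(x, 2 * x + 1)
        assert rep.r == pytest.approx(1.0)
        assert rep.p_value < 1e-12

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert correlate(x, y).r == pytest.approx(correlate(y, x).r, abs=1e-12)
        assert correlate(3 * x + 7, y).r == pytest.approx(correlate(x, y).r, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate(np.ones(10), np.arange(10.0))

    def test_sqrt_transform_applied(self, rng):
        x = rng.normal(size=30) + 5
        y = (2 * x + rng.normal(size=30)) ** 2
        assert correlate(x, y, "sqrt").r > correlate(x, y).r

    def test_sqrt_of_full_pair_count_increases_with_degree(self):
        n = np.arange(3, 20)
        s = np.sqrt(n * (n - 1) / 2)
        assert np.all(np.diff(s) > 0)

    def test_pvalue_matches_permutation_oracle(self, rng):
        """Two-sided t p-value inside the exact binomial CI of a permutation test."""
        cov = [[1.0, 0.5], [0.5, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=100)
        rep = correlate(xy[:, 0], xy[:, 1])
        k, n_perm = permutation_pvalue_counts(xy[:, 0], xy[:, 1], n_perm=20000, seed=5)
        lo, hi = sps.binomtest(k, n_perm).proportion_ci(0.999)
        assert lo <= rep.p_value <= hi or abs(rep.p_value - k / n_perm) < 5e-3


class TestKSCompare:
    def test_identical_samples_d_zero(self):
        a = np.arange(10.0)
        cmp = ks_compare(a, a)
        assert cmp.statistic == 0.0

    def test_disjoint_supports_d_one(self):
        cmp = ks_compare([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert cmp.statistic == 1.0

    def test_d_equals_ecdf_scan(self, rng):
        a, b = rng.normal(size=40), rng.normal(loc=0.6, size=55)
        cmp = ks_compare(a, b)
        pts = np.concatenate([a, b])
        d_brute = max(
            abs(np.mean(a <= t) - np.mean(b <= t)) for t in pts
        )
        assert cmp.statistic == pytest.approx(d_brute, abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestRegression:
    def test_exact_linear_response(self):
        drugs = [f"D{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        desc = pd.DataFrame(
            {
                "mw": rng.uniform(100, 500, 12),
                "logp": rng.normal(1, 2, 12),
                "rotatable_abs": rng.normal(size=12),
                "rotatable_rel": rng.uniform(0, 1, 12),
                "conformer_cluster_count": rng.integers(1, 6, size=12),
            },
            index=pd.Index(drugs, name="drug"),
        )
        y = (
            2.0 * desc["logp"] + 0.01 * desc["mw"]
            + 0.5 * desc["conformer_cluster_count"]
            + 1.0 * desc["rotatable_rel"] + 0.3 * desc["rotatable_abs"] + 4.0
        )
        table = desc.copy()
        table["target_count"] = y
        rep = regress_combined(table)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-9)
        assert rep.coefficients["logp"] == pytest.approx(2.0, abs=1e-6)

    def test_independent_response_low_r2(self):
        rng = np.random.default_rng(1)
        drugs = [f"D{i}" for i in range(200)]
        table = pd.DataFrame(
            {
                "logp": rng.normal(size=200),
                "mw": rng.normal(size=200),
                "conformer_cluster_count": rng.integers(1, 5, 200),
                "rotatable_rel": rng.uniform(0, 1, 200),
                "rotatable_abs": rng.integers(0, 9, 200),
                "target_count": rng.normal(size=200),
            },
            index=drugs,
        )
        rep = regress_combined(table)
        assert rep.r_squared < 0.1
        # closed-form OLS on the same data agrees
        X = np.column_stack(
            [np.ones(200)] + [table[c] for c in
             ("logp", "mw", "conformer_cluster_count", "rotatable_rel", "rotatable_abs")]
        )
        beta = np.linalg.lstsq(X, table["target_count"], rcond=None)[0]
        assert rep.coefficients["logp"] == pytest.approx(beta[1], abs=1e-8)

    def test_too_few_rows_errors(self):
        table = pd.DataFrame(
            {
                "logp": [1.0, 2.0, 3.0],
                "mw": [1.0, 2.0, 1.0],
                "conformer_cluster_count": [1, 2, 3],
                "rotatable_rel": [0.1, 0.2, 0.3],
                "rotatable_abs": [1, 2, 3],
                "target_count": [3, 4, 5],
            }
        )
        with pytest.raises(ValueError, match="at least"):
            regress_combined(table)

    def test_collinear_design_named(self):
        rng = np.random.default_rng(2)
        n = 30
        table = pd.DataFrame(
            {
                "logp": rng.normal(size=n),
                "mw": rng.normal(size=n),
                "conformer_cluster_count": rng.integers(1, 5, n),
                "rotatable_rel": rng.uniform(0, 1, n),
                "target_count": rng.normal(size=n),
            }
        )
        table["rotatable_abs"] = 2.0 * table["rotatable_rel"]  # exactly collinear
        with pytest.raises(ValueError, match="rotatable"):
            regress_combined(table)


class TestSummarize:
    def _table(self, similar):
        n = len(similar)
        degrees = [4] * n
        return pd.DataFrame(
            {
                "drug": [f"D{i}" for i in range(n)],
                "target_count": degrees,
                "similar_pair_count": similar,
            }
        )

    def test_all_pairs_similar_everywhere(self):
        s = summarize_drugs(self._table([6, 6, 6]))
        assert s["fraction_with_similar_pair"] == 1.0
        assert s["fraction_all_pairs_similar"] == 1.0

    def test_no_similar_pairs(self):
        s = summarize_drugs(self._table([0, 0]))
        assert s["fraction_with_similar_pair"] == 0.0
        assert s["fraction_all_pairs_similar"] == 0.0

    def test_planted_fraction(self):
        similar = [1] * 71 + [0] * 29
        s = summarize_drugs(self._table(similar))
        assert s["fraction_with_similar_pair"] == pytest.approx(0.71)

    def test_histogram_open_last_bin(self):
        table = self._table([0, 0, 0])
        table["target_count"] = [3, 9, 25]
        s = summarize_drugs(table, histogram_max=10)
        assert s["target_count_histogram"]["3"] == 1
        assert s["target_count_histogram"][">=10"] == 1
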