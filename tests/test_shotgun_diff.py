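"""IP-MS differential enrichment: imputation, roll-up, iBAQ, moderated test, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceprm.shotgun_diff import (
    adjust_multiplicity,
    differential_enrichment,
    enrichment_filter,
    fit_scaled_f,
    ibaq,
    knn_impute,
    moderated_test,
    rollup_protein,
)


def _design(n=5):
    cols = [f"ctl{i}" for i in range(n)] + [f"case{i}" for i in range(n)]
    return cols, pd.Series(["ctl"] * n + ["case"] * n, index=cols)


class TestKnnImpute:
    def test_complete_matrix_returned_unchanged(self):
        df = pd.DataFrame(np.full((3, 4), 8.0))
        out = knn_impute(df, k=2)
        assert np.allclose(out, df)

    def test_duplicate_row_donates_its_value_at_k1(self):
        df = pd.DataFrame(
            [[4.0, 8.0, 16.0], [4.0, 8.0, np.nan], [1024.0, 2048.0, 4096.0]],
            columns=list("abc"),
        )
        out = knn_impute(df, k=1)
        assert out.iloc[1, 2] == pytest.approx(16.0)

    def test_k_clipped_with_warning_gives_all_row_rule(self):
        # rows equidistant from the incomplete row: clipped-k weighted mean
        # over all donors reduces to the plain mean of their log2 values
        df = pd.DataFrame(
            [[2.0, 4.0], [8.0, 16.0], [4.0, np.nan]], columns=list("ab")
        )
        with pytest.warns(UserWarning, match="clipped"):
            out = knn_impute(df, k=10)
        assert out.iloc[2, 1] == pytest.approx(8.0)  # 2**((log2 4 + log2 16)/2)

    def test_fully_missing_row_dropped_with_warning(self):
        df = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan], [2.0, np.nan]])
        with pytest.warns(UserWarning, match="fully missing"):
            out = knn_impute(df, k=1)
        assert len(out) == 2

    def test_observed_entries_untouched(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(10, 1, (20, 6))
        mask = rng.random((20, 6)) < 0.2
        df = pd.DataFrame(np.where(mask, np.nan, x))
        df.iloc[0] = x[0]  # keep one complete row
        out = knn_impute(df, k=3)
        observed = ~df.isna()
        assert np.allclose(out.to_numpy()[observed], df.to_numpy()[observed])


class TestRollupAndIbaq:
    def _matrix(self):
        idx = pd.MultiIndex.from_tuples(
            [("P1", "a"), ("P1", "b"), ("P2", "c")], names=["protein", "peptide"]
        )
        return pd.DataFrame([[10.0, 1.0], [20.0, 2.0], [5.0, 5.0]], index=idx,
                            columns=["s1", "s2"])

    def test_rollup_sums_peptides_per_protein(self):
        out = rollup_protein(self._matrix())
        assert out.loc["P1", "s1"] == 30.0
        assert out.loc["P2", "s1"] == 5.0

    def test_rollup_invariant_to_peptide_order(self):
        mat = self._matrix()
        shuffled = mat.iloc[[2, 0, 1]]
        assert rollup_protein(mat).equals(rollup_protein(shuffled))

    def test_ibaq_divides_by_observable_count(self):
        prot = pd.DataFrame({"s1": [3000.0, 3000.0]}, index=["P1", "P2"])
        out = ibaq(prot, {"P1": 10, "P2": 5})
        assert out.loc["P1", "s1"] == 300.0
        assert out.loc["P1", "s1"] * 2 == out.loc["P2", "s1"]

    def test_ibaq_excludes_zero_count_with_warning(self):
        prot = pd.DataFrame({"s1": [100.0, 50.0]}, index=["P1", "P2"])
        with pytest.warns(UserWarning, match="without observable"):
            out = ibaq(prot, {"P1": 1, "P2": 0})
        assert list(out.index) == ["P1"]


class TestModeratedTest:
    def test_zero_prior_df_recovers_ordinary_t_test(self):
        rng = np.random.default_rng(7)
        cols, design = _design()
        mat = pd.DataFrame(rng.normal(10, 1, (50, 10)), columns=cols)
        res = moderated_test(mat, design, "case", "ctl", prior_df=0)
        t_ref, p_ref = stats.ttest_ind(
            mat[cols[5:]], mat[cols[:5]], axis=1, equal_var=True
        )
        assert np.allclose(res["t"], t_ref, atol=1e-10)
        assert np.allclose(res["p"], p_ref, atol=1e-10)

    def test_homogeneous_variances_collapse_onto_common_prior(self):
        # identical within-group variance for every protein: the moment fit
        # detects no excess dispersion (infinite prior df) and every posterior
        # variance collapses onto the single common prior value, which is the
        # common s2 times the scaled-F estimator's chi-square bias correction
        # exp(log(d/2) - digamma(d/2))
        from scipy.special import digamma

        cols, design = _design(3)
        base = np.array([1.0, 2.0, 4.0] * 2, dtype=float)
        mat = pd.DataFrame(np.add.outer(np.arange(8.0), base), columns=cols)
        res = moderated_test(mat, design, "case", "ctl")
        assert np.isinf(res["df_prior"].iloc[0])
        assert res["s2_post"].nunique() == 1
        common_s2 = res["s2"].iloc[0]
        expected = common_s2 * np.exp(np.log(2.0) - digamma(2.0))  # d = 4
        assert res["s2_post"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_matches_limma_reference_values(self):
        """Cross-check against R/Bioconductor limma 3.58.1 (eBayes on the
        identical fixture; values computed once and frozen)."""
        rng = np.random.default_rng(42)
        mat = rng.normal(8, 1, (12, 10)) * np.repeat([0.5, 1.0, 2.0, 0.8], 3)[:, None]
        mat[:4, 5:] += 1.5
        cols = [f"s{i}" for i in range(10)]
        design = pd.Series(["ctl"] * 5 + ["case"] * 5, index=cols)
        res = moderated_test(pd.DataFrame(mat, columns=cols), design, "case", "ctl")
        assert res["df_prior"].iloc[0] == pytest.approx(3.03211931632, abs=1e-8)
        limma_t = [
            4.07366005827695, 4.14296339536135, 6.41392307176431, 2.1383441597809,
            0.682131459522768, 0.743458665123171, 0.53054088949046, 1.81446129491178,
            2.08989511910218, -1.05465030372253, -0.973845987303235, 0.951827377907827,
        ]
        limma_p = [
            0.00182905057064862, 0.00162579841236345, 4.91748662192601e-05,
            0.0556949162485663, 0.509224208043678, 0.472740548147053,
            0.606251484986447, 0.0968659799725381, 0.0605793709584651,
            0.314135346381118, 0.351002595420959, 0.361572871977767,
        ]
        assert np.allclose(res["t"], limma_t, atol=1e-8)
        assert np.allclose(res["p"], limma_p, atol=1e-8)

    def test_invariance_to_replicate_relabelling_and_global_scale(self):
        rng = np.random.default_rng(3)
        cols, design = _design()
        mat = pd.DataFrame(rng.lognormal(8, 1, (30, 10)), columns=cols)
        logmat = np.log2(mat)
        res = moderated_test(logmat, design, "case", "ctl")
        permuted = logmat.copy()
        permuted.columns = cols[4::-1] + cols[9:4:-1]  # relabel within groups
        res_perm = moderated_test(permuted, design, "case", "ctl")
        assert np.allclose(res["p"], res_perm["p"], atol=1e-12)
        res_scaled = moderated_test(np.log2(mat * 1000.0), design, "case", "ctl")
        assert np.allclose(res["p"], res_scaled["p"], atol=1e-8)

    def test_too_few_replicates_rejected(self):
        cols = ["a", "b", "c"]
        design = pd.Series(["ctl", "ctl", "case"], index=cols)
        mat = pd.DataFrame(np.ones((3, 3)), columns=cols)
        from spliceprm.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            moderated_test(mat, design, "case", "ctl")


def _bh_bruteforce(p):
    """Step-up definition: q_(i) = min_{j>=i} min(1, n*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum(1.0, p[order] * n / np.arange(1, n + 1))
    for i in range(n - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


class TestMultiplicity:
    def test_bh_hand_example(self):
        q = adjust_multiplicity([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_multiplicity([0.2], "bh")[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(adjust_multiplicity([1.0, 1.0, 1.0], "bh"), 1.0)

    def test_bh_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for n in (2, 3, 5, 8, 20):
            p = rng.random(n)
            assert np.allclose(adjust_multiplicity(p, "bh"), _bh_bruteforce(p), atol=1e-12)

    def test_bky_is_no_less_powerful_than_bh(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 1e-3, 10), rng.random(90)])
        q_bh = adjust_multiplicity(p, "bh")
        q_bky = adjust_multiplicity(p, "bky")
        assert (q_bky <= q_bh + 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_multiplicity([0.5, 1.5], "bh")


class TestEnrichmentFilter:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["log2_fc", "q"],
                            index=[f"P{i}" for i in range(len(rows))])

    def test_passing_protein_included(self):
        res = self._results([[np.log2(3.0), 0.01]])
        assert list(enrichment_filter(res).index) == ["P0"]

    def test_fold_change_exactly_two_excluded(self):
        res = self._results([[1.0, 0.001]])  # linear FC exactly 2.0
        assert enrichment_filter(res).empty

    def test_relaxing_thresholds_never_shrinks_the_set(self):
        rng = np.random.default_rng(2)
        res = self._results(
            np.column_stack([rng.normal(0.8, 0.8, 50), rng.random(50) * 0.2])
        )
        strict = set(enrichment_filter(res, 2.0, 0.05).index)
        relaxed_fc = set(enrichment_filter(res, 1.5, 0.05).index)
        relaxed_q = set(enrichment_filter(res, 2.0, 0.10).index)
        assert strict <= relaxed_fc
        assert strict <= relaxed_q

    def test_sorted_by_q_then_fold_change(self):
        res = self._results([[2.0, 0.02], [3.0, 0.01], [4.0, 0.01]])
        assert list(enrichment_filter(res).index) == ["P2", "P1", "P0"]
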