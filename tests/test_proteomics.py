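"""LFQ filtering, mixed imputation, permutation t-test and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import sleepomics as so
from oracles import fisher_two_sided_p, t_s0_oracle


def make_matrix(values, groups, proteins=None):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    return so.LFQMatrix(
        values=pd.DataFrame(values, index=proteins, columns=samples),
        design=pd.Series(groups, index=samples),
    )


class TestSampleQc:
    def test_low_count_sample_dropped(self, rng):
        # detected counts 90, 88, 91, 40 -> median 89, cutoff 44.5
        vals = np.full((100, 4), 20.0)
        for j, keep in enumerate([90, 88, 91, 40]):
            vals[keep:, j] = np.nan
        m = make_matrix(vals, ["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="s3"):
            out = so.filter_sample_qc(m)
        assert list(out.values.columns) == ["s0", "s1", "s2"]
        assert out.meta["dropped_samples"] == ["s3"]

    def test_equal_counts_drop_nothing(self):
        m = make_matrix(np.ones((10, 4)), ["a", "a", "b", "b"])
        out = so.filter_sample_qc(m)
        assert out.n_samples == 4

    def test_median_about_90_reproduces_45_protein_cutoff(self):
        # when the median detected count is ~90, the 50% rule is a 45-protein
        # per-sample threshold
        counts = [90, 90, 92, 46, 44]
        vals = np.full((120, 5), 20.0)
        for j, c in enumerate(counts):
            vals[c:, j] = np.nan
        m = make_matrix(vals, ["a", "a", "a", "b", "b"])
        with pytest.warns(UserWarning):
            out = so.filter_sample_qc(m)
        assert out.meta["qc_cutoff_proteins"] == 45.0
        assert out.meta["dropped_samples"] == ["s4"]

    def test_all_dropped_is_error(self):
        vals = np.full((4, 2), np.nan)
        vals[0, 0] = 20.0
        vals[:3, 1] = 20.0
        m = make_matrix(vals, ["a", "b"])
        # cutoff is median(1,3)/2 = 1 -> nothing dropped; force via fraction 4
        with pytest.raises(ValueError, match="every sample"):
            so.filter_sample_qc(m, min_fraction_of_median=4.0)


class TestGroupCompleteness:
    def test_five_of_six_in_one_group_kept_at_70pct(self):
        vals = np.full((1, 12), 20.0)
        vals[0, 5] = np.nan  # 5/6 in group a
        vals[0, 6:] = np.nan  # 0/6 in group b
        m = make_matrix(vals, ["a"] * 6 + ["b"] * 6)
        out = so.filter_group_completeness(m, 0.7)
        assert out.n_proteins == 1

    def test_four_of_six_in_both_groups_dropped_at_90pct(self):
        vals = np.full((1, 12), 20.0)
        vals[0, [4, 5, 10, 11]] = np.nan
        m = make_matrix(vals, ["a"] * 6 + ["b"] * 6)
        with pytest.warns(UserWarning, match="every protein"):
            out = so.filter_group_completeness(m, 0.9)
        assert out.n_proteins == 0

    def test_random_masks_match_bruteforce_oracle(self, rng):
        import math

        for _ in range(50):
            mask = rng.random((30, 8)) < 0.6
            vals = np.where(mask, 20.0, np.nan)
            groups = ["a"] * 4 + ["b"] * 4
            m = make_matrix(vals, groups)
            frac = rng.choice([0.5, 0.7, 0.9])
            want = {
                f"P{i}"
                for i in range(30)
                if mask[i, :4].sum() >= math.ceil(frac * 4)
                or mask[i, 4:].sum() >= math.ceil(frac * 4)
            }
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = so.filter_group_completeness(m, frac)
            assert set(out.values.index) == want

    def test_idempotent(self, rng):
        mask = rng.random((40, 8)) < 0.7
        m = make_matrix(np.where(mask, 21.0, np.nan), ["a"] * 4 + ["b"] * 4)
        once = so.filter_group_completeness(m, 0.7)
        twice = so.filter_group_completeness(once, 0.7)
        assert once.values.equals(twice.values)


class TestMixedImputer:
    def test_complete_matrix_unchanged_for_any_seed(self, rng):
        vals = rng.normal(25, 2, (20, 6))
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        for seed in (0, 1, 99):
            out = so.impute_mixed(m, seed=seed)
            assert out.values.equals(m.values)

    def test_observed_cells_never_altered(self, rng):
        vals = rng.normal(25, 2, (50, 6))
        vals[rng.random((50, 6)) < 0.3] = np.nan
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        out = so.impute_mixed(m, seed=3)
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])
        assert not out.values.isna().any().any()

    def test_seed_determinism_bit_identical(self, rng):
        vals = rng.normal(25, 2, (50, 6))
        vals[rng.random((50, 6)) < 0.3] = np.nan
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        a = so.impute_mixed(m, seed=5)
        b = so.impute_mixed(m, seed=5)
        assert a.values.equals(b.values)

    def test_downshifted_gaussian_moments(self, rng):
        # many fully-missing proteins = many iid draws from the downshifted
        # Gaussian of each sample
        n_obs, n_miss = 200, 10_000
        observed = rng.normal(25, 2, (n_obs, 4))
        vals = np.vstack([observed, np.full((n_miss, 4), np.nan)])
        m = make_matrix(vals, ["a", "a", "b", "b"])
        out = so.impute_mixed(m, seed=11).values.to_numpy()[n_obs:]
        for j in range(4):
            mu = observed[:, j].mean()
            sd = observed[:, j].std(ddof=1)
            target_mean = mu - 1.8 * sd
            target_sd = 0.3 * sd
            se = target_sd / np.sqrt(n_miss)
            assert abs(out[:, j].mean() - target_mean) < 3 * se
            assert out[:, j].std(ddof=1) == pytest.approx(target_sd, rel=0.10)

    def test_knn_uses_exact_duplicate_neighbor(self):
        base = np.array([20.0, 21.0, 22.0, 23.0, 24.0, 25.0])
        vals = np.vstack([
            np.where(np.arange(6) == 5, np.nan, base),  # P0: missing s5
            base,                                        # P1: exact duplicate
            base[::-1],                                  # anticorrelated
            np.full(6, 30.0),                            # constant
        ])
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        out = so.impute_mixed(m, k_neighbors=1, seed=0)
        assert out.values.iloc[0, 5] == pytest.approx(base[5])

    def test_sample_with_single_value_rejected(self):
        vals = np.full((5, 3), np.nan)
        vals[:, 0] = 20.0
        vals[:, 1] = 21.0
        vals[0, 2] = 22.0
        m = make_matrix(vals, ["a", "a", "b"])
        with pytest.raises(ValueError, match="< 2 observed"):
            so.impute_mixed(m)


class TestPermutationTTest:
    def test_identical_groups_with_zero_s0_all_null(self):
        vals = np.tile(np.arange(10.0)[:, None], (1, 6)) + 20
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        est = so.PermutationTTest(s0=0.0, n_permutations=50, random_state=0)
        est.fit(m)
        assert np.allclose(est.t_s0_, 0.0)
        assert not est.significant_.any()

    def test_exhaustive_enumeration_for_3v3(self, rng):
        vals = rng.normal(25, 1, (15, 6))
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        est = so.PermutationTTest(s0=0.5, n_permutations=250, random_state=0)
        with pytest.warns(UserWarning, match="distinct"):
            est.fit(m)
        assert est.exhaustive_ and est.n_distinct_permutations_ == 20
        # oracle: recompute the permutation distribution by itertools
        arr = vals
        for i in range(arr.shape[0]):
            want = sorted(
                t_s0_oracle(arr[i, list(c)],
                            arr[i, [j for j in range(6) if j not in c]], 0.5)
                for c in itertools.combinations(range(6), 3)
            )
            got = sorted(est._t_s0(arr, np.array(c),
                                   np.setdiff1d(np.arange(6), np.array(c)))[i]
                         for c in itertools.combinations(range(6), 3))
            assert np.allclose(got, want)

    def test_statistic_matches_independent_oracle(self, rng):
        vals = rng.normal(25, 1, (30, 12))
        vals[:5, 6:] += 2.0
        m = make_matrix(vals, ["a"] * 6 + ["b"] * 6)
        est = so.PermutationTTest(random_state=1).fit(m)
        for i in range(30):
            assert est.t_s0_[i] == pytest.approx(
                t_s0_oracle(vals[i, :6], vals[i, 6:], 0.5), rel=1e-12
            )

    def test_label_exchange_flips_log2fc_and_preserves_q(self, rng):
        vals = rng.normal(25, 1, (100, 12))
        vals[:10, 6:] += 1.5
        m1 = make_matrix(vals, ["a"] * 6 + ["b"] * 6)
        m2 = make_matrix(vals, ["b"] * 6 + ["a"] * 6)
        e1 = so.PermutationTTest(random_state=2).fit(m1, group_pair=("a", "b"))
        e2 = so.PermutationTTest(random_state=2).fit(m2, group_pair=("a", "b"))
        assert np.allclose(e1.log2fc_, -e2.log2fc_)
        assert np.allclose(e1.q_values_, e2.q_values_)

    def test_power_monotone_in_effect_size(self, rng):
        detected = []
        for effect in (0.5, 1.0, 2.0):
            matrix, truth = so.gen_lfq_matrix(so.LFQSimSpec(
                n_proteins=300, effect_log2fc=effect, frac_regulated=0.1,
                mnar_slope=0.0, mnar_midpoint_log2=-np.inf, seed=77,
            ))
            est = so.PermutationTTest(random_state=7).fit(matrix)
            tp = int((truth["regulated"] & est.significant_).sum())
            detected.append(tp)
        assert detected[0] <= detected[1] <= detected[2]
        assert detected[2] > 10

    def test_null_calibration_small(self, rng):
        # pure-null: realized false-discovery proportion stays at/below 5%
        fdps = []
        for rep in range(20):
            vals = rng.normal(25, 0.5, (300, 12))
            m = make_matrix(vals, ["a"] * 6 + ["b"] * 6)
            est = so.PermutationTTest(n_permutations=100, random_state=rep).fit(m)
            n_sig = int(est.significant_.sum())
            fdps.append(1.0 if n_sig else 0.0)
        assert np.mean(fdps) <= 0.05 + 0.05  # MC slack on 20 reps


class TestQcSummaries:
    def test_duplicated_sample_correlates_perfectly(self, rng):
        vals = rng.normal(25, 2, (30, 3))
        vals[:, 1] = vals[:, 0]
        m = make_matrix(vals, ["a", "a", "b"])
        qc = so.qc_summaries(m)
        assert qc["correlation"].iloc[0, 1] == pytest.approx(1.0)

    def test_constant_proteins_have_zero_cv(self):
        m = make_matrix(np.full((10, 4), 20.0), ["a", "a", "b", "b"])
        qc = so.qc_summaries(m)
        assert (qc["cv_median"] == 0).all()

    def test_rank2_matrix_explained_by_two_components(self, rng):
        u = rng.normal(size=(50, 2))
        v = rng.normal(size=(2, 8))
        m = make_matrix(25 + u @ v, ["a"] * 4 + ["b"] * 4)
        qc = so.qc_summaries(m)
        evr = qc["pca_scores"].attrs["explained_variance_ratio"]
        assert evr[:2].sum() > 0.999


class TestFisherEnrichment:
    def test_set_equal_to_hits_is_most_enriched(self):
        background = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(10)}
        sets = {"exact": set(hits), "random": {f"g{i}" for i in range(50, 90)}}
        res = so.fisher_enrichment(hits, background, sets)
        top = res.table.iloc[0]
        assert top["gene_set"] == "exact"
        assert np.isinf(top["odds_ratio"])

    def test_disjoint_set_not_enriched(self):
        # small disjoint set (expected overlap < 1): no evidence either way
        background = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(10)}
        sets = {"disjoint": {f"g{i}" for i in range(60, 65)}}
        res = so.fisher_enrichment(hits, background, sets)
        row = res.table.iloc[0]
        assert row["odds_ratio"] <= 1.0
        assert row["p_value"] >= 0.5

    def test_p_matches_hypergeometric_enumeration(self):
        # table (8, 2, 2, 88)
        background = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(10)}
        members = {f"g{i}" for i in range(8)} | {"g97", "g98"}
        res = so.fisher_enrichment(hits, background, {"s": members})
        assert res.table["p_value"].iloc[0] == pytest.approx(
            fisher_two_sided_p(8, 2, 2, 88), rel=1e-9
        )

    def test_zero_overlap_sets_skipped_and_reported(self):
        background = {"a", "b", "c"}
        res = so.fisher_enrichment({"a"}, background, {"outside": {"x", "y"}})
        assert res.skipped_sets == ["outside"]
        assert len(res.table) == 0

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2,
                    max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bh_adjustment_monotone_in_raw_p(self, pvals):
        adj = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
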