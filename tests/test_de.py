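"""Unit and property tests for the differential-expression core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from seramir import CountMatrix, bh_fdr, compute_cpm, filter_low_expression, tmm_factors
from seramir.de import (
    DEResult,
    DispersionFit,
    average_log_cpm,
    fit_dispersions,
    pca_variance,
    ql_f_test,
    summarize_de,
    volcano_classes,
    zscore_matrix,
)
from seramir import SimulationConfig, simulate_null


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------


class TestCpm:
    def test_definition(self):
        cm = CountMatrix(
            pd.DataFrame({"s": [5]}, index=["m"]), pd.Series({"s": 5_000_000.0})
        )
        assert compute_cpm(cm).loc["m", "s"] == pytest.approx(1.0)

    def test_all_zero_mirna_stays_zero(self, toy_counts):
        cm = CountMatrix(toy_counts.counts * 0 + toy_counts.counts, toy_counts.library_sizes)
        cm.counts.loc["mir-0"] = 0
        cpm = compute_cpm(CountMatrix(cm.counts, cm.library_sizes))
        assert (cpm.loc["mir-0"] == 0).all()

    def test_matches_elementwise_division(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(0, 500, size=(20, 6)),
            index=[f"m{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        cm = CountMatrix(df)
        cpm = compute_cpm(cm)
        lib = df.sum(axis=0).to_numpy(dtype=float)
        expected = df.to_numpy() / lib[None, :] * 1e6
        np.testing.assert_allclose(cpm.to_numpy(), expected)


class TestFilter:
    def test_boundary_and_removal(self):
        # rows engineered so CPM is count/10 with library size 100,000
        df = pd.DataFrame(
            {"s1": [20, 10, 99970], "s2": [5, 10, 99985], "s3": [2, 0, 99998]},
            index=["removed", "retained", "big"],
        )
        cm = CountMatrix(df, pd.Series({"s1": 1e7, "s2": 1e7, "s3": 1e7}))
        # CPM rows: removed = {2.0, 0.5, 0.2}; retained = {1.0, 1.0, 0}
        out = filter_low_expression(cm, min_cpm=1.0, min_libraries=2)
        assert "removed" not in out.mirnas
        assert "retained" in out.mirnas  # boundary is inclusive (>=)

    def test_matches_bruteforce_row_scan(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.integers(0, 40, size=(60, 8)),
            index=[f"m{i}" for i in range(60)],
            columns=[f"s{j}" for j in range(8)],
        )
        cm = CountMatrix(df)
        out = filter_low_expression(cm, min_cpm=100.0, min_libraries=3)
        cpm = df.to_numpy() / df.sum(axis=0).to_numpy(dtype=float)[None, :] * 1e6
        expected = [
            df.index[g] for g in range(60) if (cpm[g] >= 100.0).sum() >= 3
        ]
        assert list(out.mirnas) == expected

    def test_idempotent_and_subset(self, small_null_dataset):
        cm = small_null_dataset.counts
        once = filter_low_expression(cm)
        twice = filter_low_expression(once)
        assert list(once.mirnas) == list(twice.mirnas)
        assert set(once.mirnas) <= set(cm.mirnas)

    def test_empty_result_warns(self):
        df = pd.DataFrame({"s1": [1, 1], "s2": [1, 1]}, index=["a", "b"])
        cm = CountMatrix(df, pd.Series({"s1": 1e9, "s2": 1e9}))
        with pytest.warns(UserWarning):
            out = filter_low_expression(cm)
        assert out.shape[0] == 0


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_oracle(counts: pd.DataFrame, libsizes: pd.Series):
    """Independent brute-force TMM: explicit M/A enumeration, trims, weights."""
    cpm = counts / libsizes.to_numpy() * 1e6
    q75 = cpm.quantile(0.75)
    ref = (q75 - q75.mean()).abs().idxmin()
    raw = {}
    for s in counts.columns:
        if s == ref:
            raw[s] = 1.0
            continue
        rows = [
            g
            for g in counts.index
            if counts.loc[g, s] > 0 and counts.loc[g, ref] > 0
        ]
        entries = []
        for g in rows:
            ps = counts.loc[g, s] / libsizes[s]
            pr = counts.loc[g, ref] / libsizes[ref]
            m = np.log2(ps / pr)
            a = 0.5 * np.log2(ps * pr)
            v = (libsizes[s] - counts.loc[g, s]) / (libsizes[s] * counts.loc[g, s]) + (
                libsizes[ref] - counts.loc[g, ref]
            ) / (libsizes[ref] * counts.loc[g, ref])
            entries.append((g, m, a, v))
        n = len(entries)
        lo_l, lo_s = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        hi_l, hi_s = n + 1 - lo_l, n + 1 - lo_s
        rank_m = stats.rankdata([e[1] for e in entries])
        rank_a = stats.rankdata([e[2] for e in entries])
        kept = [
            e
            for e, rm, ra in zip(entries, rank_m, rank_a)
            if lo_l <= rm <= hi_l and lo_s <= ra <= hi_s
        ]
        num = sum(e[1] / e[3] for e in kept)
        den = sum(1.0 / e[3] for e in kept)
        raw[s] = 2.0 ** (num / den)
    f = pd.Series(raw).reindex(counts.columns)
    return f / np.exp(np.mean(np.log(f)))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = [100, 50, 20, 400, 10, 77, 5, 300]
        df = pd.DataFrame({f"s{i}": col for i in range(4)}, index=[f"m{i}" for i in range(8)])
        norm = tmm_factors(CountMatrix(df))
        np.testing.assert_allclose(norm.factors.to_numpy(), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        col = np.array([100, 50, 20, 400, 10, 77, 5, 300])
        df = pd.DataFrame(
            {"a": col, "b": 2 * col, "c": col}, index=[f"m{i}" for i in range(8)]
        )
        norm = tmm_factors(CountMatrix(df))
        np.testing.assert_allclose(norm.factors.to_numpy(), 1.0, atol=1e-6)

    def test_toy_matches_bruteforce_oracle(self, toy_counts):
        norm = tmm_factors(toy_counts)
        oracle = _tmm_oracle(toy_counts.counts, toy_counts.library_sizes)
        np.testing.assert_allclose(norm.factors.to_numpy(), oracle.to_numpy(), rtol=1e-10)

    def test_geometric_mean_is_one(self, small_null_dataset):
        norm = tmm_factors(filter_low_expression(small_null_dataset.counts))
        assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0)

    def test_permutation_equivariance(self, toy_counts):
        norm = tmm_factors(toy_counts)
        permuted = toy_counts.counts[["s3", "s1", "s2"]]
        norm_p = tmm_factors(CountMatrix(permuted, toy_counts.library_sizes[["s3", "s1", "s2"]]))
        for s in toy_counts.samples:
            assert norm_p.factors[s] == pytest.approx(norm.factors[s])

    def test_global_depth_scaling_invariance(self, toy_counts):
        norm = tmm_factors(toy_counts)
        scaled = CountMatrix(toy_counts.counts * 2, toy_counts.library_sizes * 2)
        norm_s = tmm_factors(scaled)
        np.testing.assert_allclose(norm_s.factors.to_numpy(), norm.factors.to_numpy())

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["x", "y"])
        with pytest.raises(ValueError):
            tmm_factors(CountMatrix(df, pd.Series({"a": 3.0, "b": 1.0})))


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Direct definition: p*m/rank with a running minimum from the largest p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


class TestBhFdr:
    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.01] * 10), 0.01)

    def test_three_value_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.42]), [0.42])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_matches_exhaustive_definition_up_to_length_six(self, p):
        np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), rtol=1e-12, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_never_decreases_pvalues(self, p):
        assert (bh_fdr(p) >= np.asarray(p) - 1e-15).all()


# ---------------------------------------------------------------------------
# dispersions and the QL F-test
# ---------------------------------------------------------------------------


class TestDispersions:
    def test_poisson_data_gives_near_zero_common_dispersion(self, two_group_sheet):
        ds = simulate_null(
            SimulationConfig(n_mirnas=300, n_patients=8, n_controls=22, dispersion=0.0, seed=7)
        )
        f = filter_low_expression(ds.counts)
        norm = tmm_factors(f)
        disp = fit_dispersions(f, ds.sample_sheet, norm)
        assert disp.common <= 0.05

    def test_infinite_prior_df_pins_tagwise_to_trend(self, small_null_dataset):
        f = filter_low_expression(small_null_dataset.counts)
        norm = tmm_factors(f)
        disp = fit_dispersions(f, small_null_dataset.sample_sheet, norm, prior_df=np.inf)
        np.testing.assert_allclose(disp.tagwise.to_numpy(), disp.trended.to_numpy())

    def test_tagwise_between_raw_and_trend(self, small_null_dataset):
        f = filter_low_expression(small_null_dataset.counts)
        norm = tmm_factors(f)
        disp = fit_dispersions(f, small_null_dataset.sample_sheet, norm, prior_df=10)
        lo = np.minimum(disp.raw, disp.trended)
        hi = np.maximum(disp.raw, disp.trended)
        assert ((disp.tagwise >= lo - 1e-12) & (disp.tagwise <= hi + 1e-12)).all()

    def test_too_few_samples_rejected(self, two_group_sheet):
        df = pd.DataFrame(
            {"a": [10, 20], "b": [12, 18], "c": [11, 19], "d": [9, 21]},
            index=["x", "y"],
        )
        cm = CountMatrix(df)
        sheet = two_group_sheet(["a", "b", "c", "d"], 2)
        norm = tmm_factors(cm)
        with pytest.raises(ValueError):
            fit_dispersions(cm, sheet, norm)


def _nb_loglik_scalar(y, mu, phi):
    if phi <= 1e-12:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / phi
    return float(np.sum(stats.nbinom.logpmf(y, r, r / (r + mu))))


class TestQlFTest:
    def test_constant_mirna_has_no_signal(self, two_group_sheet):
        # equal counts AND equal library sizes: identical columns
        df = pd.DataFrame(
            {f"s{i}": [50, 120, 400, 30, 75, 200] for i in range(8)},
            index=[f"m{i}" for i in range(6)],
        )
        cm = CountMatrix(df)
        sheet = two_group_sheet([f"s{i}" for i in range(8)], 4)
        norm = tmm_factors(cm)
        disp = fit_dispersions(cm, sheet, norm)
        de = ql_f_test(cm, sheet, norm, disp)
        assert (de.table["log2FC"].abs() < 1e-6).all()
        assert (de.table["p_value"] > 0.5).all()

    def test_pvalue_agrees_with_exact_lr_oracle(self, two_group_sheet):
        # 4 samples, 1 miRNA, known dispersion; compare against a direct
        # likelihood-ratio oracle maximized by a scalar optimizer.
        phi = 0.1
        df = pd.DataFrame({"a": [55], "b": [70], "c": [120], "d": [150]}, index=["m"])
        lib = pd.Series({"a": 1e6, "b": 1.2e6, "c": 1e6, "d": 1.1e6})
        cm = CountMatrix(df, lib)
        sheet = two_group_sheet(["a", "b", "c", "d"], 2)
        norm = tmm_factors(cm)
        # pin the QL machinery to the plain LR test at a fixed dispersion
        disp = DispersionFit(
            common=phi,
            trended=pd.Series([phi], index=["m"]),
            tagwise=pd.Series([phi], index=["m"]),
            raw=pd.Series([phi], index=["m"]),
            ql_dispersion=pd.Series([1.0], index=["m"]),
            ql_prior_df=np.inf,
            residual_df=pd.Series([2.0], index=["m"]),
            average_log_cpm=average_log_cpm(cm),
        )
        de = ql_f_test(cm, sheet, norm, disp)

        y = df.iloc[0].to_numpy(dtype=float)
        off = norm.effective_library_sizes[["a", "b", "c", "d"]].to_numpy()
        grp = np.array([1, 1, 0, 0], dtype=float)

        def nll_null(logp):
            return -_nb_loglik_scalar(y, np.exp(logp) * off, phi)

        def nll_full(params):
            b0, b1 = params
            return -_nb_loglik_scalar(y, np.exp(b0 + b1 * grp) * off, phi)

        r0 = optimize.minimize_scalar(nll_null, bounds=(-30, 0), method="bounded")
        r1 = optimize.minimize(nll_full, x0=[r0.x, 0.0], method="Nelder-Mead")
        lr = 2.0 * (r0.fun - r1.fun)
        p_oracle = stats.chi2.sf(lr, 1)
        p_mine = de.table["p_value"].iloc[0]
        assert p_oracle / 2 <= p_mine <= p_oracle * 2

    def test_fdr_dominates_pvalue(self, planted_dataset):
        from seramir import run_de

        de = run_de(planted_dataset.counts, planted_dataset.sample_sheet)
        assert (de.table["FDR"] >= de.table["p_value"] - 1e-15).all()
        assert de.table["p_value"].between(0, 1).all()

    def test_deterministic_tie_break_ordering(self):
        table = pd.DataFrame(
            {
                "log2FC": [1.0, -2.0, 2.0, 0.5],
                "logCPM": [5.0] * 4,
                "F": [1.0] * 4,
                "p_value": [0.01, 0.01, 0.01, 0.001],
                "FDR": [0.02] * 4,
            },
            index=["b", "c", "a", "d"],
        )
        ordered = DEResult(table).sorted()
        # d first (smallest p); then ties by |log2FC| desc: c (2.0) and a (2.0)
        # tie at |2.0| broken lexicographically: a before c; then b
        assert list(ordered.index) == ["d", "a", "c", "b"]


# ---------------------------------------------------------------------------
# summaries and descriptive outputs
# ---------------------------------------------------------------------------


class TestSummaries:
    def test_reporting_mode_zero_significant(self):
        s = summarize_de(n_tested=100, n_significant=0)
        assert s.percent_significant == 0.0

    def test_zero_tested_rejected(self):
        with pytest.raises(ValueError):
            summarize_de(n_tested=0, n_significant=0)

    def test_counts_partition(self, planted_dataset):
        from seramir import run_de

        de = run_de(planted_dataset.counts, planted_dataset.sample_sheet)
        s = summarize_de(de)
        assert s.n_over + s.n_under == s.n_significant
        assert s.percent_significant == pytest.approx(
            round(100 * s.n_significant / s.n_tested, 1), abs=0.051
        )

    def test_volcano_classes_match_predicates(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {
                "log2FC": rng.normal(0, 2, 100),
                "logCPM": rng.normal(5, 1, 100),
                "F": rng.random(100),
                "p_value": rng.random(100),
                "FDR": rng.random(100),
            },
            index=[f"m{i}" for i in range(100)],
        )
        labels = volcano_classes(DEResult(table))
        for m in table.index:
            p, fc = table.loc[m, "p_value"], table.loc[m, "log2FC"]
            expected = "over" if p < 0.05 and fc > 1 else (
                "under" if p < 0.05 and fc < -1 else "ns"
            )
            assert labels[m] == expected

    def test_volcano_simple_cases(self):
        table = pd.DataFrame(
            {"log2FC": [2.0, -0.5], "logCPM": [1, 1], "F": [1, 1],
             "p_value": [0.01, 0.01], "FDR": [0.1, 0.1]},
            index=["x", "y"],
        )
        labels = volcano_classes(DEResult(table))
        assert labels["x"] == "over" and labels["y"] == "ns"


class TestZscore:
    def test_simple_row(self):
        z = zscore_matrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=list("abc")))
        np.testing.assert_allclose(z.loc["m"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zero(self):
        z = zscore_matrix(pd.DataFrame([[5.0, 5.0, 5.0]], index=["m"], columns=list("abc")))
        np.testing.assert_allclose(z.loc["m"].to_numpy(), 0.0)

    def test_rows_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(12, 9)))
        z = zscore_matrix(df)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            zscore_matrix(pd.DataFrame([[1.0]], columns=["a"]))


class TestPca:
    def test_rank_one_data(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame(np.outer(np.arange(1, 6), base))
        pct = pca_variance(df, n_components=2)
        assert pct[0] == pytest.approx(100.0)

    def test_two_equal_orthogonal_directions(self):
        # sample profiles at (+-1, 0) and (0, +-1): two equal-variance axes
        df = pd.DataFrame([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        pct = pca_variance(df, n_components=2)
        np.testing.assert_allclose(pct, [50.0, 50.0])

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(10, 8)))
        pct = pca_variance(df, n_components=3)
        x = df.to_numpy().T
        cov = np.cov(x, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(pct, eig[:3] / eig.sum() * 100.0, rtol=1e-8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pca_variance(pd.DataFrame(np.ones((4, 5))))
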