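"""CPM/log-CPM, filtering, TMM and paired tests, against independent oracles."""

import itertools
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sccref import (
    CountMatrix,
    cpm,
    filter_min_cpm,
    log_cpm,
    paired_t,
    per_gene_fold_change,
    region_summary,
    tmm_factors,
    wilcoxon_signed_rank,
)


def cm(array, samples=None, genes=None, lib=None):
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    meta = None
    if lib is not None:
        meta = pd.DataFrame({"library_size": lib}, index=samples)
    return CountMatrix(pd.DataFrame(array, index=genes, columns=samples), meta)


class TestCpm:
    def test_definition(self):
        counts = cm([[250], [750]])
        vals = cpm(counts)
        assert vals.iloc[0, 0] == 250_000 and vals.iloc[1, 0] == 750_000

    def test_all_zero_gene_and_conservation(self):
        rng = np.random.default_rng(0)
        counts = cm(np.vstack([rng.integers(0, 500, (30, 4)), np.zeros((1, 4), int)]))
        vals = cpm(counts)
        assert (vals.iloc[-1] == 0).all()
        np.testing.assert_allclose(vals.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            cpm(cm([[0], [0]]))


class TestLogCpm:
    def test_zero_count_floor_at_average_gtex_library(self):
        counts = cm([[0]], lib=[79.76e6])
        expr = log_cpm(counts, prior=0.25)
        assert round(float(expr.values.iloc[0, 0]), 2) == -8.32
        assert expr.floor().iloc[0] == expr.values.iloc[0, 0]

    def test_one_cpm_count(self):
        # a (fractional) count equal to L in millions is exactly 1 CPM
        counts = CountMatrix(
            pd.DataFrame({"s0": [79.76]}, index=["g0"]),
            pd.DataFrame({"library_size": [79.76e6]}, index=["s0"]),
        )
        val = float(log_cpm(counts, prior=0.25).values.iloc[0, 0])
        assert val == pytest.approx(math.log2((79.76 + 0.25) / 79.76))
        assert round(val, 4) == 0.0045

    def test_prior_zero_errors(self):
        with pytest.raises(ValueError):
            log_cpm(cm([[1]]), prior=0.0)

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=8, unique=True))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_count_floor_at_zero(self, counts_list):
        counts_list = sorted(counts_list)
        mat = cm(np.array(counts_list)[:, None], lib=[5e6])
        vals = log_cpm(mat).values.iloc[:, 0].to_numpy()
        assert (np.diff(vals) > 0).all()
        if counts_list[0] == 0:
            assert vals[0] == log_cpm(mat).floor().iloc[0]

    def test_tmm_factors_rescale_effective_library(self):
        counts = cm([[100], [200]], lib=[1e6])
        plain = log_cpm(counts)
        scaled = log_cpm(counts, tmm_factors={"s0": 2.0})
        np.testing.assert_allclose(
            scaled.values.to_numpy(), plain.values.to_numpy() - 1.0
        )


class TestFilterMinCpm:
    def setup_method(self):
        # library sizes 1e6 so counts == CPM
        self.groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def _mat(self, rows):
        return cm(rows, samples=list(self.groups), lib=[1e6] * 4)

    def test_kept_if_any_group_passes(self):
        counts = self._mat([[2, 1, 0, 0]])  # group means A=1.5, B=0
        out = filter_min_cpm(counts, self.groups)
        assert out.genes == ["g0"]

    def test_removed_cases(self):
        # all-zero gene, and a gene below 1 CPM in both group means
        counts = cm([[0, 0, 0, 0], [1, 0, 1, 1]], samples=list(self.groups),
                    lib=[2e6] * 4)  # group-mean CPM (0.25, 0.5)
        out = filter_min_cpm(counts, self.groups, min_cpm=1.0)
        assert out.genes == []

    def test_partition_and_order(self):
        rng = np.random.default_rng(1)
        counts = self._mat(rng.integers(0, 4, (50, 4)))
        out = filter_min_cpm(counts, self.groups)
        assert len(out.genes) + (50 - len(out.genes)) == 50
        assert out.genes == [g for g in counts.genes if g in set(out.genes)]
        # survivors all reach the threshold in some group
        vals = cpm(counts)
        for g in out.genes:
            means = [vals.loc[g, ["a1", "a2"]].mean(), vals.loc[g, ["b1", "b2"]].mean()]
            assert max(means) >= 1.0


def brute_force_tmm(mat, lib, logratio_trim=0.3, abs_trim=0.05):
    """Direct evaluation of the TMM definition (independent of the package)."""
    f75 = np.quantile(mat / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(mat.shape[1]):
        ok = (mat[:, j] > 0) & (mat[:, ref] > 0)
        o, r = mat[ok, j], mat[ok, ref]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        if np.abs(m).max() < 1e-6:
            factors.append(1.0)
            continue
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        n = len(m)
        import scipy.stats as ss

        rm, ra = ss.rankdata(m), ss.rankdata(a)
        lo_m, lo_a = np.floor(n * logratio_trim) + 1, np.floor(n * abs_trim) + 1
        keep = ((rm >= lo_m) & (rm <= n + 1 - lo_m)
                & (ra >= lo_a) & (ra <= n + 1 - lo_a))
        factors.append(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_columns_unit_factors(self):
        counts = cm([[10, 10], [20, 20], [5, 5]])
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        a = np.array([10, 50, 100, 3, 7])
        counts = cm(np.column_stack([a, 2 * a]))
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_inflated_gene_shrinks_factor(self):
        a = np.array([100, 200, 300, 400, 500])
        b = a.copy()
        b[0] = 5000  # one inflated gene in B
        counts = cm(np.column_stack([a, b]))
        f = tmm_factors(counts)
        assert f["s1"] < 1.0 < f["s0"]
        np.testing.assert_allclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        mat = rng.negative_binomial(5, 0.01, size=(80, 5)).astype(float)
        counts = cm(mat.astype(int))
        lib = mat.sum(axis=0)
        np.testing.assert_allclose(
            tmm_factors(counts).to_numpy(), brute_force_tmm(mat, lib), rtol=1e-10
        )

    def test_matches_edger_calcnormfactors(self, tmp_path):
        rng = np.random.default_rng(11)
        mat = rng.negative_binomial(4, 0.02, size=(60, 4))
        counts = cm(mat)
        tsv = tmp_path / "counts.tsv"
        counts.to_tsv(tsv)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{tsv}", row.names=1))
            f <- calcNormFactors(x, method="TMM")
            cat(sprintf("%.10f", f), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        expected = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), expected, rtol=1e-6)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            tmm_factors(cm([[1], [2]]))


class TestPairedT:
    def test_closed_form(self):
        t, df, p = paired_t([1, 2, 3], [0, 0, 0])
        assert round(t, 4) == 3.4641 and df == 2 and round(p, 4) == 0.0742

    def test_near_zero_differences(self):
        rng = np.random.default_rng(3)
        eps = rng.normal(0, 1e-9, 20)
        t, _, p = paired_t(eps, np.zeros(20))
        assert abs(t) < 3 and p > 0.01

    def test_errors(self):
        with pytest.raises(ValueError):
            paired_t([1], [0])
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [0, 1, 2])  # constant differences

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        for n in range(2, 11):
            x, y = rng.normal(size=n), rng.normal(size=n)
            d = x - y
            t_exp = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            t, df, p = paired_t(x, y)
            assert t == pytest.approx(t_exp)
            assert df == n - 1
            from scipy.stats import t as tdist

            assert p == pytest.approx(2 * tdist.sf(abs(t_exp), n - 1))


def wilcoxon_exact_oracle(diffs):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    import scipy.stats as ss

    r = ss.rankdata([abs(d) for d in diffs])
    w_obs = sum(r[i] for i in range(n) if diffs[i] > 0)
    w_minus = sum(r[i] for i in range(n) if diffs[i] < 0)
    stat = min(w_obs, w_minus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r[i] for i in range(n) if signs[i])
        w_min = sum(r) - w_plus
        if min(w_plus, w_min) <= stat:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    def test_all_positive_small_n(self):
        w, p = wilcoxon_signed_rank([1, 2, 3])
        assert p == 0.25 == wilcoxon_exact_oracle([1, 2, 3])

    def test_sign_symmetry(self):
        _, p_pos = wilcoxon_signed_rank([1, 2, 3])
        _, p_neg = wilcoxon_signed_rank([-1, -2, -3])
        assert p_pos == p_neg

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0, 0, 0])

    @pytest.mark.parametrize("n", range(3, 11))
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(size=n)
        d = np.where(np.abs(d) < 1e-6, 0.5, d)
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(wilcoxon_exact_oracle(list(d)))


class TestFoldChangeAndRegions:
    def _expr_pair(self, delta):
        counts = cm(np.array([[10, 20], [30, 40]]), lib=[1e6, 1e6])
        base = log_cpm(counts)
        shifted = log_cpm(counts)
        shifted.values = shifted.values + delta
        return shifted, base

    def test_identity_and_shift(self):
        same, base = self._expr_pair(0.0)
        res = per_gene_fold_change(same, base)
        assert (res.fold_change["log2fc_mean"] == 0).all()
        up, base = self._expr_pair(1.0)
        res = per_gene_fold_change(up, base)
        np.testing.assert_allclose(res.fold_change["log2fc_mean"], 1.0)

    def test_floor_to_value_fold_change(self):
        informed = log_cpm(cm([[100]], lib=[1e6]))
        default = log_cpm(cm([[0]], lib=[1e6]))
        res = per_gene_fold_change(informed, default)
        expected = float(informed.values.iloc[0, 0] - default.floor().iloc[0])
        assert res.fold_change["log2fc_mean"].iloc[0] == pytest.approx(expected)
        assert expected > 0

    def test_sample_mismatch_errors(self):
        a = log_cpm(cm([[1]], samples=["s0"]))
        b = log_cpm(cm([[1]], samples=["other"]))
        with pytest.raises(ValueError):
            per_gene_fold_change(a, b)

    def test_region_summary_mean_median(self):
        counts = cm([[1], [3]], lib=[1e6])
        expr = log_cpm(counts)
        expr.values.iloc[:, 0] = [1.0, 3.0]
        summ = region_summary(expr, {"g0": "PAR1", "g1": "PAR1"})
        row = summ.iloc[0]
        assert row["mean_logcpm"] == 2.0 and row["median_logcpm"] == 2.0

    def test_region_gain_shows_in_cpm_ratio(self):
        from sccref import region_ratio_table

        counts = cm([[100, 100]], lib=[1e6, 1e6])
        base_expr = log_cpm(counts)
        up = log_cpm(counts)
        up.values = up.values + 2.0  # +2 log2 everywhere
        regions = {"g0": "PAR1"}
        s_def = region_summary(base_expr, regions, cpm_values=cpm(counts))
        s_inf = region_summary(up, regions, cpm_values=cpm(counts) * 4)
        merged = region_ratio_table(s_inf, s_def)
        assert merged["cpm_mean_ratio"].iloc[0] == pytest.approx(4.0)
        assert merged["logcpm_mean_diff"].iloc[0] == pytest.approx(2.0)

    def test_unlabeled_gene_errors(self):
        expr = log_cpm(cm([[1], [2]]))
        with pytest.raises(KeyError):
            region_summary(expr, {"g0": "PAR1"})
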