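"""Normalization and NB Wald test: definitions, symmetry, calibration, power."""

import numpy as np
import pandas as pd
import pytest

from triadex import detest
from triadex.io import CountMatrix


def _nb_frame(rng, mu, disp, n_samples, n_genes, prefix="s"):
    size = 1.0 / disp
    c = rng.negative_binomial(size, size / (size + mu), size=(n_genes, n_samples))
    return pd.DataFrame(
        c, index=[f"g{i}" for i in range(n_genes)],
        columns=[f"{prefix}{j}" for j in range(n_samples)],
    )


class TestSizeFactors:
    def test_identical_samples_unity(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=list("xyz"))
        sf = detest.size_factors(df)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_ratio_and_geomean(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=list("xyz"))
        sf = detest.size_factors(df)
        assert np.isclose(sf["b"] / sf["a"], 2.0)
        assert np.isclose(np.exp(np.log(sf).mean()), 1.0)

    def test_matches_bruteforce_median_of_ratios(self, tiny_counts):
        sf = detest.size_factors(tiny_counts)
        # independent per-sample oracle: exp(median log(count/geomean)) over
        # genes detected everywhere, rescaled to geometric mean 1
        arr = tiny_counts.to_numpy(float)
        keep = (arr > 0).all(axis=1)
        geo = np.exp(np.log(arr[keep]).mean(axis=1))
        raw = np.array(
            [np.exp(np.median(np.log(arr[keep, j] / geo)))
             for j in range(arr.shape[1])]
        )
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(sf.to_numpy(), expected)

    def test_all_zero_matrix_errors(self):
        df = pd.DataFrame(np.zeros((3, 2), int), columns=["a", "b"])
        with pytest.raises(ValueError):
            detest.size_factors(df)

    def test_upper_quartile_fallback(self):
        # no gene detected in every sample
        df = pd.DataFrame({"a": [10, 0, 5, 0], "b": [0, 10, 0, 5]})
        sf = detest.size_factors(df)
        assert np.allclose(sf, 1.0)  # symmetric design


class TestNormalization:
    def test_fpkm_definition(self):
        # two identical samples (factors 1), library size 1e6, length 1 kb
        col = np.zeros(101, dtype=int)
        col[0] = 100
        col[1:] = 9999  # 100 genes x 9999 + 100 = 1e6
        df = pd.DataFrame({"a": col, "b": col},
                          index=[f"g{i}" for i in range(101)])
        assert df["a"].sum() == 1_000_000
        lengths = pd.Series(1000.0, index=df.index)
        fpkm = detest.to_fpkm(df, lengths)
        assert np.isclose(fpkm.values.loc["g0", "a"], 100.0)

    def test_zero_count_zero_everywhere(self, tiny_counts):
        df = tiny_counts.copy()
        df.iloc[0] = 0
        cpm = detest.to_cpm(df)
        assert (cpm.values.iloc[0] == 0).all()

    def test_cpm_invariant_to_doubling_one_sample(self, tiny_counts):
        cpm1 = detest.to_cpm(tiny_counts)
        doubled = tiny_counts.copy()
        doubled["a"] = doubled["a"] * 2
        cpm2 = detest.to_cpm(doubled)  # factors recomputed
        assert np.allclose(cpm1.values["a"], cpm2.values["a"], rtol=1e-10)

    def test_missing_length_errors(self, tiny_counts):
        lengths = pd.Series(500.0, index=tiny_counts.index[:-1])
        with pytest.raises(KeyError):
            detest.to_fpkm(tiny_counts, lengths)


class TestCountExpressed:
    def test_threshold_zero_counts_all_detected(self, tiny_counts):
        cpm = detest.to_cpm(tiny_counts)
        n = detest.count_expressed(cpm, ["a", "b", "c"], 0.0)
        assert n == (tiny_counts[["a", "b", "c"]].mean(axis=1) > 0).sum()

    def test_threshold_infinite_zero(self, tiny_counts):
        cpm = detest.to_cpm(tiny_counts)
        assert detest.count_expressed(cpm, ["a"], np.inf) == 0

    def test_planted_above_threshold(self):
        # 50 genes far above, 30 far below a CPM threshold of 1
        vals = np.full((80, 2), 0.01)
        vals[:50] = 100.0
        nm = detest.NormalizedMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(80)],
                         columns=["a", "b"]),
            pd.Series([1.0, 1.0], index=["a", "b"]),
            "CPM",
        )
        assert detest.count_expressed(nm, ["a", "b"], 1.0) == 50

    def test_unknown_sample_errors(self, tiny_counts):
        cpm = detest.to_cpm(tiny_counts)
        with pytest.raises(KeyError):
            detest.count_expressed(cpm, ["nope"], 0.0)


class TestNBTest:
    def test_identical_counts_ns(self):
        df = pd.DataFrame(
            np.tile([[100], [200], [50]], (1, 6)),
            index=list("xyz"), columns=list("abcdef"),
        )
        res = detest.nb_pairwise_test(df, list("abc"), list("def"))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["state"] == "ns").all()

    def test_group_swap_negates_lfc(self, tiny_counts):
        r1 = detest.nb_pairwise_test(tiny_counts, list("abc"), list("def"))
        r2 = detest.nb_pairwise_test(tiny_counts, list("def"), list("abc"))
        assert np.allclose(r1["log2fc"], -r2["log2fc"])
        assert np.allclose(
            r1["pvalue"].dropna(), r2["pvalue"].dropna(), rtol=1e-12
        )

    def test_fewer_than_two_replicates_errors(self, tiny_counts):
        with pytest.raises(ValueError, match="replicates"):
            detest.nb_pairwise_test(tiny_counts, ["a"], list("def"))

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(101)
        df = _nb_frame(rng, mu=100, disp=0.05, n_samples=6, n_genes=2000)
        res = detest.nb_pairwise_test(df, list(df.columns[:3]), list(df.columns[3:]))
        rate = (res.loc[res["tested"], "pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_on_planted_fourfold(self):
        rng = np.random.default_rng(202)
        null = _nb_frame(rng, mu=100, disp=0.05, n_samples=6, n_genes=1000)
        size = 1 / 0.05
        g1 = rng.negative_binomial(size, size / (size + 200), size=(200, 3))
        g2 = rng.negative_binomial(size, size / (size + 800), size=(200, 3))
        planted = pd.DataFrame(
            np.hstack([g1, g2]),
            index=[f"p{i}" for i in range(200)], columns=null.columns,
        )
        df = pd.concat([null, planted])
        res = detest.nb_pairwise_test(df, list(df.columns[:3]), list(df.columns[3:]))
        power = (res.loc[planted.index, "state"] == "up").mean()
        assert power >= 0.9

    def test_power_monotone_in_effect_and_replicates(self):
        rng = np.random.default_rng(303)
        size = 1 / 0.05

        def power(lfc, n):
            # planted genes kept to ~10% so median-of-ratios stays valid
            null = _nb_frame(rng, 100, 0.05, 2 * n, 1800)
            mu2 = 100 * 2**lfc
            g1 = rng.negative_binomial(size, size / (size + 100), size=(200, n))
            g2 = rng.negative_binomial(size, size / (size + mu2), size=(200, n))
            planted = pd.DataFrame(
                np.hstack([g1, g2]),
                index=[f"p{i}" for i in range(200)], columns=null.columns,
            )
            df = pd.concat([null, planted])
            cols = list(df.columns)
            res = detest.nb_pairwise_test(df, cols[:n], cols[n:])
            return (res.loc[planted.index, "state"] == "up").mean()

        p_eff = [power(lfc, 3) for lfc in (1.2, 2.0, 3.0)]
        assert p_eff[0] <= p_eff[1] + 0.02 and p_eff[1] <= p_eff[2] + 0.02
        p_rep = [power(1.5, n) for n in (2, 4, 8)]
        assert p_rep[0] <= p_rep[1] + 0.02 and p_rep[1] <= p_rep[2] + 0.02

    def test_bh_monotone_with_p(self, tiny_counts):
        res = detest.nb_pairwise_test(tiny_counts, list("abc"), list("def"))
        sub = res[res["tested"]].sort_values("pvalue", kind="mergesort")
        assert sub["qvalue"].is_monotonic_increasing or np.allclose(
            sub["qvalue"], np.maximum.accumulate(sub["qvalue"])
        )
        assert (sub["qvalue"] >= sub["pvalue"] - 1e-12).all()


class TestThresholds:
    def _frame(self, lfc, p):
        return pd.DataFrame(
            {"log2fc": [lfc], "se": [0.1], "pvalue": [p],
             "qvalue": [p], "tested": [True]},
            index=["g"],
        )

    @pytest.mark.parametrize(
        "lfc,p,expected",
        [
            (1.0, 0.001, "ns"),    # fold threshold is strict
            (3.0, 0.2, "ns"),      # both criteria required
            (-1.5, 0.01, "down"),
            (1.5, 0.01, "up"),
            (-1.0, 0.001, "ns"),
        ],
    )
    def test_state_rules(self, lfc, p, expected):
        out = detest.apply_de_thresholds(self._frame(lfc, p))
        assert out["state"].iloc[0] == expected

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            detest.apply_de_thresholds(self._frame(0, 1), alpha=2.0)
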