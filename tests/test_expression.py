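"""Normalization, differential expression, CLR and correlation."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circrbp.expression import (
    clr,
    correlate,
    correlation_direction_concordance,
    de_test,
    estimate_common_dispersion,
    filter_rbps,
    spearman,
    tmm_factors,
)


def _nb_matrix(rng, nfeat, means, dispersion=0.1):
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + means))
    return pd.DataFrame(counts, index=[f"f{i}" for i in range(nfeat)],
                        columns=[f"s{i}" for i in range(means.shape[1])])


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 0, 30, 7, 2, 100, 55, 1, 9])
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(tmm_factors(df).to_numpy(), 1.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(4, 1, size=(500, 1)) * np.array([0.5, 1, 2, 3])[None, :]
        df = _nb_matrix(rng, 500, mu)
        f = tmm_factors(df).to_numpy()
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-9

    def test_two_sample_manual_trimmed_mean_oracle(self):
        """Factor on a 12-feature 2-sample matrix equals an explicit
        enumerate-the-trim-set computation done independently here."""
        rng = np.random.default_rng(5)
        y1 = rng.integers(20, 2000, 12).astype(float)
        y2 = (y1 * rng.lognormal(0, 0.4, 12)).round()
        df = pd.DataFrame({"s1": y1, "s2": y2}).astype(int)
        n1, n2 = y1.sum(), y2.sum()
        frac = df.to_numpy() / np.array([n1, n2])
        f75 = np.quantile(frac, 0.75, axis=0)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))  # reference column
        obs = df.to_numpy()[:, 1 - ref].astype(float)
        refv = df.to_numpy()[:, ref].astype(float)
        no, nr = (n2, n1) if ref == 0 else (n1, n2)
        m = np.log2((obs / no) / (refv / nr))
        a = 0.5 * np.log2((obs / no) * (refv / nr))
        n = len(m)
        keep = np.ones(n, dtype=bool)
        order_m = np.argsort(np.argsort(m)) + 1  # ranks, no ties by construction
        order_a = np.argsort(np.argsort(a)) + 1
        lo_m = int(np.floor(n * 0.3)) + 1
        lo_a = int(np.floor(n * 0.05)) + 1
        keep &= (order_m >= lo_m) & (order_m <= n + 1 - lo_m)
        keep &= (order_a >= lo_a) & (order_a <= n + 1 - lo_a)
        w = 1.0 / ((no - obs[keep]) / (no * obs[keep]) + (nr - refv[keep]) / (nr * refv[keep]))
        f_nonref = 2 ** (np.sum(w * m[keep]) / np.sum(w))
        expected = np.array([1.0, f_nonref] if ref == 0 else [f_nonref, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        got = tmm_factors(df).to_numpy()
        assert np.allclose(got, expected, rtol=1e-12)

    def test_matches_bioconductor_reference(self, tmp_path):
        """Independent oracle: edgeR's calcNormFactors on the same matrix."""
        rng = np.random.default_rng(3)
        mu = rng.lognormal(4, 1, size=(400, 1)) * np.array([0.6, 1.0, 1.5, 2.2, 0.9])[None, :]
        df = _nb_matrix(rng, 400, mu)
        df.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        script = (
            'suppressMessages(library(edgeR)); '
            f'm <- as.matrix(read.delim("{tmp_path}/m.tsv")); '
            'cat(calcNormFactors(m, method="TMM"), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        theirs = np.array([float(x) for x in out.stdout.split()])
        assert np.allclose(tmm_factors(df).to_numpy(), theirs, rtol=1e-5)

    def test_scaling_one_sample_leaves_factors_stable(self):
        """Multiplying one sample's counts by a constant is absorbed by the
        library size: TMM factors change only through trim discreteness."""
        rng = np.random.default_rng(1)
        mu = rng.lognormal(4, 1, size=(2000, 1)) * np.ones((1, 4))
        df = _nb_matrix(rng, 2000, mu)
        f1 = tmm_factors(df).to_numpy()
        df2 = df.copy()
        df2["s0"] = df2["s0"] * 5
        f2 = tmm_factors(df2).to_numpy()
        assert np.allclose(f1, f2, rtol=0.02)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            tmm_factors(df)


class TestDETest:
    def test_identical_groups_null_everywhere(self):
        rng = np.random.default_rng(2)
        col = rng.negative_binomial(10, 0.1, size=(300, 3))
        df = pd.DataFrame(np.hstack([col, col]),
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        res = de_test(df, ["g1"] * 3 + ["g2"] * 3)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)
        assert (res["status"] == "null").all()

    def test_bh_adjustment_arithmetic(self):
        # de_test delegates BH to statsmodels; pin the classic worked example
        assert np.allclose(
            multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1], [0.03, 0.03, 0.04]
        )

    def test_recovery_of_planted_fold_changes(self):
        """fc=4 features at n=20/group, dispersion 0.1: sensitivity >= 0.9
        at FDR 0.05, with the realized false-discovery fraction <= 0.07."""
        rng = np.random.default_rng(11)
        n, nfeat = 20, 1000
        status = np.array(["null"] * 800 + ["up"] * 100 + ["down"] * 100)
        rng.shuffle(status)
        fc = np.where(status == "up", 4.0, np.where(status == "down", 0.25, 1.0))
        sf = np.exp(rng.uniform(-0.55, 0.55, 2 * n))
        mean = np.where(np.arange(2 * n)[None, :] < n, 100.0 * fc[:, None], 100.0) * sf[None, :]
        df = _nb_matrix(rng, nfeat, mean)
        res = de_test(df, ["2_tumor"] * n + ["1_control"] * n)
        called = res["status"].to_numpy() != "null"
        truth_de = status != "null"
        assert (called & truth_de).sum() / truth_de.sum() >= 0.9
        assert (called & ~truth_de).sum() / max(called.sum(), 1) <= 0.07
        # signs agree with the planted direction
        assert (res["status"].to_numpy()[status == "up"] != "down").all()

    def test_dispersion_estimator_recovers_truth(self):
        rng = np.random.default_rng(4)
        mu = np.full((2000, 10), 200.0)
        df = _nb_matrix(rng, 2000, mu, dispersion=0.15)
        idx = [np.arange(5), np.arange(5, 10)]
        est = estimate_common_dispersion(df.to_numpy(dtype=float), idx)
        assert 0.10 < est < 0.20

    def test_single_sample_group_rejected(self):
        df = pd.DataFrame(np.ones((5, 3), dtype=int), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="2 samples"):
            de_test(df, ["g1", "g1", "g2"])


class TestCLR:
    def test_symmetry_point(self):
        t = clr(pd.Series({"c": 10}), pd.Series({"c": 10}))
        assert t.loc["c", "clr"] == 0.5 and not t.loc["c", "high_circ"]

    def test_circ_exceeding_linear(self):
        t = clr(pd.Series({"c": 3}), pd.Series({"c": 1}))
        assert t.loc["c", "clr"] == 0.75 and bool(t.loc["c", "high_circ"])

    def test_zero_denominator_missing(self):
        t = clr(pd.Series({"c": 0}), pd.Series({"c": 0}))
        assert np.isnan(t.loc["c", "clr"]) and not t.loc["c", "high_circ"]

    @pytest.mark.parametrize("a,b", [(1, 9), (50, 50), (7, 0), (0, 3)])
    def test_bounded_and_complementary(self, a, b):
        fwd = clr(pd.Series({"c": a}), pd.Series({"c": b})).loc["c", "clr"]
        rev = clr(pd.Series({"c": b}), pd.Series({"c": a})).loc["c", "clr"]
        assert 0.0 <= fwd <= 1.0
        assert fwd + rev == pytest.approx(1.0)

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            clr(pd.Series({"c1": 5}), pd.Series({"other": 5}))


class TestFilterRBPs:
    def _de(self, ids):
        return pd.DataFrame({"feature_id": ids, "fdr": 0.01}).set_index("feature_id", drop=False)

    def test_case_insensitive_intersection(self):
        out = filter_rbps(self._de(["Fus", "ELAVL2", "GAPDH"]), ["FUS", "elavl2"])
        assert set(out["feature_id"]) == {"Fus", "ELAVL2"}

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning):
            out = filter_rbps(self._de(["GAPDH"]), ["FUS"])
        assert out.empty

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            filter_rbps(self._de(["FUS"]), [])


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([0.1, 1.5, 2.2, 3.9, 5.0, 7.7])
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(6.0)
        rho, p = spearman(x, -x)
        assert rho == pytest.approx(-1.0) and p == 0.0

    def test_constant_vector_is_missing(self):
        rho, p = spearman(np.ones(6), np.arange(6.0))
        assert np.isnan(rho) and np.isnan(p)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_then_pearson_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 12).astype(float)  # heavy ties
        y = rng.integers(0, 4, 12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        rho, _ = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_correlate_matrix_equals_pairwise(self):
        rng = np.random.default_rng(9)
        rbp = pd.DataFrame(rng.normal(size=(3, 10)), index=["r1", "r2", "r3"],
                           columns=[f"s{i}" for i in range(10)])
        circ = pd.DataFrame(rng.normal(size=(2, 10)), index=["c1", "c2"],
                            columns=[f"s{i}" for i in range(10)])
        table = correlate(rbp, circ).set_index(["rbp_id", "circ_id"])
        for r in rbp.index:
            for c in circ.index:
                rho, p = spearman(rbp.loc[r].to_numpy(), circ.loc[c].to_numpy())
                assert table.loc[(r, c), "rho"] == pytest.approx(rho, abs=1e-12)
                assert table.loc[(r, c), "pvalue"] == pytest.approx(p, abs=1e-12)


class TestConcordance:
    def _tables(self):
        rng = np.random.default_rng(1)
        rbp = pd.DataFrame(rng.normal(size=(2, 12)), index=["r1", "r2"],
                           columns=[f"s{i}" for i in range(12)])
        circ = pd.DataFrame(rng.normal(size=(4, 12)) + 3 * rbp.iloc[0].to_numpy(),
                            index=list("abcd"), columns=rbp.columns)
        return correlate(rbp, circ)

    def test_identical_tables_all_same(self):
        t = self._tables()
        out = correlation_direction_concordance(t, t, alpha=0.05)
        assert (out["opposite"] == 0).all() and (out["none"] == 0).all()

    def test_negated_table_all_opposite(self):
        t = self._tables()
        neg = t.copy()
        neg["rho"] = -neg["rho"]
        out = correlation_direction_concordance(t, neg, alpha=0.05)
        assert (out["same"] == 0).all()
        assert out["opposite"].sum() == (t["pvalue"] < 0.05).sum()

    def test_counts_conserved(self):
        t = self._tables()
        out = correlation_direction_concordance(t, t, alpha=0.05)
        n_pairs = (t["pvalue"] < 0.05).sum()
        assert out[["same", "opposite", "none"]].to_numpy().sum() == n_pairs
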