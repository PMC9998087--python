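import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import somnopharm as sp

from ._oracles import oracle_bh, oracle_rm_anova


class TestPairedT:
    def test_effect_size_identity_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            eff = sp.paired_t(x, y)
            assert abs(abs(eff.d) - abs(eff.t) / math.sqrt(n)) < 1e-10
            assert eff.df == n - 1

    def test_two_tailed_doubles_smaller_one_tail(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0.5, 1, 10), rng.normal(0, 1, 10)
        two = sp.paired_t(x, y, "two-sided").p
        one = min(sp.paired_t(x, y, "greater").p, sp.paired_t(x, y, "less").p)
        assert two == pytest.approx(2 * one)

    def test_constant_shift_is_undefined(self):
        x = np.arange(8.0)
        with pytest.raises(sp.ParameterError, match="identical"):
            sp.paired_t(x + 1.0, x)

    def test_cohens_d_balanced_diffs_is_zero(self):
        assert sp.cohens_d_paired([1.0, -1.0]) == 0.0

    def test_cohens_d_zero_variance_rejected(self):
        with pytest.raises(sp.ParameterError):
            sp.cohens_d_paired([2.0, 2.0, 2.0])


class TestRMAnova:
    def test_identical_columns_give_zero_F(self):
        x = np.random.default_rng(2).normal(size=8)
        res = sp.rm_anova_gg(pd.DataFrame({"a": x, "b": x, "c": x}))
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p == 1.0

    def test_two_conditions_degenerate_to_paired_t(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 1, 9), rng.normal(0, 1, 9)
        res = sp.rm_anova_gg(pd.DataFrame({"a": x, "b": y}))
        eff = sp.paired_t(x, y)
        assert res.F == pytest.approx(eff.t ** 2, rel=1e-10)
        assert res.epsilon == 1.0
        assert res.p == pytest.approx(eff.p, rel=1e-10)

    def test_agrees_with_sums_of_squares_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n, k = int(rng.integers(5, 12)), int(rng.integers(3, 6))
            y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            res = sp.rm_anova_gg(pd.DataFrame(y))
            F, eps = oracle_rm_anova(y)
            assert res.F == pytest.approx(F, abs=1e-8)
            assert res.epsilon == pytest.approx(min(max(eps, 1 / (k - 1)), 1.0), abs=1e-8)
            assert res.df1 == pytest.approx(res.epsilon * (k - 1))
            assert res.df2 == pytest.approx(res.epsilon * (k - 1) * (n - 1))
            assert 1 / (k - 1) <= res.epsilon <= 1.0

    def test_missing_cells_use_mixed_model(self):
        rng = np.random.default_rng(5)
        y = pd.DataFrame(rng.normal(size=(10, 3)), columns=["saline", "lo", "hi"])
        y.iloc[0, 1] = np.nan
        y.iloc[3, 2] = np.nan
        res = sp.rm_anova_gg(y)
        assert res.method == "mixedlm_reml"
        assert res.n_complete == 8 and res.n_total == 10
        assert math.isfinite(res.F) and 0 < res.p <= 1
        assert math.isnan(res.epsilon)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(sp.ParameterError):
            sp.rm_anova_gg(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        empty = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [np.nan] * 3})
        with pytest.raises(sp.ParameterError):
            sp.rm_anova_gg(empty)


class TestDunnett:
    def test_single_comparison_equals_paired_t(self):
        rng = np.random.default_rng(6)
        saline = rng.normal(0, 1, 8)
        wide = pd.DataFrame({"saline": saline, "drug": saline + rng.normal(1.5, 0.5, 8)})
        out = sp.dunnett_vs_reference(wide, "saline")
        eff = sp.paired_t(wide["drug"].to_numpy(), wide["saline"].to_numpy())
        assert out.loc[0, "p_adj"] == pytest.approx(eff.p)
        assert out.loc[0, "p_raw"] == pytest.approx(eff.p)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(7)
        wide = pd.DataFrame(
            rng.normal(size=(9, 4)) + [0, 0.5, 1.0, 1.5],
            columns=["saline", "a", "b", "c"],
        )
        out = sp.dunnett_vs_reference(wide, "saline")
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_gate_blocks_posthocs_without_main_effect(self):
        rng = np.random.default_rng(8)
        wide = pd.DataFrame(rng.normal(size=(8, 3)), columns=["saline", "a", "b"])
        main = sp.rm_anova_gg(wide)
        assert main.p >= 0.05  # fixed null draw; precondition for the gate check
        out = sp.dunnett_vs_reference(wide, "saline", main_effect=main)
        assert (~out["tested"]).all()
        assert out["p_adj"].isna().all()

    def test_max_t_tail_matches_monte_carlo(self):
        rng = np.random.default_rng(9)
        m, df = 3, 10
        n_mc = 400_000
        z = rng.normal(size=(n_mc, m + 1))
        w = np.sqrt(rng.chisquare(df, n_mc) / df)
        T = np.abs((z[:, 1:] - z[:, :1]) / math.sqrt(2)) / w[:, None]
        maxt = T.max(axis=1)
        for t in (1.5, 2.0, 2.5, 3.0):
            mc = (maxt >= t).mean()
            assert sp.dunnett_sf_two_sided(t, m, df) == pytest.approx(mc, abs=0.01)

    def test_tail_monotone_in_comparisons(self):
        p1 = sp.dunnett_sf_two_sided(2.0, 1, 9)
        p3 = sp.dunnett_sf_two_sided(2.0, 3, 9)
        p6 = sp.dunnett_sf_two_sided(2.0, 6, 9)
        assert p1 < p3 < p6


class TestBH:
    def test_all_ones_reject_nothing(self):
        reject, padj = sp.bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any()
        assert (padj == 1.0).all()

    def test_single_p_unchanged(self):
        reject, padj = sp.bh_adjust([0.03])
        assert reject[0] and padj[0] == pytest.approx(0.03)

    def test_matches_manual_step_up_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            reject, padj = sp.bh_adjust(p, q=0.05)
            assert reject.tolist() == oracle_bh(p.tolist(), 0.05)
            assert ((padj >= 0) & (padj <= 1)).all()
            order = np.argsort(p)
            assert (np.diff(padj[order]) >= -1e-12).all()  # monotone in rank

    def test_out_of_range_rejected(self):
        with pytest.raises(sp.ParameterError):
            sp.bh_adjust([0.5, 1.5])


class TestPower:
    def test_power_monotone_in_n(self):
        powers = [sp.paired_t_power(1.0, n) for n in range(3, 30)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(sp.ParameterError):
            sp.paired_t_sample_size(0.0)
        with pytest.raises(sp.ParameterError):
            sp.paired_t_sample_size(1.0, alpha=0.0)
        with pytest.raises(sp.ParameterError):
            sp.paired_t_sample_size(1.0, power=1.5)

    def test_two_sided_needs_more_samples(self):
        one = sp.paired_t_sample_size(0.8, side="one-sided")
        two = sp.paired_t_sample_size(0.8, side="two-sided")
        assert two >= one

    def test_noncentral_power_matches_simulation(self):
        d, n = 1.0, 11
        rng = np.random.default_rng(11)
        x = rng.normal(d, 1.0, size=(100_000, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(n))
        crit = sps.t.ppf(0.95, n - 1)
        assert (t > crit).mean() == pytest.approx(sp.paired_t_power(d, n), abs=0.01)
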