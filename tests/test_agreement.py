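import numpy as np
import pandas as pd
import pytest

import turnkit as tk


def _anova_icc_oracle(x):
    """Brute-force ICC(2,1) from explicit ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


class TestIcc:
    def test_identical_columns_give_one(self):
        x = np.column_stack([[1.0, 2, 3, 4, 5]] * 2)
        assert tk.icc_2_1(x) == pytest.approx(1.0)

    def test_constant_offset_depresses_icc_not_rho(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        x = np.column_stack([a, a + 10.0])
        icc = tk.icc_2_1(x)
        from scipy.stats import spearmanr
        rho = spearmanr(x[:, 0], x[:, 1]).statistic
        assert rho == pytest.approx(1.0)
        assert icc < 0.5 < rho

    def test_matches_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            x = rng.normal(10, 3, (8, 2))
            assert tk.icc_2_1(x) == pytest.approx(_anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(5, 2, (10, 2))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 2),
            "raters": np.tile([0, 1], 10),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="score")
        # ICC(A,1): two-way, absolute agreement, single measures
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert tk.icc_2_1(x) == pytest.approx(icc2, abs=1e-9)

    def test_symmetric_in_raters(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (9, 2))
        assert tk.icc_2_1(x) == pytest.approx(tk.icc_2_1(x[:, ::-1]), abs=1e-12)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="variance"):
            out = tk.icc_2_1(np.ones((5, 2)))
        assert np.isnan(out)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            tk.icc_2_1(np.ones((2, 2)))


class TestLimitsOfAgreement:
    def test_identical_series(self):
        a = np.array([1.0, 2, 3, 4])
        loa, pct, bias = tk.limits_of_agreement(a, a)
        assert loa == 0.0 and bias == 0.0 and pct == 0.0

    def test_hand_arithmetic(self):
        loa, pct, bias = tk.limits_of_agreement([10.0, 12, 14], [9.0, 12, 15])
        assert bias == pytest.approx(0.0)
        assert loa == pytest.approx(1.96)  # 1.96 * SD({1,0,-1}) = 1.96
        assert pct == pytest.approx(100 * 1.96 / 12.0)

    def test_sampling_distribution(self):
        rng = np.random.default_rng(102)
        a = rng.normal(10, 1, 200)
        b = a - rng.normal(0, 0.25, 200)
        loa, _, _ = tk.limits_of_agreement(a, b)
        assert loa == pytest.approx(1.96 * 0.25, abs=0.05)

    def test_zero_grand_mean_flags_pct(self):
        with pytest.warns(UserWarning, match="LOA"):
            _, pct, _ = tk.limits_of_agreement([1.0, -1.0], [-1.0, 1.0])
        assert np.isnan(pct)

    def test_rmse_at_least_abs_bias(self):
        rng = np.random.default_rng(11)
        a = rng.normal(5, 1, 50)
        b = a + 0.4 + rng.normal(0, 0.2, 50)
        d = a - b
        rmse = float(np.sqrt(np.mean(d**2)))
        assert rmse >= abs(np.mean(d))


def _events(times, dur=2.5):
    return [tk.TurnEvent("L5", s, s + dur, 180.0) for s in times]


class TestEventSeriesComparison:
    def test_identical_series_perfect_agreement(self):
        ev = _events(np.arange(5) * 12.0 + 3)
        rep = tk.compare_event_series(ev, ev)
        for boundary in ("start", "end"):
            assert rep[boundary].icc21 == pytest.approx(1.0)
            assert rep[boundary].rmse == 0.0
            assert rep[boundary].n == 5

    def test_jittered_series_rmse_matches_noise(self):
        rng = np.random.default_rng(21)
        starts = np.arange(50) * 15.0 + 5
        ref = _events(starts)
        test = [tk.TurnEvent("L5", s + rng.normal(0, 0.3),
                             e + rng.normal(0, 0.3), 180.0)
                for s, e in ((x.start_s, x.end_s) for x in ref)]
        rep = tk.compare_event_series(ref, test)
        assert rep["start"].rmse == pytest.approx(0.3, abs=0.05)
        assert rep["end"].rmse == pytest.approx(0.3, abs=0.05)
        assert rep["start"].icc21 > 0.99  # jitter tiny vs between-turn spread

    def test_missing_event_bookkeeping(self):
        ref = _events(np.arange(10) * 12.0)
        test = _events(np.arange(9) * 12.0)
        rep = tk.compare_event_series(ref, test)
        assert rep["start"].n == 9
        assert rep["start"].n_unmatched_ref == 1
        assert rep["start"].n_unmatched_test == 0

    def test_too_few_matches_fatal(self):
        with pytest.raises(ValueError, match="matched"):
            tk.compare_event_series(_events([0.0, 50.0]), _events([100.0]))

    def test_pooled_multisession_agreement(self):
        sessions = [( _events([3.0, 20.0]), _events([3.1, 20.1]) ),
                    ( _events([5.0, 25.0]), _events([5.05, 24.9]) )]
        rep = tk.pooled_event_agreement(sessions)
        assert rep["start"].n == 4
        assert rep["start"].rmse < 0.15


class TestGroupComparison:
    def test_shifted_feature_detected(self):
        rng = np.random.default_rng(31)
        a = pd.DataFrame({"f": rng.normal(2.0, 1, 30)})
        b = pd.DataFrame({"f": rng.normal(0.0, 1, 30)})
        out = tk.compare_groups(a, b)
        assert bool(out.loc[0, "significant"])
        assert out.loc[0, "z_pd"] > 0 > out.loc[0, "z_cl"]

    def test_constant_feature_skipped(self):
        a = pd.DataFrame({"f": np.ones(10)})
        b = pd.DataFrame({"f": np.ones(10)})
        out = tk.compare_groups(a, b)
        assert out.loc[0, "test"] == "skipped"

    def test_nonnormal_data_routed_to_mannwhitney(self):
        rng = np.random.default_rng(41)
        a = pd.DataFrame({"f": rng.exponential(1.0, 40) ** 3})
        b = pd.DataFrame({"f": rng.exponential(1.0, 40) ** 3})
        out = tk.compare_groups(a, b)
        assert out.loc[0, "test"] == "mann-whitney"

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(51)
        p = 400
        a = pd.DataFrame(rng.standard_normal((30, p)),
                         columns=[f"f{i}" for i in range(p)])
        b = pd.DataFrame(rng.standard_normal((30, p)),
                         columns=[f"f{i}" for i in range(p)])
        out = tk.compare_groups(a, b)
        rate = out["significant"].mean()
        assert 0.02 < rate < 0.09

    def test_fdr_option_reduces_null_hits(self):
        rng = np.random.default_rng(61)
        p = 200
        a = pd.DataFrame(rng.standard_normal((20, p)))
        a.columns = [f"f{i}" for i in range(p)]
        b = pd.DataFrame(rng.standard_normal((20, p)))
        b.columns = [f"f{i}" for i in range(p)]
        out = tk.compare_groups(a, b, fdr=True)
        assert out["significant_fdr"].sum() <= out["significant"].sum()
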