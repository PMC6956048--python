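"""Comparative-Ct fold changes and the t / ANOVA statistics vs independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from corneaquant.expression import (
    DegenerateStatisticError,
    delta_delta_ct,
    holm_adjust,
    one_way_anova,
    two_sample_t,
    two_sample_t_from_summary,
)
from corneaquant.synthetic import CtTableParams, generate_ct_table


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


class TestDeltaDeltaCt:
    def test_hand_computed_fold_of_4(self):
        # control dCt {5, 5}, treated dCt {3} -> treated fold 2^(5-3) = 4
        table = ct_table(
            [
                ("c1", "control", "Gapdh", 18.0),
                ("c1", "control", "X", 23.0),
                ("c2", "control", "Gapdh", 18.5),
                ("c2", "control", "X", 23.5),
                ("t1", "treated", "Gapdh", 18.0),
                ("t1", "treated", "X", 21.0),
            ]
        )
        fc = delta_delta_ct(table)
        t1 = fc.per_sample.query("sample_id == 't1' and gene == 'X'")
        assert t1["fold_change"].iloc[0] == pytest.approx(4.0)

    def test_sample_at_control_mean_has_unit_fold(self):
        table = ct_table(
            [
                ("c1", "control", "Gapdh", 18.0),
                ("c1", "control", "X", 22.0),
                ("c2", "control", "Gapdh", 18.0),
                ("c2", "control", "X", 22.0),
            ]
        )
        fc = delta_delta_ct(table)
        assert np.allclose(fc.per_sample.query("gene == 'X'")["fold_change"], 1.0)

    def test_control_geometric_mean_exactly_one(self):
        params = CtTableParams(
            genes=["Gapdh", "A", "B"],
            groups=["control", "KC"],
            log2_effects={("KC", "A"): 1.3},
            ct_noise_sd=0.4,
            seed=2,
        )
        fc = delta_delta_ct(generate_ct_table(params))
        ctrl = fc.group_summary.query("group == 'control'")
        assert np.allclose(ctrl["geo_mean_fold"], 1.0, rtol=1e-12)

    def test_housekeeping_fold_exactly_one_per_sample(self):
        params = CtTableParams(
            genes=["Gapdh", "A"], groups=["control", "KC"], ct_noise_sd=0.4, seed=3
        )
        fc = delta_delta_ct(generate_ct_table(params))
        hk = fc.per_sample.query("gene == 'Gapdh'")
        assert np.allclose(hk["fold_change"], 1.0, rtol=1e-12)

    def test_downregulation_recovered(self):
        params = CtTableParams(
            genes=["Gapdh", "A"],
            groups=["control", "KC"],
            log2_effects={("KC", "A"): -1.0},
            ct_noise_sd=0.1,
            replicates_per_group=6,
            seed=4,
        )
        fc = delta_delta_ct(generate_ct_table(params))
        kc = fc.group_summary.query("group == 'KC' and gene == 'A'")
        # 3 SE tolerance on the log2 scale: sd(ddCt) ~ 0.1*sqrt(2)*sqrt(1+1/6)
        assert kc["geo_mean_fold"].iloc[0] == pytest.approx(0.5, rel=0.2)

    def test_plate_shift_invariance(self):
        params = CtTableParams(
            genes=["Gapdh", "A"], groups=["control", "KC"], ct_noise_sd=0.3, seed=5
        )
        table = generate_ct_table(params)
        shifted = table.copy()
        mask = shifted["sample_id"] == "KC_2"
        shifted.loc[mask, "ct"] += 1.7  # plate offset on one sample
        a = delta_delta_ct(table)
        b = delta_delta_ct(shifted)
        assert np.allclose(a.per_sample["fold_change"], b.per_sample["fold_change"])

    def test_missing_housekeeping_lists_samples(self):
        table = ct_table(
            [
                ("c1", "control", "Gapdh", 18.0),
                ("c1", "control", "X", 22.0),
                ("c2", "control", "X", 22.0),
            ]
        )
        with pytest.raises(ValueError, match="c2"):
            delta_delta_ct(table)

    def test_duplicate_measurement_rejected(self):
        table = ct_table(
            [
                ("c1", "control", "Gapdh", 18.0),
                ("c1", "control", "Gapdh", 18.1),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            delta_delta_ct(table)


def t_pdf(x, df):
    """Student-t density from its gamma-function formula (independent oracle)."""
    return (
        special.gamma((df + 1) / 2)
        / (np.sqrt(df * np.pi) * special.gamma(df / 2))
        * (1 + x**2 / df) ** (-(df + 1) / 2)
    )


class TestTwoSampleT:
    def test_identical_samples_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, x)
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    @pytest.mark.parametrize("variant,scipy_kw", [("student", True), ("welch", False)])
    def test_matches_scipy_on_random_data(self, variant, scipy_kw):
        rng = np.random.default_rng(10)
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.3, 1.4, rng.integers(3, 12))
            mine = two_sample_t(x, y, variant=variant)
            ref = stats.ttest_ind(x, y, equal_var=scipy_kw)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_welch_on_denaturation_summaries(self):
        """Summary-statistics Welch test on the two thermal-stability groups
        (control 66.8 +/- 0.27 vs ectatic 62.57 +/- 1.11, n=3 each), checked
        against direct numerical integration of the t density."""
        res = two_sample_t_from_summary((66.8, 0.27, 3), (62.57, 1.11, 3), variant="welch")
        p_oracle, _ = integrate.quad(lambda u: t_pdf(u, res.df), abs(res.statistic), np.inf)
        assert res.p_two_sided == pytest.approx(2 * p_oracle, rel=1e-6)
        assert res.p_two_sided < 0.05
        assert res.statistic > 0

    def test_welch_df_equals_student_df_under_equal_var_and_n(self):
        s = two_sample_t_from_summary((1.0, 0.5, 6), (2.0, 0.5, 6), variant="student")
        w = two_sample_t_from_summary((1.0, 0.5, 6), (2.0, 0.5, 6), variant="welch")
        assert w.df == pytest.approx(s.df, abs=1e-12)

    def test_zero_variance_equal_means_undefined(self):
        with pytest.raises(DegenerateStatisticError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestOneWayAnova:
    def test_identical_constants_undefined(self):
        with pytest.raises(DegenerateStatisticError):
            one_way_anova([[2.0, 2.0], [2.0, 2.0]])

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 6)
            f = one_way_anova([x, y])
            t = two_sample_t(x, y, variant="student")
            assert f.statistic == pytest.approx(t.statistic**2, abs=1e-10)
            assert f.p_two_sided == pytest.approx(t.p_two_sided, abs=1e-10)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1, 7) for m in (0.0, 0.4, 1.0)]
        mine = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)
        assert mine.df == (2.0, 18.0)

    def test_shifted_group_detected_with_high_power(self):
        """One group shifted by 3x the noise SD is detected at alpha=0.05
        in nearly all replicates (power simulation)."""
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 6) for _ in range(4)] + [rng.normal(3.0, 1, 6)]
            if one_way_anova(groups).p_two_sided < 0.05:
                hits += 1
        assert hits >= int(0.95 * n_rep)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n="):
            one_way_anova([[1.0, 2.0], [3.0]])


def test_holm_adjustment_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    p = np.array([0.01, 0.04, 0.03, 0.2, 0.5])
    _, ref, _, _ = multipletests(p, method="holm")
    assert np.allclose(holm_adjust(p), ref)
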