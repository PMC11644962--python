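"""Method-agreement statistics: alignment, regression, Bland-Altman,
agreement labels and stratification."""
import numpy as np
import pandas as pd
import pytest

from thermoknee import (AgreementLabel, PairedSeries, ZoneProfile, align,
                        bland_altman, classify_agreement, fit_linear,
                        leg_thermal_match, rmse_vs_trend, stratify)


def profile(times, temps, **kw):
    return ZoneProfile(zone=None, times=np.asarray(times, float),
                       temps_c=np.asarray(temps, float), **kw)


def paired(a, b, times=None):
    a = np.asarray(a, float)
    t = np.arange(len(a), dtype=float) if times is None else times
    return PairedSeries(times=t, a=a, b=np.asarray(b, float))


class TestAlign:
    def test_protocol_grids_give_20_pairs(self):
        t_auto = np.arange(1.0, 601.0)           # 1 Hz automatic
        t_semi = 30.0 * np.arange(1, 21)          # 30 s semi-automatic
        auto = profile(t_auto, 30 + 0.001 * t_auto)
        semi = profile(t_semi, 30 + 0.001 * t_semi)
        pair = align(auto, semi)
        assert len(pair) == 20
        assert pair.n_dropped == 0

    def test_identical_grids_are_exact(self):
        t = np.arange(10.0)
        y = np.sin(t)
        pair = align(profile(t, y), profile(t, y + 1))
        np.testing.assert_array_equal(pair.b, y)

    def test_linear_series_interpolates_exactly(self):
        t_auto = np.arange(0.0, 100.0, 1.0)
        auto = profile(t_auto, 2.0 * t_auto + 1.0)
        t_semi = np.array([10.5, 20.25, 33.75, 80.5])
        semi = profile(t_semi, np.zeros(4))
        pair = align(auto, semi)
        np.testing.assert_allclose(pair.b, 2.0 * t_semi + 1.0, rtol=1e-12)

    def test_points_outside_coverage_dropped(self):
        auto = profile(np.arange(10.0, 50.0), np.zeros(40))
        semi = profile([5.0, 15.0, 25.0, 35.0, 55.0], np.zeros(5))
        pair = align(auto, semi)
        assert len(pair) == 3
        assert pair.n_dropped == 2

    def test_insufficient_overlap_raises(self):
        auto = profile(np.arange(10.0, 12.0), np.zeros(2))
        semi = profile([10.0, 11.0, 20.0, 30.0], np.zeros(4))
        with pytest.raises(ValueError):
            align(auto, semi)


class TestFitLinear:
    def test_identity_and_exact_line(self):
        a = np.arange(20.0)
        r = fit_linear(paired(a, a))
        assert (r.slope, r.intercept, r.r2) == pytest.approx((1.0, 0.0, 1.0))
        r2 = fit_linear(paired(a, 2 * a + 1))
        assert (r2.slope, r2.intercept, r2.r2) == pytest.approx((2.0, 1.0, 1.0))
        assert r2.strong

    def test_matches_independent_ols_oracle(self, rng):
        # oracle: normal-equation arithmetic coded from scratch
        a = rng.normal(31, 1, 20)
        b = 0.9 * a + 0.5 + rng.normal(0, 0.3, 20)
        r = fit_linear(paired(a, b))
        am, bm = a.mean(), b.mean()
        slope = np.sum((a - am) * (b - bm)) / np.sum((a - am) ** 2)
        intercept = bm - slope * am
        ss_res = np.sum((b - intercept - slope * a) ** 2)
        ss_tot = np.sum((b - bm) ** 2)
        assert abs(r.slope - slope) < 1e-10
        assert abs(r.intercept - intercept) < 1e-10
        assert abs(r.r2 - (1 - ss_res / ss_tot)) < 1e-10

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            fit_linear(paired(np.full(5, 30.0), np.arange(5.0)))

    def test_r2_invariant_under_affine_rescaling_of_b(self, rng):
        a = rng.normal(31, 1, 30)
        b = a + rng.normal(0, 0.5, 30)
        r1 = fit_linear(paired(a, b))
        r2 = fit_linear(paired(a, 3.0 * b - 7.0))
        assert r1.r2 == pytest.approx(r2.r2, abs=1e-12)

    def test_strength_threshold(self, rng):
        a = rng.normal(31, 1, 50)
        noise_pair = paired(a, rng.normal(31, 1, 50))
        assert not fit_linear(noise_pair, strength_threshold=0.5).strong


class TestRmseVsTrend:
    def test_linear_and_constant_are_zero(self):
        t = np.arange(100.0)
        assert rmse_vs_trend(profile(t, 2 * t + 3)) < 1e-10
        assert rmse_vs_trend(profile(t, np.full(100, 30.0))) < 1e-10

    def test_noise_level_recovered(self, rng):
        t = np.arange(600.0)
        y = 30 + 0.001 * t + rng.normal(0, 0.1, 600)
        assert rmse_vs_trend(profile(t, y)) == pytest.approx(0.1, rel=0.1)


class TestBlandAltman:
    def test_self_agreement(self):
        a = np.arange(10.0)
        ba = bland_altman(paired(a, a))
        assert ba.bias == ba.sd_diff == ba.loa_low == ba.loa_high == 0.0

    def test_constant_offset(self):
        a = np.arange(10.0)
        ba = bland_altman(paired(a, a + 0.3))
        assert ba.bias == pytest.approx(0.3)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_low == pytest.approx(0.3)
        assert ba.loa_high == pytest.approx(0.3)

    def test_matches_direct_arithmetic_oracle(self, rng):
        a = rng.normal(31, 1, 40)
        b = a + rng.normal(0.2, 0.15, 40)
        ba = bland_altman(paired(a, b))
        d = b - a
        bias = d.mean()
        sd = np.sqrt(np.sum((d - bias) ** 2) / (len(d) - 1))
        assert abs(ba.bias - bias) < 1e-10
        assert abs(ba.sd_diff - sd) < 1e-10
        assert abs(ba.loa_low - (bias - 1.96 * sd)) < 1e-10
        assert abs(ba.loa_high - (bias + 1.96 * sd)) < 1e-10
        assert ba.loa_low <= ba.bias <= ba.loa_high

    def test_swapping_methods_negates_bias_and_limits(self, rng):
        a = rng.normal(31, 1, 40)
        b = a + rng.normal(0.2, 0.15, 40)
        ba = bland_altman(paired(a, b))
        ba_swapped = bland_altman(paired(b, a))
        assert ba_swapped.bias == pytest.approx(-ba.bias, abs=1e-12)
        assert ba_swapped.loa_low == pytest.approx(-ba.loa_high, abs=1e-12)
        assert ba_swapped.loa_high == pytest.approx(-ba.loa_low, abs=1e-12)


class TestAgreementLabels:
    @pytest.mark.parametrize("m1,m2,expected", [
        (True, True, AgreementLabel.AG),
        (False, False, AgreementLabel.NAG),
        (True, False, AgreementLabel.PAG),
        (False, True, AgreementLabel.PAG),
    ])
    def test_truth_table(self, m1, m2, expected):
        assert classify_agreement(m1, m2) is expected

    def test_symmetric_in_methods(self):
        for m1 in (True, False):
            for m2 in (True, False):
                assert classify_agreement(m1, m2) is classify_agreement(m2, m1)

    def test_heating_match_picks_steeper_warming_leg(self):
        t = np.arange(0.0, 600.0, 30.0)
        left = profile(t, 31 + 0.002 * t)    # 0.12 degC/min
        right = profile(t, 31 + 0.001 * t)   # 0.06 degC/min
        assert leg_thermal_match(left, right, "left", "heating_SM") is True
        assert leg_thermal_match(left, right, "right", "heating_SM") is False

    def test_cooling_match_picks_steeper_cooling_leg(self):
        t = np.arange(0.0, 600.0, 30.0)
        left = profile(t, 31 - 0.002 * t)
        right = profile(t, 31 - 0.001 * t)
        assert leg_thermal_match(left, right, "left", "cooling_P") is True

    def test_slope_tie_is_indeterminate(self):
        t = np.arange(0.0, 600.0, 30.0)
        p = profile(t, 31 + 0.001 * t)
        with pytest.warns(UserWarning):
            assert leg_thermal_match(p, p, "left", "heating_SM") is None


class TestStratify:
    def _records(self, rows):
        return pd.DataFrame(rows)

    def test_two_member_group_mean_and_sd(self):
        rows = [
            dict(participant="a", gender="M", bmi=22, asymmetric=False,
                 r2=0.6, strong=True),
            dict(participant="b", gender="M", bmi=23, asymmetric=False,
                 r2=0.8, strong=True),
        ]
        out = stratify(self._records(rows))["r2_by_group"]
        assert out.loc["M", "mean_r2"] == pytest.approx(0.7)
        assert out.loc["M", "sd_r2"] == pytest.approx(np.std([0.6, 0.8], ddof=1))

    def test_single_member_group_sd_undefined(self):
        rows = [dict(participant="a", gender="F", bmi=22, asymmetric=True,
                     r2=0.9, strong=True)]
        out = stratify(self._records(rows))["r2_by_group"]
        assert np.isnan(out.loc["F", "sd_r2"])
        assert "M" not in out.index  # empty group absent, not zero

    def test_matches_groupby_oracle(self, rng):
        rows = []
        for i in range(20):
            rows.append(dict(
                participant=f"p{i}", gender="M" if i % 3 else "F",
                bmi=float(rng.uniform(19, 30)), asymmetric=bool(i % 2),
                r2=float(rng.uniform(0, 1)), strong=bool(rng.random() < 0.7),
                label_heating="AG", label_cooling="NAG"))
        df = self._records(rows)
        out = stratify(df, bmi_cutoff=25.0)
        strong = df[df.strong]
        for gender in ("M", "F"):
            grp = strong[strong.gender == gender]
            if len(grp):
                assert out["r2_by_group"].loc[gender, "mean_r2"] == \
                    pytest.approx(grp.r2.mean())
        low = strong[strong.bmi < 25.0]
        assert out["r2_by_group"].loc["bmi<25", "n"] == len(low)
        counts = out["label_counts"]
        m_ag = counts[(counts["mode"] == "heating") & (counts.gender == "M")
                      & (counts.label == "AG")]["count"].iloc[0]
        assert m_ag == df.drop_duplicates("participant").gender.value_counts()["M"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            stratify(pd.DataFrame({"participant": ["a"]}))
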