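import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import fisher_two_sided, grid_cox_mle, pl_median, product_limit
from irskit.survival import (
    PowerSpec,
    cmh_ratio_test,
    fisher_frequency_compare,
    fit_cox,
    km_estimate,
    lrt_nested,
    overlap_weight_analysis,
    power_two_group_cox,
    rmst_compare,
    schoenfeld_ph_check,
)


def cox_df(durations, events, group):
    return pd.DataFrame({"d": durations, "e": events, "z": group})


class TestKaplanMeier:
    def test_point_mass_median(self):
        s = km_estimate([5, 5, 5, 5], [1, 1, 1, 1])
        assert s.median == 5 and s.n_events == 4

    def test_matches_hand_product_limit(self):
        dur = [2, 3, 4, 6, 9]
        ev = [1, 1, 0, 1, 1]
        s = km_estimate(dur, ev)
        hand = dict(product_limit(dur, ev))
        curve = s.curve.set_index("time")["survival"]
        for t, surv in hand.items():
            assert curve.loc[t] == pytest.approx(surv, abs=1e-12)
        assert s.median == pl_median(dur, ev) == 6

    def test_exponential_median_closed_form(self, rng):
        lam = 0.25
        t = rng.exponential(1 / lam, size=4000)
        s = km_estimate(t, np.ones_like(t))
        assert s.median == pytest.approx(np.log(2) / lam, rel=0.06)

    def test_all_censored_median_not_reached(self):
        s = km_estimate([3, 4, 5], [0, 0, 0])
        assert np.isinf(s.median)

    def test_invariant_under_duplication(self):
        dur = [2, 3, 4, 6, 9]
        ev = [1, 1, 0, 1, 1]
        a = km_estimate(dur, ev)
        b = km_estimate(dur * 2, ev * 2)
        pd.testing.assert_frame_equal(a.curve, b.curve)

    def test_positive_durations_required(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestCox:
    def test_exchangeable_groups_give_null_hr(self):
        # two groups carrying identical survival data
        dur = [1, 2, 3, 4, 5, 6] * 2
        ev = [1, 1, 0, 1, 1, 0] * 2
        z = [0] * 6 + [1] * 6
        fit = fit_cox(cox_df(dur, ev, z), "d", "e", ["z"], term="z")
        assert fit.ahr == pytest.approx(1.0, abs=1e-6)

    def test_six_record_grid_oracle(self):
        dur = [1.0, 2.0, 2.0, 3.0, 5.0, 7.0]
        ev = [1, 1, 1, 0, 1, 1]
        z = [1, 0, 1, 1, 0, 0]
        fit = fit_cox(cox_df(dur, ev, z), "d", "e", ["z"], term="z")
        beta_oracle = grid_cox_mle(dur, ev, z)
        assert np.log(fit.ahr) == pytest.approx(beta_oracle, abs=1e-3)

    def test_random_small_datasets_match_oracle(self, rng):
        trials = 0
        while trials < 150:
            n = int(rng.integers(4, 9))
            dur = rng.integers(1, 10, size=n).astype(float)
            ev = rng.uniform(size=n) < 0.7
            z = rng.integers(0, 2, size=n)
            if ev.sum() < 2 or len(set(z[ev])) < 2 or z.std() == 0:
                continue
            beta_oracle = grid_cox_mle(dur, ev, z)
            if abs(beta_oracle) > 2.5:
                continue  # near-separation; MLE unstable by design
            fit = fit_cox(cox_df(dur, ev, z), "d", "e", ["z"], term="z")
            if fit.penalized:
                continue
            assert np.log(fit.ahr) == pytest.approx(beta_oracle, abs=1e-3)
            trials += 1

    def test_time_rescaling_leaves_hr_unchanged(self, rng):
        n = 120
        z = rng.integers(0, 2, n)
        t = rng.exponential(1.0, n) * np.where(z == 1, 2.0, 1.0)
        c = rng.uniform(0.5, 4, n)
        dur, ev = np.minimum(t, c), t <= c
        f1 = fit_cox(cox_df(dur, ev, z), "d", "e", ["z"], term="z")
        f2 = fit_cox(cox_df(dur * 12, ev, z), "d", "e", ["z"], term="z")
        assert f1.ahr == pytest.approx(f2.ahr, rel=1e-8)
        k1 = km_estimate(dur, ev)
        k2 = km_estimate(dur * 12, ev)
        assert k2.median == pytest.approx(12 * k1.median, rel=1e-12)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(cox_df([1, 2, 3], [1, 0, 0], [0, 1, 0]), "d", "e", ["z"], "z")


class TestNestedLRT:
    def _fits(self, rng):
        n = 100
        z = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) * np.where(z == 1, 1.8, 1.0)
        df = pd.DataFrame({"d": t, "e": np.ones(n, bool), "z": z, "x": x})
        full = fit_cox(df, "d", "e", ["z", "x"], term="z")
        reduced = fit_cox(df, "d", "e", ["z"], term="z")
        return full, reduced

    def test_identical_models_give_p_one(self, rng):
        full, _ = self._fits(rng)
        stat, df, p = lrt_nested(full, full)
        assert stat == 0 and p == 1.0

    def test_chi2_quantile(self):
        # 2*delta-loglik of 3.841 on 1 df sits at the 5% point
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_nested_p_matches_chi2(self, rng):
        full, reduced = self._fits(rng)
        stat, df, p = lrt_nested(full, reduced)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)

    def test_mismatched_records_rejected(self, rng):
        full, _ = self._fits(rng)
        _, other_reduced = self._fits(rng)
        with pytest.raises(ValueError):
            lrt_nested(full, other_reduced)


class TestRMST:
    def test_rectangle(self):
        groups = {"a": (np.array([5.0] * 4), np.array([1, 1, 1, 1]))}
        out = rmst_compare(groups, tau=10)
        assert out.loc["a", "rmst"] == pytest.approx(5.0)

    def test_exponential_closed_form(self, rng):
        lam, tau = 0.4, 4.0
        t = rng.exponential(1 / lam, size=6000)
        out = rmst_compare({"a": (t, np.ones_like(t))}, tau=tau)
        assert out.loc["a", "rmst"] == pytest.approx(
            (1 - np.exp(-lam * tau)) / lam, rel=0.03
        )

    def test_identical_groups_zero_difference(self):
        d = np.array([2.0, 3, 5, 7, 11])
        e = np.array([1, 1, 0, 1, 1])
        out = rmst_compare({"a": (d, e), "b": (d, e)})
        assert out.loc["b - a", "rmst"] == pytest.approx(0.0, abs=1e-12)

    def test_tau_beyond_followup_names_group(self):
        groups = {"short": (np.array([1.0, 2.0]), np.array([1, 0])),
                  "long": (np.array([8.0, 9.0]), np.array([1, 1]))}
        with pytest.raises(ValueError, match="short"):
            rmst_compare(groups, tau=5.0)


class TestSchoenfeld:
    def test_strong_time_varying_effect_rejected(self, rng):
        # hazard effect reverses midway: a gross PH violation
        n = 400
        z = rng.integers(0, 2, n)
        # treated hazard 0.5x before t=1, 3x after; control constant
        early = rng.exponential(1.0, n) * np.where(z == 1, 2.0, 1.0)
        late = 1.0 + rng.exponential(1.0, n) * np.where(z == 1, 1 / 3.0, 1.0)
        t = np.where(early < 1.0, early, late)
        df = cox_df(t, np.ones(n, bool), z)
        fit = fit_cox(df, "d", "e", ["z"], term="z")
        table = schoenfeld_ph_check(fit)
        assert table.loc["z", "p"] < 0.01
        assert table.loc["GLOBAL", "p"] < 0.01

    def test_degenerate_input_rejected(self):
        fit = fit_cox(cox_df([1, 2, 3, 4], [1, 1, 0, 0], [0, 1, 0, 1]),
                      "d", "e", ["z"], "z")
        fit.n_events = 1
        with pytest.raises(ValueError):
            schoenfeld_ph_check(fit)


class TestPower:
    def test_study_design_value(self):
        # n=180, HR 0.5, 50% events, 1:1, alpha .05 -> ~90% power
        assert power_two_group_cox(PowerSpec(180, 0.5, 0.5)) == pytest.approx(
            0.90, abs=0.01
        )

    def test_null_hr_gives_one_sided_tail(self):
        assert power_two_group_cox(PowerSpec(180, 1.0, 0.5)) == pytest.approx(
            0.025, abs=1e-9
        )

    def test_monotonicity_sweep(self):
        base = PowerSpec(100, 0.6, 0.4)
        in_n = [power_two_group_cox(PowerSpec(n, 0.6, 0.4)) for n in (50, 100, 200, 400)]
        assert in_n == sorted(in_n)
        in_hr = [power_two_group_cox(PowerSpec(100, hr, 0.4)) for hr in (0.8, 0.6, 0.4)]
        assert in_hr == sorted(in_hr)
        in_ev = [power_two_group_cox(PowerSpec(100, 0.6, r)) for r in (0.2, 0.5, 0.9)]
        assert in_ev == sorted(in_ev)
        assert power_two_group_cox(base) == pytest.approx(
            power_two_group_cox(PowerSpec(100, 1 / 0.6, 0.4)), abs=1e-12
        )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PowerSpec(100, -0.5, 0.5)
        with pytest.raises(ValueError):
            PowerSpec(100, 0.5, 0.0)


class TestCMH:
    def test_single_stratum_equals_cross_product(self):
        or_mh, ci, p = cmh_ratio_test([np.array([[13, 5], [14, 45]])])
        assert or_mh == pytest.approx(585 / 70, abs=1e-12)
        assert ci[0] < or_mh < ci[1]

    def test_null_table(self):
        or_mh, _, p = cmh_ratio_test([np.array([[10, 10], [10, 10]])])
        assert or_mh == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_two_strata_pooling(self):
        t1 = np.array([[10, 5], [6, 12]])
        t2 = np.array([[8, 9], [7, 14]])
        or_mh, _, _ = cmh_ratio_test([t1, t2])
        # Mantel-Haenszel hand formula
        num = sum(t[0, 0] * t[1, 1] / t.sum() for t in (t1, t2))
        den = sum(t[0, 1] * t[1, 0] / t.sum() for t in (t1, t2))
        assert or_mh == pytest.approx(num / den, abs=1e-12)

    def test_degenerate_stratum_dropped(self):
        good = np.array([[13, 5], [14, 45]])
        empty_margin = np.array([[0, 0], [5, 7]])
        with pytest.warns(UserWarning, match="degenerate"):
            or_mh, _, _ = cmh_ratio_test([good, empty_margin])
        assert or_mh == pytest.approx(585 / 70, abs=1e-12)


class TestFisher:
    def test_matches_enumeration_oracle(self):
        out = fisher_frequency_compare({"ref": (11, 14), "g": (1, 10)}, "ref")
        assert out.loc["g", "p_value"] == pytest.approx(
            fisher_two_sided(1, 9, 11, 3), abs=1e-12
        )

    def test_identical_proportions_large_n(self):
        out = fisher_frequency_compare({"ref": (200, 1000), "g": (200, 1000)}, "ref")
        assert out.loc["g", "p_value"] > 0.95

    def test_reference_vs_itself(self):
        out = fisher_frequency_compare({"ref": (5, 10)}, "ref")
        assert out.loc["ref", "p_value"] == 1.0

    def test_zero_total_group_skipped(self):
        with pytest.warns(UserWarning, match="zero-total"):
            out = fisher_frequency_compare({"ref": (5, 10), "g": (0, 0)}, "ref")
        assert "g" not in out.index


def _confounded_cohort(rng, n=300, beta_treat=-0.7):
    x1 = rng.normal(0, 1, n)
    x2 = rng.binomial(1, 0.4, n).astype(float)
    logit = 0.8 * x1 - 1.0 * x2 + 0.3
    z = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
    lam = np.exp(0.5 * x1 + beta_treat * z)
    t = rng.exponential(1 / lam)
    c = rng.uniform(0.2, 3, n)
    return pd.DataFrame(
        {"arm": np.where(z, "T", "C"), "x1": x1, "x2": x2,
         "dur": np.minimum(t, c), "ev": t <= c}
    )


class TestOverlapWeighting:
    def test_exact_mean_balance(self, rng):
        df = _confounded_cohort(rng)
        res = overlap_weight_analysis(df, "arm", ["x1", "x2"], "dur", "ev")
        assert res.balance["abs_diff"].max() < 1e-8

    def test_no_confounding_limit(self, rng):
        df = _confounded_cohort(rng, n=500)
        df["arm"] = np.where(rng.uniform(size=len(df)) < 0.5, "T", "C")  # randomized
        res = overlap_weight_analysis(df, "arm", ["x1", "x2"], "dur", "ev")
        assert np.log(res.cox.ahr) == pytest.approx(
            np.log(res.unweighted_cox.ahr), abs=0.12
        )

    def test_weighting_reduces_confounding_bias(self, rng):
        truth = -0.7
        err_w, err_u = [], []
        for _ in range(20):
            df = _confounded_cohort(rng)
            res = overlap_weight_analysis(df, "arm", ["x1", "x2"], "dur", "ev")
            err_w.append(abs(np.log(res.cox.ahr) - truth))
            err_u.append(abs(np.log(res.unweighted_cox.ahr) - truth))
        assert np.mean(err_w) < np.mean(err_u)

    def test_requires_two_arms(self, rng):
        df = _confounded_cohort(rng)
        df["arm"] = "T"
        with pytest.raises(ValueError):
            overlap_weight_analysis(df, "arm", ["x1"], "dur", "ev")
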