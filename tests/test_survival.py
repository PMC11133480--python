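"""KM / log-rank / Cox / Mann-Whitney / AE / PK / 3+3 escalation."""

import math

import numpy as np
import pandas as pd
import pytest

from cxsurv.survival import (EscalationState, ae_summary, cox_hr,
                             escalation_decision, km_estimate, logrank_test,
                             mann_whitney, pk_summary)
from cxsurv.synthetic import SynthConfig, generate_pk_series

from conftest import survival_df
from oracles import escalation_oracle, km_oracle, logrank_oracle


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = list(range(1, 10))
        curve = km_estimate(survival_df(times, [True] * 9))
        assert curve.median == 5
        expected = km_oracle(times, [True] * 9)
        for t, s in expected:
            assert curve.survival_at(t) == pytest.approx(s)
        # steps of exactly 1/9
        assert curve.survival_at(1) == pytest.approx(8 / 9)

    def test_six_month_rate(self):
        # 6 of 10 events before day 183, no earlier censoring -> S(183)=0.40
        times = [30, 60, 90, 120, 150, 180, 200, 220, 250, 300]
        events = [True] * 6 + [False] * 4
        curve = km_estimate(survival_df(times, events), query_day=183)
        assert curve.survival_at_query == pytest.approx(0.40)

    def test_single_censored_record(self):
        curve = km_estimate(survival_df([100.0], [False]))
        assert curve.all_censored
        assert math.isinf(curve.median) or math.isnan(curve.median)
        assert curve.survival_at(365) == 1.0

    def test_random_agreement_with_hand_product_limit(self):
        rng = np.random.default_rng(2)
        times = rng.integers(1, 50, size=30).astype(float)
        events = rng.random(30) < 0.7
        curve = km_estimate(survival_df(list(times), list(events)))
        for t, s in km_oracle(list(times), list(events)):
            assert curve.survival_at(t) == pytest.approx(s)


class TestLogrank:
    def test_identical_groups(self):
        g = survival_df([5, 10, 15, 20], [True] * 4)
        chi2, p = logrank_test(g, g.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_worked_dataset_matches_risk_tables(self):
        a = survival_df([2, 4, 6], [True] * 3)
        b = survival_df([10, 12, 14], [True] * 3)
        chi2, _ = logrank_test(a, b)
        assert chi2 == pytest.approx(
            logrank_oracle([2, 4, 6], [1, 1, 1], [10, 12, 14], [1, 1, 1]))

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(1)
        ta = rng.exponential(100, 15)
        tb = rng.exponential(150, 15)
        ea = rng.random(15) < 0.8
        eb = rng.random(15) < 0.8
        chi2_raw, _ = logrank_test(survival_df(ta, ea), survival_df(tb, eb))
        chi2_log, _ = logrank_test(survival_df(np.log1p(ta), ea),
                                   survival_df(np.log1p(tb), eb))
        assert chi2_raw == pytest.approx(chi2_log)

    def test_permutation_calibration(self):
        """Label shuffling of a null cohort rejects ~5% of the time."""
        rng = np.random.default_rng(7)
        times = rng.exponential(174, 40)
        events = rng.random(40) < 0.9
        df = survival_df(list(times), list(events))
        rejections = 0
        n_shuffles = 1000
        for _ in range(n_shuffles):
            labels = rng.permutation(np.repeat([0, 1], 20))
            _, p = logrank_test(df[labels == 0], df[labels == 1])
            rejections += p < 0.05
        assert 0.03 <= rejections / n_shuffles <= 0.07


class TestCox:
    def test_self_comparison_gives_unit_hr(self):
        df = survival_df([5, 10, 15, 20, 30, 40], [True] * 6)
        doubled = pd.concat([df, df], ignore_index=True)
        res = cox_hr(doubled, [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, 40)
        g = np.repeat([0, 1], 20)
        t[g == 1] *= 2
        df = survival_df(list(t), [True] * 40)
        res = cox_hr(df, g)
        res_swapped = cox_hr(df, 1 - g)
        assert res.hr == pytest.approx(1 / res_swapped.hr, rel=1e-6)

    def test_simulated_hr_recovery(self):
        """True HR 0.5, n=200: estimate within [0.35, 0.72] in >=90% of seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            g = np.repeat([0, 1], 100)
            lam = np.where(g == 1, 0.5, 1.0) / 100.0
            t = rng.exponential(1 / lam)
            df = survival_df(list(t), [True] * 200)
            hr = cox_hr(df, g).hr
            hits += 0.35 <= hr <= 0.72
        assert hits >= 0.90 * n_seeds


class TestMannWhitney:
    def test_identical_multisets_exact_p_one(self):
        u, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    def test_full_separation_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)   # 2 of 20 arrangements as extreme

    def test_shift_invariance(self):
        x = [1.0, 5.0, 3.0]
        y = [2.0, 8.0, 4.0, 9.0]
        u1, _ = mann_whitney(x, y)
        u2, _ = mann_whitney([v + 7 for v in x], [v + 7 for v in y])
        assert u1 == u2

    def test_exact_close_to_asymptotic_moderate_n(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.5, 1, 6)
        _, p_ex = mann_whitney(x, y, method="exact")
        _, p_as = mann_whitney(x, y, method="asymptotic")
        assert p_ex == pytest.approx(p_as, abs=0.08)


class TestAeSummary:
    def make_listing(self, grade_counts, rel_counts):
        rows = []
        for g, c in grade_counts.items():
            rows += [{"patient_id": "x", "term": "t", "grade": g,
                      "relationship": "none"}] * c
        df = pd.DataFrame(rows)
        rels = []
        for r, c in rel_counts.items():
            rels += [r] * c
        df["relationship"] = rels
        return df

    def test_trial_style_tabulation(self):
        grades = {1: 87, 2: 59, 3: 24, 4: 1}
        rels = {"none": 81, "gbm": 43, "rt": 20, "rt_gbm": 6, "drug": 13,
                "drug_gbm": 4, "drug_rt": 2, "drug_rt_gbm": 2}
        s = ae_summary(self.make_listing(grades, rels))
        assert s.total == 171
        assert s.grade_pct(1) == 50.9
        assert s.drug_related_sole_pct() == 7.6

    def test_percentages_rederivable_and_sum(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "patient_id": "p", "term": "t",
            "grade": rng.integers(1, 6, 50),
            "relationship": rng.choice(["none", "drug", "rt"], 50)})
        s = ae_summary(df)
        assert sum(s.by_grade.values()) == s.total
        for g in range(1, 6):
            expect = round(100.0 * s.by_grade[g] / s.total, 1)
            assert abs(s.grade_pct(g) - expect) <= 0.05

    def test_empty_listing(self):
        s = ae_summary(pd.DataFrame(columns=["patient_id", "term", "grade",
                                             "relationship"]))
        assert s.total == 0
        assert math.isnan(s.grade_pct(1))

    def test_unknown_category_rejected(self):
        df = pd.DataFrame([{"patient_id": "p", "term": "t", "grade": 1,
                            "relationship": "martian"}])
        with pytest.raises(ValueError, match="martian"):
            ae_summary(df)

    def test_bad_grade_rejected(self):
        df = pd.DataFrame([{"patient_id": "p", "term": "t", "grade": 7,
                            "relationship": "none"}])
        with pytest.raises(ValueError, match="grade"):
            ae_summary(df)


class TestPkSummary:
    def test_default_series_exceeds_threshold(self):
        cfg = SynthConfig()
        series = generate_pk_series(cfg, np.arange(0, 29, 3.5), dose_mg=200)
        s = pk_summary(series)
        assert s["exceeds_threshold"]
        assert s["drug_over_target"]

    def test_week_one_near_steady_state(self):
        cfg = SynthConfig()
        series = generate_pk_series(cfg, [0, 3.5, 7, 10.5, 14, 21, 28])
        c7 = series.loc[series["day"] == 7, "drug_um"].iloc[0]
        plateau = series["drug_um"].iloc[-1]
        assert c7 / plateau >= 0.9

    def test_constant_series_steady_from_day_one(self):
        df = pd.DataFrame({"day": [0, 5, 10, 15, 20], "drug_um": [2.0] * 5})
        assert pk_summary(df)["steady_state_day"] == 0.0

    def test_nonmonotone_grid_rejected(self):
        df = pd.DataFrame({"day": [0, 10, 5, 15, 20], "drug_um": [1] * 5})
        with pytest.raises(ValueError, match="increasing"):
            pk_summary(df)

    def test_too_short_series_rejected(self):
        df = pd.DataFrame({"day": [0, 1, 2, 3], "drug_um": [1] * 4})
        with pytest.raises(ValueError):
            pk_summary(df)


class TestEscalation:
    def test_full_decision_table_matches_protocol(self):
        for level in range(3):
            for n in range(7):
                for d in range(n + 1):
                    got = escalation_decision(EscalationState(level, n, d))
                    want = escalation_oracle(level, 3, n, d)
                    assert got == want, (level, n, d)

    def test_top_level_tolerated_declares_rp2d(self):
        assert escalation_decision(EscalationState(2, 3, 0)) == "declare_RP2D"

    def test_one_dlt_expands(self):
        assert escalation_decision(EscalationState(0, 3, 1)) == "expand_same_level"

    def test_two_of_six_stops(self):
        assert escalation_decision(EscalationState(1, 6, 2)) == "stop_declare_MTD"

    def test_protocol_violation(self):
        with pytest.raises(ValueError, match="protocol"):
            EscalationState(0, 7, 0)
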