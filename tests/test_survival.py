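import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from ilcgate.io_cohort import ClinicalRecord
from ilcgate.survival import (
    build_design,
    cox_fit,
    km_estimate,
    logrank_test,
    survival_report,
)

from conftest import make_records


class TestKaplanMeier:
    def test_three_subject_hand_computation(self):
        records = make_records([1, 2, 3], [1, 1, 0])
        curves = km_estimate(records, [0, 0, 0], labels=("all", "unused"))
        c = curves["all"]
        np.testing.assert_array_equal(c.times, [1, 2])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3])
        assert c.survival_at(3) == pytest.approx(1 / 3)

    def test_no_events_flat_one(self):
        records = make_records([5, 6, 7], [0, 0, 0])
        c = km_estimate(records, [0, 0, 0])["low"]
        assert c.times.size == 0
        assert c.survival_at(100) == 1.0

    def test_full_attrition(self):
        records = make_records([1, 2, 3, 4], [1, 1, 1, 1])
        c = km_estimate(records, [0] * 4)["low"]
        assert c.survival[-1] == 0.0

    def test_common_event_time_binomial_fraction(self):
        # 10 subjects, 3 die at t=1, rest censored just after
        records = make_records([1] * 3 + [1.5] * 7, [1] * 3 + [0] * 7)
        c = km_estimate(records, [0] * 10)["low"]
        assert c.survival_at(1) == pytest.approx(0.7)

    def test_absent_group_omitted(self):
        records = make_records([1, 2], [1, 1])
        curves = km_estimate(records, [0, 0])
        assert set(curves) == {"low"}

    def test_no_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])

    def test_invalid_record_rejected(self):
        bad = [ClinicalRecord("p", time=None, event=1)]
        with pytest.raises(ValueError, match="valid"):
            km_estimate(bad, [0])

    def test_median_ordering_at_true_hr_half(self):
        rng = np.random.default_rng(0)
        n = 1000
        group = rng.integers(0, 2, size=n)
        lam = 0.01 * 0.5 ** group
        t = rng.exponential(1 / lam)
        records = make_records(t, np.ones(n, dtype=int))
        curves = km_estimate(records, group)
        assert curves["high"].median_time > curves["low"].median_time


class TestLogRank:
    def test_mirrored_groups_null(self):
        records = make_records([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        res = logrank_test(records, [0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_brute_force(self):
        times = [2, 4, 5, 6, 8, 9]
        events = [1, 1, 0, 1, 1, 1]
        group = [0, 1, 0, 1, 0, 1]
        res = logrank_test(make_records(times, events), group)
        # independent accumulation over event times
        t_arr, e_arr, g_arr = map(np.array, (times, events, group))
        O = E = V = 0.0
        for t in sorted(set(t_arr[e_arr == 1])):
            at = t_arr >= t
            n, n1 = at.sum(), (at & (g_arr == 1)).sum()
            dying = (t_arr == t) & (e_arr == 1)
            d, d1 = dying.sum(), (dying & (g_arr == 1)).sum()
            O += d1
            E += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert res.statistic == pytest.approx((O - E) ** 2 / V, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(500):
            n = 60
            t = rng.exponential(100.0, size=n)
            c = rng.exponential(200.0, size=n)
            obs = np.minimum(t, c)
            ev = (t <= c).astype(int)
            group = rng.integers(0, 2, size=n)
            if group.sum() in (0, n):
                continue
            pvals.append(logrank_test(make_records(obs, ev), group).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_label_exchange_invariant(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10, size=30)
        ev = rng.integers(0, 2, size=30)
        group = rng.integers(0, 2, size=30)
        records = make_records(t, ev)
        a = logrank_test(records, group).statistic
        b = logrank_test(records, 1 - group).statistic
        assert a == pytest.approx(b, abs=1e-12)


def _cox_partial_loglik(beta: float, time, event, group) -> float:
    """Brute-force partial likelihood for one binary covariate, no ties."""
    ll = 0.0
    for i in np.where(event == 1)[0]:
        at_risk = time >= time[i]
        ll += beta * group[i] - np.log(np.sum(np.exp(beta * group[at_risk])))
    return ll


class TestCox:
    def test_four_subject_grid_search_oracle(self):
        time = np.array([2.0, 5.0, 7.0, 11.0])
        event = np.array([1, 1, 1, 1])
        group = np.array([1.0, 0.0, 1.0, 0.0])
        design = pd.DataFrame({"time": time, "event": event, "grp": group})
        fit = cox_fit(design)
        grid = np.arange(-5, 5, 1e-4)
        lls = [_cox_partial_loglik(b, time, event, group) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.table.loc["grp", "coef"] == pytest.approx(beta_grid,
                                                             abs=1e-3)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            n = 1000
            t = rng.exponential(100, size=n)
            cov = rng.normal(size=n)
            design = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int),
                                   "x": cov})
            beta = cox_fit(design).table.loc["x", "coef"]
            hits += abs(beta) <= 0.15
        assert hits >= 19

    def test_recovers_known_hazard_ratio(self):
        rng = np.random.default_rng(12)
        target = np.log(0.72)
        hits = 0
        for _ in range(20):
            n = 2000
            group = rng.integers(0, 2, size=n)
            lam = 0.01 * np.exp(target * group)
            t = rng.exponential(1 / lam)
            c = rng.exponential(1 / 0.0043, size=n)  # ≈30% censoring
            obs = np.minimum(t, c)
            ev = (t <= c).astype(int)
            design = pd.DataFrame({"time": obs, "event": ev,
                                   "grp": group.astype(float)})
            beta = cox_fit(design).table.loc["grp", "coef"]
            hits += abs(beta - target) <= 0.1
        assert hits >= 18

    def test_group_relabel_flips_sign(self):
        rng = np.random.default_rng(13)
        n = 200
        group = rng.integers(0, 2, size=n)
        t = rng.exponential(50 * (1 + group))
        design = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int),
                               "grp": group.astype(float)})
        flipped = design.assign(grp=1.0 - design["grp"])
        b1 = cox_fit(design).table.loc["grp", "coef"]
        b2 = cox_fit(flipped).table.loc["grp", "coef"]
        assert b1 == pytest.approx(-b2, abs=1e-6)

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(17)
        n = 300
        group = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(100, size=n)
        design = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int),
                               "grp": group})
        row = cox_fit(design).table.loc["grp"]
        assert row["hr_lo"] <= row["hr"] <= row["hr_hi"]
        assert row["hr"] > 0

    def test_small_n_flagged(self):
        design = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 0],
            "a": [0.0, 1.0, 0.5, 0.2], "b": [1.0, 0.0, 0.3, 0.9]})
        fit = cox_fit(design)
        assert any("complete cases" in f for f in fit.flags)


class TestDesign:
    def test_complete_case_dropping(self):
        records = [
            ClinicalRecord("a", 10.0, 1, age=60.0, sex="male",
                           node_positive=1, stage=2),
            ClinicalRecord("b", 20.0, 0, age=None, sex="female",
                           node_positive=0, stage=1),
            ClinicalRecord("c", 30.0, 1, age=70.0, sex="female",
                           node_positive=0, stage=3),
        ]
        design = build_design(records, {"a": 1, "b": 0, "c": 0},
                              ["age", "ilc2"])
        assert len(design) == 2  # record b dropped: missing age
        assert design["age"].tolist() == [6.0, 7.0]  # decades

    def test_encodings(self):
        records = [ClinicalRecord("a", 10.0, 1, age=55.0, sex="male",
                                  node_positive=1, stage=4),
                   ClinicalRecord("b", 9.0, 0, age=45.0, sex="female",
                                  node_positive=0, stage=1)]
        d = build_design(records, {"a": 1, "b": 0},
                         ["age", "sex", "node", "stage", "ilc2"])
        assert d.loc[0, "sex"] == 1.0 and d.loc[1, "sex"] == 0.0
        assert d.loc[0, "stage"] == 4.0
        assert d.loc[0, "ilc2"] == 1.0

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_design([], None, ["weight"])


class TestReport:
    def test_counts_and_sections(self):
        rng = np.random.default_rng(3)
        n = 80
        group = rng.integers(0, 2, size=n)
        t = rng.exponential(100 * (1 + group))
        records = [ClinicalRecord(f"p{i}", float(t[i]), 1,
                                  age=float(rng.normal(65, 8)))
                   for i in range(n)]
        calls = {f"p{i}": int(group[i]) for i in range(n)}
        rep = survival_report(records, calls, covariates=("age", "ilc2"))
        assert rep["n_valid_survival"] == n
        assert rep["n_ilc2_high"] == int(group.sum())
        assert "logrank" in rep and rep["logrank"]["p_value"] <= 1.0
        cov_names = [r["covariate"] for r in rep["cox"]["table"]]
        assert "ilc2" in cov_names
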