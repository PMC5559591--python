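"""Dichotomization, Kaplan-Meier, log-rank and Cox models against oracles."""

import numpy as np
import pandas as pd
import pytest

from necrofract.errors import ParameterError
from necrofract.survival import (
    RISK_INDICATORS,
    cox_fit,
    cox_partial_loglik,
    dichotomize_cohort,
    km_estimate,
    logrank_test,
    multivariate_table,
    univariate_table,
)
from necrofract.synthetic import CohortSpec, make_cohort


def toy_cohort(n=60, hr_lac=1.0, hr_fd=1.0, seed=0, censor=0.2, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    feats = pd.DataFrame(
        {"fd": rng.uniform(1.3, 1.8, n), "lacunarity": rng.uniform(0.2, 0.8, n)}
    )
    spec = CohortSpec(
        n_patients=n, hr_lacunarity=hr_lac, hr_fd=hr_fd, censor_rate=censor, seed=seed
    )
    return make_cohort(spec, feats, lac_cut=0.5)


class TestDichotomize:
    def test_boundary_values_follow_printed_inequalities(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a"],
                "age": [50],
                "kps": [80],
                "volume_cm3": [50.0],
                "gtr_flag": [False],
                "rt_tmz_flag": [True],
                "fd": [1.56],
                "lacunarity": [0.46],
                "pfs_time": [100.0],
                "pfs_event": [True],
                "os_time": [200.0],
                "os_event": [True],
            }
        )
        out = dichotomize_cohort(df)
        row = out.iloc[0]
        assert row["fd_low"] == 0          # strict fd < 1.56
        assert row["lac_high"] == 0        # strict lacunarity > 0.46
        assert row["age_high"] == 1        # age >= 50
        assert row["kps_low"] == 0         # strict kps < 80
        assert row["vol_high"] == 1        # volume >= 50
        assert row["subtotal_resection"] == 1

    def test_missing_covariate_excluded(self, caplog):
        df = toy_cohort(10)
        df.loc[3, "kps"] = np.nan
        out = dichotomize_cohort(df)
        assert len(out) == 9

    def test_missing_column_rejected(self):
        with pytest.raises(ParameterError):
            dichotomize_cohort(pd.DataFrame({"age": [50]}))


def km_oracle(times, events, t):
    """Closed-form product over risk sets, brute force."""
    s = 1.0
    for tt in sorted(set(np.asarray(times)[np.asarray(events, bool)])):
        if tt > t:
            break
        at_risk = (np.asarray(times) >= tt).sum()
        deaths = ((np.asarray(times) == tt) & np.asarray(events, bool)).sum()
        s *= 1.0 - deaths / at_risk
    return s


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([5, 8, 12], [True, True, True])
        assert km(8) == pytest.approx(1 / 3)
        assert km(0) == pytest.approx(1.0)

    def test_all_censored_flat_at_one(self):
        km = km_estimate([3, 6, 9], [False, False, False])
        assert km(100) == pytest.approx(1.0)

    def test_single_subject(self):
        km = km_estimate([4.0], [True])
        assert km(3.9) == pytest.approx(1.0)
        assert km(4.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        times = rng.integers(1, 10, n).astype(float)  # forces ties
        events = rng.random(n) < 0.7
        if not events.any():
            events[0] = True
        km = km_estimate(times, events)
        for t in np.unique(times):
            assert km(t) == pytest.approx(km_oracle(times, events, t))

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [2, 4, 6, 8]
        events = [True, True, False, True]
        stat, p = logrank_test(times + times, events + events, [0] * 4 + [1] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # groups A={1,2} B={3,4}, all events; walk the four risk sets by hand
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, True, True])
        group = np.array([1, 1, 0, 0])
        o_a, e_a, var = 2.0, 0.0, 0.0
        for t in times:
            risk = times >= t
            n = risk.sum()
            n_a = (risk & (group == 1)).sum()
            d = 1
            e_a += d * n_a / n
            if n > 1:
                var += d * n_a * (n - n_a) * (n - d) / (n**2 * (n - 1))
        expected_stat = (o_a - e_a) ** 2 / var
        stat, _ = logrank_test(times, events, group)
        assert stat == pytest.approx(expected_stat, rel=1e-10)

    def test_group_swap_invariance(self):
        cohort = toy_cohort(40, rng_seed=3)
        grp = (cohort["lacunarity"] > 0.5).to_numpy()
        s1, p1 = logrank_test(cohort["os_time"], cohort["os_event"], grp)
        s2, p2 = logrank_test(cohort["os_time"], cohort["os_event"], ~grp)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            logrank_test([1, 2], [True, True], [1, 1])


class TestCox:
    def test_tiny_data_matches_brute_force_grid(self):
        # 4 subjects, distinct times, single binary covariate: the fitted
        # coefficient must maximize the exposed partial likelihood
        df = pd.DataFrame(
            {
                "pfs_time": [2.0, 5.0, 7.0, 11.0],
                "pfs_event": [1, 1, 1, 0],
                "x": [1, 0, 1, 0],
            }
        )
        fit = cox_fit(df, "pfs", ["x"])
        coef = fit.table.loc["x", "coef"]
        grid = np.linspace(coef - 2.0, coef + 2.0, 40001)
        ll = [
            cox_partial_loglik(
                df["pfs_time"].to_numpy(), df["pfs_event"].to_numpy(bool), df[["x"]].to_numpy(), np.array([b])
            )
            for b in grid
        ]
        assert abs(grid[int(np.argmax(ll))] - coef) < 1e-4

    def test_optimum_beats_random_perturbations(self):
        cohort = dichotomize_cohort(toy_cohort(80, hr_lac=2.0, seed=4), lac_cut=0.5)
        fit = cox_fit(cohort, "os", ["lac_high"])
        times = cohort["os_time"].to_numpy()
        events = cohort["os_event"].to_numpy(bool)
        X = cohort[["lac_high"]].to_numpy(float)
        beta_hat = fit.table["coef"].to_numpy()
        ll_hat = cox_partial_loglik(times, events, X, beta_hat)
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert ll_hat >= cox_partial_loglik(
                times, events, X, beta_hat + rng.normal(0, 0.5, beta_hat.shape)
            )

    def test_hr_equals_exp_coef_and_ci_brackets(self):
        cohort = dichotomize_cohort(toy_cohort(100, hr_lac=2.0, seed=1), lac_cut=0.5)
        fit = cox_fit(cohort, "pfs", ["lac_high", "age_high"])
        for _, row in fit.table.iterrows():
            assert row["hr"] == pytest.approx(np.exp(row["coef"]))
            assert row["ci_lower"] <= row["hr"] <= row["ci_upper"]

    def test_noise_covariate_ci_coverage(self):
        # pure-noise indicator: the 95% Wald CI should cover HR=1 in >= 90%
        covered = 0
        n_reps = 60
        rng = np.random.default_rng(9)
        for rep in range(n_reps):
            cohort = toy_cohort(200, seed=rep, rng_seed=rep)
            cohort["noise"] = (rng.random(len(cohort)) < 0.5).astype(int)
            fit = cox_fit(cohort, "os", ["noise"])
            row = fit.table.loc["noise"]
            covered += row["ci_lower"] <= 1.0 <= row["ci_upper"]
        assert covered / n_reps >= 0.90

    def test_constant_covariate_rejected(self):
        cohort = toy_cohort(20)
        cohort["flat"] = 1
        with pytest.raises(ParameterError, match="flat"):
            cox_fit(cohort, "os", ["flat"])

    def test_too_few_events_rejected(self):
        cohort = toy_cohort(10, censor=0.0)
        cohort["os_event"] = False
        cohort.loc[0, "os_event"] = True
        cohort["x"] = [0, 1] * 5
        with pytest.raises(ParameterError):
            cox_fit(cohort, "os", ["x"])


class TestTables:
    def test_univariate_layout(self):
        cohort = dichotomize_cohort(toy_cohort(80, seed=2), lac_cut=0.5)
        table = univariate_table(cohort)
        assert len(table) == len(RISK_INDICATORS) * 2
        assert set(table["endpoint"]) == {"pfs", "os"}

    def test_degenerate_rows_flagged_not_crashed(self):
        cohort = dichotomize_cohort(toy_cohort(40, seed=5), lac_cut=0.5)
        cohort["rt_tmz"] = 1  # everyone treated: row must fail gracefully
        table = univariate_table(cohort)
        assert (table.loc[table["covariate"] == "rt_tmz", "status"] == "failed").all()
        assert (table.loc[table["covariate"] == "fd_low", "status"] == "ok").all()

    def test_planted_effects_dominate_over_seeds(self):
        hits = {c: 0 for c in RISK_INDICATORS}
        n_seeds = 10
        for seed in range(n_seeds):
            cohort = dichotomize_cohort(
                toy_cohort(150, hr_lac=2.5, hr_fd=2.5, seed=seed, rng_seed=seed), lac_cut=0.5
            )
            table = univariate_table(cohort)
            for cov in RISK_INDICATORS:
                sub = table[(table["covariate"] == cov) & (table["status"] == "ok")]
                if (sub["p"] < 0.05).all() and len(sub) == 2:
                    hits[cov] += 1
        assert hits["fd_low"] > n_seeds / 2
        assert hits["lac_high"] > n_seeds / 2
        for cov in ("age_high", "kps_low", "vol_high", "subtotal_resection", "rt_tmz"):
            assert hits[cov] < n_seeds / 2

    def test_multivariate_adjusted_recovery(self):
        cohort = dichotomize_cohort(toy_cohort(500, hr_lac=2.0, seed=3, rng_seed=3), lac_cut=0.5)
        fits = multivariate_table(cohort, "lacunarity")
        hr = fits["os"].table.loc["lac_high", "hr"]
        assert 1.5 <= hr <= 2.6

    def test_covariate_order_invariance(self):
        cohort = dichotomize_cohort(toy_cohort(120, hr_lac=2.0, seed=6), lac_cut=0.5)
        a = cox_fit(cohort, "os", ["lac_high", "age_high", "kps_low"])
        b = cox_fit(cohort, "os", ["kps_low", "lac_high", "age_high"])
        for cov in ("lac_high", "age_high", "kps_low"):
            assert a.table.loc[cov, "coef"] == pytest.approx(b.table.loc[cov, "coef"], rel=1e-6)

    def test_constant_fractal_indicator_degenerate(self):
        cohort = dichotomize_cohort(toy_cohort(40, seed=7), lac_cut=0.5)
        cohort["lac_high"] = 1
        with pytest.raises(ParameterError):
            multivariate_table(cohort, "lacunarity")
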