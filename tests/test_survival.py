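"""Cox models, IPCW Brier scores, conditional KM, maxstat cut points."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from ubcsig import survival as sv
from ubcsig.normalization import log2_rpkm, tmm_factors
from ubcsig.synthetic import SyntheticConfig, generate_cohort


def _expr_frame(cohort):
    expr = log2_rpkm(cohort.counts, tmm_factors(cohort.counts))
    return expr.to_frame().T


def brute_force_brier(time, event, S, t):
    """Independent IPCW sum: explicit loops, own censoring-KM computation."""
    n = len(time)
    # Kaplan-Meier of censoring (event = censored), right-continuous
    order = np.argsort(time)
    ts, cs = time[order], (1 - event[order])
    km_t, km_s = [], []
    s = 1.0
    for ti in sorted(set(ts[cs == 1])):
        at_risk = np.sum(ts >= ti)
        d = np.sum((ts == ti) & (cs == 1))
        s *= 1 - d / at_risk
        km_t.append(ti)
        km_s.append(s)

    def G(u, left=False):
        out = 1.0
        for ti, si in zip(km_t, km_s):
            if (ti < u) if left else (ti <= u):
                out = si
        return out

    total = 0.0
    for i in range(n):
        if time[i] <= t and event[i] == 1:
            total += S[i] ** 2 / G(time[i], left=True)
        elif time[i] > t:
            total += (1 - S[i]) ** 2 / G(t)
    return total / n


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        times, surv = sv.kaplan_meier(t, np.ones(5, dtype=int))
        # S(t_k) = fraction strictly surviving past t_k
        assert np.allclose(surv, [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_matches_lifelines_with_censoring(self, mixed_censoring_surv):
        d = mixed_censoring_surv
        times, surv = sv.kaplan_meier(d.time, d.event)
        kmf = KaplanMeierFitter().fit(d.time, d.event)
        for t, s in zip(times, surv):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
            )


class TestUnivariateScreen:
    def test_degenerate_gene_flagged_not_fatal(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        surv = sv.SurvivalData(rng.exponential(size=30) + 0.1,
                               np.ones(30, dtype=int))
        out = sv.univariate_cox_screen(X, surv)
        assert bool(out.loc[0, "degenerate"])
        assert not bool(out.loc[1, "degenerate"])
        assert np.isfinite(out.loc[1, "wald_p"])

    def test_log_hr_recovery(self):
        """True standardized log-hazard 1.0 is recovered within 0.25."""
        errs = []
        for seed in range(10):
            # enough background genes that normalization is stable
            c = generate_cohort(
                SyntheticConfig(
                    n_samples=300, n_genes=100, n_signature_genes=0,
                    cox_betas={"G0002": 1.0}, target_censoring=0.2, seed=seed,
                )
            )
            X = _expr_frame(c).loc[:, ["G0002"]]
            surv = sv.SurvivalData.from_annotation(c.annotation)
            out = sv.univariate_cox_screen(X, surv)
            est = out.set_index("gene").loc["G0002", "log_hr"]
            errs.append(abs(est - 1.0))
        assert np.median(errs) < 0.25

    def test_needs_two_events(self):
        with pytest.raises(ValueError):
            sv.univariate_cox_screen(
                np.ones((5, 1)),
                sv.SurvivalData(np.arange(1.0, 6.0), np.zeros(5, dtype=int)),
            )


class TestRidgeCox:
    def test_lambda_zero_matches_lifelines(self):
        rng = np.random.default_rng(1)
        n = 20
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1 / np.exp(0.8 * X[:, 0] - 0.5 * X[:, 1]))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        m = sv.fit_ridge_cox(X, sv.SurvivalData(t, e), n_folds=5,
                             lambdas=[1e-8])
        df = pd.DataFrame({
            "t": t, "e": e,
            "x0": (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(),
            "x1": (X[:, 1] - X[:, 1].mean()) / X[:, 1].std(),
        })
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(m.coefficients, cph.params_.to_numpy(), atol=1e-3)

    def test_infinite_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        t = rng.exponential(size=40) + 0.01
        e = np.ones(40, dtype=int)
        m = sv.fit_ridge_cox(X, sv.SurvivalData(t, e), lambdas=[1e8])
        assert np.all(np.abs(m.coefficients) < 1e-5)
        eta = m.linear_predictor(X)
        assert np.ptp(eta) < 1e-3

    def test_penalty_monotonicity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        t = rng.exponential(1 / np.exp(X[:, 0])) + 0.01
        e = np.ones(50, dtype=int)
        surv = sv.SurvivalData(t, e)
        norms = [
            np.linalg.norm(
                sv.fit_ridge_cox(X, surv, lambdas=[lam]).coefficients
            )
            for lam in (0.1, 0.2, 0.4, 0.8, 1.6)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_partial_loglik_time_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(25, 2))
        t = rng.exponential(size=25) + 0.01
        e = (rng.uniform(size=25) < 0.7).astype(int)
        beta = np.array([0.5, -0.2])
        ll1 = sv.breslow_partial_loglik(Z, t, e, beta)
        ll2 = sv.breslow_partial_loglik(Z, 7.3 * t, e, beta)
        assert ll1 == pytest.approx(ll2, abs=1e-10)


class TestBrier:
    def test_constant_half_prediction(self):
        surv = sv.SurvivalData(np.arange(1.0, 9.0), np.ones(8, dtype=int))
        for t in (0.5, 3.0, 7.5):
            assert sv.brier_score(surv, np.full(8, 0.5), t) == pytest.approx(
                0.25, abs=1e-12
            )

    def test_perfect_oracle_zero_error(self):
        time = np.array([1.0, 2.0, 5.0, 6.0])
        surv = sv.SurvivalData(time, np.ones(4, dtype=int))
        t = 3.0  # between the first two events and the last two survivors
        S = np.where(time > t, 1.0, 0.0)
        assert sv.brier_score(surv, S, t) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_mixed_censoring(self, mixed_censoring_surv):
        d = mixed_censoring_surv
        rng = np.random.default_rng(5)
        S = rng.uniform(size=8)
        for t in (0.7, 1.9, 2.6, 3.4):
            assert sv.brier_score(d, S, t) == pytest.approx(
                brute_force_brier(d.time, d.event, S, t), abs=1e-10
            )

    def test_agrees_with_sksurv(self, mixed_censoring_surv):
        from sksurv.metrics import brier_score as sks_brier

        d = mixed_censoring_surv
        rng = np.random.default_rng(6)
        S = rng.uniform(size=8)
        y = d.to_structured()
        times, scores = sks_brier(y, y, S[:, None], [2.2])
        assert sv.brier_score(d, S, 2.2) == pytest.approx(scores[0], abs=1e-10)

    def test_out_of_range_probabilities_rejected(self, mixed_censoring_surv):
        with pytest.raises(ValueError):
            sv.brier_score(mixed_censoring_surv, np.full(8, 1.5), 2.0)


class TestIntegratedBrier:
    def test_constant_curve_integrates_to_constant(self):
        surv = sv.SurvivalData(np.arange(1.0, 9.0) / 2.0,
                               np.ones(8, dtype=int))
        pec = sv.integrated_brier(
            surv, lambda ts: np.full((8, len(ts)), 0.5), t_max=3.0
        )
        assert pec.ibs == pytest.approx(0.25, abs=1e-12)

    def test_invariant_to_duplicating_test_set(self):
        time = np.array([0.5, 1.2, 2.0, 2.8, 3.5])
        event = np.array([1, 0, 1, 1, 0])
        rng = np.random.default_rng(7)
        base = rng.uniform(0.3, 0.9, size=5)

        def pred1(ts):
            return np.tile(base[:, None], (1, len(ts)))

        def pred2(ts):
            return np.tile(np.r_[base, base][:, None], (1, len(ts)))

        p1 = sv.integrated_brier(sv.SurvivalData(time, event), pred1)
        p2 = sv.integrated_brier(
            sv.SurvivalData(np.r_[time, time], np.r_[event, event]), pred2
        )
        assert p1.ibs == pytest.approx(p2.ibs, abs=1e-12)


class TestCVPredictionError:
    def test_leave_one_out_finite(self):
        c = generate_cohort(
            SyntheticConfig(n_samples=30, n_genes=6, n_signature_genes=3,
                            target_censoring=0.2, seed=8)
        )
        X = _expr_frame(c)
        surv = sv.SurvivalData.from_annotation(c.annotation)
        pec = sv.cv_prediction_error("null", X, surv, n_folds=30, seed=0)
        assert np.isfinite(pec.ibs)
        assert np.all((pec.brier >= 0) & (pec.brier <= 1))

    def test_signal_beats_null(self, prognostic_cohort):
        c = prognostic_cohort
        X = _expr_frame(c).loc[:, c.truth["signature_genes"]]
        surv = sv.SurvivalData.from_annotation(c.annotation)
        null = sv.cv_prediction_error("null", X, surv, n_folds=10, seed=1)
        ridge = sv.cv_prediction_error(
            "ridge", X, surv, n_folds=10, seed=1,
            lambdas=np.geomspace(0.1, 100, 8),
        )
        assert ridge.ibs < null.ibs


class TestConditionalKM:
    def test_span_one_equals_global_km(self, prognostic_cohort):
        c = prognostic_cohort
        surv = sv.SurvivalData.from_annotation(c.annotation)
        rng = np.random.default_rng(9)
        values = rng.normal(size=len(surv))
        curves = sv.conditional_km(values, surv, span=1.0)
        kmf = KaplanMeierFitter().fit(surv.time, surv.event)
        for df in curves.values():
            for t, s in zip(df["time"], df["survival"]):
                assert s == pytest.approx(
                    float(kmf.survival_function_at_times(t).iloc[0]),
                    abs=1e-12,
                )

    def test_neighborhood_km_hand_computed(self):
        # values 0,1,2,3; span .5 -> two nearest per anchor
        surv = sv.SurvivalData(np.array([1.0, 2.0, 3.0, 4.0]),
                               np.array([1, 1, 1, 1]))
        curves = sv.conditional_km(np.array([0.0, 1.0, 2.0, 3.0]), surv,
                                  span=0.5)
        low = curves["low"]  # samples {0, 1}: events at 1, 2
        assert list(low["survival"])[-2:] == [0.5, 0.0]
        high = curves["high"]  # samples {2, 3}: events at 3, 4
        assert list(high["survival"])[-2:] == [0.5, 0.0]

    def test_prognostic_ordering(self, prognostic_cohort):
        c = prognostic_cohort
        X = _expr_frame(c).loc[:, c.truth["signature_genes"]]
        surv = sv.SurvivalData.from_annotation(c.annotation)
        model = sv.fit_ridge_cox(X, surv, lambdas=[1.0])
        curves = sv.conditional_km(model.linear_predictor(X), surv)

        def at3(df):
            mask = df["time"] <= 3.0
            return df.loc[mask, "survival"].iloc[-1] if mask.any() else 1.0

        assert at3(curves["low"]) > at3(curves["high"])

    def test_span_too_small_rejected(self):
        surv = sv.SurvivalData(np.array([1.0, 2.0, 3.0, 4.0]),
                               np.array([1, 1, 1, 1]))
        with pytest.raises(ValueError):
            sv.conditional_km(np.arange(4.0), surv, span=0.2)


class TestBootLasso:
    def test_single_bootstrap_is_single_lasso_support(self):
        c = generate_cohort(
            SyntheticConfig(n_samples=120, n_genes=10, n_signature_genes=0,
                            cox_betas={"G0000": 1.5}, target_censoring=0.2,
                            seed=10)
        )
        X = _expr_frame(c)
        surv = sv.SurvivalData.from_annotation(c.annotation)
        res = sv.boot_lasso_cox(X, surv, B=1, seed=4)
        support = set(res.selection_count.index[res.selection_count > 0])
        assert set(res.retained_set) == support

    def test_retained_set_shrinks_with_threshold(self):
        c = generate_cohort(
            SyntheticConfig(n_samples=150, n_genes=15, n_signature_genes=0,
                            cox_betas={"G0000": 1.2, "G0001": 0.8},
                            target_censoring=0.3, seed=12)
        )
        X = _expr_frame(c)
        surv = sv.SurvivalData.from_annotation(c.annotation)
        res_lo = sv.boot_lasso_cox(X, surv, B=15, retain_fraction=0.3, seed=2)
        res_hi = sv.boot_lasso_cox(X, surv, B=15, retain_fraction=0.8, seed=2)
        assert set(res_hi.retained_set) <= set(res_lo.retained_set)

    def test_gene_order_invariance(self):
        c = generate_cohort(
            SyntheticConfig(n_samples=100, n_genes=8, n_signature_genes=0,
                            cox_betas={"G0003": 1.5}, target_censoring=0.2,
                            seed=13)
        )
        X = _expr_frame(c)
        surv = sv.SurvivalData.from_annotation(c.annotation)
        r1 = sv.boot_lasso_cox(X, surv, B=10, seed=5)
        cols = list(X.columns[::-1])
        r2 = sv.boot_lasso_cox(X.loc[:, cols], surv, B=10, seed=5)
        assert set(r1.retained_set) == set(r2.retained_set)


class TestMaxstat:
    def test_single_candidate_gives_pointwise_p(self):
        rng = np.random.default_rng(14)
        n = 40
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        t = rng.exponential(1 / np.exp(1.0 * x)) + 0.01
        e = np.ones(n, dtype=int)
        res = sv.maxstat_cutpoint(x, sv.SurvivalData(t, e),
                                  epsilon=(0.5, 0.5))
        from scipy.stats import norm

        assert res.adjusted_p == pytest.approx(
            2 * norm.sf(res.max_statistic), abs=1e-12
        )

    def test_adjusted_p_at_least_pointwise(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=80)
        t = rng.exponential(size=80) + 0.01
        e = (rng.uniform(size=80) < 0.7).astype(int)
        res = sv.maxstat_cutpoint(x, sv.SurvivalData(t, e))
        from scipy.stats import norm

        assert res.adjusted_p >= 2 * norm.sf(res.max_statistic) - 1e-12
        assert res.adjusted_p <= 1.0
        assert res.epsilon_range[0] <= res.cut_quantile <= res.epsilon_range[1]

    def test_identical_values_rejected(self):
        surv = sv.SurvivalData(np.arange(1.0, 13.0), np.ones(12, dtype=int))
        with pytest.raises(ValueError, match="identical"):
            sv.maxstat_cutpoint(np.ones(12), surv)

    def test_recovers_planted_cutpoint(self):
        rng = np.random.default_rng(16)
        n = 200
        x = rng.normal(size=n)
        thr = np.quantile(x, 0.4)
        t = rng.exponential(1 / np.exp(np.log(4) * (x > thr))) + 1e-9
        e = (rng.uniform(size=n) < 0.8).astype(int)
        res = sv.maxstat_cutpoint(x, sv.SurvivalData(t, e))
        assert abs(res.cut_quantile - 0.4) <= 0.05
        assert res.adjusted_p < 0.05
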