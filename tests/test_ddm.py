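"""Wiener diffusion: density validity, simulators, likelihood fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from cogeffort.ddm import (
    HR,
    LR,
    DDMParams,
    RecoveryTruthConfig,
    choice_probability,
    fit_mle,
    fpt_cdf_grid,
    fpt_density,
    inclusion_filter,
    loglik,
    mean_decision_time,
    parameter_recovery,
    simulate_ddm,
)
from cogeffort.exceptions import ConfigError, FitError, InsufficientDataError


def random_params(rng, v_lo=-3.0, v_hi=3.0):
    return DDMParams(
        v=rng.uniform(v_lo, v_hi),
        a=rng.uniform(0.8, 2.5),
        w=rng.uniform(0.2, 0.8),
        t0=rng.uniform(0.1, 0.5),
    )


def empirical_ks(latencies, params):
    """KS distance of total latencies against the mixture CDF over both
    boundaries."""
    t_hr, c_hr = fpt_cdf_grid(params, HR)
    t_lr, c_lr = fpt_cdf_grid(params, LR)
    grid = np.union1d(t_hr, t_lr)
    F = np.interp(grid, t_hr, c_hr) + np.interp(grid, t_lr, c_lr)
    srt = np.sort(latencies)
    Fs = np.interp(srt, grid, F)
    n = len(srt)
    return max(
        float(np.max(np.arange(1, n + 1) / n - Fs)),
        float(np.max(Fs - np.arange(0, n) / n)),
    )


class TestChoiceProbability:
    @pytest.mark.parametrize(
        "params,expected",
        [
            (DDMParams(0.0, 1.5, 0.5, 0.2), 0.5),
            (DDMParams(0.0, 1.5, 0.7, 0.2), 0.7),
            (
                DDMParams(1.0, 2.0, 0.5, 0.2),
                (1 - np.exp(-2)) / (1 - np.exp(-4)),
            ),
        ],
    )
    def test_closed_form(self, params, expected):
        assert choice_probability(params) == pytest.approx(expected, rel=1e-9)

    def test_continuity_at_zero_drift(self):
        near = choice_probability(DDMParams(1e-9, 1.5, 0.63, 0.2))
        assert near == pytest.approx(0.63, abs=1e-7)

    def test_invalid_parameters_rejected(self):
        for bad in [dict(v=0, a=-1, w=0.5, t0=0.1), dict(v=0, a=1, w=1.2, t0=0.1),
                    dict(v=0, a=1, w=0.5, t0=-0.1)]:
            with pytest.raises(ValueError):
                DDMParams(**bad)


class TestDensity:
    def test_zero_below_nondecision_time(self):
        p = DDMParams(1.0, 1.5, 0.5, 0.3)
        assert fpt_density(0.29, p, HR) == 0.0
        assert fpt_density(0.3, p, HR) == 0.0

    def test_normalisation_and_choice_probability(self, rng):
        for _ in range(10):
            p = random_params(rng)
            q_hr = integrate.quad(
                lambda t: fpt_density(t, p, HR), p.t0, np.inf, limit=300
            )[0]
            q_lr = integrate.quad(
                lambda t: fpt_density(t, p, LR), p.t0, np.inf, limit=300
            )[0]
            assert q_hr + q_lr == pytest.approx(1.0, abs=1e-4)
            assert q_hr == pytest.approx(choice_probability(p), abs=1e-4)

    def test_reflection_symmetry_pointwise(self, rng):
        for _ in range(20):
            p = random_params(rng)
            mirror = DDMParams(-p.v, p.a, 1 - p.w, p.t0)
            t = p.t0 + rng.uniform(0.01, 3.0, size=50)
            np.testing.assert_allclose(
                fpt_density(t, p, HR), fpt_density(t, mirror, LR), rtol=1e-10
            )

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ConfigError):
            fpt_density(1.0, DDMParams(1, 1.5, 0.5, 0.2), HR, err=-1e-6)

    def test_cdf_grid_reaches_boundary_probability(self, rng):
        p = random_params(rng)
        t, cdf = fpt_cdf_grid(p, HR)
        assert cdf[-1] == pytest.approx(choice_probability(p), abs=1e-5)


class TestSimulators:
    def test_symmetric_diffusion_hr_fraction(self, rng):
        p = DDMParams(0.0, 1.5, 0.5, 0.2)
        is_hr, _ = simulate_ddm(p, 100_000, rng, method="inverse_cdf")
        se = 0.5 / np.sqrt(100_000)
        assert abs(is_hr.mean() - 0.5) < 3 * se

    @pytest.mark.parametrize("method", ["euler", "inverse_cdf"])
    def test_hr_fraction_matches_closed_form(self, rng, method):
        for _ in range(3):
            p = random_params(rng, v_lo=-1.5, v_hi=1.5)
            n = 20_000
            is_hr, rt = simulate_ddm(p, n, rng, method=method)
            target = choice_probability(p)
            se = np.sqrt(target * (1 - target) / n)
            assert abs(is_hr.mean() - target) < 4 * se + 1e-3
            assert (rt > p.t0).all()

    def test_euler_latency_distribution_matches_density(self, rng):
        p = DDMParams(0.8, 1.6, 0.6, 0.3)
        _, rt = simulate_ddm(p, 20_000, rng)
        assert empirical_ks(rt, p) < 0.01

    def test_mean_decision_time_matches_quadrature(self, rng):
        p = DDMParams(0.0, 1.4, 0.5, 0.25)
        _, rt = simulate_ddm(p, 40_000, rng, method="inverse_cdf")
        assert rt.mean() == pytest.approx(mean_decision_time(p), rel=0.02)

    def test_zero_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_ddm(DDMParams(1, 1.5, 0.5, 0.2), 0, rng)


class TestMLE:
    def test_recovers_known_parameters(self, rng):
        true = DDMParams(v=1.5, a=1.6, w=0.65, t0=0.3)
        is_hr, rt = simulate_ddm(true, 2000, rng, method="inverse_cdf")
        fit = fit_mle(is_hr, rt, seed=rng)
        rel = np.abs(fit.params.as_array() - true.as_array()) / true.as_array()
        assert np.all(rel < 0.10)
        assert fit.converged
        assert fit.n_trials_used == 2000

    def test_duplicating_trials_leaves_argmax_unchanged(self, rng):
        true = DDMParams(0.8, 1.4, 0.55, 0.25)
        is_hr, rt = simulate_ddm(true, 300, rng, method="inverse_cdf")
        f1 = fit_mle(is_hr, rt, seed=1)
        f2 = fit_mle(np.tile(is_hr, 2), np.tile(rt, 2), seed=1)
        np.testing.assert_allclose(
            f1.params.as_array(), f2.params.as_array(), atol=0.02
        )
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=0.01)

    def test_t0_bounded_by_minimum_latency(self, rng):
        is_hr, rt = simulate_ddm(DDMParams(1.0, 1.5, 0.5, 0.4), 200, rng, method="inverse_cdf")
        fit = fit_mle(is_hr, rt, seed=0)
        assert fit.params.t0 < rt.min()

    def test_insufficient_trials_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_mle(np.array([True, False] * 3), np.full(6, 0.7))

    def test_one_sided_choices_rejected(self):
        with pytest.raises(FitError):
            fit_mle(np.ones(20, dtype=bool), np.linspace(0.5, 1.5, 20))

    def test_loglik_floor_for_latency_below_t0(self):
        p = DDMParams(1.0, 1.5, 0.5, 0.5)
        ll = loglik(p, np.array([True]), np.array([0.4]))
        assert ll <= -1e9


class TestInclusionFilter:
    def _trials(self, pid, n_hr, n_lr, hr_correct=1, lr_correct=1):
        rows = []
        for i in range(n_hr):
            rows.append({"participant_id": pid, "choice": "HR",
                         "performed_correct": i < hr_correct, "choice_latency": 1.0})
        for i in range(n_lr):
            rows.append({"participant_id": pid, "choice": "LR",
                         "performed_correct": i < lr_correct, "choice_latency": 1.0})
        return rows

    def test_rules(self):
        df = pd.DataFrame(
            self._trials(1, 30, 0)            # only HR: excluded
            + self._trials(2, 4, 26)          # boundary case: included
            + self._trials(3, 3, 27)          # 3 HR choices: excluded
            + self._trials(4, 10, 20, hr_correct=0)  # no correct HR: excluded
        )
        eligible, log = inclusion_filter(df)
        assert eligible == [2]
        reasons = dict(zip(log["participant_id"], log["reason"]))
        assert reasons[1] == "fewer_than_4_lr_choices"
        assert reasons[3] == "fewer_than_4_hr_choices"
        assert reasons[4] == "no_correct_hr_trial"


class TestRecovery:
    def test_degenerate_truth_rejected(self, rng):
        cfg = RecoveryTruthConfig(w_range=(0.5, 0.5))
        with pytest.raises(ConfigError):
            parameter_recovery(cfg, 5, 100, rng)

    def test_report_invariants(self):
        rep = parameter_recovery(RecoveryTruthConfig(), 8, 120, rng=3)
        for p in ("v", "a", "w", "t0"):
            assert rep.rmse[p] >= abs(rep.bias[p])
        assert not rep.low_information
        rep30 = parameter_recovery(RecoveryTruthConfig(), 8, 30, rng=3)
        assert rep30.low_information
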