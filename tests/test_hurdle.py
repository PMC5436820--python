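import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy.stats import spearmanr

import lobstat as lb
from lobstat.hurdle import (
    HurdleDesign,
    SeparationError,
    _trunc_count_nll,
    fit_hurdle,
    hurdle_loglik,
    lrt,
    lrt_pvalue,
    predict_cpue,
    residuals_vs_fitted,
    select_family,
    stepwise_simplify,
)
from lobstat.types import ValidationError

from conftest import hurdle_frame, nb_pots


# ---------------------------------------------------------------------------
# independent oracle: per-observation probabilities by direct enumeration

def _oracle_logpmf(y, mu, theta):
    if math.isinf(theta):
        return -mu + y * math.log(mu) - math.lgamma(y + 1)
    log_p = math.log(theta) - math.log(theta + mu)
    log_1mp = math.log(mu) - math.log(theta + mu)
    return (
        math.lgamma(y + theta) - math.lgamma(theta) - math.lgamma(y + 1)
        + theta * log_p + y * log_1mp
    )


def _log1mexp(log_x):
    # log(1 - exp(log_x)) for log_x < 0
    return math.log(-math.expm1(log_x))


def _oracle_loglik(zero_coefs, count_coefs, theta, ntz, pots, counts):
    total = 0.0
    for o, p_, y in zip(ntz, pots, counts):
        eta_z = (
            zero_coefs[0] + zero_coefs[1] * o + zero_coefs[2] * p_
            + zero_coefs[3] * o * p_
        )
        log_pi = -math.log1p(math.exp(-eta_z)) if eta_z > -30 else eta_z
        log_1mpi = -math.log1p(math.exp(eta_z)) if eta_z < 30 else -eta_z
        mu = math.exp(
            count_coefs[0] + count_coefs[1] * o + count_coefs[2] * p_
            + count_coefs[3] * o * p_
        )
        if y == 0:
            total += log_1mpi
        else:
            total += (
                log_pi
                + _oracle_logpmf(y, mu, theta)
                - _log1mexp(min(_oracle_logpmf(0, mu, theta), -1e-12))
            )
    return total


def _design(ntz, pots, **kwargs):
    return HurdleDesign(
        data=pd.DataFrame({"ntz_open": ntz, "pots": pots}), **kwargs
    )


class TestHurdleLoglik:
    def test_single_zero_at_predictor_zero(self):
        d = _design([0.0], [0.0], zero_terms=("intercept",),
                    count_terms=("intercept",), family="poisson")
        ll = hurdle_loglik([0.0, 0.3], [0], d)
        assert ll == pytest.approx(math.log(0.5))

    def test_truncated_poisson_closed_form(self):
        # y=3, mu=2, hurdle certainly crossed (huge zero intercept)
        d = _design([0.0], [0.0], zero_terms=("intercept",),
                    count_terms=("intercept",), family="poisson")
        ll = hurdle_loglik([700.0, math.log(2.0)], [3], d)
        expected = math.log((math.exp(-2) * 2**3 / 6) / (1 - math.exp(-2)))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_counts(self):
        d = _design([0.0], [1.0])
        with pytest.raises(ValidationError):
            hurdle_loglik(np.zeros(9), [-1], d)
        with pytest.raises(ValidationError):
            hurdle_loglik(np.zeros(9), [1.5], d)

    @given(
        st.integers(0, 10_000),
        st.integers(1, 50),
        st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_enumeration(self, seed, n, use_nb):
        rng = np.random.default_rng(seed)
        ntz = (rng.random(n) < 0.5).astype(float)
        pots = rng.integers(1, 8, n).astype(float)
        counts = rng.integers(0, 6, n)
        bz = rng.normal(0, 0.5, 4)
        bc = rng.normal(0, 0.3, 4)
        theta = float(rng.uniform(0.5, 5.0)) if use_nb else math.inf
        d = _design(ntz, pots, family="negbin" if use_nb else "poisson")
        params = np.concatenate([bz, bc, [math.log(theta)]]) if use_nb else np.concatenate([bz, bc])
        got = hurdle_loglik(params, counts, d)
        want = _oracle_loglik(bz, bc, theta, ntz, pots, counts)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


class TestFitHurdle:
    def test_intercept_only_zero_part_closed_form(self, rng):
        counts = np.concatenate([np.zeros(40, dtype=int),
                                 rng.poisson(2.0, 60) + 1])
        d = _design(np.zeros(100), np.zeros(100),
                    zero_terms=("intercept",), count_terms=("intercept",),
                    family="poisson")
        fit = fit_hurdle(counts, d)
        assert fit.zero_coefs[0] == pytest.approx(math.log(0.6 / 0.4), abs=1e-6)

    def test_parameter_recovery_within_3se(self, rng):
        bz = np.array([-0.4, 0.7, 0.03, 0.015])
        bc = np.array([0.3, 0.4, 0.02, 0.01])
        theta = 1.5
        frame = hurdle_frame(rng, 3000)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(), bz, bc, theta
        )
        fit = fit_hurdle(y, HurdleDesign(data=frame))
        assert fit.converged
        for est, se, true in zip(
            np.concatenate([fit.zero_coefs, fit.count_coefs]),
            np.concatenate([fit.zero_se, fit.count_se]),
            np.concatenate([bz, bc]),
        ):
            assert abs(est - true) < 3 * se

    def test_poisson_truth_gives_large_theta(self, rng):
        frame = hurdle_frame(rng, 4000)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.2, 0.5, 0.02, 0.0), (0.3, 0.4, 0.02, 0.0), math.inf,
        )
        fit_nb = fit_hurdle(y, HurdleDesign(data=frame, family="negbin"))
        fit_p = fit_hurdle(y, HurdleDesign(data=frame, family="poisson"))
        assert fit_nb.dispersion > 50
        assert fit_p.aic <= fit_nb.aic + 2 + 1e-6

    def test_all_zero_or_all_positive_errors(self):
        d = _design(np.zeros(10), np.ones(10))
        with pytest.raises(ValidationError, match="zero"):
            fit_hurdle(np.zeros(10, dtype=int), d)
        with pytest.raises(ValidationError, match="zero part"):
            fit_hurdle(np.ones(10, dtype=int), d)

    def test_separation_detected(self):
        # zero/positive outcome perfectly determined by ntz status
        ntz = np.array([0.0] * 10 + [1.0] * 10)
        counts = np.array([0] * 10 + [2] * 10)
        d = _design(ntz, np.ones(20), zero_terms=("intercept", "ntz_open"),
                    count_terms=("intercept",), family="poisson")
        with pytest.raises(SeparationError):
            fit_hurdle(counts, d)

    def test_aic_identity(self, rng):
        frame = hurdle_frame(rng, 400)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.2, 0.5, 0.02, 0.0), (0.3, 0.4, 0.02, 0.0), 2.0,
        )
        fit = fit_hurdle(y, HurdleDesign(data=frame))
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        assert fit.n_params == 9  # 4 + 4 + theta


class TestLikelihoodSeparability:
    def test_joint_optimum_equals_separate_fits(self, rng):
        frame = hurdle_frame(rng, 800)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.3, 0.6, 0.02, 0.0), (0.2, 0.3, 0.02, 0.0), 2.0,
        )
        d = HurdleDesign(data=frame)
        fit = fit_hurdle(y, d)
        sep = np.concatenate(
            [fit.zero_coefs, fit.count_coefs, [math.log(fit.dispersion)]]
        )
        res = optimize.minimize(
            lambda p: -hurdle_loglik(p, y, d), sep * 0.9 + 0.01,
            method="BFGS", options={"gtol": 1e-9, "maxiter": 2000},
        )
        assert -res.fun == pytest.approx(fit.loglik, abs=1e-5)
        np.testing.assert_allclose(res.x[:-1], sep[:-1], atol=1e-3)

    def test_loglik_is_sum_of_parts(self, rng):
        frame = hurdle_frame(rng, 300)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.3, 0.6, 0.02, 0.0), (0.2, 0.3, 0.02, 0.0), 2.0,
        )
        d = HurdleDesign(data=frame)
        fit = fit_hurdle(y, d)
        pos = y > 0
        z = pos.astype(float)
        eta = d.zero_matrix() @ fit.zero_coefs
        from scipy.special import expit

        pr = expit(eta)
        ll_zero = float(np.sum(z * np.log(pr) + (1 - z) * np.log(1 - pr)))
        ll_count = -_trunc_count_nll(
            np.append(fit.count_coefs, math.log(fit.dispersion)),
            d.count_matrix()[pos], y[pos].astype(float), "negbin",
        )
        assert fit.loglik == pytest.approx(ll_zero + ll_count, rel=1e-9)


class TestLrt:
    def test_identical_fits(self, rng):
        frame = hurdle_frame(rng, 200)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.3, 0.6, 0.02, 0.0), (0.2, 0.3, 0.02, 0.0), 2.0,
        )
        fit = fit_hurdle(y, HurdleDesign(data=frame))
        res = lrt(fit, fit)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_published_chi2_to_p(self):
        assert lrt_pvalue(9.710, 1) == pytest.approx(0.00183, abs=5e-5)
        assert round(lrt_pvalue(9.710, 1), 3) == 0.002

    def test_critical_value(self):
        assert lrt_pvalue(3.84, 1) == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_rejected(self, rng):
        frame = hurdle_frame(rng, 300)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.3, 0.6, 0.02, 0.0), (0.2, 0.3, 0.02, 0.0), 2.0,
        )
        f1 = fit_hurdle(y, HurdleDesign(
            data=frame, zero_terms=("intercept", "ntz_open"),
            count_terms=("intercept",), family="poisson"))
        f2 = fit_hurdle(y, HurdleDesign(
            data=frame, zero_terms=("intercept", "pots"),
            count_terms=("intercept",), family="poisson"))
        with pytest.raises(ValidationError):
            lrt(f1, f2)

    def test_zanb_nests_zap(self, rng):
        frame = hurdle_frame(rng, 600)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.3, 0.6, 0.02, 0.0), (0.2, 0.3, 0.02, 0.0), 1.0,
        )
        _, fits, res = select_family(y, HurdleDesign(data=frame))
        assert fits["negbin"].loglik >= fits["poisson"].loglik - 1e-6
        assert res.df == 1
        assert res.chi2 >= 0


class TestSelectFamily:
    def test_overdispersed_chooses_negbin(self, rng):
        frame = hurdle_frame(rng, 2000)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.2, 0.5, 0.03, 0.0), (0.3, 0.4, 0.02, 0.0), 0.8,
        )
        family, _, _ = select_family(y, HurdleDesign(data=frame))
        assert family == "negbin"

    def test_equidispersed_chooses_poisson(self, rng):
        frame = hurdle_frame(rng, 2000)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.2, 0.5, 0.03, 0.0), (0.3, 0.4, 0.02, 0.0), math.inf,
        )
        family, _, _ = select_family(y, HurdleDesign(data=frame))
        assert family == "poisson"


class TestStepwise:
    def _simulate_and_simplify(self, rng, bz, bc, theta=1.5, n=4000):
        frame = hurdle_frame(rng, n)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            bz, bc, theta,
        )
        fit = fit_hurdle(y, HurdleDesign(data=frame))
        return stepwise_simplify(fit)

    def test_null_interactions_dropped(self, rng):
        mam = self._simulate_and_simplify(
            rng, (-0.3, 0.6, 0.03, 0.0), (0.3, 0.4, 0.02, 0.0)
        )
        assert "ntz_open:pots" not in mam.design.zero_terms
        assert "ntz_open:pots" not in mam.design.count_terms

    def test_strong_interactions_keep_full_model(self, rng):
        mam = self._simulate_and_simplify(
            rng, (-1.5, 0.5, 0.05, 0.10), (0.1, 0.2, 0.02, 0.05)
        )
        assert mam.design.zero_terms == HurdleDesign.__dataclass_fields__["zero_terms"].default
        assert mam.design.count_terms == mam.design.zero_terms

    def test_intercept_only_truth(self, rng):
        mam = self._simulate_and_simplify(
            rng, (0.2, 0.0, 0.0, 0.0), (0.7, 0.0, 0.0, 0.0), n=3000
        )
        assert mam.design.zero_terms == ("intercept",)
        assert mam.design.count_terms == ("intercept",)

    def test_marginality_enforced(self):
        with pytest.raises(ValidationError, match="interaction"):
            HurdleDesign(
                data=pd.DataFrame({"ntz_open": [0.0], "pots": [1.0]}),
                zero_terms=("intercept", "ntz_open", "ntz_open:pots"),
            )


class TestPredict:
    def test_truncated_poisson_limit(self, rng):
        # pi ~ 1 via huge zero intercept, Poisson family
        frame = hurdle_frame(rng, 300)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (2.0, 0, 0, 0), (0.5, 0, 0, 0), math.inf,
        )
        y[0] = 0  # keep the zero part estimable
        fit = fit_hurdle(y, HurdleDesign(
            data=frame, zero_terms=("intercept",), count_terms=("intercept",),
            family="poisson"))
        mu = math.exp(fit.count_coefs[0])
        pi = 1 / (1 + math.exp(-fit.zero_coefs[0]))
        want = pi * mu / (1 - math.exp(-mu))
        got = predict_cpue(fit, [0.0], [0.0])[0]
        assert got == pytest.approx(want, rel=1e-9)

    def test_monte_carlo_agreement(self, rng):
        bz = (-0.2, 0.6, 0.03, 0.0)
        bc = (0.3, 0.4, 0.02, 0.0)
        theta = 1.2
        frame = hurdle_frame(rng, 1500)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(), bz, bc, theta
        )
        fit = fit_hurdle(y, HurdleDesign(data=frame))
        n = 100_000
        draws = lb.simulate_hurdle_counts(
            rng, np.ones(n), np.full(n, 19.6), fit.zero_coefs, fit.count_coefs,
            fit.dispersion,
        )
        pred = predict_cpue(fit, [1.0], [19.6])[0]
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(pred - draws.mean()) < 4 * se

    def test_zero_hurdle_probability_gives_zero(self, rng):
        frame = hurdle_frame(rng, 200)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.3, 0, 0, 0), (0.3, 0, 0, 0), math.inf,
        )
        fit = fit_hurdle(y, HurdleDesign(
            data=frame, zero_terms=("intercept",), count_terms=("intercept",),
            family="poisson"))
        fit.zero_coefs[0] = -1e3  # pi -> 0
        assert predict_cpue(fit, [0.0], [5.0])[0] == pytest.approx(0.0, abs=1e-200)


class TestResiduals:
    def test_well_specified_no_trend(self, rng):
        frame = hurdle_frame(rng, 3000)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (-0.3, 0.6, 0.03, 0.0), (0.3, 0.4, 0.02, 0.0), 1.5,
        )
        fit = fit_hurdle(y, HurdleDesign(data=frame))
        table = residuals_vs_fitted(fit)
        assert set(table.columns) == {"fitted", "residual"}
        rho = spearmanr(table["fitted"], table["residual"]).statistic
        assert abs(rho) < 0.08

    def test_misspecified_poisson_overdispersed_residuals(self, rng):
        frame = hurdle_frame(rng, 3000)
        y = lb.simulate_hurdle_counts(
            rng, frame["ntz_open"].to_numpy(), frame["pots"].to_numpy(),
            (0.5, 0.0, 0.0, 0.0), (0.8, 0.0, 0.01, 0.0), 0.5,
        )
        fit_p = fit_hurdle(
            y, HurdleDesign(data=frame, zero_terms=("intercept",), family="poisson")
        )
        fit_nb = fit_hurdle(
            y, HurdleDesign(data=frame, zero_terms=("intercept",), family="negbin")
        )
        sd_p = residuals_vs_fitted(fit_p)["residual"].std()
        sd_nb = residuals_vs_fitted(fit_nb)["residual"].std()
        assert sd_p > 1.3  # Poisson variance badly understates the spread
        assert sd_nb < sd_p
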