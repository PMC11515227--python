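import math

import numpy as np
import pytest
from scipy import stats

from ipbkit import (
    DegenerateDesignError,
    Direction,
    InsufficientStudiesError,
    classify,
    egger_test,
    one_sided_p,
    peters_test,
)
from conftest import make_effects


def ols_oracle(x, y):
    """Independent ordinary least squares via normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


def wls_oracle(x, y, w):
    """Independent weighted least squares with multiplicative dispersion."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ beta
    s2 = (resid @ W @ resid) / (len(y) - 2)
    cov = s2 * np.linalg.inv(xtwx)
    return beta, np.sqrt(np.diag(cov))


class TestEgger:
    def test_exact_null(self):
        res = egger_test(make_effects([0, 0, 0, 0], [0.1, 0.2, 0.3, 0.4]))
        assert res.coef == pytest.approx(0.0, abs=1e-12)
        assert res.p_two == pytest.approx(1.0)

    def test_exactly_linear_fixture(self):
        # y = -0.1 + 2*se exactly, so z = 2 - 0.1/se: intercept 2, no residual
        res = egger_test(make_effects([0.1, 0.3, 0.5, 0.7, 0.9], [0.1, 0.2, 0.3, 0.4, 0.5]))
        assert res.coef == pytest.approx(2.0)
        assert res.df == 3

    def test_matches_ols_oracle(self, five_study_fixture):
        res = egger_test(five_study_fixture)
        se = np.array([s.se for s in five_study_fixture])
        y = np.array([s.y for s in five_study_fixture])
        beta, bse = ols_oracle(1.0 / se, y / se)
        assert res.coef == pytest.approx(beta[0], rel=1e-10)
        assert res.se_coef == pytest.approx(bse[0], rel=1e-10)

    def test_matches_metafor_regtest(self):
        # frozen: metafor regtest(..., model="lm", predictor="sei") on this fixture
        res = egger_test(
            make_effects(
                [0.2, -0.3, 0.6, 0.1, -0.5, 0.4, 0.0, 0.8],
                [0.15, 0.2, 0.3, 0.25, 0.35, 0.18, 0.22, 0.4],
            )
        )
        assert res.t == pytest.approx(0.1230487229, abs=1e-8)
        assert res.p_two == pytest.approx(0.9060868024, abs=1e-8)
        assert res.df == 6

    def test_weighted_form_equivalence(self, five_study_fixture):
        """OLS of z on 1/se and WLS of y on se (weights 1/se^2) are one regression."""
        res = egger_test(five_study_fixture)
        se = np.array([s.se for s in five_study_fixture])
        y = np.array([s.y for s in five_study_fixture])
        beta, bse = wls_oracle(se, y, 1.0 / se**2)  # asymmetry term = slope on se
        assert res.coef == pytest.approx(beta[1], abs=1e-10)
        assert res.se_coef == pytest.approx(bse[1], abs=1e-10)

    def test_mirror_antisymmetry(self, five_study_fixture):
        res = egger_test(five_study_fixture)
        mirrored = make_effects(
            [-s.y for s in five_study_fixture], [s.se for s in five_study_fixture]
        )
        res_m = egger_test(mirrored)
        assert res.p_one + res_m.p_one == pytest.approx(1.0)

    def test_insufficient_and_degenerate(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test(make_effects([0.1, 0.2], [0.1, 0.2]))
        with pytest.raises(DegenerateDesignError):
            egger_test(make_effects([0.1, 0.2, 0.3], [0.2, 0.2, 0.2]))


class TestPeters:
    def test_exact_null(self):
        effs = make_effects([0, 0, 0, 0], [0.1, 0.2, 0.3, 0.4], n=[100, 200, 300, 400])
        res = peters_test(effs)
        assert res.coef == pytest.approx(0.0, abs=1e-12)
        assert res.p_two == pytest.approx(1.0)

    def test_matches_wls_oracle(self, five_study_fixture):
        res = peters_test(five_study_fixture)
        y = np.array([s.y for s in five_study_fixture])
        n = np.array([s.n_total for s in five_study_fixture])
        s_ev = np.array([s.events_total for s in five_study_fixture])
        f_ev = np.array([s.nonevents_total for s in five_study_fixture])
        beta, bse = wls_oracle(1.0 / n, y, 1.0 / (1.0 / s_ev + 1.0 / f_ev))
        assert res.coef == pytest.approx(beta[1], rel=1e-10)
        assert res.se_coef == pytest.approx(bse[1], rel=1e-10)

    def test_covariate_rescaling(self, five_study_fixture):
        """Doubling every N halves 1/N, doubling the slope; t and p are unchanged."""
        res = peters_test(five_study_fixture)
        doubled = make_effects(
            [s.y for s in five_study_fixture],
            [s.se for s in five_study_fixture],
            n=[2 * s.n_total for s in five_study_fixture],
            events=[s.events_total for s in five_study_fixture],
            nonevents=[s.nonevents_total for s in five_study_fixture],
        )
        res2 = peters_test(doubled)
        assert res2.coef == pytest.approx(2 * res.coef)
        assert res2.t == pytest.approx(res.t)
        assert res2.p_two == pytest.approx(res.p_two)

    def test_identical_n_degenerate(self):
        effs = make_effects([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], n=[100, 100, 100])
        with pytest.raises(DegenerateDesignError):
            peters_test(effs)


class TestOneSidedP:
    def test_t_zero_is_half(self):
        assert one_sided_p(0.0, 5, -1) == pytest.approx(0.5)
        assert one_sided_p(0.0, 5, +1) == pytest.approx(0.5)

    def test_quantile_identity(self):
        t_crit = stats.t.ppf(0.1, 4)  # about -1.533
        assert one_sided_p(t_crit, 4, -1) == pytest.approx(0.1)

    def test_symmetry(self):
        for t in (-2.3, -0.4, 0.9, 3.1):
            assert one_sided_p(t, 7, -1) + one_sided_p(-t, 7, -1) == pytest.approx(1.0)

    def test_halving_relation(self, five_study_fixture, rng):
        """p_one = p_two/2 when the coefficient sign matches the alternative."""
        for _ in range(20):
            effs = make_effects(rng.normal(0, 0.5, 6), rng.uniform(0.1, 0.6, 6))
            for res in (egger_test(effs), peters_test(effs)):
                if res.t < 0:  # matches suppress_high alternative
                    assert res.p_one == pytest.approx(res.p_two / 2)
                else:
                    assert res.p_one == pytest.approx(1 - res.p_two / 2)

    def test_direction_flip(self, five_study_fixture):
        hi = egger_test(five_study_fixture, direction=Direction.SUPPRESS_HIGH)
        lo = egger_test(five_study_fixture, direction=Direction.SUPPRESS_LOW)
        assert hi.p_one + lo.p_one == pytest.approx(1.0)
        assert hi.p_two == lo.p_two


class TestClassify:
    def _result(self, p_one, p_two):
        from ipbkit import AsymmetryTestResult

        return AsymmetryTestResult("egger", -1, 1, -1, 10, p_two, p_one,
                                   Direction.SUPPRESS_HIGH, 12)

    def test_one_sided_threshold(self):
        assert classify(self._result(0.09, 0.18), 0.1, "one").significant

    def test_discordance_two_sig_one_not(self):
        # wrong-direction asymmetry: two-sided significant, one-sided not
        r = self._result(0.955, 0.09)
        assert classify(r, 0.1, "two").significant
        assert not classify(r, 0.1, "one").significant

    def test_discordance_one_sig_two_not(self):
        r = self._result(0.075, 0.15)
        assert classify(r, 0.1, "one").significant
        assert not classify(r, 0.1, "two").significant
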