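import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipbkit import (
    ContingencyTable,
    InvalidInputError,
    StudyEffect,
    ZeroCellError,
    ZeroStatus,
    apply_zero_handling,
    log_odds_ratio,
    pool_fixed,
    pool_random,
    study_effect,
    tau2_dl,
    tau2_reml,
)
from conftest import make_effects

# metafor::rma oracle values for the 8-study fixture (frozen)
ORACLE_Y = [0.2, -0.3, 0.6, 0.1, -0.5, 0.4, 0.0, 0.8]
ORACLE_SE = [0.15, 0.2, 0.3, 0.25, 0.35, 0.18, 0.22, 0.4]
ORACLE_DL_TAU2 = 0.0661702746  # rma(method="DL")
ORACLE_REML_TAU2 = 0.066168528691  # bounded maximization of the restricted likelihood


class TestZeroHandling:
    @pytest.mark.parametrize(
        "cells,status",
        [
            ((0, 50, 5, 50), ZeroStatus.CONTINUITY_CORRECTED),
            ((5, 50, 0, 50), ZeroStatus.CONTINUITY_CORRECTED),
            ((0, 50, 0, 50), ZeroStatus.EXCLUDED_DOUBLE_ZERO),
            ((3, 50, 7, 50), ZeroStatus.UNMODIFIED),
            ((50, 50, 5, 50), ZeroStatus.CONTINUITY_CORRECTED),  # zero non-events arm
        ],
    )
    def test_status(self, cells, status):
        assert apply_zero_handling(ContingencyTable(*cells)).status is status

    def test_correction_hits_all_four_cells(self):
        out = apply_zero_handling(ContingencyTable(0, 50, 5, 50))
        assert out.corrected_table.cells() == (0.5, 50.5, 5.5, 45.5)
        assert out.corrected_table.total_trt == 51 and out.corrected_table.total_ctl == 51

    def test_degenerate_table_rejected(self):
        with pytest.raises(InvalidInputError):
            ContingencyTable(0, 0, 5, 50)
        with pytest.raises(InvalidInputError):
            ContingencyTable(6, 5, 1, 50)  # events exceed total


class TestLogOddsRatio:
    def test_identical_arms_null(self):
        y, se = log_odds_ratio(ContingencyTable(10, 100, 10, 100))
        assert y == 0.0
        assert se == pytest.approx(math.sqrt(2 * (1 / 10 + 1 / 90)))

    def test_direct_arithmetic(self):
        y, _ = log_odds_ratio(ContingencyTable(12, 100, 6, 100))
        assert y == pytest.approx(math.log(1128 / 528))

    def test_corrected_table_value(self):
        out = apply_zero_handling(ContingencyTable(0, 50, 5, 50))
        y, _ = log_odds_ratio(out.corrected_table)
        assert y == pytest.approx(math.log((0.5 * 45.5) / (50.5 * 5.5)))

    def test_zero_cell_refused(self):
        with pytest.raises(ZeroCellError):
            log_odds_ratio(ContingencyTable(0, 50, 5, 50))

    @given(
        a=st.integers(1, 49), c=st.integers(1, 49),
        nt=st.integers(50, 200), nc=st.integers(50, 200),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_arm_swap_antisymmetry(self, a, c, nt, nc):
        y1, se1 = log_odds_ratio(ContingencyTable(a, nt, c, nc))
        y2, se2 = log_odds_ratio(ContingencyTable(c, nc, a, nt))
        assert y2 == pytest.approx(-y1)
        assert se2 == pytest.approx(se1)

    def test_study_effect_keeps_raw_covariates(self):
        eff = study_effect(ContingencyTable(0, 50, 5, 50), "t1")
        assert eff.zero_status is ZeroStatus.CONTINUITY_CORRECTED
        assert eff.n_total == 100 and eff.events_total == 5 and eff.nonevents_total == 95
        assert study_effect(ContingencyTable(0, 50, 0, 50)) is None


class TestPooling:
    def test_single_study(self):
        r = pool_fixed(make_effects([0.5], [0.2]))
        assert (r.mu, r.se_mu, r.k) == (0.5, 0.2, 1)

    def test_equal_weights(self):
        r = pool_fixed(make_effects([0, 1], [1, 1]))
        assert r.mu == pytest.approx(0.5)
        assert r.se_mu == pytest.approx(1 / math.sqrt(2))

    def test_hand_computed_weights(self):
        r = pool_fixed(make_effects([0, 1], [0.5, 1]))
        assert r.mu == pytest.approx(0.2)
        assert r.se_mu == pytest.approx(math.sqrt(0.2))

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            pool_fixed([])

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 1)), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pooled_mu_is_convex_combination(self, pairs):
        effs = make_effects([p[0] for p in pairs], [p[1] for p in pairs])
        for r in (pool_fixed(effs), pool_random(effs)):
            assert min(p[0] for p in pairs) - 1e-9 <= r.mu <= max(p[0] for p in pairs) + 1e-9


class TestTau2:
    def test_homogeneous_is_zero(self):
        effs = make_effects([0.3] * 4, [0.1, 0.2, 0.3, 0.4])
        assert tau2_dl(effs) == 0.0
        t2, conv = tau2_reml(effs)
        assert t2 == pytest.approx(0.0, abs=1e-8) and conv

    def test_dl_closed_form_two_studies(self):
        assert tau2_dl(make_effects([0, 2], [1, 1])) == pytest.approx(1.0)

    def test_dl_matches_brute_force_q(self, rng):
        for _ in range(20):
            k = rng.integers(3, 12)
            y = rng.normal(0, 1, k)
            se = rng.uniform(0.1, 0.8, k)
            effs = make_effects(y, se)
            # independent brute-force moment computation
            w = 1 / se**2
            q = sum(wi * (yi - np.sum(w * y) / w.sum()) ** 2 for wi, yi in zip(w, y))
            expected = max(0.0, (q - (k - 1)) / (w.sum() - (w**2).sum() / w.sum()))
            assert tau2_dl(effs) == pytest.approx(expected, rel=1e-12)

    def test_dl_matches_metafor(self):
        assert tau2_dl(make_effects(ORACLE_Y, ORACLE_SE)) == pytest.approx(
            ORACLE_DL_TAU2, abs=1e-8
        )

    def test_reml_matches_likelihood_maximizer(self):
        t2, conv = tau2_reml(make_effects(ORACLE_Y, ORACLE_SE))
        assert conv
        assert t2 == pytest.approx(ORACLE_REML_TAU2, abs=1e-8)

    def test_reml_recovers_true_tau2(self, rng):
        # parameter recovery at k=50, tau2=0.25, se=0.1
        true = 0.25
        ests = []
        for _ in range(200):
            y = rng.normal(0.0, math.sqrt(0.1**2 + true), 50)
            t2, conv = tau2_reml(make_effects(y, [0.1] * 50))
            if conv:
                ests.append(t2)
        mean, sd = np.mean(ests), np.std(ests, ddof=1)
        assert abs(mean - true) < 3 * sd / math.sqrt(len(ests))

    def test_reml_and_dl_agree_on_large_k(self, rng):
        y = rng.normal(0.2, math.sqrt(0.3**2 + 0.2), 200)
        effs = make_effects(y, [0.3] * 200)
        t2, conv = tau2_reml(effs)
        assert conv
        assert t2 == pytest.approx(tau2_dl(effs), abs=0.05)

    def test_k1_rejected(self):
        with pytest.raises(InvalidInputError):
            tau2_dl(make_effects([0.1], [0.1]))


class TestPoolRandom:
    def test_tau2_zero_matches_fixed(self):
        effs = make_effects([0.3] * 5, [0.1, 0.2, 0.3, 0.25, 0.15])
        rr, rf = pool_random(effs), pool_fixed(effs)
        assert rr.mu == pytest.approx(rf.mu) and rr.se_mu == pytest.approx(rf.se_mu)
        assert rr.tau2_method == "REML"

    def test_symmetric_effects_pool_to_zero(self):
        r = pool_random(make_effects([-1, -0.5, 0.5, 1], [0.2] * 4))
        assert r.mu == pytest.approx(0.0, abs=1e-12)

    def test_nonconvergence_triggers_dl_fallback(self):
        # pathological two-study case: wildly unequal variances stall scoring
        effs = make_effects([0.0, 1.0], [1e-4, 10.0])
        _, conv = tau2_reml(effs)
        assert not conv
        r = pool_random(effs)
        assert r.tau2_method == "DL" and not r.converged
        assert r.tau2 == pytest.approx(tau2_dl(effs))

    def test_explicit_dl_request(self):
        effs = make_effects(ORACLE_Y, ORACLE_SE)
        r = pool_random(effs, tau2_method="DL")
        assert r.tau2_method == "DL"
        assert r.tau2 == pytest.approx(ORACLE_DL_TAU2, abs=1e-8)
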