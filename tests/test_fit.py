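"""Likelihood, grid search and pseudo-R2: hand values, oracle equivalence,
invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitbox import (
    AgentParams,
    SessionData,
    SessionFormatError,
    choice_probabilities,
    fit_grid,
    make_contingency,
    pseudo_r2,
    session_loglik,
    simulate_session,
    update_weight,
)
from fruitbox.agents import TRIAL_COLUMNS
from fruitbox.fit import FitGrid
from fruitbox.task import LEFT, RIGHT, STIMULI

CHANCE_96 = 96 * math.log(0.5)  # -66.5421


def make_session(rows, subject_id="t"):
    """Build a SessionData from (stimulus, response, us) triples."""
    records = [
        (i + 1, (i // 12) + 1, s, r, u, u) for i, (s, r, u) in enumerate(rows)
    ]
    return SessionData(
        subject_id=subject_id,
        schedule_seed=-1,
        agent_seed=-1,
        trials=pd.DataFrame(records, columns=TRIAL_COLUMNS),
    )


def naive_loglik(rows, alpha, beta, w_init=0.5):
    """Independent brute-force replay: pure-python dict-of-weights oracle."""
    w = {(s, r): w_init for s in STIMULI for r in (LEFT, RIGHT)}
    ll = 0.0
    for stim, resp, us in rows:
        el = math.exp(w[(stim, LEFT)] / beta)
        er = math.exp(w[(stim, RIGHT)] / beta)
        ll += math.log((el if resp == LEFT else er) / (el + er))
        w[(stim, resp)] += alpha * (us - w[(stim, resp)])
    return ll


class TestUpdateWeight:
    @pytest.mark.parametrize(
        "w,us,alpha,expected",
        [(0.5, 1, 0.5, 0.75), (0.5, 0, 0.5, 0.25), (0.3, 1, 0.0, 0.3)],
    )
    def test_hand_values(self, w, us, alpha, expected):
        assert update_weight(w, us, alpha) == pytest.approx(expected, abs=1e-15)

    @given(
        w=st.floats(0, 1), us=st.sampled_from([0, 1]), alpha=st.floats(0, 1)
    )
    @settings(derandomize=True)
    def test_closure_in_unit_interval(self, w, us, alpha):
        assert 0.0 <= update_weight(w, us, alpha) <= 1.0

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 1.0])
    def test_zero_prediction_error_is_fixed_point(self, alpha):
        assert update_weight(1.0, 1, alpha) == 1.0
        assert update_weight(0.0, 0, alpha) == 0.0


class TestChoiceProbabilities:
    def test_symmetry(self):
        assert choice_probabilities(0.4, 0.4, 0.2) == (0.5, 0.5)

    def test_hand_value(self):
        # e^{1.5} / (e^{1.5} + e^{1.0})
        p_left, p_right = choice_probabilities(0.75, 0.5, 0.5)
        assert p_left == pytest.approx(0.622459, abs=1e-6)
        assert p_right == pytest.approx(1 - 0.622459, abs=1e-6)

    def test_flat_limit_large_beta(self):
        p_left, _ = choice_probabilities(1.0, 0.0, 1e6)
        assert p_left == pytest.approx(0.5, abs=1e-6)

    def test_saturated_margin_keeps_tail_probability(self):
        # the losing side must stay strictly positive even when saturated
        _, p_right = choice_probabilities(1.0, 0.0, 0.01)
        assert 0 < p_right < 1e-40

    @given(
        wl=st.floats(0, 1), wr=st.floats(0, 1),
        beta=st.floats(0.01, 1.0),
    )
    @settings(derandomize=True)
    def test_probabilities_sum_to_one(self, wl, wr, beta):
        p_left, p_right = choice_probabilities(wl, wr, beta)
        assert p_left + p_right == pytest.approx(1.0, abs=1e-12)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            choice_probabilities(0.5, 0.5, 0.0)


class TestSessionLoglik:
    def test_chance_closed_form(self, contingency, example_session):
        lle, p = session_loglik(example_session, contingency, alpha=0.0, beta=0.37)
        assert lle == pytest.approx(CHANCE_96, abs=1e-9)
        assert np.allclose(p, 0.5)

    def test_single_trial_is_coin_flip(self, contingency):
        sess = make_session([(STIMULI[0], LEFT, 1)])
        for alpha, beta in [(0.1, 0.2), (0.9, 0.9)]:
            lle, _ = session_loglik(sess, contingency, alpha, beta)
            assert lle == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_brute_force_oracle_on_simulated_session(
        self, contingency, example_session
    ):
        rows = list(
            zip(
                example_session.trials["stimulus"],
                example_session.trials["response"],
                example_session.trials["us"],
            )
        )
        rng = np.random.default_rng(0)
        for _ in range(25):
            alpha, beta = rng.uniform(0, 1), rng.uniform(0.02, 1)
            lle, _ = session_loglik(example_session, contingency, alpha, beta)
            assert lle == pytest.approx(
                naive_loglik(rows, alpha, beta), rel=1e-12, abs=1e-12
            )

    def test_exhaustive_oracle_equivalence_short_sessions(self, contingency):
        # all 2-stimulus sessions of length <= 3, at several grid points
        stims = STIMULI[:2]
        params = [(0.0, 0.5), (0.3, 0.11), (0.77, 0.04), (1.0, 1.0)]
        events = [
            (s, r, int(r == contingency.correct_response[s]))
            for s in stims
            for r in (LEFT, RIGHT)
        ]
        for length in (1, 2, 3):
            for rows in itertools.product(events, repeat=length):
                sess = make_session(list(rows))
                for alpha, beta in params:
                    lle, _ = session_loglik(sess, contingency, alpha, beta)
                    assert lle == pytest.approx(
                        naive_loglik(list(rows), alpha, beta), abs=1e-12
                    )

    def test_malformed_sessions_rejected(self, contingency, example_session):
        bad = example_session.trials.copy()
        bad.loc[10, "stimulus"] = "S99"
        with pytest.raises(SessionFormatError, match="trial 11"):
            session_loglik(
                SessionData("x", -1, -1, bad), contingency, 0.5, 0.5
            )
        gap = example_session.trials.iloc[1:].reset_index(drop=True)
        with pytest.raises(SessionFormatError, match="without gaps"):
            session_loglik(
                SessionData("x", -1, -1, gap), contingency, 0.5, 0.5
            )


class TestFitGrid:
    def test_default_grid_axes(self):
        g = FitGrid.default()
        assert g.alpha_values[0] == 0.0 and g.alpha_values[-1] == 1.0
        assert len(g.alpha_values) == 101
        assert g.beta_values[0] == pytest.approx(0.01) and len(g.beta_values) == 100

    def test_grid_rejects_beta_zero(self):
        with pytest.raises(ValueError):
            FitGrid(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def test_landscape_matches_sequential_replay(
        self, contingency, example_session
    ):
        res = fit_grid(example_session, contingency)
        lle, _ = session_loglik(
            example_session, contingency, res.alpha_hat, res.beta_hat
        )
        assert res.lle == pytest.approx(lle, abs=1e-9)

    def test_optimum_dominates_generating_parameters(self, contingency, schedule):
        for seed in range(10):
            sess = simulate_session(
                AgentParams(0.25, 0.6), contingency, schedule, seed=seed
            )
            res = fit_grid(sess, contingency)
            at_truth, _ = session_loglik(sess, contingency, 0.25, 0.6)
            assert res.lle >= at_truth - 1e-9
            assert res.lle >= CHANCE_96 - 1e-9
            assert res.pseudo_r2 >= 0.0

    def test_tie_break_smallest_beta_then_alpha(self, contingency):
        # a single-trial session is chance at every grid point: full tie
        sess = make_session([(STIMULI[0], LEFT, 1)])
        res = fit_grid(sess, contingency)
        assert res.alpha_hat == 0.0
        assert res.beta_hat == pytest.approx(0.01)

    def test_recovery_rank_correlation_positive(self, contingency):
        # recoverability is monotone, not sharp, at 96 trials: the frozen
        # expectation (Spearman ~ 0.37 over alpha U[0.05,0.45], beta
        # U[0.4,1.0]) was measured with this seeded simulation itself
        from scipy.stats import spearmanr

        from fruitbox import build_schedule

        rng = np.random.default_rng(1)
        true_a, hat_a = [], []
        for ss in np.random.SeedSequence(42).spawn(120):
            s = np.random.default_rng(ss).integers(2**31, size=3)
            a, b = rng.uniform(0.05, 0.45), rng.uniform(0.4, 1.0)
            c = make_contingency(int(s[0]))
            sched = build_schedule(c, int(s[1]))
            res = fit_grid(
                simulate_session(AgentParams(a, b), c, sched, int(s[2])), c
            )
            true_a.append(a)
            hat_a.append(res.alpha_hat)
        assert spearmanr(true_a, hat_a).statistic > 0.25


class TestPseudoR2:
    @pytest.mark.parametrize(
        "lle,n,expected",
        [
            (CHANCE_96, 96, 0.0),
            (-50.0, 96, 0.248587),
            (0.0, 96, 1.0),
        ],
    )
    def test_values(self, lle, n, expected):
        assert pseudo_r2(lle, n) == pytest.approx(expected, abs=1e-5)

    def test_rejects_positive_loglik(self):
        with pytest.raises(ValueError):
            pseudo_r2(0.1, 96)
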