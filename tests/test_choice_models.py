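from itertools import combinations

import numpy as np
import pytest

from accumtowers.choice_models import (
    CueOrderDesign,
    HistoryModelParams,
    StrategyModelSpec,
    alternation_bias,
    build_cue_order_design,
    estimate_side_lapses,
    fit_history_model,
    fixed_total_linearity_test,
    history_model_pR,
    history_vector,
    k_random_tower_pRm,
    perseveration_run_mask,
    psychometric_excluding_perseveration,
    strategy_predict,
)
from accumtowers.datamodel import mirror_trial, NoTrialsError, UndefinedStatisticError
from accumtowers.agents import AgentSpec, simulate_dataset

from conftest import make_trial, draw_stimulus_trials


def brute_force_k_random(n_right, n_left, k):
    towers = ["R"] * n_right + ["L"] * n_left
    total = 0.0
    count = 0
    for chosen in combinations(range(len(towers)), k):
        k_r = sum(1 for i in chosen if towers[i] == "R")
        count += 1
        if 2 * k_r > k:
            total += 1.0
        elif 2 * k_r == k:
            total += 0.5
    return total / count


class TestStrategyModels:
    def test_hypergeometric_matches_enumeration_exactly(self):
        for total in range(1, 11):
            for n_r in range(total + 1):
                for k in (1, 3, 5, 7):
                    if k > total:
                        continue
                    assert k_random_tower_pRm(n_r, total - n_r, k) == pytest.approx(
                        brute_force_k_random(n_r, total - n_r, k), abs=1e-12
                    )

    def test_k3_example(self):
        # k=3 of (3R, 1L): at most one L can be drawn, majority always right
        assert k_random_tower_pRm(3, 1, 3) == pytest.approx(1.0)

    def test_k1_with_lapses(self):
        spec = StrategyModelSpec(kind="k_random", k=1, lapse_r=0.1, lapse_l=0.2)
        t = make_trial((40.0,), (25.0, 80.0, 120.0))
        assert strategy_predict(spec, t) == pytest.approx(0.1 + 0.7 * 0.75)

    def test_full_information_limit(self):
        t = make_trial((40.0,), (25.0, 80.0, 120.0))
        spec = StrategyModelSpec(kind="k_random", k=4)
        assert strategy_predict(spec, t) == pytest.approx(1.0)
        tm = mirror_trial(t)
        assert strategy_predict(spec, tm) == pytest.approx(0.0)

    def test_first_last_tower(self):
        t = make_trial((30.0,), (20.0, 60.0))  # first tower R, last tower R
        assert strategy_predict(StrategyModelSpec(kind="first_tower"), t) == 1.0
        assert strategy_predict(StrategyModelSpec(kind="last_tower"), t) == 1.0
        t2 = make_trial((10.0, 199.0), (20.0, 60.0, 100.0))
        assert strategy_predict(StrategyModelSpec(kind="first_tower"), t2) == 0.0
        assert strategy_predict(StrategyModelSpec(kind="last_tower"), t2) == 0.0


class TestSideLapses:
    def test_counting(self):
        only_left = [
            make_trial((20.0, 60.0), (), choice="R" if i < 12 else "L", index=i)
            for i in range(100)
        ]
        only_right = [
            make_trial((), (20.0, 60.0), choice="R", index=100 + i) for i in range(50)
        ]
        lr, ll = estimate_side_lapses(only_left + only_right)
        assert lr == pytest.approx(0.12)
        assert ll == pytest.approx(0.0)

    def test_missing_side_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            estimate_side_lapses([make_trial((), (20.0,), index=0)])


class TestHistoryModel:
    def test_zero_parameters_give_f_right(self):
        trials = draw_stimulus_trials(400, seed=1)
        params = HistoryModelParams(beta_delta=np.zeros(5))
        from accumtowers.evidence_weighting import spatial_evidence_matrix

        X = spatial_evidence_matrix(trials)
        h = np.tile(history_vector("R", True), (len(trials), 1))
        e = -np.ones(len(trials))
        p0 = 0.37  # arbitrary dataset logit
        p = history_model_pR(params, p0, X, h, e)
        assert np.allclose(p, 1.0 / (1.0 + np.exp(-p0)))

    def test_mirror_invariance_of_likelihood(self):
        # mirroring the data while flipping beta0, negating the outcome-history
        # weight, and swapping the side-lapse baselines leaves the likelihood
        # identical to machine precision
        from accumtowers.evidence_weighting import spatial_evidence_matrix
        from accumtowers.choice_models import previous_trial_features

        ds = simulate_dataset(
            AgentSpec(kind="k_random_tower", k=1, lapse_r=0.1, lapse_l=0.15),
            n_sessions=3, trials_per_session=120,
            rng=np.random.default_rng(2), include_protocol=False,
        )
        params = HistoryModelParams(
            beta0=0.3, beta_delta=np.array([0.4, 0.3, 0.2, 0.2, 0.1]),
            beta_e=0.2, beta0_r=0.4, beta0_l=0.25,
            beta_h=np.array([0.15, -0.08, 0.05]),
        )
        mirrored_params = HistoryModelParams(
            beta0=-params.beta0, beta_delta=params.beta_delta,
            beta_e=params.beta_e, beta0_r=params.beta0_l, beta0_l=params.beta0_r,
            beta_h=params.beta_h * np.array([1.0, -1.0, 1.0]),
        )

        def loglik(trials, pars, p0):
            X = spatial_evidence_matrix(trials)
            h, e, valid = previous_trial_features(trials)
            keep = np.where(valid)[0]
            p = history_model_pR(pars, p0, X[keep], h[keep], e[keep])
            c = np.array([1.0 if trials[i].choice == "R" else 0.0 for i in keep])
            return float(np.sum(c * np.log(p) + (1 - c) * np.log(1 - p)))

        mirrored = [mirror_trial(t) for t in ds.trials]
        a = loglik(ds.trials, params, p0=0.11)
        b = loglik(mirrored, mirrored_params, p0=-0.11)
        assert a == pytest.approx(b, rel=1e-12)

    def test_l1_path_shrinks_history_weights(self):
        true = HistoryModelParams(
            beta_delta=np.array([0.3] * 5), beta0_r=0.5, beta0_l=0.5,
            beta_h=np.array([0.4, -0.3, 0.1]),
        )
        ds = simulate_dataset(
            AgentSpec(kind="logistic_history", history=true),
            n_sessions=6, trials_per_session=250,
            rng=np.random.default_rng(3), include_protocol=False,
        )
        norms = []
        for pen in (0.0, 30.0, 300.0):
            fit = fit_history_model(ds.trials, penalty=pen, n_starts=1)
            norms.append(np.sum(np.abs(fit.params.beta_h)))
        assert norms[0] > 0.1  # history clearly present without penalty
        assert norms[0] >= norms[1] - 1e-6 >= norms[2] - 2e-6
        assert norms[2] < 0.5 * norms[0]

    def test_parameter_recovery(self):
        true = HistoryModelParams(
            beta0=0.0,
            beta_delta=np.array([0.35, 0.3, 0.25, 0.2, 0.15]),
            beta_e=0.15, beta0_r=0.35, beta0_l=0.30,
            beta_h=np.array([0.2, -0.1, 0.05]),
        )
        ds = simulate_dataset(
            AgentSpec(kind="logistic_history", history=true, history_p0=0.0),
            n_sessions=25, trials_per_session=400,
            rng=np.random.default_rng(7), include_protocol=False,
        )
        fit = fit_history_model(ds.trials, penalty=1e-3)
        assert np.allclose(fit.params.beta_delta, true.beta_delta, atol=0.08)
        assert fit.params.beta_e == pytest.approx(true.beta_e, abs=0.08)
        assert np.allclose(fit.params.beta_h, true.beta_h, atol=0.08)
        assert fit.params.beta0_r == pytest.approx(true.beta0_r, abs=0.12)
        assert fit.params.beta0_l == pytest.approx(true.beta0_l, abs=0.12)


class TestCueOrderDesign:
    def test_hand_ranking(self):
        # pooled ranks: R@20, L@30, R@50 -> first triplet #R - #L = 1
        t = make_trial((30.0,), (20.0, 50.0))
        design = build_cue_order_design([t] * 60)
        assert design.dimension == 1
        assert np.allclose(design.matrix[:, 0], 1.0)  # <|delta|>_3 = 1

    def test_dimension_rule(self):
        rich = [
            make_trial(tuple(np.arange(20.0, 20.0 + 12.0 * 4, 12.0)),
                       tuple(np.arange(26.0, 26.0 + 12.0 * 5, 12.0)), index=i)
            for i in range(60)
        ]  # 9 cues
        poor = [
            make_trial((30.0,), tuple(20.0 + 12.0 * k for k in range(5)), index=100 + i)
            for i in range(40)
        ]  # 6 cues
        design = build_cue_order_design(rich[:20] + poor + rich[20:40])
        # 60 trials with >= 6 cues, only 40 with >= 9 -> D = 2
        assert design.dimension == 2

    def test_cross_side_tie_break_right_first(self):
        t = make_trial((20.0,), (20.0, 40.0))
        pooled = t.all_towers()
        assert pooled[0] == (20.0, "R")


class TestAlternationBias:
    def test_history_blind_agent_near_zero(self, rng):
        # open-loop stimulus (independent sides): a history-blind agent shows
        # no alternation bias.  (Closed-loop debiasing genuinely induces
        # small sequential correlations, so it is bypassed here.)
        trials = []
        for i, t in enumerate(draw_stimulus_trials(2500, seed=13)):
            p = t.n_right / (t.n_right + t.n_left)
            p = 0.1 + 0.8 * p
            choice = "R" if rng.uniform() < p else "L"
            trials.append(make_trial(t.towers_left, t.towers_right, choice=choice,
                                     index=i))
        for cond in ("post_reward", "post_error"):
            assert abs(alternation_bias(trials, cond)) < 4.0

    def test_alternating_agent_mixture(self, rng):
        # agent alternates with p 0.8 after reward, 0.5 after error
        trials = []
        prev_choice, prev_correct = "R", True
        for i in range(6000):
            p_alt = 0.8 if prev_correct else 0.5
            alt = rng.uniform() < p_alt
            choice = ("L" if prev_choice == "R" else "R") if alt else prev_choice
            rewarded = "R" if rng.uniform() < 0.5 else "L"
            trials.append(make_trial((40.0,), (25.0, 80.0), choice=choice, index=i)
                          if rewarded == "R" else
                          make_trial((25.0, 80.0), (40.0,), choice=choice, index=i))
            prev_choice, prev_correct = choice, choice == rewarded
        post_r = alternation_bias(trials, "post_reward")
        post_e = alternation_bias(trials, "post_error")
        # overall alternation = 0.5 * 0.8 + 0.5 * 0.5 = 0.65
        assert post_r == pytest.approx(100 * (0.80 - 0.65), abs=2.5)
        assert post_e == pytest.approx(100 * (0.50 - 0.65), abs=2.5)

    def test_perseverating_agent_negative_run_bias(self, rng):
        # repeats after error with p 0.9; alternates after reward with p 0.6
        trials = []
        prev_choice, prev_correct = "R", True
        for i in range(8000):
            p_alt = 0.6 if prev_correct else 0.1
            alt = rng.uniform() < p_alt
            choice = ("L" if prev_choice == "R" else "R") if alt else prev_choice
            rewarded = "R" if rng.uniform() < 0.5 else "L"
            trials.append(make_trial((40.0,), (25.0, 80.0), choice=choice, index=i)
                          if rewarded == "R" else
                          make_trial((25.0, 80.0), (40.0,), choice=choice, index=i))
            prev_choice, prev_correct = choice, choice == rewarded
        biases = [
            alternation_bias(trials, "run_unrewarded", run_length=r) for r in (1, 2, 3)
        ]
        assert biases[0] < 0
        assert biases[2] <= biases[0] + 2.0  # magnitude grows with run length


class TestPerseverationExclusion:
    def test_mask_finds_runs(self):
        choices = ["R", "R", "R", "L", "R", "L", "L", "L", "L"]
        trials = [make_trial((40.0,), (25.0, 80.0), choice=c, index=i)
                  for i, c in enumerate(choices)]
        mask = perseveration_run_mask(trials, run_len=3)
        assert mask.tolist() == [True, True, True, False, False, True, True, True, True]

    def test_run_len_one_removes_everything(self):
        trials = [make_trial((40.0,), (25.0, 80.0), index=i) for i in range(10)]
        with pytest.raises(NoTrialsError):
            psychometric_excluding_perseveration(trials, run_len=1)


class TestFixedTotalLinearity:
    @staticmethod
    def _fixed_total_trials(n, total, p_of_delta, rng):
        trials = []
        for i in range(n):
            n_r = int(rng.integers(0, total + 1))
            if 2 * n_r == total:
                n_r += 1 if rng.uniform() < 0.5 else -1
            n_l = total - n_r
            tl = tuple(10.0 + 12.1 * k for k in range(n_l))
            tr = tuple(10.5 + 12.1 * k for k in range(n_r))
            choice = "R" if rng.uniform() < p_of_delta(n_r - n_l, total) else "L"
            trials.append(make_trial(tl, tr, choice=choice, index=i))
        return trials

    def test_line_model_data_uniformish_p(self, rng):
        trials = self._fixed_total_trials(
            800, 10, lambda d, tot: (d + tot) / (2 * tot), rng
        )
        _, p = fixed_total_linearity_test(trials, total=10, n_null=300,
                                          rng=np.random.default_rng(0), min_trials=100)
        assert p > 0.01

    def test_steep_sigmoid_rejected(self, rng):
        trials = self._fixed_total_trials(
            2000, 10, lambda d, tot: 1.0 / (1.0 + np.exp(-d / 1.5)), rng
        )
        _, p = fixed_total_linearity_test(trials, total=10, n_null=500,
                                          rng=np.random.default_rng(0), min_trials=100)
        assert p < 0.01

    def test_insufficient_trials(self, rng):
        trials = self._fixed_total_trials(50, 10, lambda d, tot: 0.5, rng)
        with pytest.raises(NoTrialsError):
            fixed_total_linearity_test(trials, total=10)
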