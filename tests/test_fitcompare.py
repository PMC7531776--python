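import dataclasses
import itertools
import math

import numpy as np
import pytest

from flyforage import fitcompare as fc
from flyforage.rlmodels import RLParams, simulate_rl_agent
from flyforage.trials import ChoiceSequence


def _seq(rewards, choices):
    return ChoiceSequence(rewards=rewards, choices=choices)


class TestSequenceLogLikelihood:
    def test_beta_zero_gives_log_half(self):
        p = RLParams(model="FQ", alpha=0.7, beta=0.0, bias=0.9)
        seq = _seq([1, 0, 1, 1, 0], [0, 1, 1, 0, 0])
        assert fc.sequence_log_likelihood(p, seq) == pytest.approx(np.log(0.5))

    def test_perfect_fit_limit(self):
        # all returns, P driven to ~1
        p = RLParams(model="FQ", alpha=0.0, beta=50.0, bias=-1.0)
        seq = _seq([1] * 20, [1] * 20)
        ll = fc.sequence_log_likelihood(p, seq)
        assert -1e-6 < ll <= 0.0

    def test_tiny_instance_matches_hand_evaluation(self):
        # independent per-trial enumeration of the mean log likelihood
        p = RLParams(model="FQ", alpha=0.5, beta=2.0, bias=0.25)
        r = [1, 0, 1, 0]
        c = [1, 0, 0, 1]
        q = 0.0
        terms = []
        for rt, ct in zip(r, c):
            prob = 1.0 / (1.0 + math.exp(p.beta * (p.bias - q)))
            terms.append(ct * math.log(prob) + (1 - ct) * math.log(1 - prob))
            q = q + p.alpha * (rt - q) if ct else q - p.phi * q
        expected = sum(terms) / 4
        assert fc.sequence_log_likelihood(p, _seq(r, c)) == pytest.approx(expected)

    def test_empty_rejected(self):
        p = RLParams(model="FQ")
        with pytest.raises(ValueError):
            fc.sequence_log_likelihood(p, _seq([], []))


class TestAic:
    def test_example(self):
        assert fc.aic_score(-100.0, 3) == pytest.approx(206.0)

    def test_extra_parameter_penalized(self):
        assert fc.aic_score(-100.0, 4) == pytest.approx(208.0)

    def test_zero(self):
        assert fc.aic_score(0.0, 0) == 0.0


class TestFitMultistart:
    def test_determinism(self):
        seq, _ = simulate_rl_agent(RLParams(model="FQ", alpha=0.4, beta=6.0,
                                            bias=0.5), 0.3, 400, seed=0)
        a = fc.fit_mle_multistart("FQ", seq, n_init=5, seed=11)
        b = fc.fit_mle_multistart("FQ", seq, n_init=5, seed=11)
        assert a.params == b.params
        assert a.logL_mean == b.logL_mean

    def test_fit_dominates_generator(self):
        gen = RLParams(model="FQ", alpha=0.4, beta=6.0, bias=0.5)
        seq, _ = simulate_rl_agent(gen, 0.3, 2000, seed=1)
        fit = fc.fit_mle_multistart("FQ", seq, n_init=10, seed=2)
        assert fit.logL_mean >= fc.sequence_log_likelihood(gen, seq) - 1e-12

    def test_aic_relation(self):
        seq, _ = simulate_rl_agent(RLParams(model="FQ", alpha=0.3, beta=5.0,
                                            bias=0.3), 0.3, 300, seed=3)
        fit = fc.fit_mle_multistart("FQ", seq, n_init=5, seed=4)
        assert fit.logL_total == pytest.approx(fit.n_trials * fit.logL_mean)
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.logL_total)
        assert fit.logL_mean <= 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fc.fit_mle_multistart("FQ", _seq([1, 0], [0, 1]), n_init=2, seed=0)

    def test_mle_matches_grid_search_small_instance(self):
        # N <= 6: dense grid over (alpha, beta, bias) as independent oracle
        seq = _seq([1, 0, 1, 1, 0, 1], [1, 0, 1, 1, 1, 0])
        fit = fc.fit_mle_multistart("FQ", seq, n_init=40, seed=5, min_length=1)
        alphas = np.linspace(0, 1, 21)
        betas = np.linspace(0, 50, 51)
        biases = np.linspace(-1, 2, 31)
        best = -np.inf
        for a, b, d in itertools.product(alphas, betas, biases):
            p = RLParams(model="FQ", alpha=a, beta=b, bias=d)
            ll = fc.sequence_log_likelihood(p, seq)
            if ll > best:
                best = ll
        assert fit.logL_mean >= best - 1e-9  # optimum dominates grid
        assert fit.logL_mean - best < 0.05   # and grid is close at this density

    def test_nested_model_never_fits_worse(self):
        seq, _ = simulate_rl_agent(RLParams(model="FQ", alpha=0.35, beta=6.0,
                                            bias=0.4), 0.3, 1500, seed=6)
        fq = fc.fit_mle_multistart("FQ", seq, n_init=15, seed=7)
        fqaf = fc.fit_mle_multistart("FQaF", seq, n_init=30, seed=8)
        assert fqaf.logL_total >= fq.logL_total - 1e-6


class TestSelectModel:
    @staticmethod
    def _fit(model, aic):
        p = RLParams(model=model, alpha=0.3, beta=5.0, bias=0.3,
                     alpha_f=0.2 if model == "FQaF" else None)
        return fc.FitResult(params=p, logL_mean=-0.5, logL_total=-50.0,
                            aic=aic, n_trials=100, n_init=1, best_init=0,
                            converged=True)

    def test_minimum_aic_wins(self):
        fits = {"RW": self._fit("RW", 210.0), "FQ": self._fit("FQ", 205.0),
                "FQaF": self._fit("FQaF", 207.0)}
        winner, delta = fc.select_model(fits)
        assert winner == "FQ"
        assert delta["FQ"] == 0.0 and delta["RW"] == pytest.approx(5.0)

    def test_tie_prefers_fewer_parameters(self):
        fits = {"RW": self._fit("RW", 206.0), "FQaF": self._fit("FQaF", 206.0)}
        winner, _ = fc.select_model(fits)
        assert winner == "RW"

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            fc.select_model({"FQ": self._fit("FQ", 100.0)})


class TestPredictiveF1:
    def test_perfect_predictions(self):
        p = RLParams(model="FQ", alpha=0.0, beta=50.0, bias=-1.0)  # P ~ 1
        seq = _seq([1, 1, 1, 1], [1, 1, 1, 1])
        s = fc.predictive_f1(p, seq)
        assert s.precision == s.recall == s.f1 == 1.0

    def test_rate_arithmetic(self):
        # TP=FP=FN=0.25 -> precision=recall=F1=0.5 (checked via Eqs on rates)
        tp = fp = fn = 0.25
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall)
        assert precision == recall == f1 == 0.5

    def test_never_predicts_returns_f1_zero(self):
        p = RLParams(model="FQ", alpha=0.0, beta=50.0, bias=2.0)  # P ~ 0
        seq = _seq([1, 0, 1, 0], [1, 0, 1, 0])
        s = fc.predictive_f1(p, seq)
        assert s.tp == 0.0 and s.f1 == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fc.predictive_f1(RLParams(model="FQ"), _seq([], []))

    def test_split_is_chronological_halves(self):
        seq = ChoiceSequence(rewards=[1, 0, 1, 0, 1], choices=[0, 1, 0, 1, 0],
                             t_reward=np.arange(5.0))
        train, test = fc.split_sequence(seq)
        assert len(train) == 2 and len(test) == 3
        np.testing.assert_array_equal(train.rewards, [1, 0])
        np.testing.assert_array_equal(test.t_reward, [2.0, 3.0, 4.0])


class TestGenerativeTest:
    def test_random_agent_reward_independent(self):
        out = fc.generative_test("random", None, [0.3], n_seq=200, n_trials=300,
                                 seed=0)
        res = out[0.3]
        assert abs(res["p_return_rewarded"] - 0.5) < 0.02
        assert abs(res["p_return_unrewarded"] - 0.5) < 0.02

    def test_deterministic_agent_zero_unrewarded(self):
        out = fc.generative_test("deterministic", None, [0.3], n_seq=100,
                                 n_trials=200, seed=1)
        assert out[0.3]["p_return_unrewarded"] == 0.0

    def test_fq_returns_more_after_rewards(self):
        p = RLParams(model="FQ", alpha=0.3, beta=6.0, bias=0.3)
        out = fc.generative_test("FQ", p, [0.3], n_seq=300, n_trials=300, seed=2)
        res = out[0.3]
        assert res["p_return_rewarded"] > res["p_return_unrewarded"]

    def test_run_length_bookkeeping(self):
        p = RLParams(model="FQ", alpha=0.3, beta=6.0, bias=0.3)
        out = fc.generative_test("FQ", p, [0.15, 0.6], n_seq=50, n_trials=100,
                                 seed=3)
        assert set(out) == {0.15, 0.6}
        for res in out.values():
            assert res["run_length_mean"].shape == (20,)
            assert np.all(res["run_length_mean"] >= 0)
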