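import numpy as np
import pytest

from accumtowers.datamodel import mirror_trial, UndefinedStatisticError
from accumtowers.psychometrics import (
    DeltaBins,
    bin_delta,
    fit_psychometric,
    jeffreys_interval,
    lapse_rate,
    performance_factors,
    surrogate_top_block_test,
)

from conftest import make_trial


def trials_with_deltas(delta_counts, choice_p=None, rng=None):
    """Trials realizing given {delta: n} counts; choices optional Bernoulli."""
    trials = []
    i = 0
    for delta, n in delta_counts.items():
        for _ in range(n):
            nr = max(delta, 0) + 3
            nl = nr - delta
            tl = tuple(10.0 + 12.5 * k for k in range(nl))
            tr = tuple(11.0 + 12.5 * k for k in range(nr))
            choice = None
            if choice_p is not None:
                choice = "R" if rng.uniform() < choice_p(delta) else "L"
            trials.append(make_trial(tl, tr, choice=choice, index=i))
            i += 1
    return trials


class TestBinDelta:
    def test_weighted_abscissa(self):
        trials = trials_with_deltas({0: 10, 1: 20, 2: 10})
        bins = bin_delta(trials)
        assert len(bins.abscissa) == 1
        assert bins.abscissa[0] == pytest.approx(1.0)

    def test_single_delta(self):
        bins = bin_delta(trials_with_deltas({3: 25}))
        assert bins.abscissa[0] == pytest.approx(3.0)
        assert bins.n[0] == 25

    def test_symmetric_dataset_antisymmetric_bins(self):
        counts = {d: 10 + 2 * abs(d) for d in range(-4, 5)}  # 9 unique values
        bins = bin_delta(trials_with_deltas(counts))
        assert np.allclose(bins.abscissa, -bins.abscissa[::-1])


class TestFitPsychometric:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        b, a, d0, lam = 0.05, 0.9, 0.0, 3.0

        def curve(d):
            return b + a / (1 + np.exp(-(d - d0) / lam))

        counts = {d: 400 for d in range(-12, 13, 2)}
        trials = trials_with_deltas(counts, choice_p=curve, rng=rng)
        fit = fit_psychometric(trials)
        assert fit.b == pytest.approx(b, abs=0.05)
        assert fit.a == pytest.approx(a, abs=0.08)
        assert fit.delta0 == pytest.approx(d0, abs=0.6)
        assert fit.lam_sig == pytest.approx(lam, abs=0.6)

    def test_slope_closed_form(self):
        # a=1, b=0, lam=1 -> slope a/(4 lam) = 0.25
        from accumtowers.psychometrics import PsychometricFit

        f = PsychometricFit(b=0.0, a=1.0, delta0=0.0, lam_sig=1.0,
                            bins=None, converged=True, n_trials=0)
        assert f.slope == pytest.approx(0.25)

    def test_step_function_flagged(self):
        rng = np.random.default_rng(1)
        deltas = [d for d in range(-6, 7) if d != 0]  # 12 values -> 4 pure bins
        trials = trials_with_deltas(
            {d: 60 for d in deltas}, choice_p=lambda d: 1.0 if d > 0 else 0.0,
            rng=rng,
        )
        with pytest.warns(UserWarning):
            fit = fit_psychometric(trials)
        assert not fit.converged
        assert np.isfinite(fit.slope) and fit.slope > 1.0

    def test_self_consistency_on_simulated_curve(self):
        rng = np.random.default_rng(9)
        counts = {d: 300 for d in range(-13, 14)}
        trials = trials_with_deltas(counts, choice_p=lambda d: 0.1 + 0.8 / (1 + np.exp(-d / 2.5)), rng=rng)
        fit = fit_psychometric(trials)
        resim = trials_with_deltas(counts, choice_p=lambda d: float(fit.predict(np.array([d]))[0]), rng=rng)
        refit = fit_psychometric(resim)
        assert refit.slope == pytest.approx(fit.slope, abs=3 * 0.015)


class TestLapseRate:
    def test_perfect_agent_zero(self):
        trials = trials_with_deltas({11: 40, -12: 40})
        rate, _ = lapse_rate(trials)
        assert rate == 0.0

    def test_counting_arithmetic(self):
        trials = trials_with_deltas({11: 34})
        bad = trials_with_deltas({11: 6})
        bad = [make_trial(t.towers_left, t.towers_right, choice="L", index=100 + i)
               for i, t in enumerate(bad)]
        rate, (lo, hi) = lapse_rate(trials + bad)
        assert rate == pytest.approx(15.0)
        assert lo < 15.0 < hi

    def test_no_easy_trials(self):
        with pytest.raises(UndefinedStatisticError):
            lapse_rate(trials_with_deltas({2: 50}))

    def test_agrees_with_sigmoid_asymptote(self):
        rng = np.random.default_rng(10)
        b, a = 0.08, 0.84  # implied lapse: (b + 1 - (b+a)) / 2 = 12%
        trials = trials_with_deltas(
            {d: 500 for d in list(range(-14, -9)) + list(range(10, 15))},
            choice_p=lambda d: b + a / (1 + np.exp(-d / 2.0)), rng=rng)
        rate, _ = lapse_rate(trials)
        implied = 100.0 * 0.5 * (b + 1 - (b + a))
        assert rate == pytest.approx(implied, abs=1.5)


class TestJeffreys:
    def test_interval_brackets_fraction(self):
        lo, hi = jeffreys_interval(30, 100)
        assert lo < 0.3 < hi
        assert hi - lo < 0.12


def _session_blocks(rng, n_blocks, trials_per_block, lapse_by_block, mouse="m1"):
    trials = []
    idx = 0
    for b in range(n_blocks):
        lapse = lapse_by_block(b)

        def curve(d, lapse=lapse):
            return lapse + (1 - 2 * lapse) / (1 + np.exp(-d / 2.5))

        for _ in range(trials_per_block):
            d = int(rng.integers(-12, 13))
            nr = max(d, 0) + 3
            nl = nr - d
            tl = tuple(10.0 + 12.5 * k for k in range(nl))
            tr = tuple(11.0 + 12.5 * k for k in range(nr))
            choice = "R" if rng.uniform() < curve(d) else "L"
            trials.append(
                make_trial(tl, tr, choice=choice, index=idx, mouse=mouse,
                           session=f"s{b:03d}", block=0)
            )
            idx += 1
    return trials


class TestSurrogateTopBlock:
    def test_planted_lapse_detected_slope_not(self):
        rng = np.random.default_rng(77)
        # 20 blocks; five "good" blocks have much lower lapse, same slope scale
        trials = _session_blocks(
            rng, 20, 100, lambda b: 0.02 if b < 5 else 0.25
        )
        res = surrogate_top_block_test(
            trials, n_surrogates=60, min_trials=200, rng=np.random.default_rng(0)
        )
        stats = res.per_mouse["m1"]
        assert stats["p_lapse"] < 0.05
        # static-curve sampling explains the slope improvement
        static = _session_blocks(rng, 20, 100, lambda b: 0.15, mouse="m2")
        res2 = surrogate_top_block_test(
            static, n_surrogates=60, min_trials=200, rng=np.random.default_rng(1)
        )
        assert res2.per_mouse["m2"]["p_slope"] > 0.05

    def test_small_mouse_excluded(self):
        rng = np.random.default_rng(3)
        tiny = _session_blocks(rng, 3, 30, lambda b: 0.2)
        res = surrogate_top_block_test(tiny, n_surrogates=5, min_trials=300)
        assert res.excluded_mice == ["m1"]


class TestPerformanceFactors:
    def test_recovery_of_planted_coefficients(self):
        rng = np.random.default_rng(55)
        trials = []
        idx = 0
        for mouse in ("m1", "m2", "m3"):
            base = {"m1": 0.70, "m2": 0.75, "m3": 0.65}[mouse]
            for _ in range(5000):
                nl = int(rng.integers(0, 7))
                d = int(rng.integers(1, 9))
                nr = nl + d
                total = nl + nr
                tl = tuple(float(v) for v in np.sort(rng.uniform(10, 200, nl)))
                tr = tuple(float(v) for v in np.sort(rng.uniform(10, 200, nr)))
                # planted: performance rises with |delta| (2 %/tower), falls
                # with total (-0.5 %/tower), ignores duration
                p = np.clip(base + 0.02 * d - 0.005 * total, 0.05, 0.98)
                choice = "R" if (rng.uniform() < p) else "L"
                trials.append(make_trial(tl, tr, choice=choice, index=idx, mouse=mouse))
                idx += 1
        fit = performance_factors(trials)
        c_delta, c_total, c_dur = fit.coefficients
        assert c_delta > 0 and fit.p_values[0] < 0.05
        assert c_total < 0 and fit.p_values[1] < 0.05
        assert fit.p_values[2] > 0.01  # duration not significant
        # recovered magnitudes on the percent scale (2 %/tower, -0.5 %/tower);
        # the binned-cell design attenuates somewhat, so bands are broad
        assert 1.0 < c_delta < 3.2
        assert -1.3 < c_total < -0.1

    def test_invariant_to_mouse_offsets(self):
        rng = np.random.default_rng(56)
        base_trials = []
        for mouse, base in (("m1", 0.7), ("m2", 0.7)):
            for i in range(1500):
                d = int(rng.integers(1, 10))
                tl = tuple(float(v) for v in np.sort(rng.uniform(10, 200, 2)))
                tr = tuple(float(v) for v in np.sort(rng.uniform(10, 200, 2 + d)))
                p = np.clip(base + 0.02 * d, 0, 0.99)
                choice = "R" if rng.uniform() < p else "L"
                base_trials.append(make_trial(tl, tr, choice=choice, index=i, mouse=mouse))
        fit = performance_factors(base_trials)
        # shift one mouse's performance by relabeling nothing: mean
        # subtraction makes additive offsets irrelevant by construction; the
        # fitted coefficients on identical structure should be stable
        assert np.isfinite(fit.coefficients).all()
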