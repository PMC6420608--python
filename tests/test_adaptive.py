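"""Grid posterior, lapse-weighted updates, entropy placement and stopping."""

import numpy as np
import pytest

from lapsewatch.adaptive import (
    ParameterGrid,
    PsychometricModel,
    QuestEngine,
    StimulusDomain,
    StopPolicy,
    estimate_threshold,
    expected_posterior_entropies,
    init_posterior,
    posterior_entropy,
    psychometric_p_correct,
    select_stimulus,
    should_stop,
    trial_likelihood,
    weighted_update,
)
from lapsewatch.errors import DegenerateUpdateError, ValidationError


def _grid(thresholds, slopes=(1.0,)):
    return ParameterGrid(thresholds=np.asarray(thresholds, float),
                         slopes=np.asarray(slopes, float))


class TestInitPosterior:
    def test_uniform_prior_normalizes(self):
        st = init_posterior(_grid(np.linspace(0, 1, 11)))
        np.testing.assert_allclose(st.mass, np.full(11, 1 / 11))

    def test_delta_prior(self):
        prior = np.zeros(5)
        prior[2] = 3.0
        st = init_posterior(_grid(np.arange(5.0)), prior)
        np.testing.assert_allclose(st.mass, [0, 0, 1, 0, 0], atol=1e-15)

    def test_invalid_priors_rejected(self):
        g = _grid(np.arange(3.0))
        with pytest.raises(ValidationError):
            init_posterior(g, np.array([1.0, -0.1, 0.2]))
        with pytest.raises(ValidationError):
            init_posterior(g, np.zeros(3))


class TestPsychometricModel:
    def test_chance_floor_at_low_magnitude(self):
        m = PsychometricModel(threshold=10.0, slope=2.0)
        assert float(m.p_correct(-1e3)) == pytest.approx(0.5, abs=1e-12)

    def test_upper_asymptote_is_one_minus_lapse(self):
        m = PsychometricModel(threshold=10.0, slope=2.0, lapse=0.03)
        assert float(m.p_correct(1e4)) == pytest.approx(0.97, abs=1e-9)

    def test_midpoint_performance_is_75_percent(self):
        m = PsychometricModel(threshold=10.0, slope=2.0)
        assert float(m.p_correct(10.0)) == pytest.approx(0.75)

    def test_monotone_in_magnitude(self):
        m = PsychometricModel(threshold=5.0, slope=1.5)
        x = np.linspace(-10, 30, 100)
        assert np.all(np.diff(m.p_correct(x)) > 0)

    def test_weibull_family_midpoint(self):
        p = psychometric_p_correct(4.0, 4.0, 2.0, family="weibull")
        assert float(p) == pytest.approx(0.75)


class TestWeightedUpdate:
    def test_alpha_zero_leaves_posterior_unchanged(self):
        st = init_posterior(_grid(np.linspace(0, 10, 7)))
        st2 = weighted_update(st, 5.0, True, alpha=0.0)
        np.testing.assert_allclose(st2.mass, st.mass, atol=1e-15)
        assert st2.history == [(5.0, True, 0.0)]

    def test_alpha_one_matches_plain_bayes_oracle(self, rng):
        g = _grid(np.linspace(0, 20, 31), slopes=[1.0, 3.0])
        st = init_posterior(g, rng.random(g.n_nodes) + 0.1)
        for _ in range(30):
            x = float(rng.uniform(0, 20))
            r = bool(rng.random() < 0.6)
            # independent oracle: direct products in the probability domain
            lik = trial_likelihood(x, r, g)
            expected = st.mass * lik
            expected /= expected.sum()
            st = weighted_update(st, x, r, alpha=1.0)
            np.testing.assert_allclose(st.mass, expected, rtol=1e-12,
                                       atol=1e-300)

    def test_half_weight_hand_example(self):
        # two nodes with per-trial likelihoods 0.9 and 0.6, uniform prior:
        # posterior mass ~ (0.9^0.5, 0.6^0.5) per the weighted product rule
        s = np.log(4.0)  # logistic: p = 0.5 + 0.5*expit((x - t)/1)
        g = _grid([-s, s])
        lik = trial_likelihood(0.0, True, g)
        np.testing.assert_allclose(lik, [0.9, 0.6], atol=1e-12)
        expected = lik**0.5 / np.sum(lik**0.5)
        st = weighted_update(init_posterior(g), 0.0, True, alpha=0.5)
        np.testing.assert_allclose(st.mass, expected, atol=1e-12)
        assert st.mass[0] == pytest.approx(0.55051, abs=1e-4)

    def test_alpha_out_of_range_rejected(self):
        st = init_posterior(_grid([0.0, 1.0]))
        with pytest.raises(ValidationError):
            weighted_update(st, 0.0, True, alpha=1.5)

    def test_mass_normalized_after_every_update(self, rng):
        st = init_posterior(_grid(np.linspace(0, 10, 21), slopes=[1.0, 2.0]))
        for _ in range(225):
            st = weighted_update(st, float(rng.uniform(0, 12)),
                                 bool(rng.random() < 0.7),
                                 alpha=float(rng.random()))
            assert abs(st.mass.sum() - 1.0) < 1e-12

    def test_update_order_invariance(self, rng):
        g = _grid(np.linspace(0, 10, 15))
        triples = [
            (float(rng.uniform(0, 12)), bool(rng.random() < 0.6),
             float(rng.random()))
            for _ in range(12)
        ]
        st_a = init_posterior(g)
        for x, r, a in triples:
            st_a = weighted_update(st_a, x, r, a)
        st_b = init_posterior(g)
        for x, r, a in reversed(triples):
            st_b = weighted_update(st_b, x, r, a)
        np.testing.assert_allclose(st_a.mass, st_b.mass, rtol=1e-10)

    def test_annihilated_posterior_raises(self):
        # the 2AFC likelihood is never exactly zero, so force the
        # degenerate case through an all-zero mass vector directly
        bad = init_posterior(_grid([0.0]))
        bad.log_mass = np.array([-np.inf])
        with pytest.raises(DegenerateUpdateError):
            weighted_update(bad, 0.0, True, alpha=1.0)


class TestEstimates:
    def test_delta_posterior_returns_its_node(self):
        g = _grid(np.linspace(0, 10, 11))
        prior = np.zeros(11)
        prior[4] = 1.0
        st = init_posterior(g, prior)
        assert estimate_threshold(st) == pytest.approx(4.0)

    def test_symmetric_two_node_posterior_returns_midpoint(self):
        st = init_posterior(_grid([2.0, 8.0]))
        assert estimate_threshold(st) == pytest.approx(5.0)

    def test_entropy_of_delta_and_uniform(self):
        g = _grid(np.linspace(0, 7, 8))
        prior = np.zeros(8)
        prior[0] = 1.0
        assert posterior_entropy(init_posterior(g, prior)) == 0.0
        assert posterior_entropy(init_posterior(g)) == pytest.approx(3.0)

    def test_entropy_bounded_by_log_grid_size(self, rng):
        g = _grid(np.linspace(0, 7, 12))
        st = init_posterior(g, rng.random(12) + 1e-6)
        assert 0.0 <= posterior_entropy(st) <= np.log2(12) + 1e-12


class TestSelectStimulus:
    def test_delta_posterior_ties_break_to_smallest(self):
        g = _grid(np.linspace(0, 10, 11))
        prior = np.zeros(11)
        prior[5] = 1.0
        st = init_posterior(g, prior)
        dom = StimulusDomain(candidates=[1.0, 5.0, 9.0])
        assert select_stimulus(st, dom) == 1.0

    def test_zero_alpha_forecast_is_uninformative(self):
        st = init_posterior(_grid(np.linspace(0, 10, 11)))
        dom = StimulusDomain(candidates=[2.0, 6.0])
        assert select_stimulus(st, dom, alpha_forecast=0.0) == 2.0

    def test_matches_exhaustive_two_node_enumeration(self):
        g = _grid([2.0, 8.0])
        st = init_posterior(g)
        dom = StimulusDomain(candidates=[3.0, 7.0])

        def oracle_expected_entropy(x):
            h = 0.0
            for r in (True, False):
                lik = trial_likelihood(x, r, g)
                pred = float(np.sum(st.mass * lik))
                post = st.mass * lik / pred
                h += pred * -np.sum(post * np.log2(post))
            return h

        ours = expected_posterior_entropies(st, dom)
        expect = [oracle_expected_entropy(x) for x in dom.candidates]
        np.testing.assert_allclose(ours, expect, atol=1e-12)
        assert select_stimulus(st, dom) == dom.candidates[int(np.argmin(expect))]

    def test_expected_entropy_never_exceeds_current(self, rng):
        # conditioning cannot increase expected Shannon entropy
        g = _grid(np.linspace(0, 15, 25), slopes=[1.0, 4.0])
        dom = StimulusDomain(candidates=np.linspace(0.5, 14.0, 9))
        for _ in range(20):
            st = init_posterior(g, rng.random(g.n_nodes) + 1e-9)
            h0 = posterior_entropy(st)
            assert np.all(
                expected_posterior_entropies(st, dom, 1.0) <= h0 + 1e-10
            )

    def test_empty_domain_rejected(self):
        with pytest.raises(ValidationError):
            StimulusDomain(candidates=[])


class TestStopping:
    def test_zero_entropy_stops(self):
        g = _grid([0.0, 1.0])
        prior = np.zeros(2)
        prior[0] = 1.0
        st = init_posterior(g, prior)
        assert should_stop(st, StopPolicy(entropy_bits=0.5))

    def test_fresh_state_does_not_stop_on_trial_count(self):
        st = init_posterior(_grid(np.linspace(0, 10, 11)))
        assert not should_stop(st, StopPolicy(max_trials=225))

    def test_policy_needs_a_criterion(self):
        with pytest.raises(ValidationError):
            StopPolicy()

    def test_attentive_observer_stops_sooner_than_lapser(self):
        obs = PsychometricModel(threshold=11.5, slope=3.0)
        stop = StopPolicy(max_trials=400, entropy_bits=4.5)

        def trials_to_stop(seed, lapse_occupancy):
            rng = np.random.default_rng(seed)
            eng = QuestEngine(stop=stop)
            while not eng.finished:
                x = eng.next_stimulus()
                lapsed = rng.random() < lapse_occupancy
                p = 0.5 if lapsed else float(obs.p_correct(x))
                eng.update(x, bool(rng.random() < p), 1.0)
            return eng.state.n_trials

        attentive = [trials_to_stop(s, 0.0) for s in range(15)]
        lapsing = [trials_to_stop(s, 0.35) for s in range(15)]
        assert np.median(attentive) < np.median(lapsing)


class TestParameterRecovery:
    def test_lapse_free_recovery_within_twice_grid_spacing(self):
        obs = PsychometricModel(threshold=11.5, slope=3.0)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            eng = QuestEngine(stop=StopPolicy(max_trials=225))
            for _ in range(225):
                x = eng.next_stimulus()
                eng.update(x, bool(rng.random() < obs.p_correct(x)), 1.0)
            errs.append(abs(eng.threshold - obs.threshold))
        spacing = np.diff(eng.grid.thresholds)[0]
        assert np.median(errs) < 2.0 * spacing
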