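"""Latent-state model core: emissions, likelihood, EM, decoding, relabeling."""
import math

import numpy as np
import pytest

from nsdlsm.hmm import (
    FitConfig,
    LatentStateParams,
    decode,
    em_fit,
    emission_density,
    forward_loglik,
    relabel_states,
)

from _util import (
    RECOVERY_TRUTH,
    brute_force_loglik,
    brute_force_viterbi,
    make_series,
    random_params,
    sample_from_model,
)


def simple_params(**kw):
    defaults = dict(
        mu=np.array([0.1, 0.8]),
        sigma=np.array([0.05, 0.08]),
        Q=np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.1, 0.1, 0.8]]),
        pi0=np.array([0.5, 0.3, 0.2]),
    )
    defaults.update(kw)
    return LatentStateParams(**defaults)


class TestEmissionDensity:
    def test_gaussian_mode_height(self):
        p = simple_params()
        assert emission_density(0.1, 1, p) == pytest.approx(
            1.0 / (0.05 * math.sqrt(2 * math.pi))
        )

    def test_missing_value_contributes_nothing(self):
        p = simple_params()
        for state in (1, 2, 3):
            assert emission_density(float("nan"), state, p) == 1.0

    def test_pseudo_uniform_near_flat(self):
        # density ratio across [0, 1] for the fixed N(0.5, 1) emission
        p = simple_params()
        ratio = emission_density(0.0, 3, p) / emission_density(0.5, 3, p)
        assert ratio == pytest.approx(math.exp(-0.125), rel=1e-12)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            emission_density(0.5, 4, simple_params())


class TestParamsValidation:
    def test_non_stochastic_q_rejected(self):
        Q = np.full((3, 3), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            simple_params(Q=Q)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simple_params(sigma=np.array([0.1, -0.1]))

    def test_serialization_round_trip(self):
        p = simple_params()
        q = LatentStateParams.from_dict(p.to_dict())
        np.testing.assert_allclose(q.Q, p.Q)
        np.testing.assert_allclose(q.mu, p.mu)


class TestForwardLoglik:
    def test_single_observation_is_mixture(self):
        p = simple_params()
        s = make_series(np.array([0.3, 0.3]))
        # closed form for T=2 is awkward; check T=1 via the enumeration oracle
        s1 = make_series(np.array([0.3]))
        mix = sum(
            p.pi0[i - 1] * emission_density(0.3, i, p) for i in (1, 2, 3)
        )
        assert forward_loglik(s1, p) == pytest.approx(math.log(mix), abs=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_enumeration_with_missing_days(self, trial):
        rng = np.random.default_rng(1000 + trial)
        T = int(rng.integers(2, 7))
        y = rng.uniform(0, 1, size=T)
        observed = rng.random(T) > 0.3
        y[~observed] = np.nan
        p = random_params(rng)
        s = make_series(y, observed)
        assert forward_loglik(s, p) == pytest.approx(
            brute_force_loglik(np.nan_to_num(y, nan=0.5), observed, p), abs=1e-10
        )

    def test_frozen_chain_gap_insertion(self):
        # with Q = identity the latent state is frozen; adding a missing
        # day between two observations must not change the likelihood of
        # the observed data
        p = simple_params(Q=np.eye(3))
        y2 = np.array([0.1, 0.12])
        s2 = make_series(y2)
        y3 = np.array([0.1, np.nan, 0.12])
        s3 = make_series(y3)
        assert forward_loglik(s3, p) == pytest.approx(
            forward_loglik(s2, p), abs=1e-10
        )


class TestDecode:
    @pytest.mark.parametrize("trial", range(20))
    def test_viterbi_matches_enumeration(self, trial):
        rng = np.random.default_rng(2000 + trial)
        T = int(rng.integers(2, 7))
        y = rng.uniform(0, 1, size=T)
        p = random_params(rng)
        s = make_series(y)
        seq = decode(s, p, method="viterbi")
        np.testing.assert_array_equal(
            seq.modes - 1, brute_force_viterbi(y, np.ones(T, bool), p)
        )

    def test_posterior_rows_normalized_including_missing(self):
        p = simple_params()
        y = np.array([0.1, np.nan, np.nan, 0.8, 0.5])
        s = make_series(y)
        seq = decode(s, p, method="posterior")
        np.testing.assert_allclose(seq.posterior.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(seq.modes == np.argmax(seq.posterior, axis=1) + 1)

    def test_frozen_chain_stays_in_initial_mode(self):
        p = simple_params(Q=np.eye(3), pi0=np.array([1.0, 0.0, 0.0]))
        s = make_series(np.full(20, 0.1))
        seq = decode(s, p)
        assert np.all(seq.modes == 1)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            decode(make_series(np.array([0.1, 0.2])), simple_params(), "magic")


class TestRelabel:
    def _decoded(self, params, y):
        return decode(make_series(y), params)

    def test_swap_yields_canonical(self):
        p = simple_params(pi0=np.array([0.0, 1.0, 0.0]))
        y = np.concatenate([np.full(10, 0.8), np.full(10, 0.1)])
        seq = self._decoded(p, y)
        assert seq.modes[0] == 2  # high mode labeled 2 before relabeling
        p2, seq2 = relabel_states(p, seq)
        assert seq2.modes[0] == 1
        assert p2.mu[0] == pytest.approx(0.8)
        # applying again is a no-op
        p3, seq3 = relabel_states(p2, seq2)
        np.testing.assert_array_equal(seq3.modes, seq2.modes)
        np.testing.assert_allclose(p3.Q, p2.Q)

    def test_likelihood_invariant(self):
        p = simple_params(pi0=np.array([0.0, 1.0, 0.0]))
        y = np.concatenate([np.full(10, 0.8), np.full(10, 0.1)])
        s = make_series(y)
        seq = decode(s, p)
        p2, _ = relabel_states(p, seq)
        assert forward_loglik(s, p2) == pytest.approx(
            forward_loglik(s, p), abs=1e-9
        )

    def test_exploratory_only_rejected(self):
        p = simple_params()
        seq = decode(make_series(np.full(10, 0.5)), p)
        seq.modes[:] = 3
        with pytest.raises(ValueError, match="exploratory-only"):
            relabel_states(p, seq)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    y, modes = sample_from_model(RECOVERY_TRUTH, 600, rng)
    s = make_series(y)
    return s, em_fit(s, FitConfig(seed=3))


class TestEMFit:

    def test_loglik_trace_monotone(self, fitted):
        _, (_, _, diag) = fitted
        assert np.all(np.diff(diag.loglik_trace) > -1e-8)

    def test_q_row_stochastic(self, fitted):
        _, (params, _, _) = fitted
        np.testing.assert_allclose(params.Q.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(params.Q >= 0)

    def test_recovers_means(self, fitted):
        _, (params, _, _) = fitted
        np.testing.assert_allclose(np.sort(params.mu), [0.1, 0.8], atol=0.03)

    def test_same_seed_bit_identical(self, fitted):
        s, (params, _, _) = fitted
        params2, _, _ = em_fit(s, FitConfig(seed=3))
        np.testing.assert_array_equal(params.Q, params2.Q)
        np.testing.assert_array_equal(params.mu, params2.mu)

    def test_short_series_rejected(self):
        s = make_series(np.random.default_rng(0).uniform(size=30))
        with pytest.raises(ValueError, match="too short"):
            em_fit(s, FitConfig(seed=0))

    def test_median_q_diagonal_error_bounded(self):
        # estimation-quality property at T=1000: median |error| of the Q
        # diagonal below 0.05, of mu below 0.03
        errs_q, errs_mu = [], []
        for rep in range(8):
            rng = np.random.default_rng(300 + rep)
            y, _ = sample_from_model(RECOVERY_TRUTH, 1000, rng)
            params, _, _ = em_fit(make_series(y), FitConfig(seed=rep))
            order = np.argsort(params.mu)
            errs_mu.append(np.abs(params.mu[order] - RECOVERY_TRUTH.mu).max())
            qd = np.diag(params.Q)[[*order, 2]]
            errs_q.append(np.abs(qd - np.diag(RECOVERY_TRUTH.Q)))
        assert np.median(errs_mu) < 0.03
        assert np.median(np.concatenate(errs_q)) < 0.05

    def test_missing_midrun_days_do_not_change_decoding(self):
        rng = np.random.default_rng(11)
        y, _ = sample_from_model(RECOVERY_TRUTH, 400, rng)
        s = make_series(y)
        params, seq, _ = em_fit(s, FitConfig(seed=5))
        # blank out days deep inside a long single-mode stretch
        runs = np.flatnonzero(np.diff(seq.modes) != 0)
        start = 0
        target = None
        for end in list(runs) + [len(seq.modes) - 1]:
            if end - start > 30:
                target = (start + 10, start + 15)
                break
            start = end + 1
        assert target is not None, "fixture produced no long run"
        y2 = y.copy()
        observed = np.ones(400, bool)
        observed[target[0]:target[1]] = False
        y2[~observed] = np.nan
        s2 = make_series(y2, observed)
        seq2 = decode(s2, params)
        keep = observed.copy()
        np.testing.assert_array_equal(seq2.modes[keep], seq.modes[keep])
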