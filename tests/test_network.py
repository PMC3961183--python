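"""Core network: kWTA update, Hamming metric, noise and perturbation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prnet.network import (
    NetworkConfig,
    NetworkParams,
    apply_flip_noise,
    hamming_distance,
    initialize_network,
    kwta_step,
    perturb_state,
    random_state,
)


def _params_zero(N):
    return NetworkParams(
        W=np.zeros((N, N)), mask=np.zeros((N, N), dtype=bool), T=np.zeros(N)
    )


class TestConfig:
    def test_defaults_match_simulation_conditions(self):
        cfg = NetworkConfig()
        assert (cfg.N, cfg.k) == (100, 12)
        assert cfg.eta_stdp == cfg.eta_ip == 0.001
        assert cfg.connectivity == 0.10

    @pytest.mark.parametrize("kwargs", [
        dict(N=10, k=10), dict(N=10, k=12), dict(k=0),
        dict(connectivity=0.0), dict(eta_stdp=-1.0),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)


class TestInitialize:
    def test_connectivity_fraction(self, rng):
        cfg = NetworkConfig(N=100, k=12, connectivity=0.10)
        params, _ = initialize_network(cfg, rng)
        frac = params.mask.sum() / (100 * 99)
        # binomial 3-sigma band around 0.10
        assert abs(frac - 0.10) < 3 * np.sqrt(0.1 * 0.9 / (100 * 99))

    def test_full_connectivity_mask(self, rng):
        cfg = NetworkConfig(N=30, k=5, connectivity=1.0)
        params, _ = initialize_network(cfg, rng)
        assert np.all(params.mask == ~np.eye(30, dtype=bool))
        assert np.all(np.diag(params.W) == 0)

    def test_same_seed_identical(self):
        cfg = NetworkConfig(N=50, k=6)
        p1, s1 = initialize_network(cfg, np.random.default_rng(7))
        p2, s2 = initialize_network(cfg, np.random.default_rng(7))
        assert np.array_equal(p1.W, p2.W)
        assert np.array_equal(p1.T, p2.T)
        assert np.array_equal(s1, s2)

    def test_initial_state_has_k_ones(self, small_net):
        cfg, _, state = small_net
        assert state.sum() == cfg.k


class TestKwtaStep:
    def test_top_k_of_explicit_potentials(self):
        params = _params_zero(4)
        state = np.zeros(4, dtype=bool)
        out = kwta_step(state, params, np.array([3.0, 1.0, 2.0, 0.5]), k=2)
        assert np.array_equal(out, [True, False, True, False])

    def test_all_ties_k1_deterministic_lowest_index(self):
        params = _params_zero(5)
        out = kwta_step(np.zeros(5, bool), params, np.ones(5), k=1)
        assert out.sum() == 1 and out[0]

    def test_all_ties_random_rule_still_one_winner(self, rng):
        params = _params_zero(5)
        winners = {
            int(np.flatnonzero(kwta_step(np.zeros(5, bool), params, np.ones(5), 1, rng))[0])
            for _ in range(50)
        }
        assert len(winners) > 1  # the random rule actually randomizes

    def test_k_equals_n_saturates(self, rng):
        params = _params_zero(6)
        out = kwta_step(np.zeros(6, bool), params, rng.standard_normal(6), k=6)
        assert out.all()

    def test_every_output_has_k_ones(self, small_net, rng):
        cfg, params, state = small_net
        for _ in range(20):
            state = kwta_step(state, params, rng.standard_normal(cfg.N), cfg.k, rng)
            assert state.sum() == cfg.k

    def test_deterministic_given_inputs(self, small_net):
        cfg, params, state = small_net
        d = np.linspace(-1, 1, cfg.N)
        assert np.array_equal(
            kwta_step(state, params, d, cfg.k), kwta_step(state, params, d, cfg.k)
        )

    def test_wrong_drive_length_rejected(self, small_net):
        cfg, params, state = small_net
        with pytest.raises(ValueError):
            kwta_step(state, params, np.zeros(cfg.N + 1), cfg.k)


class TestHamming:
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=50, deadline=None)
    def test_metric_axioms(self, a, b, c):
        to_vec = lambda v: np.array([(v >> i) & 1 for i in range(16)], dtype=bool)
        x, y, z = to_vec(a), to_vec(b), to_vec(c)
        assert hamming_distance(x, x) == 0
        assert hamming_distance(x, y) == hamming_distance(y, x)
        assert hamming_distance(x, z) <= hamming_distance(x, y) + hamming_distance(y, z)
        assert (hamming_distance(x, y) == 0) == np.array_equal(x, y)

    def test_direct_count(self):
        assert hamming_distance(np.array([1, 1, 0, 0]), np.array([0, 1, 1, 0])) == 2

    def test_valid_states_have_even_distance(self, rng):
        # equal Hamming length forces even distances between valid states
        for _ in range(20):
            x, y = random_state(30, 7, rng), random_state(30, 7, rng)
            assert hamming_distance(x, y) % 2 == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance(np.zeros(3), np.zeros(4))


class TestFlipNoise:
    def test_zero_noise_is_identity(self, rng):
        x = random_state(50, 8, rng)
        assert np.array_equal(apply_flip_noise(x, 0.0, rng), x)

    def test_output_keeps_k_ones(self, rng):
        for nu in (0.1, 0.5, 1.0):
            x = random_state(50, 8, rng)
            assert apply_flip_noise(x, nu, rng).sum() == 8

    def test_expected_flip_count_matches_binomial(self, rng):
        # each of k=12 active spikes flips with prob nu=0.1 -> mean 1.2
        x = random_state(100, 12, rng)
        flips = [
            hamming_distance(x, apply_flip_noise(x, 0.1, rng)) // 2
            for _ in range(10_000)
        ]
        mean = np.mean(flips)
        sem = np.sqrt(12 * 0.1 * 0.9 / 10_000)
        assert abs(mean - 1.2) < 4 * sem

    def test_invalid_nu_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_flip_noise(random_state(10, 2, rng), 1.5, rng)


class TestPerturbState:
    def test_zero_is_identity(self, rng):
        x = random_state(40, 6, rng)
        assert np.array_equal(perturb_state(x, 0, rng), x)

    @pytest.mark.parametrize("eps", [2, 4, 8, 12])
    def test_exact_distance(self, eps, rng):
        x = random_state(100, 12, rng)
        y = perturb_state(x, eps, rng)
        assert hamming_distance(x, y) == eps
        assert y.sum() == 12

    def test_maximal_perturbation_replaces_all(self, rng):
        x = random_state(40, 6, rng)
        y = perturb_state(x, 12, rng)
        assert not np.any(x & y)

    @pytest.mark.parametrize("eps", [3, -2, 26])
    def test_invalid_epsilon_rejected(self, eps, rng):
        with pytest.raises(ValueError):
            perturb_state(random_state(40, 6, rng), eps, rng)
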