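"""STDP/IP update rules, weight shuffling and training protocols."""

import numpy as np
import pytest

from prnet.network import NetworkConfig, NetworkParams, initialize_network
from prnet.plasticity import (
    ip_update,
    run_plasticity_phase,
    shuffle_weights,
    stdp_update,
    train_condition,
)
from prnet.tasks import make_task


def _one_hot(N, idx):
    x = np.zeros(N, dtype=bool)
    x[list(np.atleast_1d(idx))] = True
    return x


def _full_params(N, w=0.5):
    mask = ~np.eye(N, dtype=bool)
    return NetworkParams(W=np.where(mask, w, 0.0), mask=mask, T=np.zeros(N))


class TestStdp:
    def test_pre_before_post_potentiates(self):
        p = _full_params(4)
        stdp_update(p, _one_hot(4, 1), _one_hot(4, 0), eta=0.01)
        assert p.W[0, 1] == pytest.approx(0.51)  # post 0 at t, pre 1 at t-1
        assert p.W[1, 0] == pytest.approx(0.49)  # reverse pair depressed

    def test_post_before_pre_depresses(self):
        p = _full_params(4)
        stdp_update(p, _one_hot(4, 0), _one_hot(4, 1), eta=0.01)
        assert p.W[0, 1] == pytest.approx(0.49)

    def test_hard_bounds_hold(self):
        p = _full_params(3, w=1.0)
        stdp_update(p, _one_hot(3, 1), _one_hot(3, 0), eta=0.5)
        assert p.W.max() <= 1.0 and p.W.min() >= 0.0
        assert p.W[0, 1] == 1.0

    def test_simultaneous_bidirectional_cancels(self):
        # both neurons active at t-1 and t: antisymmetric terms cancel
        p = _full_params(4)
        before = p.W.copy()
        stdp_update(p, _one_hot(4, [0, 1]), _one_hot(4, [0, 1]), eta=0.01)
        assert np.allclose(p.W, before)

    def test_diagonal_stays_zero(self):
        p = _full_params(4)
        stdp_update(p, _one_hot(4, [0, 1]), _one_hot(4, [0, 2]), eta=0.01)
        assert np.all(np.diag(p.W) == 0)

    def test_mask_restricted_mode_respects_mask(self):
        N = 4
        mask = np.zeros((N, N), dtype=bool)
        mask[0, 1] = True
        p = NetworkParams(W=np.where(mask, 0.5, 0.0), mask=mask, T=np.zeros(N))
        stdp_update(p, _one_hot(N, [1, 2]), _one_hot(N, 0), eta=0.01, respect_mask=True)
        assert p.W[0, 1] == pytest.approx(0.51)
        assert p.W[0, 2] == 0.0  # no synapse, no potentiation

    def test_maskfree_mode_recruits_new_synapse(self):
        N = 4
        mask = np.zeros((N, N), dtype=bool)
        p = NetworkParams(W=np.zeros((N, N)), mask=mask, T=np.zeros(N))
        stdp_update(p, _one_hot(N, 1), _one_hot(N, 0), eta=0.01, respect_mask=False)
        assert p.W[0, 1] == pytest.approx(0.01)
        assert p.mask[0, 1]


class TestIp:
    def test_spiking_and_silent_deltas(self):
        p = _full_params(10)
        x = _one_hot(10, [0, 1])
        ip_update(p, x, eta_ip=0.01, target_rate=0.2)
        assert p.T[0] == pytest.approx(0.01 * 0.8)
        assert p.T[5] == pytest.approx(-0.01 * 0.2)

    def test_threshold_sum_conserved(self, rng):
        p = _full_params(50)
        for _ in range(100):
            x = np.zeros(50, dtype=bool)
            x[rng.choice(50, 10, replace=False)] = True
            ip_update(p, x, eta_ip=0.001, target_rate=10 / 50)
        assert abs(p.T.sum()) < 1e-9 * 100


class TestShuffle:
    def test_weight_multiset_preserved(self, small_net, rng):
        _, params, _ = small_net
        shuffled = shuffle_weights(params, rng)
        assert np.allclose(
            np.sort(params.W[~np.eye(params.W.shape[0], dtype=bool)]),
            np.sort(shuffled.W[~np.eye(params.W.shape[0], dtype=bool)]),
        )

    def test_diagonal_zero_and_valid(self, small_net, rng):
        _, params, _ = small_net
        shuffled = shuffle_weights(params, rng)
        shuffled.validate()

    def test_single_weight_lands_anywhere_off_diagonal(self, rng):
        N = 5
        W = np.zeros((N, N))
        W[1, 2] = 0.7
        p = NetworkParams(W=W, mask=W > 0, T=np.zeros(N))
        spots = set()
        for _ in range(100):
            s = shuffle_weights(p, rng)
            i, j = np.argwhere(s.W == 0.7)[0]
            assert i != j
            spots.add((int(i), int(j)))
        assert len(spots) > 10  # moves around off-diagonal slots


class TestTrainingProtocols:
    def test_frozen_rates_leave_params_unchanged(self, rng):
        cfg = NetworkConfig(N=30, k=4, eta_stdp=0.0, eta_ip=0.0)
        task = make_task("rand4", N=30, field_size=5)
        params, state = initialize_network(cfg, rng)
        W0, T0 = params.W.copy(), params.T.copy()
        run_plasticity_phase(cfg, params, state, task, 500, rng)
        assert np.array_equal(params.W, W0) and np.array_equal(params.T, T0)

    def test_sip_invariants_along_run(self, rng):
        cfg = NetworkConfig(N=30, k=4)
        task = make_task("rand4", N=30, field_size=5)
        trained = None
        from prnet.plasticity import train_condition

        trained = train_condition(cfg, "SIP", task, 2_000, rng,
                                  checkpoints=(500, 1000, 2000))
        t_sum0 = None
        for step, params in sorted(trained.checkpoints.items()):
            assert params.W.min() >= 0.0 and params.W.max() <= 1.0
            assert np.all(np.diag(params.W) == 0)
            if t_sum0 is None:
                t_sum0 = params.T.sum()
            # IP conserves the threshold sum to floating tolerance
            assert params.T.sum() == pytest.approx(t_sum0, abs=1e-9 * step)

    def test_unknown_condition_rejected(self, rng):
        cfg = NetworkConfig(N=30, k=4)
        task = make_task("rand4", N=30, field_size=5)
        with pytest.raises(ValueError):
            train_condition(cfg, "BOGUS", task, 10, rng)

    def test_ip_condition_shuffles_then_adapts_thresholds(self, rng):
        cfg = NetworkConfig(N=30, k=4)
        task = make_task("rand4", N=30, field_size=5)
        trained = train_condition(cfg, "IP", task, 300, rng)
        assert trained.condition == "IP"
        trained.params.validate()

    def test_nonplastic_weights_carry_no_structure_but_same_distribution(self, rng):
        cfg = NetworkConfig(N=30, k=4)
        task = make_task("rand4", N=30, field_size=5)
        sp = train_condition(cfg, "SP", task, 300, np.random.default_rng(3))
        np_ = train_condition(cfg, "NONPLASTIC", task, 300, np.random.default_rng(3))
        off = ~np.eye(30, dtype=bool)
        assert np.allclose(np.sort(sp.params.W[off]), np.sort(np_.params.W[off]))
        assert not np.array_equal(sp.params.W, np_.params.W)
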