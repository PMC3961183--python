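# prnet — self-organizing k-winner-take-all recurrent networks

`prnet` is a simulator and analysis library for studying how two local
plasticity rules — spike-timing-dependent synaptic plasticity (STDP)
and homeostatic intrinsic plasticity (IP) — jointly organize a binary
recurrent network into a substrate for spatiotemporal computation. It
is aimed at computational-neuroscience work on reservoir-style
recurrent networks, neural coding, and input-driven (nonautonomous)
attractor dynamics.

## Model

The network has `N = 100` binary neurons of which exactly `k = 12`
fire each step (k-winner-take-all): with state `x(t) ∈ {0,1}^N`,

    x(t+1) = kWTA_k( W x(t) + u(t+1) − T )

where `W` is the bounded recurrent weight matrix (zero diagonal,
entries in `[0,1]`, initialized sparse at 10% connectivity), `T` the
threshold vector, and `u` the external drive delivered to the disjoint
receptive field of the current input symbol. Plasticity rules:

    ΔW_ij = η (x_i(t) x_j(t−1) − x_i(t−1) x_j(t))      (STDP, η = 0.001)
    ΔT_i  = η_ip (x_i(t) − k/N)                        (IP,   η_ip = 0.001)

Training conditions: `SIP` (both rules), `SP` (STDP only), `IP`
(pre-phase with both rules, weight shuffle, IP-only phase),
`NONPLASTIC` (SP then shuffle, frozen). Probes include per-lag linear
readouts (`W_out = pinv(X) Y`, winner-take-all decoding), plug-in state
entropy, Kraskov k-NN mutual information between states and 3-step
input windows, clamped-input limit cycles, and volumes of
representation with their inclusion property.

Three benchmark drives: `rand4` (i.i.d. uniform 4 symbols, memory),
`markov85` (4-symbol cycle with 0.85/0.05 transitions, prediction) and
`parity3` (XOR of 3 successive binary inputs, nonlinearity).

## Worked example

```python
import numpy as np
from prnet import (NetworkConfig, make_task, train_condition,
                   record_trajectory, plugin_entropy, distinct_states,
                   random_state, lag_sweep)

cfg = NetworkConfig()                      # N=100, k=12, eta=0.001
task = make_task("rand4")                  # uniform 4-symbol input
rng = np.random.default_rng(0)

sp = train_condition(cfg, "SP", task, 50_000, rng)      # STDP only
states, seq, _ = record_trajectory(cfg, sp.params, sp.state, task, 5_000, rng)
print(f"SP entropy:         {plugin_entropy(states):.2f} bits")
print(f"SP distinct states: {distinct_states(states[100:])}")

rng = np.random.default_rng(0)
sip = train_condition(cfg, "SIP", task, 50_000, rng)    # STDP + IP
init = random_state(cfg.N, cfg.k, rng)                  # random reset
perf = lag_sweep(cfg, sip.params, init, task, [-3, -2, -1], 5_000, 5_000, rng)
for lag, p in perf.items():
    print(f"SIP performance at lag {lag:+d}: {p:.2f}")
```

Output:

```
SP entropy:         2.00 bits
SP distinct states: 4
SIP performance at lag -3: 0.29
SIP performance at lag -2: 0.31
SIP performance at lag -1: 0.58
```

The STDP-only network has collapsed onto a *minimal code*: a four-state
(2-bit), input-insensitive limit cycle that supports no decoding. The
jointly trained network, reset to a random state (a large perturbation
that moves it into its input-sensitive regime), lets linear readouts
recover inputs up to three steps back well above the 0.25 chance level.

## Command line

```sh
prn train --task rand4 --condition SIP --seed 1 --out runs/demo
prn evaluate --config cfg.json --seed 1 --out runs/sweep
prn info        --seed 1 --out runs/info        # entropy/MI timecourse
prn attractors  --seed 1 --out runs/cycles      # clamped limit cycles
prn perturb-sweep --seed 1 --out runs/eps
prn noise-sweep --mode robustness --seed 1 --out runs/noise
```

Each command writes delimited metric tables and a JSON manifest with
the full configuration and seeds.

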