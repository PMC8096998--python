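# spikewm

A spiking-network model of working memory in which the memory trace lives
in the synapses, not (only) in the firing. A 30-neuron prefrontal-style
circuit of Izhikevich neurons encodes a stimulus as a **rank-order spike
pattern** on 15 coding neurons, stores it within one second through
**nearest-neighbor spike-timing-dependent plasticity (STDP)**, and recalls
it after a multi-second delay in a delay-match-to-sample (DMS) task — in
two regimes:

- **persistent activity**: a +1.5 offset on the excitatory background
  current keeps the stored pattern replaying throughout the delay;
- **activity-silent**: a −0.3 offset lets firing fall back to baseline
  during the delay, and a non-specific recall current in the response
  period regenerates the stored pattern from the weights alone.

The package is for computational neuroscientists who want a small, fully
tested, deterministic testbed for synaptic working-memory mechanisms:
rank-order coding, polychronous coincidence detection, short-term
depression/facilitation, and STDP-based storage/erasure, with population
decoding built in.

## Model core

Neurons follow the two-variable Izhikevich model (excitatory preset
a=0.02, b=0.2, c=−65, d=8; inhibitory 0.04, 0.24, −65, 2), integrated by
explicit Euler at dt = 0.5 ms:

    v' = 0.04 v² + 5v + 140 − u + I,   u' = a(bv − u),
    if v > 30 mV:  v ← c, u ← u + d.

Each spike arrival evokes an alpha-shaped postsynaptic response
`(t/τ)·e^{1−t/τ}` (τ = 4 ms) scaled by the synaptic weight and by the
short-term-plasticity efficacy `u·x` (utilization/resources with
τ_F = 20 ms, τ_D = 50 ms). Excitatory–excitatory synapses (all-to-all,
4 synapses per connection with conduction delays R + 3k, R ~ U[3,12] ms,
mean 12 ms) are plastic under the asymmetric STDP window

    ΔW(Δt) = A₊ e^{Δt/τ₊}      if Δt < 0   (pre arrives before post)
           = −A₋ e^{−Δt/τ₋}    if Δt ≥ 0

with A₊ = A₋ = 1, τ₊ = 3 ms, τ₋ = 18 ms, learning rate η = 0.2, and
nearest-neighbor pairing on spike *arrival* times. A stimulus is a
permutation of the 15 coding neurons (one spike per 4 ms slot — n
neurons can represent n! stimuli this way); each stimulus has a read-out
detector neuron whose afferent delays make a correctly ordered volley
arrive in exact coincidence (polychronization), so the detector fires for
its own pattern and stays silent for others.

## Worked example

One activity-silent DMS trial (1 s preparation, 1 s cue, 3 s delay,
0.5 s response):

```python
import spikewm as sw

circuit = sw.build_circuit(seed=3)
trial = sw.run_trial(circuit, sw.TrialSpec(sample="green", regime="silent"))
print(trial.detector_counts)           # {'red': 0, 'green': 2}
print(trial.recalled, trial.correct)   # green True
```

On this seed the excitatory population fires at 10.0 Hz during the cue,
is completely silent through the 3 s delay (0.0 Hz — no persistent
activity), and still recalls the right sample: the green detector spikes
twice in the 0.5 s readout while the red detector stays silent, because
the recall current replays the stored order from the synapses. The cue
reshapes the plastic weights from their uniform start (mean 0.070) into a
strongly right-skewed distribution: 40% of weights fall below 0.02 while
4.8% strengthen past 0.2.

The same API drives the persistent regime
(`regime="persistent"`), multi-trial sessions with carried synaptic state
(`sw.run_session`, which reproduces interference between consecutive
memories), delay × intertrial accuracy sweeps (`sw.accuracy_sweep`), and
per-time-bin linear-SVM population decoding (`sw.decode_over_time`).
A `spikewm` command-line tool wraps these as `simulate-trial`,
`run-session`, `sweep`, `decode`, `inspect-weights` and `make-fixture`,
writing text-based run archives that re-simulate exactly from their own
config snapshots.

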