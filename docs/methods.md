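# Methods

This note documents the model, its numerical treatment, the parameters
that matter (and how their defaults were set), and the limits of what the
simulations can show.

## Circuit

The circuit is a single functional cluster: N_E = 24 excitatory and
N_I = 6 inhibitory Izhikevich neurons plus one read-only detector unit
per stimulus. Excitatory neurons are all-to-all connected (no
self-connections); each ordered pair carries S_EE = 4 plastic synapses
with conduction delays d = R + 3k ms, R drawn once per connection from
U[3, 12] and k = 0..3, giving a 12 ms mean delay and, importantly, four
*different* temporal channels per connection for STDP to select among.
E→I and I→E links are sampled independently per directed pair with
p = 0.8, carry one non-plastic synapse each (w_EI = 0.4 excitatory,
w_IE = 0.5 applied negatively) and delays U[1, 20] ms. There are no I–I
connections. Initial E–E weights are U[0, 0.14] (mean 0.07).

Detector units are part of the simulated network but project nowhere and
receive no background noise: they are pure read-out taps, so they can be
counted in rasters without feeding information back into the circuit.

## Neuron, synapse and noise

Membrane dynamics are the standard two-variable quadratic
integrate-and-reset equations (parameters in the README), advanced by
explicit Euler with dt = 0.5 ms, v and u updated together from the
pre-tick state; a spike is registered when the updated v exceeds 30 mV,
and the spike time is the tick of the crossing. dt is a config knob; all
shipped results use 0.5 ms, which resolves the finest delay granularity
(1 ms) and the 4 ms response kernel.

Transmission uses the alpha kernel (t/τ)e^{1−t/τ}, τ = 4 ms, scaled by
w·u·x. The kernel nominally describes a postsynaptic *potential*; we
inject the weighted sum as a *current* into the membrane equation (the
two are conflated in this model family), and a `syn_gain`
potential-to-current factor is exposed in config (default 1; see
"Calibration" for why it stayed there). Short-term plasticity follows
the usual utilization/resource pair: on each spike both variables first
relax toward their resting values (τ_F = 20 ms for u → U, τ_D = 50 ms
for x → 1), then the spike facilitates, u ← u + U(1−u), and depletes,
x ← x − u·x; the transmitted efficacy is post-facilitation u times
pre-depression x. A first spike on a fully recovered synapse with
U = 0.2 therefore transmits 0.36.

Background noise is an independent Gaussian current per neuron per tick
with per-neuron mean frozen at construction from U[1.5, 2.0] and
variance 1.8 (read literally as σ²). "Per neuron" (not per tick) for the
mean and "per tick" for the jitter is our resolution of an ambiguity in
the model description; the regime offsets (+1.5 persistent, −0.3 silent)
shift the mean of every excitatory neuron and the recall signal adds a
further +1.5 to excitatory neurons during the response period only. The
regime offset stays on for the whole trial, including response and any
intertrial interval: it models the tonic state of the network during the
task, not a stimulus.

## STDP

The window is deliberately asymmetric (τ₊ = 3 ms, τ₋ = 18 ms): with
symmetric windows the recurrently coupled population locks into strict
synchrony, which destroys rank information. Δt is measured as
presynaptic *arrival* time (emission + conduction delay) minus
postsynaptic spike time — the causal event at the synapse is the
arrival, and this is what lets the four different-delay synapses of one
connection learn differently. Δt < 0 potentiates, Δt ≥ 0 depresses, with
the update W ← clip(W + η·ΔW, w_min, w_max) and η = 0.2.

Pairing is consuming nearest-neighbor: each spike pairs with the most
recent unpaired opposite-side spike and each spike is used at most once
per direction. STDP runs during every period — storage during the cue
and erosion during delay/intertrial are the same mechanism, not gated
phases.

## Coding and read-out

A stimulus is a permutation of the 15 coding neurons; the neuron with
rank r fires at r·4 ms within a 60 ms cycle, and the cue repeats the
cycle 16 times per second. Injected cue spikes are forced emissions
(membrane driven over threshold at the scheduled tick), so downstream
short-term plasticity and STDP see ordinary spikes. The two shipped
stimuli, red and green, map to the identity and reversed permutations —
maximally dissimilar orders; recall works for any permutation pair.

Each stimulus has a detector whose afferent delay from coding neuron i
is max_j(t_j) − t_i + 1 ms, so a correctly ordered volley arrives in
exact coincidence. The afferent weight is solved at build time by
bisection on a single-neuron simulation: the smallest weight for which
k_coincident = 7 simultaneous arrivals (at first-spike efficacy) fire
the unit, scaled by a 1.3 margin. At that setting 6–7 coincident
arrivals fire the detector while 5 arrivals — even exactly coincident
ones, and certainly ones spread over 4 ms slots — do not. A useful
property of this read-out under cyclic replay: if replay starts
mid-pattern, arrivals form two coincident groups (ranks after and before
the start), so a detector still fires whenever a long enough contiguous
run of the order is reproduced; a wrong-order volley never produces more
than a couple of coincident arrivals. For the three-neuron textbook case
with 1 ms spacing the coincident-versus-spread threshold window is only
~3.5%, so constructions at that scale need a tighter margin (the
acceptance test uses 1.02).

## Protocol and analyses

A DMS trial is preparation (1 s), cue (1 s), delay (3 s default) and
response (0.5 s), run on persisting circuit state with weight snapshots
at each boundary. The recalled label is the detector with strictly the
most spikes in the 0.5 s readout; ties, including zero–zero, count as
unresolved and incorrect. Sessions chain trials on one circuit with an
intertrial interval of unstimulated simulation; sweeps grid delay ×
intertrial with randomly drawn samples (2 trials per session, fraction
of correct trials reported). Delay and intertrial values are taken on
the model's own time scale — animal-experiment intervals are compressed
by one eighth before being passed in, while the cue keeps the model's
1 s duration (a 125 ms cue, two pattern cycles, cannot store anything at
η = 0.2, which we verified directly).

Decoding: per-neuron rates in 500 ms windows at 200 ms stride, linear
SVM (default regularization) per time bin under stratified 5-fold CV on
the 24 excitatory neurons; detectors and inhibitory neurons are excluded
(detectors would leak the label trivially). Decoding batches run
repeated trials on *one* network (fixed topology/weight seed) with
independent noise streams per trial — the repeated-measurement setting a
decoder needs; with a fresh random topology per trial the delay-period
rate vectors carry no trial-transferable signal and decoding sits at
chance (verified).

## Numerics

The engine advances all neurons on the tick grid and evaluates the
alpha-kernel superposition *exactly* with a two-state recursive filter
per neuron (the alpha function is the impulse response of a critically
damped second-order linear system), so there is no truncation horizon in
the hot loop. The object-level `synaptic_input` helper truncates at
100 ms = 25τ, where the kernel is below 1e−9 of peak. Delayed spike
propagation uses a circular per-tick event buffer; delays are rounded to
the nearest tick (minimum one). Circuit state — membrane variables,
synaptic resources, pairing memory, pending arrivals, filter states, the
noise stream and the clock — persists across `run` calls, so chained
runs are bit-identical to one long run. The full engine is verified
spike-for-spike and weight-for-weight against a brute-force object-level
simulator that rescans the entire arrival history every tick.

Randomness uses one master seed split into named child streams
(topology, initial weights, noise baselines, run noise), so topology is
reproducible independently of noise realizations; `noise_seed` swaps
only the run-noise stream.

## Calibration

Four constants are not determined by the model description and were
calibrated, jointly, so that the circuit expresses the target phenomena
(elevated delay firing under +1.5 but not −0.3; silent-regime recall;
delay-period decodability; interference between consecutive memories):
U = 0.5, w_max = 2.0, w_EI = 0.4, w_IE = 0.5, k_coincident = 7 with
detector margin 1.3. Two calibration findings are worth recording.
First, at U = 0.2 / w_max = 0.5 the recurrent currents are an order of
magnitude too weak for any delay-period persistence or response-period
replay — the memory stores but cannot be read. Second, the alternative
fix (keeping w_max = 0.5 and scaling all synaptic currents with
`syn_gain` ≈ 4) makes recall perfect but *immortal*: individual STDP
steps (η·ΔW up to 0.2) then rewrite a large fraction of a weight's range
at once, every replay fully re-consolidates the pattern, and
interference between memories disappears entirely. w_max = 2.0 keeps
STDP steps at 10% of the range, which preserves graded, interferable
memories, so `syn_gain` stays at 1.

## What the simulations do and do not show

The simulator itself is the data source; no external data enters. The
network is a 30-neuron caricature: conductance-free synapses, one cell
class per sign, no spatial structure, and a read-out invented for
exactly two stimuli. Passing tests show the *mechanism* is coherent —
storage, silent recall, persistent replay, decodability, interference —
not that real prefrontal tissue works this way.

Three honest limitations, all measured:

1. **Within-trial memory does not decay in the persistent regime.**
   Replay actively re-carves the synapses that support it: the weight
   vector decorrelates from its post-cue snapshot with a 5–8 s half-life,
   yet the *order* content is continuously rewritten and single-trial
   recall stays perfect out to 24 s delays. Accuracy degradation over
   delays therefore arises from between-trial interference in continuous
   sessions, not from within-trial forgetting.
2. **The intertrial-interval benefit is not reproduced.** During any
   unstimulated interval the stored attractor self-refreshes while
   unrelated synapses depress, so a longer interval slightly *sharpens*
   the previous memory rather than washing it out; the measured
   intertrial effect on the next trial's accuracy is weakly negative
   (not statistically significant at these scales). The corresponding
   trend assertion in the test suite is left to fail rather than
   weakened.
3. **Delay-period decodability depends on the network realization.**
   Whether a topology draws a few strongly pattern-selective neurons is
   luck of the delay structure; across eight network seeds the
   40-trial delay decoding ranged from 0.56 to 0.99 (about half the
   realizations exceed 0.9). The acceptance script reports the
   realization its seed produces.

Sweep and batch sizes in the shipped tests (40 decoding trials, 25
silent trials, 3 delays × 2 intervals × 20 reps with 2-trial sessions)
were chosen as the smallest designs whose pass/fail criteria are stable
under the stochasticity just described.
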