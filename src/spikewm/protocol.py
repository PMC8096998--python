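"""Delay-match-to-sample (DMS) trial orchestration.

A trial is four periods run back-to-back on the same circuit state:
preparation (noise only), cue (the sample pattern is injected cyclically
on the coding neurons), delay (no stimulus) and response (a non-specific
recall current is added to all excitatory neurons and the detector units
are read out over a 0.5 s window; the label of the more active detector
is the recalled sample).

The noise regime shifts the mean background current of every excitatory
neuron: +1.5 in the persistent regime (delay-period firing stays
elevated) or -0.3 in the silent regime (activity falls back to baseline
and the memory survives only in the synaptic weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circuit import Circuit, CircuitConfig, SpikeRaster, build_circuit, \
    ROLE_INPUT, ROLE_EXC
from .coding import RankPattern

__all__ = [
    "TrialSpec",
    "TrialResult",
    "run_trial",
    "run_trial_batch",
    "run_session",
    "accuracy_sweep",
    "REGIME_OFFSETS",
]

#: Additive shift of the excitatory noise-current mean per regime.
REGIME_OFFSETS = {"persistent": 1.5, "silent": -0.3}


@dataclass(frozen=True)
class TrialSpec:
    """Timing, sample and noise regime of one DMS trial (times in ms)."""

    sample: str = "red"
    regime: str = "persistent"
    prep_ms: float = 1000.0
    cue_ms: float = 1000.0
    delay_ms: float = 3000.0
    response_ms: float = 500.0
    intertrial_ms: float = 0.0
    recall_offset: float = 1.5
    readout_ms: float | None = None  # None -> response_ms

    def __post_init__(self) -> None:
        if self.regime not in REGIME_OFFSETS:
            raise ValueError(f"unknown regime {self.regime!r}")

    @property
    def readout(self) -> float:
        return self.response_ms if self.readout_ms is None else self.readout_ms


@dataclass
class TrialResult:
    """Raster, detector readout and weight snapshots of one trial."""

    spec: TrialSpec
    raster: SpikeRaster
    detector_counts: dict
    recalled: str | None
    correct: bool
    weights: dict  # period name -> plastic-weight snapshot (np.ndarray)
    periods: dict  # period name -> (t0_ms, t1_ms), absolute


def _excitatory_offsets(circuit: Circuit, amount: float) -> np.ndarray:
    off = np.zeros(circuit.n)
    exc = (circuit.roles == ROLE_INPUT) | (circuit.roles == ROLE_EXC)
    off[exc] = amount
    return off


def _cue_schedule(pattern: RankPattern, cue_ms: float) -> list:
    """Forced-spike schedule: the pattern volley repeated cyclically.

    Full cycles only; with the default 15-neuron pattern and 4 ms slots
    one cycle is 60 ms, so a 1 s cue holds 16 repetitions.
    """
    sched = []
    n_cycles = int(cue_ms // pattern.cycle_ms)
    for j in range(n_cycles):
        t0 = j * pattern.cycle_ms
        for neuron, t in enumerate(pattern.firing_times(t0)):
            sched.append((float(t), neuron))
    return sched


def run_trial(circuit: Circuit, spec: TrialSpec, record: bool = True) -> TrialResult:
    """Run one DMS trial on ``circuit`` (state persists afterwards)."""
    if spec.sample not in circuit.patterns:
        raise ValueError(
            f"unknown sample label {spec.sample!r}; "
            f"circuit has patterns {list(circuit.patterns)}")
    regime = _excitatory_offsets(circuit, REGIME_OFFSETS[spec.regime])
    recall = regime + _excitatory_offsets(circuit, spec.recall_offset)

    weights = {"start": circuit.ee_weights()}
    periods = {}
    rasters = []

    t0 = circuit.time_ms
    rasters.append(circuit.run(spec.prep_ms, offsets=regime, record=record))
    periods["prep"] = (t0, circuit.time_ms)
    weights["prep"] = circuit.ee_weights()

    t0 = circuit.time_ms
    sched = _cue_schedule(circuit.patterns[spec.sample], spec.cue_ms)
    rasters.append(circuit.run(spec.cue_ms, forced_spikes=sched,
                               offsets=regime, record=record))
    periods["cue"] = (t0, circuit.time_ms)
    weights["cue"] = circuit.ee_weights()

    t0 = circuit.time_ms
    rasters.append(circuit.run(spec.delay_ms, offsets=regime, record=record))
    periods["delay"] = (t0, circuit.time_ms)
    weights["delay"] = circuit.ee_weights()

    t0 = circuit.time_ms
    # the response period is always recorded: the readout needs its spikes
    rasters.append(circuit.run(spec.response_ms, offsets=recall, record=True))
    periods["response"] = (t0, circuit.time_ms)
    weights["response"] = circuit.ee_weights()

    raster = SpikeRaster.concat(rasters)
    r0 = periods["response"][0]
    counts = {
        lbl: int(raster.counts(t0=r0, t1=r0 + spec.readout)[det])
        for lbl, det in circuit.detector_of.items()
    }
    recalled = _argmax_label(counts)
    return TrialResult(
        spec=spec, raster=raster, detector_counts=counts,
        recalled=recalled, correct=(recalled == spec.sample),
        weights=weights, periods=periods,
    )


def _argmax_label(counts: dict) -> str | None:
    """Label with the strictly largest count; ties (including all-zero)
    are unresolved."""
    best = max(counts.values())
    winners = [lbl for lbl, c in counts.items() if c == best]
    if best == 0 or len(winners) != 1:
        return None
    return winners[0]


def run_session(circuit_factory, trials, carry_state: bool = True,
                record: bool = True) -> list:
    """Run ``trials`` back-to-back.

    With ``carry_state`` the circuit from ``circuit_factory()`` persists
    across trials, separated by each trial's ``intertrial_ms`` of
    unstimulated simulation (the tonic regime offset stays on: within a
    continuous task the network remains in the task's noise state).  The
    carried weights are what lets one memory interfere with the next.
    Without ``carry_state`` a fresh circuit is built per trial.
    """
    results = []
    circuit = circuit_factory() if carry_state else None
    for spec in trials:
        c = circuit if carry_state else circuit_factory()
        results.append(run_trial(c, spec, record=record))
        if carry_state and spec.intertrial_ms > 0:
            c.run(spec.intertrial_ms,
                  offsets=_excitatory_offsets(c, REGIME_OFFSETS[spec.regime]),
                  record=record)
    return results


def run_trial_batch(
    cfg: CircuitConfig | None = None,
    n_trials: int = 40,
    regime: str = "persistent",
    seed: int = 0,
    base_spec: TrialSpec | None = None,
    record: bool = True,
) -> list:
    """Independent repeated trials on one and the same network.

    All trials share the circuit seed (identical topology, delays and
    initial weights — the repeated-measurements setting a decoder needs)
    but each gets a fresh noise realization and starts from the reset
    circuit state.  Sample labels alternate across the available
    patterns, so ``n_trials=40`` with two stimuli gives 20 per class.
    """
    if cfg is None:
        cfg = CircuitConfig()
    ss = np.random.SeedSequence(seed)
    s_net, s_noise = ss.spawn(2)
    net_seed = int(s_net.generate_state(1)[0] % (2 ** 31))
    noise_seeds = s_noise.generate_state(n_trials) % (2 ** 31)
    labels = list(cfg.resolved_patterns())
    if base_spec is None:
        base_spec = TrialSpec()
    results = []
    for i in range(n_trials):
        circuit = build_circuit(cfg, seed=net_seed, noise_seed=int(noise_seeds[i]))
        spec = replace(base_spec, sample=labels[i % len(labels)], regime=regime)
        results.append(run_trial(circuit, spec, record=record))
    return results


def accuracy_sweep(
    delays,
    intertrials,
    reps: int,
    regime: str = "persistent",
    *,
    cfg: CircuitConfig | None = None,
    cue_ms: float = 1000.0,
    prep_ms: float = 1000.0,
    response_ms: float = 500.0,
    recall_offset: float = 1.5,
    trials_per_session: int = 2,
    seed: int = 0,
    record: bool = False,
) -> pd.DataFrame:
    """Recall accuracy over a (delay x intertrial) grid of continuous DMS runs.

    Each cell runs ``reps`` sessions of ``trials_per_session`` consecutive
    trials with randomly drawn samples and carried circuit state, and
    reports the fraction of correct trials.  Delay and intertrial values
    are taken on the model's own time scale (animal-experiment intervals
    are compressed by one eighth before being passed in); the cue keeps
    the model's standard 1 s duration.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if cfg is None:
        cfg = CircuitConfig()
    ss = np.random.SeedSequence(seed)
    labels = list(cfg.resolved_patterns())
    rows = []
    for delay in delays:
        for it in intertrials:
            n_corr = 0
            n_tot = 0
            for _ in range(reps):
                s_build, s_samples = ss.spawn(2)
                rng = np.random.default_rng(s_samples)
                samples = rng.choice(labels, size=trials_per_session)
                trials = [
                    TrialSpec(sample=str(s), regime=regime, prep_ms=prep_ms,
                              cue_ms=cue_ms, delay_ms=float(delay),
                              response_ms=response_ms, intertrial_ms=float(it),
                              recall_offset=recall_offset)
                    for s in samples
                ]
                build_seed = int(s_build.generate_state(1)[0] % (2 ** 31))
                results = run_session(
                    lambda: build_circuit(cfg, seed=build_seed),
                    trials, carry_state=True, record=record)
                n_corr += sum(r.correct for r in results)
                n_tot += len(results)
            rows.append({"delay_ms": float(delay), "intertrial_ms": float(it),
                         "n_trials": n_tot, "accuracy": n_corr / n_tot})
    return pd.DataFrame(rows)
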