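"""Rank-order encoding and polychronous pattern detectors.

A stimulus is a permutation of the coding neurons: the neuron with rank r
fires at ``r * slot_width`` ms after the cycle start, so exactly one
coding neuron fires per slot.  With n coding neurons this order code can
represent n! stimuli, against at most n+1 for a rate code on the same
population.

A detector for a given pattern is a read-only Izhikevich unit whose
afferent conduction delays are chosen so that a volley fired in the
target order arrives *simultaneously* at the detector; any other order
spreads the arrivals out and, because of membrane leak, fails to drive
the detector over threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import IzhikevichParams, STPParams, psp_kernel, step_neuron

__all__ = [
    "RankPattern",
    "DetectorSpec",
    "encode",
    "make_detector",
    "detector_delays",
    "capacity",
    "solve_detector_weight",
    "default_patterns",
    "SLOT_WIDTH_MS",
]

#: Minimum distinguishable spacing between two spikes of a volley (ms).
SLOT_WIDTH_MS = 4.0


@dataclass(frozen=True)
class RankPattern:
    """Permutation assigning each coding neuron a firing-time slot.

    ``slots[i]`` is the 1-based rank of coding neuron ``i``; the neuron
    fires at ``rank * slot_width`` ms after the cycle start.
    """

    slots: tuple
    slot_width: float = SLOT_WIDTH_MS
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.slots)
        if sorted(self.slots) != list(range(1, n + 1)):
            raise ValueError(
                f"slots must be a permutation of 1..{n}, got {self.slots}"
            )
        object.__setattr__(self, "slots", tuple(int(r) for r in self.slots))

    @property
    def n(self) -> int:
        return len(self.slots)

    def firing_times(self, cycle_start: float = 0.0) -> np.ndarray:
        """Firing time of each coding neuron (ms), in neuron order."""
        return cycle_start + np.asarray(self.slots, dtype=float) * self.slot_width

    @property
    def cycle_ms(self) -> float:
        """Length of one full pattern cycle (ms)."""
        return self.n * self.slot_width


@dataclass(frozen=True)
class DetectorSpec:
    """Afferent delays and weight that make one unit selective for a pattern.

    ``delays[i]`` is the conduction delay from coding neuron ``i``; all
    spikes of a matching volley arrive at ``max(firing_times) + base_delay``.
    """

    target: RankPattern
    delays: tuple
    weight: float
    params: IzhikevichParams = field(default_factory=IzhikevichParams.excitatory)


def encode(pattern: RankPattern, cycle_start: float = 0.0) -> np.ndarray:
    """Injection time for each coding neuron for one cycle of the pattern."""
    return pattern.firing_times(cycle_start)


def capacity(n: int) -> tuple[int, int]:
    """(order-code states, rate-code states) representable by n neurons."""
    if n < 1:
        raise ValueError("need at least one neuron")
    return math.factorial(n), n + 1


def solve_detector_weight(
    k_coincident: int,
    stp: STPParams = STPParams(),
    params: IzhikevichParams | None = None,
    dt: float = 0.5,
    margin: float = 1.3,
    syn_gain: float = 1.0,
) -> float:
    """Afferent weight such that ``k_coincident`` simultaneous arrivals spike.

    Simulates the detector from rest receiving ``k`` coincident arrivals,
    each transmitting the first-spike efficacy ``u*x`` of a fully recovered
    synapse through the circuit's synaptic gain, and bisects for the
    minimal per-afferent weight that produces a spike within one PSP rise;
    the result is scaled by ``margin``.
    """
    if params is None:
        params = IzhikevichParams.excitatory()
    u1 = stp.U + stp.U * (1.0 - stp.U)
    eff = u1 * 1.0  # first spike on a fully recovered synapse

    def fires(w: float) -> bool:
        state = params.rest_state()
        amp = syn_gain * k_coincident * w * eff
        t = 0.0
        for _ in range(int(100.0 / dt)):
            I = amp * psp_kernel(t)
            state, spiked = step_neuron(state, params, I, dt)
            if spiked:
                return True
            t += dt
        return False

    lo, hi = 0.0, 1.0
    while not fires(hi):
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("detector weight bisection failed to bracket")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi * margin


def detector_delays(firing_times, base_delay: float = 1.0) -> tuple:
    """Afferent delays aligning a volley with the given firing times.

    ``delay_i = max_j t_j - t_i + base_delay``; a volley fired at exactly
    the given times then arrives simultaneously at
    ``max(firing_times) + base_delay``.
    """
    if base_delay < 1.0:
        raise ValueError("base_delay must be >= 1 ms")
    t = np.asarray(firing_times, dtype=float)
    return tuple(float(d) for d in (t.max() - t + base_delay))


def make_detector(
    target: RankPattern,
    base_delay: float = 1.0,
    *,
    k_coincident: int = 10,
    stp: STPParams = STPParams(),
    params: IzhikevichParams | None = None,
    dt: float = 0.5,
    weight: float | None = None,
    margin: float = 1.3,
    syn_gain: float = 1.0,
) -> DetectorSpec:
    """Build the detector for ``target``.

    Delay for coding neuron i is ``max_t - t_i + base_delay`` so that a
    volley fired in the target order arrives simultaneously; the afferent
    weight is solved numerically so that ``k_coincident`` coincident
    arrivals drive the unit over threshold while a handful of spread-out
    arrivals do not.
    """
    if params is None:
        params = IzhikevichParams.excitatory()
    delays = detector_delays(target.firing_times(), base_delay)
    if weight is None:
        weight = solve_detector_weight(k_coincident, stp, params, dt, margin,
                                       syn_gain)
    return DetectorSpec(target=target, delays=delays, weight=weight, params=params)


def default_patterns(n: int = 15, slot_width: float = SLOT_WIDTH_MS) -> dict:
    """The two stimulus labels mapped to maximally dissimilar permutations.

    ``red`` is the identity order, ``green`` the reversed order; results
    should not depend on this particular choice.
    """
    fwd = tuple(range(1, n + 1))
    rev = tuple(range(n, 0, -1))
    return {
        "red": RankPattern(slots=fwd, slot_width=slot_width, label="red"),
        "green": RankPattern(slots=rev, slot_width=slot_width, label="green"),
    }
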