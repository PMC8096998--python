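"""Single-neuron and single-synapse dynamics.

Izhikevich two-variable neurons, the alpha-shaped postsynaptic response
kernel, and Tsodyks-Markram-style short-term depression/facilitation.
These scalar/object-level primitives define the model; the circuit engine
in :mod:`spikewm.circuit` evaluates the same equations in vectorized form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "NoiseSpec",
    "STPParams",
    "Synapse",
    "step_neuron",
    "psp_kernel",
    "on_presynaptic_spike",
    "synaptic_input",
    "PSP_TAU_MS",
    "KERNEL_HORIZON_MS",
]

#: Time constant of the postsynaptic response kernel (ms).
PSP_TAU_MS = 4.0

#: Arrivals older than this contribute nothing to the synaptic current.
#: The kernel at 25*tau is below 1e-9 of its peak, so truncation is
#: invisible at 1e-6 even for dense trains.  (The circuit engine itself
#: uses an exact recursive evaluation of the kernel superposition and
#: needs no truncation at all.)
KERNEL_HORIZON_MS = 100.0

SPIKE_THRESHOLD_MV = 30.0


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters (a, b, c, d) of the Izhikevich neuron model.

    ``a`` sets the recovery time scale, ``b`` the recovery sensitivity to
    the membrane potential, ``c`` the post-spike reset potential (mV) and
    ``d`` the post-spike recovery increment.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0

    @classmethod
    def excitatory(cls) -> "IzhikevichParams":
        """Regular-spiking preset used for excitatory neurons."""
        return cls(0.02, 0.2, -65.0, 8.0)

    @classmethod
    def inhibitory(cls) -> "IzhikevichParams":
        """Fast, low-adaptation preset used for inhibitory neurons."""
        return cls(0.04, 0.24, -65.0, 2.0)

    def rest_state(self) -> "NeuronState":
        """Resting fixed point (v*, u* = b v*) with zero input current."""
        # v' = 0 and u = b v: 0.04 v^2 + (5 - b) v + 140 = 0, stable root.
        bb = 5.0 - self.b
        disc = bb * bb - 4.0 * 0.04 * 140.0
        v = (-bb - math.sqrt(disc)) / (2.0 * 0.04)
        return NeuronState(v=v, u=self.b * v)


@dataclass
class NeuronState:
    """Membrane potential ``v`` (mV) and recovery variable ``u``."""

    v: float = -65.0
    u: float = -13.0


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise current: per-neuron baseline mean plus per-tick jitter.

    Each neuron draws a baseline mean once, uniformly in
    ``[mean_low, mean_high]``; every tick an independent Gaussian with that
    mean (plus the regime-dependent ``offset``) and variance ``variance``
    is injected.  ``variance`` is a variance, not a standard deviation.
    """

    mean_low: float = 1.5
    mean_high: float = 2.0
    variance: float = 1.8
    offset: float = 0.0

    @property
    def sigma(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class STPParams:
    """Short-term plasticity constants.

    ``U`` is the baseline utilization fraction; ``tau_F`` and ``tau_D``
    (ms) govern recovery of utilization and of available resources.
    """

    U: float = 0.2
    tau_F: float = 20.0
    tau_D: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.U < 1.0:
            raise ValueError(f"U must be in (0, 1), got {self.U}")


@dataclass
class Synapse:
    """One delayed connection with weight and short-term-plasticity state.

    ``x`` is the fraction of available resources, ``u_util`` the current
    utilization; ``arrivals`` holds ``(arrival_time_ms, efficacy)`` pairs
    for spikes already emitted but still propagating or still shaping the
    postsynaptic current.
    """

    pre: int
    post: int
    w: float
    delay: float
    plastic: bool = False
    sign: int = 1
    x: float = 1.0
    u_util: float = 0.2
    t_last: float = -math.inf
    arrivals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.delay < 1.0:
            raise ValueError(f"conduction delay must be >= 1 ms, got {self.delay}")
        if self.w < 0:
            raise ValueError("weight must be non-negative")


class NumericalInstabilityError(FloatingPointError):
    """Membrane state became non-finite during integration."""


def step_neuron(
    state: NeuronState,
    params: IzhikevichParams,
    I: float,
    dt: float,
    *,
    neuron: int | None = None,
    tick: int | None = None,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one explicit-Euler tick of length ``dt`` ms.

    ``v`` and ``u`` are updated together from the pre-tick state.  If the
    updated ``v`` exceeds 30 mV a spike is registered and the reset
    ``v <- c``, ``u <- u + d`` is applied, so the returned ``v`` never
    exceeds the threshold.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, u = state.v, state.u
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u_new = u + dt * params.a * (params.b * v - u)
    spiked = False
    if v_new > SPIKE_THRESHOLD_MV:
        spiked = True
        v_new = params.c
        u_new = u_new + params.d
    if not (math.isfinite(v_new) and math.isfinite(u_new)):
        where = f" (neuron {neuron}, tick {tick})" if neuron is not None else ""
        raise NumericalInstabilityError(
            f"non-finite membrane state after update{where}: v={v_new}, u={u_new}"
        )
    return NeuronState(v=v_new, u=u_new), spiked


def psp_kernel(t_since, tau: float = PSP_TAU_MS):
    """Unit postsynaptic response ``(t/tau) * exp(1 - t/tau)`` for t >= 0.

    Zero for negative times; peaks at exactly 1 when ``t == tau``.
    Accepts scalars or arrays.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t_since, dtype=float)
    s = t / tau
    out = np.where(t >= 0.0, s * np.exp(1.0 - s), 0.0)
    if np.ndim(t_since) == 0:
        return float(out)
    return out


def on_presynaptic_spike(s: Synapse, stp: STPParams, t: float) -> Synapse:
    """Apply one presynaptic spike at time ``t`` ms to synapse ``s``.

    Both short-term variables first relax toward their resting values
    (x -> 1 with tau_D, u_util -> U with tau_F) over the interval since the
    last event; the spike then facilitates utilization
    (``u_util += U * (1 - u_util)``) and depletes resources
    (``x -= u_util * x``).  The transmitted efficacy recorded for the spike
    is ``u_util * x`` with post-facilitation ``u_util`` and pre-depression
    ``x``; the arrival is queued at ``t + delay``.
    """
    if t < s.t_last:
        raise ValueError(f"spike at t={t} precedes last synapse event at {s.t_last}")
    dt_ev = t - s.t_last
    if math.isinf(dt_ev):
        x, u = 1.0, stp.U
    else:
        x = 1.0 - (1.0 - s.x) * math.exp(-dt_ev / stp.tau_D)
        u = stp.U + (s.u_util - stp.U) * math.exp(-dt_ev / stp.tau_F)
    u = u + stp.U * (1.0 - u)
    efficacy = u * x
    x = x - u * x
    arrivals = s.arrivals + [(t + s.delay, efficacy)]
    return replace(s, x=x, u_util=u, t_last=t, arrivals=arrivals)


def synaptic_input(
    neuron: int,
    t: float,
    afferents,
    tau: float = PSP_TAU_MS,
    horizon: float = KERNEL_HORIZON_MS,
) -> float:
    """Total synaptic current onto ``neuron`` at time ``t`` ms.

    Sums ``w * efficacy * psp_kernel(t - t_arrival)`` over all past
    arrivals on the afferent synapses, signed negative for inhibitory
    presynaptic neurons.  Arrivals older than ``horizon`` ms are dropped;
    the kernel there is below 1e-3 of its peak.
    """
    total = 0.0
    for s in afferents:
        if s.post != neuron:
            continue
        for t_arr, eff in s.arrivals:
            dt_arr = t - t_arr
            if dt_arr < 0.0 or dt_arr > horizon:
                continue
            total += s.sign * s.w * eff * psp_kernel(dt_arr, tau)
    return total
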