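"""Spike-timing-dependent plasticity with nearest-neighbor pairing.

The exponential STDP window is deliberately asymmetric (potentiation
window 3 ms, depression window 18 ms): a symmetric window drives the
recurrently coupled excitatory population into strict synchrony, which
destroys the rank-order information the circuit is meant to store.

The time difference is ``delta_t = t_pre_arrival - t_post``, where the
presynaptic time is the spike's *arrival* at the synapse (emission plus
conduction delay): the causal event at the postsynaptic site is the
arrival, and with four different-delay synapses per connection this lets
the four synapses of one connection learn differently.

Pairing is the consuming nearest-neighbor scheme: each spike pairs with
the most recent opposite-side spike, and each spike is used at most once
per pairing direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dynamics import Synapse

__all__ = ["STDPParams", "PairingState", "stdp_dw", "on_spike_event"]


@dataclass(frozen=True)
class STDPParams:
    """STDP window and update parameters.

    ``A_plus`` / ``A_minus`` are the maximal potentiation / depression
    magnitudes, ``tau_plus`` / ``tau_minus`` (ms) the window widths,
    ``eta`` the learning rate of the update ``W <- W + eta * dW``, and
    ``w_min`` / ``w_max`` hard clip bounds on the weight.
    """

    A_plus: float = 1.0
    A_minus: float = 1.0  # magnitude; applied with negative sign
    tau_plus: float = 3.0
    tau_minus: float = 18.0
    eta: float = 0.2
    w_min: float = 0.0
    w_max: float = 0.5


@dataclass
class PairingState:
    """Most recent unpaired pre-arrival and post-spike times for one synapse."""

    last_pre: float | None = None
    last_post: float | None = None


def stdp_dw(delta_t: float, params: STDPParams = STDPParams()) -> float:
    """Raw weight change for pre/post time difference ``delta_t`` ms.

    ``delta_t < 0`` (pre arrives before post) potentiates by
    ``A_plus * exp(delta_t / tau_plus)``; ``delta_t >= 0`` depresses by
    ``-|A_minus| * exp(-delta_t / tau_minus)``.
    """
    if delta_t < 0:
        return params.A_plus * math.exp(delta_t / params.tau_plus)
    return -abs(params.A_minus) * math.exp(-delta_t / params.tau_minus)


def on_spike_event(
    s: Synapse,
    p: PairingState,
    params: STDPParams,
    event: str,
    t: float,
) -> float:
    """Process one pre-arrival or post-spike event; return the updated weight.

    On a ``"post"`` event the spike pairs with the stored last pre-arrival
    (potentiation, since the arrival precedes the spike) and consumes it;
    on a ``"pre"`` event it pairs with the stored last post spike
    (depression) and consumes that.  The event's own time is then stored
    on its side of the pairing state.  ``s.w`` is updated in place on the
    synapse and also returned.
    """
    if not s.plastic:
        raise ValueError(f"STDP applied to non-plastic synapse {s.pre}->{s.post}")
    if event not in ("pre", "post"):
        raise ValueError(f"unknown event kind {event!r}")
    w = s.w
    if event == "post":
        if p.last_pre is not None:
            w += params.eta * stdp_dw(p.last_pre - t, params)
            p.last_pre = None
        p.last_post = t
    else:
        if p.last_post is not None:
            w += params.eta * stdp_dw(t - p.last_post, params)
            p.last_post = None
        p.last_pre = t
    w = min(max(w, params.w_min), params.w_max)
    s.w = w
    return w
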