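"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the model definitions in the
most literal, brute-force way (full-history rescans, object-level event
processing) and stays independent of the vectorized engine it checks.
"""

from __future__ import annotations

import math

import numpy as np

from spikewm.dynamics import (
    IzhikevichParams,
    NeuronState,
    STPParams,
    psp_kernel,
    step_neuron,
)
from spikewm.plasticity import STDPParams, stdp_dw


def stdp_trajectory_oracle(pre_times, post_times, w0, params: STDPParams):
    """Consuming nearest-neighbor STDP walked event-by-event over full lists.

    ``pre_times`` are presynaptic *arrival* times.  Each spike pairs with
    the stored most recent unpaired opposite-side spike, then stores its
    own time on its side.  Returns the final weight.
    """
    events = sorted(
        [(t, 0) for t in pre_times] + [(t, 1) for t in post_times])
    w = w0
    pending_pre = None
    pending_post = None
    for t, kind in events:
        if kind == 0:  # pre arrival
            if pending_post is not None:
                w += params.eta * stdp_dw(t - pending_post, params)
                pending_post = None
            pending_pre = t
        else:  # post spike
            if pending_pre is not None:
                w += params.eta * stdp_dw(pending_pre - t, params)
                pending_pre = None
            pending_post = t
        w = min(max(w, params.w_min), params.w_max)
    return w


def all_to_all_pairing_count(pre_times, post_times):
    """Number of pre/post pairings under the all-to-all scheme."""
    return len(pre_times) * len(post_times)


def nearest_neighbor_pairing_count(pre_times, post_times):
    """Number of pairings actually applied by the consuming NN scheme."""
    events = sorted(
        [(t, 0) for t in pre_times] + [(t, 1) for t in post_times])
    n = 0
    pending = [None, None]  # pending[0]=pre, pending[1]=post
    for t, kind in events:
        other = 1 - kind
        if pending[other] is not None:
            n += 1
            pending[other] = None
        pending[kind] = t
    return n


def psp_sum_rescan(t, arrivals, tau=4.0, horizon=math.inf):
    """Brute-force Eq-superposition: rescan every past arrival each call."""
    total = 0.0
    for t_arr, amp in arrivals:
        dt_arr = t - t_arr
        if 0.0 <= dt_arr <= horizon:
            total += amp * psp_kernel(dt_arr, tau)
    return total


def bin_counts_rescan(times, neurons, n_neurons, starts, bin_width):
    """Per-neuron per-window spike counts by full rescan."""
    out = np.zeros((n_neurons, len(starts)))
    for t, nn in zip(times, neurons):
        for b, s in enumerate(starts):
            if s <= t < s + bin_width:
                out[nn, b] += 1
    return out


def reference_network_sim(circuit, duration, forced_spikes=None, offsets=None):
    """Object-level re-simulation of a (noise-free) circuit, tick by tick.

    Reads the topology/weight tables off ``circuit`` (which must be
    freshly built with a zero-noise config) and re-runs the dynamics with
    the scalar primitives: full-history PSP rescans, per-synapse
    short-term plasticity applied at emission, pairing state walked with
    the object-level event rule.  Returns (times, neurons) spike lists.
    """
    cfg = circuit.cfg
    dt = cfg.dt
    n = circuit.n
    nticks = int(round(duration / dt))
    S = circuit.S
    stp = cfg.stp
    p = cfg.stdp

    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, float)
    forced = {}
    if forced_spikes:
        for t_f, nrn in forced_spikes:
            forced.setdefault(max(1, int(round(t_f / dt))), []).append(int(nrn))

    v = circuit.c.copy()
    u = circuit.b * v
    w = circuit.w.copy()
    x = np.ones(S)
    uu = np.full(S, stp.U)
    t_last = np.full(S, -np.inf)
    last_pre = [None] * S
    last_post = [None] * S
    arrivals = [[] for _ in range(S)]  # (arrival_tick, efficacy)
    eff_of = [np.nonzero(circuit.pre == i)[0] for i in range(n)]
    aff_of = [np.nonzero(circuit.post == i)[0] for i in range(n)]

    ev_t, ev_n = [], []
    for k in range(1, nticks + 1):
        tt = k * dt
        # STDP 'pre' events for arrivals due this tick
        for s in range(S):
            if not circuit.plastic[s]:
                continue
            for at, _ in arrivals[s]:
                if at == k and last_post[s] is not None:
                    w[s] += p.eta * stdp_dw(tt - last_post[s], p)
                    w[s] = min(max(w[s], p.w_min), p.w_max)
                    last_post[s] = None
            if any(at == k for at, _ in arrivals[s]):
                last_pre[s] = tt

        # input currents by full rescan, then Euler step
        spiked_now = []
        I = np.empty(n)
        for i in range(n):
            tot = 0.0
            for s in aff_of[i]:
                for at, eff in arrivals[s]:
                    d_arr = tt - at * dt
                    if d_arr >= 0.0:
                        tot += circuit.sign[s] * w[s] * eff * psp_kernel(d_arr)
            I[i] = cfg.syn_gain * tot + offsets[i]
        for i in range(n):
            params = IzhikevichParams(circuit.a[i], circuit.b[i],
                                      circuit.c[i], circuit.d[i])
            state, sp = step_neuron(NeuronState(v[i], u[i]), params, I[i], dt)
            v[i], u[i] = state.v, state.u
            if i in forced.get(k, []) and not sp:
                v[i] = params.c
                u[i] = u[i] + params.d
                sp = True
            if sp:
                spiked_now.append(i)

        for i in spiked_now:
            ev_t.append(tt)
            ev_n.append(i)
            for s in eff_of[i]:
                dte = tt - t_last[s]
                if math.isinf(dte):
                    xs, us = 1.0, stp.U
                else:
                    xs = 1.0 - (1.0 - x[s]) * math.exp(-dte / stp.tau_D)
                    us = stp.U + (uu[s] - stp.U) * math.exp(-dte / stp.tau_F)
                us = us + stp.U * (1.0 - us)
                eff = us * xs
                x[s] = xs - eff
                uu[s] = us
                t_last[s] = tt
                arrivals[s].append((k + int(circuit.dticks[s]), eff))
            # 'post' STDP on plastic afferents
            for s in aff_of[i]:
                if not circuit.plastic[s]:
                    continue
                if last_pre[s] is not None:
                    w[s] += p.eta * stdp_dw(last_pre[s] - tt, p)
                    w[s] = min(max(w[s], p.w_min), p.w_max)
                    last_pre[s] = None
                last_post[s] = tt

    return np.array(ev_t), np.array(ev_n, dtype=int), w
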