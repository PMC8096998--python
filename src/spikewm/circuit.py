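"""The 30-neuron working-memory circuit and its simulation loop.

Topology: ``N_E`` excitatory neurons all-to-all connected with ``S_EE``
synapses per ordered pair (different conduction delays, plastic weights),
``N_I`` inhibitory neurons coupled to the excitatory population with
probability ``p_EI`` in each direction (fixed weights, no I-I links), and
one read-only detector unit per stimulus pattern whose afferent delays
implement the polychronous coincidence readout.

The engine advances all neurons on a fixed time grid (explicit Euler,
default dt = 0.5 ms) and keeps the synaptic currents in a pair of exact
exponential filter states per neuron, so the alpha-kernel superposition
of all past arrivals is evaluated recursively without truncation error.
Delayed spike propagation uses a circular per-tick event buffer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coding import DetectorSpec, RankPattern, default_patterns, make_detector
from .dynamics import (
    IzhikevichParams,
    NoiseSpec,
    STPParams,
    NumericalInstabilityError,
    PSP_TAU_MS,
    SPIKE_THRESHOLD_MV,
)
from .plasticity import STDPParams

__all__ = [
    "CircuitConfig",
    "Circuit",
    "SpikeRaster",
    "build_circuit",
    "run",
    "ROLE_INPUT",
    "ROLE_EXC",
    "ROLE_INH",
    "ROLE_DETECTOR",
    "ROLE_NAMES",
]

ROLE_INPUT = 0  # excitatory, receives the stimulus volley
ROLE_EXC = 1  # excitatory, non-input
ROLE_INH = 2
ROLE_DETECTOR = 3
ROLE_NAMES = {ROLE_INPUT: "input", ROLE_EXC: "excitatory",
              ROLE_INH: "inhibitory", ROLE_DETECTOR: "detector"}


@dataclass(frozen=True)
class CircuitConfig:
    """Sizes, connectivity, delays and parameter blocks of the circuit.

    Defaults are the reference prefrontal micro-circuit: 24 excitatory
    neurons (15 of them coding/input), 6 inhibitory, 4 synapses per E-E
    connection with delays ``R + 3k`` (R uniform on [3, 12] ms per
    connection, k = 0..3, mean 12 ms), E<->I delays uniform on [1, 20] ms,
    initial E-E weights uniform on [0, 0.14].
    """

    N_E: int = 24
    N_I: int = 6
    S_EE: int = 4
    p_EI: float = 0.8
    N_input: int = 15
    w_init_low: float = 0.0
    w_init_high: float = 0.14
    delay_EE_low: float = 3.0
    delay_EE_high: float = 12.0
    delay_EE_step: float = 3.0
    delay_EI_low: float = 1.0
    delay_EI_high: float = 20.0
    w_EI: float = 0.4
    w_IE: float = 0.5
    syn_gain: float = 1.0
    dt: float = 0.5
    seed: int = 0
    detector_base_delay: float = 1.0
    k_coincident: int = 7
    detector_margin: float = 1.3
    detector_weight: float | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    stp: STPParams = field(default_factory=lambda: STPParams(U=0.5))
    stdp: STDPParams = field(default_factory=lambda: STDPParams(w_max=2.0))
    izh_exc: IzhikevichParams = field(default_factory=IzhikevichParams.excitatory)
    izh_inh: IzhikevichParams = field(default_factory=IzhikevichParams.inhibitory)
    patterns: tuple | None = None  # ((label, RankPattern), ...); None -> red/green defaults

    def __post_init__(self) -> None:
        if self.N_input > self.N_E:
            raise ValueError(
                f"N_input ({self.N_input}) cannot exceed N_E ({self.N_E})"
            )
        if self.N_E < 1 or self.N_I < 0 or self.S_EE < 1:
            raise ValueError("invalid circuit sizes")
        if not 0.0 <= self.p_EI <= 1.0:
            raise ValueError("p_EI must be a probability")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def resolved_patterns(self) -> dict:
        if self.patterns is None:
            return default_patterns(self.N_input)
        return {lbl: pat for lbl, pat in self.patterns}


@dataclass
class SpikeRaster:
    """Time-stamped spike events of one run (times in absolute ms)."""

    times: np.ndarray
    neurons: np.ndarray
    t_start: float
    t_stop: float
    roles: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.neurons = np.asarray(self.neurons, dtype=int)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def counts(self, neurons=None, t0: float | None = None,
               t1: float | None = None) -> np.ndarray:
        """Spike count per neuron (length = total neurons), optionally windowed.

        The window is half-open: ``t0 <= t < t1``.
        """
        t0 = self.t_start if t0 is None else t0
        t1 = self.t_stop if t1 is None else t1
        mask = (self.times >= t0) & (self.times < t1)
        out = np.bincount(self.neurons[mask], minlength=len(self.roles)).astype(float)
        if neurons is not None:
            out = out[np.asarray(neurons)]
        return out

    def select(self, neurons=None, t0=None, t1=None) -> "SpikeRaster":
        mask = np.ones(len(self.times), dtype=bool)
        if t0 is not None:
            mask &= self.times >= t0
        if t1 is not None:
            mask &= self.times < t1
        if neurons is not None:
            mask &= np.isin(self.neurons, neurons)
        return SpikeRaster(self.times[mask], self.neurons[mask],
                           self.t_start if t0 is None else t0,
                           self.t_stop if t1 is None else t1, self.roles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.times,
            "neuron": self.neurons,
            "role": [ROLE_NAMES[r] for r in self.roles[self.neurons]],
        })

    @staticmethod
    def concat(rasters: list["SpikeRaster"]) -> "SpikeRaster":
        if not rasters:
            raise ValueError("nothing to concatenate")
        return SpikeRaster(
            np.concatenate([r.times for r in rasters]),
            np.concatenate([r.neurons for r in rasters]),
            rasters[0].t_start, rasters[-1].t_stop, rasters[0].roles,
        )


class Circuit:
    """Full network state plus the tick-loop engine.

    Built by :func:`build_circuit`.  State (membrane variables, synaptic
    resources, pairing memory, pending arrivals, the noise stream and the
    simulation clock) persists across :meth:`run` calls, so consecutive
    runs are equivalent to one long run.
    """

    def __init__(self, cfg: CircuitConfig, seed: int | None = None,
                 noise_seed: int | None = None):
        self.cfg = cfg
        master = cfg.seed if seed is None else seed
        ss = np.random.SeedSequence(master)
        s_topo, s_weights, s_noise_init, s_run = ss.spawn(4)
        if noise_seed is not None:
            # fresh noise realization on an otherwise identical circuit
            s_run = np.random.SeedSequence(noise_seed)
        rng_topo = np.random.default_rng(s_topo)
        rng_w = np.random.default_rng(s_weights)
        rng_ni = np.random.default_rng(s_noise_init)
        self._rng_noise = np.random.default_rng(s_run)

        n_E, n_I = cfg.N_E, cfg.N_I
        self.patterns = cfg.resolved_patterns()
        self.labels = list(self.patterns)
        n_det = len(self.labels)
        self.n = n_E + n_I + n_det
        self.n_E, self.n_I, self.n_det = n_E, n_I, n_det
        self.exc_idx = np.arange(n_E)
        self.inh_idx = np.arange(n_E, n_E + n_I)
        self.det_idx = np.arange(n_E + n_I, self.n)
        self.detector_of = {lbl: int(self.det_idx[j])
                            for j, lbl in enumerate(self.labels)}

        roles = np.full(self.n, ROLE_EXC, dtype=int)
        roles[:cfg.N_input] = ROLE_INPUT
        roles[self.inh_idx] = ROLE_INH
        roles[self.det_idx] = ROLE_DETECTOR
        self.roles = roles

        # neuron parameter arrays
        pe, pi = cfg.izh_exc, cfg.izh_inh
        self.a = np.empty(self.n)
        self.b = np.empty(self.n)
        self.c = np.empty(self.n)
        self.d = np.empty(self.n)
        for idx, p in ((self.exc_idx, pe), (self.inh_idx, pi), (self.det_idx, pe)):
            self.a[idx], self.b[idx], self.c[idx], self.d[idx] = p.a, p.b, p.c, p.d

        # background noise: per-neuron baseline mean, frozen at construction
        self.noise_mean = np.zeros(self.n)
        circ = np.concatenate([self.exc_idx, self.inh_idx])
        self.noise_mean[circ] = rng_ni.uniform(
            cfg.noise.mean_low, cfg.noise.mean_high, size=len(circ))
        self.noise_mask = np.zeros(self.n)
        self.noise_mask[circ] = 1.0  # detectors are noise-free read-out taps
        self.noise_sigma = cfg.noise.sigma

        # --- synapse tables -------------------------------------------------
        pre_l, post_l, w_l, delay_l, sign_l, plastic_l, k_l = [], [], [], [], [], [], []

        # E-E: all-to-all, S_EE synapses per ordered pair, delays R + step*k
        for i in range(n_E):
            for j in range(n_E):
                if i == j:
                    continue
                R = rng_topo.uniform(cfg.delay_EE_low, cfg.delay_EE_high)
                for k in range(cfg.S_EE):
                    pre_l.append(i)
                    post_l.append(j)
                    delay_l.append(R + cfg.delay_EE_step * k)
                    w_l.append(rng_w.uniform(cfg.w_init_low, cfg.w_init_high))
                    sign_l.append(1)
                    plastic_l.append(True)
                    k_l.append(k)

        # E->I and I->E: independent directed Bernoulli(p_EI), one synapse,
        # fixed weights, delays uniform on [1, 20] ms
        for i in range(n_E):
            for j in self.inh_idx:
                if rng_topo.random() < cfg.p_EI:
                    pre_l.append(i)
                    post_l.append(int(j))
                    delay_l.append(rng_topo.uniform(cfg.delay_EI_low, cfg.delay_EI_high))
                    w_l.append(cfg.w_EI)
                    sign_l.append(1)
                    plastic_l.append(False)
                    k_l.append(0)
        for j in self.inh_idx:
            for i in range(n_E):
                if rng_topo.random() < cfg.p_EI:
                    pre_l.append(int(j))
                    post_l.append(i)
                    delay_l.append(rng_topo.uniform(cfg.delay_EI_low, cfg.delay_EI_high))
                    w_l.append(cfg.w_IE)
                    sign_l.append(-1)
                    plastic_l.append(False)
                    k_l.append(0)

        # detector afferents from the coding neurons (read-only taps)
        self.detectors: dict[str, DetectorSpec] = {}
        for j, lbl in enumerate(self.labels):
            spec = make_detector(
                self.patterns[lbl], cfg.detector_base_delay,
                k_coincident=cfg.k_coincident, stp=cfg.stp,
                params=pe, dt=cfg.dt, weight=cfg.detector_weight,
                margin=cfg.detector_margin, syn_gain=cfg.syn_gain)
            self.detectors[lbl] = spec
            for i in range(cfg.N_input):
                pre_l.append(i)
                post_l.append(int(self.det_idx[j]))
                delay_l.append(spec.delays[i])
                w_l.append(spec.weight)
                sign_l.append(1)
                plastic_l.append(False)
                k_l.append(0)

        self.S = len(pre_l)
        self.pre = np.array(pre_l, dtype=np.int64)
        self.post = np.array(post_l, dtype=np.int64)
        self.w = np.array(w_l, dtype=float)
        self.delay = np.array(delay_l, dtype=float)
        self.sign = np.array(sign_l, dtype=float)
        self.plastic = np.array(plastic_l, dtype=bool)
        self.syn_k = np.array(k_l, dtype=np.int64)
        self.dticks = np.maximum(1, np.rint(self.delay / cfg.dt)).astype(np.int64)

        # efferent adjacency (synapses grouped by presynaptic neuron)
        order = np.argsort(self.pre, kind="stable")
        self._eff_idx = order
        self._eff_ptr = np.searchsorted(self.pre[order], np.arange(self.n + 1))
        self._eff_pairs = [
            list(zip(
                self._eff_idx[self._eff_ptr[i]:self._eff_ptr[i + 1]].tolist(),
                self.dticks[self._eff_idx[self._eff_ptr[i]:self._eff_ptr[i + 1]]].tolist(),
            ))
            for i in range(self.n)
        ]
        # plastic afferent adjacency (for post-spike STDP updates)
        pl = np.nonzero(self.plastic)[0]
        order2 = pl[np.argsort(self.post[pl], kind="stable")]
        self._ap_idx = order2
        self._ap_ptr = np.searchsorted(self.post[order2], np.arange(self.n + 1))
        self._ap_lists = [
            self._ap_idx[self._ap_ptr[i]:self._ap_ptr[i + 1]].copy()
            for i in range(self.n)
        ]

        # --- mutable state ---------------------------------------------------
        self.v = self.c.copy()
        self.u = self.b * self.v
        self.x = np.ones(self.S)
        self.uu = np.full(self.S, cfg.stp.U)
        self.t_last = np.full(self.S, -np.inf)
        self.last_pre = np.full(self.S, np.nan)
        self.last_post = np.full(self.S, np.nan)
        self._g = np.zeros(self.n)  # exp filter states of the alpha kernel
        self._h = np.zeros(self.n)
        self.tick = 0
        self._L = int(self.dticks.max()) + 1
        self._ring: list[list[int]] = [[] for _ in range(self._L)]

    # -- convenience --------------------------------------------------------
    @property
    def time_ms(self) -> float:
        return self.tick * self.cfg.dt

    @property
    def ee_mask(self) -> np.ndarray:
        return self.plastic

    def ee_weights(self) -> np.ndarray:
        """Current weights of the plastic E-E synapses."""
        return self.w[self.plastic].copy()

    def weight_table(self) -> pd.DataFrame:
        """Per-synapse table of the plastic E-E weights."""
        m = self.plastic
        return pd.DataFrame({
            "pre": self.pre[m], "post": self.post[m], "k": self.syn_k[m],
            "delay_ms": self.delay[m], "w": self.w[m],
        })

    # -- engine -------------------------------------------------------------
    def run(self, duration: float, forced_spikes=None, offsets=None,
            record: bool = True) -> SpikeRaster:
        """Advance the circuit by ``duration`` ms.

        ``forced_spikes`` is a sequence of ``(t_ms, neuron)`` pairs with
        times relative to the start of this run; at the scheduled tick the
        neuron's membrane is forced over threshold so downstream synapses
        see an ordinary spike.  ``offsets`` is an additive per-neuron
        current (length-n array), applied on top of the baseline noise
        mean for the whole run.
        """
        cfg = self.cfg
        dt = cfg.dt
        nticks = int(round(duration / dt))
        t_start = self.time_ms

        if offsets is None:
            offsets = np.zeros(self.n)
        else:
            offsets = np.asarray(offsets, dtype=float)
        base_mean = self.noise_mask * self.noise_mean + offsets

        forced: dict[int, list[int]] = {}
        if forced_spikes is not None:
            for t_f, nrn in forced_spikes:
                rel = max(1, int(round(t_f / dt)))
                if rel > nticks:
                    raise ValueError(
                        f"forced spike at {t_f} ms outside run of {duration} ms")
                forced.setdefault(rel, []).append(int(nrn))

        p = cfg.stdp
        alpha = math.exp(-dt / PSP_TAU_MS)
        coef = math.e / PSP_TAU_MS
        U, tauF, tauD = cfg.stp.U, cfg.stp.tau_F, cfg.stp.tau_D
        sigma = self.noise_sigma
        g, h = self._g, self._h
        v, u = self.v, self.u
        w, x, uu = self.w, self.x, self.uu
        t_last, last_pre, last_post = self.t_last, self.last_pre, self.last_post
        ring, L = self._ring, self._L
        ev_t: list[float] = []
        ev_n: list[int] = []

        with np.errstate(under="ignore"):
            for k in range(1, nticks + 1):
                tick_abs = self.tick + k
                tt = tick_abs * dt

                # decay the synaptic filters to the current tick
                h *= alpha
                h += (alpha * dt) * g
                g *= alpha

                # deliver arrivals scheduled for this tick
                slot = tick_abs % L
                arr = ring[slot]
                if arr:
                    ring[slot] = []
                    s = np.asarray(arr, dtype=np.int64)
                    dte = tt - t_last[s]
                    xs = 1.0 - (1.0 - x[s]) * np.exp(-dte / tauD)
                    us = U + (uu[s] - U) * np.exp(-dte / tauF)
                    us = us + U * (1.0 - us)
                    eff = us * xs
                    x[s] = xs - eff
                    uu[s] = us
                    t_last[s] = tt
                    np.add.at(g, self.post[s],
                              cfg.syn_gain * self.sign[s] * w[s] * eff)
                    ps = s[self.plastic[s]]
                    if len(ps):
                        lp = last_post[ps]
                        m = ~np.isnan(lp)
                        if m.any():
                            q = ps[m]
                            dwq = -abs(p.A_minus) * np.exp(-(tt - lp[m]) / p.tau_minus)
                            w[q] = np.clip(w[q] + p.eta * dwq, p.w_min, p.w_max)
                            last_post[q] = np.nan
                        last_pre[ps] = tt

                # total input current and Euler step
                I = coef * h + base_mean
                if sigma > 0:
                    I = I + (sigma * self.noise_mask) * \
                        self._rng_noise.standard_normal(self.n)
                v_new = v + dt * ((0.04 * v + 5.0) * v + 140.0 - u + I)
                u += dt * self.a * (self.b * v - u)
                fk = forced.get(k)
                if fk is not None:
                    v_new[fk] = SPIKE_THRESHOLD_MV + 1.0

                spk = v_new > SPIKE_THRESHOLD_MV
                if spk.any():
                    idx = np.nonzero(spk)[0]
                    v_new[idx] = self.c[idx]
                    u[idx] += self.d[idx]
                    if record:
                        ev_t.extend([tt] * len(idx))
                        ev_n.extend(idx.tolist())
                    for i in idx:
                        for sidx, dk in self._eff_pairs[i]:
                            ring[(tick_abs + dk) % L].append(sidx)
                        ap = self._ap_lists[i]
                        if len(ap):
                            lpv = last_pre[ap]
                            m = ~np.isnan(lpv)
                            if m.any():
                                q = ap[m]
                                dtv = lpv[m] - tt
                                dwv = np.where(
                                    dtv < 0.0,
                                    p.A_plus * np.exp(dtv / p.tau_plus),
                                    -abs(p.A_minus) * np.exp(-dtv / p.tau_minus),
                                )
                                w[q] = np.clip(w[q] + p.eta * dwv, p.w_min, p.w_max)
                                last_pre[q] = np.nan
                            last_post[ap] = tt
                v = v_new
                if not np.isfinite(v).all():
                    bad = int(np.nonzero(~np.isfinite(v))[0][0])
                    raise NumericalInstabilityError(
                        f"non-finite membrane potential (neuron {bad}, tick {tick_abs})")

        self.v, self.u = v, u
        self._g, self._h = g, h
        self.tick += nticks
        return SpikeRaster(np.array(ev_t), np.array(ev_n, dtype=int),
                           t_start, t_start + duration, self.roles)


def build_circuit(cfg: CircuitConfig | None = None, seed: int | None = None,
                  noise_seed: int | None = None) -> Circuit:
    """Construct a circuit from ``cfg`` (defaults if None), reproducibly.

    ``seed`` overrides ``cfg.seed``.  Two builds with the same seed yield
    bitwise-identical weight and delay tables and identical noise streams.
    ``noise_seed`` replaces only the per-tick noise stream, so repeated
    trials on one and the same network (identical topology, delays and
    initial weights) see independent noise realizations.
    """
    if cfg is None:
        cfg = CircuitConfig()
    return Circuit(cfg, seed=seed, noise_seed=noise_seed)


def run(circuit: Circuit, duration: float, forced_spikes=None,
        offsets=None) -> SpikeRaster:
    """Advance ``circuit`` by ``duration`` ms; see :meth:`Circuit.run`."""
    return circuit.run(duration, forced_spikes=forced_spikes, offsets=offsets)
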