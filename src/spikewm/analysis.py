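"""Population decoding and weight-distribution analyses.

Firing rates are spike counts in sliding windows (500 ms bins, 200 ms
stride by default).  Stimulus identity is decoded per time bin with a
linear-kernel SVM under stratified k-fold cross-validation on the
excitatory neurons' rate vectors; detector and inhibitory neurons are
excluded so the readout units cannot leak the label.  With two stimuli
the chance level is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Circuit, SpikeRaster, ROLE_EXC, ROLE_INPUT

__all__ = [
    "RateMatrix",
    "DecodingCurve",
    "bin_rates",
    "decode_over_time",
    "weight_histogram",
    "plot_raster",
    "plot_decoding_curve",
    "plot_weight_histogram",
]


@dataclass
class RateMatrix:
    """Per-neuron firing rates (Hz) in sliding windows.

    ``rates`` has shape (n_neurons, n_bins); ``bins`` holds window center
    times in ms (relative to the raster's start).
    """

    bins: np.ndarray
    rates: np.ndarray
    neurons: np.ndarray
    bin_width: float
    stride: float


@dataclass
class DecodingCurve:
    """Cross-validated decoding accuracy per time bin."""

    bins: np.ndarray
    accuracy: np.ndarray
    n_trials: int
    cv_folds: int


def _window_starts(duration: float, bin_width: float, stride: float) -> np.ndarray:
    n = int(np.floor((duration - bin_width) / stride + 1e-9)) + 1
    if n < 1:
        return np.zeros(0)
    return np.arange(n) * stride


def bin_rates(
    raster: SpikeRaster,
    bin_width: float = 500.0,
    stride: float = 200.0,
    neurons=None,
) -> RateMatrix:
    """Count spikes per neuron in half-open windows [t, t + bin_width).

    Window start times tile ``[0, duration - bin_width]`` at the stride,
    measured from the raster's start; counts are normalized to Hz.
    """
    if bin_width <= 0 or stride <= 0:
        raise ValueError("bin_width and stride must be positive")
    if neurons is None:
        neurons = np.arange(len(raster.roles))
    else:
        neurons = np.asarray(neurons, dtype=int)
    if len(neurons) == 0:
        raise ValueError("empty neuron subset")
    starts = _window_starts(raster.duration, bin_width, stride)
    rates = np.zeros((len(neurons), len(starts)))
    t = raster.times - raster.t_start
    pos = {int(nn): i for i, nn in enumerate(neurons)}
    sel = np.isin(raster.neurons, neurons)
    t_sel = t[sel]
    n_sel = raster.neurons[sel]
    for b, s in enumerate(starts):
        m = (t_sel >= s) & (t_sel < s + bin_width)
        if m.any():
            cnt = np.bincount(n_sel[m], minlength=len(raster.roles))
            for nn, i in pos.items():
                rates[i, b] = cnt[nn]
    rates /= bin_width / 1000.0
    return RateMatrix(bins=starts + bin_width / 2.0, rates=rates,
                      neurons=neurons, bin_width=bin_width, stride=stride)


def decode_over_time(
    trials,
    labels=None,
    bin_width: float = 500.0,
    stride: float = 200.0,
    cv_folds: int = 5,
    seed: int = 0,
    neurons=None,
) -> DecodingCurve:
    """Per-bin linear-SVM decoding accuracy across trials.

    ``trials`` is a list of :class:`~spikewm.protocol.TrialResult` (or of
    rasters); ``labels`` defaults to each trial's sample.  Rate vectors
    use all excitatory neurons (input and non-input) unless ``neurons``
    overrides the subset.  Accuracy per bin is the mean held-out score of
    a linear-kernel SVM under stratified ``cv_folds``-fold CV.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.svm import SVC

    rasters = [t.raster if hasattr(t, "raster") else t for t in trials]
    if labels is None:
        labels = [t.spec.sample for t in trials]
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to decode")
    if counts.min() < cv_folds:
        raise ValueError(
            f"class with {counts.min()} trials cannot support {cv_folds}-fold CV")
    roles = rasters[0].roles
    if neurons is None:
        neurons = np.nonzero((roles == ROLE_EXC) | (roles == ROLE_INPUT))[0]
    mats = [bin_rates(r, bin_width, stride, neurons) for r in rasters]
    bins = mats[0].bins
    acc = np.zeros(len(bins))
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for b in range(len(bins)):
        X = np.stack([m.rates[:, b] for m in mats])
        clf = SVC(kernel="linear")
        acc[b] = cross_val_score(clf, X, labels, cv=cv).mean()
    return DecodingCurve(bins=bins, accuracy=acc, n_trials=len(rasters),
                         cv_folds=cv_folds)


def weight_histogram(circuit_or_weights, edges=None, threshold: float = 0.2):
    """Histogram and summary of the plastic E-E weights.

    Returns ``(counts, edges, summary)`` where ``summary`` holds the mean
    weight and the fractions above ``threshold`` and below 0.02.
    """
    if isinstance(circuit_or_weights, Circuit):
        w = circuit_or_weights.ee_weights()
    else:
        w = np.asarray(circuit_or_weights, dtype=float)
    if edges is None:
        edges = np.linspace(0.0, 0.5, 26)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    counts, edges = np.histogram(w, bins=edges)
    summary = {
        "mean": float(w.mean()),
        "frac_above": float((w > threshold).mean()),
        "frac_below_002": float((w < 0.02).mean()),
        "n": int(w.size),
    }
    return counts, edges, summary


# --- plotting --------------------------------------------------------------

_ROLE_COLORS = {0: "tab:red", 1: "tab:red", 2: "tab:blue", 3: "black"}


def plot_raster(raster: SpikeRaster, ax=None, periods: dict | None = None):
    """Spike raster colored by role (excitatory red, inhibitory blue,
    detectors black); optional period boundaries as vertical lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    colors = [_ROLE_COLORS[r] for r in raster.roles[raster.neurons]]
    ax.scatter(raster.times / 1000.0, raster.neurons, s=3, c=colors,
               linewidths=0)
    if periods:
        for name, (t0, _) in periods.items():
            ax.axvline(t0 / 1000.0, color="gray", lw=0.6, ls="--")
            ax.text(t0 / 1000.0, ax.get_ylim()[1], name, fontsize=8,
                    va="bottom")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron")
    return ax


def plot_decoding_curve(curve: DecodingCurve, ax=None, chance: float = 0.5):
    """Decoding accuracy over time with the chance level marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(curve.bins / 1000.0, curve.accuracy, marker="o", ms=3)
    ax.axhline(chance, color="gray", ls=":")
    ax.set_ylim(0.0, 1.05)
    ax.set_xlabel("bin center (s)")
    ax.set_ylabel("decoding accuracy")
    return ax


def plot_weight_histogram(weights, ax=None, edges=None):
    """Histogram of plastic weights (e.g. before/after a cue)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    counts, edges, _ = weight_histogram(weights, edges=edges)
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           edgecolor="white")
    ax.set_xlabel("synaptic weight")
    ax.set_ylabel("count")
    return ax
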