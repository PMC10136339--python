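"""Twitch force model: impulse-response twitches, fusion gain, summation.

Each discharge of a motor unit produces a twitch modelled as the impulse
response of a second-order critically damped system,

    f(t) = g * P * (t/T) * exp(1 - t/T),

which peaks at the unit's twitch force ``P`` (au) at the contraction time
``T`` (ms).  The per-discharge gain ``g`` captures the nonlinear summation
of unfused/fused twitches: it is 1 when the preceding inter-spike interval
is long relative to T (T/ISI <= 0.4), and otherwise follows the sigmoid
saturation S(u) = (1 - exp(-2 u^3)) / u with u = T/ISI, normalized by
S(0.4) so that the gain is continuous at the boundary.  Whole-muscle force
is the linear sum of all unit force outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ForceTrace", "twitch_kernel", "isi_gain", "unit_force", "total_force"]

#: Twitch kernels are evaluated out to this many contraction times; beyond
#: 8 T the kernel amplitude is below 1% of its peak.
KERNEL_SUPPORT_T = 8.0

_U_KNEE = 0.4


@dataclass
class ForceTrace:
    """Uniformly sampled force signal (au)."""

    samples: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def mean(self, t_start: float | None = None, t_stop: float | None = None) -> float:
        """Mean force over ``[t_start, t_stop)`` seconds (whole trace by default)."""
        i0 = 0 if t_start is None else int(round(t_start * self.fs))
        i1 = len(self.samples) if t_stop is None else int(round(t_stop * self.fs))
        return float(np.mean(self.samples[i0:i1]))


def twitch_kernel(p: float, t_contract: float, t, g: float = 1.0):
    """Twitch force (au) at time ``t`` (ms) after a discharge.

    ``p`` is the peak twitch force (au), ``t_contract`` the contraction
    time (ms), ``g`` the fusion gain of this discharge.
    """
    if t_contract <= 0:
        raise ValueError("t_contract must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return g * p * (t / t_contract) * np.exp(1.0 - t / t_contract)


def _saturation(u):
    return (1.0 - np.exp(-2.0 * u**3)) / u


def isi_gain(t_contract: float, isi):
    """Fusion gain of a discharge given the preceding ISI (same time unit as T).

    Returns 1 for ``T/ISI <= 0.4``; above that, the normalized saturation
    ``S(u)/S(0.4)``, continuous at the knee.  The gain rises above 1 as
    twitches fuse, peaks near u ~ 1 and decays as 1/u at high rates, so
    tetanic force saturates instead of growing linearly with rate.
    """
    isi = np.asarray(isi, dtype=float)
    if np.any(isi <= 0):
        raise ValueError("isi must be positive")
    u = t_contract / isi
    return np.where(u <= _U_KNEE, 1.0, _saturation(np.maximum(u, _U_KNEE)) / _saturation(_U_KNEE))


def _scatter_add(spike_idx: np.ndarray, weights: np.ndarray, kernel: np.ndarray, n: int) -> np.ndarray:
    """Sum ``weights[j] * kernel`` placed at ``spike_idx[j]`` into a length-n trace."""
    m = len(kernel)
    idx = spike_idx[:, None] + np.arange(m)[None, :]
    vals = weights[:, None] * kernel[None, :]
    out = np.bincount(idx.ravel(), weights=vals.ravel(), minlength=n + m)
    return out[:n]


def unit_force(
    spikes: np.ndarray,
    p: float,
    t_contract: float,
    fs: float,
    duration: float,
) -> ForceTrace:
    """Force trace of one motor unit from its discharge times.

    A twitch kernel is superposed at every discharge; the gain of each
    discharge is determined by the ISI preceding it (the first discharge
    has gain 1, no preceding ISI existing).  Kernels are truncated at
    ``8 T`` where their amplitude is below 1% of the peak.
    """
    n = int(round(fs * duration))
    spikes = np.asarray(spikes, dtype=float)
    if len(spikes) == 0:
        return ForceTrace(samples=np.zeros(n), fs=fs)

    gains = np.ones(len(spikes))
    if len(spikes) > 1:
        isis_ms = np.diff(spikes) * 1000.0
        gains[1:] = isi_gain(t_contract, isis_ms)

    m = int(round(KERNEL_SUPPORT_T * t_contract / 1000.0 * fs))
    t_ms = np.arange(m) / fs * 1000.0
    kernel = twitch_kernel(p, t_contract, t_ms, g=1.0)

    spike_idx = np.round(spikes * fs).astype(int)
    keep = spike_idx < n
    samples = _scatter_add(spike_idx[keep], gains[keep], kernel, n)
    return ForceTrace(samples=samples, fs=fs)


def total_force(unit_traces: list[ForceTrace]) -> ForceTrace:
    """Whole-muscle force: element-wise sum of per-unit traces."""
    if not unit_traces:
        raise ValueError("need at least one trace")
    fs = unit_traces[0].fs
    n = len(unit_traces[0].samples)
    for tr in unit_traces:
        if tr.fs != fs or len(tr.samples) != n:
            raise ValueError("traces must share sampling rate and length")
    return ForceTrace(samples=np.sum([tr.samples for tr in unit_traces], axis=0), fs=fs)


def pool_force(
    trains,
    pool,
    fs: float,
    duration: float,
) -> ForceTrace:
    """Total force of a pool for one spike-train set (convenience wrapper)."""
    n = int(round(fs * duration))
    acc = np.zeros(n)
    for u, spikes in enumerate(trains.spike_times):
        if len(spikes) == 0:
            continue
        acc += unit_force(spikes, pool.p[u], pool.t_contract[u], fs, duration).samples
    return ForceTrace(samples=acc, fs=fs)
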