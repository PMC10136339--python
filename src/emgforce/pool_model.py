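"""Motor neuron pool model: recruitment, rate coding and spike-train generation.

The pool follows the classic motor-unit population model in which both the
recruitment threshold excitation (RTE) and the number of muscle fibers per
unit follow exponential distributions across the recruitment order, so that
most units are small and low-threshold.  The distributions are deterministic
exponential interpolations over the unit index: randomness enters only
through inter-spike-interval (ISI) variability and through the geometric
placement of units (see :mod:`emgforce.volume_conductor`).

Rate coding: once the excitatory drive exceeds a unit's RTE the unit fires
at a minimum rate (8 Hz by default) and its rate increases linearly with
excitation up to a peak firing rate (PFR).  Two firing-rate organisations
are supported: "onion skin" (early-recruited units attain the highest peak
rates) and "reverse onion skin" (late-recruited, larger units attain the
highest peak rates, 35 Hz for the largest vs 25 Hz for the smallest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PoolParams",
    "MotorUnitPool",
    "SpikeTrainSet",
    "build_pool",
    "firing_rate",
    "generate_spike_trains",
]

#: Ratio between the largest and smallest recruitment threshold.  Matches the
#: 100-fold twitch-force range so that RTE and twitch force grow together.
RTE_RANGE_RATIO = 100.0

_STRATEGIES = ("onion_skin", "reverse_onion_skin")


@dataclass(frozen=True)
class PoolParams:
    """Parameters defining the motor neuron pool.

    Attributes
    ----------
    n_units:
        Number of motor units in the pool.
    fibers_min, fibers_max:
        Muscle fibers innervated by the smallest and largest unit.
    rte_max_fraction:
        Fraction of maximum excitation at which the last (largest) unit is
        recruited.  0.4 mimics small hand muscles where rate coding
        dominates; 0.8 mimics large muscles such as biceps brachii.
    mfr:
        Minimum firing rate at recruitment, Hz.
    pfr_low_threshold, pfr_high_threshold:
        Peak firing rates (Hz) of the lowest- and highest-threshold unit.
        Defaults (25, 35) encode the reverse onion-skin organisation;
        with ``strategy="onion_skin"`` the assignment is flipped so the
        earliest-recruited unit gets the higher rate.
    strategy:
        "onion_skin" or "reverse_onion_skin".
    twitch_p_min, twitch_p_max:
        Peak twitch forces of the smallest and largest unit, au.
    twitch_t_max, twitch_t_min:
        Contraction times of the smallest and largest unit, ms (the
        smallest unit is the slowest).
    isi_cv:
        Coefficient of variation of inter-spike intervals.
    excitation_rate_gain:
        Firing-rate increase per percent excitation above threshold,
        Hz/%.  ``None`` (default) assigns each unit the gain at which it
        reaches its peak rate exactly at 100% excitation, so the firing
        strategy's rate ordering (onion skin / reverse onion skin) is
        realised at maximal drive; a scalar applies one common gain to
        every unit.
    """

    n_units: int = 150
    fibers_min: int = 22
    fibers_max: int = 2137
    rte_max_fraction: float = 0.4
    mfr: float = 8.0
    pfr_low_threshold: float = 25.0
    pfr_high_threshold: float = 35.0
    strategy: str = "reverse_onion_skin"
    twitch_p_min: float = 1.0
    twitch_p_max: float = 100.0
    twitch_t_max: float = 90.0
    twitch_t_min: float = 30.0
    isi_cv: float = 0.2
    excitation_rate_gain: float | None = None

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2 (interpolation undefined)")
        if self.fibers_min > self.fibers_max:
            raise ValueError("fibers_min must not exceed fibers_max")
        if not (0.0 < self.rte_max_fraction <= 1.0):
            raise ValueError("rte_max_fraction must be in (0, 1]")
        if self.mfr <= 0:
            raise ValueError("mfr must be positive")
        if self.twitch_p_min <= 0 or self.twitch_p_max <= 0:
            raise ValueError("twitch forces must be positive")
        if self.twitch_t_min <= 0 or self.twitch_t_max <= 0:
            raise ValueError("contraction times must be positive")
        if self.isi_cv < 0:
            raise ValueError("isi_cv must be non-negative")
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"strategy must be one of {_STRATEGIES}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MotorUnitPool:
    """Per-unit arrays of a built pool, ordered by recruitment (index 0 = first recruited).

    ``rte`` is in percent of maximum excitation; ``p`` is peak twitch force
    (au); ``t_contract`` is twitch contraction time (ms); ``pfr`` is the
    peak firing rate (Hz).
    """

    params: PoolParams
    rte: np.ndarray
    n_fibers: np.ndarray
    p: np.ndarray
    t_contract: np.ndarray
    pfr: np.ndarray
    excitation_rate_gain: np.ndarray | float = field(default=0.0)

    @property
    def n_units(self) -> int:
        return self.params.n_units

    def recruited(self, excitation: float) -> np.ndarray:
        """Boolean mask of units active at the given excitation (%)."""
        return excitation >= self.rte

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "unit": np.arange(1, self.n_units + 1),
                "rte": self.rte,
                "n_fibers": self.n_fibers,
                "p": self.p,
                "t_contract": self.t_contract,
                "pfr": self.pfr,
            }
        )


@dataclass
class SpikeTrainSet:
    """Discharge times (s) for every unit at one excitation level."""

    excitation: float
    duration: float
    spike_times: list  # list of 1-D float arrays, one per unit

    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spike_times))


def build_pool(params: PoolParams | None = None) -> MotorUnitPool:
    """Construct the motor unit pool from exponential interpolations.

    Recruitment thresholds span ``rte_max_fraction * 100 / R`` to
    ``rte_max_fraction * 100`` percent excitation with range ratio
    ``R = 100``; fiber counts, twitch forces and contraction times are
    exponential across the recruitment order with the configured endpoint
    values (fiber counts rounded to integers).  Contraction time follows a
    power law of twitch force chosen so that a 100-fold force range
    coincides with a 3-fold contraction-time range.
    """
    if params is None:
        params = PoolParams()
    n = params.n_units
    i = np.arange(1, n + 1, dtype=float)

    rte = (
        params.rte_max_fraction
        * 100.0
        * np.exp(i * np.log(RTE_RANGE_RATIO) / n)
        / RTE_RANGE_RATIO
    )

    fiber_ratio = params.fibers_max / params.fibers_min
    n_fibers = np.rint(
        params.fibers_min * np.exp((i - 1) * np.log(fiber_ratio) / (n - 1))
    ).astype(int)

    p_ratio = params.twitch_p_max / params.twitch_p_min
    p = params.twitch_p_min * np.exp((i - 1) * np.log(p_ratio) / (n - 1))

    # T_i = T_max * (P_min / P_i)^c with c chosen so the full P range maps
    # onto the full T range (c = ln(T_max/T_min)/ln(P_max/P_min)).
    c = np.log(params.twitch_t_max / params.twitch_t_min) / np.log(p_ratio)
    t_contract = params.twitch_t_max * (params.twitch_p_min / p) ** c

    if params.strategy == "reverse_onion_skin":
        pfr = np.linspace(params.pfr_low_threshold, params.pfr_high_threshold, n)
    else:
        pfr = np.linspace(params.pfr_high_threshold, params.pfr_low_threshold, n)

    gain = params.excitation_rate_gain
    if gain is None:
        # every unit reaches its PFR exactly at 100% excitation
        gain = (pfr - params.mfr) / (100.0 - rte)
    else:
        gain = float(gain)

    return MotorUnitPool(
        params=params,
        rte=rte,
        n_fibers=n_fibers,
        p=p,
        t_contract=t_contract,
        pfr=pfr,
        excitation_rate_gain=gain,
    )


def firing_rate(pool: MotorUnitPool, unit: int, excitation: float) -> float:
    """Mean firing rate (Hz) of ``unit`` (0-based) at ``excitation`` (%).

    Zero below the unit's recruitment threshold; above it the rate rises
    linearly from the minimum firing rate and saturates at the unit's PFR.
    """
    if not 0 <= unit < pool.n_units:
        raise IndexError(f"unit index {unit} out of range")
    if not 0.0 <= excitation <= 100.0:
        raise ValueError("excitation must be in [0, 100]")
    return float(firing_rates(pool, excitation)[unit])


def firing_rates(pool: MotorUnitPool, excitation: float) -> np.ndarray:
    """Vector of firing rates for all units at ``excitation`` (%)."""
    rates = pool.params.mfr + pool.excitation_rate_gain * (excitation - pool.rte)
    rates = np.minimum(rates, pool.pfr)
    rates[excitation < pool.rte] = 0.0
    return rates


def _unit_train(rate: float, duration: float, isi_cv: float, rng: np.random.Generator) -> np.ndarray:
    """Spike times for one unit: Gaussian renewal process, positive ISIs only."""
    if rate <= 0:
        return np.empty(0)
    mean_isi = 1.0 / rate
    if isi_cv == 0.0:
        first = rng.uniform(0.0, mean_isi)
        return np.arange(first, duration, mean_isi)
    sd = isi_cv * mean_isi
    expected = int(duration / mean_isi) + 1
    times = [rng.uniform(0.0, mean_isi)]
    t = times[0]
    while t < duration:
        block = rng.normal(mean_isi, sd, size=max(expected, 8))
        block = block[block > 0]  # resample truncation: drop non-positive draws
        for isi in block:
            t += isi
            if t >= duration:
                break
            times.append(t)
        expected = 8
    return np.asarray(times)


def generate_spike_trains(
    pool: MotorUnitPool,
    excitation: float,
    duration: float,
    isi_cv: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrainSet:
    """Simulate discharge trains for all units at one excitation level.

    ISIs are drawn from a Gaussian with mean ``1/rate`` and standard
    deviation ``isi_cv/rate``; non-positive draws are rejected and redrawn
    (truncation by resampling, which preserves the mean to first order).
    The first discharge is placed uniformly within one mean ISI of t = 0 to
    decorrelate units.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isi_cv is None:
        isi_cv = pool.params.isi_cv
    rng = np.random.default_rng(seed)
    rates = firing_rates(pool, excitation)
    trains = [_unit_train(r, duration, isi_cv, rng) for r in rates]
    return SpikeTrainSet(excitation=excitation, duration=duration, spike_times=trains)
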