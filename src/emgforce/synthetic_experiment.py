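"""End-to-end study runners.

Two studies are implemented:

* the depth-condition simulation study: one pool, three motor-unit depth
  distributions (superficial / random / deep), EMG and force simulated at
  excitation levels of 10-100% in 10% steps, the log-log EMG-force slope
  ``b`` fitted per repetition and compared across conditions with a
  one-way ANOVA and Bonferroni-corrected pairwise tests;

* a synthetic high-density grid session generator and analyser emulating
  an isometric biceps protocol: two 13 x 5 electrode arrays (pitch 8 mm,
  represented as one logical 13 x 10 grid), monopolar EMG at 2048 Hz,
  contractions at 20/40/60/80% MVC, per-channel slope maps and regional
  (proximal/distal, lateral/medial) comparisons across subjects with the
  Wilcoxon signed-rank test.  A configurable proximal-distal depth
  gradient (large units shallower proximally) is the generator's ground
  truth for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pool_model import PoolParams, MotorUnitPool, build_pool, firing_rates, generate_spike_trains
from .force_model import ForceTrace, isi_gain, pool_force
from .slope_analysis import (
    LevelSeries,
    RegionSpec,
    fit_loglog,
    slope_map,
    region_mean,
    rms,
    wilcoxon_signed_rank,
    anova_bonferroni,
    ks_normality,
)
from .volume_conductor import (
    MuscleGeometry,
    TripoleSpec,
    place_units,
    muap_templates,
    synthesize_emg,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimStudyConfig",
    "GridSessionConfig",
    "StudyResult",
    "GridSession",
    "GridStudyResult",
    "run_depth_condition_study",
    "calibrate_excitation_for_mvc",
    "generate_grid_session",
    "generate_cohort",
    "analyze_grid_session",
]

_CONDITIONS = ("superficial", "random", "deep")

#: z offset (mm) of the single simulation electrode from the innervation
#: zone; directly over the zone the travelling sources partially cancel.
SIM_ELECTRODE_Z = 20.0


@dataclass(frozen=True)
class SimStudyConfig:
    """Configuration of the three-condition depth simulation study."""

    conditions: tuple = _CONDITIONS
    repetitions: int = 50
    excitation_levels: tuple = tuple(range(10, 101, 10))
    strategy: str = "reverse_onion_skin"
    rte_max_fraction: float = 0.4
    duration: float = 3.0
    analysis_window: float = 2.0
    fs: float = 2000.0
    jitter_sd: float = 2.5
    highpass_hz: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if len(self.excitation_levels) < 3:
            raise ValueError("need at least 3 excitation levels")
        if self.analysis_window > self.duration:
            raise ValueError("analysis window cannot exceed the simulated duration")
        for c in self.conditions:
            if c not in _CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")

    def pool_params(self) -> PoolParams:
        return PoolParams(strategy=self.strategy, rte_max_fraction=self.rte_max_fraction)


@dataclass
class StudyResult:
    """Per-condition log-log slopes and the study statistics."""

    conditions: tuple
    b: dict  # condition -> (repetitions,) array
    stats: list = field(default_factory=list)  # records: name, statistic, p, ...
    config: SimStudyConfig | None = None

    def mean(self, condition: str) -> float:
        return float(np.mean(self.b[condition]))

    def sd(self, condition: str) -> float:
        return float(np.std(self.b[condition], ddof=1)) if len(self.b[condition]) > 1 else 0.0

    def summary(self) -> dict:
        return {
            c: {"mean_b": self.mean(c), "sd_b": self.sd(c), "n": len(self.b[c])}
            for c in self.conditions
        }


def _window_bounds(duration: float, window: float, fs: float) -> tuple[int, int]:
    """Sample bounds of a centered analysis window."""
    start = (duration - window) / 2.0
    i0 = int(round(start * fs))
    i1 = i0 + int(round(window * fs))
    return i0, i1


def _simulate_levels(
    pool: MotorUnitPool,
    levels,
    duration: float,
    fs: float,
    master_seed: int,
    rep: int,
):
    """Spike trains and total force per level (shared across depth conditions)."""
    trains, forces = [], []
    for k, exc in enumerate(levels):
        tr = generate_spike_trains(
            pool, exc, duration, seed=np.random.default_rng([master_seed, rep, 2, k])
        )
        trains.append(tr)
        forces.append(pool_force(tr, pool, fs, duration))
    return trains, forces


def run_depth_condition_study(config: SimStudyConfig | None = None) -> StudyResult:
    """Run the depth-condition simulation study.

    Per repetition, unit depths are re-drawn for every condition with
    paired random draws (the same jitter realisation, only the
    depth-size slope target differs) and the same spike trains are reused
    across conditions, so the force signal is identical within a
    repetition and condition differences reflect the volume conductor
    only.  Per repetition and condition the log-log slope b of
    (normalized) EMG RMS on force is fitted over the excitation levels;
    across repetitions the conditions are compared with a one-way ANOVA
    and Bonferroni-corrected pairwise t-tests after a normality check.
    """
    if config is None:
        config = SimStudyConfig()
    pool = build_pool(config.pool_params())
    geometry = MuscleGeometry()
    tripole = TripoleSpec()
    electrode = np.array([[0.0, SIM_ELECTRODE_Z]])
    i0, i1 = _window_bounds(config.duration, config.analysis_window, config.fs)
    levels = config.excitation_levels

    b = {c: np.empty(config.repetitions) for c in config.conditions}
    for rep in range(config.repetitions):
        trains, forces = _simulate_levels(
            pool, levels, config.duration, config.fs, config.seed, rep
        )
        mean_force = np.array([f.samples[i0:i1].mean() for f in forces])
        for c in config.conditions:
            placement = place_units(
                pool,
                c,
                geometry,
                jitter_sd=config.jitter_sd,
                seed=np.random.default_rng([config.seed, rep, 1]),
            )
            templates = muap_templates(placement, electrode, tripole, geometry, config.fs)
            amps = np.empty(len(levels))
            for k, tr in enumerate(trains):
                rec = synthesize_emg(
                    tr, templates, config.fs, config.duration, electrode,
                    highpass_hz=config.highpass_hz,
                )
                amps[k] = rms(rec.data[0, i0:i1])
            series = LevelSeries(force=mean_force, amplitude=amps).normalized()
            b[c][rep] = fit_loglog(series).b

    stats: list = []
    if config.repetitions >= 2 and len(config.conditions) >= 2:
        for c in config.conditions:
            try:
                stats.append(
                    {"test": "ks_normality", "condition": c, "p": ks_normality(b[c])}
                )
            except ValueError:
                pass
        groups = [b[c] for c in config.conditions]
        p_overall, pairwise = anova_bonferroni(groups)
        stats.append({"test": "anova", "p": p_overall})
        for (i, j), p in pairwise.items():
            stats.append(
                {
                    "test": "bonferroni_pairwise",
                    "pair": (config.conditions[i], config.conditions[j]),
                    "p": p,
                }
            )
    return StudyResult(conditions=config.conditions, b=b, stats=stats, config=config)


def _rate_based_mean_force(pool: MotorUnitPool, excitation: float) -> float:
    """Noise-free steady-state mean force at an excitation level.

    For a unit firing periodically at rate r (Hz) the mean of the twitch
    superposition is r * g * P * T * e / 1000 (T in ms), with g the
    fusion gain at ISI = 1/r.
    """
    rates = firing_rates(pool, excitation)
    active = rates > 0
    if not np.any(active):
        return 0.0
    r = rates[active]
    t_c = pool.t_contract[active]
    gains = isi_gain(t_c, 1000.0 / r)
    return float(np.sum(r * gains * pool.p[active] * t_c * np.e / 1000.0))


def calibrate_excitation_for_mvc(
    pool: MotorUnitPool,
    target_pcts,
    tol: float = 0.1,
) -> np.ndarray:
    """Excitation levels producing given %MVC forces (bisection, rate-based).

    %MVC is relative to the noise-free mean force at 100% excitation.
    Each returned excitation reproduces its target force fraction within
    ``tol`` percentage points.
    """
    target_pcts = np.asarray(target_pcts, dtype=float)
    if np.any(target_pcts <= 0) or np.any(target_pcts > 100):
        raise ValueError("targets must be in (0, 100]")
    f_max = _rate_based_mean_force(pool, 100.0)
    assert f_max > 0
    out = np.empty(len(target_pcts))
    for i, pct in enumerate(target_pcts):
        if pct == 100.0:
            out[i] = 100.0
            continue
        lo, hi = 0.0, 100.0
        target = pct / 100.0 * f_max
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _rate_based_mean_force(pool, mid) < target:
                lo = mid
            else:
                hi = mid
            if 100.0 * abs(_rate_based_mean_force(pool, mid) / f_max - pct / 100.0) < tol:
                break
        out[i] = 0.5 * (lo + hi)
    return out


@dataclass(frozen=True)
class GridSessionConfig:
    """Configuration of the synthetic high-density grid experiment.

    The two physical 13 x 5 arrays (lateral and medial) are represented
    as one logical 13-row x 10-column grid; rows run along the fiber
    direction (z), proximal rows at negative z.  ``depth_gradient`` is
    the ground-truth tilt (mm of extra depth per mm along +z for the
    largest unit; smaller units tilt proportionally to normalized size),
    so a positive value puts large units shallower proximally.
    """

    rows: int = 13
    cols: int = 10
    pitch: float = 8.0
    fs: float = 2048.0
    mvc_levels: tuple = (20.0, 40.0, 60.0, 80.0)
    duration: float = 3.0
    segment: float = 2.0
    n_subjects: int = 9
    depth_gradient: float = 0.10
    gradient_jitter: float = 0.25
    strategy: str = "onion_skin"
    rte_max_fraction: float = 0.8
    max_fibers_per_unit: int | None = 64
    highpass_hz: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment > self.duration:
            raise ValueError("analysis segment cannot exceed the contraction duration")
        if list(self.mvc_levels) != sorted(set(self.mvc_levels)):
            raise ValueError("mvc_levels must be strictly increasing")
        if len(self.mvc_levels) < 3:
            raise ValueError("need at least 3 contraction levels")

    def pool_params(self) -> PoolParams:
        return PoolParams(strategy=self.strategy, rte_max_fraction=self.rte_max_fraction)

    def electrode_positions(self) -> np.ndarray:
        """(rows*cols, 2) electrode (x, z) positions, row-major, grid centered on z=0."""
        z = (np.arange(self.rows) - (self.rows - 1) / 2.0) * self.pitch
        x = (np.arange(self.cols) - (self.cols - 1) / 2.0) * self.pitch
        zz, xx = np.meshgrid(z, x, indexing="ij")
        return np.column_stack([xx.ravel(), zz.ravel()])


@dataclass
class GridSession:
    """One synthetic subject's grid recordings across contraction levels."""

    subject: int
    config: GridSessionConfig
    excitations: np.ndarray  # per level
    emg: dict  # %MVC level -> EMGRecording
    force: dict  # %MVC level -> ForceTrace
    ground_truth: dict


@dataclass
class GridStudyResult:
    """Per-subject regional slopes and the across-subject statistics."""

    per_subject: "object"  # pandas DataFrame: subject, whole, proximal, distal, lateral, medial
    stats: list


def generate_grid_session(
    config: GridSessionConfig | None = None,
    subject: int = 0,
) -> GridSession:
    """Synthesize one subject's high-density grid session.

    The subject's pool placement uses the random depth condition as the
    baseline; the configured proximal-distal depth gradient (jittered
    per subject) tilts each unit's apparent depth along z in proportion
    to its normalized size.  Excitation levels are calibrated so the
    simulated mean forces hit the configured %MVC targets.
    """
    if config is None:
        config = GridSessionConfig()
    pool = build_pool(config.pool_params())
    geometry = MuscleGeometry()
    tripole = TripoleSpec()

    rng = np.random.default_rng([config.seed, subject, 0])
    gradient = config.depth_gradient
    if gradient != 0.0:
        gradient *= max(0.0, 1.0 + config.gradient_jitter * rng.standard_normal())
    s = (pool.p - pool.p.min()) / (pool.p.max() - pool.p.min())
    tilt = gradient * s

    placement = place_units(
        pool,
        "random",
        geometry,
        depth_tilt=tilt,
        seed=np.random.default_rng([config.seed, subject, 1]),
    )
    electrodes = config.electrode_positions()
    templates = muap_templates(
        placement,
        electrodes,
        tripole,
        geometry,
        config.fs,
        max_fibers_per_unit=config.max_fibers_per_unit,
        seed=np.random.default_rng([config.seed, subject, 2]),
    )
    excitations = calibrate_excitation_for_mvc(pool, config.mvc_levels)

    emg, force = {}, {}
    for k, (pct, exc) in enumerate(zip(config.mvc_levels, excitations)):
        tr = generate_spike_trains(
            pool, exc, config.duration, seed=np.random.default_rng([config.seed, subject, 3, k])
        )
        force[pct] = pool_force(tr, pool, config.fs, config.duration)
        emg[pct] = synthesize_emg(
            tr,
            templates,
            config.fs,
            config.duration,
            electrodes,
            grid_shape=(config.rows, config.cols),
            pitch=config.pitch,
            highpass_hz=config.highpass_hz,
        )
    return GridSession(
        subject=subject,
        config=config,
        excitations=excitations,
        emg=emg,
        force=force,
        ground_truth={"depth_gradient": gradient, "tilt": tilt, "seed": config.seed},
    )


def generate_cohort(config: GridSessionConfig | None = None) -> list:
    """Generate all subjects of a synthetic cohort."""
    if config is None:
        config = GridSessionConfig()
    return [generate_grid_session(config, s) for s in range(config.n_subjects)]


def session_level_series(session: GridSession) -> LevelSeries:
    """Per-channel RMS and mean force over the centered analysis segment, normalized."""
    cfg = session.config
    i0, i1 = _window_bounds(cfg.duration, cfg.segment, cfg.fs)
    levels = list(cfg.mvc_levels)
    amp = np.empty((len(levels), cfg.rows * cfg.cols))
    frc = np.empty(len(levels))
    for k, pct in enumerate(levels):
        seg = session.emg[pct].data[:, i0:i1]
        amp[k] = np.sqrt(np.mean(seg**2, axis=1))
        frc[k] = session.force[pct].samples[i0:i1].mean()
    return LevelSeries(force=frc, amplitude=amp, labels=np.asarray(levels)).normalized()


def analyze_grid_session(
    sessions: list,
    regions: RegionSpec | None = None,
) -> GridStudyResult:
    """Regional slope analysis across a cohort of grid sessions.

    Per subject: a per-channel slope map, its regional means (proximal,
    distal, lateral, medial) and the whole-array b (fitted on the
    channel-averaged RMS).  Across subjects: Wilcoxon signed-rank tests
    of proximal vs distal and lateral vs medial b with effect sizes
    r = |Z| / sqrt(n).
    """
    import pandas as pd

    if regions is None:
        regions = RegionSpec()
    if len(sessions) < 5:
        raise ValueError("need at least 5 subjects for the signed-rank test")
    rows = []
    for sess in sessions:
        series = session_level_series(sess)
        shape = (sess.config.rows, sess.config.cols)
        smap = slope_map(series, shape)
        mean_series = LevelSeries(
            force=series.force, amplitude=series.amplitude.mean(axis=1)
        )
        rows.append(
            {
                "subject": sess.subject,
                "whole": fit_loglog(mean_series).b,
                **{
                    reg: region_mean(smap, regions, reg)
                    for reg in ("proximal", "distal", "lateral", "medial")
                },
            }
        )
    df = pd.DataFrame(rows)
    stats = []
    for name, a_col, b_col in (
        ("proximal_vs_distal", "proximal", "distal"),
        ("lateral_vs_medial", "lateral", "medial"),
    ):
        z, p, r = wilcoxon_signed_rank(df[a_col].to_numpy(), df[b_col].to_numpy())
        stats.append(
            {
                "test": "wilcoxon_signed_rank",
                "comparison": name,
                "z": z,
                "p": p,
                "effect_size_r": r,
                "n": len(df),
                "mean_a": float(df[a_col].mean()),
                "mean_b": float(df[b_col].mean()),
            }
        )
    return GridStudyResult(per_subject=df, stats=stats)
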