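"""Log-transformed EMG-force relation: slope fitting, maps, regional statistics.

Across contraction levels, EMG RMS amplitude Y and force X follow an
approximate power law Y = a X^b, linearised by the natural log transform
ln Y = b ln X + ln a.  The slope b distinguishes linear (b = 1),
faster-than-linear (b > 1) and slower-than-linear (b < 1) EMG growth with
force, and is invariant to rescaling of either axis (only the intercept
moves), so normalizing X and Y to their maximum-level values changes
nothing about b.

For high-density grids, b is fitted per channel into a slope map, and
named electrode regions (proximal/distal rows, lateral/medial columns)
are compared with the Wilcoxon signed-rank test; depth-condition effects
on b are compared with a one-way ANOVA and Bonferroni-corrected pairwise
tests after a Kolmogorov-Smirnov (Lilliefors) normality check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "LevelSeries",
    "SlopeFit",
    "SlopeMap",
    "RegionSpec",
    "rms",
    "fit_loglog",
    "slope_map",
    "region_mean",
    "wilcoxon_signed_rank",
    "effect_size_r",
    "anova_bonferroni",
    "ks_normality",
]


@dataclass
class LevelSeries:
    """Force and per-channel RMS amplitude across contraction levels.

    ``force`` is (n_levels,); ``amplitude`` is (n_levels, n_channels) (a
    1-D array is treated as a single channel).  ``labels`` names the
    levels (% excitation or % MVC).
    """

    force: np.ndarray
    amplitude: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim == 1:
            self.amplitude = self.amplitude[:, None]
        if len(self.force) != self.amplitude.shape[0]:
            raise ValueError("force and amplitude must have one entry per level")
        if len(self.force) < 3:
            raise ValueError("need at least 3 levels for the log-log regression")
        if np.any(self.force <= 0):
            raise ValueError("forces must be positive (log-transform)")

    @property
    def n_channels(self) -> int:
        return self.amplitude.shape[1]

    def normalized(self) -> "LevelSeries":
        """Both axes divided by their value at the maximum-force level."""
        imax = int(np.argmax(self.force))
        return LevelSeries(
            force=self.force / self.force[imax],
            amplitude=self.amplitude / self.amplitude[imax],
            labels=self.labels,
        )


@dataclass
class SlopeFit:
    """OLS fit of ln Y = b ln X + ln a."""

    b: float
    ln_a: float
    r_squared: float


@dataclass
class SlopeMap:
    """Per-channel slopes arranged on the electrode grid; NaN marks missing channels."""

    values: np.ndarray  # (rows, cols)

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass(frozen=True)
class RegionSpec:
    """Named 1-based row/column index sets of the electrode grid.

    Defaults follow the biceps protocol on a 13-row logical grid made of
    two side-by-side 5-column arrays (lateral array: columns 1-5, medial
    array: columns 6-10): proximal = rows 3-4, distal = rows 10-11,
    lateral = columns 1-2, medial = the two outermost medial columns.
    """

    proximal_rows: tuple = (3, 4)
    distal_rows: tuple = (10, 11)
    lateral_cols: tuple = (1, 2)
    medial_cols: tuple = (9, 10)

    def region_indices(self, region: str, shape: tuple) -> tuple[np.ndarray, np.ndarray]:
        """(row_idx, col_idx) 0-based index arrays selecting a named region."""
        rows, cols = shape
        if region == "proximal":
            r, c = self.proximal_rows, tuple(range(1, cols + 1))
        elif region == "distal":
            r, c = self.distal_rows, tuple(range(1, cols + 1))
        elif region == "lateral":
            r, c = tuple(range(1, rows + 1)), self.lateral_cols
        elif region == "medial":
            r, c = tuple(range(1, rows + 1)), self.medial_cols
        else:
            raise ValueError(f"unknown region {region!r}")
        r = np.asarray(r, dtype=int) - 1
        c = np.asarray(c, dtype=int) - 1
        if np.any(r < 0) or np.any(r >= rows) or np.any(c < 0) or np.any(c >= cols):
            raise IndexError(f"region {region!r} indices exceed grid shape {shape}")
        return r, c


def rms(segment) -> float:
    """Root-mean-square amplitude of a signal segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.sqrt(np.mean(segment**2)))


def fit_loglog(series: LevelSeries, channel: int = 0) -> SlopeFit:
    """Fit the log-transformed EMG-force relation for one channel by OLS."""
    y = series.amplitude[:, channel]
    x = series.force
    if np.any(y <= 0):
        raise ValueError("amplitudes must be positive (log-transform)")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise ValueError("degenerate regression: all forces equal")
    res = sps.linregress(lx, ly)
    return SlopeFit(b=float(res.slope), ln_a=float(res.intercept), r_squared=float(res.rvalue**2))


def slope_map(
    series: LevelSeries,
    grid_shape: tuple,
    channel_to_cell: np.ndarray | None = None,
) -> SlopeMap:
    """Per-channel log-log slopes arranged on the electrode grid.

    ``channel_to_cell`` maps channel index to (row, col), 0-based; by
    default channels fill the grid row-major.  Channels whose fit fails
    (non-positive amplitudes) are marked NaN rather than raising.
    """
    rows, cols = grid_shape
    values = np.full((rows, cols), np.nan)
    if channel_to_cell is None:
        if series.n_channels != rows * cols:
            raise ValueError("channel count does not match grid shape")
        channel_to_cell = np.column_stack(
            [np.repeat(np.arange(rows), cols), np.tile(np.arange(cols), rows)]
        )
    for ch in range(series.n_channels):
        r, c = channel_to_cell[ch]
        try:
            values[r, c] = fit_loglog(series, ch).b
        except ValueError:
            pass  # leave missing
    return SlopeMap(values=values)


def region_mean(smap: SlopeMap, regions: RegionSpec, region: str) -> float:
    """Mean slope over the non-missing channels of a named region."""
    r, c = regions.region_indices(region, smap.shape)
    block = smap.values[np.ix_(r, c)]
    if np.all(np.isnan(block)):
        raise ValueError(f"region {region!r} has no valid channels")
    return float(np.nanmean(block))


def wilcoxon_signed_rank(
    paired_a,
    paired_b,
    method: str = "auto",
) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test for paired samples: (Z, p, effect size r).

    Zero differences are dropped; ranks of tied |differences| are
    averaged.  The normal approximation uses the tie-corrected variance
    and a 0.5 continuity correction; the effect size is r = |Z| / sqrt(n)
    with n the number of pairs supplied.  ``method="exact"`` (or "auto"
    with <= 12 non-zero differences and no ties) computes the two-sided p
    by exhaustive sign-flip enumeration instead; Z is always reported
    from the normal approximation.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n_pairs = len(a)
    if n_pairs < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    m = len(d)
    if m == 0:
        raise ValueError("all paired differences are zero; test degenerate")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var_w = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    if var_w <= 0:
        raise ValueError("zero variance; test degenerate")
    dev = w_plus - mean_w
    correction = 0.5 * np.sign(dev)
    z = (dev - correction) / np.sqrt(var_w) if dev != 0 else 0.0

    has_ties = np.any(tie_counts > 1)
    if method == "exact" or (method == "auto" and m <= 12 and not has_ties):
        p = _exact_signflip_p(ranks, w_plus)
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    r_effect = abs(z) / np.sqrt(n_pairs)
    return float(z), float(min(p, 1.0)), float(r_effect)


def effect_size_r(z: float, n: int) -> float:
    """Effect size of a signed-rank test: r = |Z| / sqrt(n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return abs(z) / np.sqrt(n)


def _exact_signflip_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p over all 2^m assignments of signs to the ranks."""
    m = len(ranks)
    total = m * (m + 1) / 2.0
    # distribution of W+ by dynamic programming over integer rank sums
    scaled = np.rint(ranks * 2).astype(int)  # halves are integers after averaging ties
    max_sum = int(scaled.sum())
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for s in scaled:
        counts[s:] = counts[s:] + counts[:-s] if s else counts[s:] * 2
    counts /= counts.sum()
    w_scaled = int(round(w_obs * 2))
    lo = counts[: w_scaled + 1].sum()
    hi = counts[w_scaled:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def anova_bonferroni(groups: list) -> tuple[float, dict]:
    """One-way ANOVA across groups plus Bonferroni-corrected pairwise t-tests.

    Returns (overall p, {(i, j): adjusted p}); adjusted p values are the
    raw two-sample t-test p multiplied by the number of pairwise
    comparisons, capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    if all(np.var(g) == 0 for g in groups):
        if len({g[0] for g in groups}) == 1:
            # identical constant groups: no effect by definition
            return 1.0, {pair: 1.0 for pair in combinations(range(len(groups)), 2)}
        raise ValueError("zero within-group variance in all groups")
    _, p_overall = sps.f_oneway(*groups)
    pairs = list(combinations(range(len(groups)), 2))
    k = len(pairs)
    pairwise = {}
    for i, j in pairs:
        _, p = sps.ttest_ind(groups[i], groups[j])
        pairwise[(i, j)] = float(min(1.0, p * k))
    return float(p_overall), pairwise


def ks_normality(sample) -> float:
    """Kolmogorov-Smirnov normality p-value with estimated parameters.

    Mean and SD are estimated from the sample, so the Lilliefors-corrected
    p-value is reported rather than the plain KS p.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(sample) == 0:
        raise ValueError("constant sample")
    from statsmodels.stats.diagnostic import lilliefors

    _, p = lilliefors(sample, dist="norm")
    return float(p)
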