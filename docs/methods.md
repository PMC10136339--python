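# Methods

This note documents the models implemented in `emgforce`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic data do and do not emulate.

## Motor neuron pool

The pool is the classic size-ordered population model.  For `n = 150`
units indexed in recruitment order:

* **Recruitment threshold excitation (RTE)**, % of maximal drive:
  `rte_i = f · 100 · exp(i ln R / n) / R` with range ratio `R = 100` and
  `f` the fraction of maximal drive at which the last unit is recruited
  (0.4 by default, mimicking small muscles where rate coding dominates;
  0.8 available for large muscles).  The exponential form concentrates
  thresholds at low drive, so most units are recruited early.  `R` is a
  convention (it is not independently constrained); it is matched to the
  100-fold twitch range so threshold and size grow together.
* **Fibers per unit**: geometric interpolation from 22 to 2137, rounded;
  the closed-form series sum is ≈69,950 ≈ 70,000 fibers.
* **Twitch parameters**: peak forces `P_i` geometric from 1 to 100 au;
  contraction times `T_i = 90·(1/P_i)^(ln3/ln100)` ms, a power law chosen
  so a 100-fold `P` range coincides exactly with a 3-fold `T` range
  (90 ms → 30 ms).
* **Rate coding**: below threshold a unit is silent; at threshold it
  fires at the minimum rate (8 Hz); above threshold its rate rises
  linearly and saturates at the unit's peak firing rate (PFR).  PFRs are
  linear across the pool between 25 and 35 Hz; under *reverse onion
  skin* the largest unit holds the 35 Hz end, under *onion skin* the
  smallest does.  The default excitation→rate gain is per unit, chosen
  so every unit attains its PFR exactly at 100% drive.  Rationale: the
  onion-skin/reverse-onion-skin organisations are statements about the
  rates actually reached at high drive; with a single common gain the
  late-recruited units would plateau near 18 Hz and the nominal 35 Hz
  PFR of the largest unit would never be expressed.  A scalar gain can
  be supplied to recover the common-gain convention.
* **Discharge timing**: a Gaussian renewal process; ISIs have mean
  `1/rate` and SD `cv/rate` with `cv = 0.2` by default (a typical value
  for voluntary contractions; the CV is exposed in `PoolParams`).
  Non-positive draws are rejected and redrawn, which preserves the mean
  to first order (at `cv = 0.2` the truncated mass is ~3·10⁻⁷).  The
  first discharge is uniform in one mean ISI to decorrelate units.

## Twitch force and fusion

Each discharge contributes `f(t) = g · P · (t/T) · e^(1−t/T)`, the
impulse response of a critically damped second-order system, peaking at
`P` at `t = T`.  The fusion gain depends on the normalized rate
`u = T/ISI` of the preceding interval:

```
g(u) = 1                      u ≤ 0.4
g(u) = S(u) / S(0.4),         u > 0.4,      S(u) = (1 − e^(−2u³)) / u
```

Normalizing by `S(0.4)` makes the gain continuous at the knee.  `g`
rises above 1 as twitches fuse, peaks near `u ≈ 1`, and decays as `1/u`
at high rates, so a unit's tetanic force saturates rather than growing
linearly with rate.  The first discharge of a train has gain 1 (there is
no preceding interval).  Kernels are truncated at `8T`, where the
amplitude is below 1% of peak (at `5T` it would still be 9%); whole-
muscle force is the linear sum of unit traces.

## Volume conductor and surface EMG

Coordinates: skin surface is the plane `y = 0`; depth increases into the
tissue; fibers run along `z`.  The muscle is a 24 mm cylinder under a
3 mm fat+skin stand-off; conductivities are σz = 0.33 and σx = 0.06 S/m
(anisotropy `Ka = 5.5`).

A fiber's action potential is modelled as two mirrored triplets of
balanced point sources (amplitudes `(1, −2.6, 1.6)`, spacing 2 mm —
conventions, exposed in `TripoleSpec`) that emerge at the innervation
zone, travel at 4 m/s toward the fiber ends (±60 mm) and collapse there,
extinguishing the potential at the tendons.  The potential at a surface
electrode is

```
φ = (1 / 2πσx) Σ_i P_i / (Ka((x−x_i)² + y_i²) + (z−z_i)²)
```

Each pole's contribution falls off with the *square* of the
anisotropically scaled distance.  This quadratic decay is steeper than a
homogeneous-medium point source and acts as an effective detection
volume: sources deeper than ~10–15 mm contribute little, which is what
makes the log-log slope `b` strongly sensitive to whether the large
units sit inside or outside that volume.  With first-power decay the
three depth conditions remain ordered but the spread of `b` shrinks by
roughly half and the characteristic asymmetry (deep ≈ random,
superficial strongly elevated) disappears.

MUAPs are sums of fiber potentials, cached per (unit, electrode); fibers
are uniform over a disc territory sized from the fiber count at
20 fibers/mm², intersected with the muscle cross-section.  EMG is the
frequency-domain convolution of each unit's spike train with its MUAP
template, summed over units.

**No filtering precedes RMS by default.**  The monopolar synthesis
carries a force-proportional baseline (the DC line of the MUAP-train
spectrum), and the RMS of the raw signal includes it.  An optional
zero-phase Butterworth high-pass (`highpass_hz`) emulates the AC
coupling of a physical amplifier; enabling it removes the baseline and
lowers `b` by ≈0.2–0.3 in every depth condition — a sensitivity users
comparing against hardware recordings should be aware of.

## Depth conditions

Unit territory depths are drawn as
`d_i = d_mid + k(P_i − mean(P)) + ε_i`, `ε ~ N(0, 2.5 mm)`, reflected
into the muscle.  The tilt `k` (mm of depth per au of twitch force) is
−0.13 for *superficial* (large units shallow), 0 for *random* (depth
independent of size) and +0.12 for *deep*; with the default jitter the
fitted regression slope of depth on twitch force reproduces those values
(mean fitted slopes −0.129 / −0.000 / +0.119 over 30 draws).  Across the
1–100 au twitch range the tilt moves the largest units by roughly half
the muscle diameter.  The x-centers are uniform across the chord of the
cross-section at the drawn depth.

## The simulation study

Per repetition: one deterministic pool; per condition, fresh placements
drawn with *paired* jitter (the same random draws, only `k` differs);
excitation stepped 10–100% in 10% steps; 3 s of activity per level at
2000 Hz with a centered 2 s analysis window (the simulated duration is a
package choice; the window matches the experimental convention).  Spike
trains are shared across conditions within a repetition, so the force
signal is identical across conditions and all condition differences are
volume-conductor effects.  Force and RMS are normalized to the
maximum-level values before fitting (the slope is provably invariant to
this; it only aids comparability of intercepts).  Across repetitions the
conditions are compared by one-way ANOVA with Bonferroni-corrected
pairwise t-tests (×3), after a Lilliefors-corrected normality check —
the correction is used because mean and SD are estimated from the same
sample.  Per-repetition slopes enter the ANOVA (not their means).

Defaults follow the headline protocol: reverse onion skin, 40%
recruitment range.  At 10 repetitions (the scaled default of
`scripts/acceptance.py`; the full protocol uses 50) the study runs in
~15 s on one CPU and yields mean slopes of ≈1.23 (superficial), ≈0.90
(random) and ≈0.73 (deep) with between-seed variation below 0.01.

## Synthetic grid experiment

The generator emulates a two-array high-density recording of an elbow
flexor: two 13×5 grids at 8 mm pitch represented as one logical 13×10
grid (lateral array = columns 1–5, medial = 6–10), columns parallel to
the fibers, the grid centered over the innervation zone, monopolar
signals at 2048 Hz, contractions at 20/40/60/80% MVC with 2 s analysis
segments.  Excitation levels are calibrated by bisection on the
noise-free rate-based mean force so the simulated forces hit the %MVC
targets (closed-loop error < 1%).  Defaults use onion-skin firing and an
80% recruitment range, the regime typical of large limb muscles.

Ground truth for recovery tests is a proximal–distal depth gradient:
each unit's apparent depth grows along +z by `gradient · s_i` mm/mm
(`s_i` = normalized size), i.e. large units lie shallower proximally, as
if fast-twitch fibers ran at an angle to the skin.  The default gradient
of 0.10 was set so the cohort-mean proximal-minus-distal difference in
`b` is ≈0.1 — the order of magnitude reported for real biceps
recordings — and is jittered ±25% across subjects.  Regional analysis
averages `b` over proximal rows 3–4, distal rows 10–11, lateral columns
1–2 and medial columns 9–10 (the two outermost medial columns; region
indices are configuration).  Proximal–distal and lateral–medial
contrasts use the Wilcoxon signed-rank test with `r = |Z|/√n`.

What the generator does **not** emulate: measurement noise and line
interference, electrode-skin impedance variation, innervation-zone
scatter across fibers, fiber curvature and anatomical asymmetry,
force-signal drift, and between-subject anatomical variability beyond
placement seeds and gradient jitter.  Passing recovery tests therefore
shows the *analysis* recovers the generator's spatial structure, not
that real recordings would be as clean; in particular the lateral–medial
null holds by construction of the symmetric geometry.

## Statistics

The Wilcoxon signed-rank statistic is computed directly: zero
differences dropped, tied |differences| mid-ranked, normal approximation
with tie-corrected variance and a 0.5 continuity correction; an exact
mode enumerates the sign-flip distribution by dynamic programming and is
used automatically for ≤12 untied non-zero differences.  The effect size
divides |Z| by √(number of pairs supplied).  ANOVA, t-tests and the
normality test are delegated to scipy/statsmodels; pairwise p-values are
Bonferroni-multiplied by the number of comparisons and capped at 1.
Significance is 0.05 throughout.

## Numerical conventions and degenerate inputs

* Spike times are rounded to the nearest sample for convolution; spikes
  beyond the recording are dropped with a warning.
* Twitch kernels truncated at `8T` (<1% of peak); MUAP waveforms end
  when the trailing pole reaches the fiber end (~16 ms at defaults).
* Log–log fits require ≥3 levels, strictly positive force and
  amplitude, and non-degenerate force; per-channel fit failures mark the
  slope-map cell missing (NaN) instead of aborting the session.
* The signed-rank test requires ≥5 pairs and at least one non-zero
  difference; the ANOVA rejects all-constant groups unless the groups
  are identical (then F = 0, p = 1 by definition).
* All randomness flows from integer seed lists passed to NumPy
  generators; identical master seeds give bit-identical results,
  including across the CLI.

## Problem sizes

The defaults were sized for interactive desk-scale use: the
three-condition study at 10 repetitions ≈15 s; one 9-subject grid cohort
at full settings ≈80 s, or ≈17 s at the reduced settings used in the
recovery tests (1 s segments at 1024 Hz with 32-fiber MUAP
subsampling — amplitudes are rescaled by the true fiber count, and the
fitted slopes are insensitive to the subsampling because `b` is
scale-invariant).

## Known limitations

* The volume conductor is a homogeneous anisotropic half-space with the
  fat/skin layer as a pure stand-off; no layered Green's functions, no
  cylindrical boundary conditions, point electrodes only.
* The quadratic source decay is the model's empirically motivated
  detection-volume form, not a first-principles solution of the
  anisotropic Poisson equation (which would give first-power decay for a
  point source).
* No motor-unit synchronisation, fatigue, or force-length/velocity
  effects; force is isometric twitch summation only.
* The grid generator's two arrays share one planar skin; curvature of a
  real arm (which separates lateral and medial arrays physically) is not
  modelled.
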