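# emgforce

Motor-unit pool simulation of surface EMG and isometric force, with an
analysis pipeline for the **log-transformed EMG–force relation** and its
sensitivity to where small and large motor units sit in the muscle.

## The problem

Surface EMG amplitude grows with contraction force, but not always
linearly.  Writing the relation as a power law

```
Y = a X^b        ⇔        ln Y = b ln X + ln a
```

with `X` the force and `Y` the EMG root-mean-square (RMS) amplitude, the
slope `b` of the log–log regression summarises the shape of the relation:
`b = 1` means EMG grows linearly with force, `b > 1` faster than force,
`b < 1` slower.  Because the volume conductor (muscle, fat, skin)
attenuates deep sources far more than superficial ones, `b` is sensitive
to the *spatial distribution of motor units by depth*: if the large,
high-threshold units lie superficially, their late recruitment inflates
EMG growth at high forces and raises `b`.

`emgforce` implements this study end to end for researchers in
neuromuscular physiology and EMG modelling:

* **Pool model** — 150 motor units with exponentially distributed
  recruitment thresholds and fiber counts (22–2137 fibers, ~70,000
  total), twitch forces of 1–100 au with contraction times of 90–30 ms,
  recruitment up to 40% or 80% of maximal drive, linear rate coding from
  8 Hz to per-unit peak rates of 25–35 Hz under "onion-skin" or
  "reverse onion-skin" organisations, and Gaussian inter-spike-interval
  variability.
* **Force model** — per-discharge twitches `g·P·(t/T)·e^(1−t/T)` with the
  nonlinear fusion gain `g(T/ISI)` and linear summation across units.
* **Volume conductor** — a cylindrical muscle (24 mm diameter, 3 mm
  fat+skin stand-off, conductivity anisotropy `Ka = σz/σx = 5.5`) with
  motor-unit territories placed under three depth conditions
  (*superficial*, *random*, *deep*, parameterised by the regression slope
  of unit depth on twitch force), fiber action potentials as travelling
  balanced source triplets, and surface EMG as the convolution of unit
  spike trains with motor-unit action potential (MUAP) templates.
* **Slope analysis** — RMS amplitudes, per-channel log–log fits, slope
  maps over high-density electrode grids, regional means, and the
  study's statistics (one-way ANOVA with Bonferroni-corrected post-hocs,
  Lilliefors normality check, Wilcoxon signed-rank with effect size
  `r = |Z|/√n`).
* **Synthetic experiment** — an end-to-end three-condition simulation
  study, plus a generator/analyser for synthetic high-density grid
  sessions (two 13×5 arrays at 8 mm pitch, monopolar 2048 Hz, 20–80%
  MVC) with a configurable proximal–distal depth gradient as ground
  truth for parameter-recovery checks.

## Worked example

```python
from emgforce import SimStudyConfig, run_depth_condition_study

result = run_depth_condition_study(SimStudyConfig(repetitions=10, seed=1))
for cond in result.conditions:
    print(f"{cond:12s} b = {result.mean(cond):.3f} ± {result.sd(cond):.3f}")
```

prints

```
superficial  b = 1.230 ± 0.028
random       b = 0.898 ± 0.013
deep         b = 0.730 ± 0.007
```

Each repetition draws new unit placements and spike trains, simulates EMG
and force at ten excitation levels (10–100%), and fits `b` on the
normalized log–log relation.  Placing the large units superficially
raises `b` well above the random-depth condition, and burying them
lowers it — EMG growth with force steepens when the units recruited last
are also the units the electrode sees best.  The accompanying ANOVA
(`result.stats`) confirms the condition effect with Bonferroni-corrected
pairwise comparisons.

The same pipeline is available from the shell:

```bash
emgforce simulate-study --reps 10 --seed 1 --out study/
emgforce generate-session --subjects 9 --seed 1 --out session/
emgforce analyze-session --session session/ --out analysis/
```

`analyze-session` reports, per cohort, the proximal-vs-distal and
lateral-vs-medial comparisons of `b` (Z, p, effect size); the seed-1
cohort generated with the default proximal–distal depth gradient prints

```
proximal_vs_distal: Z = 2.61, p = 0.0039, r = 0.87
lateral_vs_medial: Z = 0.36, p = 0.7344, r = 0.12
```

— the imposed depth gradient is detected along the fiber direction while
the symmetric lateral–medial contrast stays non-significant.

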