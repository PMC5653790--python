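# ringclock

Circadian ring-pattern analysis for fungal colony photographs.

Some fungi deposit one concentric ring of dense growth per circadian
cycle while the colony front advances at constant radial speed, so a
single end-point photograph records the clock's whole history: radial
position maps linearly to time, and ring spacing encodes period.
`ringclock` is for chronobiologists and image analysts who want to
quantify such plates reproducibly — from raw photograph to
free-running period (FRP), double-plotted actograms with jet-lag
phase-shift estimates, and temperature-compensation (Q10) summaries —
plus a synthetic colony generator with known ground truth so the whole
chain is testable without any plate data.

## The analysis in brief

1. **Profile extraction** — a radial rectangle is sampled from the
   photograph, smoothed with a Gaussian blur (σ = 3 px), corrected
   with a pseudo flat-field filter (divide by a heavily blurred copy),
   and each radial row of pixels is averaged into one intensity value.
2. **Calibration** — pixels convert to hours by the first/last-ring
   rule: `px_per_h = Δposition / Δtime` between two anchor events.
3. **Period** — the profile is detrended by subtracting its best
   quadratic fit; the periodogram is the magnitude-squared DFT of the
   residual (zero-padded 8×) and the in-band (16–36 h) peak, refined
   by parabolic interpolation, gives the period. Rhythmicity is called
   from the peak-to-median in-band power ratio.
4. **Entrainment** — actogram rows of 48 h (double-plotted) visualize
   phase; the shift across a schedule change is the circular phase
   difference of cosine fits before and after the transient.
5. **Temperature compensation** — with rate = 1/period,
   `Q10 = (P_low / P_high)^(10/ΔT)`, computed on group means, plus a
   one-way ANOVA across temperatures.

The synthetic generator drives a phase-model clock (entrained at
1/24 cycles·h⁻¹, free-running at 1/P, exponential re-entrainment after
schedule shifts), deposits one ring per cycle, and renders radially
symmetric band images with illumination gradients and camera noise —
returning exact ring times/radii and the true period for recovery
tests. See `docs/methods.md` for the model and its assumptions.

## Worked example

Regenerate a study-style analysis entirely from synthetic plates —
three temperatures × three plates through the full image pipeline,
plus a jet-lag run:

```sh
ringclock demo --seed 1 --out demo_out
```

```
 temperature_C  plate_id  period_h  true_period_h   snr  rhythmic
         10.00         0     27.52          27.25 57.05      True
         10.00         1     27.49          27.23 53.32      True
         10.00         2     25.32          25.11 30.49      True
         14.00         0     25.18          24.98 29.67      True
         14.00         1     23.82          23.70 32.49      True
         14.00         2     25.06          24.87 33.10      True
         20.00         0     25.07          24.88 32.39      True
         20.00         1     25.44          25.21 35.55      True
         20.00         2     23.68          23.54 29.56      True
Q10(10-20 C) = 1.1; ANOVA p = 0.071; jet-lag delta = +7.77 h
```

Each row is one simulated plate: `true_period_h` is the plate's
ground-truth FRP (drawn around the temperature mean with 1.3 h
replicate scatter), `period_h` the value the image pipeline recovered
(within ~0.2 h throughout), and `snr` the periodogram peak over the
median in-band power (≥ 12 ⇒ rhythmic). The group means give a
rate-based Q10(10–20 °C) of 1.1 — temperature compensation — and the
ANOVA finds no significant period difference across temperatures. The
jet-lag delta is the recovered phase shift after an 8 h delay of the
light cycle (delays positive; the readout sits slightly under 8 h
because the clock is still completing its exponential re-entrainment
when the post-shift window opens).

Other entry points: `ringclock simulate` (scenario → PNG + truth JSON
+ profile CSV), `ringclock analyze` (image or profile CSV → rings CSV,
periodogram CSV, estimate JSON), `ringclock actogram`,
`ringclock compensation` (periods CSV → Q10/ANOVA report). Bundled
scenarios: `ld_20C`, `ld_dd_20C`, `dd_10C`, `dd_14C`, `dd_20C`,
`jetlag_8h`. Everything is also available as a library:

```python
import ringclock as rc

estimate, truth = rc.recover_period(rc.get_scenario("dd_20C"), seed=1)
print(estimate.period, truth.true_period_dd)   # 24.62  24.5
```

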