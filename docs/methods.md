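# Methods

## The measurement problem

Some fungi lay down one concentric ring of dense, pigmented growth per
circadian cycle as the colony expands radially at constant speed. The
colony is therefore its own chart recorder: radial position is a linear
proxy for time, and the spacing of the rings encodes the period of the
underlying oscillator. `ringclock` turns a grayscale photograph of such
a colony into a free-running period (FRP), an entrainment/phase-shift
readout, and a temperature-compensation (Q10) summary.

Because no photographed plates ship with the package, a synthetic
colony generator with fully known ground truth stands in for them, and
every downstream stage is validated by parameter recovery against that
truth.

## Clock and colony model (the generator)

The oscillator is a phase model. Phase φ is measured in cycles and
advances at 1/C per hour while entrained to a light cycle of length C
(24 h, 12:12 LD by default) and at 1/P per hour after transfer to
constant darkness (DD), where P is the free-running period. A schedule
shift of d hours (the jet-lag protocol) moves the entrained target
phase by d while the realized phase stays continuous and relaxes toward
the new target as `(d/C)·exp(−Δt/τ)`. The exponential form is a
modeling choice — the underlying biology only shows a transiently
longer period over a few days before the pattern stabilizes — and τ
(default 36 h) is an exposed parameter. With τ = 0 the post-shift
trajectory is exactly the pre-shift one translated by d.

A ring is deposited each time φ passes a fixed cycle fraction, by
default the fraction corresponding to dark onset (`entrained_phase`
shifts this in hours; the true deposition phase of real colonies is
unknown, so it is a parameter rather than an assumption). Ring radius
follows from a constant radial growth rate v (default 3 px/h) and a
start radius (24 px) marking the inner edge of the banded zone:
`r_k = r0 + v·t_k`. In DD, consecutive ring radii therefore differ by
exactly v·P — the spacing law the recovery tests lean on.

The band intensity profile is a raised cosine peaking at each ring
time, raised to a sharpness exponent (default 2; the real band shape is
not documented, so this too is a parameter), with a polarity flag
because whether rings photograph brighter or darker than inter-ring
zones depends on optics. Between rings the local phase used by the band
function is interpolated through the ring times, so the band stays
periodic in the locally correct period through LD→DD transitions and
jet-lag transients.

An image is the radial band law swept around the seed center,
multiplied by a smooth illumination field (default: planar gradient of
10% across the frame; vignette available), plus i.i.d. Gaussian camera
noise (default SD 2% of the 8-bit range) and quantization. All
randomness flows from one integer seed per call; identical
configuration and seed give bit-identical output.

What the generator does not emulate: colony texture and hyphal
irregularity, ring-to-ring amplitude variation, non-circular colonies,
growth-rate drift, condensation/reflection artifacts, and plate-edge
effects. Passing recovery tests therefore demonstrate the correctness
of the analysis chain under the stated model, not robustness to every
failure mode of real plate photography.

## Image pipeline

A user-supplied rotated rectangle, long axis radial, is sampled with
bilinear interpolation. The chain is then: Gaussian blur (σ = 3 px,
reflective boundaries) to suppress pixel noise; pseudo flat-field
correction — divide by a heavily blurred copy of the patch and rescale
by the blurred patch's mean, the common flat-field idiom (the exact
historical variant is not documented anywhere, so the formula here is
declared, not inferred); then each radial row of pixels is averaged
into one profile value. The background blur defaults to a quarter of
the ROI length; a warning can be requested when it is under 5× the
expected ring spacing. Near the record ends a reflective heavy blur
bends the background estimate slightly, which costs ~0.3% profile
fidelity — irrelevant for period estimation (the DFT peak is unmoved)
but visible in the strictest profile-correlation checks, which
therefore use a half-length background blur.

RGB images are converted with Rec. 601 luminance weights. Coordinates
are 0-based pixel centers; the radial axis increases away from the
seed, with the seed end declared by the user.

## Period estimation

Pixels convert to hours by the first/last-ring rule: the distance in
pixels between two anchor events divided by the hours between them
(`px_per_h`). The generator's truth anchors make this exact; on real
plates the anchors are the first and last ring, or any two events of
known time such as the LD→DD transfer mark.

The profile is detrended by subtracting its least-squares quadratic
fit (computed on a scaled domain for conditioning; the residual is
orthogonal to {1, x, x²} and the operation is idempotent). The
periodogram is the magnitude-squared DFT of the mean-removed residual,
zero-padded 8-fold, rectangular window (Hann behind a flag). A six-day
record has a raw resolution of ±2 h near 24 h, so the in-band peak is
refined by three-point parabolic interpolation on log power; together
with padding this brings recovery error to ~0.1–0.2 h on simulated
plates. The search band is 16–36 h — wide enough for long fungal
periods, narrow enough to exclude detrending leakage.

Rhythmicity is peak power over the median in-band power (SNR). The
threshold (12) was calibrated on 200 simulated rhythm-free plates of
the standard geometry: the in-band grid holds only ~5 independent
bins, so the null SNR distribution is heavy (median ~4, 95th
percentile ~8); 12 sits at the null 99th percentile while simulated
banded plates never drop below ~30. Ring calls are prominence-filtered
local maxima (prominence ≥ 0.5 × profile SD, separation ≥ half the
expected ring spacing). An SD-relative prominence cannot reject
structure in a profile that contains nothing but noise — the threshold
scales with the noise — so ring *counts* are meaningful only once the
rhythmicity call has passed; this is a documented limitation, not a
tuning target.

The ring-formation rate is `(count − 1) / (time span first→last ring)
× 24` rings per day; under 12:12 LD entrainment simulated plates give
1.00 ± 0.01.

## Actograms and the jet-lag readout

Actograms resample the calibrated signal onto a 0.5 h grid and stack
48 h rows offset by 24 h (double plotting); the right half of each row
is by construction identical to the left half of the next, and light
onset/offset marks follow the schedule through shift events.

The phase shift across a schedule change is estimated by fitting
`c + a·cos(ωt) + b·sin(ωt)` separately to the pre-shift segment and to
the segment starting 72 h (3 days, configurable) after the shift, and
reporting the circular difference of the cosine phases mapped to
(−T/2, T/2], delays positive. Uncertainty propagates from the
residual-based least-squares covariance. With τ = 36 h the clock has
only reached ~87% of an 8 h delay by the end of the transient skip, so
the estimator reads ~7.6–7.8 h rather than 8.0 on simulated runs — a
property of the relaxation model plus the fixed 3-day skip, not an
estimator bias; with τ = 0 the readout is exact.

## Temperature compensation

Q10 is defined on the oscillation rate (1/period):
`Q10 = (P_low/P_high)^(10/ΔT)`, computed on per-temperature group mean
periods (plates are unpaired across temperatures). A perfectly
compensated clock gives exactly 1 at any ΔT, and swapping the two
temperature–period pairs inverts the value. The report carries full
precision plus a one-decimal display field, both SD and SEM per group,
and a classical one-way fixed-effects ANOVA across temperatures
(flagged degenerate when any group has n < 2 or all within-group
variance vanishes).

The bundled scenarios use free-running periods of 26.8 h at 10 °C,
24.4 h at 14 °C and 24.5 h at 20 °C; the corresponding rate-based
Q10(10–20 °C) is 1.094, printed as 1.1. The CLI `demo` additionally
draws each plate's true period around its temperature mean with a
1.3 h SD, emulating biological replicate scatter — without it the
recovered periods are so precise that the ANOVA resolves the small
true differences between temperatures that replicate spread masks in
real cultures.

## Problem sizes and numerical choices

Simulated plates are 1024² px (8-bit), growth 3 px/h for 144 h
(≈ 6 days), giving ~430 px of banded radius and 5–6 rings; recovery
statistics use 50 seeded plates per condition and 20 jet-lag runs,
which reproduces the study-scale quantities in well under a minute.
Ring deposition times are located by bracketing integer phase
crossings on a 0.05 h grid and polishing with Brent's method
(xtol 1e−10). ROI sampling and all convolutions use reflective
boundaries; bit-depth quantization rounds to nearest. Degenerate
inputs (all-zero patches, sub-cycle records, <2 rings) return flagged
or empty results rather than raising where the condition is
scientifically meaningful (zero rings is a result, not an error).

## Known limitations

- The exponential re-entrainment transient is a convenience form; real
  transients may be asymmetric between delays and advances.
- Period recovery assumes constant radial growth; growth-rate drift
  would alias into apparent period drift and is not modeled.
- The SD-relative ring-call prominence cannot, on its own, distinguish
  noise peaks from rings (see above).
- No multi-ROI averaging, Lomb–Scargle or wavelet alternatives; single
  rectangular ROI per analysis.
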