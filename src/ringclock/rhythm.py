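"""Ring calls, pixel-to-hour calibration, detrending and period estimation.

The free-running period is read out of a radial profile in four steps:
calibrate pixels to hours from two anchor events (by default the first
and last ring), subtract the best-fitting quadratic trend, take the
magnitude-squared DFT of the residual (zero-padded for a finer
frequency grid), and refine the in-band peak with 3-point parabolic
interpolation on log power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .profiles import RadialProfile

__all__ = [
    "TimeCalibration",
    "RingSet",
    "Periodogram",
    "PeriodEstimate",
    "calibrate",
    "detect_rings",
    "detrend_quadratic",
    "compute_periodogram",
    "estimate_period",
    "rings_per_day",
]

#: Default prominence threshold for ring calls, as a multiple of the
#: detrended profile's SD.  Low by design: edge rings on simulated
#: plates can dip to ~0.5 profile SDs of prominence, so the factor is
#: set to keep every true ring.  Because an SD-relative threshold
#: scales with whatever the profile contains, ring counting is only
#: meaningful once banding dominates the profile; the rhythmicity call
#: (see DEFAULT_SNR_THRESHOLD), not the ring count, is the gate
#: against rhythm-free noise.
DEFAULT_PROMINENCE_FACTOR = 0.5

#: Default SNR (peak over median in-band power) above which a profile
#: is called rhythmic.  Calibrated on 200 simulated rhythm-free
#: profiles of the standard six-day geometry: the null 95th/99th SNR
#: percentiles are ~8/12, while simulated banded plates never drop
#: below ~30, so 12 keeps the false-positive rate near 1% with a
#: >2x margin on real signal.
DEFAULT_SNR_THRESHOLD = 12.0

DEFAULT_SEARCH_BAND = (16.0, 36.0)


@dataclass(frozen=True)
class TimeCalibration:
    """Affine pixel <-> hour mapping derived from two anchor events.

    The scale follows the first/last-ring rule: distance in pixels
    between the anchors divided by the hours elapsed between them.
    """

    anchor_a: tuple[float, float]  # (position px, time h)
    anchor_b: tuple[float, float]

    def __post_init__(self) -> None:
        (pa, ta), (pb, tb) = self.anchor_a, self.anchor_b
        if tb == ta:
            raise ValueError("anchor times must differ")
        if pb == pa:
            raise ValueError("anchor positions must differ")

    @property
    def px_per_h(self) -> float:
        (pa, ta), (pb, tb) = self.anchor_a, self.anchor_b
        return abs((pb - pa) / (tb - ta))

    def position_to_time(self, position):
        (pa, ta), (pb, tb) = self.anchor_a, self.anchor_b
        return ta + (np.asarray(position, dtype=float) - pa) * (tb - ta) / (pb - pa)

    def time_to_position(self, time):
        (pa, ta), (pb, tb) = self.anchor_a, self.anchor_b
        return pa + (np.asarray(time, dtype=float) - ta) * (pb - pa) / (tb - ta)


def calibrate(anchor_a: tuple[float, float], anchor_b: tuple[float, float]) -> TimeCalibration:
    """Build a :class:`TimeCalibration` from two (position px, time h) anchors."""
    return TimeCalibration(tuple(map(float, anchor_a)), tuple(map(float, anchor_b)))


@dataclass
class RingSet:
    """Detected concentric rings along a profile."""

    positions: np.ndarray
    prominences: np.ndarray
    times: np.ndarray | None = None

    @property
    def count(self) -> int:
        return int(self.positions.size)


def detect_rings(
    profile: RadialProfile,
    min_separation: float | None = None,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
    calibration: TimeCalibration | None = None,
    expected_period_h: float = 24.0,
    polarity: str = "bright",
) -> RingSet:
    """Call rings as prominent local maxima of the detrended profile.

    Peaks must exceed ``prominence_factor x SD`` of the detrended
    profile in topographic prominence and be at least
    ``min_separation`` pixels apart (default: half the expected ring
    spacing when a calibration is available, else 10 px).  Dark rings
    are found by negating the profile first.  Zero rings is a valid
    result.
    """
    work = profile
    if not work.processed_by("detrend"):
        work = detrend_quadratic(work)
    y = work.intensities.copy()
    if polarity == "dark":
        y = -y
    elif polarity != "bright":
        raise ValueError("polarity must be 'bright' or 'dark'")
    if min_separation is None:
        if calibration is not None:
            min_separation = 0.5 * expected_period_h * calibration.px_per_h
        else:
            min_separation = 10.0
    sd = float(y.std())
    if sd == 0.0:
        return RingSet(positions=np.array([]), prominences=np.array([]))
    step = float(np.median(np.diff(work.positions)))
    idx, props = find_peaks(
        y,
        prominence=prominence_factor * sd,
        distance=max(1, int(round(min_separation / step))),
    )
    positions = work.positions[idx]
    times = calibration.position_to_time(positions) if calibration is not None else None
    return RingSet(positions=positions, prominences=props["prominences"], times=times)


def detrend_quadratic(profile: RadialProfile) -> RadialProfile:
    """Subtract the least-squares quadratic fit from the profile.

    The residual is orthogonal to {1, x, x^2}; applying the operation
    twice changes nothing (idempotence).
    """
    x, y = profile.positions, profile.intensities
    if x.size < 8:
        raise ValueError("need >= 8 points to detrend")
    # scaled-domain fit for conditioning
    fit = np.polynomial.Polynomial.fit(x, y, deg=2)
    residual = y - fit(x)
    return profile.with_intensities(residual, "detrend_quadratic")


@dataclass
class Periodogram:
    """Magnitude-squared DFT of a detrended profile on an hourly frequency axis."""

    frequencies: np.ndarray  # cycles per hour, increasing
    power: np.ndarray
    pad_factor: int
    n_samples: int
    search_band: tuple[float, float] = DEFAULT_SEARCH_BAND


def compute_periodogram(
    profile: RadialProfile,
    calibration: TimeCalibration,
    pad_factor: int = 8,
    window: str = "rectangular",
) -> Periodogram:
    """DFT periodogram of the mean-removed profile.

    Uniform pixel spacing and a constant growth rate make the profile
    uniformly sampled in time with step ``1/px_per_h`` hours, so the
    DFT frequency axis converts directly to cycles per hour.  The
    signal is zero-padded ``pad_factor``-fold for a finer grid;
    windowing is rectangular by default (Hann available).
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    x = profile.intensities - profile.intensities.mean()
    n = x.size
    if window == "hann":
        x = x * np.hanning(n)
    elif window != "rectangular":
        raise ValueError("window must be 'rectangular' or 'hann'")
    step_px = float(np.median(np.diff(profile.positions)))
    dt_h = step_px / calibration.px_per_h
    n_pad = pad_factor * n
    spectrum = np.fft.rfft(x, n_pad)
    return Periodogram(
        frequencies=np.fft.rfftfreq(n_pad, d=dt_h),
        power=np.abs(spectrum) ** 2,
        pad_factor=pad_factor,
        n_samples=n,
    )


@dataclass
class PeriodEstimate:
    """A free-running-period readout from a periodogram peak."""

    period: float
    peak_power: float
    snr: float
    rhythmic: bool
    method_meta: dict


def estimate_period(
    pg: Periodogram,
    band: tuple[float, float] = DEFAULT_SEARCH_BAND,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    interpolate: bool = True,
) -> PeriodEstimate:
    """Read the period off the highest in-band periodogram peak.

    ``band`` is in hours; the peak bin is refined by 3-point parabolic
    interpolation on log power.  The SNR is peak power over the median
    in-band power; profiles below ``snr_threshold`` are flagged
    non-rhythmic.
    """
    lo_h, hi_h = band
    if not 0 < lo_h < hi_h:
        raise ValueError("band must satisfy 0 < min < max (hours)")
    f = pg.frequencies
    mask = (f >= 1.0 / hi_h) & (f <= 1.0 / lo_h)
    if not np.any(mask):
        raise ValueError("search band lies outside the periodogram's frequency grid")
    band_idx = np.nonzero(mask)[0]
    power = pg.power
    i_peak = band_idx[np.argmax(power[band_idx])]
    f_peak = f[i_peak]
    if interpolate and 0 < i_peak < f.size - 1 and power[i_peak] > 0:
        trio = power[i_peak - 1 : i_peak + 2]
        if np.all(trio > 0):
            lm, l0, lp = np.log(trio)
            denom = lm - 2 * l0 + lp
            if denom < 0:
                delta = 0.5 * (lm - lp) / denom
                f_peak = f_peak + np.clip(delta, -0.5, 0.5) * (f[1] - f[0])
    period = 1.0 / f_peak
    in_band = power[band_idx]
    med = float(np.median(in_band))
    snr = float(power[i_peak] / med) if med > 0 else np.inf
    rhythmic = bool(snr >= snr_threshold and lo_h <= period <= hi_h)
    return PeriodEstimate(
        period=float(period),
        peak_power=float(power[i_peak]),
        snr=snr,
        rhythmic=rhythmic,
        method_meta={
            "pad_factor": pg.pad_factor,
            "band_h": list(band),
            "interpolated": bool(interpolate),
            "snr_threshold": snr_threshold,
        },
    )


def rings_per_day(rings: RingSet, calibration: TimeCalibration | None = None) -> float | None:
    """Ring-formation rate in rings per 24 h; ``None`` below two rings.

    Computed as (count - 1) over the time spanned between the first
    and last ring, times 24.
    """
    if rings.count < 2:
        return None
    if rings.times is not None:
        times = np.asarray(rings.times, dtype=float)
    else:
        if calibration is None:
            raise ValueError("need calibrated ring times or a calibration")
        times = np.asarray(calibration.position_to_time(rings.positions), dtype=float)
    span = abs(times[-1] - times[0])
    if span == 0:
        return None
    return (rings.count - 1) / span * 24.0
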