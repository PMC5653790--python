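"""End-to-end convenience workflows over the module surface.

These functions chain the generator, the image pipeline and the rhythm
analysis exactly the way a plate would be analyzed: simulate (or load)
a photograph, extract the radial rectangle, smooth, flat-field, row-
average, calibrate pixels to hours from the first/last-ring anchors,
detrend, and read the period off the padded DFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actogram import PhaseShiftEstimate, estimate_phase_shift
from .pipeline import ROI, image_to_profile
from .profiles import RadialProfile
from .rhythm import (
    PeriodEstimate,
    RingSet,
    TimeCalibration,
    calibrate,
    compute_periodogram,
    detect_rings,
    detrend_quadratic,
    rings_per_day,
)
from .rhythm import estimate_period as _estimate_period
from .scenarios import Scenario
from .synthetic import (
    ColonyImage,
    SyntheticTruth,
    render_colony_image,
    render_profile,
    ring_deposition_times,
)

__all__ = [
    "simulate_plate",
    "default_roi",
    "truth_calibration",
    "AnalysisResult",
    "analyze_image",
    "recover_period",
    "ld_ring_rate",
    "jetlag_shift",
]


def simulate_plate(scenario: Scenario, seed: int) -> tuple[ColonyImage, SyntheticTruth]:
    """Render one synthetic plate photograph plus its ground truth."""
    truth = ring_deposition_times(
        scenario.schedule, scenario.clock, scenario.colony.duration,
        colony=scenario.colony, seed=seed,
    )
    image, truth = render_colony_image(
        truth,
        scenario.colony,
        illumination=scenario.illumination,
        noise_sd=scenario.noise_sd,
        image_size=_image_size_for(scenario),
        seed=seed,
        bit_depth=scenario.bit_depth,
    )
    return image, truth


def _image_size_for(scenario: Scenario) -> tuple[int, int]:
    cx, cy = scenario.colony.seed_center
    side = int(np.ceil(2 * max(cx, cy)))
    return (side, side)


def default_roi(scenario: Scenario, width: int = 40, angle: float = 0.0) -> ROI:
    """Radial rectangle from the banded zone's inner edge to the colony rim."""
    colony = scenario.colony
    length = int(np.floor(colony.final_radius - colony.start_radius)) - 2
    theta = np.deg2rad(angle)
    anchor = (
        colony.seed_center[0] + colony.start_radius * np.cos(theta),
        colony.seed_center[1] + colony.start_radius * np.sin(theta),
    )
    return ROI(anchor=anchor, length=length, width=width, angle=angle)


def truth_calibration(truth: SyntheticTruth, roi_offset_px: float) -> TimeCalibration:
    """First/last-ring calibration in ROI coordinates.

    ``roi_offset_px`` is the radius at which the ROI starts (its anchor
    distance from the seed), so ring radii convert to ROI positions by
    subtraction.
    """
    if truth.ring_radii is None or len(truth.ring_times) < 2:
        raise ValueError("need >= 2 rings with radii for the first/last-ring rule")
    first = (truth.ring_radii[0] - roi_offset_px, truth.ring_times[0])
    last = (truth.ring_radii[-1] - roi_offset_px, truth.ring_times[-1])
    return calibrate(first, last)


@dataclass
class AnalysisResult:
    """Every intermediate of one plate analysis."""

    profile: RadialProfile
    detrended: RadialProfile
    rings: RingSet
    estimate: PeriodEstimate
    rings_per_day: float | None
    calibration: TimeCalibration


def analyze_image(
    image: ColonyImage,
    roi: ROI,
    calibration: TimeCalibration,
    blur_sigma: float = 3.0,
    background_sigma: float | None = None,
    pad_factor: int = 8,
    band: tuple[float, float] = (16.0, 36.0),
    polarity: str = "bright",
) -> AnalysisResult:
    """Photograph -> profile -> rings -> detrended DFT period estimate."""
    profile = image_to_profile(image, roi, blur_sigma=blur_sigma,
                               background_sigma=background_sigma)
    detrended = detrend_quadratic(profile)
    rings = detect_rings(detrended, calibration=calibration, polarity=polarity)
    pg = compute_periodogram(detrended, calibration, pad_factor=pad_factor)
    estimate = _estimate_period(pg, band=band)
    rate = rings_per_day(rings, calibration)
    return AnalysisResult(profile=profile, detrended=detrended, rings=rings,
                          estimate=estimate, rings_per_day=rate, calibration=calibration)


def recover_period(scenario: Scenario, seed: int) -> tuple[PeriodEstimate, SyntheticTruth]:
    """Simulate one plate and run the full recovery pipeline on it."""
    image, truth = simulate_plate(scenario, seed)
    roi = default_roi(scenario)
    calibration = truth_calibration(truth, roi_offset_px=scenario.colony.start_radius)
    result = analyze_image(image, roi, calibration, polarity=scenario.colony.ring_polarity)
    return result.estimate, truth


def ld_ring_rate(scenario: Scenario, seed: int) -> float | None:
    """Rings per 24 h recovered from one simulated entrained plate."""
    image, truth = simulate_plate(scenario, seed)
    roi = default_roi(scenario)
    calibration = truth_calibration(truth, roi_offset_px=scenario.colony.start_radius)
    result = analyze_image(image, roi, calibration, polarity=scenario.colony.ring_polarity)
    return result.rings_per_day


def jetlag_shift(
    scenario: Scenario,
    seed: int,
    skip_transient: float = 72.0,
    period: float | None = None,
) -> PhaseShiftEstimate:
    """Simulate the jet-lag protocol and estimate the phase shift.

    Works on the 1-D band series (trend-free rendering plus camera
    noise); the schedule's first shift event defines the split point.
    """
    if not scenario.schedule.shift_events:
        raise ValueError("scenario has no schedule shift event")
    shift_time = scenario.schedule.shift_events[0][0]
    colony = scenario.colony
    truth = ring_deposition_times(scenario.schedule, scenario.clock, colony.duration,
                                  colony=colony, seed=seed)
    profile = render_profile(truth, colony, noise_sd=scenario.noise_sd, seed=seed)
    detrended = detrend_quadratic(profile)
    cal = calibrate((colony.start_radius, 0.0),
                    (colony.final_radius, colony.duration))
    return estimate_phase_shift(
        detrended, cal, shift_time=shift_time,
        period=period if period is not None else scenario.schedule.cycle_length,
        skip_transient=skip_transient,
    )
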