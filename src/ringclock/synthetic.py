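"""Synthetic colony generator with known clock parameters.

Emulates a fungal colony growing at constant radial speed while an
internal circadian oscillator deposits one concentric ring per cycle:
entrained to the LD schedule while lights cycle, free-running at its
own period after transfer to constant darkness, and re-entraining with
an exponential transient after a schedule shift (jet-lag).  The
generator returns the ground truth (ring times/radii and the true
period) alongside every image or profile, so downstream recovery is
testable without photographed plates.

Phase bookkeeping: the clock phase ``phi`` is measured in cycles.
Under LD the entrained target is ``(t - phase_offset - D(t)) / C``
with ``D(t)`` the cumulative schedule delay; after a shift of ``d``
hours the realized phase carries a transient ``(d/C)·exp(-(t-t_e)/tau)``
that keeps it continuous and relaxes toward the new target.  After
``dd_start`` the phase advances at ``1/P`` (the free-running period)
from wherever it was.  A ring is deposited each time the phase passes
the deposition fraction (``entrained_phase`` hours after dark onset).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .profiles import RadialProfile
from .schedule import LightSchedule

__all__ = [
    "ClockParams",
    "ColonyModel",
    "IlluminationField",
    "SyntheticTruth",
    "ColonyImage",
    "clock_phase_trajectory",
    "ring_deposition_times",
    "render_profile",
    "render_colony_image",
    "write_image",
    "write_truth",
]


# ---------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ClockParams:
    """Parameters of the internal circadian oscillator.

    ``free_running_period`` is the period P (h) under constant
    darkness; ``entrained_phase`` the ring-deposition phase in hours
    after dark onset under entrainment; ``relaxation_tau`` the time
    constant (h) of exponential phase re-entrainment after a schedule
    shift (0 = instantaneous re-entrainment).
    """

    free_running_period: float = 24.5
    entrained_phase: float = 0.0
    relaxation_tau: float = 36.0

    def __post_init__(self) -> None:
        if self.free_running_period <= 0:
            raise ValueError("free_running_period must be positive")
        if self.relaxation_tau < 0:
            raise ValueError("relaxation_tau must be >= 0")


@dataclass(frozen=True)
class ColonyModel:
    """Geometry and optics of the growing colony.

    Growth is purely radial at a constant ``growth_rate`` (px/h), so a
    ring deposited at time t sits at radius ``start_radius +
    growth_rate * t``.
    """

    growth_rate: float = 3.0
    seed_center: tuple[float, float] = (512.0, 512.0)
    start_radius: float = 24.0
    duration: float = 144.0
    baseline_intensity: float = 120.0
    ring_amplitude: float = 60.0
    ring_sharpness: float = 2.0
    ring_polarity: str = "bright"

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.ring_amplitude < 0:
            raise ValueError("ring_amplitude must be >= 0")
        if self.ring_sharpness < 1:
            raise ValueError("ring_sharpness must be >= 1")
        if self.ring_polarity not in ("bright", "dark"):
            raise ValueError("ring_polarity must be 'bright' or 'dark'")

    @property
    def final_radius(self) -> float:
        return self.start_radius + self.growth_rate * self.duration

    @property
    def polarity_sign(self) -> float:
        return 1.0 if self.ring_polarity == "bright" else -1.0


@dataclass(frozen=True)
class IlluminationField:
    """Smooth multiplicative illumination artifact.

    kinds: ``uniform``; ``planar`` (relative slopes ``gx``/``gy``
    across the full frame, default a 10% left-to-right gradient);
    ``vignette`` (quadratic falloff of relative ``depth`` toward the
    corners).  The field is strictly positive and has mean ~1.
    """

    kind: str = "planar"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "planar", "vignette"):
            raise ValueError(f"unknown illumination kind {self.kind!r}")

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        if self.kind == "uniform":
            fld = np.ones(shape)
        elif self.kind == "planar":
            gx = float(self.params.get("gx", 0.10))
            gy = float(self.params.get("gy", 0.0))
            fld = 1.0 + gx * (xx / max(w - 1, 1) - 0.5) + gy * (yy / max(h - 1, 1) - 0.5)
        else:  # vignette
            depth = float(self.params.get("depth", 0.2))
            cy, cx = self.params.get("center", ((h - 1) / 2, (w - 1) / 2))
            rho2 = (xx - cx) ** 2 + (yy - cy) ** 2
            fld = 1.0 - depth * rho2 / max(rho2.max(), 1e-12)
        if fld.min() <= 0:
            raise ValueError("illumination field must be strictly positive")
        return fld


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every synthetic colony."""

    ring_times: np.ndarray
    ring_radii: np.ndarray | None
    true_period_dd: float
    px_per_h: float | None
    schedule: LightSchedule
    seed: int
    duration: float

    def with_colony(self, colony: ColonyModel) -> "SyntheticTruth":
        radii = colony.start_radius + colony.growth_rate * np.asarray(self.ring_times)
        return replace(self, ring_radii=radii, px_per_h=colony.growth_rate,
                       duration=colony.duration)

    def to_dict(self) -> dict:
        return {
            "ring_times_h": list(map(float, self.ring_times)),
            "ring_radii_px": None if self.ring_radii is None else list(map(float, self.ring_radii)),
            "true_period_dd_h": float(self.true_period_dd),
            "px_per_h": None if self.px_per_h is None else float(self.px_per_h),
            "seed": int(self.seed),
            "duration_h": float(self.duration),
            "schedule": {
                "cycle_length": self.schedule.cycle_length,
                "light_fraction": self.schedule.light_fraction,
                "phase_offset": self.schedule.phase_offset,
                "dd_start": self.schedule.dd_start,
                "shift_events": list(map(list, self.schedule.shift_events)),
            },
        }


@dataclass
class ColonyImage:
    """A grayscale colony photograph (real or synthetic)."""

    pixels: np.ndarray
    bit_depth: int | str = 8
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ColonyImage pixels must be 2-D grayscale")
        if min(self.pixels.shape) < 64:
            raise ValueError("image dimensions must both be >= 64")
        if self.bit_depth in (8, 16):
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < 0 or hi > 2 ** int(self.bit_depth) - 1:
                raise ValueError("intensities outside bit-depth range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------
# clock phase model


def _phase_cycles(schedule: LightSchedule, clock: ClockParams, t) -> np.ndarray:
    """Clock phase in cycles at time(s) ``t`` (closed form)."""
    t = np.asarray(t, dtype=float)
    C = schedule.cycle_length
    tau = clock.relaxation_tau

    def ld_phase(tt: np.ndarray) -> np.ndarray:
        phi = (tt - schedule.phase_offset - schedule.cumulative_delay(tt)) / C
        for t_e, d in schedule.shift_events:
            if tau > 0:
                phi = phi + np.where(tt >= t_e, (d / C) * np.exp(-np.clip(tt - t_e, 0, None) / tau), 0.0)
            # tau == 0: the transient vanishes instantly (phase jumps at t_e)
        return phi

    if schedule.dd_start is None:
        return ld_phase(t)
    dd = schedule.dd_start
    phi_dd0 = float(ld_phase(np.asarray(dd)))
    return np.where(t < dd, ld_phase(t), phi_dd0 + (t - dd) / clock.free_running_period)


def _deposition_fraction(schedule: LightSchedule, clock: ClockParams) -> float:
    """Cycle fraction at which a ring is deposited (dark onset + entrained_phase)."""
    return float((schedule.light_fraction + clock.entrained_phase / schedule.cycle_length) % 1.0)


@dataclass
class PhaseTrajectory:
    """Sampled clock phase: subjective hours versus real time."""

    times: np.ndarray
    phase_hours: np.ndarray

    @property
    def phase_cycles(self) -> np.ndarray:
        return self.phase_hours / 24.0


def clock_phase_trajectory(
    schedule: LightSchedule,
    clock: ClockParams,
    duration: float,
    dt: float = 0.1,
) -> PhaseTrajectory:
    """Sample the clock's subjective time against real time.

    The phase advances at rate ``1/cycle_length`` cycles/h while
    entrained and ``1/free_running_period`` after ``dd_start``; each
    shift event moves the entrained target by its delay while the
    realized phase relaxes there exponentially with ``relaxation_tau``.
    One subjective hour is 1/24 cycle, so deposition events recur every
    24 subjective hours.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    late = [t_e for t_e, _ in schedule.shift_events if t_e > duration]
    if late:
        warnings.warn(f"shift events after end of duration are inert: {late}", stacklevel=2)
    times = np.arange(0.0, duration + dt / 2, dt)
    phi = _phase_cycles(schedule, clock, times)
    return PhaseTrajectory(times=times, phase_hours=phi * 24.0)


def ring_deposition_times(
    schedule: LightSchedule,
    clock: ClockParams,
    duration: float,
    colony: ColonyModel | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Times (and radii, if a colony is given) at which rings are laid down.

    One ring per full phase cycle, at the cycle fraction set by
    ``entrained_phase``.  A run shorter than one cycle legitimately
    yields zero rings.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dep = _deposition_fraction(schedule, clock)
    grid = np.arange(0.0, duration * (1 + 1e-12) + 0.05, 0.05)
    grid = grid[grid <= duration]
    y = _phase_cycles(schedule, clock, grid) - dep
    times: list[float] = []
    k_lo = int(np.ceil(y.min() - 1e-9))
    k_hi = int(np.floor(y.max() + 1e-9))
    for k in range(k_lo, k_hi + 1):
        # bracket each upward crossing of level k on the sampled grid
        above = y >= k
        crossings = np.nonzero(~above[:-1] & above[1:])[0]
        for i in crossings:
            f = lambda t: float(_phase_cycles(schedule, clock, t)) - dep - k
            a, b = grid[i], grid[i + 1]
            if f(a) == 0.0:
                root = a
            else:
                root = brentq(f, a, b, xtol=1e-10)
            if 0.0 < root <= duration:
                times.append(root)
    times_arr = np.array(sorted(times))
    truth = SyntheticTruth(
        ring_times=times_arr,
        ring_radii=None,
        true_period_dd=clock.free_running_period,
        px_per_h=None,
        schedule=schedule,
        seed=seed,
        duration=duration,
    )
    return truth.with_colony(colony) if colony is not None else truth


# ---------------------------------------------------------------------
# rendering


def _band_values(truth: SyntheticTruth, t: np.ndarray, sharpness: float) -> np.ndarray:
    """Raised-cosine band, peaking at the truth's ring times.

    A local phase is interpolated through the ring times (ring k ↦
    phase k) and extended at both ends with the edge spacing, so the
    band is periodic in the locally correct period even through the
    LD→DD transition or a jet-lag transient.
    """
    rt = np.asarray(truth.ring_times, dtype=float)
    if rt.size == 0:
        return np.zeros_like(t)
    if rt.size == 1:
        knots_t = np.array([rt[0] - truth.true_period_dd, rt[0], rt[0] + truth.true_period_dd])
        knots_k = np.array([-1.0, 0.0, 1.0])
    else:
        first_gap = rt[1] - rt[0]
        last_gap = rt[-1] - rt[-2]
        knots_t = np.concatenate([[rt[0] - first_gap], rt, [rt[-1] + last_gap]])
        knots_k = np.arange(-1.0, rt.size + 1.0)
    # linear interpolation with linear extrapolation at the ends
    psi = np.interp(t, knots_t, knots_k)
    below, above = t < knots_t[0], t > knots_t[-1]
    if np.any(below):
        slope = (knots_k[1] - knots_k[0]) / (knots_t[1] - knots_t[0])
        psi = np.where(below, knots_k[0] + (t - knots_t[0]) * slope, psi)
    if np.any(above):
        slope = (knots_k[-1] - knots_k[-2]) / (knots_t[-1] - knots_t[-2])
        psi = np.where(above, knots_k[-1] + (t - knots_t[-1]) * slope, psi)
    return (0.5 * (1.0 + np.cos(2.0 * np.pi * psi))) ** sharpness


def _radial_law(truth: SyntheticTruth, colony: ColonyModel, radii: np.ndarray) -> np.ndarray:
    """Signed band contribution at each radius (0 outside the banded zone)."""
    t = (radii - colony.start_radius) / colony.growth_rate
    band = _band_values(truth, t, colony.ring_sharpness)
    inside = (radii >= colony.start_radius) & (radii <= colony.final_radius)
    return np.where(inside, colony.polarity_sign * colony.ring_amplitude * band, 0.0)


def render_profile(
    truth: SyntheticTruth,
    colony: ColonyModel,
    trend_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RadialProfile:
    """1-D band-intensity profile: quadratic trend + rings + noise.

    ``trend_coeffs`` are highest-power-first quadratic coefficients in
    radial pixels (``a·x² + b·x + c``).  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth.px_per_h is None:
        truth = truth.with_colony(colony)
    n = int(np.ceil(colony.final_radius)) + 1
    positions = np.arange(n, dtype=float)
    trend = np.polyval(trend_coeffs, positions)
    signal = trend + _radial_law(truth, colony, positions)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    return RadialProfile(
        positions=positions,
        intensities=signal,
        provenance=[f"synthetic profile (seed={seed}, noise_sd={noise_sd})"],
    )


def render_colony_image(
    truth: SyntheticTruth,
    colony: ColonyModel,
    illumination: IlluminationField | None = None,
    noise_sd: float = 0.0,
    image_size: tuple[int, int] = (1024, 1024),
    seed: int = 0,
    bit_depth: int | str = 8,
) -> tuple[ColonyImage, SyntheticTruth]:
    """Render the radially symmetric colony photograph.

    The 1-D radial law is swept around ``seed_center``, multiplied by
    the illumination field, corrupted with additive Gaussian noise and
    quantized to the requested bit depth.  The unchanged truth is
    returned for downstream recovery tests.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth.px_per_h is None:
        truth = truth.with_colony(colony)
    h, w = image_size
    cx, cy = colony.seed_center
    r_final = colony.final_radius
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("seed_center must lie inside the image")
    if cx - r_final < 0 or cx + r_final > w - 1 or cy - r_final < 0 or cy + r_final > h - 1:
        raise ValueError("final colony radius exceeds the image bounds")
    illumination = illumination or IlluminationField(kind="uniform")
    illum = illumination.evaluate((h, w))

    # evaluate the radial law on a fine 1-D grid, then map onto the image
    rmax = float(np.hypot(max(cx, w - 1 - cx), max(cy, h - 1 - cy))) + 1.0
    rgrid = np.arange(0.0, rmax + 0.25, 0.25)
    law = colony.baseline_intensity + _radial_law(truth, colony, rgrid)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rr = np.hypot(xx - cx, yy - cy)
    img = np.interp(rr, rgrid, law) * illum

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    if bit_depth in (8, 16):
        top = 2 ** int(bit_depth) - 1
        img = np.clip(np.rint(img), 0, top)
    meta = {
        "capture_time_h": float(truth.duration),
        "seed": int(seed),
        "schedule": "DD" if truth.schedule.dd_start == 0 else "LD/DD",
    }
    return ColonyImage(pixels=img, bit_depth=bit_depth, metadata=meta), truth


# ---------------------------------------------------------------------
# output


def write_image(image: ColonyImage, path: str | Path) -> None:
    """Write a PNG (8/16-bit) or TIFF (any depth) grayscale image."""
    path = Path(path)
    if image.bit_depth == 8:
        arr = image.pixels.astype(np.uint8)
    elif image.bit_depth == 16:
        arr = image.pixels.astype(np.uint16)
    else:
        arr = image.pixels.astype(np.float32)
    suffix = path.suffix.lower()
    if suffix == ".png":
        import imageio.v3 as iio

        if arr.dtype == np.float32:
            raise ValueError("float images must be written as TIFF")
        iio.imwrite(path, arr)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))
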