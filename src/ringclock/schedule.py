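"""Light schedules: LD/DD regimes, schedule-shift (jet-lag) events.

A :class:`LightSchedule` describes the zeitgeber a culture experienced:
cycle length, light fraction, an optional transfer to constant darkness
(DD), and an ordered list of shift events, each delaying (positive) or
advancing (negative) the whole light cycle from that moment on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LightSchedule"]


@dataclass(frozen=True)
class LightSchedule:
    """An LD/DD light regime.

    Parameters
    ----------
    cycle_length
        Zeitgeber cycle length in hours (24 for a 12:12 LD cycle).
    light_fraction
        Fraction of the cycle that is light, strictly between 0 and 1
        (0.5 for 12:12).
    phase_offset
        Time of the first light onset relative to experiment start, in
        hours.
    dd_start
        Time of transfer to constant darkness, in hours; ``None`` means
        the LD cycle runs for the whole experiment.  ``0`` means the
        whole run is in DD (free run of a previously entrained culture).
    shift_events
        Ordered ``(event_time, delay)`` pairs in hours.  A positive
        delay moves every subsequent light onset later (the jet-lag
        protocol); a negative delay is an advance.
    """

    cycle_length: float = 24.0
    light_fraction: float = 0.5
    phase_offset: float = 0.0
    dd_start: float | None = None
    shift_events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if not 0.0 < self.light_fraction < 1.0:
            raise ValueError("light_fraction must lie strictly in (0, 1)")
        if self.dd_start is not None and self.dd_start < 0:
            raise ValueError("dd_start must be >= 0")
        events = tuple((float(t), float(d)) for t, d in self.shift_events)
        times = [t for t, _ in events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("shift_events must be strictly increasing in time")
        object.__setattr__(self, "shift_events", events)

    # -- cumulative schedule delay -------------------------------------

    def cumulative_delay(self, t):
        """Total schedule delay (h) accumulated by time ``t`` (vectorized)."""
        t = np.asarray(t, dtype=float)
        if not self.shift_events:
            return np.zeros_like(t)
        times = np.array([e[0] for e in self.shift_events])
        delays = np.concatenate([[0.0], np.cumsum([e[1] for e in self.shift_events])])
        idx = np.searchsorted(times, t, side="right")
        return delays[idx]

    # -- light state ---------------------------------------------------

    def is_light(self, t):
        """Whether the lights are on at time ``t`` (vectorized)."""
        t = np.asarray(t, dtype=float)
        local = np.mod(t - self.phase_offset - self.cumulative_delay(t), self.cycle_length)
        lit = local < self.light_fraction * self.cycle_length
        if self.dd_start is not None:
            lit = lit & (t < self.dd_start)
        return lit

    def light_intervals(self, t_start: float, t_stop: float) -> list[tuple[float, float]]:
        """Light-on intervals intersecting ``[t_start, t_stop)``, clipped.

        Used to place the filled/empty light marks on actogram rows.
        Shift events move every subsequent onset/offset; after
        ``dd_start`` there is no light at all.
        """
        if t_stop <= t_start:
            return []
        stop = t_stop if self.dd_start is None else min(t_stop, self.dd_start)
        out: list[tuple[float, float]] = []
        light_h = self.light_fraction * self.cycle_length
        # walk cycle by cycle; delays only ever push onsets later, so
        # start a couple of cycles early to be safe with advances too
        total_delay = self.cumulative_delay(stop)
        k0 = int(np.floor((t_start - self.phase_offset - abs(total_delay)) / self.cycle_length)) - 2
        k1 = int(np.ceil((stop - self.phase_offset + abs(total_delay)) / self.cycle_length)) + 2
        for k in range(k0, k1 + 1):
            onset = self.phase_offset + k * self.cycle_length
            # fixed point: the delay in effect at the shifted onset moves
            # the onset itself
            onset_eff = onset
            for _ in range(4):
                onset_eff = onset + float(self.cumulative_delay(onset_eff))
            offset_eff = onset_eff + light_h
            a, b = max(onset_eff, t_start), min(offset_eff, stop)
            if b > a:
                out.append((a, b))
        # merge/deduplicate overlapping intervals from the delay handling
        out.sort()
        merged: list[tuple[float, float]] = []
        for a, b in out:
            if merged and a <= merged[-1][1] + 1e-9:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        return merged
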