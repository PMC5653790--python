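"""Temperature compensation: Q10 and the cross-temperature comparison.

A temperature-compensated circadian clock keeps its free-running
period nearly constant across physiological temperatures.  Q10 is
defined on the oscillation *rate* (1/period):

    Q10 = (rate_high / rate_low) ** (10 / (T_high - T_low))
        = (period_low / period_high) ** (10 / (T_high - T_low))

so a perfectly compensated clock has Q10 = 1 regardless of the
temperature gap, and typical uncompensated biochemistry runs 2-3.
Group periods are compared with a one-way fixed-effects ANOVA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CompensationResult", "q10", "anova_periods", "compensation_report",
           "load_period_table"]


def q10(period_low: float, t_low: float, period_high: float, t_high: float) -> float:
    """Rate-based temperature coefficient between two temperatures.

    ``period_low``/``period_high`` are the periods measured at the
    lower/higher temperature ``t_low``/``t_high`` (degrees C).
    Swapping the two temperature-period pairs inverts the result.
    """
    if t_high <= t_low:
        raise ValueError("t_high must exceed t_low")
    if period_low <= 0 or period_high <= 0:
        raise ValueError("periods must be positive")
    return float((period_low / period_high) ** (10.0 / (t_high - t_low)))


def anova_periods(groups: list[np.ndarray] | list[list[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA over per-temperature periods.

    Returns ``(F, p)``; with zero within-group variance the statistic
    is undefined and ``(nan, nan)`` is returned (flagged degenerate by
    the caller).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    pooled_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if pooled_within == 0.0:
        return float("nan"), float("nan")
    f_stat, p_val = stats.f_oneway(*arrays)
    return float(f_stat), float(p_val)


@dataclass
class CompensationResult:
    """Per-temperature period summaries plus Q10 and the ANOVA."""

    temperatures: list[float]
    groups: list[list[float]]
    group_means: list[float]
    group_sds: list[float]
    group_sems: list[float]
    q10: float
    q10_display: float  # rounded to one decimal for reporting
    reference_pair: tuple[float, float]
    anova_F: float
    anova_p: float
    degenerate_anova: bool

    def to_dict(self) -> dict:
        return {
            "temperatures_C": self.temperatures,
            "n_per_group": [len(g) for g in self.groups],
            "group_means_h": self.group_means,
            "group_sds_h": self.group_sds,
            "group_sems_h": self.group_sems,
            "q10": self.q10,
            "q10_display": self.q10_display,
            "q10_reference_pair_C": list(self.reference_pair),
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "degenerate_anova": self.degenerate_anova,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True))

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_C": self.temperatures,
                "n": [len(g) for g in self.groups],
                "period_mean_h": self.group_means,
                "period_sd_h": self.group_sds,
                "period_sem_h": self.group_sems,
            }
        )


def compensation_report(
    groups: dict[float, list[float]],
    reference_pair: tuple[float, float] = (10.0, 20.0),
) -> CompensationResult:
    """Aggregate per-temperature period estimates into the compensation readout.

    ``groups`` maps temperature (C) to the list of per-plate period
    estimates (h).  Q10 is computed on the group means of the two
    reference temperatures (plates are unpaired across temperatures);
    the ANOVA runs across all groups when every group has n >= 2 and
    within-group variance exists, otherwise it is flagged degenerate.
    Both SD and SEM are reported.
    """
    temps = sorted(groups)
    t_lo, t_hi = sorted(reference_pair)
    for t in (t_lo, t_hi):
        if t not in groups:
            raise ValueError(f"reference temperature {t} missing from groups")
    arrays = [np.asarray(groups[t], dtype=float) for t in temps]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs n >= 1")
    means = [float(a.mean()) for a in arrays]
    sds = [float(a.std(ddof=1)) if a.size > 1 else 0.0 for a in arrays]
    sems = [sd / np.sqrt(a.size) for sd, a in zip(sds, arrays)]
    mean_by_temp = dict(zip(temps, means))
    q = q10(mean_by_temp[t_lo], t_lo, mean_by_temp[t_hi], t_hi)
    degenerate = any(a.size < 2 for a in arrays) or all(
        float(((a - a.mean()) ** 2).sum()) == 0.0 for a in arrays
    )
    if degenerate:
        f_stat, p_val = float("nan"), float("nan")
    else:
        f_stat, p_val = anova_periods(arrays)
        degenerate = bool(np.isnan(f_stat))
    return CompensationResult(
        temperatures=[float(t) for t in temps],
        groups=[list(map(float, groups[t])) for t in temps],
        group_means=means,
        group_sds=sds,
        group_sems=sems,
        q10=q,
        q10_display=round(q, 1),
        reference_pair=(t_lo, t_hi),
        anova_F=f_stat,
        anova_p=p_val,
        degenerate_anova=degenerate,
    )


def load_period_table(path: str | Path) -> dict[float, list[float]]:
    """Read a (temperature_C, plate_id, period_h) CSV into groups."""
    df = pd.read_csv(path)
    if not {"temperature_C", "period_h"} <= set(df.columns):
        raise ValueError("CSV needs temperature_C and period_h columns")
    return {
        float(t): sub["period_h"].astype(float).tolist()
        for t, sub in df.groupby("temperature_C")
    }
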