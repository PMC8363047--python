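"""Thermal-dose metrics: CEM43 and per-region treatment summaries.

CEM43 (cumulative equivalent minutes at 43 C) follows the standard
Sapareto-Dewey rule,

    CEM43 = sum_t dt * R**(43 - T(t))   [minutes],

with R = 0.5 at or above the 43 C breakpoint and R = 0.25 below it.  Both
R values and the breakpoint are parameters.  Doses are computed on the
per-region maximum- and minimum-temperature traces to bracket the spatial
heterogeneity a single intratumoral probe cannot see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sources import PulseSchedule
from .solver import TimeSeriesResult

#: Sapareto-Dewey defaults.
BREAKPOINT_C = 43.0
R_ABOVE = 0.5
R_BELOW = 0.25


def cem43(trace, dt_s: float, breakpoint_c: float = BREAKPOINT_C,
          r_above: float = R_ABOVE, r_below: float = R_BELOW) -> float:
    """Cumulative equivalent minutes at 43 C for a uniformly sampled trace.

    Parameters
    ----------
    trace : array-like
        Temperatures in C, sampled every ``dt_s`` seconds.
    dt_s : float
        Sampling interval in seconds.

    Returns
    -------
    float
        Thermal dose in equivalent minutes at 43 C.  A constant 43 C trace
        of N minutes returns N; each degree above the breakpoint doubles the
        rate, each degree below quarters it.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        warnings.warn("empty temperature trace: CEM43 = 0", stacklevel=2)
        return 0.0
    if not np.all(np.isfinite(trace)):
        raise ValueError("temperature trace contains non-finite values")
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    r = np.where(trace >= breakpoint_c, r_above, r_below)
    return float(np.sum(dt_s / 60.0 * r ** (breakpoint_c - trace)))


def time_above(trace, dt_s: float, threshold_c: float = BREAKPOINT_C) -> float:
    """Total time (s) a trace spends at or above a temperature threshold."""
    trace = np.asarray(trace, dtype=float)
    return float(np.count_nonzero(trace >= threshold_c) * dt_s)


@dataclass
class DoseReport:
    """Per-region thermal-dose summary of one treatment.

    ``table`` has one row per region with the peak and floor temperatures,
    CEM43 of the max- and min-temperature traces, and time at/above 43 C.
    ``muscle_peak_c`` is the nonspecific (eddy-current) heating readout.
    """

    table: pd.DataFrame
    duty_percent: float | None
    elapsed_s: float
    total_on_s: float | None
    muscle_peak_c: float | None

    def region(self, name: str) -> pd.Series:
        sub = self.table[self.table["region"] == name]
        if sub.empty:
            raise KeyError(f"region {name!r} not in report")
        return sub.iloc[0]

    def to_text(self) -> str:
        lines = ["Thermal dose report",
                 f"  elapsed time : {self.elapsed_s / 60.0:.1f} min"]
        if self.total_on_s is not None:
            lines.append(f"  AMF-on time  : {self.total_on_s / 60.0:.1f} min")
        if self.duty_percent is not None:
            lines.append(f"  duty cycle   : {self.duty_percent:.1f} %")
        if self.muscle_peak_c is not None:
            lines.append(
                f"  muscle peak (nonspecific heating): "
                f"{self.muscle_peak_c:.2f} C")
        lines.append(self.table.to_string(index=False,
                                          float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def summarize(result: TimeSeriesResult,
              schedule: PulseSchedule | None = None,
              breakpoint_c: float = BREAKPOINT_C,
              r_above: float = R_ABOVE, r_below: float = R_BELOW
              ) -> DoseReport:
    """Reduce a simulation's extrema traces to a :class:`DoseReport`.

    Regions are reported individually, plus a ``tumor_all`` union of the
    tumor shell and the MION-loaded core when both exist (the whole-lesion
    readout a probe at the hottest point would approximate).
    """
    if result.times.size == 0:
        raise ValueError("empty time-series result")
    schedule = schedule or result.schedule
    dt = result.dt
    regions = list(result.region_names)
    if "tumor" in regions and "mion" in regions:
        regions.append("tumor+mion")

    rows = []
    for name in regions:
        hi = result.trace(name, "max")
        lo = result.trace(name, "min")
        # sample at index i > 0 represents the dt interval it terminates;
        # the t = 0 baseline sample carries no exposure time
        rows.append({
            "region": "tumor_all" if name == "tumor+mion" else name,
            "peak_C": float(hi.max()),
            "floor_C": float(lo.min()),
            "cem43_max_trace_min": cem43(hi[1:], dt, breakpoint_c, r_above,
                                         r_below) if hi.size > 1 else 0.0,
            "cem43_min_trace_min": cem43(lo[1:], dt, breakpoint_c, r_above,
                                         r_below) if lo.size > 1 else 0.0,
            "time_above_43_s": time_above(hi[1:], dt, breakpoint_c),
        })
    table = pd.DataFrame(rows)
    muscle_peak = None
    if "muscle" in result.region_names:
        muscle_peak = float(result.trace("muscle", "max").max())
    return DoseReport(
        table=table,
        duty_percent=None if schedule is None else schedule.duty_percent,
        elapsed_s=float(result.times[-1]),
        total_on_s=None if schedule is None else schedule.total_on_s,
        muscle_peak_c=muscle_peak)
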