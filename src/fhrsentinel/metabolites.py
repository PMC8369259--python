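"""Intermittent blood-sample analytes: piecewise-linear interpolation and
the pH = 7.00 crossing time.

Blood gases are drawn only every ~20 min during an occlusion protocol; a
linear drift is assumed between successive draws.  Values are never
extrapolated beyond an analyte's sampled span.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MetaboliteSeries", "interpolate_metabolites", "find_ph_crossing"]

ANALYTES = ("ph", "lactate", "be")


@dataclass
class MetaboliteSeries:
    """pH, lactate (mmol/L) and base excess (mmol/L) at sample times (s).

    Any analyte may be absent (NaN) at any time.  Times are strictly
    increasing; pH values outside the physiologic sanity range (6.5, 7.8)
    trigger a warning.
    """

    sample_times: np.ndarray
    ph: np.ndarray
    lactate: np.ndarray
    be: np.ndarray

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, float)
        for name in ANALYTES:
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.sample_times.shape:
                raise ValueError(f"{name} must match sample_times in length")
            setattr(self, name, arr)
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        ph = self.ph[np.isfinite(self.ph)]
        if ph.size and (ph.min() <= 6.5 or ph.max() >= 7.8):
            warnings.warn("pH outside the (6.5, 7.8) sanity range", stacklevel=2)

    def analyte(self, name: str):
        times = self.sample_times
        vals = np.asarray(getattr(self, name), float)
        ok = np.isfinite(vals)
        return times[ok], vals[ok]


def interpolate_metabolites(series: MetaboliteSeries, query_times) -> dict[str, np.ndarray]:
    """Piecewise-linear analyte values at ``query_times``.

    Exact at sample times; NaN (absent, not extrapolated) outside an
    analyte's sampled span.  An analyte with fewer than 2 samples is absent
    everywhere except at its own sample times.
    """
    q = np.atleast_1d(np.asarray(query_times, float))
    out: dict[str, np.ndarray] = {}
    for name in ANALYTES:
        t, v = series.analyte(name)
        if t.size == 0:
            out[name] = np.full(q.shape, np.nan)
            continue
        if t.size == 1:
            vals = np.full(q.shape, np.nan)
            vals[np.isclose(q, t[0], rtol=0, atol=1e-9)] = v[0]
            out[name] = vals
            continue
        vals = np.interp(q, t, v)
        vals[(q < t[0]) | (q > t[-1])] = np.nan
        out[name] = vals
    return out


def find_ph_crossing(series: MetaboliteSeries, level: float = 7.00) -> float | None:
    """Earliest time the piecewise-linear pH interpolant reaches ``level`` from above.

    An exact hit at a sample returns that sample's time; ``None`` if the
    level is never reached.  A series that starts at or below the level
    returns its first pH sample time.
    """
    t, v = series.analyte("ph")
    if t.size < 2:
        if t.size == 1 and v[0] <= level:
            return float(t[0])
        return None
    if v[0] <= level:
        return float(t[0])
    for i in range(1, t.size):
        if v[i] <= level:
            # downward crossing inside segment [i-1, i]
            if v[i] == level:
                return float(t[i])
            frac = (v[i - 1] - level) / (v[i - 1] - v[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None
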