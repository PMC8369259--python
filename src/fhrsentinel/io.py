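"""Data model and plain-text I/O for heart-rate, blood-pressure and
metabolite recordings.

All series are uniformly sampled with an explicit validity mask; gaps are
never filled by interpolation beyond the bounded-gap rule of
:func:`resample_rr`.  The CSV dialect is fixed (comma separated, ``.``
decimal, optional ``#`` comment lines, UTF-8) so that round-trips are
bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FhrSeries",
    "AbpSeries",
    "RegimeSchedule",
    "AnalysisConfig",
    "load_fhr_csv",
    "save_fhr_csv",
    "load_abp_csv",
    "save_abp_csv",
    "resample_rr",
    "load_metabolite_csv",
    "save_metabolite_csv",
    "load_schedule_csv",
    "save_schedule_csv",
]

REGIME_NAMES = ("mild", "moderate", "severe", "recovery")


@dataclass
class UniformSeries:
    """Uniformly sampled signal with a validity mask.

    Sample ``n`` sits at time ``start_time + n / sample_rate``; a window
    ``[a, b)`` is half-open in time.  Invalid samples carry NaN values and
    are never used in any statistic.
    """

    sample_rate: float
    values: np.ndarray
    valid_mask: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must have equal length")
        # non-finite inputs are missing, never zeros
        finite = np.isfinite(self.values)
        self.valid_mask = self.valid_mask & finite
        self.values = np.where(self.valid_mask, self.values, np.nan)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    def valid_fraction(self, start: int = 0, stop: int | None = None) -> float:
        sl = self.valid_mask[start:stop]
        return float(sl.mean()) if sl.size else 0.0


class FhrSeries(UniformSeries):
    """Fetal heart rate in bpm, default 4 Hz."""


class AbpSeries(UniformSeries):
    """Arterial blood pressure in mmHg."""


@dataclass
class RegimeSchedule:
    """Onset times (s) of the occlusion regimes; ``mild`` may be absent."""

    mild: float | None
    moderate: float
    severe: float
    recovery: float

    def __post_init__(self) -> None:
        onsets = [o for o in (self.mild, self.moderate, self.severe, self.recovery) if o is not None]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("present regime onsets must be strictly increasing")

    def onsets(self) -> dict[str, float | None]:
        return {"mild": self.mild, "moderate": self.moderate, "severe": self.severe, "recovery": self.recovery}

    def regime_at(self, t: float) -> str:
        """Name of the regime containing time ``t`` ('baseline' before the first onset)."""
        name = "baseline"
        for key in REGIME_NAMES:
            onset = getattr(self, key)
            if onset is not None and t >= onset:
                name = key
        return name


@dataclass
class AnalysisConfig:
    """Tunable parameters of the sliding-window analysis.

    ``window_length_T`` and ``window_shift_dT`` are in seconds (defaults
    20 min and 5 min, a 75% overlap); ``tau_grid`` holds integer sample
    lags; ``lt_band`` is the long-term scale band in seconds (closed).
    ``theiler_exclusion=None`` means "use the current lag".
    """

    window_length_T: float = 1200.0
    window_shift_dT: float = 300.0
    tau_grid: tuple[int, ...] = tuple(range(2, 129))
    lt_band: tuple[float, float] = (2.5, 8.0)
    entropy_neighbors: int = 5
    theiler_exclusion: int | None = None
    min_valid_fraction: float = 0.5
    min_entropy_pairs: int = 500
    sentinel_threshold: float = 2.5
    sentinel_run_length: int = 3
    alert_level: float = 2.0

    def __post_init__(self) -> None:
        self.tau_grid = tuple(int(t) for t in self.tau_grid)
        if self.window_shift_dT > self.window_length_T:
            raise ValueError("window_shift_dT must not exceed window_length_T")
        if not self.lt_band[0] < self.lt_band[1]:
            raise ValueError("lt_band must be an increasing pair")
        if any(t < 2 for t in self.tau_grid):
            raise ValueError("all lags must be >= 2 samples")
        if self.sentinel_threshold <= 0 or self.alert_level <= 0:
            raise ValueError("thresholds must be positive")

    def lt_lags(self, sample_rate: float) -> tuple[int, ...]:
        """Integer sample lags of ``tau_grid`` whose scale lies in the closed LT band."""
        lo, hi = self.lt_band
        eps = 1e-9
        return tuple(t for t in self.tau_grid
                     if lo * sample_rate - eps <= t <= hi * sample_rate + eps)

    def lt_only(self, sample_rate: float = 4.0) -> "AnalysisConfig":
        """Copy of the config whose lag grid is restricted to the LT band."""
        lo, hi = self.lt_band
        lags = tuple(range(max(2, math.ceil(lo * sample_rate - 1e-9)),
                           math.floor(hi * sample_rate + 1e-9) + 1))
        return replace(self, tau_grid=lags)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_rows(path: str | Path, n_cols: int, header_names: Sequence[str]) -> list[list[float]]:
    """Parse the fixed CSV dialect; returns rows of floats (NaN for blanks)."""
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 or not rows:
                # optional header
                lowered = [p.lower() for p in parts]
                if lowered[: len(header_names)] == list(header_names)[: len(parts)] or (
                    parts and not _is_number(parts[0])
                ):
                    if all(not _is_number(p) for p in parts if p):
                        continue
            if len(parts) < n_cols:
                parts = parts + [""] * (n_cols - len(parts))
            try:
                rows.append([float(p) if p != "" else math.nan for p in parts[:n_cols]])
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable row at line {lineno}: {raw.rstrip()}") from exc
    return rows


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_fhr_csv(path: str | Path, config: AnalysisConfig | None = None,
                 sample_rate: float = 4.0) -> FhrSeries:
    """Load a ``time_s,fhr_bpm`` table onto a uniform grid.

    Rows are snapped to the nearest grid point; grid points with no row, or
    with a non-finite value, are invalid.  No interpolation is performed.
    """
    rows = _read_rows(path, 2, ("time_s", "fhr_bpm"))
    return _table_to_series(rows, sample_rate, FhrSeries, path)


def load_abp_csv(path: str | Path, sample_rate: float = 4.0) -> AbpSeries:
    rows = _read_rows(path, 2, ("time_s", "abp_mmhg"))
    return _table_to_series(rows, sample_rate, AbpSeries, path)


def _table_to_series(rows: list[list[float]], sample_rate: float, cls, path) -> UniformSeries:
    if not rows:
        return cls(sample_rate=sample_rate, values=np.empty(0), valid_mask=np.empty(0, bool))
    times = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    if np.any(np.diff(times) < 0):
        raise ValueError(f"{path}: time column must be nondecreasing")
    start = times[0]
    idx = np.rint((times - start) * sample_rate).astype(int)
    n = int(idx[-1]) + 1
    values = np.full(n, np.nan)
    values[idx] = vals
    mask = np.zeros(n, bool)
    mask[idx] = np.isfinite(vals)
    return cls(sample_rate=sample_rate, values=values, valid_mask=mask, start_time=float(start))


def save_fhr_csv(series: UniformSeries, path: str | Path, value_name: str = "fhr_bpm") -> None:
    """Write a uniform series in the exchange dialect (invalid samples -> nan)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"time_s,{value_name}\n")
        for t, v, ok in zip(series.times, series.values, series.valid_mask):
            fh.write(f"{float(t)!r},{float(v)!r}\n" if ok else f"{float(t)!r},nan\n")


def save_abp_csv(series: AbpSeries, path: str | Path) -> None:
    save_fhr_csv(series, path, value_name="abp_mmHg")


def resample_rr(rr_event_times: np.ndarray, rr_values: np.ndarray,
                target_rate: float = 4.0, max_gap: float = 2.0) -> FhrSeries:
    """Convert beat events (times s, R-R intervals ms) to uniform heart rate.

    FHR = 60000 / RR (bpm), linearly interpolated between adjacent beats
    only where the inter-beat spacing is at most ``max_gap`` seconds.  Grid
    points inside longer gaps, or outside the span of beats, are invalid —
    no spline, no extrapolation, no fabricated samples.
    """
    t = np.asarray(rr_event_times, dtype=float)
    rr = np.asarray(rr_values, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("R-R intervals must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("beat event times must be strictly increasing")
    if t.size < 2:
        n = 0 if t.size == 0 else 1
        return FhrSeries(sample_rate=target_rate, values=np.full(n, np.nan),
                         valid_mask=np.zeros(n, bool), start_time=float(t[0]) if n else 0.0)
    bpm = 60000.0 / rr
    start = t[0]
    n = int(math.floor((t[-1] - start) * target_rate)) + 1
    grid = start + np.arange(n) / target_rate
    values = np.interp(grid, t, bpm)
    # invalidate grid points that fall strictly inside an over-long inter-beat gap
    seg = np.searchsorted(t, grid, side="right") - 1
    seg = np.clip(seg, 0, t.size - 2)
    nearest = np.clip(np.searchsorted(t, grid), 0, t.size - 1)
    on_beat = (np.abs(grid - t[nearest]) < 1e-9) | (np.abs(grid - t[np.maximum(nearest - 1, 0)]) < 1e-9)
    gap_len = t[seg + 1] - t[seg]
    mask = (gap_len <= max_gap) | on_beat
    values = np.where(mask, values, np.nan)
    return FhrSeries(sample_rate=target_rate, values=values, valid_mask=mask, start_time=float(start))


def load_metabolite_csv(path: str | Path):
    """Load a ``time_s,ph,lactate,be`` table into a :class:`MetaboliteSeries`."""
    from .metabolites import MetaboliteSeries

    rows = _read_rows(path, 4, ("time_s", "ph", "lactate", "be"))
    if not rows:
        raise ValueError(f"{path}: metabolite table has no rows")
    times = np.array([r[0] for r in rows])
    if np.any(np.diff(times) <= 0):
        if np.any(np.diff(times) == 0):
            raise ValueError(f"{path}: duplicate sample times")
        raise ValueError(f"{path}: sample times must be strictly increasing")
    return MetaboliteSeries(
        sample_times=times,
        ph=np.array([r[1] for r in rows]),
        lactate=np.array([r[2] for r in rows]),
        be=np.array([r[3] for r in rows]),
    )


def save_metabolite_csv(series, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,ph,lactate,be\n")
        for t, p, l, b in zip(series.sample_times, series.ph, series.lactate, series.be):
            fh.write(",".join("nan" if not np.isfinite(v) else repr(float(v))
                              for v in (t, p, l, b)) + "\n")


def load_schedule_csv(path: str | Path) -> RegimeSchedule:
    """Load a ``regime,onset_s`` table (regime names mild/moderate/severe/recovery)."""
    onsets: dict[str, float | None] = {k: None for k in REGIME_NAMES}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, _, val = line.partition(",")
            name = name.strip().lower()
            if name == "regime":
                continue
            if name not in onsets:
                raise ValueError(f"{path}: unknown regime {name!r} at line {lineno}")
            v = val.strip()
            onsets[name] = None if v.lower() in ("", "nan") else float(v)
    for key in ("moderate", "severe", "recovery"):
        if onsets[key] is None:
            raise ValueError(f"{path}: missing onset for regime {key!r}")
    return RegimeSchedule(**onsets)  # type: ignore[arg-type]


def save_schedule_csv(schedule: RegimeSchedule, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regime,onset_s\n")
        for name, onset in schedule.onsets().items():
            fh.write(f"{name},{'nan' if onset is None else repr(float(onset))}\n")
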