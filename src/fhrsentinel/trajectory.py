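"""Long-term feature aggregation, state vector, distance and sentinel.

Per window the four features are summed over the long-term (LT) scale band
(2.5–8 s by default, i.e. lags 10–32 samples at 4 Hz), normalized by
cohort-level standard deviations, and referenced to the subject's own first
valid window:

    u_k = (m_LT/m_rms, sigma_LT/sigma_rms, R_LT/R_rms, h_LT/h_rms)
    D_k = || u_k - u_0 ||_2

The sentinel fires at the first run of ``run_length`` consecutive windows
with ``D > threshold``; an invalid window breaks a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import WindowFeatureGrid
from .io import AnalysisConfig

__all__ = [
    "LtFeatureVector",
    "NormalizationConstants",
    "StateTrajectory",
    "SentinelResult",
    "lt_aggregate",
    "compute_normalization",
    "build_trajectory",
    "detect_sentinel",
    "TABLE_NORMALIZATION",
]

#: Cohort normalization constants reported for the original 14-animal study
#: (std of m_LT, sigma_LT, R_LT, h_LT over all animals and windows); usable
#: in "supplied" mode when no cohort is available for normalization.
TABLE_NORMALIZATION = (0.0155, 0.0282, 0.1630, 0.4127)

COMPONENTS = ("m_lt", "sigma_lt", "r_lt", "h_lt")


@dataclass
class LtFeatureVector:
    """LT-band sums of the four features for one window."""

    window_index: int
    t_k: float
    m_lt: float        # bpm * lags
    sigma_lt: float    # bpm * lags
    r_lt: float        # dimensionless sum
    h_lt: float        # nats * lags
    valid: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.m_lt, self.sigma_lt, self.r_lt, self.h_lt])


@dataclass
class NormalizationConstants:
    """Per-component RMS used to normalize the state vector."""

    m_lt: float
    sigma_lt: float
    r_lt: float
    h_lt: float
    source: str = "supplied"

    def __post_init__(self) -> None:
        if not all(v > 0 for v in self.as_array()):
            raise ValueError("all normalization constants must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.m_lt, self.sigma_lt, self.r_lt, self.h_lt])

    @classmethod
    def table_defaults(cls) -> "NormalizationConstants":
        return cls(*TABLE_NORMALIZATION, source="supplied")


@dataclass
class StateTrajectory:
    """Normalized state vectors and distances to the subject's reference state."""

    t_k: np.ndarray
    u: np.ndarray            # (K, 4), NaN rows where invalid
    u0: np.ndarray           # reference vector (4,)
    D: np.ndarray            # (K,), NaN where invalid
    valid: np.ndarray        # bool (K,)
    reference_index: int
    ph_at_windows: np.ndarray | None = None


@dataclass
class SentinelResult:
    t_D: float | None
    run_start_index: int | None
    threshold: float
    run_length: int

    @property
    def detected(self) -> bool:
        return self.t_D is not None


def lt_aggregate(grid: WindowFeatureGrid, lt_band=(2.5, 8.0),
                 sample_rate: float = 4.0) -> LtFeatureVector:
    """Sum each feature over all integer sample lags in the closed LT band.

    The vector is valid only if every contributing lag is valid for every
    feature (23 lags at 4 Hz for the default 2.5–8 s band).
    """
    lo, hi = lt_band
    eps = 1e-9
    taus = np.asarray(grid.tau_grid)
    in_band = (taus >= lo * sample_rate - eps) & (taus <= hi * sample_rate + eps)
    if not in_band.any():
        raise ValueError("the lag grid does not cover the LT band")
    vals = {}
    ok = True
    for name in ("m", "sigma", "R", "h"):
        arr = grid.feature(name)[in_band]
        ok = ok and bool(np.all(np.isfinite(arr)))
        vals[name] = float(arr.sum()) if np.all(np.isfinite(arr)) else math.nan
    return LtFeatureVector(
        window_index=grid.window_index, t_k=grid.window_center_time,
        m_lt=vals["m"], sigma_lt=vals["sigma"], r_lt=vals["R"], h_lt=vals["h"],
        valid=ok,
    )


def lt_aggregate_all(grids, config: AnalysisConfig | None = None,
                     sample_rate: float = 4.0) -> list[LtFeatureVector]:
    """Convenience: LT vectors for a whole recording's feature grids."""
    band = (config or AnalysisConfig()).lt_band
    return [lt_aggregate(g, band, sample_rate) for g in grids]


def compute_normalization(cohort: list[LtFeatureVector]) -> NormalizationConstants:
    """Population standard deviation per component over all valid (animal, window) vectors.

    ``cohort`` is the flat pool of LT vectors from every animal and window.
    """
    arr = np.array([v.as_array() for v in cohort if v.valid])
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 valid LT vectors to compute normalization")
    stds = arr.std(axis=0)  # population (divisor n)
    for name, s in zip(COMPONENTS, stds):
        if s <= 0:
            raise ValueError(f"zero spread in component {name}; cannot normalize")
    return NormalizationConstants(*stds, source="cohort-computed")


def build_trajectory(vectors: list[LtFeatureVector],
                     constants: NormalizationConstants) -> StateTrajectory:
    """Normalize LT vectors and compute distances to the first valid window."""
    if not any(v.valid for v in vectors):
        raise ValueError("no valid window; cannot build a trajectory")
    t_k = np.array([v.t_k for v in vectors])
    raw = np.array([v.as_array() for v in vectors])
    valid = np.array([v.valid for v in vectors])
    u = np.where(valid[:, None], raw / constants.as_array(), np.nan)
    ref = int(np.flatnonzero(valid)[0])
    u0 = u[ref].copy()
    D = np.where(valid, np.linalg.norm(u - u0, axis=1), np.nan)
    return StateTrajectory(t_k=t_k, u=u, u0=u0, D=D, valid=valid, reference_index=ref)


def detect_sentinel(traj: StateTrajectory, threshold: float = 2.5,
                    run: int = 3) -> SentinelResult:
    """First run of ``run`` consecutive valid windows with ``D > threshold``.

    ``t_D`` is the center time of the run's first window; absence (no such
    run) is a valid result.  Consecutive means consecutive window indices —
    a window with invalid D breaks a run.
    """
    if traj.D.size == 0:
        raise ValueError("empty trajectory")
    above = traj.valid & (traj.D > threshold)
    count = 0
    for i, flag in enumerate(above):
        count = count + 1 if flag else 0
        if count >= run:
            start = i - run + 1
            return SentinelResult(float(traj.t_k[start]), start, threshold, run)
    return SentinelResult(None, None, threshold, run)
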