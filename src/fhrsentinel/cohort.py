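"""Cohort-level analyses: pooled feature–metabolite correlations, blood-
pressure occlusion responses, rule-based decompensation timing, and the
sentinel-vs-decompensation comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AbpSeries, AnalysisConfig, RegimeSchedule
from .features import compute_feature_grid
from .metabolites import MetaboliteSeries, interpolate_metabolites, find_ph_crossing
from .trajectory import (LtFeatureVector, NormalizationConstants, StateTrajectory,
                         SentinelResult, build_trajectory, compute_normalization,
                         detect_sentinel, lt_aggregate_all)

__all__ = [
    "CohortRecord",
    "pooled_correlation",
    "delta_abp",
    "detect_cvd",
    "compare_sentinel_to_cvd",
    "analyze_cohort",
]


@dataclass
class CohortRecord:
    """One animal's analysis products, time-aligned to a shared clock."""

    animal_id: str
    hypoxic: bool
    grids: list = field(default_factory=list)
    lt_vectors: list[LtFeatureVector] = field(default_factory=list)
    trajectory: StateTrajectory | None = None
    sentinel: SentinelResult | None = None
    metabolites: MetaboliteSeries | None = None
    schedule: RegimeSchedule | None = None
    abp: AbpSeries | None = None
    occlusions: list = field(default_factory=list)
    t_cvd: float | None = None


def _record_feature_values(rec: CohortRecord, feature: str, tau: int | None) -> np.ndarray:
    """Per-window values of a feature selector for one record.

    ``feature`` is one of m/sigma/R/h (LT sums, or per-lag when ``tau`` is
    given) or ``D`` (distance).
    """
    if feature == "D":
        if rec.trajectory is None:
            raise ValueError("record has no trajectory")
        return rec.trajectory.D
    if tau is not None:
        vals = []
        for g in rec.grids:
            arr = g.feature(feature)
            i = int(np.flatnonzero(np.asarray(g.tau_grid) == tau)[0])
            vals.append(arr[i])
        return np.asarray(vals, float)
    key = {"m": "m_lt", "sigma": "sigma_lt", "R": "r_lt", "h": "h_lt"}[feature]
    return np.array([getattr(v, key) if v.valid else math.nan for v in rec.lt_vectors])


def pooled_correlation(cohort: list[CohortRecord], feature: str, analyte: str,
                       tau: int | None = None) -> tuple[float, int]:
    """Pearson correlation over all valid (animal, window) pairs.

    The analyte is interpolated at each window's center time; pairs where
    either margin is missing are dropped.  Returns ``(r, n_pairs)``.
    """
    xs, ys = [], []
    for rec in cohort:
        if rec.metabolites is None:
            continue
        t_k = np.array([v.t_k for v in rec.lt_vectors]) if rec.lt_vectors else \
            (rec.trajectory.t_k if rec.trajectory is not None else None)
        if t_k is None:
            continue
        fv = _record_feature_values(rec, feature, tau)
        av = interpolate_metabolites(rec.metabolites, t_k)[analyte]
        ok = np.isfinite(fv) & np.isfinite(av)
        xs.append(fv[ok])
        ys.append(av[ok])
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if x.size < 3:
        raise ValueError("need at least 3 pooled pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a correlation margin")
    r = float(stats.pearsonr(x, y).statistic)
    return r, int(x.size)


def delta_abp(abp: AbpSeries, occlusion_intervals: list[tuple[float, float]]) -> np.ndarray:
    """Per-occlusion pressure differential ABP_max(occlusion) - <ABP>(preceding gap).

    The reference is the mean pressure over the inter-occlusion segment
    immediately preceding each occlusion (from the recording start for the
    first one).  NaN where a needed segment has no valid sample.
    """
    fs = abp.sample_rate
    out = np.full(len(occlusion_intervals), np.nan)
    prev_end = abp.start_time
    for i, (a, b) in enumerate(occlusion_intervals):
        i0 = int(round((a - abp.start_time) * fs))
        i1 = int(round((b - abp.start_time) * fs))
        j0 = int(round((prev_end - abp.start_time) * fs))
        occ = abp.values[i0:i1][abp.valid_mask[i0:i1]]
        gap = abp.values[j0:i0][abp.valid_mask[j0:i0]]
        if occ.size and gap.size:
            out[i] = occ.max() - gap.mean()
        prev_end = b
    return out


def detect_cvd(deltas, occlusion_starts, run: int = 3,
               threshold: float = 0.0) -> float | None:
    """Rule-based decompensation time from per-occlusion pressure responses.

    Finds the earliest run of ``run`` consecutive occlusions whose response
    fails to rise above the preceding baseline (``delta <= threshold``) and
    returns the start time of the run's first occlusion; ``None`` if no
    such run.  A NaN response breaks a run.
    """
    deltas = np.asarray(deltas, float)
    starts = np.asarray(occlusion_starts, float)
    if deltas.size < run:
        return None
    count = 0
    for i, d in enumerate(deltas):
        count = count + 1 if (np.isfinite(d) and d <= threshold) else 0
        if count >= run:
            return float(starts[i - run + 1])
    return None


def _hhmm(seconds: float) -> str:
    sign = "-" if seconds < 0 else ""
    mins = int(round(abs(seconds) / 60.0))
    return f"{sign}{mins // 60:02d}:{mins % 60:02d}"


def compare_sentinel_to_cvd(t_D: float | None, t_CVD: float | None,
                            t_pH: float | None = None) -> dict:
    """Signed timing differences t_CVD - t_D and t_pH - t_CVD (s and hh:mm)."""
    out: dict = {"t_D_s": t_D, "t_CVD_s": t_CVD, "t_pH_s": t_pH,
                 "cvd_minus_d_s": None, "cvd_minus_d_hhmm": None,
                 "ph_minus_cvd_s": None, "ph_minus_cvd_hhmm": None}
    if t_D is not None and t_CVD is not None:
        d = t_CVD - t_D
        out["cvd_minus_d_s"] = float(d)
        out["cvd_minus_d_hhmm"] = _hhmm(d)
    if t_pH is not None and t_CVD is not None:
        d = t_pH - t_CVD
        out["ph_minus_cvd_s"] = float(d)
        out["ph_minus_cvd_hhmm"] = _hhmm(d)
    return out


def analyze_cohort(recordings, config: AnalysisConfig | None = None,
                   constants: NormalizationConstants | None = None,
                   lt_only: bool = True) -> list[CohortRecord]:
    """Full pipeline over synthetic (or loaded) recordings.

    Features -> LT aggregation -> cohort normalization (unless ``constants``
    supplied) -> per-animal trajectory and sentinel -> pressure-based
    decompensation time where arterial pressure is present.  ``lt_only``
    restricts the lag grid to the LT band (all the distance metric needs),
    which keeps the nearest-neighbor entropy estimation affordable.
    """
    config = config or AnalysisConfig()
    records: list[CohortRecord] = []
    for i, rec in enumerate(recordings):
        fs = rec.fhr.sample_rate
        cfg = config.lt_only(fs) if lt_only else config
        grids = compute_feature_grid(rec.fhr, cfg)
        record = CohortRecord(
            animal_id=f"syn{i:03d}",
            hypoxic=getattr(rec.params, "hypoxic", False),
            grids=grids,
            lt_vectors=lt_aggregate_all(grids, cfg, fs),
            metabolites=rec.metabolites,
            schedule=rec.schedule,
            abp=rec.abp,
            occlusions=list(rec.occlusions),
        )
        records.append(record)
    if constants is None:
        pool = [v for r in records for v in r.lt_vectors]
        constants = compute_normalization(pool)
    for record in records:
        record.trajectory = build_trajectory(record.lt_vectors, constants)
        record.sentinel = detect_sentinel(record.trajectory,
                                          config.sentinel_threshold,
                                          config.sentinel_run_length)
        if record.abp is not None and record.occlusions:
            deltas = delta_abp(record.abp, record.occlusions)
            record.t_cvd = detect_cvd(deltas, [a for a, _ in record.occlusions])
    return records
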