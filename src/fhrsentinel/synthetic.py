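"""Synthetic umbilical-cord-occlusion recordings.

Simulates labor-like experiments so the whole analysis chain is testable
without animal data: a 4 Hz heart-rate trace with regime-scheduled
decelerations (1 min every 2.5 min; mild ~-30 bpm, moderate ~-60 bpm,
severe down to a floor), short-range-correlated variability whose
amplitude grows and whose temporal correlation rises (lowering the entropy
rate) as acidemia progresses, a piecewise-linear pH decline crossing 7.00
in the severe regime with matching lactate / base-excess trends,
arterial-pressure responses that convert from hypertensive to hypotensive
at the injected decompensation time and stay converted, and regime-
dependent missing-data rates.

The physiological default values (baseline 160 bpm, 40 mmHg mean arterial
pressure, pH 7.35 -> nadir 6.88, and the noise ramps) are this module's own
choices of a realistic healthy near-term fetus; they are configurable and
documented in the methods note.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import AbpSeries, FhrSeries, RegimeSchedule
from .metabolites import MetaboliteSeries

__all__ = ["SimulationParams", "SyntheticRecording", "simulate_recording", "simulate_cohort"]


@dataclass
class SimulationParams:
    """Ground-truth generator settings (one recording).

    Durations are minutes, depths bpm, pressures mmHg.  ``dropout_rates``
    are per-regime missing-sample probabilities for
    (baseline, mild, moderate, severe, recovery).
    """

    seed: int = 0
    sample_rate: float = 4.0
    baseline_fhr: float = 160.0
    baseline_minutes: float = 120.0
    mild_minutes: float = 60.0
    moderate_minutes: float = 60.0
    severe_minutes: float = 110.0
    recovery_minutes: float = 30.0
    occlusion_period_s: float = 150.0
    occlusion_duration_s: float = 60.0
    mild_depth_bpm: float = 30.0
    moderate_depth_bpm: float = 60.0
    severe_floor_bpm: float = 45.0
    decel_ramp_s: float = 30.0
    depth_jitter_frac: float = 0.15
    decel_onset_jitter_s: float = 8.0
    decel_duration_jitter_s: float = 8.0
    # variability model: AR(1) noise, marginal sd and lag-1 coefficient ramp
    # with acidemia severity s(t) in [0, 1]; the marginal sd additionally
    # cycles slowly (behavioral-state cycling of heart-rate variability)
    noise_sd_bpm: float = 8.0
    noise_sd_gain: float = 0.9
    noise_phi: float = 0.88
    noise_phi_gain: float = 0.08
    state_cycle_amplitude: float = 0.55
    state_cycle_period_s: float = 2220.0
    state_cycle_phase: float = 0.0
    decel_sd_boost_per_bpm: float = 0.02
    surge_phi: float = 0.75
    # within-deceleration shape irregularity (variable decelerations):
    # relative smooth modulation of the depth profile, fading to zero as
    # the response stereotypes near decompensation
    shape_irregularity: float = 0.15
    shape_phi: float = 0.97
    # fraction of occlusions (while compensating) that evoke only a
    # partial deceleration response
    response_failure_prob: float = 0.35
    # slow baseline wander (fetal behavioral state; bpm, s)
    wander_amplitude_bpm: float = 1.5
    wander_period_s: float = 2600.0
    bradycardia_drift_bpm: float = 35.0
    drift_ph_start: float = 7.28
    # metabolite trajectory (piecewise linear in time through regime knots)
    ph_start: float = 7.35
    ph_baseline_end: float = 7.33
    ph_mild_end: float = 7.30
    ph_moderate_end: float = 7.25
    ph_nadir: float = 6.88
    ph_recovery_end: float = 6.92
    lactate_start: float = 1.5
    lactate_per_ph: float = 24.0      # mmol/L rise per unit pH fall
    be_start: float = 3.0
    be_per_ph: float = 40.0           # mmol/L fall per unit pH fall
    blood_sample_interval_min: float = 20.0
    # decompensation: anchored at the pH = 7.20 crossing, offset in minutes
    cvd_anchor_ph: float = 7.20
    cvd_offset_min: float = 0.0
    # acidemia-severity ramp driving the FHR dynamics: 0 above
    # ph_severity_start, 1 below ph_severity_full (deterioration is a
    # threshold phenomenon concentrated around decompensation)
    ph_severity_start: float = 7.25
    ph_severity_full: float = 7.15
    # arterial pressure
    abp_baseline: float = 40.0
    abp_noise_sd: float = 1.0
    abp_hypertensive_bump: float = 12.0
    abp_hypotensive_drop: float = 8.0
    dropout_rates: tuple[float, ...] = (0.03, 0.02, 0.04, 0.15, 0.03)
    # signal loss during profound decelerations: the transducer loses the
    # trace when the heart rate collapses, so missing data concentrates at
    # deep deceleration bottoms (probability ramps up beyond the onset
    # depth over the given width)
    signal_loss_onset_bpm: float = 85.0
    signal_loss_width_bpm: float = 8.0
    signal_loss_max: float = 0.65
    mild_absent: bool = False
    hypoxic: bool = False
    hypoxic_variability_factor: float = 0.85

    def __post_init__(self) -> None:
        for name in ("baseline_minutes", "moderate_minutes", "severe_minutes",
                     "recovery_minutes", "occlusion_period_s", "occlusion_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(not 0 <= r < 1 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if not self.ph_nadir < 7.00 < self.ph_start:
            raise ValueError("pH must start above 7.00 and reach a nadir below it")
        if min(self.mild_depth_bpm, self.moderate_depth_bpm) < 0:
            raise ValueError("deceleration depths must be non-negative")


@dataclass
class SyntheticRecording:
    fhr: FhrSeries
    abp: AbpSeries
    metabolites: MetaboliteSeries
    schedule: RegimeSchedule
    truth: dict
    params: SimulationParams
    occlusions: list = field(default_factory=list)  # (start_s, end_s, regime)

    def write(self, directory: str | Path) -> None:
        """Emit the exchange CSV dialects plus a ground-truth JSON."""
        from . import io as fio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fio.save_fhr_csv(self.fhr, directory / "fhr.csv")
        fio.save_abp_csv(self.abp, directory / "abp.csv")
        fio.save_metabolite_csv(self.metabolites, directory / "metabolites.csv")
        fio.save_schedule_csv(self.schedule, directory / "schedule.csv")
        truth = dict(self.truth)
        truth["params"] = asdict(self.params)
        with open(directory / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1)


def _regime_spans(p: SimulationParams) -> list[tuple[str, float, float]]:
    spans = []
    t = 0.0
    order = [("baseline", p.baseline_minutes)]
    if not p.mild_absent:
        order.append(("mild", p.mild_minutes))
    order += [("moderate", p.moderate_minutes), ("severe", p.severe_minutes),
              ("recovery", p.recovery_minutes)]
    for name, minutes in order:
        spans.append((name, t, t + minutes * 60.0))
        t += minutes * 60.0
    return spans


def _ph_curve(p: SimulationParams, spans) -> tuple[np.ndarray, np.ndarray]:
    """Knot times/values of the underlying (noise-free) pH trajectory."""
    end = {name: e for name, _, e in spans}
    knots_t = [0.0, end["baseline"]]
    knots_v = [p.ph_start, p.ph_baseline_end]
    if "mild" in end:
        knots_t.append(end["mild"])
        knots_v.append(p.ph_mild_end)
    knots_t += [end["moderate"], end["severe"], end["recovery"]]
    knots_v += [p.ph_moderate_end, p.ph_nadir, p.ph_recovery_end]
    return np.array(knots_t), np.array(knots_v)


def _crossing_time(kt: np.ndarray, kv: np.ndarray, level: float) -> float:
    """First downward crossing of a piecewise-linear curve."""
    for i in range(1, kt.size):
        if kv[i - 1] > level >= kv[i]:
            frac = (kv[i - 1] - level) / (kv[i - 1] - kv[i])
            return float(kt[i - 1] + frac * (kt[i] - kt[i - 1]))
    raise ValueError(f"pH curve never crosses {level}")


def _severity(ph: np.ndarray, start: float = 7.25, full: float = 7.15) -> np.ndarray:
    """Acidemia severity ramp: 0 while pH >= start, 1 at pH <= full."""
    return np.clip((start - ph) / (start - full), 0.0, 1.0)


def _decel_shape(n: int, ramp: int) -> np.ndarray:
    """Trapezoid in [0, 1]: half-cosine ramps of ``ramp`` samples at each edge."""
    shape = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        edge = 0.5 * (1 - np.cos(np.linspace(0, math.pi, r)))
        shape[:r] = edge
        shape[n - r:] = edge[::-1]
    return shape


def simulate_recording(params: SimulationParams | None = None) -> SyntheticRecording:
    """One deterministic (seeded) synthetic occlusion experiment."""
    p = params or SimulationParams()
    rng = np.random.default_rng(p.seed)
    fs = p.sample_rate
    spans = _regime_spans(p)
    total_s = spans[-1][2]
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    kt, kv = _ph_curve(p, spans)
    ph_t = np.interp(t, kt, kv)
    sev = _severity(ph_t, p.ph_severity_start, p.ph_severity_full)
    t_ph = _crossing_time(kt, kv, 7.00)
    t_cvd = _crossing_time(kt, kv, p.cvd_anchor_ph) + p.cvd_offset_min * 60.0

    # baseline drifts down with acidemia (progressive bradycardia),
    # proportional to the pH fall below drift_ph_start
    drift_sev = np.clip((p.drift_ph_start - ph_t) / (p.drift_ph_start - p.ph_nadir), 0.0, 1.0)
    wander = p.wander_amplitude_bpm * np.sin(
        2 * math.pi * t / p.wander_period_s + rng.uniform(0.0, 2 * math.pi))
    baseline = p.baseline_fhr - p.bradycardia_drift_bpm * drift_sev + wander

    # occlusion schedule: one occlusion per period, from mild (or moderate) on
    occlusions: list[tuple[float, float, str]] = []
    for name, s0, s1 in spans:
        if name in ("baseline", "recovery"):
            continue
        k = 0
        while s0 + k * p.occlusion_period_s + p.occlusion_duration_s <= s1 + 1e-9:
            a = s0 + k * p.occlusion_period_s
            occlusions.append((a, a + p.occlusion_duration_s, name))
            k += 1

    # deceleration waveform; decelerations are highly variable (depth,
    # timing, ramp shape) while the fetus compensates, and become
    # stereotyped deep plunges as decompensation approaches — loss of the
    # adaptive variability of the response
    decel = np.zeros(n)
    for a, b, name in occlusions:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        if name == "mild":
            depth = p.mild_depth_bpm
        elif name == "moderate":
            depth = p.moderate_depth_bpm
        else:
            depth = max(baseline[i0] - p.severe_floor_bpm, p.moderate_depth_bpm)
        j = 1.0 - sev[i0]  # jitter scale: 1 compensating, 0 decompensating
        depth *= max(1.0 + p.depth_jitter_frac * j * rng.standard_normal(), 0.1)
        if rng.random() < p.response_failure_prob * j:
            depth *= rng.uniform(0.25, 0.6)
        # the waveform bottom stays above the saturation zone of the floor
        depth = min(depth, baseline[i0] - 40.0)
        # waveform jitter stays inside the scheduled occlusion interval;
        # ramps steepen as the response stereotypes
        delay = int(round(rng.uniform(0.0, p.decel_onset_jitter_s * j + 1e-9) * fs))
        shorten = int(round(rng.uniform(0.0, p.decel_duration_jitter_s * j + 1e-9) * fs))
        ramp = int(round(p.decel_ramp_s * (0.55 + 0.45 * j)
                         * (1.0 + 0.8 * j * rng.uniform(-1.0, 1.0)) * fs))
        j0 = min(i0 + delay, i1 - 1)
        j1 = max(i1 - shorten, j0 + 1)
        shape = depth * _decel_shape(j1 - j0, ramp)
        if p.shape_irregularity > 0 and j > 0:
            # each occlusion produces its own jagged depth path while the
            # fetus still mounts a variable response
            wig = _ar1(rng, j1 - j0, p.shape_phi, 1.0)
            shape = shape * np.clip(1.0 + p.shape_irregularity * j * wig, 0.1, None)
        decel[j0:j1] = np.maximum(decel[j0:j1], shape)

    # short-range-correlated variability, two components:
    #  * a global AR(1) whose marginal sd grows and whose lag-1 coefficient
    #    rises with acidemia severity (raising lag correlation at the LT
    #    scales lowers the entropy rate there);
    #  * a deceleration-proportional "surge" AR(1) (variability bursts
    #    during occlusions) that, like the deceleration shape itself, fades
    #    away as decompensation approaches.
    regime_depth = np.zeros(n)
    for name, s0, s1 in spans:
        i0, i1 = int(round(s0 * fs)), int(round(s1 * fs))
        if name == "mild":
            regime_depth[i0:i1] = p.mild_depth_bpm
        elif name == "moderate":
            regime_depth[i0:i1] = p.moderate_depth_bpm
        elif name == "severe":
            regime_depth[i0:i1] = np.maximum(baseline[i0:i1] - p.severe_floor_bpm,
                                             p.moderate_depth_bpm)
    # chronic hypoxia lowers the variability of the pre-occlusion baseline
    var_scale = np.where(t < (spans[0][2]),
                         p.hypoxic_variability_factor if p.hypoxic else 1.0, 1.0)
    # behavioral-state cycling of variability, suppressed while the
    # occlusion series is running (labor stress overrides state cycling)
    cycle_amp = p.state_cycle_amplitude * np.where(regime_depth > 0, 0.3, 1.0)
    cycle = 1.0 + cycle_amp * np.sin(
        2 * math.pi * t / p.state_cycle_period_s + p.state_cycle_phase)
    phi_target = min(p.noise_phi + p.noise_phi_gain, 0.995)
    # marginal variability grows with occlusion-driven stress
    sd_global = np.maximum(
        var_scale * p.noise_sd_bpm * cycle * (1.0 + p.noise_sd_gain * sev), 0.5)
    phi_global = p.noise_phi + (phi_target - p.noise_phi) * sev
    sd_surge = var_scale * p.noise_sd_bpm * p.decel_sd_boost_per_bpm * decel * (1.0 - sev)
    noise = (_ar1_varying(rng, sd_global, phi_global)
             + _ar1_varying(rng, sd_surge, np.full(n, p.surge_phi)))

    # smooth saturation toward a physiological floor (a hard clip would
    # create exact duplicate samples, which no real tachogram has)
    raw = baseline - decel + noise
    w = 3.0
    fhr_vals = 25.0 + w * np.logaddexp(0.0, (raw - 25.0) / w)
    # small acquisition jitter: monitors quantize at ~0.25 bpm and the
    # 4 Hz resampling leaves residual wiggle; keeps no stretch perfectly flat
    fhr_vals = fhr_vals + 0.05 * rng.standard_normal(n)

    # regime-dependent dropout
    rate_map = dict(zip(("baseline", "mild", "moderate", "severe", "recovery"),
                        p.dropout_rates))
    p_drop = np.zeros(n)
    for name, s0, s1 in spans:
        i0, i1 = int(round(s0 * fs)), int(round(s1 * fs))
        p_drop[i0:i1] = rate_map[name]
    if p.signal_loss_max > 0:
        depth_gate = 1.0 / (1.0 + np.exp(-(decel - p.signal_loss_onset_bpm)
                                         / p.signal_loss_width_bpm))
        # the transducer re-locks slowly: the loss zone extends past the
        # deceleration bottom into the recovery limb
        relock = int(round(15.0 * fs))
        dilated = np.copy(depth_gate)
        for shift in range(4, relock + 1, 4):
            dilated[shift:] = np.maximum(dilated[shift:], depth_gate[:-shift])
        p_loss = p.signal_loss_max * dilated
        p_drop = 1.0 - (1.0 - p_drop) * (1.0 - p_loss)
    mask = rng.random(n) >= p_drop
    fhr = FhrSeries(sample_rate=fs, values=np.where(mask, fhr_vals, np.nan),
                    valid_mask=mask)

    # arterial pressure: hypertensive bumps per occlusion, converting to a
    # persistent hypotensive pattern at the injected decompensation time
    abp_vals = p.abp_baseline + _ar1(rng, n, 0.9, p.abp_noise_sd)
    scale = {"mild": 0.6, "moderate": 0.8, "severe": 1.0}
    for a, b, name in occlusions:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        if a < t_cvd:
            bump = p.abp_hypertensive_bump * scale[name]
            abp_vals[i0:i1] += bump * np.sin(np.linspace(0, math.pi, i1 - i0))
        else:
            abp_vals[i0:i1] -= p.abp_hypotensive_drop
    abp = AbpSeries(sample_rate=fs, values=abp_vals, valid_mask=np.ones(n, bool))

    # blood samples every 20 min plus the protocol end
    sample_times = np.arange(0.0, total_s, p.blood_sample_interval_min * 60.0)
    if total_s - sample_times[-1] > 60.0:
        sample_times = np.append(sample_times, total_s - 1.0)
    ph_s = np.interp(sample_times, kt, kv)
    lact = p.lactate_start + p.lactate_per_ph * (p.ph_start - ph_s) \
        + 0.05 * rng.standard_normal(sample_times.size)
    be = p.be_start - p.be_per_ph * (p.ph_start - ph_s) \
        + 0.1 * rng.standard_normal(sample_times.size)
    metab = MetaboliteSeries(sample_times=sample_times, ph=ph_s,
                             lactate=np.maximum(lact, 0.3), be=be)

    onset = {name: s0 for name, s0, _ in spans}
    schedule = RegimeSchedule(mild=onset.get("mild"), moderate=onset["moderate"],
                              severe=onset["severe"], recovery=onset["recovery"])
    truth = {"t_cvd_s": float(t_cvd), "t_ph_s": float(t_ph), "seed": int(p.seed)}
    return SyntheticRecording(fhr=fhr, abp=abp, metabolites=metab,
                              schedule=schedule, truth=truth, params=p,
                              occlusions=[(a, b) for a, b, _ in occlusions])


def _ar1_varying(rng, sd_t: np.ndarray, phi_t: np.ndarray) -> np.ndarray:
    """AR(1) with time-varying coefficient, scaled to marginal sd ``sd_t``."""
    n = sd_t.size
    innov = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = sd_t[0] * innov[0]
    innov_sd = sd_t * np.sqrt(1.0 - phi_t ** 2)
    for i in range(1, n):
        out[i] = phi_t[i] * out[i - 1] + innov_sd[i] * innov[i]
    return out


def _ar1(rng, n: int, phi: float, sd: float) -> np.ndarray:
    from scipy.signal import lfilter

    innov = rng.standard_normal(n) * sd * math.sqrt(1 - phi ** 2)
    innov[0] = sd * rng.standard_normal()
    return lfilter([1.0], [1.0, -phi], innov)


def simulate_cohort(n: int = 14, params: SimulationParams | None = None,
                    hypoxic_fraction: float = 5.0 / 14.0,
                    master_seed: int | None = None) -> list[SyntheticRecording]:
    """Cohort of ``n`` recordings with per-animal jittered physiology.

    The first ``round(n * hypoxic_fraction)`` animals carry the chronic-
    hypoxia label (lowered baseline variability).  Jitters (baseline level,
    variability, state-cycle timing, regime durations, decompensation
    offset) are drawn from the master seed, so two cohorts with the same
    master seed are identical.  Regime durations are jittered in whole
    occlusion periods, as in the timed occlusion protocol.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    base = params or SimulationParams()
    if master_seed is None:
        master_seed = base.seed
    rng = np.random.default_rng(master_seed)
    n_hypoxic = int(round(n * hypoxic_fraction))
    period_min = base.occlusion_period_s / 60.0

    def _period_multiple(minutes: float, lo: float, hi: float) -> float:
        return max(period_min, round(minutes * rng.uniform(lo, hi) / period_min) * period_min)

    cohort = []
    for i in range(n):
        seed_i = int(rng.integers(2 ** 31))
        # individual cardiovascular reactivity: deceleration depths and
        # variability scale together, so the depth-to-variability ratio
        # (which shapes the window features) is a cohort property, not a
        # per-animal accident
        react = rng.uniform(0.75, 1.25)
        p = replace(
            base,
            seed=seed_i,
            hypoxic=i < n_hypoxic,
            baseline_fhr=base.baseline_fhr + rng.normal(0.0, 8.0),
            noise_sd_bpm=base.noise_sd_bpm * react * rng.uniform(0.9, 1.15),
            noise_phi=min(base.noise_phi + rng.uniform(-0.04, 0.04), 0.93),
            mild_depth_bpm=base.mild_depth_bpm * react,
            moderate_depth_bpm=base.moderate_depth_bpm * react,
            state_cycle_period_s=rng.uniform(1800.0, 2700.0),
            state_cycle_phase=rng.uniform(0.0, 2 * math.pi),
            baseline_minutes=_period_multiple(base.baseline_minutes, 0.55, 1.0),
            severe_minutes=_period_multiple(base.severe_minutes, 0.9, 1.1),
            cvd_offset_min=base.cvd_offset_min + rng.normal(0.0, 3.0),
        )
        cohort.append(simulate_recording(p))
    return cohort
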