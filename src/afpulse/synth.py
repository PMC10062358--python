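"""Synthetic paired ECG/PPG/accelerometer cohort generator.

Emulates the measurement setting of a persistent-AF rate-control study:
each patient wears a Holter ECG (reference beat times) together with a
wrist smartwatch recording a 25 Hz multi-channel PPG and a 50 Hz 3-axis
accelerometer over >= 24 h. The generator reproduces the statistical
features the downstream analysis depends on:

* irregularly irregular AF RR intervals (serially independent log-normal
  draws, day/night means switched on the wall-clock schedule, RMSSD
  calibrated via RMSSD = sqrt(2)*SD for iid intervals);
* rate-dependent pulse deficit — pulse amplitude follows the diastolic
  filling law A_i = A_max * (1 - exp(-RR_{i-1}/tau)), so beats after
  short intervals produce weak peripheral pulses that beat detection can
  miss, biasing PPG heart rate low at fast rates;
* motion-artefact bursts co-timed between accelerometer and PPG noise;
* minute-level quality dropouts (PPG replaced by noise) at a configured
  fraction, with the true quality label retained as ground truth;
* a day/night activity schedule (sleep 23:00-07:00 local) driving both
  the RR regime and the motion schedule.

Everything is deterministic given (SimConfig, seed): per-patient streams
are derived with numpy SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from afpulse.config import SimConfig

# Fixed physical / morphology constants (not study parameters).
GRAVITY = 9.81  # m/s^2
PULSE_TRANSIT_DELAY = 0.25  # s, beat time -> peripheral pulse foot
A_MAX = 1.0
_SYS_CENTER, _SYS_WIDTH = 0.15, 0.05  # systolic peak, s
_DIC_CENTER, _DIC_WIDTH, _DIC_AMP = 0.42, 0.07, 0.18  # dicrotic bump
_NOISE_FLOOR_SD = 0.03
_DROPOUT_NOISE_SD = 0.35
_ARTEFACT_GAIN = 1.5  # PPG noise SD per (m/s^2) of motion intensity
_ARTEFACT_DEADBAND = 0.05  # ambient motion below this adds no PPG noise
_SLEEP_START_H, _SLEEP_END_H = 23.0, 7.0


@dataclass
class PatientProfile:
    """Per-patient generative parameters and schedules.

    ``motion_schedule`` rows are (start_s, end_s, intensity) in seconds
    relative to recording start; intensity is the extra acceleration
    amplitude in m/s^2 riding on gravity. ``dropout_minutes`` and
    ``ecg_bad_minutes`` index minutes whose PPG (resp. ECG) is unusable.
    """

    patient_id: str
    chf_flag: bool
    day_rr_params: tuple[float, float]  # (mean, sd) of RR in seconds
    night_rr_params: tuple[float, float]
    motion_schedule: np.ndarray  # (k, 3) start, end, intensity
    dropout_minutes: np.ndarray
    ecg_bad_minutes: np.ndarray
    start_s: float  # seconds since local midnight at recording start
    duration_h: float

    def __post_init__(self) -> None:
        if len(self.motion_schedule) and np.any(self.motion_schedule[:, 2] < 0):
            raise ValueError("motion intensities must be >= 0")


@dataclass
class RhythmTrace:
    """Reference beat times (seconds from recording start)."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if len(bt) > 1:
            d = np.diff(bt)
            if np.any(d <= 0):
                raise ValueError("beat times must be strictly increasing")
            if d.min() < 0.25 - 1e-9 or d.max() > 4.0 + 1e-9:
                raise ValueError("beat intervals must lie in [0.25, 4.0] s")
        self.beat_times = bt

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)


@dataclass
class SensorBundle:
    """Smartwatch streams with a wall-clock anchor for day/night labels."""

    ppg: np.ndarray  # (n_samples, n_channels)
    ppg_rate: float
    accel: np.ndarray  # (n_samples, 3)
    accel_rate: float
    start_s: float  # seconds since local midnight

    def __post_init__(self) -> None:
        span_ppg = self.ppg.shape[0] / self.ppg_rate
        span_acc = self.accel.shape[0] / self.accel_rate
        tol = max(1.0 / self.ppg_rate, 1.0 / self.accel_rate)
        if abs(span_ppg - span_acc) > tol:
            raise ValueError("ppg and accel must cover the same span")


@dataclass
class PatientRecord:
    """One patient's paired streams plus simulation ground truth."""

    profile: PatientProfile
    rhythm: RhythmTrace
    sensors: SensorBundle
    truth_minutes: pd.DataFrame = field(repr=False)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _is_sleep(t_abs: np.ndarray | float) -> np.ndarray | bool:
    """Sleep schedule: local [23:00, 07:00)."""
    hour = (np.asarray(t_abs) / 3600.0) % 24.0
    return (hour >= _SLEEP_START_H) | (hour < _SLEEP_END_H)


def _regime_segments(start_s: float, total_s: float) -> list[tuple[float, float, bool]]:
    """Split [0, total_s) at sleep/wake wall-clock transitions."""
    edges = [0.0]
    for day in range(int(np.ceil((start_s + total_s) / 86400.0)) + 1):
        for h in (_SLEEP_END_H, _SLEEP_START_H):
            t = day * 86400.0 + h * 3600.0 - start_s
            if 0.0 < t < total_s:
                edges.append(t)
    edges.append(total_s)
    edges = sorted(set(edges))
    return [
        (a, b, bool(_is_sleep(start_s + (a + b) / 2.0)))
        for a, b in zip(edges[:-1], edges[1:])
    ]


def simulate_af_rr(
    profile: PatientProfile,
    duration_h: float,
    seed: int,
) -> RhythmTrace:
    """Draw AF beat times over ``duration_h`` hours.

    Intervals are independent log-normal draws from the day or night
    distribution selected by the wall-clock sleep schedule, clipped to
    the physiologic range [0.25, 4.0] s. Serial independence is a
    deliberate simplification of AF; it yields near-zero lag-1 interval
    autocorrelation, consistent with the irregularly irregular rhythm.
    """
    if duration_h <= 0:
        raise ValueError(f"duration must be positive, got {duration_h}")
    rng = np.random.default_rng(seed)
    total = duration_h * 3600.0
    times: list[np.ndarray] = []
    t = 0.0
    for _a, b, sleeping in _regime_segments(profile.start_s, total):
        mean, sd = profile.night_rr_params if sleeping else profile.day_rr_params
        mu, sigma = _lognormal_params(mean, sd)
        while t < b:
            chunk = np.clip(rng.lognormal(mu, sigma, size=512), 0.25, 4.0)
            beats = t + np.cumsum(chunk)
            inside = beats[beats <= b]
            if len(inside):
                times.append(inside)
                t = inside[-1]
            if len(inside) < len(beats):
                break  # crossed the regime boundary; beat past it dropped
    beat_times = np.concatenate(times) if times else np.array([])
    return RhythmTrace(beat_times=beat_times)


def pulse_amplitudes(
    rr_prev: np.ndarray, tau: float, a_max: float = A_MAX
) -> np.ndarray:
    """Diastolic filling law: A_i = A_max * (1 - exp(-RR_{i-1}/tau)).

    Monotone increasing in the preceding interval, so short diastole
    (fast, irregular rates) yields weak peripheral pulses — the pulse
    deficit. Larger tau means slower refilling, hence a stronger deficit.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return a_max * (1.0 - np.exp(-np.asarray(rr_prev, dtype=float) / tau))


def _intensity_envelope(
    schedule: np.ndarray, n: int, rate: float
) -> np.ndarray:
    """Per-sample motion intensity: max over overlapping schedule rows."""
    env = np.zeros(n, dtype=np.float32)
    for s, e, inten in schedule:
        i0 = max(0, int(np.floor(s * rate)))
        i1 = min(n, int(np.ceil(e * rate)))
        if i1 > i0:
            np.maximum(env[i0:i1], inten, out=env[i0:i1])
    return env


def render_ppg(
    rhythm: RhythmTrace,
    profile: PatientProfile,
    config: SimConfig,
    seed: int,
) -> np.ndarray:
    """Render the (n_samples, n_channels) 25 Hz PPG waveform.

    Each beat contributes a pulse template (systolic peak + dicrotic
    bump) at beat time + transit delay, scaled by the filling law
    A_i = A_max*(1 - exp(-RR_{i-1}/tau)) — the pulse-deficit mechanism:
    short preceding diastole -> reduced perfusion -> small pulse.
    Additive components: slow baseline wander, a white noise floor,
    motion-artefact noise proportional to the scheduled intensity, and
    noise-only replacement of dropout minutes. CHF morphology damps and
    broadens the template and jitters amplitudes beat-to-beat.
    """
    bt = rhythm.beat_times
    if len(bt) == 0:
        raise ValueError("rhythm is empty")
    rng = np.random.default_rng(seed)
    fs = config.ppg_rate
    n = int(round(profile.duration_h * 3600.0 * fs))
    tau = config.pulse_deficit_tau

    rr_prev = np.empty_like(bt)
    rr_prev[1:] = np.diff(bt)
    rr_prev[0] = np.median(rr_prev[1:]) if len(bt) > 1 else 1.0
    amp = pulse_amplitudes(rr_prev, tau)

    sys_w, dic_w, dic_a = _SYS_WIDTH, _DIC_WIDTH, _DIC_AMP
    if profile.chf_flag:
        amp = 0.8 * amp * rng.lognormal(0.0, 0.25, size=len(bt))
        sys_w *= 1.35
        dic_w *= 1.35
        dic_a *= 0.5

    # scatter-add the per-beat template over a 0.9 s window
    w = int(round(0.9 * fs))
    t0 = bt + PULSE_TRANSIT_DELAY - 0.1
    idx0 = np.floor(t0 * fs).astype(np.int64)
    trel = (idx0[:, None] + np.arange(w)) / fs - (bt + PULSE_TRANSIT_DELAY)[:, None]
    vals = amp[:, None] * (
        np.exp(-0.5 * ((trel - _SYS_CENTER) / sys_w) ** 2)
        + dic_a * np.exp(-0.5 * ((trel - _DIC_CENTER) / dic_w) ** 2)
    )
    idx = idx0[:, None] + np.arange(w)
    valid = (idx >= 0) & (idx < n)
    pulse = np.zeros(n, dtype=np.float64)
    np.add.at(pulse, idx[valid], vals[valid])

    t = np.arange(n) / fs
    wander = 0.15 * np.sin(2 * np.pi * 0.08 * t + rng.uniform(0, 2 * np.pi))
    env = _intensity_envelope(profile.motion_schedule, n, fs)
    art_sd = _ARTEFACT_GAIN * np.maximum(0.0, env - _ARTEFACT_DEADBAND)

    minute_len = int(round(60.0 * fs))
    channels = []
    for _c in range(config.ppg_channels):
        gain = 1.0 - 0.08 * _c
        x = gain * (pulse + wander)
        x = x + rng.normal(0.0, _NOISE_FLOOR_SD, size=n)
        x = x + art_sd * rng.normal(0.0, 1.0, size=n)
        for m in profile.dropout_minutes:
            i0, i1 = m * minute_len, min((m + 1) * minute_len, n)
            x[i0:i1] = rng.normal(0.0, _DROPOUT_NOISE_SD, size=i1 - i0)
        channels.append(x.astype(np.float32))
    return np.stack(channels, axis=1)


def render_accelerometer(
    profile: PatientProfile,
    config: SimConfig,
    seed: int,
) -> np.ndarray:
    """Render the (n_samples, 3) 50 Hz accelerometer trace.

    At rest the device reads exactly (0, 0, g): minute-mean vector
    magnitudes equal 9.81 m/s^2. Scheduled motion adds a rectified
    oscillatory component of the scheduled intensity along the gravity
    axis (mean uplift ~ 2/pi * intensity) plus proportional jitter on
    the horizontal axes, so minute means span the ~9.8-10.1 m/s^2 range
    seen on wrist-worn devices.
    """
    if profile.duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    fs = config.accel_rate
    n = int(round(profile.duration_h * 3600.0 * fs))
    acc = np.zeros((n, 3), dtype=np.float32)
    acc[:, 2] = GRAVITY
    env = _intensity_envelope(profile.motion_schedule, n, fs)
    moving = env > 0
    if moving.any():
        t = np.arange(n) / fs
        carrier = np.abs(np.sin(2 * np.pi * 1.3 * t + rng.uniform(0, 2 * np.pi)))
        acc[moving, 2] += (env * carrier)[moving].astype(np.float32)
        jitter = rng.normal(0.0, 1.0, size=(int(moving.sum()), 2))
        xy = 0.15 * env[moving][:, None] * jitter
        acc[moving, 0] += xy[:, 0].astype(np.float32)
        acc[moving, 1] += xy[:, 1].astype(np.float32)
    return acc


def make_profile(config: SimConfig, patient_index: int, seed: int) -> PatientProfile:
    """Draw one patient's parameters and schedules.

    CHF status is assigned deterministically to the first
    round(chf_fraction * n_patients) patient indices so the cohort mix
    is exact; per-patient RR means are jittered around the configured
    day/night means to create between-patient heterogeneity.
    """
    rng = np.random.default_rng(seed)
    n_minutes = int(np.floor(config.duration_h * 60.0))
    total_s = config.duration_h * 3600.0
    start_s = config.start_hour * 3600.0

    n_chf = int(round(config.chf_fraction * config.n_patients))
    chf = patient_index < n_chf

    day_mean = float(np.clip(config.rr_mean_day * rng.lognormal(0, 0.08), 0.35, 1.9))
    night_mean = float(
        np.clip(config.rr_mean_night * rng.lognormal(0, 0.08), 0.35, 1.9)
    )

    rows = []
    # ambient per-minute motion (wake: light activity; sleep: near-still)
    minute_starts = np.arange(n_minutes) * 60.0
    sleeping = _is_sleep(start_s + minute_starts + 30.0)
    amb_wake = np.abs(rng.normal(0.10, 0.07, size=n_minutes))
    amb_sleep = np.abs(rng.normal(0.01, 0.01, size=n_minutes))
    ambient = np.where(sleeping, amb_sleep, amb_wake)
    for m in range(n_minutes):
        if ambient[m] > 0:
            rows.append((minute_starts[m], minute_starts[m] + 60.0, ambient[m]))
    # discrete bursts during waking hours
    wake_hours = float(np.sum(~sleeping)) / 60.0
    n_bursts = rng.poisson(config.artefact_burst_rate * wake_hours)
    wake_starts = minute_starts[~sleeping]
    if len(wake_starts) and n_bursts:
        for _ in range(n_bursts):
            s = float(rng.choice(wake_starts)) + rng.uniform(0, 60.0)
            dur = float(np.clip(rng.lognormal(np.log(60.0), 0.7), 10.0, 600.0))
            inten = rng.uniform(0.1, 0.6)
            rows.append((s, min(s + dur, total_s), inten))
    schedule = np.array(rows, dtype=float) if rows else np.zeros((0, 3))

    dropout = np.flatnonzero(rng.random(n_minutes) < config.dropout_fraction)
    ecg_bad = np.flatnonzero(rng.random(n_minutes) < config.ecg_dropout_fraction)

    return PatientProfile(
        patient_id=f"P{patient_index:03d}",
        chf_flag=bool(chf),
        day_rr_params=(day_mean, config.rr_sd),
        night_rr_params=(night_mean, config.rr_sd),
        motion_schedule=schedule,
        dropout_minutes=dropout,
        ecg_bad_minutes=ecg_bad,
        start_s=start_s,
        duration_h=config.duration_h,
    )


def _truth_minutes(
    rhythm: RhythmTrace, profile: PatientProfile
) -> pd.DataFrame:
    n_minutes = int(np.floor(profile.duration_h * 60.0))
    bt = rhythm.beat_times
    rows = []
    drop = set(profile.dropout_minutes.tolist())
    ecg_bad = set(profile.ecg_bad_minutes.tolist())
    for m in range(n_minutes):
        lo, hi = m * 60.0, (m + 1) * 60.0
        sel = bt[(bt >= lo) & (bt < hi)]
        if len(sel) >= 2:
            true_hr = 60.0 / np.mean(np.diff(sel))
        else:
            true_hr = np.nan
        rows.append(
            {
                "minute_index": m,
                "t_start": lo,
                "true_hr": true_hr,
                "n_beats": len(sel),
                "ppg_ok": m not in drop,
                "ecg_ok": m not in ecg_bad,
            }
        )
    return pd.DataFrame(rows)


def simulate_patient(config: SimConfig, patient_index: int) -> PatientRecord:
    """Assemble one patient's profile, rhythm, sensors and ground truth."""
    if not 0 <= patient_index < config.n_patients:
        raise IndexError(
            f"patient_index {patient_index} out of range [0, {config.n_patients})"
        )
    ss = np.random.SeedSequence([config.seed, patient_index])
    s_prof, s_rr, s_ppg, s_acc = [int(s) for s in ss.generate_state(4) >> 1]
    profile = make_profile(config, patient_index, s_prof)
    rhythm = simulate_af_rr(profile, config.duration_h, s_rr)
    ppg = render_ppg(rhythm, profile, config, s_ppg)
    accel = render_accelerometer(profile, config, s_acc)
    sensors = SensorBundle(
        ppg=ppg,
        ppg_rate=config.ppg_rate,
        accel=accel,
        accel_rate=config.accel_rate,
        start_s=profile.start_s,
    )
    truth = _truth_minutes(rhythm, profile)
    return PatientRecord(
        profile=profile, rhythm=rhythm, sensors=sensors, truth_minutes=truth
    )


def simulate_cohort(config: SimConfig):
    """Yield PatientRecords one at a time (waveforms are memory-heavy)."""
    for i in range(config.n_patients):
        yield simulate_patient(config, i)


# ---------------------------------------------------------------------------
# Segment-level scenario generators
# ---------------------------------------------------------------------------
# The correction models consume the minute-level segment table, not raw
# waveforms. These generators produce tables with controlled error
# structure directly at segment level, for fast, targeted experiments on
# the correction models (bias recovery, threshold bias, transient
# outliers, the bias-free null).


def simulate_segment_table(
    kind: str,
    n_patients: int = 10,
    minutes_per_patient: int = 200,
    seed: int = 0,
    noise_sd: float = 3.0,
    outcome_noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Minute-level segment table with a controlled PPG error structure.

    kind:
      ``unbiased``          hr_ppg = hr_ecg + noise (no correctable bias)
      ``linear_bias``       hr_ecg = 5 + 1.1*hr_ppg + eps (eps sd =
                            ``outcome_noise_sd``): an exactly linear
                            systematic bias on the measured value,
                            recoverable by regression
      ``threshold_bias``    PPG reads 12 bpm low whenever hr_ecg > 110
      ``transient_outlier`` isolated single-minute spikes of +/-25 bpm
                            in hr_ppg (detectable from history)
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        if kind == "threshold_bias":
            # rate-control failures must be well represented for the
            # step-shaped bias to matter
            base = rng.uniform(85.0, 120.0)
        else:
            base = rng.uniform(60.0, 95.0)
        hr = base + np.cumsum(rng.normal(0, 1.0, minutes_per_patient))
        hr = np.clip(hr + rng.normal(0, 4.0, minutes_per_patient), 40.0, 160.0)
        noise = rng.normal(0, noise_sd, minutes_per_patient)
        if kind == "unbiased":
            ppg = hr + noise
        elif kind == "linear_bias":
            ppg = hr + noise
            hr = 5.0 + 1.1 * ppg + rng.normal(0, outcome_noise_sd, minutes_per_patient)
            hr = np.clip(hr, 25.0, 220.0)
        elif kind == "threshold_bias":
            ppg = hr + noise - 12.0 * (hr > 110.0)
        elif kind == "transient_outlier":
            ppg = hr + noise
            n_spikes = max(1, minutes_per_patient // 15)
            pos = rng.choice(
                np.arange(1, minutes_per_patient - 1), n_spikes, replace=False
            )
            ppg[pos] += rng.choice([-25.0, 25.0], n_spikes)
        else:
            raise ValueError(f"unknown scenario kind: {kind!r}")
        minute = np.arange(minutes_per_patient)
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": f"P{p:03d}",
                    "minute_start": minute * 60.0,
                    "hr_ecg": hr,
                    "hr_ppg": np.clip(ppg, 20.0, 250.0),
                    "rmssd": np.abs(rng.normal(0.26, 0.05, minutes_per_patient)),
                    "quality": rng.uniform(0.5, 1.0, minutes_per_patient),
                    "motion_index": GRAVITY
                    + np.abs(rng.normal(0.05, 0.05, minutes_per_patient)),
                    "motion_sd": np.abs(rng.normal(0.05, 0.03, minutes_per_patient)),
                    "included": True,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
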