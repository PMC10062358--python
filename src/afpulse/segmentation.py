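"""Alignment and 1-min segmentation: reference HR, covariates, strata.

ECG and PPG streams are aligned on wall-clock minute boundaries, each
minute gets the ECG reference HR (60 / mean beat-to-beat interval inside
the minute), motion covariates (mean and SD of the accelerometer vector
magnitude), a day/night label, a motion quartile, and the inclusion flag
(both modalities present and sufficient). Exclusion reasons are counted
separately (ECG-only / PPG-only / both), so every recorded minute falls
in exactly one of four categories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from afpulse.synth import PatientRecord

# Day/night wall-clock windows (half-open, local time). Transitional
# periods 22:00-24:00 and 06:00-08:00 are excluded from the comparison.
DAY_WINDOW = (8.0, 22.0)
NIGHT_WINDOW = (0.0, 6.0)

# Fixed motion-quartile boundaries (m/s^2) as printed for the emulated
# cohort; "empirical" mode recomputes them from the included segments.
PAPER_MOTION_BOUNDARIES = (9.855, 9.925, 10.045)

RATE_CATEGORIES = ("<=80", "80-110", ">110")


def ecg_minute_hr(beat_times: np.ndarray, start: float, end: float) -> float:
    """Reference 1-min mean HR: 60 / mean interval fully inside the window.

    Returns NaN when fewer than two beats fall inside (no full interval).
    """
    if not np.isclose(end - start, 60.0):
        raise ValueError("window must be 60 s")
    bt = np.asarray(beat_times, dtype=float)
    sel = bt[(bt >= start) & (bt < end)]
    if len(sel) < 2:
        return float("nan")
    return 60.0 / float(np.mean(np.diff(sel)))


def motion_features(
    accel: np.ndarray, rate: float, max_missing: float = 0.10
) -> tuple[float, float]:
    """Minute motion covariates: (mean, SD) of the 3-axis vector magnitude.

    Flagged missing (NaN, NaN) when more than ``max_missing`` of the
    expected samples are absent or non-finite.
    """
    accel = np.asarray(accel, dtype=float)
    expected = int(round(60.0 * rate))
    finite = np.all(np.isfinite(accel), axis=1) if len(accel) else np.array([], bool)
    n_good = int(finite.sum())
    if n_good < (1.0 - max_missing) * expected:
        return float("nan"), float("nan")
    mag = np.linalg.norm(accel[finite], axis=1)
    return float(np.mean(mag)), float(np.std(mag))


def assign_daynight(minute_start_s: float) -> str:
    """Label by local time of day: day [08, 22), night [00, 06), else excluded."""
    hour = (minute_start_s / 3600.0) % 24.0
    if DAY_WINDOW[0] <= hour < DAY_WINDOW[1]:
        return "day"
    if NIGHT_WINDOW[0] <= hour < NIGHT_WINDOW[1]:
        return "night"
    return "excluded"


def assign_motion_quartile(
    motion_index: float | np.ndarray,
    boundaries: tuple[float, float, float] = PAPER_MOTION_BOUNDARIES,
) -> np.ndarray | str:
    """G1..G4 by half-open intervals: G1 <= q1 < G2 <= q2 < G3 <= q3 < G4."""
    q1, q2, q3 = boundaries
    if not q1 <= q2 <= q3:
        raise ValueError("boundaries must be non-decreasing")
    x = np.asarray(motion_index, dtype=float)
    labels = np.select(
        [x <= q1, x <= q2, x <= q3], ["G1", "G2", "G3"], default="G4"
    )
    if np.ndim(motion_index) == 0:
        return str(labels)
    return labels


def empirical_motion_boundaries(
    motion_index: np.ndarray,
) -> tuple[float, float, float]:
    """Quartile boundaries of the included segments' motion index."""
    q = np.nanquantile(np.asarray(motion_index, dtype=float), [0.25, 0.5, 0.75])
    return float(q[0]), float(q[1]), float(q[2])


def build_segment_table(
    record: PatientRecord,
    minute_estimates: pd.DataFrame,
    motion_boundaries: str | tuple[float, float, float] = "empirical",
) -> pd.DataFrame:
    """Assemble the per-patient segment table (one row per recorded minute).

    The PPG side comes from the processed minute estimates; the ECG side
    from the reference beat times (masked in simulated ECG-dropout
    minutes). Motion quartiles are attached later at cohort level when
    ``motion_boundaries == 'empirical'`` (they depend on the pooled
    distribution); here the column is filled only for fixed boundaries.
    """
    prof = record.profile
    acc = record.sensors.accel
    fs_a = record.sensors.accel_rate
    la = int(round(60.0 * fs_a))
    ecg_bad = set(prof.ecg_bad_minutes.tolist())

    est = minute_estimates.set_index("minute_index")
    n_minutes = int(np.floor(prof.duration_h * 60.0))
    rows = []
    for m in range(n_minutes):
        hr_ecg = (
            float("nan")
            if m in ecg_bad
            else ecg_minute_hr(record.rhythm.beat_times, m * 60.0, (m + 1) * 60.0)
        )
        mi, ms = motion_features(acc[m * la : (m + 1) * la], fs_a)
        start_abs = prof.start_s + m * 60.0
        row = {
            "patient_id": prof.patient_id,
            "minute_start": start_abs,
            "minute_index": m,
            "hr_ecg": hr_ecg,
            "hr_ppg": float("nan"),
            "rmssd": float("nan"),
            "quality": 0.0,
            "motion_index": mi,
            "motion_sd": ms,
            "daynight": assign_daynight(start_abs),
            "chf": prof.chf_flag,
            "true_hr": float(record.truth_minutes["true_hr"].iloc[m]),
            "true_ppg_ok": bool(record.truth_minutes["ppg_ok"].iloc[m]),
        }
        if m in est.index:
            row["hr_ppg"] = float(est.loc[m, "hr_ppg"])
            row["rmssd"] = float(est.loc[m, "rmssd"])
            row["quality"] = float(est.loc[m, "quality_fraction"])
        rows.append(row)
    df = pd.DataFrame(rows)
    if motion_boundaries != "empirical":
        df["motion_quartile"] = assign_motion_quartile(
            df["motion_index"].to_numpy(), motion_boundaries
        )
    return df


def apply_inclusion(
    table: pd.DataFrame,
    motion_boundaries: str | tuple[float, float, float] = "empirical",
) -> pd.DataFrame:
    """Inclusion rule + exclusion accounting + motion quartiles.

    A minute is included iff both the ECG reference and the PPG estimate
    are present. ``exclusion_reason`` is one of
    {included, ecg_only, ppg_only, both}; the four categories partition
    the recorded minutes. Empirical motion quartile boundaries are
    computed over included segments only (the same convention as the
    emulated analysis) and then applied to all rows with motion data.
    """
    df = table.copy()
    ecg_ok = df["hr_ecg"].notna()
    ppg_ok = df["hr_ppg"].notna()
    df["included"] = ecg_ok & ppg_ok
    df["exclusion_reason"] = np.select(
        [ecg_ok & ppg_ok, ~ecg_ok & ppg_ok, ecg_ok & ~ppg_ok],
        ["included", "ecg_only", "ppg_only"],
        default="both",
    )
    if motion_boundaries == "empirical":
        inc = df.loc[df["included"], "motion_index"].dropna()
        if len(inc):
            boundaries = empirical_motion_boundaries(inc.to_numpy())
        else:
            boundaries = PAPER_MOTION_BOUNDARIES
    else:
        boundaries = motion_boundaries  # type: ignore[assignment]
    has_motion = df["motion_index"].notna()
    labels = np.full(len(df), "NA", dtype=object)
    labels[has_motion.to_numpy()] = assign_motion_quartile(
        df.loc[has_motion, "motion_index"].to_numpy(), boundaries
    )
    df["motion_quartile"] = labels
    df.attrs["motion_boundaries"] = tuple(boundaries)
    return df


def exclusion_counts(table: pd.DataFrame) -> dict[str, int]:
    """Counts of the four-way inclusion partition (plus the total)."""
    counts = table["exclusion_reason"].value_counts().to_dict()
    out = {k: int(counts.get(k, 0)) for k in ("included", "ecg_only", "ppg_only", "both")}
    out["total"] = int(len(table))
    return out
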