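"""Method-comparison statistics for paired 1-min heart-rate series.

Implements the full agreement battery: RMSE, Bland-Altman bias and
limits of agreement, the strict +/-10% accuracy rule, rate-control
categories (<=80 / 80-110 / >110 bpm with a <=40 bpm sub-band), 3x3
confusion matrices with row percentages and rough-categorization
accuracy, per-patient summaries with the <95% low-agreement split,
Fisher's exact test by exact hypergeometric enumeration, and stratified
reports over day/night and motion quartiles.

Conventions (where the emulated analysis leaves a choice):

* 110 bpm belongs to the middle band — categories are <=80, (80, 110],
  >110, half-open so they partition the axis;
* the +/-10% rule is strict ("deviated less than +/-10%"): a deviation of
  exactly 10% counts as inaccurate;
* Bland-Altman SD is the sample SD (ddof=1) by default, switchable;
* two-sided Fisher P sums all tables with point probability <= that of
  the observed table (the standard enumeration definition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LOW_AGREEMENT_THRESHOLD = 95.0  # % of minutes within +/-10%


@dataclass
class BlandAltmanResult:
    bias: float
    lower_limit: float
    upper_limit: float
    sd: float

    def __post_init__(self) -> None:
        if not self.lower_limit <= self.bias <= self.upper_limit:
            raise ValueError("limits must bracket the bias")


@dataclass
class ConfusionMatrix:
    """3x3 cross-tabulation: ECG category rows, PPG category columns."""

    counts: np.ndarray
    categories: tuple[str, ...] = ("<=80", "80-110", ">110")
    n_le40: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        self.counts = c

    @classmethod
    def from_counts(cls, counts, n_le40: int = 0) -> "ConfusionMatrix":
        return cls(counts=np.asarray(counts), n_le40=n_le40)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Each row as percentages of its row total (NaN for empty rows)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / sums

    def rough_accuracy(self) -> float:
        """% of segments placed in the correct rate-control category."""
        if self.total == 0:
            return float("nan")
        return 100.0 * float(np.trace(self.counts)) / self.total


@dataclass
class AgreementSummary:
    rmse: float
    bland_altman: BlandAltmanResult
    pct_within_10: float
    confusion: ConfusionMatrix
    n_segments: int


@dataclass
class PatientSummary:
    patient_id: str
    n_segments: int
    mean_ecg: float
    min_ecg: float
    max_ecg: float
    mean_ppg: float
    min_ppg: float
    max_ppg: float
    prop_le110_ecg: float
    prop_le110_ppg: float
    agreement_rate: float  # % of minutes within +/-10%
    low_agreement_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        self.low_agreement_flag = self.agreement_rate < LOW_AGREEMENT_THRESHOLD


def _paired(hr_ecg, hr_ppg) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(hr_ecg, dtype=float)
    b = np.asarray(hr_ppg, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired series must be finite")
    return a, b


def rmse(hr_ecg, hr_ppg) -> float:
    """sqrt(mean((HR_PPG - HR_ECG)^2)) in bpm."""
    a, b = _paired(hr_ecg, hr_ppg)
    if len(a) == 0:
        raise ValueError("rmse of an empty series is undefined")
    return float(np.sqrt(np.mean((b - a) ** 2)))


def bland_altman(hr_ecg, hr_ppg, ddof: int = 1) -> BlandAltmanResult:
    """Bias and limits of agreement (bias +/- 1.96 SD) of PPG - ECG."""
    a, b = _paired(hr_ecg, hr_ppg)
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = b - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=ddof))
    return BlandAltmanResult(
        bias=bias, lower_limit=bias - 1.96 * sd, upper_limit=bias + 1.96 * sd, sd=sd
    )


def accuracy_within_tolerance(hr_ecg, hr_ppg, tol: float = 0.10) -> float:
    """% of pairs with |HR_PPG - HR_ECG| strictly less than tol * HR_ECG."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    a, b = _paired(hr_ecg, hr_ppg)
    if len(a) == 0:
        raise ValueError("accuracy of an empty series is undefined")
    return 100.0 * float(np.mean(np.abs(b - a) < tol * a))


def categorize_rate(hr) -> np.ndarray | str:
    """Rate-control category: <=80, (80, 110], >110 bpm."""
    x = np.asarray(hr, dtype=float)
    if np.any(x <= 0):
        raise ValueError("heart rate must be > 0")
    labels = np.select([x <= 80.0, x <= 110.0], ["<=80", "80-110"], default=">110")
    if np.ndim(hr) == 0:
        return str(labels)
    return labels


def is_le40(hr) -> np.ndarray | bool:
    """Very-low-rate sub-band flag (<=40 bpm, inside the <=80 category)."""
    x = np.asarray(hr, dtype=float)
    out = x <= 40.0
    return bool(out) if np.ndim(hr) == 0 else out


_CAT_INDEX = {"<=80": 0, "80-110": 1, ">110": 2}


def confusion_matrix(hr_ecg, hr_ppg) -> ConfusionMatrix:
    """3x3 cross-tabulation of ECG (rows) vs PPG (columns) categories."""
    a, b = _paired(hr_ecg, hr_ppg)
    counts = np.zeros((3, 3), dtype=np.int64)
    if len(a):
        ia = np.array([_CAT_INDEX[c] for c in categorize_rate(a)])
        ib = np.array([_CAT_INDEX[c] for c in categorize_rate(b)])
        np.add.at(counts, (ia, ib), 1)
        n40 = int(np.sum(a <= 40.0))
    else:
        n40 = 0
    return ConfusionMatrix(counts=counts, n_le40=n40)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact P by exact hypergeometric enumeration.

    Sums, over all 2x2 tables with the observed margins, the point
    probabilities that do not exceed the observed table's. All
    arithmetic is exact (integer hypergeometric numerators over a
    common denominator), so probability ties are resolved exactly.
    Degenerate margins (an empty row or column) give P = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    num_obs = nums[a - lo]
    total = sum(num for num in nums if num <= num_obs)
    return min(1.0, total / denom)


def compare_groups_fisher(flags, characteristic) -> tuple[np.ndarray, float]:
    """2x2 table and two-sided Fisher P for a boolean patient characteristic
    split across the low/high-agreement groups.

    Rows: flag (low agreement) true/false; columns: characteristic yes/no.
    """
    f = np.asarray(flags, dtype=bool)
    ch = np.asarray(characteristic, dtype=bool)
    if f.shape != ch.shape:
        raise ValueError("flags and characteristic must align")
    table = np.array(
        [
            [int(np.sum(f & ch)), int(np.sum(f & ~ch))],
            [int(np.sum(~f & ch)), int(np.sum(~f & ~ch))],
        ]
    )
    return table, fisher_exact_2x2(table)


def summarize_agreement(hr_ecg, hr_ppg) -> AgreementSummary:
    """Full agreement bundle for one segment set."""
    a, b = _paired(hr_ecg, hr_ppg)
    if len(a) < 2:
        raise ValueError("need at least 2 paired segments")
    return AgreementSummary(
        rmse=rmse(a, b),
        bland_altman=bland_altman(a, b),
        pct_within_10=accuracy_within_tolerance(a, b),
        confusion=confusion_matrix(a, b),
        n_segments=len(a),
    )


def per_patient_summary(table: pd.DataFrame) -> list[PatientSummary]:
    """Per-patient aggregates over included segments.

    Patients with zero included minutes are omitted with a warning.
    """
    out = []
    for pid, grp in table[table["included"]].groupby("patient_id", sort=True):
        a = grp["hr_ecg"].to_numpy(float)
        b = grp["hr_ppg"].to_numpy(float)
        if len(a) == 0:
            continue
        out.append(
            PatientSummary(
                patient_id=str(pid),
                n_segments=len(a),
                mean_ecg=float(a.mean()),
                min_ecg=float(a.min()),
                max_ecg=float(a.max()),
                mean_ppg=float(b.mean()),
                min_ppg=float(b.min()),
                max_ppg=float(b.max()),
                prop_le110_ecg=float(np.mean(a <= 110.0)),
                prop_le110_ppg=float(np.mean(b <= 110.0)),
                agreement_rate=accuracy_within_tolerance(a, b),
            )
        )
    missing = set(table["patient_id"].unique()) - {s.patient_id for s in out}
    if missing:
        warnings.warn(
            f"patients with no included minutes omitted: {sorted(missing)}",
            stacklevel=2,
        )
    return out


def patient_level_agreement(summaries: list[PatientSummary]) -> dict[str, float]:
    """Cohort-level RMSE of the per-patient mean/min/max HR pairs."""
    if not summaries:
        raise ValueError("no patient summaries")
    mean_e = [s.mean_ecg for s in summaries]
    mean_p = [s.mean_ppg for s in summaries]
    return {
        "rmse_of_means": rmse(mean_e, mean_p),
        "rmse_of_mins": rmse([s.min_ecg for s in summaries], [s.min_ppg for s in summaries]),
        "rmse_of_maxes": rmse([s.max_ecg for s in summaries], [s.max_ppg for s in summaries]),
        "n_low_agreement": float(sum(s.low_agreement_flag for s in summaries)),
    }


def _accuracy_2x2(
    grp_a: pd.DataFrame, grp_b: pd.DataFrame, tol: float = 0.10
) -> np.ndarray:
    def acc_counts(g):
        a = g["hr_ecg"].to_numpy(float)
        b = g["hr_ppg"].to_numpy(float)
        ok = int(np.sum(np.abs(b - a) < tol * a))
        return ok, len(a) - ok

    return np.array([acc_counts(grp_a), acc_counts(grp_b)])


def _clustered_accuracy_p(
    grp_a: pd.DataFrame, grp_b: pd.DataFrame, tol: float = 0.10
) -> float:
    """Per-patient clustered sensitivity check: paired t on per-patient
    accuracy differences for patients present in both strata."""

    def per_patient(g):
        return g.groupby("patient_id").apply(
            lambda x: accuracy_within_tolerance(x["hr_ecg"], x["hr_ppg"], tol),
            include_groups=False,
        )

    a = per_patient(grp_a)
    b = per_patient(grp_b)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        return float("nan")
    diff = a.loc[common] - b.loc[common]
    if np.allclose(diff, 0):
        return 1.0
    return float(stats.ttest_rel(a.loc[common], b.loc[common]).pvalue)


def stratified_report(table: pd.DataFrame) -> dict:
    """AgreementSummary per stratum + naive and clustered comparisons.

    Strata: day/night, motion quartiles G1-G4, and ECG rate categories.
    Comparisons: day vs night and G1 vs G4 accuracy, each as a naive
    Fisher's exact on the accurate/inaccurate 2x2 (segments treated as
    independent) plus a per-patient clustered paired check.
    Empty strata are omitted with a warning.
    """
    inc = table[table["included"]].copy()
    if inc.empty:
        raise ValueError("no included segments")
    inc["rate_cat"] = categorize_rate(inc["hr_ecg"].to_numpy(float))

    report: dict = {"strata": {}, "comparisons": {}}

    def add(name: str, grp: pd.DataFrame) -> None:
        if len(grp) < 2:
            warnings.warn(f"stratum {name!r} empty or singleton; omitted", stacklevel=3)
            return
        report["strata"][name] = summarize_agreement(
            grp["hr_ecg"].to_numpy(float), grp["hr_ppg"].to_numpy(float)
        )

    add("all", inc)
    for name in ("day", "night"):
        add(name, inc[inc["daynight"] == name])
    for g in ("G1", "G2", "G3", "G4"):
        add(g, inc[inc["motion_quartile"] == g])
    for cat in ("<=80", "80-110", ">110"):
        add(f"rate_{cat}", inc[inc["rate_cat"] == cat])

    day = inc[inc["daynight"] == "day"]
    night = inc[inc["daynight"] == "night"]
    if len(day) and len(night):
        t2 = _accuracy_2x2(day, night)
        report["comparisons"]["day_vs_night"] = {
            "table": t2,
            "fisher_p": fisher_exact_2x2(t2),
            "clustered_p": _clustered_accuracy_p(day, night),
        }
    g1 = inc[inc["motion_quartile"] == "G1"]
    g4 = inc[inc["motion_quartile"] == "G4"]
    if len(g1) and len(g4):
        t2 = _accuracy_2x2(g1, g4)
        report["comparisons"]["g1_vs_g4"] = {
            "table": t2,
            "fisher_p": fisher_exact_2x2(t2),
            "clustered_p": _clustered_accuracy_p(g1, g4),
        }
    return report
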