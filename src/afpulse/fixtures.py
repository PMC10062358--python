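"""Published summary tables of the emulated study, as machine-readable
fixtures.

These are the printed counts of the validation study the simulator
emulates: the clinical 2x2 for chronic heart failure across the
low/high-agreement patient split, the day/night and motion-quartile
confusion matrices (ECG rate category rows x PPG rate category columns),
and the segment-accounting totals. They exercise the confusion-matrix
and Fisher machinery on real printed numbers, independent of any
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Chronic heart failure: rows = (low agreement n=15, high agreement n=35),
# columns = (CHF yes, CHF no).
TABLE1_CHF_2X2 = np.array([[7, 8], [6, 29]])

# Day-time / night-time confusion matrices (rows: ECG <=80 / 80-110 / >110).
TABLE2_DAY = np.array(
    [
        [10720, 722, 23],
        [836, 8593, 77],
        [9, 451, 745],
    ]
)
TABLE2_NIGHT = np.array(
    [
        [13422, 120, 1],
        [256, 2514, 5],
        [0, 15, 20],
    ]
)

# Motion-quartile confusion matrices G1..G4 (same layout).
TABLE3_MOTION = {
    "G1": np.array([[11537, 180, 7], [227, 2733, 6], [0, 39, 67]]),
    "G2": np.array([[9539, 294, 11], [450, 3688, 18], [2, 124, 195]]),
    "G3": np.array([[6796, 347, 3], [383, 3784, 36], [4, 164, 241]]),
    "G4": np.array([[3079, 202, 5], [238, 2757, 35], [3, 169, 298]]),
}

# Segment accounting.
ACCOUNTING = {
    "total_simultaneous_minutes": 79443,
    "included": 47661,
    "excluded_total": 31782,
    "excluded_ecg_only": 90,
    "excluded_ppg_only": 24006,
    "excluded_both": 7686,
    "ecg_le80": 30968,
    "ecg_80_110": 15239,
    "ecg_gt110": 1454,
    "ecg_le40": 299,
    "day_night_available": 38529,
    "day_segments": 22176,
    "night_segments": 16353,
    "motion_counts": {"G1": 14796, "G2": 14321, "G3": 11758, "G4": 6786},
    "n_patients": 50,
    "n_low_agreement": 15,
    "n_high_agreement": 35,
}

# Toy beat series for hand-checkable formula tests.
TOY_INTERVALS_CONSTANT = [1.0, 1.0, 1.0]
TOY_INTERVALS_ALTERNATING = [0.8, 1.0, 0.8]


@dataclass
class FixtureSet:
    chf_2x2: np.ndarray = field(default_factory=lambda: TABLE1_CHF_2X2.copy())
    day: np.ndarray = field(default_factory=lambda: TABLE2_DAY.copy())
    night: np.ndarray = field(default_factory=lambda: TABLE2_NIGHT.copy())
    motion: dict = field(
        default_factory=lambda: {k: v.copy() for k, v in TABLE3_MOTION.items()}
    )
    accounting: dict = field(default_factory=lambda: dict(ACCOUNTING))
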