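"""Four approaches to PPG-based 1-min mean HR estimation and their
5-fold cross-validated comparison.

A (naive)  — the PPG estimate at face value; no fitting.
B (linear) — OLS of the ECG reference on the five watch-derived minute
             features (PPG HR, RMSSD, quality fraction, motion index,
             motion SD) plus intercept; corrects any systematic linear
             bias or trend.
C (MLP)    — feed-forward net 5 -> 10 -> 10 -> 1 (two hidden layers with
             ten neurons each) for non-linear biases.
D (LSTM)   — dual-path recurrent net over a 10-minute history window
             (current minute + up to nine preceding minutes, with a
             missing-minute mask): two parallel paths of four stacked
             LSTM layers with five units, a fully connected layer of
             eight per path, concatenated into one output neuron.
             Targets transient outliers that history could reveal.

Models B-D are fitted and tested with k-fold cross-validation (default
5 folds, grouped by patient to prevent within-patient leakage); model A
is evaluated on the identical pooled out-of-fold set without fitting.
Feature standardization constants are fit on training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from afpulse.agreement import BlandAltmanResult, bland_altman, rmse
from afpulse.lstm import DualPathLSTMRegressor

FEATURES = ["hr_ppg", "rmssd", "quality", "motion_index", "motion_sd"]
MODEL_KINDS = ("A_naive", "B_linear", "C_mlp", "D_lstm")
_SHORT = {"A": "A_naive", "B": "B_linear", "C": "C_mlp", "D": "D_lstm"}


@dataclass
class ModelSpec:
    """Model definition; architecture constants default to the study's."""

    kind: str
    hidden_layers: tuple[int, ...] = (10, 10)  # model C
    lstm_units: int = 5  # model D
    lstm_depth: int = 4
    lstm_dense: int = 8
    history: int = 10
    epochs: int = 50
    batch_size: int = 256
    lr: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind in _SHORT:
            self.kind = _SHORT[self.kind]
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.history < 1:
            raise ValueError("history must be >= 1")


@dataclass
class CVResult:
    kind: str
    fold_rmse: list[float]
    rmse: float  # pooled out-of-fold RMSE
    ci95: tuple[float, float]
    bland_altman: BlandAltmanResult
    predictions: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.fold_rmse:
            lo, hi = min(self.fold_rmse), max(self.fold_rmse)
            if not lo - 1e-9 <= self.rmse <= hi + 1e-9:
                raise ValueError("pooled RMSE must lie within fold RMSE range")


def build_features(table: pd.DataFrame, history: int = 10) -> dict:
    """Per-minute feature matrix + LSTM history windows from a segment table.

    Only included segments contribute rows. Windows cover the current
    minute plus up to ``history - 1`` preceding minutes of the same
    patient; slots where the preceding minute is missing (excluded, or
    before the recording start) are zero-filled and masked out. The last
    window slot is always the minute under analysis.
    """
    if history < 1:
        raise ValueError("history must be >= 1")
    inc = table[table["included"]].copy()
    inc = inc.sort_values(["patient_id", "minute_start"]).reset_index(drop=True)
    n = len(inc)
    X = inc[FEATURES].to_numpy(float)
    y = inc["hr_ecg"].to_numpy(float)
    groups = inc["patient_id"].to_numpy()

    windows = np.zeros((n, history, len(FEATURES)))
    mask = np.zeros((n, history))
    by_minute: dict[tuple, int] = {
        (pid, int(round(ms / 60.0))): i
        for i, (pid, ms) in enumerate(zip(groups, inc["minute_start"].to_numpy(float)))
    }
    minutes = np.round(inc["minute_start"].to_numpy(float) / 60.0).astype(int)
    for i in range(n):
        for lag in range(history):
            j = by_minute.get((groups[i], minutes[i] - lag))
            if j is not None:
                windows[i, history - 1 - lag] = X[j]
                mask[i, history - 1 - lag] = 1.0
    return {
        "X": X,
        "y": y,
        "groups": groups,
        "windows": windows,
        "mask": mask,
        "index": inc.index.to_numpy(),
        "table": inc,
    }


def predict_naive(features: dict | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Model A: the PPG-based estimate at face value."""
    if isinstance(features, dict):
        return features["X"][:, 0].copy()
    if isinstance(features, pd.DataFrame):
        return features["hr_ppg"].to_numpy(float)
    return np.asarray(features, dtype=float)[:, 0].copy()


def fit_predict_linear(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Model B: OLS of the reference HR on the five features + intercept.

    Falls back to a lightly regularized ridge fit (with a warning) when
    the design is rank-deficient.
    """
    if len(X_train) == 0:
        raise ValueError("empty training set")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X_train)), X_train]))
    if rank < X_train.shape[1] + 1:
        warnings.warn("rank-deficient design; using ridge fallback", stacklevel=2)
        model = Ridge(alpha=1e-6)
    else:
        model = LinearRegression()
    model.fit(X_train, y_train)
    return model.predict(X_test)


def fit_predict_mlp(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Model C: feed-forward net with two hidden layers of ten neurons."""
    spec = spec or ModelSpec("C_mlp")
    if spec.kind != "C_mlp":
        raise ValueError("spec.kind must be C_mlp")
    scaler = StandardScaler().fit(X_train)
    y_mean, y_sd = float(np.mean(y_train)), float(np.std(y_train)) or 1.0
    net = MLPRegressor(
        hidden_layer_sizes=spec.hidden_layers,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.lr,
        max_iter=max(spec.epochs * 6, 200),
        batch_size=min(spec.batch_size, len(X_train)),
        random_state=spec.seed,
        tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at capped iters
        net.fit(scaler.transform(X_train), (y_train - y_mean) / y_sd)
    pred = net.predict(scaler.transform(X_test)) * y_sd + y_mean
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError("MLP produced non-finite predictions")
    return pred


def fit_predict_lstm(
    W_train: np.ndarray,
    M_train: np.ndarray,
    y_train: np.ndarray,
    W_test: np.ndarray,
    M_test: np.ndarray,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Model D: dual-path LSTM over 10-step history windows."""
    spec = spec or ModelSpec("D_lstm")
    if spec.kind != "D_lstm":
        raise ValueError("spec.kind must be D_lstm")
    flat = W_train[M_train.astype(bool)]
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    y_mean, y_sd = float(np.mean(y_train)), float(np.std(y_train)) or 1.0

    def scale(W, M):
        Ws = (W - mu) / sd
        return Ws * M[:, :, None]  # masked slots stay zero

    net = DualPathLSTMRegressor(
        hidden=spec.lstm_units,
        depth=spec.lstm_depth,
        dense_units=spec.lstm_dense,
        lr=spec.lr,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        seed=spec.seed,
    )
    net.fit(scale(W_train, M_train), M_train, (y_train - y_mean) / y_sd)
    return net.predict(scale(W_test, M_test), M_test) * y_sd + y_mean


def _fold_assignment(
    groups: np.ndarray, k: int, grouping: str, seed: int
) -> np.ndarray:
    """Fold index per row; by_patient keeps each patient in one fold."""
    rng = np.random.default_rng(seed)
    n = len(groups)
    if grouping == "by_patient":
        patients = np.array(sorted(set(groups.tolist())))
        if len(patients) < k:
            raise ValueError(
                f"{len(patients)} patients cannot fill {k} folds in by_patient mode"
            )
        perm = rng.permutation(len(patients))
        fold_of = {p: i % k for i, p in enumerate(patients[perm])}
        return np.array([fold_of[g] for g in groups])
    if grouping == "by_segment":
        folds = np.arange(n) % k
        return rng.permutation(folds)
    raise ValueError(f"unknown grouping {grouping!r}")


def cross_validate(
    table: pd.DataFrame,
    spec: ModelSpec | str,
    k: int = 5,
    grouping: str = "by_patient",
    seed: int = 0,
) -> CVResult:
    """k-fold CV of one model; model A needs no fitting and is evaluated
    on the identical pooled segment set.

    The 95% CI is a t-interval over the k fold RMSEs (for model A, over
    the same folds evaluated without fitting, so the comparison across
    models shares the partition).
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    if k < 2:
        raise ValueError("k must be >= 2")
    feats = build_features(table, history=spec.history)
    y = feats["y"]
    folds = _fold_assignment(feats["groups"], k, grouping, seed)
    preds = np.full(len(y), np.nan)
    fold_rmse = []
    for fold in range(k):
        te = folds == fold
        tr = ~te
        if spec.kind == "A_naive":
            p = predict_naive({"X": feats["X"][te]})
        elif spec.kind == "B_linear":
            p = fit_predict_linear(feats["X"][tr], y[tr], feats["X"][te])
        elif spec.kind == "C_mlp":
            fold_spec = ModelSpec(**{**spec.__dict__, "seed": spec.seed + fold})
            p = fit_predict_mlp(feats["X"][tr], y[tr], feats["X"][te], fold_spec)
        else:
            fold_spec = ModelSpec(**{**spec.__dict__, "seed": spec.seed + fold})
            p = fit_predict_lstm(
                feats["windows"][tr],
                feats["mask"][tr],
                y[tr],
                feats["windows"][te],
                feats["mask"][te],
                fold_spec,
            )
        preds[te] = p
        fold_rmse.append(rmse(y[te], p))
    assert not np.any(np.isnan(preds)), "out-of-fold sets must partition the data"
    pooled = rmse(y, preds)
    m = float(np.mean(fold_rmse))
    se = float(np.std(fold_rmse, ddof=1) / np.sqrt(k))
    tcrit = float(stats.t.ppf(0.975, df=k - 1))
    ci = (m - tcrit * se, m + tcrit * se)
    pred_df = feats["table"][["patient_id", "minute_start", "hr_ecg", "hr_ppg"]].copy()
    pred_df["prediction"] = preds
    pred_df["fold"] = folds
    return CVResult(
        kind=spec.kind,
        fold_rmse=[float(r) for r in fold_rmse],
        rmse=float(pooled),
        ci95=ci,
        bland_altman=bland_altman(y, preds),
        predictions=pred_df,
    )
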