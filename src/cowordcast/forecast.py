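"""Background-enhanced regression forecasting of co-occurrence heat.

Each cell of the next half-year matrix is predicted from the w x w window
around that cell in the previous matrix.  Models are trained on every
(previous window -> current value) transition available before the target
bin, evaluated by R^2, and rolled forward recurrently for multi-step
horizons (predicted matrices become the next step's features; they are
never used as training targets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    OrthogonalMatchingPursuit,
    PassiveAggressiveRegressor,
    Ridge,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cooccurrence import CooccurrenceTensor
from .errors import ConfigurationError, NoHistoryError, UndefinedR2Error

__all__ = [
    "BACKENDS",
    "WindowSpec",
    "TrainingSet",
    "ForecastRun",
    "extract_window",
    "build_training_set",
    "fit",
    "predict_matrix",
    "predict_bin",
    "evaluate_r2",
    "recurrent_forecast",
    "window_size_sweep",
]

BACKENDS = ("svr", "lasso", "ridge", "elastic_net", "omp", "passive_aggressive")

#: backends whose historical ``normalize=True`` flag is reproduced as an
#: explicit per-column standardization step.
_STANDARDIZED = frozenset({"lasso", "ridge"})


@dataclass(frozen=True)
class WindowSpec:
    """Square neighborhood of odd side w; w=1 is the keyword-only baseline."""

    w: int = 3
    padding: float = 0.0

    def __post_init__(self):
        if self.w < 1 or self.w % 2 == 0:
            raise ConfigurationError(f"window size must be an odd positive integer, got {self.w}")

    @property
    def n_features(self) -> int:
        return self.w * self.w


@dataclass
class TrainingSet:
    """Aligned (window features at t-1, cell value at t) rows."""

    X: np.ndarray
    y: np.ndarray
    index: list[tuple[int, int, int]]  # (target bin t, i, j)

    def __post_init__(self):
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.index):
            raise ConfigurationError("X, y and index must be aligned")


@dataclass
class ForecastRun:
    backend: str
    window: WindowSpec
    predictions: dict[int, np.ndarray]
    r2_trace: dict[int, float]
    recurrent: bool
    seed: int = 0
    start_bin: int | None = None


def _as_counts(tensor) -> np.ndarray:
    if isinstance(tensor, CooccurrenceTensor):
        return np.asarray(tensor.counts, dtype=np.float64)
    arr = np.asarray(tensor, dtype=np.float64)
    if arr.ndim != 3:
        raise ConfigurationError("expected a CooccurrenceTensor or 3-D array")
    return arr


def extract_window(matrix: np.ndarray, i: int, j: int, spec: WindowSpec) -> np.ndarray:
    """Row-major flattening of the w x w block centred at (i, j).

    Out-of-bounds cells take the padding value; the centre cell sits at
    position (w^2 - 1) / 2 of the returned vector.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n, m = matrix.shape
    if not (0 <= i < n and 0 <= j < m):
        raise IndexError(f"cell ({i}, {j}) outside {n}x{m} matrix")
    half = spec.w // 2
    out = np.full((spec.w, spec.w), spec.padding, dtype=np.float64)
    r0, r1 = max(0, i - half), min(n, i + half + 1)
    c0, c1 = max(0, j - half), min(m, j + half + 1)
    out[r0 - (i - half) : r1 - (i - half), c0 - (j - half) : c1 - (j - half)] = matrix[r0:r1, c0:c1]
    return out.ravel()


def _window_features(matrix: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """All-cell window extraction, vectorized: returns (n*m, w^2)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    half = spec.w // 2
    padded = np.pad(matrix, half, mode="constant", constant_values=spec.padding)
    view = np.lib.stride_tricks.sliding_window_view(padded, (spec.w, spec.w))
    return view.reshape(matrix.shape[0] * matrix.shape[1], spec.w * spec.w)


def build_training_set(tensor, upto: int, spec: WindowSpec) -> TrainingSet:
    """One row per cell per transition t-1 -> t with 1 <= t <= upto."""
    counts = _as_counts(tensor)
    if upto < 1:
        raise NoHistoryError("need at least one transition (upto >= 1)")
    if upto >= counts.shape[0]:
        raise ConfigurationError(f"upto={upto} beyond last bin {counts.shape[0] - 1}")
    T, A, B = counts.shape
    X_parts, y_parts, index = [], [], []
    for t in range(1, upto + 1):
        X_parts.append(_window_features(counts[t - 1], spec))
        y_parts.append(counts[t].ravel())
        index.extend((t, i, j) for i in range(A) for j in range(B))
    return TrainingSet(X=np.vstack(X_parts), y=np.concatenate(y_parts), index=index)


def make_regressor(backend: str, seed: int = 0):
    """Instantiate a backend with the published settings, defaults elsewhere."""
    if backend == "svr":
        model = SVR()
    elif backend == "lasso":
        model = Lasso(random_state=seed)
    elif backend == "ridge":
        model = Ridge(random_state=seed)
    elif backend == "elastic_net":
        model = ElasticNet(random_state=seed)
    elif backend == "omp":
        model = OrthogonalMatchingPursuit()
    elif backend == "passive_aggressive":
        model = PassiveAggressiveRegressor(random_state=seed)
    else:
        raise ConfigurationError(f"unknown backend: {backend!r} (choose from {BACKENDS})")
    if backend in _STANDARDIZED:
        return Pipeline([("scale", StandardScaler()), ("reg", model)])
    return model


def fit(backend: str, train: TrainingSet, seed: int = 0):
    """Fit a backend on a training set; deterministic given the seed."""
    if train.X.shape[0] == 0:
        raise ConfigurationError("training set is empty")
    model = make_regressor(backend, seed)
    model.fit(train.X, train.y)
    return model


def predict_matrix(model, prev_matrix: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Predict every cell of the next matrix from its window in `prev_matrix`.

    Negative predictions are clamped to zero (counts cannot go below it).
    """
    prev_matrix = np.asarray(prev_matrix, dtype=np.float64)
    X = _window_features(prev_matrix, spec)
    pred = np.asarray(model.predict(X), dtype=np.float64)
    return np.clip(pred, 0.0, None).reshape(prev_matrix.shape)


def predict_bin(model, tensor, t: int, spec: WindowSpec) -> np.ndarray:
    """Single-step prediction of bin t from observed bin t-1."""
    counts = _as_counts(tensor)
    if t < 1 or t >= counts.shape[0] + 1:
        raise NoHistoryError(f"bin {t} has no prior bin available")
    return predict_matrix(model, counts[t - 1], spec)


def evaluate_r2(pred: np.ndarray, actual: np.ndarray) -> float:
    """Coefficient of determination over all flattened cells."""
    pred = np.asarray(pred, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if pred.shape != actual.shape:
        raise ConfigurationError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedR2Error("actual matrix has zero variance")
    ss_res = float(np.sum((actual - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def recurrent_forecast(
    tensor,
    start_bin: int,
    horizon: int,
    backend: str = "elastic_net",
    spec: WindowSpec = WindowSpec(3),
    seed: int = 0,
) -> ForecastRun:
    """Multi-step forecast: bin `start_bin` from observed history, then each
    subsequent bin from the previous *prediction*.

    The model is fit once on all observed transitions before `start_bin` and
    reused at every horizon; predicted matrices are feature inputs only,
    never training targets.  ``r2_trace`` covers only horizons where actual
    data exists.
    """
    counts = _as_counts(tensor)
    if start_bin < 1:
        raise NoHistoryError("start_bin must be >= 1")
    if horizon < 1:
        raise ConfigurationError("horizon must be >= 1")
    train = build_training_set(counts, upto=start_bin - 1, spec=spec) if start_bin > 1 else None
    if train is None:
        raise NoHistoryError("start_bin=1 leaves no transition to train on")
    model = fit(backend, train, seed)

    predictions: dict[int, np.ndarray] = {}
    r2_trace: dict[int, float] = {}
    prev = counts[start_bin - 1]
    for h in range(horizon):
        t = start_bin + h
        pred = predict_matrix(model, prev, spec)
        predictions[t] = pred
        if t < counts.shape[0]:
            r2_trace[t] = evaluate_r2(pred, counts[t])
        prev = pred
    return ForecastRun(
        backend=backend,
        window=spec,
        predictions=predictions,
        r2_trace=r2_trace,
        recurrent=True,
        seed=seed,
        start_bin=start_bin,
    )


def single_step_scores(
    tensor, spec: WindowSpec, backend: str, seed: int = 0, min_eval_bin: int = 2
) -> dict[int, float]:
    """Per-bin out-of-sample R^2: for each bin t, train on all transitions
    before t and predict t from observed bin t-1."""
    counts = _as_counts(tensor)
    scores: dict[int, float] = {}
    for t in range(max(2, min_eval_bin), counts.shape[0]):
        train = build_training_set(counts, upto=t - 1, spec=spec)
        model = fit(backend, train, seed)
        pred = predict_matrix(model, counts[t - 1], spec)
        scores[t] = evaluate_r2(pred, counts[t])
    return scores


def window_size_sweep(
    tensor,
    sizes: Sequence[int] = (1, 3, 5, 7, 9),
    backends: Sequence[str] = BACKENDS,
    seed: int = 0,
    min_eval_bin: int = 2,
):
    """Mean out-of-sample R^2 per (backend, window size).

    Returns a pandas DataFrame indexed by backend with one column per size.
    With the full semiannual 2000-2021 binning, pass ``min_eval_bin=5`` to
    aggregate from the July 2002 bin onward.
    """
    import pandas as pd

    for w in sizes:
        if w % 2 == 0:
            raise ConfigurationError(f"window sizes must be odd, got {w}")
    table = {}
    for backend in backends:
        row = {}
        for w in sizes:
            scores = single_step_scores(tensor, WindowSpec(w), backend, seed, min_eval_bin)
            row[w] = float(np.mean(list(scores.values()))) if scores else float("nan")
        table[backend] = row
    return pd.DataFrame.from_dict(table, orient="index")[list(sizes)]
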