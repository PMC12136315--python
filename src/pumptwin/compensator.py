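"""LSTM deviation forecasting and uniform per-infusion compensation.

The pump's per-infusion delivery deficit accumulates over a run of
fixed-dose infusions.  A small gated recurrent network is trained on
sliding windows of the cumulative-deviation series to predict it one
step ahead; the predicted cumulative deviation at the end of the run is
then spread uniformly over the planned infusions as a per-event add-on
to the commanded dose.

Model selection follows the usual grid-search recipe over epochs, batch
size and hidden-layer width, scored by test-set MAPE with RMSE as the
tie-break.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .deviation import InfusionRecord
from .nn import SequenceModel, TrainingDivergedError

__all__ = [
    "DeviationSeries",
    "ModelSpec",
    "FitResult",
    "CompensationPlan",
    "mape",
    "rmse",
    "chronological_split",
    "fit",
    "grid_search",
    "default_grid",
    "make_plan",
    "apply_plan",
]


@dataclass(frozen=True)
class DeviationSeries:
    """Per-infusion delivery deficits (U) and their exact running sum."""

    per_infusion_deviation: tuple[float, ...]
    cumulative_deviation: tuple[float, ...]
    commanded_dose: float

    def __post_init__(self) -> None:
        prefix = np.cumsum(self.per_infusion_deviation)
        if len(prefix) != len(self.cumulative_deviation) or not np.allclose(
            prefix, self.cumulative_deviation, rtol=0, atol=1e-12
        ):
            raise ValueError("cumulative_deviation must be the exact prefix sum")

    @classmethod
    def from_records(cls, records: Sequence[InfusionRecord]) -> "DeviationSeries":
        doses = {r.commanded_dose for r in records}
        if len(doses) != 1:
            raise ValueError("deviation series requires a constant commanded dose")
        per = tuple(r.commanded_dose - r.delivered_dose for r in records)
        return cls(
            per_infusion_deviation=per,
            cumulative_deviation=tuple(np.cumsum(per)),
            commanded_dose=doses.pop(),
        )

    def __len__(self) -> int:
        return len(self.per_infusion_deviation)

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "infusion_index": range(n),
                "commanded_dose_U": [self.commanded_dose] * n,
                "delivered_dose_U": [
                    self.commanded_dose - d for d in self.per_infusion_deviation
                ],
                "deviation_U": self.per_infusion_deviation,
                "cumulative_deviation_U": self.cumulative_deviation,
            }
        )


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters of one grid cell."""

    layer_pattern: str = "LDL"  # L = recurrent layer, D = dense layer
    hidden_units: int = 32
    epochs: int = 300
    batch_size: int = 256
    train_fraction: float = 0.85
    window_length: int = 10
    seed: int = 0
    learning_rate: float = 0.02

    def __post_init__(self) -> None:
        if len(self.layer_pattern) not in (3, 4):
            raise ValueError("layer_pattern length must be 3 or 4")
        if any(ch not in "LD" for ch in self.layer_pattern):
            raise ValueError("layer_pattern must be over 'L'/'D'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.hidden_units < 1 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid hyperparameters")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    mape: float  # percent, test set
    rmse: float  # U, test set
    train_curve: tuple[float, ...]  # per-epoch train loss (normalised units)
    test_curve: tuple[float, ...]  # per-epoch test loss (normalised units)
    train_accuracy: tuple[float, ...] = ()  # fraction within the relative band
    test_accuracy: tuple[float, ...] = ()
    predicted_final_cumulative: float = float("nan")  # U, one-step-ahead at the last index
    failed: bool = False
    error: str | None = None


@dataclass(frozen=True)
class CompensationPlan:
    """Uniform allocation of a predicted total deviation over a run."""

    predicted_total_deviation: float  # U
    n_infusions: int
    per_infusion_compensation: float  # U

    def __post_init__(self) -> None:
        if self.n_infusions < 1:
            raise ValueError("n_infusions must be >= 1")


def mape(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, excluding zero-valued targets."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    mask = a != 0
    if not np.any(mask):
        raise ValueError("MAPE undefined: all target entries are zero")
    return float(np.mean(np.abs(a[mask] - p[mask]) / np.abs(a[mask])) * 100.0)


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared error."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if a.size == 0:
        raise ValueError("rmse requires nonempty series")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def chronological_split(
    series: DeviationSeries, train_fraction: float, window_length: int = 0
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Contiguous time-ordered split of the cumulative series, no shuffling."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(series)
    boundary = int(np.floor(n * train_fraction))
    train = series.cumulative_deviation[:boundary]
    test = series.cumulative_deviation[boundary:]
    if len(test) < max(1, window_length):
        raise ValueError(
            f"split leaves a test set of {len(test)} < window_length {window_length}"
        )
    if len(train) == 0:
        raise ValueError("split leaves an empty training set")
    return train, test


def _windows(values: np.ndarray, start: int, stop: int, w: int):
    """Sliding (window, target) pairs targeting indices [start, stop)."""
    xs, ys = [], []
    for t in range(max(start, w), stop):
        xs.append(values[t - w : t])
        ys.append(values[t])
    return np.array(xs)[..., None], np.array(ys)


def fit(series: DeviationSeries, spec: ModelSpec) -> FitResult:
    """Train the recurrent forecaster on the cumulative-deviation series.

    The series is standardised with train-split statistics; sliding
    windows of ``window_length`` past values predict the next value.
    Training is plain SGD on mini-batches with gradient clipping;
    deterministic given ``spec.seed``.  Metrics (MAPE percent, RMSE in
    U) are computed on the original scale over the test split.
    """
    if len(series) < 10:
        raise ValueError("deviation series must have at least 10 entries for training")
    w = spec.window_length
    n = len(series)
    boundary = int(np.floor(n * spec.train_fraction))
    chronological_split(series, spec.train_fraction, w)  # validates feasibility

    values = np.asarray(series.cumulative_deviation, dtype=float)
    # the cumulative series trends, so the network is fed its per-step
    # increments (first differences) and predicts the next increment; the
    # one-step-ahead cumulative prediction is then last observed + increment.
    # This keeps the forecast on-scale outside the training range.
    increments = np.diff(values, prepend=0.0)
    mu = float(np.mean(increments[:boundary]))
    sd = float(np.std(increments[:boundary]))
    sd = sd if sd > 0 else 1.0
    norm = (increments - mu) / sd

    x_train, y_train = _windows(norm, 0, boundary, w)
    x_test, y_test = _windows(norm, boundary, n, w)
    if len(x_train) == 0:
        raise ValueError("window_length leaves no training windows")
    # cumulative value preceding each target index (for reconstruction)
    base_train = values[np.arange(w, boundary) - 1]
    base_test = values[np.arange(boundary, n) - 1]
    cum_train = values[np.arange(w, boundary)]
    cum_test = values[np.arange(boundary, n)]

    model = SequenceModel(spec.layer_pattern, spec.hidden_units, seed=spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    band = 0.05  # relative tolerance defining a "correct" prediction

    def _cum_pred(z: np.ndarray, base: np.ndarray) -> np.ndarray:
        return base + (z * sd + mu)

    def _accuracy(cum_true: np.ndarray, cum_hat: np.ndarray) -> float:
        mask = cum_true != 0
        if not np.any(mask):
            return float("nan")
        return float(
            np.mean(np.abs(cum_hat[mask] - cum_true[mask]) <= band * np.abs(cum_true[mask]))
        )

    train_curve, test_curve = [], []
    train_acc, test_acc = [], []
    n_train = len(x_train)
    for _ in range(spec.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            model.train_batch(x_train[idx], y_train[idx], spec.learning_rate)
        pred_train = model.forward(x_train)
        pred_test = model.forward(x_test)
        train_curve.append(float(np.mean((pred_train - y_train) ** 2)))
        test_curve.append(float(np.mean((pred_test - y_test) ** 2)))
        train_acc.append(_accuracy(cum_train, _cum_pred(pred_train, base_train)))
        test_acc.append(_accuracy(cum_test, _cum_pred(pred_test, base_test)))

    pred_test = _cum_pred(model.forward(x_test), base_test)
    return FitResult(
        spec=spec,
        mape=mape(cum_test, pred_test),
        rmse=rmse(cum_test, pred_test),
        train_curve=tuple(train_curve),
        test_curve=tuple(test_curve),
        train_accuracy=tuple(train_acc),
        test_accuracy=tuple(test_acc),
        predicted_final_cumulative=float(pred_test[-1]),
    )


def default_grid() -> list[ModelSpec]:
    """The shipped 16-cell lattice: epochs x batch x hidden widths."""
    return [
        ModelSpec(epochs=e, batch_size=b, hidden_units=h)
        for e, b, h in itertools.product((100, 300, 500, 700), (128, 256), (32, 64))
    ]


def grid_search(series: DeviationSeries, grid: Sequence[ModelSpec] | None = None) -> list[FitResult]:
    """Fit every grid cell; rank by MAPE, then RMSE, then fewer epochs.

    Cells whose training diverges are returned last, flagged as failed.
    """
    cells = list(grid) if grid is not None else default_grid()
    if not cells:
        raise ValueError("grid must be nonempty")
    results: list[FitResult] = []
    for spec in cells:
        try:
            results.append(fit(series, spec))
        except (TrainingDivergedError, ValueError) as exc:
            results.append(
                FitResult(
                    spec=spec, mape=float("inf"), rmse=float("inf"),
                    train_curve=(), test_curve=(), failed=True, error=str(exc),
                )
            )
    results.sort(key=lambda r: (r.failed, r.mape, r.rmse, r.spec.epochs))
    return results


def make_plan(predicted_total: float, n_infusions: int) -> CompensationPlan:
    """Spread a predicted total deviation uniformly over planned infusions."""
    if n_infusions < 1:
        raise ValueError("n_infusions must be >= 1")
    return CompensationPlan(
        predicted_total_deviation=predicted_total,
        n_infusions=n_infusions,
        per_infusion_compensation=predicted_total / n_infusions,
    )


def apply_plan(records: Sequence[InfusionRecord], plan: CompensationPlan) -> list[InfusionRecord]:
    """Raise each commanded dose by the per-infusion compensation.

    Delivered doses are carried over unchanged; they are meant to be
    re-simulated or re-measured downstream with the raised commands.
    """
    if plan.n_infusions != len(records):
        raise ValueError(
            f"plan covers {plan.n_infusions} infusions but {len(records)} records given"
        )
    return [
        replace(r, commanded_dose=r.commanded_dose + plan.per_infusion_compensation)
        for r in records
    ]
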