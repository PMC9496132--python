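"""Six transient-response descriptors per sensor over a fixed window.

Each sensor curve is summarised over the 30-300 s window by six scalar
descriptors of the transient and plateau behaviour:

========================  =====================================================
descriptor                definition on windowed values v_1..v_m at step dt
========================  =====================================================
integral                  trapezoidal integral of v (mg.s/L)
variance                  population variance of v (divide by m)
avg_differential          mean first difference / dt = (v_m - v_1)/((m-1) dt)
max_gradient              max_i (v_{i+1} - v_i)/dt, signed (flag for absolute)
stable_average            mean of the final `stable_fraction` of v (plateau)
energy                    sum v_i^2 * dt
========================  =====================================================

An 8-channel record therefore contributes 48 features; after the two dead
channels are excluded, 36.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import ResponseCurve, SampleRecord

__all__ = [
    "DESCRIPTOR_NAMES",
    "FeatureWindow",
    "FeatureTable",
    "integral_value",
    "variance_value",
    "average_differential",
    "maximum_gradient",
    "stable_average",
    "energy_value",
    "extract_features",
]

DESCRIPTOR_NAMES = (
    "integral",
    "variance",
    "avg_differential",
    "max_gradient",
    "stable_average",
    "energy",
)


@dataclass(frozen=True)
class FeatureWindow:
    """Time window (seconds, inclusive endpoints) used by all descriptors."""

    start_s: float = 30.0
    end_s: float = 300.0

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError("require 0 <= start_s < end_s")

    def slice(self, curve: ResponseCurve) -> np.ndarray:
        """Windowed values, validating coverage and minimum length."""
        t = curve.times
        if self.start_s < t[0] or self.end_s > t[-1]:
            raise ValueError(
                f"window [{self.start_s}, {self.end_s}] s outside the "
                f"acquired grid [{t[0]}, {t[-1]}] s"
            )
        mask = (t >= self.start_s) & (t <= self.end_s)
        v = curve.values[mask]
        if len(v) < 3:
            raise ValueError("window must contain at least 3 samples")
        return v


@dataclass
class FeatureTable:
    """n x d descriptor matrix with aligned labels and column names."""

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        if self.X.shape[0] != len(self.labels) or len(self.labels) != len(
            self.sample_ids
        ):
            raise ValueError("rows, labels and sample_ids must align")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return self.X.shape[0]


def integral_value(curve: ResponseCurve, window: FeatureWindow) -> float:
    """Trapezoidal integral of the windowed curve (mg.s/L)."""
    v = window.slice(curve)
    return float(np.trapezoid(v, dx=curve.dt))


def variance_value(curve: ResponseCurve, window: FeatureWindow) -> float:
    """Population variance of the windowed values."""
    v = window.slice(curve)
    return float(np.var(v))


def average_differential(curve: ResponseCurve, window: FeatureWindow) -> float:
    """Mean of the first differences divided by dt.

    By telescoping this equals (v_m - v_1) / ((m - 1) dt): the mean slope
    across the window.
    """
    v = window.slice(curve)
    return float(np.mean(np.diff(v)) / curve.dt)


def maximum_gradient(
    curve: ResponseCurve, window: FeatureWindow, absolute: bool = False
) -> float:
    """Largest one-step slope in the window (signed by default)."""
    v = window.slice(curve)
    grads = np.diff(v) / curve.dt
    return float(np.abs(grads).max() if absolute else grads.max())


def stable_average(
    curve: ResponseCurve, window: FeatureWindow, stable_fraction: float = 0.5
) -> float:
    """Mean of the final ``stable_fraction`` of the windowed values.

    With the default window and fraction this is the 165-300 s plateau mean,
    inside the region the acquisition treats as stable.
    """
    if not 0.0 < stable_fraction <= 1.0:
        raise ValueError("stable_fraction must be in (0, 1]")
    v = window.slice(curve)
    m = int(np.ceil(len(v) * stable_fraction))
    return float(v[-m:].mean())


def energy_value(curve: ResponseCurve, window: FeatureWindow) -> float:
    """Signal energy: sum of squared windowed values times dt."""
    v = window.slice(curve)
    return float(np.sum(v**2) * curve.dt)


def _descriptor_row(
    curve: ResponseCurve,
    window: FeatureWindow,
    stable_fraction: float,
    absolute_gradient: bool,
) -> list[float]:
    return [
        integral_value(curve, window),
        variance_value(curve, window),
        average_differential(curve, window),
        maximum_gradient(curve, window, absolute=absolute_gradient),
        stable_average(curve, window, stable_fraction=stable_fraction),
        energy_value(curve, window),
    ]


def extract_features(
    dataset: list[SampleRecord],
    window: FeatureWindow | None = None,
    stable_fraction: float = 0.5,
    absolute_gradient: bool = False,
) -> FeatureTable:
    """Assemble the feature table: one row per sample, six descriptors per
    channel in the documented order, columns named ``ch<k>_<descriptor>``.
    """
    window = window or FeatureWindow()
    if not dataset:
        return FeatureTable(
            np.empty((0, 0)), [], np.array([], dtype=object), []
        )
    channel_ids = dataset[0].channel_ids
    names = [
        f"ch{ch}_{desc}" for ch in channel_ids for desc in DESCRIPTOR_NAMES
    ]
    rows = []
    for rec in dataset:
        if rec.channel_ids != channel_ids:
            raise ValueError(
                f"record {rec.sample_id} has channels {rec.channel_ids}, "
                f"expected {channel_ids}"
            )
        row: list[float] = []
        for c in rec.curves:
            row.extend(
                _descriptor_row(c, window, stable_fraction, absolute_gradient)
            )
        rows.append(row)
    X = np.array(rows, dtype=float)
    labels = np.array([r.label for r in dataset], dtype=object)
    ids = [r.sample_id for r in dataset]
    return FeatureTable(X, names, labels, ids)
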