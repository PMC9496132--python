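"""Response-curve preprocessing and outlier screening.

Four stages, applied in acquisition order:

1. k-point linear smoothing (unweighted moving average, k in {3,5,7,9,11});
   7-point is the default used downstream.
2. The duplicated-sensor anomaly rule: two identical sensors are compared
   over a late window and the record is flagged when they disagree by more
   than a threshold (default 1.2 mg/L over 150-300 s).
3. Dead-channel exclusion: channels whose readings never leave the
   detection floor across the whole dataset are dropped.
4. Mahalanobis-distance outlier removal in feature space, per class, with a
   chi-square quantile cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synth import ResponseCurve, SampleRecord

__all__ = [
    "PairAnomalyRule",
    "OutlierReport",
    "smooth_linear",
    "smooth_record",
    "flag_pair_anomaly",
    "drop_dead_channels",
    "mahalanobis_distances",
    "remove_outliers",
]

SMOOTHING_WINDOWS = (3, 5, 7, 9, 11)

#: Condition number above which the sample covariance is ridge-regularized.
COV_CONDITION_LIMIT = 1e10
#: Ridge scale: lambda = COV_RIDGE_REL * trace(S) / d.
COV_RIDGE_REL = 1e-6


@dataclass(frozen=True)
class PairAnomalyRule:
    """Disagreement rule between the two duplicated indicator sensors."""

    channel_a: int = 0
    channel_b: int = 4
    window_s: tuple[float, float] = (150.0, 300.0)
    threshold: float = 1.2
    #: 'max' (strictest reading) or 'mean' aggregation of |a - b| over the window.
    aggregate: str = "max"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.window_s[0] >= self.window_s[1]:
            raise ValueError("window_s must be a non-empty interval")
        if self.aggregate not in ("max", "mean"):
            raise ValueError("aggregate must be 'max' or 'mean'")


@dataclass
class OutlierReport:
    """Per-sample Mahalanobis distances and the removal decision."""

    removed_indices: list[int]
    distances: np.ndarray
    cutoff: float
    n_removed_per_class: dict[str, int] = field(default_factory=dict)


def smooth_linear(curve: ResponseCurve, k: int = 7) -> ResponseCurve:
    """k-point linear smoothing: unweighted mean of the window centred at
    each point. Near the ends the symmetric window shrinks, so the output
    has the same length as the input and no phase shift.
    """
    if k not in SMOOTHING_WINDOWS:
        raise ValueError(
            f"k must be an odd window in {SMOOTHING_WINDOWS}, got {k}"
        )
    v = curve.values
    n = len(v)
    if n < k:
        raise ValueError(f"curve length {n} shorter than window {k}")
    half = (k - 1) // 2
    out = np.empty_like(v)
    # interior via cumulative sum; edges via shrunken symmetric windows
    csum = np.concatenate(([0.0], np.cumsum(v)))
    out[half : n - half] = (csum[k:] - csum[:-k]) / k
    for i in range(half):
        h = i
        out[i] = v[: 2 * h + 1].mean()
        j = n - 1 - i
        out[j] = v[j - h :].mean()
    return ResponseCurve(curve.channel_id, curve.times, out)


def smooth_record(record: SampleRecord, k: int = 7) -> SampleRecord:
    """Smooth every channel of a record."""
    return SampleRecord(
        record.sample_id,
        record.label,
        [smooth_linear(c, k) for c in record.curves],
        record.is_injected_outlier,
    )


def flag_pair_anomaly(record: SampleRecord, rule: PairAnomalyRule | None = None) -> bool:
    """True iff the duplicated sensors disagree by strictly more than the
    threshold over the rule's window."""
    rule = rule or PairAnomalyRule()
    try:
        a = record.curve(rule.channel_a)
    except KeyError:
        raise KeyError(
            f"record {record.sample_id} is missing channel {rule.channel_a}"
        ) from None
    try:
        b = record.curve(rule.channel_b)
    except KeyError:
        raise KeyError(
            f"record {record.sample_id} is missing channel {rule.channel_b}"
        ) from None
    lo, hi = rule.window_s
    mask = (a.times >= lo) & (a.times <= hi)
    if not mask.any():
        raise ValueError("anomaly window contains no samples")
    diff = np.abs(a.values[mask] - b.values[mask])
    agg = diff.max() if rule.aggregate == "max" else diff.mean()
    return bool(agg > rule.threshold)


def drop_dead_channels(
    dataset: list[SampleRecord], epsilon: float = 1e-6
) -> tuple[list[SampleRecord], list[int]]:
    """Drop channels whose every value across every sample is within
    ``epsilon`` of zero. Returns the reduced dataset and the dropped ids."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if not dataset:
        return [], []
    channel_ids = dataset[0].channel_ids
    dead = []
    for ch in channel_ids:
        if all(np.all(np.abs(r.curve(ch).values) <= epsilon) for r in dataset):
            dead.append(ch)
    if len(dead) == len(channel_ids):
        raise ValueError("all channels are dead; nothing left to analyse")
    if not dead:
        return dataset, []
    dead_set = set(dead)
    reduced = [
        SampleRecord(
            r.sample_id,
            r.label,
            [c for c in r.curves if c.channel_id not in dead_set],
            r.is_injected_outlier,
        )
        for r in dataset
    ]
    return reduced, dead


def _regularized_covariance(
    X: np.ndarray, regularize: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Column mean and (ridge-regularized, unbiased) sample covariance."""
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    d = S.shape[0]
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > COV_CONDITION_LIMIT:
        if not regularize:
            raise np.linalg.LinAlgError(
                "sample covariance is singular or ill-conditioned; enable "
                "regularization (regularize=True) to proceed"
            )
        lam = COV_RIDGE_REL * np.trace(S) / d
        if lam <= 0:
            lam = COV_RIDGE_REL
        S = S + lam * np.eye(d)
    return mu, S


def mahalanobis_distances(X: np.ndarray, regularize: bool = True) -> np.ndarray:
    """Mahalanobis distance of every row from the sample mean.

    ``d_i = sqrt((x_i - mu)^T S^{-1} (x_i - mu))`` with the unbiased sample
    covariance S. When S is near-singular a small ridge (relative to its
    trace) is added, unless ``regularize`` is off, in which case an error is
    raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    mu, S = _regularized_covariance(X, regularize)
    centered = X - mu
    sol = np.linalg.solve(S, centered.T)
    d2 = np.einsum("ij,ji->i", centered, sol)
    return np.sqrt(np.maximum(d2, 0.0))


def _screen_once(
    X: np.ndarray,
    labels: np.ndarray,
    cutoff: float,
    regularize: bool,
) -> tuple[np.ndarray, list[int], dict[str, int]]:
    """One per-class screening pass: distances and above-cutoff indices."""
    d = X.shape[1]
    distances = np.empty(len(X))
    removed: list[int] = []
    per_class: dict[str, int] = {}
    for lab in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:  # a lone survivor cannot be screened further
            distances[idx] = 0.0
            per_class[str(lab)] = 0
            continue
        if len(idx) < d + 2 and not regularize:
            raise ValueError(
                f"class {lab!r} has {len(idx)} samples for {d} features; "
                "enable covariance regularization or pool covariances"
            )
        dist = mahalanobis_distances(X[idx], regularize=regularize)
        distances[idx] = dist
        bad = idx[dist > cutoff]
        removed.extend(int(i) for i in bad)
        per_class[str(lab)] = len(bad)
    removed.sort()
    return distances, removed, per_class


def remove_outliers(
    X: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.025,
    regularize: bool = True,
    max_iter: int | None = None,
) -> tuple[np.ndarray, np.ndarray, OutlierReport]:
    """Per-class Mahalanobis screening with a chi-square cutoff.

    Distances are computed within each class (its own mean and covariance);
    samples whose distance exceeds ``sqrt(chi2.ppf(1 - alpha, d))`` are
    removed. With multivariate-normal data the squared distance is
    approximately chi-square with d degrees of freedom, so ``alpha`` is the
    nominal per-sample tail probability.

    By default the screen is iterated to a fixpoint: gross outliers inflate
    the very covariance they are judged against (masking), so after each
    removal the statistics are refit on the survivors and the screen is
    reapplied until no sample exceeds the cutoff. ``max_iter=1`` gives the
    single-pass variant.

    The report's ``distances`` are each sample's distance at the pass in
    which it was removed (survivors: the final pass), so at the returned
    fixpoint exactly the removed samples exceed the cutoff.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if max_iter is not None and max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(X) != len(labels):
        raise ValueError("X and labels must align")
    d = X.shape[1]
    cutoff = float(np.sqrt(stats.chi2.ppf(1.0 - alpha, df=d)))
    n = len(X)
    distances = np.zeros(n)
    keep = np.arange(n)
    removed_all: list[int] = []
    per_class_all: dict[str, int] = {}
    limit = max_iter if max_iter is not None else n
    for _ in range(limit):
        dist, removed, per_class = _screen_once(
            X[keep], labels[keep], cutoff, regularize
        )
        distances[keep] = dist
        for lab, cnt in per_class.items():
            per_class_all[lab] = per_class_all.get(lab, 0) + cnt
        if not removed:
            break
        removed_all.extend(int(keep[i]) for i in removed)
        keep = np.delete(keep, removed)
        if len(keep) == 0:
            warnings.warn("every sample flagged as outlier; returning empty data")
            break
    removed_all.sort()
    report = OutlierReport(
        removed_indices=removed_all,
        distances=distances,
        cutoff=cutoff,
        n_removed_per_class=per_class_all,
    )
    return X[keep], labels[keep], report
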