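"""Linear comparator measures: cross-, partial- and signal/noise correlation.

These are the standard correlation-based connectivity measures that IMI
is compared against.  The cross-correlation function conflates
connection dynamics with temporal structure in each train; the partial
cross-correlation conditions the windowed past/future of both trains
out linearly; the signal/noise decomposition uses repeated identical
trials (the "shift predictor") to isolate the stimulus-locked part.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    BinnedTrain,
    DelayProfile,
    TrialSet,
    conditioning_design_matrix,
)
from .imi import select_trial_pairs

__all__ = [
    "cross_correlation",
    "partial_cross_correlation",
    "signal_correlation",
    "noise_correlation",
]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError(
            "constant train over the overlapping range: correlation undefined "
            "(zero standard deviation)"
        )
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _overlap(x: np.ndarray, y: np.ndarray, delta: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned samples X[n], Y[n - delta] over the overlapping index range."""
    n = x.size
    lo = max(0, delta)
    hi = min(n - 1, n - 1 + delta)
    if hi < lo:
        raise ValueError(f"delay {delta} leaves no overlap for length-{n} trains")
    return x[lo : hi + 1].astype(float), y[lo - delta : hi + 1 - delta].astype(float)


def cross_correlation(x: BinnedTrain, y: BinnedTrain, deltas) -> DelayProfile:
    """Pearson correlation between X[n] and Y[n - delta] at each delay."""
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    deltas = np.asarray(deltas, dtype=np.int64)
    values = np.empty(deltas.size)
    for i, d in enumerate(deltas):
        a, b = _overlap(x.values, y.values, int(d))
        values[i] = _pearson(a, b)
    return DelayProfile(deltas=deltas, values=values, measure_name="cross_correlation")


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residual of v after least-squares regression on [1, z].

    Collinear columns are harmless: lstsq returns the minimum-norm
    solution, whose fitted values (hence residuals) are unique.  A
    warning is emitted when the design is rank deficient.
    """
    design = np.column_stack([np.ones(v.size), z])
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "conditioning design matrix is rank deficient; collinear window "
            "columns contribute nothing to the fit",
            stacklevel=3,
        )
    return v - design @ coef


def partial_cross_correlation(
    x: BinnedTrain,
    y: BinnedTrain,
    deltas,
    omega: int,
) -> DelayProfile:
    """Correlation of X[n] and Y[n - delta] residuals after linearly
    regressing each on the 4*omega window bins of the conditioning vector.

    ``omega = 0`` uses an empty conditioning set and reduces to the
    plain cross-correlation on the same valid samples.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    deltas = np.asarray(deltas, dtype=np.int64)
    values = np.empty(deltas.size)
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for i, d in enumerate(deltas):
            z, x_t, y_t = conditioning_design_matrix(x, y, int(d), omega)
            rx = _residualize(x_t, z)
            ry = _residualize(y_t, z)
            values[i] = _pearson(rx, ry)
    return DelayProfile(
        deltas=deltas, values=values, measure_name="partial_cross_correlation"
    )


def _pooled_pair_corr(
    trials: TrialSet,
    delta: int,
    pairs: list[tuple[int, int]],
) -> float:
    xs, ys = [], []
    for i, j in pairs:
        xi, yj = trials.trials[i][0], trials.trials[j][1]
        a, b = _overlap(xi.values, yj.values, delta)
        xs.append(a)
        ys.append(b)
    return _pearson(np.concatenate(xs), np.concatenate(ys))


def signal_correlation(
    trials: TrialSet,
    deltas,
    rng: np.random.Generator | None = None,
) -> DelayProfile:
    """Across-trial ("shift predictor") correlation at each delay.

    X on trial i is paired with Y on trial j != i, pooling all ordered
    pairs (or a seeded subsample when the trial count is large), so only
    the stimulus-locked dependency survives.
    """
    pairs = select_trial_pairs(trials.n_trials, rng)
    deltas = np.asarray(deltas, dtype=np.int64)
    values = np.array([_pooled_pair_corr(trials, int(d), pairs) for d in deltas])
    return DelayProfile(deltas=deltas, values=values, measure_name="signal_correlation")


def within_trial_correlation(trials: TrialSet, deltas) -> DelayProfile:
    """Total correlation pooled over within-trial samples."""
    same = [(i, i) for i in range(trials.n_trials)]
    deltas = np.asarray(deltas, dtype=np.int64)
    values = np.array([_pooled_pair_corr(trials, int(d), same) for d in deltas])
    return DelayProfile(
        deltas=deltas, values=values, measure_name="within_trial_correlation"
    )


def noise_correlation(
    trials: TrialSet,
    deltas,
    rng: np.random.Generator | None = None,
) -> DelayProfile:
    """Within-trial correlation minus the signal correlation at each delay."""
    total = within_trial_correlation(trials, deltas)
    signal = signal_correlation(trials, deltas, rng)
    return DelayProfile(
        deltas=total.deltas,
        values=total.values - signal.values,
        measure_name="noise_correlation",
    )


__all__.append("within_trial_correlation")
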