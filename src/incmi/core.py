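"""Domain containers and conditioning-vector construction.

All delay-resolved measures in this package operate on binarized spike
trains: one value per time bin, each bin holding at most one spike.  The
central construction is the *conditioning vector* — for each sample index
``n`` and delay ``delta``, the windowed past and future of both trains
around the pair of samples ``(X[n], Y[n - delta])`` whose dependency is
being measured.  The two anchor samples themselves are always excluded
from the vector.

Conventions
-----------
* bins are half-open intervals ``[t, t + bin_width)``; indices are 0-based
* positive ``delta`` means Y leads X: the measure pairs ``X[n]`` with
  ``Y[n - delta]``
* the X window is anchored on ``n`` and the Y window on ``n - delta``,
  so the excluded Y sample is exactly the one whose incremental
  contribution is being measured
* samples whose windows overrun either end of the recording are dropped
  (no padding); the number of valid samples therefore depends on both
  ``delta`` and ``omega``
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BinnedTrain",
    "TrialSet",
    "ConditioningVector",
    "DelayProfile",
    "BinningError",
    "bin_spike_times",
    "build_conditioning_words",
    "conditioning_design_matrix",
]


class BinningError(ValueError):
    """Raised when spike times cannot be represented as binary bins."""


@dataclass(frozen=True)
class BinnedTrain:
    """A binary spike train: one 0/1 value per time bin.

    Parameters
    ----------
    values
        Sequence of 0/1 spike indicators, one per bin.
    bin_width
        Bin width in seconds.  Optional metadata; abstract sequences
        (e.g. simulated trains) may leave it unset.
    """

    values: np.ndarray
    bin_width: float | None = None

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.values, dtype=np.int64)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("a binned train must be a non-empty 1-D sequence")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("binned train values must all be 0 or 1")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def n_spikes(self) -> int:
        return int(self.values.sum())

    def spike_bins(self) -> np.ndarray:
        """Indices of bins containing a spike."""
        return np.flatnonzero(self.values)


@dataclass(frozen=True)
class TrialSet:
    """Equal-length (X, Y) spike-train pairs from repeated identical trials."""

    trials: tuple[tuple[BinnedTrain, BinnedTrain], ...]

    def __post_init__(self) -> None:
        trials = tuple((x, y) for x, y in self.trials)
        if not trials:
            raise ValueError("a trial set needs at least one trial")
        length = len(trials[0][0])
        for x, y in trials:
            if len(x) != length or len(y) != length:
                raise ValueError("all trains in all trials must share one length")
        object.__setattr__(self, "trials", trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def trial_length(self) -> int:
        return len(self.trials[0][0])

    def __iter__(self):
        return iter(self.trials)


@dataclass(frozen=True)
class ConditioningVector:
    """Per-sample discrete context words for one delay.

    Each word packs the windowed past/future bins of both trains into a
    single integer with a fixed bit order (X past oldest-first, X future,
    Y past oldest-first, Y future; first bit most significant).  Words of
    a full vector carry ``4 * omega`` bits; past-only vectors carry
    ``2 * omega`` bits.
    """

    delta: int
    omega: int
    words: np.ndarray          # int64 codes in [0, 2**n_bits)
    indices: np.ndarray        # the valid sample indices n, ascending
    n_bits: int
    past_only: bool = False

    @property
    def n_samples(self) -> int:
        return int(self.words.size)


@dataclass
class DelayProfile:
    """A dependency measure evaluated on a grid of integer delays."""

    deltas: np.ndarray
    values: np.ndarray
    measure_name: str = ""
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    sig_threshold: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.deltas.shape != self.values.shape:
            raise ValueError("deltas and values must have matching shape")
        if self.deltas.size and not (np.diff(self.deltas) > 0).all():
            raise ValueError("deltas must be strictly increasing")
        for name in ("ci_low", "ci_high", "sig_threshold"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.asarray(arr, dtype=float))
        if self.ci_low is not None and self.ci_high is not None:
            # a confidence band must bracket the point estimate
            self.ci_low = np.minimum(self.ci_low, self.values)
            self.ci_high = np.maximum(self.ci_high, self.values)

    def argmax_delta(self) -> int:
        """Delay at which the profile attains its maximum."""
        return int(self.deltas[int(np.argmax(self.values))])

    def value_at(self, delta: int) -> float:
        idx = np.flatnonzero(self.deltas == delta)
        if idx.size != 1:
            raise KeyError(f"delay {delta} not on the grid")
        return float(self.values[idx[0]])

    def to_frame(self):
        import pandas as pd

        data = {"delta": self.deltas, "value": self.values}
        for name in ("ci_low", "ci_high", "sig_threshold"):
            arr = getattr(self, name)
            if arr is not None:
                data[name] = arr
        return pd.DataFrame(data)


def bin_spike_times(
    spike_times: Sequence[float],
    bin_width: float,
    t_start: float,
    t_end: float,
) -> BinnedTrain:
    """Discretize spike times into binary bins.

    Spikes are assigned to half-open bins ``[t_start + k*bin_width,
    t_start + (k+1)*bin_width)``; spikes outside ``[t_start, t_end)`` are
    ignored.  The measures in this package assume at most one spike per
    bin, so any bin receiving two or more spikes raises
    :class:`BinningError` — choose a smaller ``bin_width`` instead.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    times = np.sort(np.asarray(spike_times, dtype=float))
    n_bins = int(np.ceil((t_end - t_start) / bin_width - 1e-12))
    counts = np.zeros(n_bins, dtype=np.int64)
    times = times[(times >= t_start) & (times < t_end)]
    if times.size:
        k = np.floor((times - t_start) / bin_width).astype(np.int64)
        k = np.clip(k, 0, n_bins - 1)
        np.add.at(counts, k, 1)
    bad = np.flatnonzero(counts > 1)
    if bad.size:
        b = int(bad[0])
        raise BinningError(
            f"bin {b} ([{t_start + b * bin_width:g}, "
            f"{t_start + (b + 1) * bin_width:g}) s) holds {int(counts[b])} "
            f"spikes; use a bin_width smaller than {bin_width:g} s so that "
            "each bin contains at most one spike"
        )
    return BinnedTrain(counts, bin_width=bin_width)


def _valid_range(n: int, delta: int, omega: int, past_only: bool) -> tuple[int, int]:
    """Inclusive range of sample indices whose windows fit inside [0, n)."""
    lo = max(omega, omega + delta)
    if past_only:
        hi = min(n - 1, n - 1 + delta)
    else:
        hi = min(n - 1 - omega, n - 1 - omega + delta)
    return lo, hi


def _window_offsets(
    delta: int, omega: int, past_only: bool
) -> tuple[list[int], list[int]]:
    """Offsets (relative to n) of the window bins, in packing order."""
    x_past = [-k for k in range(omega, 0, -1)]
    x_future = [] if past_only else list(range(1, omega + 1))
    y_past = [-delta - k for k in range(omega, 0, -1)]
    y_future = [] if past_only else [-delta + k for k in range(1, omega + 1)]
    return x_past + x_future, y_past + y_future


def _aligned_columns(
    x: np.ndarray,
    y: np.ndarray,
    delta: int,
    omega: int,
    past_only: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = x.size
    lo, hi = _valid_range(n, delta, omega, past_only)
    if hi < lo:
        raise ValueError(
            f"trains of length {n} leave no valid samples for delta={delta}, "
            f"omega={omega}; need length > 2*(omega + |delta|)"
        )
    m = hi - lo + 1
    x_off, y_off = _window_offsets(delta, omega, past_only)
    cols = [x[lo + o : lo + o + m] for o in x_off]
    cols += [y[lo + o : lo + o + m] for o in y_off]
    bits = np.stack(cols, axis=1) if cols else np.empty((m, 0), dtype=np.int64)
    x_t = x[lo : hi + 1]
    y_t = y[lo - delta : hi + 1 - delta]
    return bits, x_t, y_t, np.arange(lo, hi + 1)


def build_conditioning_words(
    x: BinnedTrain,
    y: BinnedTrain,
    delta: int,
    omega: int,
    past_only: bool = False,
) -> tuple[ConditioningVector, np.ndarray, np.ndarray]:
    """Build packed conditioning words and the aligned anchor samples.

    Returns ``(vector, x_aligned, y_aligned)`` where ``x_aligned[k] =
    X[n_k]`` and ``y_aligned[k] = Y[n_k - delta]`` for the valid sample
    indices ``n_k`` recorded in ``vector.indices``.  The word at each
    sample never includes either anchor.
    """
    if omega < 1:
        raise ValueError("omega must be at least 1")
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    bits, x_t, y_t, idx = _aligned_columns(
        x.values, y.values, int(delta), int(omega), past_only
    )
    n_bits = bits.shape[1]
    weights = 1 << np.arange(n_bits - 1, -1, -1, dtype=np.int64)
    words = bits @ weights
    vec = ConditioningVector(
        delta=int(delta),
        omega=int(omega),
        words=words,
        indices=idx,
        n_bits=n_bits,
        past_only=past_only,
    )
    return vec, x_t, y_t


def conditioning_design_matrix(
    x: BinnedTrain,
    y: BinnedTrain,
    delta: int,
    omega: int,
    past_only: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window bins as real-valued regressors (for partial correlation).

    Returns ``(Z, x_aligned, y_aligned)`` with one column per window bin,
    in the same order used for word packing.  ``omega = 0`` yields an
    empty design, aligning the samples without conditioning on anything.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    bits, x_t, y_t, _ = _aligned_columns(
        x.values, y.values, int(delta), int(omega), past_only
    )
    return bits.astype(float), x_t.astype(float), y_t.astype(float)
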