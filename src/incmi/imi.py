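"""Incremental mutual information (IMI) and its variants.

IMI quantifies, at each integer delay ``delta``, the additional
reduction in the entropy of ``X[n]`` obtained by observing
``Y[n - delta]`` after first conditioning on the windowed past and
future of both trains (the conditioning vector V):

    dI(delta) = H(X[n] | V) - H(X[n] | V, Y[n - delta])      [bits]

Because V already absorbs every dependency that is predictable from the
neighbouring samples — slow shared inputs, refractoriness, burstiness —
what remains is the dependency specific to the probed delay, which is
what a direct synaptic connection produces.  The normalized variant
expresses this as a fraction of its maximum possible value,

    dI_norm(delta) = dI(delta) / H(X[n] | V),

which is 1 when Y at that delay removes all remaining uncertainty about
X and 0 when it removes none.

The past-only variant conditions only on the two pasts (the
delay-resolved relative of transfer entropy); the trial-based signal and
noise variants split the dependency into a stimulus-locked component
(measured across different trials) and the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinnedTrain, DelayProfile, TrialSet, build_conditioning_words

__all__ = [
    "IMIResult",
    "imi",
    "normalized_imi",
    "past_only_imi",
    "signal_imi",
    "noise_imi",
    "trial_imi",
    "make_imi_stat",
    "select_trial_pairs",
]

#: below this conditional entropy (bits) the normalized IMI is defined as 0
DENOM_TOL = 1e-12

#: above this many trials, ordered trial pairs are subsampled
MAX_EXHAUSTIVE_TRIALS = 50
N_SAMPLED_PAIRS = 2000


@dataclass
class IMIResult:
    """A delay profile of an IMI variant plus its estimation metadata."""

    profile: DelayProfile
    omega: int
    n_valid_samples: np.ndarray
    bias_corrected: bool

    @property
    def deltas(self) -> np.ndarray:
        return self.profile.deltas

    @property
    def values(self) -> np.ndarray:
        return self.profile.values


def _entropy_from_counts(counts: np.ndarray) -> float:
    c = counts[counts > 0]
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


def _factorize_words(words: np.ndarray) -> np.ndarray:
    """Dense 0..K-1 codes for the context words (keeps bincounts small).

    Small non-negative word values take an O(N) bincount path; anything
    else falls back to sort-based np.unique.
    """
    words = np.ascontiguousarray(words, dtype=np.int64)
    if words.size and 0 <= words.min() and words.max() < (1 << 22):
        seen = np.bincount(words) > 0
        mapping = np.cumsum(seen) - 1
        return mapping[words]
    _, codes = np.unique(words, return_inverse=True)
    return codes.astype(np.int64)


def _conditional_pair(
    x_t: np.ndarray,
    y_t: np.ndarray,
    v_codes: np.ndarray,
    bias_correct: bool,
) -> tuple[float, float]:
    """(H(X|V), H(X|V,Y)) from one histogram pass per slice.

    The joint cell index is ``v*4 + y*2 + x``; all four marginal counts
    needed by the two conditional entropies come from reshaping the one
    count vector to (K, 2, 2).
    """
    k = int(v_codes.max()) + 1 if v_codes.size else 1
    cell = v_codes * 4 + y_t * 2 + x_t

    def est(start: int, stop: int) -> np.ndarray:
        counts = np.bincount(cell[start:stop], minlength=4 * k).reshape(k, 2, 2)
        c_vy = counts.sum(axis=2)            # (K, 2)
        c_vx = counts.sum(axis=1)            # (K, 2)
        c_v = c_vy.sum(axis=1)               # (K,)
        h_x_given_v = _entropy_from_counts(c_vx.ravel()) - _entropy_from_counts(c_v)
        h_x_given_vy = _entropy_from_counts(counts.ravel()) - _entropy_from_counts(
            c_vy.ravel()
        )
        return np.array([h_x_given_v, h_x_given_vy])

    n = x_t.size
    if not bias_correct:
        out = est(0, n)
        return float(out[0]), float(out[1])
    if n < 8:
        raise ValueError(
            f"bias correction needs at least 8 valid samples (got {n}); "
            "the quarter splits are degenerate otherwise"
        )
    # vectorized analogue of entropy.quadratic_extrapolation: one
    # histogram pass per slice serves both conditional entropies
    h_full = est(0, n)
    e2 = np.linspace(0, n, 3).astype(int)
    h_half = np.mean([est(e2[i], e2[i + 1]) for i in range(2)], axis=0)
    e4 = np.linspace(0, n, 5).astype(int)
    h_quarter = np.mean([est(e4[i], e4[i + 1]) for i in range(4)], axis=0)
    sizes = np.array([n, n / 2.0, n / 4.0])
    design = np.stack([np.ones(3), 1.0 / sizes, 1.0 / sizes**2], axis=1)
    coef = np.linalg.solve(design, np.stack([h_full, h_half, h_quarter]))
    return float(coef[0, 0]), float(coef[0, 1])


def _delay_stat(
    x_t: np.ndarray,
    y_t: np.ndarray,
    words: np.ndarray,
    bias_correct: bool,
) -> tuple[float, float]:
    """(dI, H(X|V)) at one delay from aligned triples."""
    v = _factorize_words(words)
    h_xv, h_xvy = _conditional_pair(
        np.ascontiguousarray(x_t, dtype=np.int64),
        np.ascontiguousarray(y_t, dtype=np.int64),
        v,
        bias_correct,
    )
    return h_xv - h_xvy, h_xv


def make_imi_stat(bias_correct: bool = False, normalized: bool = False):
    """A statistic ``f(x_t, y_t, words) -> float`` over aligned triples.

    Used by the bootstrap routines, which resample or shuffle the
    aligned triples directly.
    """

    def stat(x_t: np.ndarray, y_t: np.ndarray, words: np.ndarray) -> float:
        di, h_xv = _delay_stat(x_t, y_t, words, bias_correct)
        if not normalized:
            return di
        if h_xv < DENOM_TOL:
            return 0.0
        return float(np.clip(di / h_xv, 0.0, 1.0))

    return stat


def _profile(
    x: BinnedTrain,
    y: BinnedTrain,
    deltas,
    omega: int,
    bias_correct: bool,
    past_only: bool,
    normalized: bool,
    measure_name: str,
) -> IMIResult:
    deltas = np.asarray(deltas, dtype=np.int64)
    values = np.empty(deltas.size, dtype=float)
    n_valid = np.empty(deltas.size, dtype=np.int64)
    for i, d in enumerate(deltas):
        vec, x_t, y_t = build_conditioning_words(x, y, int(d), omega, past_only)
        di, h_xv = _delay_stat(x_t, y_t, vec.words, bias_correct)
        if normalized:
            values[i] = 0.0 if h_xv < DENOM_TOL else np.clip(di / h_xv, 0.0, 1.0)
        else:
            values[i] = di
        n_valid[i] = vec.n_samples
    profile = DelayProfile(deltas=deltas, values=values, measure_name=measure_name)
    return IMIResult(
        profile=profile,
        omega=omega,
        n_valid_samples=n_valid,
        bias_corrected=bias_correct,
    )


def imi(
    x: BinnedTrain,
    y: BinnedTrain,
    deltas,
    omega: int,
    bias_correct: bool = True,
) -> IMIResult:
    """Incremental mutual information profile dI(delta), in bits.

    Raw (un-normalized) values keep their sign: negative bias-corrected
    values are reported as computed, as a diagnostic of estimation
    noise.
    """
    return _profile(x, y, deltas, omega, bias_correct, False, False, "imi")


def normalized_imi(
    x: BinnedTrain,
    y: BinnedTrain,
    deltas,
    omega: int,
    bias_correct: bool = True,
) -> IMIResult:
    """Normalized IMI profile dI(delta) / H(X[n] | V), clipped to [0, 1]."""
    return _profile(x, y, deltas, omega, bias_correct, False, True, "normalized_imi")


def past_only_imi(
    x: BinnedTrain,
    y: BinnedTrain,
    deltas,
    omega: int,
    bias_correct: bool = True,
    normalized: bool = True,
) -> IMIResult:
    """IMI conditioning only on the pasts of both trains (2*omega bits).

    Conditions out slow structure correctly for delays shorter than the
    true connection delay but not for longer ones, because the sample
    ``Y[n - delta_true]`` then falls outside the conditioning window.
    """
    name = "past_only_normalized_imi" if normalized else "past_only_imi"
    return _profile(x, y, deltas, omega, bias_correct, True, normalized, name)


def select_trial_pairs(
    n_trials: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Ordered trial pairs (i, j), i != j, used by signal/noise measures.

    All ordered pairs when ``n_trials <= 50``; otherwise 2000 pairs drawn
    with a seeded generator.
    """
    if n_trials < 2:
        raise ValueError("signal/noise decomposition needs at least 2 trials")
    if n_trials <= MAX_EXHAUSTIVE_TRIALS:
        return [(i, j) for i in range(n_trials) for j in range(n_trials) if i != j]
    rng = np.random.default_rng(0) if rng is None else rng
    pairs = []
    while len(pairs) < N_SAMPLED_PAIRS:
        i, j = rng.integers(0, n_trials, size=2)
        if i != j:
            pairs.append((int(i), int(j)))
    return pairs


def _pooled_trial_arrays(
    trials: TrialSet,
    delta: int,
    omega: int,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Per-trial aligned (words, x_t, y_t); alignment is identical across
    trials because all trials share one length."""
    words, xs, ys = [], [], []
    for x, y in trials:
        vec, x_t, y_t = build_conditioning_words(x, y, delta, omega)
        words.append(vec.words)
        xs.append(x_t)
        ys.append(y_t)
    return words, xs, ys


def _signal_noise_at_delay(
    trials: TrialSet,
    delta: int,
    omega: int,
    bias_correct: bool,
    pairs: list[tuple[int, int]],
) -> tuple[float, float, int]:
    """(dI_signal, dI_noise, n_pooled) at one delay.

    Signal IMI pairs the conditioning context of trial i with Y from a
    different trial j; noise IMI is the further reduction from swapping
    in trial i's own Y.  Both are computed on the same ordered-pair pool
    so the two terms telescope to the trial-wise total exactly.
    """
    words, xs, ys = _pooled_trial_arrays(trials, delta, omega)
    w_pool = np.concatenate([words[i] for i, _ in pairs])
    x_pool = np.concatenate([xs[i] for i, _ in pairs])
    yj_pool = np.concatenate([ys[j] for _, j in pairs])
    yi_pool = np.concatenate([ys[i] for i, _ in pairs])
    v = _factorize_words(w_pool)
    x_pool = np.ascontiguousarray(x_pool, dtype=np.int64)
    h_xv, h_xv_yj = _conditional_pair(x_pool, np.ascontiguousarray(yj_pool, dtype=np.int64), v, bias_correct)
    _, h_xv_yi = _conditional_pair(x_pool, np.ascontiguousarray(yi_pool, dtype=np.int64), v, bias_correct)
    return h_xv - h_xv_yj, h_xv_yj - h_xv_yi, x_pool.size


def signal_imi(
    trials: TrialSet,
    deltas,
    omega: int,
    bias_correct: bool = False,
    rng: np.random.Generator | None = None,
) -> IMIResult:
    """Stimulus-locked IMI: context from trial i, Y observed on trial j != i."""
    return _signal_noise_profile(trials, deltas, omega, bias_correct, rng)[0]


def noise_imi(
    trials: TrialSet,
    deltas,
    omega: int,
    bias_correct: bool = False,
    rng: np.random.Generator | None = None,
) -> IMIResult:
    """Trial-variable IMI: the total IMI minus the stimulus-locked part."""
    return _signal_noise_profile(trials, deltas, omega, bias_correct, rng)[1]


def _signal_noise_profile(
    trials: TrialSet,
    deltas,
    omega: int,
    bias_correct: bool,
    rng: np.random.Generator | None = None,
) -> tuple[IMIResult, IMIResult]:
    deltas = np.asarray(deltas, dtype=np.int64)
    pairs = select_trial_pairs(trials.n_trials, rng)
    sig = np.empty(deltas.size)
    noi = np.empty(deltas.size)
    n_valid = np.empty(deltas.size, dtype=np.int64)
    for i, d in enumerate(deltas):
        sig[i], noi[i], n_valid[i] = _signal_noise_at_delay(
            trials, int(d), omega, bias_correct, pairs
        )
    mk = lambda vals, name: IMIResult(
        profile=DelayProfile(deltas=deltas, values=vals, measure_name=name),
        omega=omega,
        n_valid_samples=n_valid,
        bias_corrected=bias_correct,
    )
    return mk(sig, "signal_imi"), mk(noi, "noise_imi")


def trial_imi(
    trials: TrialSet,
    deltas,
    omega: int,
    bias_correct: bool = False,
) -> IMIResult:
    """Total within-trial IMI pooled over trials.

    For the plug-in estimator this equals signal IMI + noise IMI at
    every delay (the ordered-pair pool repeats each trial's samples the
    same number of times, which leaves empirical frequencies unchanged).
    """
    deltas = np.asarray(deltas, dtype=np.int64)
    values = np.empty(deltas.size)
    n_valid = np.empty(deltas.size, dtype=np.int64)
    for i, d in enumerate(deltas):
        words, xs, ys = _pooled_trial_arrays(trials, int(d), omega)
        w = np.concatenate(words)
        x_t = np.ascontiguousarray(np.concatenate(xs), dtype=np.int64)
        y_t = np.ascontiguousarray(np.concatenate(ys), dtype=np.int64)
        di, _ = _delay_stat(x_t, y_t, w, bias_correct)
        values[i] = di
        n_valid[i] = x_t.size
    return IMIResult(
        profile=DelayProfile(deltas=deltas, values=values, measure_name="trial_imi"),
        omega=omega,
        n_valid_samples=n_valid,
        bias_corrected=bias_correct,
    )
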