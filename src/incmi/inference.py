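"""Bootstrap confidence intervals and shuffle-based significance.

Two seeded resampling procedures over the aligned triples
``(X[n], Y[n - delta], V[n])`` formed at one delay:

* **confidence** — the triples are resampled with replacement *together*
  (preserving every dependency) and the measure recomputed; the interval
  is the resample mean +/- 2 standard deviations.
* **significance** — the aligned Y samples are shuffled relative to the
  (X, V) pairs, which preserves the dependencies within (X, V) but
  destroys any X-Y dependency; the threshold is the null mean + 2
  standard deviations, and an observed value above it is flagged
  significant.

The shuffle permutes Y by default (preserving its marginal exactly); an
i.i.d. redraw with replacement is available via ``shuffle_replace``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import BinnedTrain, DelayProfile, build_conditioning_words

__all__ = [
    "BootstrapConfig",
    "bootstrap_ci",
    "significance_threshold",
    "bonferroni_n_sd",
    "profile_with_inference",
]

Stat = Callable[[np.ndarray, np.ndarray, np.ndarray], float]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings shared by both procedures."""

    n_resamples: int = 100
    seed: int = 0
    shuffle_replace: bool = False  # significance: permute (False) or redraw (True)

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be at least 2")


def _resample_values(
    stat: Stat,
    x_t: np.ndarray,
    y_t: np.ndarray,
    words: np.ndarray,
    config: BootstrapConfig,
    null: bool,
) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    n = x_t.size
    values = []
    redraws = 0
    while len(values) < config.n_resamples:
        if null:
            if config.shuffle_replace:
                yp = y_t[rng.integers(0, n, size=n)]
            else:
                yp = y_t[rng.permutation(n)]
            xs, ws = x_t, words
        else:
            idx = rng.integers(0, n, size=n)
            xs, yp, ws = x_t[idx], y_t[idx], words[idx]
        # a resample collapsing onto a single context carries no usable
        # conditional structure: redraw, with a cap to guarantee exit
        if np.all(ws == ws[0]) and np.all(xs == xs[0]) and redraws < config.n_resamples:
            redraws += 1
            continue
        v = stat(xs, yp, ws)
        if np.isnan(v) and redraws < config.n_resamples:
            redraws += 1
            continue
        values.append(v)
    return np.asarray(values, dtype=float)


def bootstrap_ci(
    stat: Stat,
    x_t: np.ndarray,
    y_t: np.ndarray,
    words: np.ndarray,
    config: BootstrapConfig = BootstrapConfig(),
) -> tuple[float, float]:
    """Mean +/- 2 SD interval of the statistic over whole-triple resamples."""
    vals = _resample_values(stat, x_t, y_t, words, config, null=False)
    m, s = vals.mean(), vals.std(ddof=0)
    return float(m - 2 * s), float(m + 2 * s)


def significance_threshold(
    stat: Stat,
    x_t: np.ndarray,
    y_t: np.ndarray,
    words: np.ndarray,
    config: BootstrapConfig = BootstrapConfig(),
    n_sd: float = 2.0,
) -> float:
    """Null mean + ``n_sd`` SD of the statistic with Y shuffled against (X, V)."""
    vals = _resample_values(stat, x_t, y_t, words, config, null=True)
    return float(vals.mean() + n_sd * vals.std(ddof=0))


def bonferroni_n_sd(n_tests: int, base_n_sd: float = 2.0) -> float:
    """SD multiplier holding the familywise rate of a base per-test level.

    The per-delay ``base_n_sd`` rule has a one-sided normal tail rate
    ``alpha``; across a grid of ``n_tests`` delays the Bonferroni
    adjustment tests each delay at ``alpha / n_tests``, i.e. at the
    corresponding larger multiplier.  Used for claims about the whole
    profile (how many delays carry significant structure) rather than
    one preselected delay.
    """
    from scipy.special import ndtri, ndtr

    alpha = 1.0 - ndtr(base_n_sd)
    return float(ndtri(1.0 - alpha / n_tests))


def profile_with_inference(
    x: BinnedTrain,
    y: BinnedTrain,
    deltas,
    omega: int,
    stat: Stat,
    config: BootstrapConfig = BootstrapConfig(),
    past_only: bool = False,
    ci: bool = True,
    significance: bool = True,
    bonferroni: bool = False,
    measure_name: str = "measure",
) -> DelayProfile:
    """Evaluate a triple statistic over a delay grid with optional bands.

    Each delay gets its own aligned triples; the seeded generator state
    is derived from ``config.seed`` and the delay so results do not
    depend on grid order.
    """
    deltas = np.asarray(deltas, dtype=np.int64)
    values = np.empty(deltas.size)
    lo = np.full(deltas.size, np.nan)
    hi = np.full(deltas.size, np.nan)
    thr = np.full(deltas.size, np.nan)
    n_sd = bonferroni_n_sd(deltas.size) if bonferroni else 2.0
    for i, d in enumerate(deltas):
        vec, x_t, y_t = build_conditioning_words(x, y, int(d), omega, past_only)
        values[i] = stat(x_t, y_t, vec.words)
        sub = BootstrapConfig(
            n_resamples=config.n_resamples,
            seed=(config.seed * 100003 + int(d) + 64) % (2**31),
            shuffle_replace=config.shuffle_replace,
        )
        if ci:
            lo[i], hi[i] = bootstrap_ci(stat, x_t, y_t, vec.words, sub)
        if significance:
            thr[i] = significance_threshold(stat, x_t, y_t, vec.words, sub, n_sd=n_sd)
    return DelayProfile(
        deltas=deltas,
        values=values,
        measure_name=measure_name,
        ci_low=lo if ci else None,
        ci_high=hi if ci else None,
        sig_threshold=thr if significance else None,
    )
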