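"""Dichotomized-Gaussian two-neuron circuit simulator.

Each neuron emits a spike in bin ``n`` when its underlying Gaussian
drive crosses a threshold ``theta``:

    Y[n] = 1{ s_y[n] >= theta }
    X[n] = 1{ s_x[n] + epsilon * drive[n] >= theta }

where ``s_x`` and ``s_y`` are zero-mean unit-variance Gaussian sources
(white, or low-pass filtered and rescaled back to unit variance so that
``theta`` keeps the same marginal rate in every mode), and the
connection drive is either the filtered activity of Y (a *dynamic*
connection: one Y spike raises X's spiking probability over several
bins) or Y delayed by a fixed lag (a *static* connection).  Shared-input
modes draw the two raw sources with a prescribed correlation
coefficient before any filtering.

With ``theta = 1`` the marginal spike probability per bin is
``1 - Phi(1) ~= 0.159``.  All outputs are reproducible from the spec's
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import BinnedTrain, TrialSet

__all__ = [
    "CircuitSpec",
    "gaussian_filter",
    "simulate_pair",
    "simulate_trials",
    "preset",
    "PRESETS",
]

#: sqrt(2 ln 2): converts a half-width at half-maximum to a Gaussian sigma
_HWHM_TO_SIGMA = math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class CircuitSpec:
    """Parameters of a simulated two-neuron circuit.

    Parameters
    ----------
    connection
        ``"dynamic"`` (drive is Y filtered by a causal Gaussian kernel),
        ``"static"`` (drive is Y delayed by ``delay_star`` bins) or
        ``"none"``.
    epsilon
        Connection strength: the drive is scaled by this factor before
        entering X's threshold comparison.
    theta
        Spiking threshold on the unit-variance Gaussian drive.
    delay_star
        Connection delay in bins (static connection).
    filter_peak_delay, filter_half_width
        Peak delay and half-width at half-maximum (bins) of the Gaussian
        kernel used for the dynamic connection and for the temporally
        correlated input modes (those use a zero-peak-delay kernel).
    input_mode
        ``"independent_white"``   — both sources white and independent;
        ``"correlated_input_on_Y"`` — Y's source low-pass filtered, X's
        white and independent;
        ``"shared_correlated"``   — both sources filtered, with raw-source
        correlation ``shared_corr``;
        ``"shared_white"``        — both sources white, correlation
        ``shared_corr``.
    shared_corr
        Correlation coefficient between the two raw Gaussian sources in
        the shared modes; in trial mode, the weight of the frozen
        stimulus (so 0 gives independent trials and 1 identical ones).
    n_samples
        Bins per train (per trial in trial mode).
    seed
        Seed for all randomness.
    n_trials, frozen_stimulus
        Trial mode: number of repeats, and whether one stimulus
        realization is frozen across them (required for signal/noise
        analyses).
    """

    connection: str = "none"
    epsilon: float = 0.5
    theta: float = 1.0
    delay_star: int = 4
    filter_peak_delay: int = 4
    filter_half_width: int = 3
    input_mode: str = "independent_white"
    shared_corr: float = 0.5
    n_samples: int = 2**16
    seed: int = 0
    n_trials: int = 1
    frozen_stimulus: bool = False

    def __post_init__(self) -> None:
        if self.connection not in ("dynamic", "static", "none"):
            raise ValueError(f"unknown connection type {self.connection!r}")
        if self.input_mode not in (
            "independent_white",
            "correlated_input_on_Y",
            "shared_correlated",
            "shared_white",
        ):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0.0 <= self.shared_corr <= 1.0:
            raise ValueError("shared_corr must lie in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


def gaussian_filter(peak_delay: int, half_width: float) -> np.ndarray:
    """Causal discrete Gaussian kernel, unit peak.

    ``g[k] = exp(-(k - peak_delay)^2 / (2 sigma^2))`` with ``sigma``
    derived from the half-width at half-maximum, truncated at
    ``|k - peak_delay| > 4 sigma`` and at ``k < 0``.  Index 0 of the
    returned array is lag 0.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    sigma = half_width / _HWHM_TO_SIGMA
    k_max = int(math.floor(peak_delay + 4.0 * sigma))
    k = np.arange(0, k_max + 1)
    g = np.exp(-((k - peak_delay) ** 2) / (2.0 * sigma**2))
    g[np.abs(k - peak_delay) > 4.0 * sigma] = 0.0
    return g


def _symmetric_kernel(half_width: float) -> np.ndarray:
    """Two-sided Gaussian kernel centred on lag 0 (for input smoothing)."""
    sigma = half_width / _HWHM_TO_SIGMA
    r = int(math.floor(4.0 * sigma))
    k = np.arange(-r, r + 1)
    return np.exp(-(k**2) / (2.0 * sigma**2))


def _smooth_input(noise: np.ndarray, half_width: float) -> np.ndarray:
    """Low-pass filter white noise, rescaled to unit variance.

    Input sources are smoothed with the *symmetric* zero-peak kernel: a
    noise input carries no propagation direction, and one-sided
    truncation would put a sharp edge on the kernel whose
    high-frequency content makes the input partly unpredictable from
    neighbouring samples (defeating its role as a slow, conditionable
    dependency).  Causal truncation applies only to connection kernels.
    """
    g = _symmetric_kernel(half_width)
    out = np.convolve(noise, g, mode="same")
    return out / np.linalg.norm(g)


def _correlated_sources(
    rng: np.random.Generator, n: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two N(0,1) sources with correlation rho (x drawn first, then y)."""
    z_x = rng.standard_normal(n)
    z_y = rng.standard_normal(n)
    if rho == 0.0:
        return z_x, z_y
    z_c = rng.standard_normal(n)
    a, b = math.sqrt(rho), math.sqrt(1.0 - rho)
    return a * z_c + b * z_x, a * z_c + b * z_y


def _drive(spec: CircuitSpec, y: np.ndarray) -> np.ndarray:
    if spec.connection == "none" or spec.epsilon == 0.0:
        return np.zeros_like(y, dtype=float)
    if spec.connection == "static":
        d = np.zeros(y.size)
        if spec.delay_star < y.size:
            d[spec.delay_star :] = y[: y.size - spec.delay_star]
        return d
    kernel = gaussian_filter(spec.filter_peak_delay, spec.filter_half_width)
    return np.convolve(y.astype(float), kernel)[: y.size]


def _sources(spec: CircuitSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = spec.n_samples
    if spec.input_mode in ("shared_correlated", "shared_white"):
        e_x, e_y = _correlated_sources(rng, n, spec.shared_corr)
    else:
        e_x = rng.standard_normal(n)
        e_y = rng.standard_normal(n)
    if spec.input_mode in ("correlated_input_on_Y", "shared_correlated"):
        e_y = _smooth_input(e_y, spec.filter_half_width)
        if spec.input_mode == "shared_correlated":
            e_x = _smooth_input(e_x, spec.filter_half_width)
    return e_x, e_y


def simulate_pair(spec: CircuitSpec) -> tuple[BinnedTrain, BinnedTrain]:
    """Simulate one (X, Y) pair of binary trains from the circuit spec."""
    rng = np.random.default_rng(spec.seed)
    s_x, s_y = _sources(spec, rng)
    y = (s_y >= spec.theta).astype(np.int64)
    x = (s_x + spec.epsilon * _drive(spec, y) >= spec.theta).astype(np.int64)
    return BinnedTrain(x), BinnedTrain(y)


def simulate_trials(spec: CircuitSpec) -> TrialSet:
    """Simulate repeated-trial responses to one frozen stimulus.

    A single slow Gaussian stimulus realization (white noise filtered by
    the zero-peak-delay kernel) is shared by both neurons and frozen
    across trials; each trial adds fresh independent noise to each
    neuron, mixed as ``sqrt(c) * stimulus + sqrt(1 - c) * noise`` with
    ``c = shared_corr`` so the drive stays unit-variance.  The
    connection acts within each trial.
    """
    if spec.n_trials < 2:
        raise ValueError("trial simulation needs n_trials >= 2")
    if not spec.frozen_stimulus:
        raise ValueError(
            "signal/noise analyses need frozen_stimulus=True: trials must "
            "share one stimulus realization"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    stimulus = _smooth_input(rng.standard_normal(n), spec.filter_half_width)
    a = math.sqrt(spec.shared_corr)
    b = math.sqrt(1.0 - spec.shared_corr)
    trials = []
    for _ in range(spec.n_trials):
        e_x = rng.standard_normal(n)
        e_y = rng.standard_normal(n)
        s_x = a * stimulus + b * e_x
        s_y = a * stimulus + b * e_y
        y = (s_y >= spec.theta).astype(np.int64)
        x = (s_x + spec.epsilon * _drive(spec, y) >= spec.theta).astype(np.int64)
        trials.append((BinnedTrain(x), BinnedTrain(y)))
    return TrialSet(tuple(trials))


#: the named circuit configurations used throughout the documentation
#: and the reproduction commands
PRESETS: dict[str, CircuitSpec] = {
    # independent white inputs, dynamic connection through the
    # peak-delay-4 / half-width-3 kernel, strength 0.5
    "dynamic": CircuitSpec(
        connection="dynamic",
        epsilon=0.5,
        input_mode="independent_white",
        filter_peak_delay=4,
        filter_half_width=3,
    ),
    # temporally correlated input to Y, static connection at lag 4
    "static-correlated": CircuitSpec(
        connection="static",
        epsilon=0.5,
        delay_star=4,
        input_mode="correlated_input_on_Y",
        filter_half_width=3,
    ),
    # shared slow input (raw-source correlation 0.5), weak static
    # connection at lag 3
    "shared-correlated": CircuitSpec(
        connection="static",
        epsilon=0.25,
        delay_star=3,
        input_mode="shared_correlated",
        shared_corr=0.5,
        filter_half_width=3,
    ),
    # same circuit with the shared input made white: its effect can no
    # longer be conditioned out and appears at zero delay
    "shared-white": CircuitSpec(
        connection="static",
        epsilon=0.25,
        delay_star=3,
        input_mode="shared_white",
        shared_corr=0.5,
    ),
}


def preset(name: str, **overrides) -> CircuitSpec:
    """A named circuit configuration, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base
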