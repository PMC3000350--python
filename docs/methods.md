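# Methods

## The measure

For two binarized spike trains `X`, `Y` (one 0/1 value per time bin) and
an integer delay δ (positive δ = Y leads X), the incremental mutual
information is the conditional mutual information

    ΔI[δ] = H(X[n] | V_δ[n]) − H(X[n] | V_δ[n], Y[n−δ])
          = I(X[n] ; Y[n−δ] | V_δ[n])        [bits]

where the conditioning vector `V_δ[n]` collects the windowed past and
future of both trains around the two anchor samples:

    V_δ[n] = (X[n−ω..n−1], X[n+1..n+ω], Y[n−δ−ω..n−δ−1], Y[n−δ+1..n−δ+ω])

The X window is anchored on `n` and the Y window on `n−δ`; the anchors
themselves are always excluded, so the word carries exactly 4ω bits.
Anchoring the Y window on `n−δ` makes the excluded sample exactly the
one whose incremental contribution is measured; it also produces the
characteristic asymmetry of the past-only variant (below), because for
δ below the true connection delay δ* the sample `Y[n−δ*]` sits inside
the conditioning window whenever ω ≥ δ*−δ.

The normalized form divides by the maximum the increment could attain,

    Δ̃I[δ] = ΔI[δ] / H(X[n] | V_δ)  ∈ [0, 1],

defined as 0 when the denominator falls below 1e−12, and clipped to
[0, 1]. Raw ΔI profiles are *not* clipped: a bias-corrected estimate
can be slightly negative, and keeping the sign is a useful diagnostic
of estimation noise.

**Timescale assumption.** The measure separates connection dynamics
from other dependencies only when those other dependencies are *slow*
relative to the bin size (so the windows predict them) and the
connection's effect is *fast* (comparable to one bin). A shared input
that is white at the bin scale cannot be conditioned out and appears as
a zero-delay peak (this failure mode is itself reproduced by the
`shared-white` simulator preset and asserted in the tests).

### Variants

- **Past-only IMI** conditions on `(X[n−ω..n−1], Y[n−δ−ω..n−δ−1])` only
  (2ω bits) — the delay-resolved relative of transfer entropy. It
  conditions slow structure out correctly for δ < δ* but leaks it for
  δ > δ*, where `Y[n−δ*]` is no longer in the window; the test suite
  asserts exactly this asymmetry.
- **Signal / noise IMI** for repeated identical trials: the signal IMI
  replaces `Y[n−δ]` with the same sample from a *different* trial j ≠ i
  (keeping trial i's conditioning context), capturing only
  stimulus-locked dependency; the noise IMI is the further reduction
  from swapping trial i's own Y back in:

      ΔI_sig[δ]   = H(X|V) − H(X|V, Y_j),
      ΔI_noise[δ] = H(X|V, Y_j) − H(X|V, Y_i).

  Both are computed on the same pooled set of ordered trial pairs (all
  pairs up to 50 trials, then 2000 seeded pairs), so the two terms
  telescope: ΔI_sig + ΔI_noise equals the trial-wise total IMI
  *exactly* for the plug-in estimator — the pair pool repeats each
  trial's samples equally often, which leaves empirical frequencies
  unchanged. With bias correction the identity holds only approximately
  (the extrapolation splits see different sample counts), so the
  identity tests use the plug-in estimator.

## Estimation

Entropies are plug-in (empirical-frequency) estimates in bits over the
packed integer words; conditional entropies are computed as
`H(T,C) − H(C)` from one joint histogram per evaluation. The bin
alphabet is binary by construction: `bin_spike_times` refuses any bin
holding two spikes and points at a smaller bin width.

**Bias correction (quadratic extrapolation).** The plug-in estimator's
negative bias has a leading 1/N term. The corrected estimate evaluates
the estimator on the full sample, on its two contiguous halves
(averaged) and four contiguous quarters (averaged), fits
`H(N′) = H∞ + a/N′ + b/N′²` exactly through the three points, and
reports `H∞`. Contiguous (not interleaved) splits preserve residual
temporal structure within each fraction. Because the fit is linear in
the three measured values, correcting `H(T|C)` directly equals
correcting `H(T,C)` and `H(C)` separately and subtracting.

The correction matters when the context alphabet is large relative to
N (bias ≈ K/(2N ln 2)). For a *scalar* Bernoulli source the bias is far
below sampling noise and extrapolation merely adds variance — the
correction is not expected to win per-replicate there, and the tests
assert only bias (mean-error) reduction in that regime; the
per-replicate benefit is asserted on 8-bit word sources, the
dimensionality of an ω = 2 conditioning vector, where it is decisive.

**Valid samples.** Samples whose windows overrun either end are
dropped, so the sample count depends on δ and ω; profiles are computed
independently per delay on the maximal valid set (not re-aligned to a
common set), and the per-delay counts are reported in `IMIResult`.

## Inference

Both procedures operate on the aligned triples
`(X[n], Y[n−δ], V_δ[n])` formed at one delay, with 100 resamples by
default and all randomness seeded:

- **Confidence:** triples resampled with replacement *together*
  (preserving their dependencies); interval = resample mean ± 2 SD.
- **Significance:** the aligned Y samples shuffled against the (X, V)
  pairs — a permutation by default, preserving Y's marginal exactly
  (i.i.d. redraw available via `shuffle_replace`); threshold = null
  mean + 2 SD.

The per-delay 2-SD rule has a one-sided false-positive rate near 2.3%,
so over a 21-delay grid roughly half a spurious flag is expected under
the null — the calibration test asserts the empirical rate stays below
15%. For *grid-wide* claims (how many delays carry significant
structure) the `bonferroni=True` option of `profile_with_inference`
divides that nominal level across the grid (SD multiplier ≈ 3.07 for
21 delays); no correction is applied by default. Bands are widened, if
necessary, to bracket the point estimate.

## The simulator

Dichotomized-Gaussian neurons: `Y[n] = 1{s_y[n] ≥ θ}`,
`X[n] = 1{s_x[n] + ε·drive[n] ≥ θ}`, with unit-variance Gaussian
sources and θ = 1, giving a marginal rate of `1 − Φ(1) ≈ 0.159` per
bin in every mode. Defaults follow the demonstration circuits:

| parameter | default | meaning |
|---|---|---|
| ε | 0.5 (0.25 in shared presets) | connection strength scaling the drive |
| θ | 1.0 | spiking threshold (dimensionless, unit-variance drive) |
| δ* | 4 (static; 3 in shared presets) | static-connection lag, bins |
| peak delay / half width | 4 / 3 bins | Gaussian connection kernel (dynamic case) |
| shared_corr | 0.5 | correlation of the two raw sources (shared modes) |

Design choices where the construction was open:

- **Half width** is read as half-width at half-maximum
  (σ = hw/√(2 ln 2)); kernels are truncated at 4σ (negligible mass
  beyond) and normalized to unit peak so that ε keeps its meaning as
  connection strength.
- **Connection kernels are causal** (truncated at negative lags): a
  connection propagates forward in time. **Input-noise smoothing is
  symmetric**: a noise input has no propagation direction, and a
  one-sided zero-peak kernel would have a sharp edge whose
  high-frequency content makes the input partly unpredictable from
  neighbouring samples — defeating its role as a slow, conditionable
  dependency (with the one-sided kernel the shared input leaks into the
  measure at zero delay and dominates the weak-connection circuit).
- **Filtered sources are rescaled to unit variance** so θ = 1 yields
  the same marginal rate across modes; shared correlation is imposed on
  the raw sources before filtering (identical filters preserve the
  lag-0 cross-correlation coefficient).
- **Trial mode** freezes one smoothed stimulus realization `u` across
  trials and mixes per-trial noise as
  `√c·u + √(1−c)·noise` with `c = shared_corr`, so c = 0 gives
  independent trials and c = 1 identical ones; the connection acts
  within each trial.

What the simulator does *not* emulate: refractoriness, bursting,
rate nonstationarity, and multi-neuron convergence. Passing tests on
these circuits therefore demonstrate the estimator's behaviour under
controlled dependency structure, not robustness to every property of
real recordings.

## Problem sizes

The demonstration analyses use 2^20 samples with ω = 2 over
δ ∈ [−10, 10]; unit and property tests use 2^10–2^18 samples, chosen so
that the asserted effects exceed their seeded sampling spread by a wide
margin (e.g. the independent-pair bound of 0.005 bits sits ~6× above
measured null maxima at 2^18 samples). Exact-identity tests
(oracle equivalence, decomposition telescoping) are size-independent
and use small instances.

## Known limitations

- Context dimensionality grows as 4ω bits; ω beyond ~4 on binary data
  requires very long recordings for stable corrected estimates.
- Pairwise only: dependencies routed through unobserved third neurons
  contaminate the measure (a fast shared input is indistinguishable
  from a zero-delay interaction).
- The significance shuffle destroys the X–Y dependency at *all* delays
  jointly, so neighbouring-delay thresholds are not independent.
- Bias-corrected ΔI is not guaranteed nonnegative; only the normalized
  output clips.
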