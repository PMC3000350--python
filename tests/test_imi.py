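"""Incremental mutual information: exact limits, oracle equivalence,
decomposition identities and qualitative circuit behaviour."""

import math
from collections import Counter

import numpy as np
import pytest

from incmi import (
    BinnedTrain,
    TrialSet,
    build_conditioning_words,
    imi,
    noise_imi,
    normalized_imi,
    past_only_imi,
    preset,
    signal_imi,
    simulate_pair,
    simulate_trials,
    trial_imi,
)
from incmi.imi import _delay_stat
from incmi.simulate import CircuitSpec


def brute_force_cmi(x_t, y_t, words) -> float:
    """Exhaustive-histogram conditional mutual information I(X; Y | V).

    Independent oracle: sums p(v) * sum_xy p(x,y|v) log2[p(x,y|v) /
    (p(x|v) p(y|v))] over the observed triples.
    """
    n = len(x_t)
    joint = Counter(zip(x_t.tolist(), y_t.tolist(), words.tolist()))
    pv = Counter(words.tolist())
    pxv = Counter(zip(x_t.tolist(), words.tolist()))
    pyv = Counter(zip(y_t.tolist(), words.tolist()))
    total = 0.0
    for (xs, ys, vs), c in joint.items():
        p_xyv = c / n
        term = (c * pv[vs]) / (pxv[(xs, vs)] * pyv[(ys, vs)])
        total += p_xyv * math.log2(term)
    return total


class TestExactLimits:
    def test_deterministic_copy_full_normalized_information(self, copy_pair):
        x, y = copy_pair
        res = normalized_imi(x, y, range(-10, 11), omega=2, bias_correct=False)
        assert res.profile.value_at(3) == pytest.approx(1.0, abs=1e-12)
        assert res.profile.argmax_delta() == 3

    def test_copy_anchor_inside_window_gives_zero(self, copy_pair):
        # at delta=1 the Y window spans n-3..n+1, so Y[n-3] = X[n] is
        # already in the conditioning vector and nothing is left to gain
        x, y = copy_pair
        res = imi(x, y, [1], omega=2, bias_correct=False)
        assert res.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_copy_raw_information_close_to_one_bit(self, copy_pair):
        x, y = copy_pair
        res = imi(x, y, [3], omega=2, bias_correct=True)
        assert res.values[0] == pytest.approx(1.0, abs=0.01)

    def test_independent_pair_near_zero_everywhere(self, independent_pair):
        x, y = independent_pair
        res = imi(x, y, range(-8, 9), omega=2, bias_correct=False)
        # plug-in null level scales like K/(2 N ln 2); generous ceiling
        assert np.abs(res.values).max() < 0.01
        norm = normalized_imi(x, y, range(-8, 9), omega=2, bias_correct=False)
        assert norm.values.max() < 0.02

    def test_plugin_increment_nonnegative(self, rng):
        for _ in range(5):
            x = BinnedTrain(rng.integers(0, 2, 600))
            y = BinnedTrain(rng.integers(0, 2, 600))
            res = imi(x, y, range(-4, 5), omega=1, bias_correct=False)
            assert (res.values >= -1e-9).all()

    def test_normalized_values_clipped_to_unit_interval(self, independent_pair):
        x, y = independent_pair
        res = normalized_imi(x, y, range(-5, 6), omega=2, bias_correct=True)
        assert (res.values >= 0.0).all() and (res.values <= 1.0).all()


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("delta", [-2, 0, 3])
    def test_plugin_imi_equals_brute_force_cmi(self, seed, delta):
        """The uncorrected increment H(X|V) - H(X|V,Y) is exactly the
        conditional mutual information I(X; Y|V) of the empirical
        histogram."""
        r = np.random.default_rng(seed)
        yv = (r.random(2**12) < 0.3).astype(int)
        xv = (r.random(2**12) < 0.25 + 0.4 * np.roll(yv, 2)).astype(int)
        x, y = BinnedTrain(xv), BinnedTrain(yv)
        vec, x_t, y_t = build_conditioning_words(x, y, delta, omega=1)
        di, _ = _delay_stat(x_t, y_t, vec.words, bias_correct=False)
        assert di == pytest.approx(brute_force_cmi(x_t, y_t, vec.words), abs=1e-12)

    def test_window_refinement_cannot_increase_conditional_entropy(self, rng):
        """On a common valid-sample set, growing omega only refines the
        context, which cannot raise the plug-in conditional entropy."""
        x = BinnedTrain(rng.integers(0, 2, 2**12))
        y = BinnedTrain(rng.integers(0, 2, 2**12))
        prev = None
        for omega in (1, 2, 3):
            vec, x_t, y_t = build_conditioning_words(x, y, 2, omega)
            keep = (vec.indices >= 5) & (vec.indices < 2**12 - 5)
            _, h_xv = _delay_stat(
                x_t[keep], y_t[keep], vec.words[keep], bias_correct=False
            )
            if prev is not None:
                assert h_xv <= prev + 1e-12
            prev = h_xv


class TestCircuitBehaviour:
    def test_static_connection_yields_sharp_peak(self):
        x, y = simulate_pair(preset("static-correlated", n_samples=2**18, seed=1))
        res = normalized_imi(x, y, range(-10, 11), omega=2)
        assert res.profile.argmax_delta() == 4
        peak = res.values.max()
        far = max(res.profile.value_at(d) for d in range(-10, 11) if abs(d - 4) >= 3)
        assert far < 0.2 * peak

    def test_past_only_fails_beyond_connection_delay(self):
        """Conditioning only on the pasts removes slow structure for
        delays short of the connection delay but leaks it for longer
        delays, where the profile stays elevated."""
        x, y = simulate_pair(preset("static-correlated", n_samples=2**18, seed=1))
        grid = range(-10, 11)
        full = normalized_imi(x, y, grid, omega=2)
        past = past_only_imi(x, y, grid, omega=2)
        assert past.profile.argmax_delta() == 4
        peak = past.values.max()
        shorter = [past.profile.value_at(d) for d in (1, 2, 3)]
        longer = [past.profile.value_at(d) for d in (5, 6, 7)]
        assert max(shorter) < 0.1 * peak          # conditioned out
        assert min(longer) > 2 * max(shorter)     # leaks through
        full_longer = [full.profile.value_at(d) for d in (5, 6, 7)]
        assert np.mean(longer) > 3 * np.mean(full_longer)

    def test_past_only_independent_pair_near_zero(self, independent_pair):
        x, y = independent_pair
        res = past_only_imi(x, y, range(-5, 6), omega=2, bias_correct=False,
                            normalized=False)
        assert np.abs(res.values).max() < 0.01


def _trials(**overrides):
    spec = CircuitSpec(
        connection="static",
        epsilon=0.5,
        delay_star=2,
        input_mode="independent_white",
        shared_corr=0.5,
        n_samples=2**10,
        n_trials=6,
        frozen_stimulus=True,
        seed=9,
    )
    import dataclasses

    return simulate_trials(dataclasses.replace(spec, **overrides))


class TestSignalNoiseIMI:
    def test_single_trial_rejected(self, rng):
        a = BinnedTrain(rng.integers(0, 2, 64))
        with pytest.raises(ValueError):
            signal_imi(TrialSet(((a, a),)), [0], omega=1)

    def test_decomposition_identity(self):
        trials = _trials()
        grid = range(-4, 5)
        sig = signal_imi(trials, grid, omega=1)
        noi = noise_imi(trials, grid, omega=1)
        tot = trial_imi(trials, grid, omega=1)
        np.testing.assert_allclose(sig.values + noi.values, tot.values, atol=1e-9)

    def test_identical_trials_noise_vanishes(self, rng):
        x = BinnedTrain(rng.integers(0, 2, 512))
        y = BinnedTrain(rng.integers(0, 2, 512))
        trials = TrialSet(tuple((x, y) for _ in range(4)))
        grid = range(-3, 4)
        noi = noise_imi(trials, grid, omega=1)
        sig = signal_imi(trials, grid, omega=1)
        tot = trial_imi(trials, grid, omega=1)
        np.testing.assert_allclose(noi.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(sig.values, tot.values, atol=1e-12)

    def test_noise_driven_connection_is_all_noise_imi(self):
        # no frozen component: everything the connection produces is
        # trial-variable
        trials = _trials(shared_corr=0.0, n_samples=2**12)
        grid = range(-4, 5)
        sig = signal_imi(trials, grid, omega=1)
        noi = noise_imi(trials, grid, omega=1)
        tot = trial_imi(trials, grid, omega=1)
        assert np.abs(sig.values).max() < 0.005
        assert noi.profile.argmax_delta() == 2
        np.testing.assert_allclose(noi.values, tot.values, atol=0.01)

    def test_slow_stimulus_leaves_signal_imi_flat(self):
        """A slow frozen stimulus produces broad signal *correlation* but
        almost no signal IMI: its effect at any delay is predictable from
        the within-trial context."""
        trials = _trials(
            shared_corr=0.8, filter_half_width=6, n_samples=2**13, n_trials=8
        )
        grid = range(-6, 7)
        sig = signal_imi(trials, grid, omega=2)
        assert np.abs(sig.values).max() < 0.01
        from incmi import signal_correlation

        csig = signal_correlation(trials, grid).values
        assert csig.max() > 0.1

    def test_noise_imi_keeps_connection_peak(self):
        trials = _trials(shared_corr=0.5, filter_half_width=4, n_samples=2**13)
        noi = noise_imi(trials, range(-6, 7), omega=2)
        assert noi.profile.argmax_delta() == 2
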