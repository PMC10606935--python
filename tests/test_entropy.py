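"""Tsallis entropy, histograms, the sigma_E' statistic and feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest

import gaitent
from gaitent import (
    CohortSpec,
    EntropyParams,
    FEATURE_COLUMNS,
    HistogramPMF,
    build_histogram,
    extract_features,
    generate_cohort,
    mask_inactive,
    preprocess_recording,
    sigma_e_prime,
    sigma_e_prime_expanded,
    tsallis_additivity_gap,
    tsallis_entropy,
)
from gaitent.detrend import detrend_walk
from gaitent.entropy import effective_bins

Q = 0.82


def _random_pmf(rng, n):
    p = rng.random(n) + 1e-3
    return p / p.sum()


class TestTsallisEntropy:
    def test_certainty_is_zero(self):
        for q in (0.3, 0.82, 1.0, 1.7):
            assert tsallis_entropy([1.0], q) == 0.0

    def test_two_state_reference_value(self):
        # (1 - 2 * 0.5**0.82) / (0.82 - 1), evaluated in extended precision
        assert tsallis_entropy([0.5, 0.5], Q) == pytest.approx(0.7382438072, abs=1e-9)

    def test_shannon_limit(self):
        for q in (1 - 1e-6, 1 + 1e-6):
            assert tsallis_entropy([0.5, 0.5], q) == pytest.approx(np.log(2), abs=1e-5)

    def test_uniform_closed_form(self):
        for n in range(2, 26):
            expected = (1 - n ** (1 - Q)) / (Q - 1)
            assert tsallis_entropy(np.full(n, 1 / n), Q) == pytest.approx(expected, abs=1e-12)

    def test_uniform_maximizes(self, rng):
        for n in range(2, 26):
            u = tsallis_entropy(np.full(n, 1 / n), Q)
            for _ in range(20):
                assert tsallis_entropy(_random_pmf(rng, n), Q) <= u + 1e-12

    def test_nonnegative_for_subunity_q(self, rng):
        for _ in range(50):
            assert tsallis_entropy(_random_pmf(rng, rng.integers(1, 30)), Q) >= 0

    def test_invalid_pmf_rejected(self):
        with pytest.raises(ValueError):
            tsallis_entropy([0.5, 0.6], Q)


class TestAdditivityIdentity:
    def test_uniform_product(self):
        lhs, rhs = tsallis_additivity_gap(np.full(2, 0.5), np.full(3, 1 / 3), Q)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_shannon_additive_limit(self):
        px, py = [0.2, 0.8], [0.4, 0.1, 0.5]
        lhs, rhs = tsallis_additivity_gap(px, py, 1.0)
        assert lhs == pytest.approx(tsallis_entropy(px, 1.0) + tsallis_entropy(py, 1.0), abs=1e-12)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_random_product_distributions(self, rng):
        worst = 0.0
        for _ in range(100):
            px = _random_pmf(rng, rng.integers(2, 12))
            py = _random_pmf(rng, rng.integers(2, 12))
            q = rng.uniform(0.3, 1.7)
            lhs, rhs = tsallis_additivity_gap(px, py, q)
            worst = max(worst, abs(lhs - rhs))
        assert worst < 1e-10


class TestHistogram:
    def test_all_zero_residuals(self):
        pmf = build_histogram(np.zeros(50), 25)
        assert pmf.probabilities.tolist() == [1.0]
        assert tsallis_entropy(pmf, Q) == 0.0

    def test_uniform_by_construction(self):
        values = 0.1 * np.arange(25)
        pmf = build_histogram(values, 25)
        np.testing.assert_allclose(pmf.probabilities, 1 / 25)

    def test_large_uniform_sample_near_closed_form(self, rng):
        pmf = build_histogram(rng.random(10_000), 25)
        expected = (1 - 25 ** (1 - Q)) / (Q - 1)  # ~4.3609
        assert tsallis_entropy(pmf, Q) == pytest.approx(expected, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([], 25)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([-0.1, 0.2], 25)

    def test_effective_bins_policy(self):
        assert effective_bins(100) == 25
        assert effective_bins(1000) == 25
        assert effective_bins(99) == 24
        assert effective_bins(9) == 2
        assert effective_bins(1) == 2


class TestMaskInactive:
    def test_all_active_unchanged(self, rng):
        r = rng.normal(size=30)
        v = rng.uniform(0.1, 1.0, size=30)
        np.testing.assert_array_equal(mask_inactive(r, v, 0.05), r)

    def test_all_inactive_empty(self, rng):
        assert mask_inactive(rng.normal(size=10), np.full(10, 0.01), 0.05).size == 0

    def test_mixed_matches_index_oracle(self, rng):
        r, v = rng.normal(size=100), rng.random(100)
        got = mask_inactive(r, v, 0.3)
        expected = np.array([ri for ri, vi in zip(r, v) if vi >= 0.3])
        np.testing.assert_array_equal(got, expected)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            mask_inactive([1.0, 2.0], [0.5], 0.05)


class TestSigmaEPrime:
    def test_plus_minus_one(self):
        assert sigma_e_prime([1.0, -1.0]) == pytest.approx(1.0)

    def test_singleton(self):
        assert sigma_e_prime([-0.7]) == pytest.approx(0.7)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_expanded_set_equals_rms(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.normal(scale=rng.uniform(0.1, 5), size=rng.integers(1, 40))
        assert sigma_e_prime(E) == pytest.approx(sigma_e_prime_expanded(E), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sigma_e_prime([])


class TestFeatureExtraction:
    def test_identical_steps_all_features_zero(self):
        from gaitent import StepSeries

        step = 0.1 + 0.8 * np.sin(np.linspace(0, np.pi, 40)) ** 2
        steps = StepSeries(
            steps={s: [step.copy() for _ in range(5)] for s in gaitent.SENSOR_NAMES},
            effective_rate=400.0,
        )
        feats = extract_features(detrend_walk(steps))
        row = feats.row()
        assert row.shape == (16,)
        np.testing.assert_allclose(row, 0.0, atol=1e-12)

    def test_row_order_and_stability(self, healthy_steps):
        res = detrend_walk(healthy_steps)
        f1, f2 = extract_features(res), extract_features(res)
        np.testing.assert_array_equal(f1.row(), f2.row())
        assert FEATURE_COLUMNS[:8] == [f"S{i}_te" for i in range(8)]
        assert FEATURE_COLUMNS[8:] == [f"S{i}_sigma" for i in range(8)]
        assert np.all(np.isfinite(f1.row()))

    def test_too_few_steps_rejected(self):
        from gaitent import StepSeries

        steps = StepSeries(steps={"S0": [np.full(30, 0.5)] * 2}, effective_rate=400.0)
        with pytest.raises(ValueError, match="steps"):
            extract_features(detrend_walk(steps))

    def test_fully_inactive_sensor_flagged_missing(self):
        from gaitent import StepSeries

        quiet = np.full(30, 0.01)
        steps = StepSeries(steps={"S0": [quiet.copy() for _ in range(4)]}, effective_rate=400.0)
        feats = extract_features(detrend_walk(steps))
        assert "S0" in feats.missing
        assert np.isnan(feats.row()[0])

    def test_stepwise_modes_differ(self, healthy_steps):
        res = detrend_walk(healthy_steps)
        d = extract_features(res, stepwise_mode="diff")
        r = extract_features(res, stepwise_mode="raw")
        assert d.te_entire_gait == r.te_entire_gait
        assert d.sigma_stepwise != r.sigma_stepwise


class TestStepJitterEffect:
    def test_amplitude_jitter_increases_sigma_e_prime(self):
        """Paired 20-seed sign test: higher step-to-step amplitude jitter
        raises the stepwise-TE deviation statistic on non-heel sensors.

        Walk-shared histogram edges make per-step TE amplitude-sensitive;
        sway is disabled to isolate the fluctuation-scale mechanism."""
        wins = 0
        for seed in range(20):
            vals = []
            for jitter in (1.0, 3.0):
                spec = CohortSpec(
                    n_healthy=0, n_diseased=1, rng_seed=seed,
                    step_jitter_diseased=jitter, heel_attenuation=1.0,
                    sway_sigma_healthy=0.0, sway_sigma_diseased=0.0,
                )
                rec = generate_cohort(spec)[0]
                feats = extract_features(
                    detrend_walk(preprocess_recording(rec)), bin_mode="shared"
                )
                vals.append(
                    np.nanmean([feats.sigma_stepwise[s] for s in gaitent.SENSOR_NAMES
                                if s not in gaitent.HEEL_SENSORS])
                )
            wins += vals[1] > vals[0]
        assert binomtest(wins, 20, 0.5, alternative="greater").pvalue < 0.01
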