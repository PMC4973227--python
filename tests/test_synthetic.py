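"""Synthetic signal and cohort generators."""

import numpy as np
import pytest

from lamflow.synthetic import (
    CohortDesign,
    GroupSpec,
    generate_ar_linear,
    generate_cohort,
    generate_intermittent_map,
    generate_mixture_epoch,
    generate_periodic_noise,
    lambda_at,
)


class TestIntermittentMap:
    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            generate_intermittent_map(0)

    def test_bounded_in_unit_interval(self):
        x = generate_intermittent_map(5000, seed=3)
        assert x.min() >= 0.0 and x.max() < 1.0

    def test_small_drift_regime_is_mostly_laminar(self):
        # tiny drift: more than half of the steps barely move
        x = generate_intermittent_map(4800, c=1e-4, z=2.5, seed=1)
        frac = np.mean(np.abs(np.diff(x)) < 1e-3)
        assert frac > 0.5

    def test_seeded_determinism(self):
        a = generate_intermittent_map(1000, seed=7)
        b = generate_intermittent_map(1000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_laminar_fraction_monotone_in_drift(self):
        # laminar fraction must not increase with c across a decade
        fracs = []
        for c in (0.02, 0.063, 0.2):
            x = generate_intermittent_map(20000, c=c, z=2.0, seed=11)
            fracs.append(np.mean(np.abs(np.diff(x)) < 1e-3))
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_intermittent_map(10, c=-1.0)
        with pytest.raises(ValueError):
            generate_intermittent_map(10, z=0.5)


class TestARLinear:
    def test_white_noise_sd(self):
        x = generate_ar_linear(100_000, (), noise_sd=1.0, seed=0)
        assert abs(np.std(x) - 1.0) < 0.05

    def test_ar1_lag1_autocorrelation(self):
        x = generate_ar_linear(100_000, (0.9,), noise_sd=1.0, seed=1)
        x = x - x.mean()
        acf1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
        assert abs(acf1 - 0.9) < 0.02

    def test_seeded_determinism(self):
        a = generate_ar_linear(500, (0.5,), seed=9)
        b = generate_ar_linear(500, (0.5,), seed=9)
        np.testing.assert_array_equal(a, b)

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError):
            generate_ar_linear(100, (1.01,))


class TestPeriodicNoise:
    def test_pure_tone_psd_peak(self):
        from scipy.signal import periodogram
        rate = 400.0
        x = generate_periodic_noise(4096, [50.0], [1.0], 0.0, rate, seed=0)
        f, p = periodogram(x, fs=rate)
        assert abs(f[np.argmax(p)] - 50.0) < rate / 4096 * 2

    def test_zero_amplitude_reduces_to_noise(self):
        x = generate_periodic_noise(2000, [10.0], [0.0], 1.0, 400.0, seed=5)
        y = np.random.default_rng(5).normal(0, 1, 2000)
        np.testing.assert_allclose(x, y)

    def test_super_nyquist_rejected(self):
        with pytest.raises(ValueError):
            generate_periodic_noise(100, [250.0], [1.0], 0.0, 400.0)


class TestMixture:
    def test_amplitude_matching(self):
        # both components are standardized before block selection, so the
        # epoch SD is close to 1 for any lambda
        for lam in (0.0, 0.5, 1.0):
            x = generate_mixture_epoch(12000, lam, 1000.0, seed=2)
            assert abs(np.std(x) - 1.0) < 0.35

    def test_lambda_zero_is_pure_ar(self):
        x = generate_mixture_epoch(6000, 0.0, 1000.0, seed=4)
        # pure AR: increments never vanish the way laminar phases do
        assert np.mean(np.abs(np.diff(x)) < 1e-4) < 0.01

    def test_lambda_one_keeps_laminar_phases(self):
        x = generate_mixture_epoch(6000, 1.0, 1000.0, seed=4)
        assert np.mean(np.abs(np.diff(x)) < 1e-3) > 0.05


def paper_shaped_design(n_subjects=2, stride_s=6 * 3600.0, duration_h=144.0,
                        seed=0):
    return CohortDesign(
        groups=(
            GroupSpec("alb", n_subjects, ((0.0, 0.8), (144.0, 0.8))),
            GroupSpec("alb+sjn", n_subjects,
                      ((0.0, 0.8), (72.0, 0.1), (144.0, 0.1))),
            GroupSpec("sham", n_subjects, ((0.0, 0.1), (144.0, 0.1))),
        ),
        epoch_len_s=12.0,
        stride_s=stride_s,
        rate=1000.0,
        duration_h=duration_h,
        seed=seed,
    )


class TestCohort:
    def test_lambda_profile_interpolation(self):
        prof = ((0.0, 0.8), (72.0, 0.1), (144.0, 0.1))
        assert lambda_at(prof, 0) == pytest.approx(0.8)
        assert lambda_at(prof, 36) == pytest.approx(0.45)
        assert lambda_at(prof, 100) == pytest.approx(0.1)
        assert lambda_at(prof, 200) == pytest.approx(0.1)  # clamped

    def test_cohort_shape_and_determinism(self):
        design = paper_shaped_design(n_subjects=1, stride_s=24 * 3600.0,
                                     duration_h=48.0, seed=5)
        a = generate_cohort(design)
        b = generate_cohort(design)
        assert len(a.subjects) == 3
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id
            assert len(sa.epochs) == 2  # t = 0 h and 24 h
            assert all(len(e) == 12000 for e in sa.epochs)
            for ea, eb in zip(sa.epochs, sb.epochs):
                np.testing.assert_array_equal(ea, eb)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(groups=(
                GroupSpec("a", 1, ((0.0, 0.5),)),
                GroupSpec("a", 1, ((0.0, 0.5),)),
            ))

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("a", 1, ((0.0, 1.5),))
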