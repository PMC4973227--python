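"""Zeroth-order cross-prediction, periodicity screen, group NCPE tests."""

import numpy as np
import pandas as pd
import pytest

from lamflow.exceptions import PredictionError
from lamflow.ncpe import (
    group_ncpe_tests,
    ncpe_for_epoch,
    periodicity_screen,
    zeroth_order_predict,
)
from lamflow.synthetic import (
    generate_ar_linear,
    generate_intermittent_map,
    generate_periodic_noise,
)


class TestPeriodicityScreen:
    def test_pure_sinusoid_flagged(self):
        rate = 400.0
        t = np.arange(4800) / rate
        x = np.sin(2 * np.pi * 20.0 * t)
        screen = periodicity_screen(x, rate)
        assert screen.periodic
        assert np.any(np.abs(screen.peak_freqs_hz - 20.0) < 2.0)

    def test_white_noise_not_flagged(self):
        x = generate_ar_linear(4800, (), seed=31)
        assert not periodicity_screen(x, 400.0).periodic

    def test_tone_in_noise_flagged(self):
        x = generate_periodic_noise(4800, [30.0], [np.sqrt(20.0)], 1.0,
                                    400.0, seed=3)  # SNR ~ 10
        assert periodicity_screen(x, 400.0).periodic

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            periodicity_screen(np.zeros(100), 400.0)


class TestZerothOrderPredict:
    def test_self_prediction_is_exact(self):
        # target is a prefix of the train series, so every target state's
        # nearest neighbour (k=1) is itself and all futures coincide
        x = generate_ar_linear(600, (0.9,), seed=1)
        steps = 10
        target = x[: x.size - steps]
        errs = zeroth_order_predict(x, target, m=3, tau=2, steps=steps,
                                    k_neighbors=1)
        np.testing.assert_allclose(errs, 0.0, atol=1e-12)

    def test_white_noise_error_floor(self):
        # i.i.d. target: best possible error is sqrt(1 + 1/k) ~ 1.095 (k=5)
        train = generate_ar_linear(4000, (), seed=5)
        target = generate_ar_linear(4000, (), seed=6)
        errs = zeroth_order_predict(train, target, m=3, tau=1, steps=20,
                                    k_neighbors=5)
        expected = np.sqrt(1.0 + 1.0 / 5.0)
        assert np.all(errs > 1.0)
        np.testing.assert_allclose(errs, expected, rtol=0.08)

    def test_deterministic_flow_short_term_predictable(self):
        # noise-free Lorenz x-component: low error at step 1, growing with h
        from scipy.integrate import solve_ivp

        def lorenz(t, s):
            x, y, z = s
            return [10.0 * (y - x), x * (28.0 - z) - y, x * y - 8.0 / 3.0 * z]

        sol = solve_ivp(lorenz, (0, 120), [1.0, 1.0, 20.0], dense_output=True,
                        rtol=1e-9, atol=1e-9)
        t = np.linspace(20, 120, 4000)  # dt = 0.025, transient dropped
        x = sol.sol(t)[0]
        half = x.size // 2
        errs = zeroth_order_predict(x[:half], x[half:], m=5, tau=4,
                                    steps=30, k_neighbors=5)
        assert errs[0] < 0.1
        assert errs[-1] > errs[0]

    def test_too_few_neighbours_raises(self):
        x = generate_ar_linear(100, (), seed=0)
        with pytest.raises(PredictionError):
            zeroth_order_predict(x[:40], x[40:], m=3, tau=2, steps=35,
                                 k_neighbors=10)


class TestNCPEForEpoch:
    def test_scale_invariance(self):
        x = generate_ar_linear(1600, (0.9,), seed=9)
        a = ncpe_for_epoch(x, steps=20)
        b = ncpe_for_epoch(1000.0 * x, steps=20)
        np.testing.assert_allclose(a.ncpe_det, b.ncpe_det, rtol=1e-9)
        np.testing.assert_allclose(a.ncpe_trev, b.ncpe_trev, rtol=1e-9)

    def test_palindrome_reversal_consistency(self):
        # for an exactly time-symmetric epoch the reversed second half
        # equals the forward second half, so the two curves coincide
        half = generate_ar_linear(800, (0.8,), seed=13)
        x = np.concatenate([half, half[::-1]])
        res = ncpe_for_epoch(x, m=3, tau=2, steps=15)
        direct = zeroth_order_predict(x[:800], x[800:][::-1], m=3, tau=2,
                                      steps=15)
        np.testing.assert_allclose(res.ncpe_trev, direct, atol=1e-12)

    def test_seeded_determinism(self):
        x = generate_intermittent_map(1200, seed=17)
        a = ncpe_for_epoch(x, steps=10)
        b = ncpe_for_epoch(x, steps=10)
        np.testing.assert_array_equal(a.ncpe_det, b.ncpe_det)
        np.testing.assert_array_equal(a.ncpe_trev, b.ncpe_trev)

    def test_white_noise_floor_above_one(self):
        # unpredictable data: the worst-step error exceeds the target SD
        maxima = []
        for s in range(8):
            x = generate_ar_linear(1600, (), seed=40 + s)
            maxima.append(ncpe_for_epoch(x, m=5, tau=1, steps=20).max_det)
        assert np.median(maxima) > 1.0


class TestGroupNCPETests:
    def _frame(self, rng, shift=0.0):
        rows = []
        for g, delta in (("a", 0.0), ("b", shift)):
            for t in (10.0, 40.0):
                for _ in range(12):
                    det = rng.normal(1.2 + delta, 0.05)
                    rows.append({"group": g, "t_hours": t,
                                 "max_det": det,
                                 "max_trev": rng.normal(1.2, 0.05)})
        return pd.DataFrame(rows)

    def test_identical_distributions_not_significant(self, rng):
        cells, bins = group_ncpe_tests(self._frame(rng, shift=0.0))
        assert (cells["mw_p"] > 0.001).all()  # no systematic det/trev gap
        assert (bins["kw_p"] > 0.05).all()

    def test_shifted_group_detected(self, rng):
        cells, bins = group_ncpe_tests(self._frame(rng, shift=1.0))
        assert (bins["kw_p"] < 0.01).all()
        dunn_cols = [c for c in bins.columns if c.startswith("dunn_")]
        assert dunn_cols and (bins[dunn_cols] < 0.05).all().all()

    def test_single_observation_cells_flagged(self):
        df = pd.DataFrame([
            {"group": "a", "t_hours": 1.0, "max_det": 1.0, "max_trev": 1.1},
        ])
        cells, _ = group_ncpe_tests(df)
        assert (cells["flag"] == "too_few").all()
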