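"""Wavelet cycle rule, transform normalization, STP and ITPC estimators."""

import numpy as np
import pytest

from gapassr.stimgen import GapAssrSpec, generate_gap_segment
from gapassr.tfr import (
    CycleFunction,
    ITPCMap,
    compute_itpc,
    compute_stp,
    cycles_at,
    mean_itpc_40hz,
    morlet_transform,
)

FS = 1024.0


def _sinusoid_trials(freq, phases, dur_s=1.0, amp=1.0, fs=FS):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t[None, :] + np.asarray(phases)[:, None])


class TestCycleFunction:
    def test_anchor_and_asymptote(self):
        fn = CycleFunction()
        assert cycles_at(fn, 1.0) == pytest.approx(3.0, abs=1e-12)
        assert cycles_at(fn, 1e4) == pytest.approx(29.0, abs=1e-6)

    def test_value_at_inflection_matches_anchored_logistic(self):
        # independent evaluation of the rescaled logistic at 70 Hz
        s = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
        s0 = s(0.05 * (1 - 70))
        expected = 3 + 26 * (0.5 - s0) / (1 - s0)
        assert cycles_at(CycleFunction(), 70.0) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self):
        f = np.linspace(1, 500, 400)
        n = cycles_at(CycleFunction(), f)
        assert np.all(np.diff(n) > 0)
        assert np.all(n >= 3) and np.all(n < 29)

    def test_domain_error_below_anchor(self):
        with pytest.raises(ValueError, match="anchor"):
            cycles_at(CycleFunction(), 0.5)


class TestMorletTransform:
    def test_unit_sinusoid_amplitude(self):
        tfr = morlet_transform(_sinusoid_trials(40.0, [0.3]), np.array([40.0]), fs=FS)
        m = np.abs(tfr.coeffs[0, 0, tfr.edge_mask[0]])
        assert np.all(np.abs(m - 1.0) < 0.02)

    def test_linearity_and_zero_signal(self):
        x = _sinusoid_trials(20.0, [0.0])
        freqs = np.array([20.0])
        a = morlet_transform(x, freqs, fs=FS).coeffs
        b = morlet_transform(3.5 * x, freqs, fs=FS).coeffs
        assert np.allclose(b, 3.5 * a)
        z = morlet_transform(np.zeros_like(x), freqs, fs=FS).coeffs
        assert np.all(z == 0)

    def test_epoch_shorter_than_wavelet_raises(self):
        x = np.zeros((1, 64))
        with pytest.raises(ValueError, match="support"):
            morlet_transform(x, np.array([10.0]), fs=FS)

    def test_bad_grid_rejected(self):
        x = _sinusoid_trials(40.0, [0.0])
        with pytest.raises(ValueError, match="grid"):
            morlet_transform(x, np.array([40.0, 30.0]), fs=FS)


class TestSTP:
    def test_unit_sinusoid_power_one(self):
        trials = _sinusoid_trials(40.0, np.zeros(5))
        tfr = morlet_transform(trials, np.array([40.0]), fs=FS)
        stp = compute_stp(tfr)
        assert np.all(np.abs(stp.power[0, tfr.edge_mask[0]] - 1.0) < 0.05)
        assert np.all(stp.power >= 0)

    def test_trial_order_invariance(self, rng):
        trials = rng.standard_normal((8, 512))
        freqs = np.array([30.0, 40.0])
        a = compute_stp(morlet_transform(trials, freqs, fs=FS)).power
        b = compute_stp(morlet_transform(trials[::-1], freqs, fs=FS)).power
        assert np.allclose(a, b)

    def test_zero_trials_zero_map(self):
        stp = compute_stp(morlet_transform(np.zeros((3, 512)), np.array([40.0]), fs=FS))
        assert np.all(stp.power == 0)


class TestITPC:
    def test_identical_trials_give_one(self):
        seg = generate_gap_segment(GapAssrSpec(), 5.0, FS, seed=3)
        trials = np.tile(seg.data, (50, 1))
        itpc = compute_itpc(morlet_transform(trials, np.array([40.0]), fs=FS))
        interior = itpc.itpc[0, itpc.edge_mask[0]]
        assert interior.size > 0
        assert np.all(np.abs(interior - 1.0) < 1e-9)

    def test_evenly_spaced_phases_give_zero(self):
        trials = _sinusoid_trials(40.0, 2 * np.pi * np.arange(8) / 8)
        itpc = compute_itpc(morlet_transform(trials, np.array([40.0]), fs=FS))
        assert np.all(itpc.itpc[0, itpc.edge_mask[0]] < 1e-9)

    def test_wrapped_normal_resultant_length(self, rng):
        """E[ITPC] ~= exp(-sigma^2/2) for wrapped-normal phase jitter."""
        for sigma in (0.5, 1.0):
            phases = rng.normal(0.0, sigma, 500)
            itpc = compute_itpc(
                morlet_transform(_sinusoid_trials(40.0, phases), np.array([40.0]), fs=FS)
            )
            observed = itpc.itpc[0, itpc.edge_mask[0]].mean()
            assert observed == pytest.approx(np.exp(-sigma**2 / 2), abs=0.06)

    def test_amplitude_scaling_invariance(self, rng):
        """ITPC is a phase-only statistic: per-trial gains do not change it."""
        phases = rng.normal(0.0, 0.8, 40)
        base = _sinusoid_trials(40.0, phases)
        gains = rng.uniform(0.2, 5.0, 40)[:, None]
        freqs = np.array([40.0])
        a = compute_itpc(morlet_transform(base, freqs, fs=FS)).itpc
        b = compute_itpc(morlet_transform(gains * base, freqs, fs=FS)).itpc
        assert np.allclose(a, b, atol=1e-12)

    def test_null_itpc_decays_with_trial_count(self, rng):
        """Uniform phases: E[ITPC] ~= sqrt(pi/4)/sqrt(N)."""
        means = {}
        for n in (25, 100):
            vals = []
            for _ in range(20):
                phases = rng.uniform(0, 2 * np.pi, n)
                itpc = compute_itpc(
                    morlet_transform(
                        _sinusoid_trials(40.0, phases, dur_s=0.4), np.array([40.0]), fs=FS
                    )
                )
                vals.append(itpc.itpc[0, itpc.edge_mask[0]].mean())
            means[n] = np.mean(vals)
            assert means[n] == pytest.approx(np.sqrt(np.pi / 4) / np.sqrt(n), rel=0.2)
        assert means[100] < means[25]

    def test_single_trial_rejected(self):
        tfr = morlet_transform(_sinusoid_trials(40.0, [0.0]), np.array([40.0]), fs=FS)
        with pytest.raises(ValueError, match="two trials"):
            compute_itpc(tfr)


class TestMeanItpc40:
    def _map(self, value, n=256):
        return ITPCMap(
            itpc=np.full((1, n), value),
            freqs_hz=np.array([40.0]),
            fs_hz=FS,
            n_trials=10,
            edge_mask=np.ones((1, n), bool),
        )

    def test_constant_map(self):
        tab = mean_itpc_40hz({w: self._map(1.0) for w in (3.0, 5.0, 9.0)})
        assert np.allclose(tab["mean_itpc"], 1.0)
        assert list(tab["gap_width_ms"]) == [3.0, 5.0, 9.0]

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            mean_itpc_40hz({3.0: self._map(0.5)}, window_s=(0.1, 0.1))

    def test_monotone_in_width_for_planted_jitter(self, rng):
        """Phase jitter shrinking with gap width -> ITPC rises with width."""
        out = {}
        for width, sigma in [(3.0, 1.2), (6.0, 0.7), (9.0, 0.3)]:
            phases = rng.normal(0, sigma, 120)
            itpc = compute_itpc(
                morlet_transform(_sinusoid_trials(40.0, phases), np.array([40.0]), fs=FS)
            )
            out[width] = itpc
        tab = mean_itpc_40hz(out)
        assert tab["mean_itpc"].is_monotonic_increasing
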