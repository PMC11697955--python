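"""Ground-truth recovery from the synthetic EEG generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.signal import welch as psd_welch

from gapassr.erp import average_erp, preprocess_trials
from gapassr.io import extract_epochs
from gapassr.stimgen import (
    GapAssrSpec,
    NoiseBurstSpec,
    SessionSchedule,
    schedule_session,
)
from gapassr.synth import (
    AnimalParams,
    EffectSizes,
    default_design,
    make_animal_params,
    response_probability,
    simulate_cohort,
    simulate_recording,
)
from gapassr.tfr import compute_itpc, morlet_transform

FS = 1024.0


def _gap_only_events(width, n_segments, spacing=0.5, t0=1.0):
    onsets = t0 + spacing * np.arange(n_segments)
    return pd.DataFrame(
        {"onset_s": onsets, "kind": "gap_segment", "gap_width_ms": float(width)}
    )


def _itpc40(rec, width):
    ep = extract_epochs(rec, "gap_segment", (0.0, 0.25), gap_width_ms=width)
    itpc = compute_itpc(morlet_transform(ep, np.array([40.0]), channel="AC"))
    return itpc.itpc[0, itpc.edge_mask[0]].mean()


class TestEffectStructure:
    def test_ko_and_treatment_multipliers(self):
        eff = EffectSizes()
        wt = make_animal_params("WT", "saline")
        ko = make_animal_params("KO", "saline")
        assert abs(ko.erp_amp_uV[1]) == pytest.approx(abs(wt.erp_amp_uV[1]) * eff.ko_n1_mult)
        assert ko.gamma_bg_scale == pytest.approx(wt.gamma_bg_scale * eff.ko_gamma_mult)
        assert ko.assr_phase_jitter_rad == pytest.approx(
            wt.assr_phase_jitter_rad * eff.ko_jitter_mult
        )
        # treatment reduces jitter in both genotypes
        for g in ("WT", "KO"):
            sal = make_animal_params(g, "saline")
            nlx = make_animal_params(g, "NLX101")
            assert nlx.assr_phase_jitter_rad < sal.assr_phase_jitter_rad
        # gamma rescue is KO x P30 specific
        assert make_animal_params("KO", "NLX101", age="P30").gamma_bg_scale == pytest.approx(1.0)
        assert make_animal_params("KO", "NLX101", age="P21").gamma_bg_scale == pytest.approx(
            eff.ko_gamma_mult
        )
        assert make_animal_params("WT", "NLX101", age="P30").gamma_bg_scale == pytest.approx(1.0)


class TestSimulateRecording:
    def test_zero_amplitudes_give_pure_noise(self, short_events):
        params = AnimalParams(
            erp_amp_uV=(0.0, 0.0, 0.0), assr_amp_uV=0.0, gamma_rms_uV=0.0, bg_rms_uV=1.0
        )
        rec = simulate_recording(params, short_events, seed=3)
        ep = extract_epochs(rec, "noise_burst", (-0.25, 0.5))
        erp = average_erp(preprocess_trials(ep))
        assert np.abs(erp.waveform).max() < 5.0 / np.sqrt(ep.n_trials)

    def test_background_spectral_slope(self):
        params = AnimalParams(gamma_rms_uV=0.0, bg_alpha=1.0)
        rec = simulate_recording(params, pd.DataFrame(columns=["onset_s", "kind", "gap_width_ms"]),
                                 seed=5, duration_s=120.0)
        f, pxx = psd_welch(rec.data[0], fs=FS, nperseg=4096)
        sel = (f >= 2) & (f <= 80)
        slope = np.polyfit(np.log(f[sel]), np.log(pxx[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_erp_template_recovered_by_averaging(self):
        params = AnimalParams(erp_amp_jitter=0.0, erp_latency_jitter_s=0.0,
                              gamma_rms_uV=0.0, assr_amp_uV=0.0, bg_rms_uV=5.0)
        events = pd.DataFrame(
            {"onset_s": 1.0 + 1.0 * np.arange(150), "kind": "noise_burst",
             "gap_width_ms": np.nan}
        )
        rec = simulate_recording(params, events, seed=9)
        erp = average_erp(preprocess_trials(extract_epochs(rec, "noise_burst", (-0.25, 0.5))))
        t = erp.times_s
        template = np.zeros_like(t)
        for amp, lat, w in zip(params.erp_amp_uV, params.erp_latency_s, params.erp_width_s):
            template += amp * np.exp(-((t - lat) ** 2) / (2 * w**2))
        # detrending/baseline slightly reshapes the template; noise floor rules
        resid = erp.waveform[0] - template
        assert np.abs(resid).max() < 6 * 5.0 / np.sqrt(150)

    def test_zero_jitter_full_response_gives_itpc_one(self):
        params = AnimalParams(assr_phase_jitter_rad=0.0, gap_response_slope=50.0,
                              bg_rms_uV=0.5, gamma_rms_uV=0.0, assr_amp_uV=30.0)
        rec = simulate_recording(params, _gap_only_events(9.0, 100), seed=1)
        assert _itpc40(rec, 9.0) > 0.99

    def test_event_outside_span_rejected(self, short_events):
        with pytest.raises(ValueError, match="span"):
            simulate_recording(AnimalParams(), short_events, duration_s=5.0)

    def test_fc_is_lagged_attenuated_copy(self):
        params = AnimalParams(bg_rms_uV=0.01, gamma_rms_uV=0.0, assr_amp_uV=30.0,
                              assr_phase_jitter_rad=0.0, gap_response_slope=50.0)
        rec = simulate_recording(params, _gap_only_events(9.0, 20), seed=2)
        lag = int(round(params.fc_lag_s * FS))
        ac, fc = rec.data
        corr = np.corrcoef(ac[: len(ac) - lag], fc[lag:])[0, 1]
        assert corr > 0.99
        assert np.std(fc) == pytest.approx(params.fc_gain * np.std(ac), rel=0.05)


class TestParameterRecovery:
    @pytest.mark.parametrize("sigma", [0.5, 1.0])
    def test_itpc_matches_wrapped_normal_times_response_prob(self, sigma):
        """Mean 40 Hz ITPC ~= p(width) * exp(-sigma^2/2) in the high-SNR limit."""
        width = 9.0
        reps = 4
        vals = []
        for rep in range(reps):
            params = AnimalParams(
                assr_phase_jitter_rad=sigma, assr_amp_uV=50.0, bg_rms_uV=1.0,
                gamma_rms_uV=0.0,
            )
            rec = simulate_recording(params, _gap_only_events(width, 150), seed=100 + rep)
            vals.append(_itpc40(rec, width))
        expected = float(response_probability(params, width)) * np.exp(-sigma**2 / 2)
        mc_sd = np.std(vals, ddof=1)
        assert abs(np.mean(vals) - expected) < max(3 * mc_sd / np.sqrt(reps), 0.02)

    def test_partial_response_probability_scales_itpc(self):
        """At threshold width the response rate is 1/2 and ITPC halves."""
        params = AnimalParams(assr_phase_jitter_rad=0.0, assr_amp_uV=50.0,
                              bg_rms_uV=1.0, gamma_rms_uV=0.0)
        width = params.gap_threshold_ms
        assert float(response_probability(params, width)) == pytest.approx(0.5)
        vals = [
            _itpc40(simulate_recording(params, _gap_only_events(width, 200), seed=s), width)
            for s in range(3)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.08)


class TestCohort:
    def test_one_animal_per_group_counts(self):
        nb = NoiseBurstSpec(repetition_rate_hz=1.0)
        ss = SessionSchedule(rest_min=2 / 60, gapassr_min=0.5, noise_min=0.25)
        recs = simulate_cohort(default_design(2), seed=0, nb=nb, ss=ss)
        assert len(recs) == 8  # 2 genotypes x 2 treatments x (1 M + 1 F)
        keys = {(r.meta["genotype"], r.meta["treatment"], r.meta["sex"]) for r in recs}
        assert len(keys) == 8

    def test_determinism_same_seed(self):
        nb = NoiseBurstSpec(repetition_rate_hz=1.0)
        ss = SessionSchedule(rest_min=2 / 60, gapassr_min=0.25, noise_min=0.25)
        design = default_design(2).iloc[:2]
        a = simulate_cohort(design, seed=77, nb=nb, ss=ss)
        b = simulate_cohort(design, seed=77, nb=nb, ss=ss)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)
            pd.testing.assert_frame_equal(ra.events, rb.events)
        c = simulate_cohort(design, seed=78, nb=nb, ss=ss)
        assert not np.array_equal(a[0].data, c[0].data)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_cohort(pd.DataFrame({"genotype": [], "treatment": [], "n": []}))
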