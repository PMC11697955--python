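"""Simulate one animal and measure its auditory ERP peaks.

A short noise-burst session is scheduled, a two-channel recording is
forward-simulated, trials are epoched, baseline-corrected and detrended,
and the P1/N1/P2 amplitudes of the trial average are measured.  The
printed amplitudes should sit near the generator's template (the average
of finitely many noisy trials wobbles around it).
"""

from gapassr import (
    AnimalParams,
    NoiseBurstSpec,
    SessionSchedule,
    average_erp,
    extract_epochs,
    measure_peaks,
    preprocess_trials,
    schedule_session,
    simulate_recording,
)

nb = NoiseBurstSpec(repetition_rate_hz=0.5)
ss = SessionSchedule(rest_min=2 / 60, gapassr_min=0.0, noise_min=2.0)
events = schedule_session(nb, ss=ss, seed=1)

params = AnimalParams(genotype="WT")
rec = simulate_recording(params, events, seed=1)
print(f"simulated {rec.duration_s:.0f} s recording, channels {rec.channel_names}")

ep = preprocess_trials(extract_epochs(rec, "noise_burst", (-0.25, 0.5)))
erp = measure_peaks(average_erp(ep))
print(f"averaged {erp.n_trials} trials; template is P1 +15, N1 -45, P2 +20 uV")
for region, pk in erp.peaks.items():
    print(
        f"  {region}: P1 {pk['P1_uV']:+6.1f} uV @ {pk['P1_lat_ms']:.0f} ms | "
        f"N1 {pk['N1_uV']:+6.1f} uV @ {pk['N1_lat_ms']:.0f} ms | "
        f"P2 {pk['P2_uV']:+6.1f} uV @ {pk['P2_lat_ms']:.0f} ms"
    )
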