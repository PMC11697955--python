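"""Build the two acoustic stimuli and inspect their geometry.

Generates a broadband noise burst (ERP stimulus) and one 40 Hz
gap-in-noise segment, then prints the quantities that define the
paradigm: the implied gap presentation rate and the envelope attenuation
inside gaps at the default 75% modulation depth.
"""

import numpy as np

from gapassr import GapAssrSpec, NoiseBurstSpec, generate_gap_segment, generate_noise_burst

fs = 44100.0

burst = generate_noise_burst(NoiseBurstSpec(), fs, seed=0)
print(f"noise burst: {burst.duration_s * 1000:.0f} ms, RMS {burst.rms:.3f} (calibration units)")

seg = generate_gap_segment(GapAssrSpec(), gap_width_ms=9.0, fs=fs, seed=0)
rate = 1.0 / np.median(np.diff(seg.gap_onsets_s))
print(f"gap segment: {len(seg.gap_onsets_s)} gaps, presentation rate {rate:.1f} Hz")

gap = np.zeros(seg.data.size, bool)
out = np.ones(seg.data.size, bool)
for t0 in seg.gap_onsets_s:
    gap[int((t0 + 0.001) * fs): int((t0 + 0.008) * fs)] = True
    out[int((t0 - 0.001) * fs): int((t0 + 0.010) * fs)] = False
ratio = np.sqrt(np.mean(seg.data[gap] ** 2) / np.mean(seg.data[out] ** 2))
print(f"envelope inside gaps: {100 * ratio:.1f}% of outside (expected 25% at 75% depth)")
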