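"""Acoustic stimulus construction and session scheduling.

Two stimuli drive the analyses downstream:

* **Noise bursts** for event-related potentials: broadband (1-12 kHz)
  noise, 100 ms long with 5 ms cosine-squared rise/fall ramps, presented at
  a slow repetition rate (0.25 Hz) so successive ERPs do not overlap.
* **40 Hz gap-in-noise ASSR** segments: 250 ms of noise in which short
  silent-ish gaps (3-9 ms wide, envelope attenuated by the modulation
  depth) are inserted every 25 ms, i.e. at a 40 Hz presentation rate.
  Segments with gaps alternate with plain-noise segments, and each gap
  segment uses one randomly drawn gap width.

The session scheduler emits the event table the analysis consumes — the
in-silico analogue of the TTL pulse train that marks stimulus onsets in a
real recording.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "NoiseBurstSpec",
    "GapAssrSpec",
    "SessionSchedule",
    "StimulusWaveform",
    "EVENT_COLUMNS",
    "generate_noise_burst",
    "generate_gap_segment",
    "schedule_session",
    "write_events",
    "read_events",
    "write_wav",
]

#: Canonical event-table columns. ``gap_width_ms`` is NaN for rows whose
#: kind carries no width (noise bursts, no-gap segments).
EVENT_COLUMNS = ("onset_s", "kind", "gap_width_ms")

EVENT_KINDS = ("noise_burst", "gap_segment", "nogap_segment")


@dataclass(frozen=True)
class StimulusWaveform:
    """A mono acoustic waveform plus any within-stimulus marker times.

    ``gap_onsets_s`` is populated for gap-ASSR segments (one entry per gap,
    relative to segment start) and ``None`` otherwise.  Amplitude is in
    arbitrary calibration units: sound level in dB SPL is symbolic in
    silico and maps to the waveform RMS through ``rms``.
    """

    data: np.ndarray
    fs_hz: float
    gap_onsets_s: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        return self.data.size / self.fs_hz

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.data)))) if self.data.size else 0.0


@dataclass(frozen=True)
class NoiseBurstSpec:
    """Broadband noise burst used for ERP measurement."""

    band_low_hz: float = 1000.0
    band_high_hz: float = 12000.0
    level_db_spl: float = 75.0
    duration_ms: float = 100.0
    ramp_ms: float = 5.0
    n_repetitions: int = 120
    repetition_rate_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("noise burst duration must be positive")
        if self.duration_ms <= 2 * self.ramp_ms:
            raise ValueError("duration_ms must exceed 2 * ramp_ms")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.repetition_rate_hz <= 0:
            raise ValueError("repetition_rate_hz must be positive")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low_hz < band_high_hz")


@dataclass(frozen=True)
class GapAssrSpec:
    """40 Hz gap-in-noise ASSR stimulus parameters.

    Gaps are spaced ``gap_interval_ms`` (25 ms) apart within each
    ``segment_ms`` (250 ms) segment, giving 10 gaps per segment and an
    implied 40 Hz presentation rate.  ``modulation_depth_pct`` of 75 means
    the noise envelope drops to 25% inside a gap.
    """

    segment_ms: float = 250.0
    gap_interval_ms: float = 25.0
    gap_widths_ms: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)
    modulation_depth_pct: float = 75.0
    block_duration_min: float = 30.0
    band_low_hz: float = 1000.0
    band_high_hz: float = 12000.0

    def __post_init__(self) -> None:
        if self.segment_ms <= 0 or self.gap_interval_ms <= 0:
            raise ValueError("segment and gap interval must be positive")
        n = self.segment_ms / self.gap_interval_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("segment_ms must be an integer multiple of gap_interval_ms")
        if not all(0 < w < self.gap_interval_ms for w in self.gap_widths_ms):
            raise ValueError("all gap widths must lie in (0, gap_interval_ms)")
        if not 0 <= self.modulation_depth_pct <= 100:
            raise ValueError("modulation_depth_pct must be in [0, 100]")

    @property
    def gaps_per_segment(self) -> int:
        return int(round(self.segment_ms / self.gap_interval_ms))


@dataclass(frozen=True)
class SessionSchedule:
    """Recording session block structure (durations in minutes)."""

    rest_min: float = 8.0
    gapassr_min: float = 30.0
    noise_min: float = 20.0
    block_order: str = "gapassr-first"

    def __post_init__(self) -> None:
        if min(self.rest_min, self.gapassr_min, self.noise_min) < 0:
            raise ValueError("block durations must be non-negative")
        if self.block_order not in ("gapassr-first", "noise-first"):
            raise ValueError("block_order must be 'gapassr-first' or 'noise-first'")

    @property
    def total_min(self) -> float:
        return self.rest_min + self.gapassr_min + self.noise_min


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-limited to [lo, hi] Hz when fs permits."""
    x = rng.standard_normal(n)
    if n < 32:
        return x
    nyq = fs / 2.0
    if hi >= nyq:  # band exceeds Nyquist: leave broadband
        if lo > 0 and lo < nyq:
            sos = signal.butter(4, lo / nyq, btype="highpass", output="sos")
            x = signal.sosfiltfilt(sos, x)
        return x
    sos = signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, x)


def _cos2_ramps(n: int, n_ramp: int) -> np.ndarray:
    """Unit envelope with cosine-squared onset/offset ramps."""
    env = np.ones(n)
    if n_ramp > 0:
        t = np.linspace(0.0, np.pi / 2, n_ramp, endpoint=False)
        env[:n_ramp] = np.sin(t) ** 2
        env[-n_ramp:] = (np.sin(t) ** 2)[::-1]
    return env


def generate_noise_burst(
    spec: NoiseBurstSpec,
    fs: float,
    seed: int | np.random.Generator = 0,
    rms_target: float = 1.0,
) -> StimulusWaveform:
    """Generate one band-limited noise burst with cosine-squared ramps.

    ``rms_target`` is the calibration constant standing in for the sound
    level (75 dB SPL maps to RMS 1.0 by default).

    Raises
    ------
    ValueError
        If ``fs`` cannot represent the upper band edge (fs <= 2 * high).
    """
    if fs <= 2 * spec.band_high_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for band edge {spec.band_high_hz} Hz"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(spec.duration_ms / 1000.0 * fs))
    if n == 0:
        raise ValueError("noise burst would contain zero samples")
    x = _band_noise(n, fs, spec.band_low_hz, spec.band_high_hz, rng)
    x *= _cos2_ramps(n, int(round(spec.ramp_ms / 1000.0 * fs)))
    r = np.sqrt(np.mean(np.square(x)))
    if r > 0:
        x *= rms_target / r
    return StimulusWaveform(data=x, fs_hz=fs)


def gap_onset_times_s(spec: GapAssrSpec) -> np.ndarray:
    """Gap onset times within one segment, seconds from segment start.

    Gaps sit at k * gap_interval for k = 0 .. gaps_per_segment - 1 so that
    every gap lies wholly inside the segment.
    """
    return np.arange(spec.gaps_per_segment) * spec.gap_interval_ms / 1000.0


def generate_gap_segment(
    spec: GapAssrSpec,
    gap_width_ms: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    rms_target: float = 1.0,
) -> StimulusWaveform:
    """Generate one 250 ms gap-interrupted noise segment.

    Inside each gap the noise envelope is scaled by
    ``1 - modulation_depth_pct / 100`` with instantaneous (unramped) edges.
    Returns the waveform plus the gap-onset times.
    """
    if gap_width_ms >= spec.gap_interval_ms:
        raise ValueError("gap width must be smaller than the gap interval")
    if not any(np.isclose(gap_width_ms, w) for w in spec.gap_widths_ms):
        raise ValueError(f"gap width {gap_width_ms} ms not in spec.gap_widths_ms")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(spec.segment_ms / 1000.0 * fs))
    x = _band_noise(n, fs, spec.band_low_hz, spec.band_high_hz, rng)
    r = np.sqrt(np.mean(np.square(x)))
    if r > 0:
        x *= rms_target / r
    atten = 1.0 - spec.modulation_depth_pct / 100.0
    onsets = gap_onset_times_s(spec)
    w = gap_width_ms / 1000.0
    for t0 in onsets:
        i0 = int(round(t0 * fs))
        i1 = min(int(round((t0 + w) * fs)), n)
        x[i0:i1] *= atten
    return StimulusWaveform(data=x, fs_hz=fs, gap_onsets_s=onsets)


def schedule_session(
    nb: NoiseBurstSpec = NoiseBurstSpec(),
    ga: GapAssrSpec = GapAssrSpec(),
    ss: SessionSchedule = SessionSchedule(),
    seed: int = 0,
) -> pd.DataFrame:
    """Build the event table for one recording session.

    The session opens with ``rest_min`` of silence, then the gap-ASSR and
    noise-burst blocks in the order given by ``ss.block_order``.  The
    gap-ASSR block is filled with alternating no-gap / gap-interrupted
    250 ms segments; each gap segment's width is drawn uniformly at random
    from ``ga.gap_widths_ms``.  Noise-burst onsets tile their block at
    ``nb.repetition_rate_hz`` (the block is duration-driven;
    ``nb.n_repetitions`` documents the nominal protocol count).

    Returns a DataFrame with columns ``onset_s, kind, gap_width_ms``,
    onsets strictly increasing; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[float, str, float]] = []

    t = ss.rest_min * 60.0
    blocks = ["gapassr", "noise"] if ss.block_order == "gapassr-first" else ["noise", "gapassr"]
    for block in blocks:
        if block == "gapassr":
            t_end = t + ss.gapassr_min * 60.0
            seg = ga.segment_ms / 1000.0
            is_gap = False  # alternate, starting with a plain-noise segment
            while t + seg <= t_end + 1e-9:
                if is_gap:
                    width = float(rng.choice(ga.gap_widths_ms))
                    rows.append((t, "gap_segment", width))
                else:
                    rows.append((t, "nogap_segment", np.nan))
                t += seg
                is_gap = not is_gap
            t = t_end
        else:
            t_end = t + ss.noise_min * 60.0
            period = 1.0 / nb.repetition_rate_hz
            onset = t
            while onset + nb.duration_ms / 1000.0 <= t_end + 1e-9:
                rows.append((onset, "noise_burst", np.nan))
                onset += period
            t = t_end

    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    if len(df):
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
        if not np.all(np.diff(df["onset_s"].to_numpy()) > 0):
            raise RuntimeError("event onsets are not strictly increasing")
    return df


def validate_events(events: pd.DataFrame) -> None:
    """Raise if an event table violates its invariants."""
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if len(events) == 0:
        return
    onsets = events["onset_s"].to_numpy(float)
    if not np.all(np.diff(onsets) > 0):
        raise ValueError("event onsets must be strictly increasing")
    bad = set(events["kind"]) - set(EVENT_KINDS)
    if bad:
        raise ValueError(f"unknown event kinds: {sorted(bad)}")
    gaps = events.loc[events["kind"] == "gap_segment", "gap_width_ms"]
    if gaps.isna().any():
        raise ValueError("every gap_segment row must carry a gap width")


def write_events(events: pd.DataFrame, path) -> None:
    """Serialize an event table as tab-separated text."""
    events.to_csv(path, sep="\t", index=False, na_rep="")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_events(df)
    return df


def write_wav(wf: StimulusWaveform, path) -> None:
    """Write a waveform as 16-bit mono WAV (documentation use only)."""
    from scipy.io import wavfile

    peak = np.max(np.abs(wf.data)) or 1.0
    wavfile.write(path, int(wf.fs_hz), np.int16(np.clip(wf.data / peak, -1, 1) * 32767))
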