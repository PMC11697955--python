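"""Trial preprocessing, ERP averaging and P1/N1/P2 peak measurement.

Each trial is baseline-corrected against the mean of the 250 ms
pre-stimulus span and then linearly detrended over the whole trial; the
ERP is the pointwise trial average.  Peaks are measured baseline-to-peak
(amplitudes relative to the corrected 0 uV baseline) inside configurable
post-onset search windows; the study does not print windows, so the
defaults bracket standard mouse ERP latencies: P1 10-40 ms, N1 25-100 ms,
P2 60-250 ms.  N1 is reported as a signed (negative) value; group
comparisons use its magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "ERPResult",
    "DEFAULT_PEAK_WINDOWS",
    "BASELINE_SPAN_S",
    "preprocess_trials",
    "average_erp",
    "measure_peaks",
    "peak_table",
]

#: Post-onset peak search windows (seconds), half-open.
DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "P1": (0.010, 0.040),
    "N1": (0.025, 0.100),
    "P2": (0.060, 0.250),
}

#: Pre-onset baseline span used for correction (seconds before onset).
BASELINE_SPAN_S = 0.250

#: Peaks smaller than this (uV) in magnitude flag a low-SNR average.
LOW_SNR_UV = 1.0


@dataclass
class ERPResult:
    """Trial-averaged ERP and, after :func:`measure_peaks`, its peaks.

    ``peaks[channel]`` maps ``P1_uV / N1_uV / P2_uV`` to baseline-to-peak
    amplitudes (N1 negative by convention) and ``*_lat_ms`` to latencies.
    """

    waveform: np.ndarray  # (n_channels, n_times), uV
    fs_hz: float
    t0_offset_s: float
    n_trials: int
    channel_names: list[str]
    peaks: dict[str, dict[str, float]] | None = None
    low_snr: dict[str, bool] = field(default_factory=dict)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.waveform.shape[1]) / self.fs_hz


def preprocess_trials(ep: EpochSet) -> EpochSet:
    """Baseline-correct (mean of the 250 ms pre-onset span) then detrend.

    Raises if the epoch window does not cover the baseline span.
    """
    t = ep.times_s
    base = (t >= -BASELINE_SPAN_S) & (t < 0)
    if ep.t0_offset_s > -BASELINE_SPAN_S + 1e-9 or not base.any():
        raise ValueError("epoch window must include the 250 ms pre-onset baseline")
    data = ep.data - ep.data[:, :, base].mean(axis=2, keepdims=True)
    data = sps.detrend(data, axis=2, type="linear")
    return EpochSet(
        data=data,
        t0_offset_s=ep.t0_offset_s,
        fs_hz=ep.fs_hz,
        labels=ep.labels.copy(),
        channel_names=list(ep.channel_names),
    )


def average_erp(ep: EpochSet) -> ERPResult:
    """Pointwise mean across trials."""
    if ep.n_trials < 2:
        raise ValueError("ERP averaging needs at least two trials")
    return ERPResult(
        waveform=ep.data.mean(axis=0),
        fs_hz=ep.fs_hz,
        t0_offset_s=ep.t0_offset_s,
        n_trials=ep.n_trials,
        channel_names=list(ep.channel_names),
    )


def measure_peaks(
    erp: ERPResult,
    windows: dict[str, tuple[float, float]] | None = None,
) -> ERPResult:
    """Measure P1 (max), N1 (min) and P2 (max) in their search windows.

    Amplitudes are relative to the corrected baseline (0 uV); ties within a
    window resolve to the earliest latency.  A channel whose peaks are all
    below ``LOW_SNR_UV`` in magnitude is flagged in ``low_snr``.

    Raises
    ------
    ValueError
        If a search window falls outside the epoch.
    """
    windows = dict(DEFAULT_PEAK_WINDOWS if windows is None else windows)
    t = erp.times_s
    peaks: dict[str, dict[str, float]] = {}
    low_snr: dict[str, bool] = {}
    for ci, ch in enumerate(erp.channel_names):
        out: dict[str, float] = {}
        for name, (w0, w1) in windows.items():
            sel = (t >= w0) & (t < w1)
            if not sel.any():
                raise ValueError(f"peak window {name}={w0, w1} outside epoch")
            seg = erp.waveform[ci, sel]
            tseg = t[sel]
            idx = int(np.argmin(seg)) if name.startswith("N") else int(np.argmax(seg))
            out[f"{name}_uV"] = float(seg[idx])
            out[f"{name}_lat_ms"] = float(tseg[idx] * 1000.0)
        peaks[ch] = out
        low_snr[ch] = all(
            abs(out[f"{n}_uV"]) < LOW_SNR_UV for n in windows
        )
        if low_snr[ch]:
            logger.warning("channel %s: all peaks < %g uV (low SNR)", ch, LOW_SNR_UV)
    return replace(erp, peaks=peaks, low_snr=low_snr)


def peak_table(erp: ERPResult, **id_fields) -> pd.DataFrame:
    """Flatten measured peaks into per-animal CohortTable rows.

    ``id_fields`` (animal_id, genotype, ...) are repeated on every row.
    """
    if erp.peaks is None:
        raise ValueError("run measure_peaks first")
    rows = []
    for ch, vals in erp.peaks.items():
        row = dict(id_fields)
        row["region"] = ch
        row.update({k: v for k, v in vals.items()})
        row["n_trials"] = erp.n_trials
        rows.append(row)
    return pd.DataFrame(rows)
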