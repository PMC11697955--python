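"""Recording containers, EDF+ and fixture I/O, resampling, epoch extraction.

A :class:`Recording` is continuous multichannel EEG in microvolts with its
event table (the TTL analogue).  Two on-disk forms are supported:

* **EDF+** (``.edf``): 16-bit physical-unit encoding with events stored as
  EDF+ annotations.  Writing is implemented here; reading goes through
  :mod:`mne`.
* a lightweight **NPZ fixture container** (``.npz``) that round-trips
  float samples exactly (used for tests and intermediate pipeline files).

Acquisition happens at a high rate in the real experiment and analysis at
1024 Hz; :func:`downsample` provides the anti-aliased rate conversion with
event times preserved in seconds.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .stimgen import EVENT_COLUMNS, validate_events

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EpochSet",
    "read_recording",
    "write_recording",
    "downsample",
    "extract_epochs",
]

ANALYSIS_FS = 1024.0


@dataclass
class Recording:
    """Continuous multichannel EEG (uV) with sampling metadata and events."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs_hz: float
    channel_names: list[str]
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class EpochSet:
    """Trials x channels x time array cut around events.

    ``t0_offset_s`` is the time of the first sample relative to the event
    onset (negative for a pre-stimulus baseline).  The window convention is
    half-open ``[t_min, t_max)`` with the onset at t = 0.
    """

    data: np.ndarray  # (n_trials, n_channels, n_times)
    t0_offset_s: float
    fs_hz: float
    labels: pd.DataFrame  # per-trial: kind, gap_width_ms, onset_s
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.data.shape[2]) / self.fs_hz


# ---------------------------------------------------------------------------
# EDF+ writing (16-bit, annotations as TALs)

_EDF_HEADER_FIELDS = 256


def _fit(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width}")
    return b.ljust(width)


def _event_description(row) -> str:
    if row["kind"] == "gap_segment" and not pd.isna(row["gap_width_ms"]):
        return f"{row['kind']}/{row['gap_width_ms']:g}"
    return str(row["kind"])


def _parse_description(desc: str) -> tuple[str, float]:
    if "/" in desc:
        kind, width = desc.split("/", 1)
        return kind, float(width)
    return desc, float("nan")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writing requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError(
            "EDF writing requires a whole number of 1 s records; "
            "pad the recording or use the .npz fixture container"
        )
    n_records = rec.n_samples // fs
    n_sig = len(rec.channel_names) + 1  # + annotation channel

    # TALs: one timestamp per record plus the events that fall inside it
    tals: list[list[bytes]] = []
    ev_iter = rec.events.sort_values("onset_s") if len(rec.events) else rec.events
    per_record: list[list[bytes]] = [[] for _ in range(n_records)]
    for _, row in ev_iter.iterrows():
        onset = float(row["onset_s"])
        ridx = min(int(onset), n_records - 1)
        desc = _event_description(row)
        per_record[ridx].append(
            f"+{onset:.7f}\x14{desc}\x14\x00".encode("ascii")
        )
    for r in range(n_records):
        tal = [f"+{r}\x14\x14\x00".encode("ascii")] + per_record[r]
        tals.append(tal)
    ann_bytes = max(len(b"".join(t)) for t in tals)
    ann_samples = math.ceil(ann_bytes / 2) + 1  # int16 samples per record

    # physical scaling: symmetric range, digital +-32767
    pmax = float(np.max(np.abs(rec.data))) if rec.data.size else 1.0
    pmax = pmax if pmax > 0 else 1.0
    scale = 32767.0 / pmax
    digital = np.round(rec.data * scale).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_fit("0", 8))
        fh.write(_fit("X X X X", 80))
        fh.write(_fit("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_fit("01.01.00", 8))
        fh.write(_fit("00.00.00", 8))
        fh.write(_fit(str(256 * (n_sig + 1)), 8))
        fh.write(_fit("EDF+C", 44))
        fh.write(_fit(str(n_records), 8))
        fh.write(_fit("1", 8))
        fh.write(_fit(str(n_sig), 4))

        labels = list(rec.channel_names) + ["EDF Annotations"]
        fh.write(b"".join(_fit(lb, 16) for lb in labels))
        fh.write(b"".join(_fit("", 80) for _ in labels))
        dims = ["uV"] * len(rec.channel_names) + [""]
        fh.write(b"".join(_fit(d, 8) for d in dims))
        pmins = [f"{-pmax:.6g}"] * len(rec.channel_names) + ["-1"]
        pmaxs = [f"{pmax:.6g}"] * len(rec.channel_names) + ["1"]
        fh.write(b"".join(_fit(v, 8) for v in pmins))
        fh.write(b"".join(_fit(v, 8) for v in pmaxs))
        fh.write(b"".join(_fit("-32767", 8) for _ in rec.channel_names) + _fit("-32768", 8))
        fh.write(b"".join(_fit("32767", 8) for _ in labels))
        fh.write(b"".join(_fit("", 80) for _ in labels))
        nsamp = [str(fs)] * len(rec.channel_names) + [str(ann_samples)]
        fh.write(b"".join(_fit(v, 8) for v in nsamp))
        fh.write(b"".join(_fit("", 32) for _ in labels))

        for r in range(n_records):
            for ch in range(len(rec.channel_names)):
                fh.write(digital[ch, r * fs : (r + 1) * fs].tobytes())
            blob = b"".join(tals[r])
            fh.write(blob.ljust(2 * ann_samples, b"\x00"))


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # corrupt / truncated file
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne scales uV channels to volts
    rows = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        kind, width = _parse_description(desc)
        rows.append((float(onset), kind, width))
    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    if len(events):
        events = events.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return Recording(
        data=data,
        fs_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=events,
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# NPZ fixture container


def _write_npz(rec: Recording, path: Path) -> None:
    np.savez_compressed(
        path,
        data=rec.data,
        fs_hz=rec.fs_hz,
        channel_names=np.array(rec.channel_names),
        ev_onset=rec.events["onset_s"].to_numpy(float) if len(rec.events) else np.empty(0),
        ev_kind=rec.events["kind"].to_numpy(str) if len(rec.events) else np.empty(0, str),
        ev_width=rec.events["gap_width_ms"].to_numpy(float)
        if len(rec.events)
        else np.empty(0),
        meta=json.dumps(rec.meta, sort_keys=True, default=str),
    )


def _read_npz(path: Path) -> Recording:
    try:
        with np.load(path, allow_pickle=False) as z:
            events = pd.DataFrame(
                {
                    "onset_s": z["ev_onset"],
                    "kind": z["ev_kind"].astype(str),
                    "gap_width_ms": z["ev_width"],
                }
            )
            return Recording(
                data=z["data"],
                fs_hz=float(z["fs_hz"]),
                channel_names=[str(c) for c in z["channel_names"]],
                events=events,
                meta=json.loads(str(z["meta"])),
            )
    except Exception as exc:
        raise ValueError(f"could not parse fixture container {path}: {exc}") from exc


def write_recording(rec: Recording, path) -> None:
    """Write a recording as EDF+ (``.edf``) or fixture container (``.npz``)."""
    path = Path(path)
    if len(rec.events):
        validate_events(rec.events)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    elif path.suffix.lower() == ".npz":
        _write_npz(rec, path)
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix.lower() == ".npz":
        return _read_npz(path)
    raise ValueError(f"unsupported recording format: {path.suffix}")


# ---------------------------------------------------------------------------


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased resampling to ``target_fs`` (e.g. 24414 -> 1024 Hz).

    A zero-phase Butterworth low-pass at 0.4 * target_fs precedes polyphase
    rational-ratio resampling.  Event onsets are stored in seconds and so
    carry over unchanged.
    """
    if target_fs > rec.fs_hz:
        raise ValueError("downsample cannot increase the sampling rate")
    if target_fs == rec.fs_hz:
        return Recording(
            data=rec.data.copy(),
            fs_hz=rec.fs_hz,
            channel_names=list(rec.channel_names),
            events=rec.events.copy(),
            meta=dict(rec.meta),
        )
    sos = signal.butter(8, 0.4 * target_fs / (rec.fs_hz / 2), output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    frac = Fraction(target_fs / rec.fs_hz).limit_denominator(1_000_000)
    out = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=-1)
    return Recording(
        data=out,
        fs_hz=float(target_fs),
        channel_names=list(rec.channel_names),
        events=rec.events.copy(),
        meta=dict(rec.meta),
    )


def extract_epochs(
    rec: Recording,
    kind: str | list[str],
    window: tuple[float, float],
    gap_width_ms: float | None = None,
    reject=None,
) -> EpochSet:
    """Cut one trial per matching event.

    ``window`` is ``(t_min, t_max)`` in seconds relative to event onset,
    half-open.  Trials whose window extends beyond the recording are
    dropped with a logged count.  ``reject`` is an optional per-trial hook
    ``f(trial_array) -> bool`` returning True to keep (default keeps all;
    the reference protocol rejected no data).

    Raises
    ------
    ValueError
        For a zero-length window or when no event matches.
    """
    t_min, t_max = window
    if not t_max > t_min:
        raise ValueError("epoch window must have positive length")
    kinds = [kind] if isinstance(kind, str) else list(kind)
    sel = rec.events[rec.events["kind"].isin(kinds)]
    if gap_width_ms is not None:
        sel = sel[np.isclose(sel["gap_width_ms"].to_numpy(float), gap_width_ms)]
    if len(sel) == 0:
        raise ValueError(f"no events of kind {kinds} in recording")

    n_samp = int(round((t_max - t_min) * rec.fs_hz))
    trials, keep_rows = [], []
    dropped = 0
    for _, row in sel.iterrows():
        i0 = int(round((row["onset_s"] + t_min) * rec.fs_hz))
        i1 = i0 + n_samp
        if i0 < 0 or i1 > rec.n_samples:
            dropped += 1
            continue
        tr = rec.data[:, i0:i1]
        if reject is not None and not reject(tr):
            dropped += 1
            continue
        trials.append(tr)
        keep_rows.append(row)
    if dropped:
        logger.info("dropped %d/%d trials (window out of range or rejected)", dropped, len(sel))
    if not trials:
        raise ValueError("all matching trials fell outside the recording")
    labels = pd.DataFrame(keep_rows).reset_index(drop=True)[list(EVENT_COLUMNS)]
    return EpochSet(
        data=np.stack(trials),
        t0_offset_s=float(t_min),
        fs_hz=rec.fs_hz,
        labels=labels,
        channel_names=list(rec.channel_names),
    )
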