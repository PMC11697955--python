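"""Forward simulation of two-channel mouse EEG with known ground truth.

The real study's raw data are not deposited, so every downstream stage is
exercised on synthetic recordings whose statistical structure mirrors the
reported phenotypes:

* a 1/f^alpha background plus a band-limited (30-100 Hz) gamma component,
  elevated in *Fmr1* KO animals;
* a P1-N1-P2 event-related template injected at each noise-burst onset
  (N1 elevated in KO) with small trial-to-trial amplitude/latency jitter;
* a 40 Hz oscillatory response locked to the gap train in gap-ASSR
  segments.  Each gap segment responds with probability
  ``sigmoid(gap_response_slope * (width - gap_threshold_ms))`` and, when it
  does, its onset phase is drawn wrapped-normal with SD
  ``assr_phase_jitter_rad`` — so the expected 40 Hz ITPC has the closed
  form ``p(width) * exp(-sigma^2 / 2)`` in the high-SNR limit.

Treatment with the 5-HT1A agonist reduces phase jitter in both genotypes
and, in KO animals at P30 only, returns the gamma background to wild-type
level.  Effect magnitudes are configuration defaults, not published
values: the study reports effect directions and significance only.

The frontal channel is the auditory-cortex source attenuated, lagged and
summed with independent noise — a deliberately phenomenological stand-in
for the reported AC/FC similarity, not a connectivity model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Recording
from .stimgen import (
    GapAssrSpec,
    NoiseBurstSpec,
    SessionSchedule,
    schedule_session,
    gap_onset_times_s,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnimalParams",
    "EffectSizes",
    "make_animal_params",
    "simulate_recording",
    "simulate_cohort",
    "simulate_cohort_measures",
    "response_probability",
]

GENOTYPES = ("WT", "KO")
TREATMENTS = ("saline", "NLX101")
SEXES = ("M", "F")
AGES = ("P21", "P30")


@dataclass(frozen=True)
class AnimalParams:
    """Generative parameters for one virtual animal.

    Amplitudes are in microvolts; the ERP template triple is (P1, N1, P2)
    with the sign convention positive-negative-positive.
    """

    genotype: str = "WT"
    treatment: str = "saline"
    sex: str = "M"
    age: str = "P30"
    # ERP template
    erp_amp_uV: tuple[float, float, float] = (15.0, -45.0, 20.0)
    erp_latency_s: tuple[float, float, float] = (0.025, 0.050, 0.110)
    erp_width_s: tuple[float, float, float] = (0.006, 0.012, 0.025)
    erp_amp_jitter: float = 0.10  # fractional SD per trial
    erp_latency_jitter_s: float = 0.002
    # background
    bg_rms_uV: float = 60.0
    bg_alpha: float = 1.0
    gamma_band_hz: tuple[float, float] = (30.0, 100.0)
    gamma_rms_uV: float = 10.0
    gamma_bg_scale: float = 1.0
    # 40 Hz gap-locked response
    assr_amp_uV: float = 15.0
    assr_phase_jitter_rad: float = 0.9
    gap_response_slope: float = 1.2  # per ms
    gap_threshold_ms: float = 4.0
    # frontal channel derivation
    fc_gain: float = 0.8
    fc_lag_s: float = 0.005
    # between-subject variability (used by cohort draws)
    subject_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in ("bg_rms_uV", "gamma_rms_uV", "gamma_bg_scale",
                     "assr_amp_uV", "assr_phase_jitter_rad", "subject_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")


@dataclass(frozen=True)
class EffectSizes:
    """Group-effect multipliers (configuration defaults, not published values)."""

    ko_n1_mult: float = 1.25          # |N1| scaling in KO
    ko_gamma_mult: float = 2.0        # gamma background amplitude in KO
    ko_jitter_mult: float = 1.5       # ASSR phase jitter in KO
    nlx_jitter_mult: float = 0.6      # jitter reduction, both genotypes
    nlx_gamma_rescue_p30: bool = True  # gamma returned to WT level in KO at P30


def make_animal_params(
    genotype: str,
    treatment: str,
    sex: str = "M",
    age: str = "P30",
    effects: EffectSizes = EffectSizes(),
    base: AnimalParams = AnimalParams(),
) -> AnimalParams:
    """Apply genotype/treatment/age effect structure to a base parameter set."""
    p1, n1, p2 = base.erp_amp_uV
    gamma = base.gamma_bg_scale
    jitter = base.assr_phase_jitter_rad
    if genotype == "KO":
        n1 *= effects.ko_n1_mult
        gamma *= effects.ko_gamma_mult
        jitter *= effects.ko_jitter_mult
    if treatment == "NLX101":
        jitter *= effects.nlx_jitter_mult
        if genotype == "KO" and age == "P30" and effects.nlx_gamma_rescue_p30:
            gamma /= effects.ko_gamma_mult
    return replace(
        base,
        genotype=genotype,
        treatment=treatment,
        sex=sex,
        age=age,
        erp_amp_uV=(p1, n1, p2),
        gamma_bg_scale=gamma,
        assr_phase_jitter_rad=jitter,
    )


def response_probability(params: AnimalParams, gap_width_ms) -> np.ndarray:
    """Per-segment probability of a 40 Hz response, sigmoid in gap width."""
    w = np.asarray(gap_width_ms, float)
    return 1.0 / (1.0 + np.exp(-params.gap_response_slope * (w - params.gap_threshold_ms)))


def _pink_noise(n: int, alpha: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha Gaussian noise with the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    r = np.sqrt(np.mean(x**2))
    return x * (rms / r) if r > 0 else x


def _gamma_noise(n: int, fs: float, band: tuple[float, float], rms: float,
                 rng: np.random.Generator) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.99 * fs / 2)
    sos = sps.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    r = np.sqrt(np.mean(x**2))
    return x * (rms / r) if r > 0 else x


def _erp_template(params: AnimalParams, fs: float, rng: np.random.Generator,
                  jitter: bool = True) -> np.ndarray:
    """One trial's evoked waveform on a 0-300 ms support."""
    t = np.arange(int(round(0.3 * fs))) / fs
    out = np.zeros_like(t)
    for amp, lat, width in zip(params.erp_amp_uV, params.erp_latency_s, params.erp_width_s):
        a = amp * (1.0 + params.erp_amp_jitter * rng.standard_normal()) if jitter else amp
        l = lat + (params.erp_latency_jitter_s * rng.standard_normal() if jitter else 0.0)
        out += a * np.exp(-((t - l) ** 2) / (2.0 * width**2))
    return out


def _cos2_onoff(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    if n_ramp > 0 and 2 * n_ramp <= n:
        ramp = np.sin(np.linspace(0, np.pi / 2, n_ramp, endpoint=False)) ** 2
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def simulate_recording(
    params: AnimalParams,
    events: pd.DataFrame,
    fs: float = 1024.0,
    seed: int | np.random.SeedSequence = 0,
    duration_s: float | None = None,
    ga: GapAssrSpec = GapAssrSpec(),
) -> Recording:
    """Simulate one two-channel (AC, FC) recording for an event table.

    The recording spans the events plus one second of padding (rounded up
    to whole seconds so it can be written as EDF), unless ``duration_s``
    is given — in which case events outside the span raise.
    """
    if fs < 256:
        raise ValueError("simulation requires fs >= 256 Hz")
    rng = np.random.default_rng(seed)

    if len(events):
        t_last = float(events["onset_s"].max()) + 1.0
    else:
        t_last = 1.0
    if duration_s is None:
        duration_s = float(np.ceil(t_last))
    elif t_last - 1.0 > duration_s:
        raise ValueError("event outside recording span")
    n = int(round(duration_s * fs))

    source = np.zeros(n)
    source += _gamma_noise(n, fs, params.gamma_band_hz,
                           params.gamma_rms_uV * params.gamma_bg_scale, rng)

    # evoked responses at noise-burst onsets
    for onset in events.loc[events["kind"] == "noise_burst", "onset_s"]:
        tmpl = _erp_template(params, fs, rng)
        i0 = int(round(onset * fs))
        i1 = min(i0 + tmpl.size, n)
        if i0 < n:
            source[i0:i1] += tmpl[: i1 - i0]

    # 40 Hz gap-locked responses, one Bernoulli draw + phase per segment
    f_assr = 1.0 / (ga.gap_interval_ms / 1000.0)
    seg_n = int(round(ga.segment_ms / 1000.0 * fs))
    seg_env = _cos2_onoff(seg_n, int(round(0.010 * fs)))
    t_seg = np.arange(seg_n) / fs
    gaps = events[events["kind"] == "gap_segment"]
    for onset, width in zip(gaps["onset_s"], gaps["gap_width_ms"]):
        p = float(response_probability(params, width))
        if rng.random() >= p:
            continue
        phi = rng.normal(0.0, params.assr_phase_jitter_rad)
        burst = params.assr_amp_uV * np.sin(2 * np.pi * f_assr * t_seg + phi) * seg_env
        i0 = int(round(onset * fs))
        i1 = min(i0 + seg_n, n)
        if i0 < n:
            source[i0:i1] += burst[: i1 - i0]

    lag = int(round(params.fc_lag_s * fs))
    fc_source = np.zeros(n)
    fc_source[lag:] = params.fc_gain * source[: n - lag]

    ac = source + _pink_noise(n, params.bg_alpha, params.bg_rms_uV, rng)
    fc = fc_source + _pink_noise(n, params.bg_alpha, params.bg_rms_uV, rng)

    return Recording(
        data=np.vstack([ac, fc]),
        fs_hz=float(fs),
        channel_names=["AC", "FC"],
        events=events.reset_index(drop=True),
        meta={"params": asdict(params), "seed": repr(seed)},
    )


def _subject_variation(base: AnimalParams, rng: np.random.Generator) -> AnimalParams:
    """Per-animal lognormal draws around the group-level parameters."""
    sd = base.subject_noise_sd
    m = lambda: float(np.exp(rng.normal(0.0, sd)))  # noqa: E731
    p1, n1, p2 = base.erp_amp_uV
    amp_m = m()
    return replace(
        base,
        erp_amp_uV=(p1 * amp_m, n1 * amp_m, p2 * amp_m),
        gamma_rms_uV=base.gamma_rms_uV * m(),
        assr_amp_uV=base.assr_amp_uV * m(),
        assr_phase_jitter_rad=base.assr_phase_jitter_rad * m(),
        bg_rms_uV=base.bg_rms_uV * m(),
    )


def default_design(n_per_group: int = 8) -> pd.DataFrame:
    """Balanced genotype x treatment design with sexes split evenly."""
    rows = []
    for g in GENOTYPES:
        for t in TREATMENTS:
            for s in SEXES:
                rows.append({"genotype": g, "treatment": t, "sex": s,
                             "n": n_per_group - n_per_group // 2
                             if s == "M" else n_per_group // 2})
    return pd.DataFrame(rows)


def simulate_cohort(
    design: pd.DataFrame,
    age: str = "P30",
    seed: int = 0,
    effects: EffectSizes = EffectSizes(),
    base: AnimalParams = AnimalParams(),
    nb: NoiseBurstSpec = NoiseBurstSpec(),
    ga: GapAssrSpec = GapAssrSpec(),
    ss: SessionSchedule = SessionSchedule(),
    fs: float = 1024.0,
) -> list[Recording]:
    """Simulate one recording per animal of a cohort design.

    ``design`` has columns genotype, treatment, sex (optional), n.  Each
    animal gets its own stimulus schedule realization and its own
    parameter draw around the group means; deterministic for a fixed seed.
    """
    if len(design) == 0 or design["n"].sum() == 0:
        raise ValueError("empty cohort design")
    if (design["n"] < 0).any():
        raise ValueError("group sizes must be non-negative")
    root = np.random.SeedSequence(seed)
    recs: list[Recording] = []
    animal_id = 0
    for _, grp in design.iterrows():
        sex = grp.get("sex", "M")
        group_params = make_animal_params(
            grp["genotype"], grp["treatment"], sex, age, effects, base
        )
        for _ in range(int(grp["n"])):
            ss_events, ss_rec = root.spawn(2)
            events = schedule_session(
                nb, ga, ss, seed=int(ss_events.generate_state(1)[0] % (2**31))
            )
            rng = np.random.default_rng(ss_rec)
            params = _subject_variation(group_params, rng)
            rec = simulate_recording(params, events, fs=fs, seed=ss_rec.spawn(1)[0], ga=ga)
            rec.meta["animal_id"] = f"a{animal_id:03d}"
            rec.meta["genotype"] = grp["genotype"]
            rec.meta["treatment"] = grp["treatment"]
            rec.meta["sex"] = sex
            rec.meta["age"] = age
            recs.append(rec)
            animal_id += 1
    return recs


def simulate_cohort_measures(
    design: pd.DataFrame,
    age: str = "P30",
    seed: int = 0,
    effects: EffectSizes = EffectSizes(),
    base: AnimalParams = AnimalParams(),
    gap_widths_ms: tuple[float, ...] = (3, 4, 5, 6, 7, 8, 9),
    measurement_sd: float = 0.03,
    fc_factor: float = 0.9,
) -> pd.DataFrame:
    """Draw per-animal mean 40 Hz ITPC tables directly from the analytic model.

    This bypasses waveform simulation: each animal's expected ITPC at gap
    width w is ``p(w) * exp(-sigma_l^2 / 2)`` with a lognormal subject draw
    on sigma, plus Gaussian measurement noise, clipped to [0, 1].  Used for
    statistics-level simulations (null calibration, power) where thousands
    of cohorts are needed; the waveform-to-measure link is validated
    separately by the parameter-recovery tests.
    """
    if len(design) == 0 or design["n"].sum() == 0:
        raise ValueError("empty cohort design")
    rng = np.random.default_rng(seed)
    widths = np.asarray(gap_widths_ms, float)
    rows = []
    animal_id = 0
    for _, grp in design.iterrows():
        sex = grp.get("sex", "M")
        gp = make_animal_params(grp["genotype"], grp["treatment"], sex, age, effects, base)
        for _ in range(int(grp["n"])):
            sigma = gp.assr_phase_jitter_rad * np.exp(rng.normal(0, gp.subject_noise_sd))
            p = response_probability(gp, widths)
            expect = p * np.exp(-(sigma**2) / 2.0)
            for region, factor in (("AC", 1.0), ("FC", fc_factor)):
                vals = np.clip(
                    expect * factor + rng.normal(0, measurement_sd, widths.size), 0, 1
                )
                for w, v in zip(widths, vals):
                    rows.append(
                        {
                            "animal_id": f"a{animal_id:03d}",
                            "region": region,
                            "age": age,
                            "genotype": grp["genotype"],
                            "treatment": grp["treatment"],
                            "sex": sex,
                            "measure": "mean_itpc_40hz",
                            "gap_width_ms": w,
                            "value": float(v),
                        }
                    )
            animal_id += 1
    return pd.DataFrame(rows)
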