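"""Synthetic ABP + NIRS recordings and subject-level tables with known truth.

The recording generator produces an arterial pressure waveform as a pulsatile
carrier at the heart rate plus a Mayer-wave low-frequency oscillation, a
respiratory component and broadband physiological noise.  Each NIRS channel
is that pressure fluctuation passed through a configurable band-wise linear
transfer function (the ground-truth cerebral autoregulation response), plus a
shared extracerebral (scalp) component, slow drift, sensor noise and injected
square-pulse artifacts.  Everything is seeded and bit-reproducible.

Phase sign convention throughout: positive phase means the NIRS oscillation
follows (lags) ABP; negative means it precedes ABP.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    ChannelMeta,
    Event,
    GroundTruth,
    NirsChannel,
    RawRecording,
)

#: analysis frequency bands, Hz (half-open intervals [lo, hi))
BANDS = {"VLF": (0.02, 0.07), "LF": (0.07, 0.2), "HF": (0.2, 0.5)}

#: relative amplitudes of the first three harmonics of the pulsatile carrier
CARRIER_HARMONICS = (1.0, 0.4, 0.15)


@dataclass(frozen=True)
class BandTransfer:
    """Ground-truth ABP→OxyHb response in one band."""

    gain_true: float  # µM·mm per mmHg
    phase_true_deg: float  # positive = OxyHb follows ABP


def default_band_transfer() -> dict[str, dict[str, BandTransfer]]:
    """Plausible band responses: moderate damping, OxyHb lagging ABP by a
    few tens of degrees in LF, as seen in adults with working autoregulation.
    """
    per_hemi = {
        "VLF": BandTransfer(gain_true=3.0, phase_true_deg=20.0),
        "LF": BandTransfer(gain_true=5.0, phase_true_deg=35.0),
        "HF": BandTransfer(gain_true=8.0, phase_true_deg=10.0),
    }
    return {
        "ischaemic": dict(per_hemi),
        "contralateral": dict(per_hemi),
    }


@dataclass
class ArtifactSpec:
    """Additive square-pulse artifacts.

    ``amplitude_sd`` scales each pulse to that many robust standard
    deviations of the clean signal it lands on, so one spec serves signals
    of different physical units.
    """

    count: int = 0
    amplitude_sd: float = 12.0
    duration_s: float = 2.0
    targets: tuple[str, ...] = ("abp", "nirs")


@dataclass
class Excursion:
    """A transient vital-sign change: ramp up over ``ramp_s``, hold ``delta``
    until ``end_s``, ramp back."""

    start_s: float
    end_s: float
    delta: float
    ramp_s: float = 5.0


@dataclass
class VitalSpec:
    baseline: float
    noise_sd: float = 0.0
    excursions: list[Excursion] = field(default_factory=list)


def default_vitals_spec() -> dict[str, VitalSpec]:
    return {
        "hr": VitalSpec(60.0, 0.3),
        "mean_abp": VitalSpec(100.0, 0.5),
        "spo2": VitalSpec(98.0, 0.1),
        "etco2": VitalSpec(4.5, 0.02),
    }


def default_event_times(duration_s: float) -> dict[str, float]:
    """Procedure timeline scaled to the recording length: anaesthesia
    induction early, recanalization attempts mid-record, anaesthesia
    termination leaving room for a post-termination window."""
    return {
        "ga_induction": 0.017 * duration_s,
        "first_attempt": 0.25 * duration_s,
        "reperfusion": 0.27 * duration_s,
        "ga_termination": 0.67 * duration_s,
    }


@dataclass
class SynthConfig:
    duration_s: float = 3600.0
    fs_raw: float = 100.0
    hr_bpm: float = 60.0
    map_mmhg: float = 100.0
    pulse_amp_mmhg: float = 20.0  # peak-to-peak carrier amplitude
    lfo_freq_hz: float = 0.1
    lfo_amp_mmhg: float = 4.0
    resp_freq_hz: float = 0.25
    resp_amp_mmhg: float = 2.0
    hr_jitter_frac: float = 0.0  # per-beat period jitter (fraction of period)
    band_transfer: dict[str, dict[str, BandTransfer]] = field(
        default_factory=default_band_transfer
    )
    # share of channel variance contributed by the shared scalp component
    extracerebral_fraction: dict[str, float] = field(
        default_factory=lambda: {"long": 0.2, "short": 1.0}
    )
    n_long_per_hemisphere: int = 3
    n_short_per_hemisphere: int = 1
    noise_sd_abp: float = 1.0  # broadband physiological ABP fluctuation, mmHg
    noise_sd_nirs: float = 0.5  # independent sensor noise, µM·mm
    nirs_drift_amp: float = 2.0  # µM·mm, very slow sinusoidal drift
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    event_times: dict[str, float] | None = None
    drug_change_times: tuple[float, ...] = ()
    vitals_spec: dict[str, VitalSpec] | None = None
    vitals_fs: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s < 300:
            raise ValueError("duration_s must be >= 300 s (one steady segment)")
        nyq = self.fs_raw / 2
        for f in (self.lfo_freq_hz, self.resp_freq_hz, self.hr_bpm / 60.0):
            if not 0 < f < nyq:
                raise ValueError(f"component frequency {f} Hz outside (0, fs/2)")
        for role, frac in self.extracerebral_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"extracerebral_fraction[{role!r}]={frac} outside [0, 1]"
                )
        for hemi, bands in self.band_transfer.items():
            for b in bands:
                if b not in BANDS:
                    raise ValueError(f"unknown band {b!r} for {hemi}")
        events = self.resolved_event_times()
        for name, t in events.items():
            if not 0 <= t <= self.duration_s:
                raise ValueError(f"event {name!r} at {t} s outside recording")

    def resolved_event_times(self) -> dict[str, float]:
        if self.event_times is not None:
            return dict(self.event_times)
        return default_event_times(self.duration_s)


def _carrier_template(n_fine: int = 10000) -> tuple[np.ndarray, float]:
    """One period of the normalized pulse shape and the cycle fraction of its
    foot (point of maximum upslope)."""
    u = np.arange(n_fine) / n_fine
    c = sum(a * np.sin(2 * np.pi * (k + 1) * u) for k, a in enumerate(CARRIER_HARMONICS))
    dc = np.gradient(c, u)
    foot = u[int(np.argmax(dc))]
    return c, foot


def _beat_phase(config: SynthConfig, t: np.ndarray, rng: np.random.Generator):
    """Cardiac phase in cycles at each sample, plus the beat onset times.

    With zero jitter the phase is exactly f0*t; with jitter the period of
    each beat is perturbed multiplicatively and the phase is piecewise
    linear, keeping the waveform continuous.
    """
    f0 = config.hr_bpm / 60.0
    _, foot = _carrier_template()
    if config.hr_jitter_frac == 0.0:
        phase = f0 * t
        n_beats = int(np.floor(f0 * config.duration_s - foot)) + 1
        onsets = (foot + np.arange(n_beats)) / f0
        onsets = onsets[onsets < config.duration_s]
        return phase, onsets
    periods = (1.0 / f0) * (
        1.0
        + config.hr_jitter_frac
        * rng.uniform(-1, 1, size=int(np.ceil(f0 * config.duration_s)) + 4)
    )
    knots = np.concatenate([[0.0], np.cumsum(periods)])
    phase = np.interp(t, knots, np.arange(len(knots), dtype=float))
    onset_phase = foot + np.arange(len(knots))
    onsets = np.interp(onset_phase, np.arange(len(knots), dtype=float), knots)
    onsets = onsets[(onsets >= 0) & (onsets < config.duration_s)]
    return phase, onsets


def _excursion_trace(t: np.ndarray, excursions: list[Excursion]) -> np.ndarray:
    out = np.zeros_like(t)
    for ex in excursions:
        r = max(ex.ramp_s, 1e-9)
        up = np.clip((t - ex.start_s) / r, 0.0, 1.0)
        down = np.clip((ex.end_s - t) / r, 0.0, 1.0)
        out += ex.delta * np.minimum(up, down) * ((t >= ex.start_s) & (t <= ex.end_s))
    return out


def _apply_band_transfer(
    fluct: np.ndarray, fs: float, bands: dict[str, BandTransfer]
) -> np.ndarray:
    """Pass a zero-mean signal through the band-wise transfer function by
    rFFT multiplication: in-band bins get gain*exp(-i*phase) (so positive
    configured phase delays the output), out-of-band bins pass unchanged.
    """
    n = len(fluct)
    spec = np.fft.rfft(fluct)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    h = np.ones(len(freqs), dtype=complex)
    for band, bt in bands.items():
        lo, hi = BANDS[band]
        m = (freqs >= lo) & (freqs < hi)
        h[m] = bt.gain_true * np.exp(-1j * np.deg2rad(bt.phase_true_deg))
    return np.fft.irfft(spec * h, n)


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _inject_artifacts(
    signal: np.ndarray,
    fs: float,
    spec: ArtifactSpec,
    rng: np.random.Generator,
    keepout_s: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add square pulses at random positions; returns (signal, truth mask)."""
    n = len(signal)
    mask = np.zeros(n, dtype=bool)
    if spec.count == 0:
        return signal, mask
    width = max(int(round(spec.duration_s * fs)), 1)
    amp = spec.amplitude_sd * max(_robust_sd(signal), 1e-12)
    lo = int(keepout_s * fs)
    hi = n - width - lo
    if hi <= lo:
        raise ValueError("recording too short for requested artifacts")
    out = signal.copy()
    for _ in range(spec.count):
        start = int(rng.integers(lo, hi))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[start : start + width] += sign * amp
        mask[start : start + width] = True
    return out, mask


def synthesize_recording(config: SynthConfig) -> RawRecording:
    """Generate one fully synthetic recording; identical (config, seed) pairs
    give bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_raw))
    t = np.arange(n) / config.fs_raw

    # --- ABP waveform ----------------------------------------------------
    template, _foot = _carrier_template()
    phase, beat_times = _beat_phase(config, t, rng)
    carrier = sum(
        a * np.sin(2 * np.pi * (k + 1) * phase) for k, a in enumerate(CARRIER_HARMONICS)
    )
    span = template.max() - template.min()
    carrier = carrier * (config.pulse_amp_mmhg / span)
    lfo = config.lfo_amp_mmhg * np.sin(2 * np.pi * config.lfo_freq_hz * t)
    resp = config.resp_amp_mmhg * np.sin(2 * np.pi * config.resp_freq_hz * t)
    abp_noise = (
        rng.normal(0.0, config.noise_sd_abp, n) if config.noise_sd_abp > 0 else 0.0
    )
    vitals_spec = (
        copy.deepcopy(config.vitals_spec)
        if config.vitals_spec is not None
        else default_vitals_spec()
    )
    map_spec = vitals_spec.get("mean_abp", VitalSpec(config.map_mmhg))
    map_slow = _excursion_trace(t, map_spec.excursions)
    fluct = carrier + lfo + resp + abp_noise + map_slow
    abp_clean = config.map_mmhg + fluct

    # --- NIRS channels ----------------------------------------------------
    # shared scalp signal: its own slow oscillation near (but off) the Mayer
    # frequency plus broadband noise, independent of ABP
    scalp_freq = 0.9 * config.lfo_freq_hz
    scalp = np.sin(2 * np.pi * scalp_freq * t + rng.uniform(0, 2 * np.pi))
    scalp = scalp + 0.3 * rng.normal(size=n)
    scalp = scalp / max(np.std(scalp), 1e-12)

    cerebral: dict[str, np.ndarray] = {}
    for hemi, bands in config.band_transfer.items():
        cerebral[hemi] = _apply_band_transfer(fluct, config.fs_raw, bands)

    channels: list[NirsChannel] = []
    artifact_masks: dict[str, np.ndarray] = {}
    hemi_code = {"ischaemic": "IH", "contralateral": "CH"}
    territories = ("MCA-ACA borderzone", "MCA-ACA borderzone", "ACA")
    for hemi in config.band_transfer:
        roles = [("long", 35.0)] * config.n_long_per_hemisphere + [
            ("short", 10.0)
        ] * config.n_short_per_hemisphere
        role_idx = {"long": 0, "short": 0}
        for role, sep in roles:
            role_idx[role] += 1
            name = f"{hemi_code[hemi]}_{role}{role_idx[role]}"
            frac = config.extracerebral_fraction.get(role, 0.0)
            cereb = cerebral[hemi]
            sd_c = np.std(cereb)
            if frac >= 1.0:
                sig = scalp * sd_c  # pure scalp, scaled to cerebral amplitude
            elif frac > 0.0:
                # additive scalp keeps the cerebral transfer (hence the true
                # gain/phase) intact; its variance share of the sum is frac
                sig = cereb + scalp * sd_c * np.sqrt(frac / (1.0 - frac))
            else:
                sig = cereb.copy()
            drift_phase = rng.uniform(0, 2 * np.pi)
            sig = sig + config.nirs_drift_amp * np.sin(
                2 * np.pi * 0.004 * t + drift_phase
            )
            if config.noise_sd_nirs > 0:
                sig = sig + rng.normal(0.0, config.noise_sd_nirs, n)
            if "nirs" in config.artifact_spec.targets:
                sig, mask = _inject_artifacts(sig, config.fs_raw, config.artifact_spec, rng)
            else:
                mask = np.zeros(n, dtype=bool)
            artifact_masks[name] = mask
            meta = ChannelMeta(
                hemisphere=hemi,
                separation_mm=sep,
                role=role,
                territory_label=territories[role_idx[role] - 1] if role == "long" else "scalp",
            )
            channels.append(NirsChannel(name=name, meta=meta, oxyhb=sig))

    if "abp" in config.artifact_spec.targets:
        abp, abp_mask = _inject_artifacts(abp_clean, config.fs_raw, config.artifact_spec, rng)
    else:
        abp, abp_mask = abp_clean, np.zeros(n, dtype=bool)
    artifact_masks["abp"] = abp_mask

    # --- vitals -----------------------------------------------------------
    tv = np.arange(int(round(config.duration_s * config.vitals_fs))) / config.vitals_fs
    vit_cols = {"time_s": tv}
    for vital, vs in vitals_spec.items():
        trace = vs.baseline + _excursion_trace(tv, vs.excursions)
        if vs.noise_sd > 0:
            trace = trace + rng.normal(0.0, vs.noise_sd, len(tv))
        vit_cols[vital] = trace
    vitals = pd.DataFrame(vit_cols)

    events = [Event(k, v) for k, v in sorted(config.resolved_event_times().items(), key=lambda kv: kv[1])]
    events += [Event("drug_change", tt) for tt in config.drug_change_times]

    truth = GroundTruth(
        beat_times=beat_times,
        artifact_masks=artifact_masks,
        scalp=scalp,
        config=replace(config),
    )
    return RawRecording(
        subject_id=f"synth-{config.seed}",
        fs_raw=config.fs_raw,
        abp=abp,
        channels=channels,
        vitals=vitals,
        vitals_fs=config.vitals_fs,
        events=events,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# subject-level tables
# ---------------------------------------------------------------------------

SEGMENTS = ("PRE", "POST", "2H")


def default_segment_effects() -> dict[str, dict[str, float]]:
    """Opposite phase-shift trajectories by 90-day functional outcome:
    good-outcome patients gain phase after recanalization, poor-outcome
    patients lose it."""
    return {
        "good": {"PRE": 0.0, "POST": 12.7, "2H": 20.3},
        "poor": {"PRE": 0.0, "POST": -10.9, "2H": -19.4},
    }


@dataclass
class SubjectSimSpec:
    """Generative model for per-subject × hemisphere × segment LF phase rows.

    phase = baseline + group offset + subject intercept + hemisphere effect
            + per-hemisphere ETCO2 slope × (ETCO2 − cohort mean)
            + group-specific segment effect + residual noise
    """

    n_subjects: int = 38
    segments: tuple[str, ...] = ("POST",)
    band: str = "LF"
    baseline_phase_deg: float = 35.0
    hemisphere_effect_deg: float = 0.0
    between_subject_sd_deg: float = 15.0
    phase_sd_deg: float = 18.0  # residual SD within subject
    etco2_mean_kpa: float = 4.5
    etco2_sd_kpa: float = 0.4
    #: degrees of LF phase per kPa ETCO2, per hemisphere
    etco2_slope_deg_per_kpa: dict[str, float] = field(
        default_factory=lambda: {"ischaemic": 0.0, "contralateral": 0.0}
    )
    group_sizes: dict[str, int] | None = None
    group_offsets_deg: dict[str, float] = field(default_factory=dict)
    segment_effects_by_group: dict[str, dict[str, float]] | None = None
    ss_phase_sd_deg: float = 15.0  # short-separation regressor spread
    ss_effect: float = 0.0  # true contribution of SS phase to outcome
    age_mean: float = 70.0
    age_sd: float = 12.0
    mean_abp_mean: float = 100.0
    mean_abp_sd: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.phase_sd_deg <= 0:
            raise ValueError("phase_sd_deg must be > 0")
        if self.group_sizes is not None:
            if any(v <= 0 for v in self.group_sizes.values()):
                raise ValueError("empty group in group_sizes")
            if sum(self.group_sizes.values()) != self.n_subjects:
                raise ValueError("group sizes must sum to n_subjects")
        for s in self.segments:
            if s not in SEGMENTS:
                raise ValueError(f"unknown segment {s!r}")


def synthesize_subject_table(spec: SubjectSimSpec) -> pd.DataFrame:
    """One row per subject × hemisphere × segment with the configured fixed
    and random effects imposed; reproducible under the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.group_sizes is None:
        groups = ["all"] * spec.n_subjects
    else:
        groups = [g for g, k in spec.group_sizes.items() for _ in range(k)]
    seg_eff = spec.segment_effects_by_group
    rows = []
    for i in range(spec.n_subjects):
        g = groups[i]
        b_i = rng.normal(0.0, spec.between_subject_sd_deg)
        etco2 = rng.normal(spec.etco2_mean_kpa, spec.etco2_sd_kpa)
        age = rng.normal(spec.age_mean, spec.age_sd)
        mean_abp = rng.normal(spec.mean_abp_mean, spec.mean_abp_sd)
        nihss = int(rng.integers(2, 25))
        if spec.group_sizes is not None and g == "good":
            mrs = int(rng.integers(0, 3))
        elif spec.group_sizes is not None and g == "poor":
            mrs = int(rng.integers(3, 7))
        else:
            mrs = int(rng.integers(0, 7))
        for seg in spec.segments:
            for hemi in ("ischaemic", "contralateral"):
                ss_phase = rng.normal(0.0, spec.ss_phase_sd_deg)
                mu = (
                    spec.baseline_phase_deg
                    + spec.group_offsets_deg.get(g, 0.0)
                    + b_i
                    + (spec.hemisphere_effect_deg if hemi == "ischaemic" else 0.0)
                    + spec.etco2_slope_deg_per_kpa.get(hemi, 0.0)
                    * (etco2 - spec.etco2_mean_kpa)
                    + (seg_eff[g][seg] if seg_eff is not None else 0.0)
                    + spec.ss_effect * ss_phase
                )
                phase = mu + rng.normal(0.0, spec.phase_sd_deg)
                rows.append(
                    {
                        "subject_id": f"S{i:03d}",
                        "hemisphere": hemi,
                        "segment": seg,
                        "band": spec.band,
                        "phase_deg": phase,
                        "gain": float(np.abs(rng.normal(8.0, 3.0))),
                        "coherence": float(rng.uniform(0.3, 0.9)),
                        "ss_phase_deg": ss_phase,
                        "age": age,
                        "etco2": etco2,
                        "mean_abp": mean_abp,
                        "nihss": nihss,
                        "mrs": mrs,
                        "independence": mrs < 3,
                        "mortality": mrs == 6,
                        "outcome_group": g,
                    }
                )
    df = pd.DataFrame(rows)
    # chronological segment order so model contrasts are relative to PRE
    df["segment"] = pd.Categorical(df["segment"], categories=list(SEGMENTS))
    return df
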