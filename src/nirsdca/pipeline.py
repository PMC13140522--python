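"""End-to-end analysis of one recording: (optional MBLL) → artifact
correction → beat averaging → steady-segment selection → per-channel TFA →
hemisphere-wise 180° phase-consistency correction → tidy results table."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mbll as _mbll
from .preprocess import (
    ArtifactParams,
    beat_average_resample,
    detect_beats,
    flag_artifacts,
    interpolate_artifacts,
)
from .segments import LABELS, SegmentCriteria, SteadySegment, select_segments
from .tfa import TFAParams, band_average, compute_tfa, correct_phase_wrap
from .types import RawRecording, UniformSeries


@dataclass
class PipelineConfig:
    tfa: TFAParams = None  # type: ignore[assignment]
    criteria: SegmentCriteria = None  # type: ignore[assignment]
    artifacts: ArtifactParams = None  # type: ignore[assignment]
    #: route OxyHb through a forward Beer–Lambert model and back, exercising
    #: the optical-density entry point (synthetic OxyHb is generated directly)
    via_od: bool = False
    #: HbR assumed proportional to HbO when fabricating two-wavelength OD
    od_hbr_ratio: float = -0.3
    output_scale: float | None = None  # µM·mm reference for normalized gain
    apply_wrap_correction: bool = True
    labels: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        self.tfa = self.tfa or TFAParams()
        self.criteria = self.criteria or SegmentCriteria()
        self.artifacts = self.artifacts or ArtifactParams()


def _channel_series(recording: RawRecording, cfg: PipelineConfig) -> dict[str, np.ndarray]:
    """OxyHb per channel, optionally via the optical-density round trip."""
    out = {}
    t = np.arange(len(recording.abp)) / recording.fs_raw
    for ch in recording.channels:
        if cfg.via_od:
            od = _mbll.mbll_forward(
                t, ch.oxyhb, cfg.od_hbr_ratio * ch.oxyhb, ch.meta
            )
            out[ch.name] = _mbll.mbll_convert(od).oxyhb
        else:
            out[ch.name] = ch.oxyhb
    return out


def preprocess_recording(
    recording: RawRecording, cfg: PipelineConfig | None = None
) -> tuple[UniformSeries, dict[str, UniformSeries], dict[str, np.ndarray]]:
    """Artifact-correct and beat-average every signal onto one 10 Hz grid.

    Returns (abp 10 Hz, {channel: 10 Hz OxyHb}, {signal: artifact mask}).
    All series share the ABP-derived beat grid, so start times and lengths
    coincide.
    """
    cfg = cfg or PipelineConfig()
    fs = recording.fs_raw
    masks: dict[str, np.ndarray] = {}
    abp_flags = flag_artifacts(recording.abp, fs, cfg.artifacts)
    masks["abp"] = abp_flags.mask
    abp_clean = interpolate_artifacts(recording.abp, abp_flags.mask)
    onsets = detect_beats(abp_clean, fs)
    abp10 = beat_average_resample(abp_clean, fs, onsets)
    chans10: dict[str, UniformSeries] = {}
    for name, sig in _channel_series(recording, cfg).items():
        flags = flag_artifacts(sig, fs, cfg.artifacts)
        masks[name] = flags.mask
        clean = interpolate_artifacts(sig, flags.mask)
        chans10[name] = beat_average_resample(clean, fs, onsets)
    return abp10, chans10, masks


def analyze_recording(
    recording: RawRecording,
    cfg: PipelineConfig | None = None,
    segments: list[SteadySegment] | None = None,
) -> pd.DataFrame:
    """Full per-recording analysis.

    One result row per segment × channel × band, with phases corrected for
    single-channel 180° flips against the other long channels of the same
    hemisphere and band.
    """
    cfg = cfg or PipelineConfig()
    abp10, chans10, masks = preprocess_recording(recording, cfg)
    if segments is None:
        segments = select_segments(
            recording, cfg.criteria, artifact_masks=masks, labels=cfg.labels
        )
    meta = {ch.name: ch.meta for ch in recording.channels}
    rows = []
    for seg in segments:
        start = max(seg.start_s, abp10.start_time)
        end = min(seg.end_s, abp10.end_time)
        x = abp10.slice(start, end)
        for name, series in chans10.items():
            y = series.slice(start, end)
            spectra = compute_tfa(x, y, cfg.tfa)
            for band, res in band_average(
                spectra, cfg.tfa, output_scale=cfg.output_scale
            ).items():
                rows.append(
                    {
                        "subject_id": recording.subject_id,
                        "segment": seg.label,
                        "hemisphere": meta[name].hemisphere,
                        "channel": name,
                        "role": meta[name].role,
                        "band": band,
                        "psd_input": res.psd_input,
                        "psd_output": res.psd_output,
                        "coherence": res.coherence,
                        "gain": res.gain,
                        "normalized_gain": res.normalized_gain,
                        "phase_deg": res.phase_deg,
                        "mean_input": res.mean_input,
                        "mean_output": res.mean_output,
                        "flags": "",
                    }
                )
    df = pd.DataFrame(rows)
    if cfg.apply_wrap_correction and len(df):
        df = apply_wrap_correction(df)
    return df


def apply_wrap_correction(df: pd.DataFrame) -> pd.DataFrame:
    """180° phase-consistency correction across the long channels of each
    segment × hemisphere × band group (short channels are left alone)."""
    df = df.copy()
    for (_, _, _), idx in df[df["role"] == "long"].groupby(
        ["segment", "hemisphere", "band"]
    ).groups.items():
        idx = list(idx)
        if len(idx) < 2:
            continue
        phases = df.loc[idx, "phase_deg"].to_numpy()
        corrected, info = correct_phase_wrap(phases)
        df.loc[idx, "phase_deg"] = corrected
        if info["corrected_channel"] is not None:
            j = idx[info["corrected_channel"]]
            df.loc[j, "flags"] = (
                (df.loc[j, "flags"] + ";" if df.loc[j, "flags"] else "")
                + "wrap-corrected"
            )
    return df
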