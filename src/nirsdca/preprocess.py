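"""Artifact handling, beat detection and beat-to-beat resampling.

The chain mirrors standard practice for spontaneous-oscillation
autoregulation studies: transient artifacts are replaced by linear
interpolation, the ABP waveform is segmented into beats at the systolic
upstroke, every signal is reduced to per-beat means on the single
ABP-derived beat grid, and the beat means are interpolated onto a uniform
10 Hz grid for spectral analysis.  Using one beat clock for ABP and OxyHb
keeps their relative timing exact, which is what the transfer-function
phase estimate depends on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, find_peaks

from .types import BeatSeries, UniformSeries

DEFAULT_RESAMPLE_FS = 10.0


class NoBeatsError(ValueError):
    """Raised when no cardiac beats can be found in a waveform."""


@dataclass
class ArtifactParams:
    z_threshold: float = 5.0
    max_gap_s: float = 5.0
    # rolling-median window used to remove slow baseline before scoring
    median_window_s: float = 10.0
    # cutoff of the low-pass applied to the residual before amplitude
    # scoring; set below the cardiac band so pulse peaks never trip it
    lowpass_hz: float = 0.6


@dataclass
class ArtifactFlags:
    mask: np.ndarray
    #: (start_idx, end_idx) of flagged runs longer than max_gap_s, which a
    #: caller should treat as unsalvageable rather than interpolate over
    long_runs: list[tuple[int, int]] = field(default_factory=list)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, end) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def flag_artifacts(
    series: np.ndarray, fs: float, params: ArtifactParams | None = None
) -> ArtifactFlags:
    """Flag samples whose amplitude or first difference is an outlier.

    Both criteria use robust z-scores (median/MAD) after removing the slow
    baseline with a rolling median, so the pulsatile and oscillatory content
    sets the scale and only genuinely aberrant excursions are flagged.
    """
    params = params or ArtifactParams()
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("series too short")
    w = max(int(round(params.median_window_s * fs)) | 1, 3)  # odd
    baseline = median_filter(x, size=w, mode="nearest")
    resid = x - baseline
    mask = np.zeros(len(x), dtype=bool)

    # amplitude criterion on the sub-cardiac residual: catches plateaus of
    # square artifacts without tripping on systolic peaks
    # degenerate near-constant series: skip the smoothed criterion (IIR
    # ringing around an isolated spike would smear the flag); the
    # derivative criterion below localizes such spikes exactly
    if _robust_sd(resid) > 1e-9 * max(np.ptp(x), 1.0):
        if params.lowpass_hz < fs / 2:
            b, a = butter(4, params.lowpass_hz / (fs / 2), btype="low")
            lp = filtfilt(b, a, resid)
        else:
            lp = resid
        s_lp = max(_robust_sd(lp), 1e-12)
        mask |= np.abs(lp - np.median(lp)) > params.z_threshold * s_lp

    # derivative criterion: a diff outlier at k marks a discontinuity
    # between k-1 and k; the artifactual side is the one farther from the
    # local baseline.  The threshold is floored at twice the 99.9th
    # percentile of observed slopes so that waveforms spending only a small
    # duty cycle on steep (systolic) upstrokes are not flagged.
    d = np.diff(x)
    ad = np.abs(d - np.median(d))
    thr_d = max(
        params.z_threshold * _robust_sd(d), 2.0 * float(np.quantile(ad, 0.999)), 1e-12
    )
    jumps = np.where(ad > thr_d)[0]
    for k in jumps + 1:  # transition between k-1 and k
        side = k if np.abs(resid[k]) >= np.abs(resid[k - 1]) else k - 1
        mask[side] = True
    if mask.all():
        raise ValueError("entire series flagged as artifact")
    max_gap = int(round(params.max_gap_s * fs))
    long_runs = [(a, b) for a, b in _runs(mask) if (b - a) > max_gap]
    return ArtifactFlags(mask=mask, long_runs=long_runs)


def interpolate_artifacts(series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace flagged samples by linear interpolation between the nearest
    unflagged neighbours; flagged edges take the nearest unflagged value.
    Unflagged samples are returned bit-identical."""
    x = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValueError("mask shape mismatch")
    if mask.all():
        raise ValueError("cannot interpolate: all samples flagged")
    if not mask.any():
        return x.copy()
    out = x.copy()
    idx = np.arange(len(x))
    out[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return out


def detect_beats(abp: np.ndarray, fs: float, refractory_s: float = 0.3) -> np.ndarray:
    """Beat onsets (s) at systolic upstrokes by maximum-slope foot detection.

    The upstroke is the dominant positive excursion of the first derivative;
    peaks of dABP/dt above half its 98th percentile, separated by the
    refractory period, are taken as beat feet.
    """
    x = np.asarray(abp, dtype=float)
    if fs < 50:
        raise ValueError("detect_beats requires fs >= 50 Hz")
    if len(x) < 10 * fs:
        raise ValueError("detect_beats requires >= 10 s of waveform")
    # light zero-phase smoothing so measurement noise does not create
    # spurious derivative peaks; 15 Hz preserves systolic upstroke timing
    b, a = butter(4, min(15.0, 0.4 * fs) / (fs / 2), btype="low")
    x = filtfilt(b, a, x)
    d = np.gradient(x) * fs
    height = 0.5 * float(np.quantile(d, 0.98))
    if height <= 0 or np.ptp(x) < 1e-9:
        raise NoBeatsError("no beats detected (flat input)")
    peaks, _ = find_peaks(d, height=height, distance=max(int(round(refractory_s * fs)), 1))
    if len(peaks) < 2:
        raise NoBeatsError("no beats detected")
    # parabolic refinement of each derivative peak for sub-sample timing
    onsets = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(d) - 1)
    p = peaks[inner]
    denom = d[p - 1] - 2 * d[p] + d[p + 1]
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (d[p - 1] - d[p + 1]) / denom, 0.0)
    onsets[inner] = p + np.clip(shift, -0.5, 0.5)
    return onsets / fs


def beat_means(signal: np.ndarray, fs: float, onsets: np.ndarray) -> BeatSeries:
    """Per-beat means of ``signal`` over each inter-onset interval."""
    x = np.asarray(signal, dtype=float)
    idx = np.round(np.asarray(onsets) * fs).astype(int)
    idx = np.clip(idx, 0, len(x))
    means = np.array(
        [x[a:b].mean() for a, b in zip(idx[:-1], idx[1:])]
    )
    return BeatSeries(beat_onsets=np.asarray(onsets, dtype=float), beat_means=means)


def beat_average_resample(
    signal: np.ndarray,
    fs: float,
    beats: np.ndarray | BeatSeries,
    target_fs: float = DEFAULT_RESAMPLE_FS,
) -> UniformSeries:
    """Beat-to-beat average then uniform resampling.

    Per-beat means are placed at the midpoint of their beat interval and
    linearly interpolated onto a uniform ``target_fs`` grid spanning the
    first to the last midpoint.
    """
    if isinstance(beats, BeatSeries):
        onsets = beats.beat_onsets
    else:
        onsets = np.asarray(beats, dtype=float)
    if len(onsets) < 2:
        raise ValueError("need at least 2 beat onsets")
    bs = beat_means(signal, fs, onsets)
    mids = bs.midpoints
    span = mids[-1] - mids[0]
    n_out = int(np.floor(span * target_fs + 1e-9)) + 1
    grid = mids[0] + np.arange(n_out) / target_fs
    values = np.interp(grid, mids, bs.beat_means)
    return UniformSeries(start_time=mids[0], fs=target_fs, values=values)


def preprocess_signal(
    signal: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    artifact_params: ArtifactParams | None = None,
    target_fs: float = DEFAULT_RESAMPLE_FS,
) -> tuple[UniformSeries, ArtifactFlags]:
    """Full chain for one signal: flag → interpolate → beat-average → 10 Hz."""
    flags = flag_artifacts(signal, fs, artifact_params)
    clean = interpolate_artifacts(signal, flags.mask)
    return beat_average_resample(clean, fs, onsets, target_fs), flags
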