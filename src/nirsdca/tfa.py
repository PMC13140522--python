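"""Welch transfer function analysis of ABP → OxyHb.

Auto- and cross-spectra are estimated with overlapping Hann-tapered,
mean-detrended windows (defaults: 100 s windows, 50% overlap, per common
guideline practice for spontaneous-oscillation autoregulation analysis).
The transfer function is H(f) = S_xy / S_xx, reported as

* gain |H| in µM·mm/mmHg,
* normalized gain (percent output change per percent input change),
* phase in degrees with the clinical sign convention: positive when the
  OxyHb oscillation follows ABP, negative when it precedes ABP,
* magnitude-squared coherence |S_xy|² / (S_xx·S_yy).

Band averages over VLF/LF/HF use input-power weighting for gain and
coherence (noise- or leakage-dominated bins carry no weight) and a
|S_xy|-weighted circular mean for phase.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .synth import BANDS

DEFAULT_BANDS = dict(BANDS)


@dataclass
class TFAParams:
    window_s: float = 100.0
    overlap_fraction: float = 0.5
    taper: str = "hann"
    detrend: str = "constant"  # mean removal per window
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )


@dataclass
class Spectra:
    """Per-frequency Welch estimates for one input/output pair."""

    f: np.ndarray
    sxx: np.ndarray  # input PSD, mmHg²/Hz
    syy: np.ndarray  # output PSD, (µM·mm)²/Hz
    sxy: np.ndarray  # cross spectrum, complex
    n_windows: int
    mean_input: float
    mean_output: float

    @property
    def gain(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.abs(self.sxy) / self.sxx

    @property
    def phase_deg(self) -> np.ndarray:
        """Positive = output follows (lags) the input."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return -np.degrees(np.angle(self.sxy / self.sxx))

    @property
    def coherence(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.abs(self.sxy) ** 2 / (self.sxx * self.syy)


@dataclass
class BandResult:
    band: str
    f_lo: float
    f_hi: float
    psd_input: float
    psd_output: float
    coherence: float
    gain: float
    normalized_gain: float | None
    phase_deg: float
    mean_input: float
    mean_output: float
    n_bins: int
    flags: list[str] = field(default_factory=list)


def compute_tfa(x, y, params: TFAParams | None = None, fs: float | None = None) -> Spectra:
    """Welch auto-/cross-spectra between input ``x`` (ABP) and output ``y``
    (OxyHb).  Accepts :class:`~nirsdca.types.UniformSeries` or plain arrays
    (then ``fs`` is required)."""
    params = params or TFAParams()
    if hasattr(x, "values"):
        if not np.isclose(x.fs, y.fs):
            raise ValueError("input and output sampling rates differ")
        fs = x.fs
        x, y = x.values, y.values
    if fs is None:
        raise ValueError("fs required for plain arrays")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("input and output lengths differ")
    nperseg = int(round(params.window_s * fs))
    # a single exact window is permitted (periodogram mode, used by the
    # direct-DFT cross-check); otherwise at least two windows must fit
    if len(x) != nperseg and len(x) < 2 * nperseg:
        raise ValueError(
            f"series too short: need >= {2 * nperseg} samples for two windows"
        )
    noverlap = int(round(params.overlap_fraction * nperseg))
    kw = dict(
        fs=fs,
        window=params.taper,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=params.detrend,
    )
    f, sxx = _sig.welch(x, **kw)
    _, syy = _sig.welch(y, **kw)
    _, sxy = _sig.csd(x, y, **kw)
    step = nperseg - noverlap
    n_windows = 1 + (len(x) - nperseg) // step
    return Spectra(
        f=f,
        sxx=sxx,
        syy=syy,
        sxy=sxy,
        n_windows=n_windows,
        mean_input=float(np.mean(x)),
        mean_output=float(np.mean(y)),
    )


def normalized_gain(gain: float, mean_input: float, output_scale: float) -> float:
    """Gain as percent output change per percent input change.

    ``output_scale`` is the reference OxyHb amplitude (µM·mm) against which
    output fluctuations are expressed in percent; it must be supplied by the
    caller because OxyHb is a change signal whose mean is near zero.
    """
    if output_scale <= 0:
        raise ValueError("output_scale must be positive")
    return gain * mean_input / output_scale


def _circular_mean_deg(phases_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    ph = np.deg2rad(np.asarray(phases_deg, dtype=float))
    w = np.ones_like(ph) if weights is None else np.asarray(weights, dtype=float)
    z = np.sum(w * np.exp(1j * ph))
    return float(np.degrees(np.angle(z)))


def wrap_deg(phase: float) -> float:
    """Map to the principal interval (−180°, 180°]."""
    p = (phase + 180.0) % 360.0 - 180.0
    return 180.0 if p == -180.0 else p


def band_average(
    spectra: Spectra,
    params: TFAParams | None = None,
    output_scale: float | None = None,
) -> dict[str, BandResult]:
    """Band averages of the per-frequency estimates.

    Gain and coherence are averaged with input-PSD weights and phase with a
    |S_xy|-weighted circular mean, so bins without input power (possible for
    narrowband or noiseless records) do not corrupt the band value; for
    frequency-flat spectra the result equals the unweighted mean.
    """
    params = params or TFAParams()
    nyq = spectra.f[-1]
    out: dict[str, BandResult] = {}
    for band, (lo, hi) in params.bands.items():
        if lo >= nyq:
            raise ValueError(f"band {band} [{lo},{hi}) outside spectrum (nyquist {nyq})")
        m = (spectra.f >= lo) & (spectra.f < hi)
        if m.sum() < 2:
            raise ValueError(f"band {band} covered by fewer than 2 frequency bins")
        sxx = spectra.sxx[m]
        syy = spectra.syy[m]
        sxy = spectra.sxy[m]
        w = sxx.copy()
        tiny = w <= 1e-14 * max(float(w.max()), 1e-300)
        w[tiny] = 0.0
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()
        gain_bins = np.where(tiny, 0.0, np.abs(sxy) / np.where(tiny, 1.0, sxx))
        coh_bins = np.where(
            tiny, 0.0, np.abs(sxy) ** 2 / np.where(tiny, 1.0, sxx * syy)
        )
        gain = float(np.sum(w * gain_bins))
        coh = float(np.sum(w * coh_bins))
        phase_bins = -np.degrees(np.angle(sxy))
        phase = wrap_deg(_circular_mean_deg(phase_bins, weights=np.abs(sxy)))
        ngain = (
            normalized_gain(gain, spectra.mean_input, output_scale)
            if output_scale is not None
            else None
        )
        out[band] = BandResult(
            band=band,
            f_lo=lo,
            f_hi=hi,
            psd_input=float(np.mean(sxx)),
            psd_output=float(np.mean(syy)),
            coherence=coh,
            gain=gain,
            normalized_gain=ngain,
            phase_deg=phase,
            mean_input=spectra.mean_input,
            mean_output=spectra.mean_output,
            n_bins=int(m.sum()),
        )
    return out


def correct_phase_wrap(
    channel_phases: np.ndarray | list[float],
    tol_deg: float = 30.0,
    min_consistent: int = 2,
) -> tuple[np.ndarray, dict]:
    """Correct a single 180°-flipped channel against a consistent majority.

    If exactly one channel sits 180° ± ``tol_deg`` (circularly) away from
    the circular mean of the remaining channels, and those remaining
    channels (at least ``min_consistent`` of them) all lie within
    ``tol_deg`` of their own circular mean, the deviant is shifted by 180°
    onto the principal interval and flagged.  Any other pattern is returned
    unchanged with a ``no-correction`` flag: the rule never rewrites more
    than one channel.
    """
    phases = np.asarray(channel_phases, dtype=float)
    if phases.ndim != 1 or len(phases) < 2:
        raise ValueError("need at least 2 channel phases")

    def circ_dist(a: float, b: float) -> float:
        return abs(wrap_deg(a - b))

    candidates = []
    for j in range(len(phases)):
        others = np.delete(phases, j)
        if len(others) < min_consistent:
            continue
        om = _circular_mean_deg(others)
        if any(circ_dist(p, om) > tol_deg for p in others):
            continue
        if abs(circ_dist(phases[j], om) - 180.0) <= tol_deg:
            candidates.append((j, om))
    if len(candidates) == 1:
        j, om = candidates[0]
        corrected = phases.copy()
        corrected[j] = wrap_deg(phases[j] + 180.0)
        return corrected, {"corrected_channel": j, "flags": ["wrap-corrected"]}
    return phases.copy(), {"corrected_channel": None, "flags": ["no-correction"]}
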