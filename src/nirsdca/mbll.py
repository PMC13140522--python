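"""Modified Beer–Lambert law conversion of optical density to haemoglobin.

The continuous-wave NIRS forward model at each sample is

    ΔOD(λ) = Σ_c ε(λ, c) · ΔC(c) · DPF(λ)

with ΔC pathlength-scaled concentration change (µM·mm) of the two
chromophores HbO2 and HbR, ε the specific extinction coefficient expressed
in OD per (µM·mm) and DPF the unitless differential pathlength factor.
Conversion inverts the 2×2 system per sample.  Outputs stay in µM·mm: no
division by the source-detector separation, so no partial-pathlength
assumption enters the pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ChannelMeta

#: Default wavelengths (nm) of a typical two-wavelength CW system.
DEFAULT_WAVELENGTHS = (760.0, 850.0)

#: Specific extinction coefficients in OD/(µM·mm), rows = wavelengths
#: (760, 850 nm), columns = (HbO2, HbR).  Derived from the Cope (1991)
#: compilation commonly shipped with fNIRS toolboxes (values there in
#: cm^-1/M; ×1e-7 converts to OD per µM per mm).
DEFAULT_EXTINCTION = np.array(
    [
        [1.4866e-4, 3.8437e-4],  # 760 nm
        [2.5264e-4, 1.7986e-4],  # 850 nm
    ]
)

#: Default differential pathlength factor per wavelength (adult forehead).
DEFAULT_DPF = (6.0, 6.0)


@dataclass
class OpticalDensitySeries:
    """Two-wavelength optical-density change for one channel."""

    time: np.ndarray  # s
    od: np.ndarray  # shape (n, 2), unitless ΔOD, columns ordered as wavelengths
    wavelengths: tuple[float, float]
    channel_meta: ChannelMeta

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.wavelengths) != 2 or self.wavelengths[0] == self.wavelengths[1]:
            raise ValueError("exactly two distinct wavelengths required")
        if self.od.ndim != 2 or self.od.shape[1] != 2:
            raise ValueError("od must have shape (n_samples, 2)")
        if len(self.time) != len(self.od):
            raise ValueError("time and od lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od contains non-finite samples")


@dataclass
class HaemoglobinSeries:
    """Oxy- and deoxyhaemoglobin concentration change in µM·mm."""

    time: np.ndarray
    oxyhb: np.ndarray
    deoxyhb: np.ndarray
    channel_meta: ChannelMeta


def _system_matrix(extinction: np.ndarray, dpf: np.ndarray) -> np.ndarray:
    a = np.asarray(extinction, dtype=float) * np.asarray(dpf, dtype=float)[:, None]
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("extinction matrix is singular or near-singular")
    return a


def mbll_convert(
    od: OpticalDensitySeries,
    extinction: np.ndarray = DEFAULT_EXTINCTION,
    dpf: tuple[float, float] | np.ndarray = DEFAULT_DPF,
) -> HaemoglobinSeries:
    """Invert the Beer–Lambert system per sample.

    Parameters
    ----------
    od : measured ΔOD per wavelength.
    extinction : (2, 2) matrix, rows = wavelengths matching ``od``, columns =
        (HbO2, HbR), in OD/(µM·mm).
    dpf : differential pathlength factor per wavelength; must be > 0.
    """
    dpf = np.asarray(dpf, dtype=float)
    if dpf.shape != (2,):
        raise ValueError("dpf must have one value per wavelength")
    if np.any(dpf <= 0):
        raise ValueError("DPF must be positive")
    a = _system_matrix(extinction, dpf)
    conc = np.linalg.solve(a, od.od.T)  # (2, n): rows HbO2, HbR
    return HaemoglobinSeries(
        time=od.time,
        oxyhb=conc[0],
        deoxyhb=conc[1],
        channel_meta=od.channel_meta,
    )


def mbll_forward(
    time: np.ndarray,
    oxyhb: np.ndarray,
    deoxyhb: np.ndarray,
    channel_meta: ChannelMeta,
    extinction: np.ndarray = DEFAULT_EXTINCTION,
    dpf: tuple[float, float] | np.ndarray = DEFAULT_DPF,
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS,
) -> OpticalDensitySeries:
    """Forward model: chromophore series → two-wavelength ΔOD.

    The exact inverse of :func:`mbll_convert`; used to emulate raw optical
    recordings from synthetic haemoglobin traces and in round-trip tests.
    """
    dpf = np.asarray(dpf, dtype=float)
    if np.any(dpf <= 0):
        raise ValueError("DPF must be positive")
    a = _system_matrix(extinction, dpf)
    conc = np.vstack([oxyhb, deoxyhb])
    od = (a @ conc).T
    return OpticalDensitySeries(
        time=np.asarray(time, dtype=float),
        od=od,
        wavelengths=wavelengths,
        channel_meta=channel_meta,
    )
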