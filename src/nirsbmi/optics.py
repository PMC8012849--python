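"""Modified Beer-Lambert law (MBLL) conversion between optical density and
chromophore concentration changes.

A continuous-wave dual-wavelength instrument measures, per channel, the
change in optical density ``dOD(t; lambda)`` at 760 and 850 nm.  The MBLL
relates it linearly to the concentration changes of oxygenated and
deoxygenated hemoglobin::

    dOD(t; lambda) = [eps_HbO(lambda) * dC_HbO(t) + eps_HbR(lambda) * dC_HbR(t)] * l * d

with ``eps`` the extinction coefficients, ``l`` the source-detector
separation (cm) and ``d`` the differential path-length factor.  Inverting
the 2x2 extinction matrix per sample yields dHbO and dHbR; total
hemoglobin is their sum.

Units: concentrations are micromolar (uM) throughout the package and the
extinction coefficients are therefore stored in 1/(uM*cm) (base-10, i.e.
matching a base-10 optical density).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ExtinctionTable",
    "OpticalGeometry",
    "RawRecording",
    "HemodynamicSeries",
    "forward_mbll",
    "invert_mbll",
    "DEFAULT_WAVELENGTHS",
]

#: Instrument wavelengths in nm.
DEFAULT_WAVELENGTHS: tuple[float, float] = (760.0, 850.0)

# Molar extinction coefficients of HbO2 / Hb at 760 and 850 nm, converted
# from a standard compiled absorption table (1/(M*cm) -> 1/(uM*cm)).
_DEFAULT_EPSILON = {
    760.0: {"hbo": 586.0e-6, "hbr": 1548.52e-6},
    850.0: {"hbo": 1058.0e-6, "hbr": 691.32e-6},
}


class IllConditionedGeometryError(ValueError):
    """The extinction matrix is singular or numerically unusable."""


@dataclass(frozen=True)
class ExtinctionTable:
    """2x2 extinction matrix; rows are wavelengths, columns (HbO, HbR)."""

    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    epsilon: Mapping[float, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_EPSILON
    )

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        if len(wl) != 2 or wl[0] == wl[1]:
            raise ValueError("exactly two distinct wavelengths are required")
        for w in wl:
            if w not in self.epsilon:
                raise ValueError(f"no extinction coefficients for {w} nm")
        m = self.matrix
        if not np.all(np.isfinite(m)) or np.linalg.cond(m) > 1e12:
            raise IllConditionedGeometryError(
                "extinction matrix is singular or ill-conditioned"
            )

    @property
    def matrix(self) -> np.ndarray:
        """Extinction matrix E (wavelength x chromophore), 1/(uM*cm)."""
        return np.array(
            [[self.epsilon[w]["hbo"], self.epsilon[w]["hbr"]] for w in self.wavelengths]
        )

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class OpticalGeometry:
    """Source-detector separation and differential path-length factor.

    The effective photon path is ``path_length_cm * dpf``; a single DPF is
    applied to both wavelengths unless ``dpf`` is given as a pair.
    """

    path_length_cm: float = 3.0
    dpf: "float | tuple[float, float]" = 6.0

    def __post_init__(self) -> None:
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be > 0")
        d = np.atleast_1d(np.asarray(self.dpf, dtype=float))
        if d.size not in (1, 2) or np.any(d <= 0):
            raise ValueError("dpf must be a positive scalar or pair")

    @property
    def effective_path(self) -> np.ndarray:
        """Per-wavelength effective path length ``l * d`` in cm (shape (2,))."""
        d = np.atleast_1d(np.asarray(self.dpf, dtype=float))
        if d.size == 1:
            d = np.repeat(d, 2)
        return self.path_length_cm * d


@dataclass
class RawRecording:
    """Per-channel, per-wavelength optical-density change time series.

    ``delta_od`` has shape ``(n_channels, 2, n_samples)``, second axis
    ordered as ``wavelengths``.
    """

    delta_od: np.ndarray
    sampling_rate: float = 8.0
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    channels: "tuple[str, ...] | None" = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta_od = np.asarray(self.delta_od, dtype=float)
        if self.delta_od.ndim != 3 or self.delta_od.shape[1] != 2:
            raise ValueError(
                "delta_od must have shape (n_channels, 2, n_samples), "
                f"got {self.delta_od.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.channels is None:
            self.channels = tuple(
                f"ch{i + 1:02d}" for i in range(self.delta_od.shape[0])
            )
        self.channels = tuple(self.channels)
        if len(self.channels) != self.delta_od.shape[0]:
            raise ValueError("channel names do not match delta_od shape")

    @property
    def n_channels(self) -> int:
        return self.delta_od.shape[0]

    @property
    def n_samples(self) -> int:
        return self.delta_od.shape[2]


@dataclass
class HemodynamicSeries:
    """dHbO / dHbR / dHbT concentration-change series in uM.

    ``hbo`` and ``hbr`` have shape ``(n_channels, n_samples)``; total
    hemoglobin is derived as their elementwise sum.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float = 8.0
    channels: "tuple[str, ...] | None" = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have identical shapes")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.channels is None:
            self.channels = tuple(f"ch{i + 1:02d}" for i in range(self.hbo.shape[0]))
        self.channels = tuple(self.channels)
        if len(self.channels) != self.hbo.shape[0]:
            raise ValueError("channel names do not match series shape")

    @property
    def hbt(self) -> np.ndarray:
        """Total hemoglobin change, dHbT = dHbO + dHbR."""
        return self.hbo + self.hbr

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def chromophore(self, name: str) -> np.ndarray:
        name = name.lower()
        if name == "hbo":
            return self.hbo
        if name == "hbr":
            return self.hbr
        if name == "hbt":
            return self.hbt
        raise ValueError(f"unknown chromophore {name!r}")

    def select_channels(self, indices) -> "HemodynamicSeries":
        idx = np.asarray(indices, dtype=int)
        return HemodynamicSeries(
            hbo=self.hbo[idx],
            hbr=self.hbr[idx],
            sampling_rate=self.sampling_rate,
            channels=tuple(self.channels[i] for i in idx),
            metadata=dict(self.metadata),
        )


def _check_wavelengths(
    data_wavelengths: tuple[float, float], table: ExtinctionTable
) -> None:
    if tuple(float(w) for w in data_wavelengths) != table.wavelengths:
        raise ValueError(
            f"wavelength mismatch: data {data_wavelengths} vs table {table.wavelengths}"
        )


def invert_mbll(
    recording: RawRecording,
    table: "ExtinctionTable | None" = None,
    geometry: "OpticalGeometry | None" = None,
) -> HemodynamicSeries:
    """Recover dHbO/dHbR (uM) from dual-wavelength optical densities.

    Per sample: ``[dHbO, dHbR] = E^-1 @ (dOD / (l*d))`` with E the
    extinction matrix in 1/(uM*cm).
    """
    table = table or ExtinctionTable()
    geometry = geometry or OpticalGeometry()
    _check_wavelengths(recording.wavelengths, table)
    path = geometry.effective_path  # (2,)
    od = recording.delta_od / path[None, :, None]
    conc = np.einsum("cw,nws->cns", table.inverse, od)  # (chromo, ch, samp)
    return HemodynamicSeries(
        hbo=conc[0],
        hbr=conc[1],
        sampling_rate=recording.sampling_rate,
        channels=recording.channels,
        metadata=dict(recording.metadata),
    )


def forward_mbll(
    series: HemodynamicSeries,
    table: "ExtinctionTable | None" = None,
    geometry: "OpticalGeometry | None" = None,
) -> RawRecording:
    """Project dHbO/dHbR (uM) onto per-wavelength optical densities.

    Exact inverse of :func:`invert_mbll` for the same table and geometry.
    """
    table = table or ExtinctionTable()
    geometry = geometry or OpticalGeometry()
    conc = np.stack([series.hbo, series.hbr])  # (chromo, ch, samp)
    od = np.einsum("wc,cns->nws", table.matrix, conc)
    od = od * geometry.effective_path[None, :, None]
    return RawRecording(
        delta_od=od,
        sampling_rate=series.sampling_rate,
        wavelengths=table.wavelengths,
        channels=series.channels,
        metadata=dict(series.metadata),
    )
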