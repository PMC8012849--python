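"""Synthetic dual-wavelength fNIRS recordings with known ground truth.

The forward model mirrors the inverse pipeline: a task boxcar (one
amplitude per workload level) is convolved with a canonical hemodynamic
response function to give the noiseless dHbO of every prefrontal channel;
dHbR is a negatively scaled copy.  Physiological nuisance (cardiac,
respiratory and Mayer-wave sinusoids with random per-channel phases) and
white channel noise are added in concentration space, and the result is
projected to per-wavelength optical densities with the same modified
Beer-Lambert law the analysis inverts.  Channels listed as bad carry noise
only, with no task coupling.

All randomness flows from ``SubjectConfig.seed``; identical configuration
and schedule give byte-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import gamma as _gamma

from .optics import (
    ExtinctionTable,
    HemodynamicSeries,
    OpticalGeometry,
    RawRecording,
    forward_mbll,
)
from .paradigm import Label, ParadigmSchedule

__all__ = ["SubjectConfig", "GroundTruth", "canonical_hrf", "hrf_kernel", "simulate_subject"]

_UNDERSHOOT_RATIO = 1.0 / 6.0
_RISE_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0


@dataclass(frozen=True)
class SubjectConfig:
    """Generator settings for one simulated participant.

    Amplitudes are peak dHbO in uM for the two workload levels (the harder
    level drives a stronger prefrontal response); ``hbr_ratio`` scales dHbR
    against dHbO; ``physio`` lists (frequency Hz, amplitude uM) sinusoidal
    nuisance components (cardiac, respiration, Mayer waves); ``noise_sd``
    is the white channel noise in uM.
    """

    amplitude_mwl1: float = 0.5
    amplitude_mwl2: float = 1.0
    hbr_ratio: float = -1.0 / 3.0
    noise_sd: float = 0.3
    physio: tuple[tuple[float, float], ...] = ((1.1, 0.1), (0.25, 0.15), (0.1, 0.1))
    n_channels: int = 12
    bad_channels: frozenset = field(default_factory=frozenset)
    channel_gains: "tuple[float, ...] | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_mwl1 < 0 or self.amplitude_mwl2 < 0:
            raise ValueError("activation amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        object.__setattr__(self, "bad_channels", frozenset(self.bad_channels))
        for ch in self.bad_channels:
            if not 0 <= int(ch) < self.n_channels:
                raise ValueError(f"bad channel index {ch} out of range")
        if self.channel_gains is not None and len(self.channel_gains) != self.n_channels:
            raise ValueError("channel_gains must have one entry per channel")

    def validate_rate(self, sampling_rate: float) -> None:
        for f, _a in self.physio:
            if f >= sampling_rate / 2:
                raise ValueError(
                    f"physiological frequency {f} Hz is not below the Nyquist "
                    f"frequency {sampling_rate / 2} Hz"
                )


@dataclass
class GroundTruth:
    """Noiseless per-channel dHbO/dHbR plus the generating schedule."""

    hbo: np.ndarray  # (n_channels, n_samples), uM
    hbr: np.ndarray
    schedule: ParadigmSchedule
    bad_channels: frozenset

    @property
    def labels(self) -> np.ndarray:
        return self.schedule.label_vector()


@lru_cache(maxsize=16)
def _hrf_scale(peak_time: float, plateau_time: float) -> float:
    grid = np.linspace(0.0, 4.0 * plateau_time, 8001)
    return float(np.max(_double_gamma(grid, peak_time, plateau_time)))


def _double_gamma(t: np.ndarray, peak_time: float, plateau_time: float) -> np.ndarray:
    rise = _gamma.pdf(t, _RISE_SHAPE, scale=peak_time / (_RISE_SHAPE - 1))
    undershoot_time = peak_time + plateau_time - 1.0
    under = _gamma.pdf(t, _UNDERSHOOT_SHAPE, scale=undershoot_time / (_UNDERSHOOT_SHAPE - 1))
    return rise - _UNDERSHOOT_RATIO * under


def canonical_hrf(t, peak_time: float = 6.0, plateau_time: float = 11.0):
    """Canonical hemodynamic response, unit-normalized to peak at 1.

    A difference of two gamma densities: the positive lobe peaks at
    ``peak_time`` seconds (within the physiological 5-8 s range) and a
    small late undershoot, placed via ``plateau_time``, makes the response
    to sustained stimulation level off about 10-12 s after onset.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("canonical_hrf is defined for t >= 0")
    if peak_time <= 0 or plateau_time <= 0:
        raise ValueError("peak_time and plateau_time must be > 0")
    out = _double_gamma(arr, peak_time, plateau_time) / _hrf_scale(peak_time, plateau_time)
    return out if arr.ndim else float(out)


def hrf_kernel(
    sampling_rate: float,
    duration_s: float = 32.0,
    peak_time: float = 6.0,
    plateau_time: float = 11.0,
) -> np.ndarray:
    """Discrete HRF kernel normalized to unit area.

    With unit area, convolving a boxcar of amplitude ``a`` with the kernel
    produces a sustained response that settles at ``a`` uM, so the config
    amplitudes are the plateau concentrations.
    """
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    k = canonical_hrf(t, peak_time=peak_time, plateau_time=plateau_time)
    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate HRF kernel")
    return k / s


def _activation_boxcar(config: SubjectConfig, schedule: ParadigmSchedule) -> np.ndarray:
    labels = schedule.label_vector()
    box = np.zeros(schedule.n_samples)
    box[labels == Label.MWL1.value] = config.amplitude_mwl1
    box[labels == Label.MWL2.value] = config.amplitude_mwl2
    return box


def _nuisance(
    rng: np.random.Generator,
    config: SubjectConfig,
    times: np.ndarray,
) -> np.ndarray:
    """One channel's physiological + white noise trace (uM)."""
    out = rng.normal(0.0, config.noise_sd, size=times.size)
    for f, a in config.physio:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += a * np.sin(2.0 * np.pi * f * times + phase)
    return out


def simulate_subject(
    config: SubjectConfig,
    schedule: ParadigmSchedule,
    table: "ExtinctionTable | None" = None,
    geometry: "OpticalGeometry | None" = None,
) -> tuple[RawRecording, GroundTruth]:
    """Generate one subject's dual-wavelength recording plus ground truth.

    Returns the optical-density recording (what the instrument would emit)
    and the noiseless concentration truth used to create it.
    """
    config.validate_rate(schedule.sampling_rate)
    rng = np.random.default_rng(config.seed)
    times = schedule.times
    n = schedule.n_samples

    kernel = hrf_kernel(schedule.sampling_rate)
    response = np.convolve(_activation_boxcar(config, schedule), kernel)[:n]

    gains = (
        np.ones(config.n_channels)
        if config.channel_gains is None
        else np.asarray(config.channel_gains, dtype=float)
    )
    truth_hbo = np.zeros((config.n_channels, n))
    truth_hbr = np.zeros((config.n_channels, n))
    hbo = np.zeros((config.n_channels, n))
    hbr = np.zeros((config.n_channels, n))
    for ch in range(config.n_channels):
        coupled = ch not in config.bad_channels
        if coupled:
            truth_hbo[ch] = gains[ch] * response
            truth_hbr[ch] = config.hbr_ratio * truth_hbo[ch]
        # dHbR noise is scaled like the signal so both chromophores carry
        # the same signal-to-noise ratio.
        hbo[ch] = truth_hbo[ch] + _nuisance(rng, config, times)
        hbr[ch] = truth_hbr[ch] + abs(config.hbr_ratio) * _nuisance(rng, config, times)

    series = HemodynamicSeries(
        hbo=hbo,
        hbr=hbr,
        sampling_rate=schedule.sampling_rate,
        metadata={"seed": config.seed},
    )
    recording = forward_mbll(series, table=table, geometry=geometry)
    truth = GroundTruth(
        hbo=truth_hbo,
        hbr=truth_hbr,
        schedule=schedule,
        bad_channels=config.bad_channels,
    )
    return recording, truth
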