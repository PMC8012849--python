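"""Channel quality control, subject rejection and trial averaging.

Each channel's dHbO is compared against the block design: per task trial, a
two-sample t-test contrasts the task samples with the samples of the
adjacent rest period.  A channel is significant when the fraction of
significant trials (p < alpha) reaches a configurable threshold (default
89.16%).  Subjects whose contaminated-channel fraction exceeds 10% are
excluded.  Channels that are noisy but retained can be reconstructed by a
least-squares projection onto a canonical HRF regressor for plotting and
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .optics import HemodynamicSeries
from .paradigm import Label, ParadigmSchedule, TASK_LABELS
from .synthesize import hrf_kernel

__all__ = [
    "ChannelQCReport",
    "SubjectQCReport",
    "reference_signal",
    "channel_significance",
    "contamination_flags",
    "reject_subject",
    "hrf_average",
    "TrialAverage",
    "hrf_model_substitution",
]


def reference_signal(schedule: ParadigmSchedule) -> np.ndarray:
    """Modeled task reference: 1 during task blocks, 0 during rest/baseline.

    This is the discrete equal-step (20 s) workload signal the channel
    statistics are computed against.
    """
    labels = schedule.label_vector()
    ref = np.zeros(schedule.n_samples)
    for lv in TASK_LABELS:
        ref[labels == lv.value] = 1.0
    return ref


@dataclass
class ChannelQCReport:
    """Per-channel significance statistics against the task reference."""

    channels: tuple[str, ...]
    t_statistic: np.ndarray  # pooled task-vs-rest t per channel
    p_value: np.ndarray  # pooled p per channel
    significance_fraction: np.ndarray  # fraction of significant trials
    passes: np.ndarray  # bool per channel
    degenerate: np.ndarray  # bool: zero-variance channel
    alpha: float
    threshold: float

    def __post_init__(self) -> None:
        if np.any((self.p_value < 0) & ~np.isnan(self.p_value)) or np.any(
            self.p_value[~np.isnan(self.p_value)] > 1
        ):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def rejected_channels(self) -> np.ndarray:
        """Indices of channels failing the significance criterion."""
        return np.flatnonzero(~self.passes)

    @property
    def passing_channels(self) -> np.ndarray:
        return np.flatnonzero(self.passes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channels,
                "t_statistic": self.t_statistic,
                "p_value": self.p_value,
                "significance_fraction": self.significance_fraction,
                "passes": self.passes,
                "degenerate": self.degenerate,
            }
        )


@dataclass
class SubjectQCReport:
    """Subject-level retention decision from contamination flags."""

    contamination_fraction: float
    retained: bool
    rejected_channels: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.retained != (self.contamination_fraction <= 0.10):
            raise ValueError("retained must equal contamination_fraction <= 0.10")


def _trial_windows(
    schedule: ParadigmSchedule, level: "Label | str | None" = None
) -> list[tuple[slice, slice]]:
    """(task, following-rest) sample slices for each trial of a level."""
    out = []
    blocks = schedule.blocks
    wanted = None if level is None else Label(str(level))
    for i, b in enumerate(blocks):
        if b.label not in TASK_LABELS:
            continue
        if wanted is not None and b.label != wanted:
            continue
        task = schedule.sample_slice(b)
        if i + 1 < len(blocks) and blocks[i + 1].label == Label.REST:
            rest = schedule.sample_slice(blocks[i + 1])
        else:  # last trial without trailing rest: reuse the baseline
            rest = schedule.sample_slice(blocks[0])
        out.append((task, rest))
    return out


def channel_significance(
    series: HemodynamicSeries,
    schedule: ParadigmSchedule,
    alpha: float = 0.05,
    threshold: float = 0.8916,
) -> ChannelQCReport:
    """Per-channel task-vs-rest significance testing on dHbO.

    For every task trial an independent two-sample t-test compares the
    trial's task samples with its adjacent rest samples; the channel's
    ``significance_fraction`` is the fraction of trials with p < ``alpha``
    and the channel passes when that fraction reaches ``threshold``.  A
    pooled whole-channel test (all task vs all rest samples) is reported
    for diagnostics.  Channels with zero variance are degenerate and fail.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    trials = _trial_windows(schedule)
    if not trials:
        raise ValueError("schedule contains no task blocks")
    labels = schedule.label_vector()
    task_mask = np.isin(labels, [lv.value for lv in TASK_LABELS])

    n_ch = series.n_channels
    t_stat = np.full(n_ch, np.nan)
    p_val = np.full(n_ch, np.nan)
    frac = np.zeros(n_ch)
    degenerate = np.zeros(n_ch, dtype=bool)
    for ch in range(n_ch):
        x = series.hbo[ch]
        if np.ptp(x) == 0:
            degenerate[ch] = True
            continue
        hits = 0
        for task, rest in trials:
            a, b = x[task], x[rest]
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                continue
            res = stats.ttest_ind(a, b)
            if res.pvalue < alpha:
                hits += 1
        frac[ch] = hits / len(trials)
        pooled = stats.ttest_ind(x[task_mask], x[~task_mask])
        t_stat[ch], p_val[ch] = pooled.statistic, pooled.pvalue
    passes = (frac >= threshold) & ~degenerate
    return ChannelQCReport(
        channels=series.channels,
        t_statistic=t_stat,
        p_value=p_val,
        significance_fraction=frac,
        passes=passes,
        degenerate=degenerate,
        alpha=alpha,
        threshold=threshold,
    )


def contamination_flags(
    series: HemodynamicSeries,
    report: "ChannelQCReport | None" = None,
    flat_window_s: float = 5.0,
    clip_fraction: float = 0.05,
) -> np.ndarray:
    """Per-channel noise-contamination flags.

    A channel counts as contaminated when it fails the significance
    criterion, is flat-lined over any window of ``flat_window_s`` seconds,
    or spends more than ``clip_fraction`` of its samples pinned at its
    extreme value (clipping).
    """
    n_ch = series.n_channels
    flags = np.zeros(n_ch, dtype=bool)
    w = max(2, int(round(flat_window_s * series.sampling_rate)))
    for ch in range(n_ch):
        x = series.hbo[ch]
        if np.ptp(x) == 0:
            flags[ch] = True
            continue
        diffs = np.abs(np.diff(x))
        run = 0
        for d in diffs:
            run = run + 1 if d == 0 else 0
            if run >= w - 1:
                flags[ch] = True
                break
        at_extreme = np.mean((x == x.max()) | (x == x.min()))
        if at_extreme > clip_fraction:
            flags[ch] = True
    if report is not None:
        flags |= ~report.passes
    return flags


def reject_subject(
    report: ChannelQCReport, noise_scan: "np.ndarray | None" = None
) -> SubjectQCReport:
    """Subject retention rule: reject when > 10% of channels are contaminated.

    ``noise_scan`` is a per-channel boolean contamination vector (e.g. from
    :func:`contamination_flags`); when omitted, significance failures are
    used directly.
    """
    flags = np.asarray(noise_scan if noise_scan is not None else ~report.passes, dtype=bool)
    if flags.size != len(report.channels):
        raise ValueError("noise_scan length must match the channel count")
    fraction = float(np.mean(flags))
    return SubjectQCReport(
        contamination_fraction=fraction,
        retained=fraction <= 0.10,
        rejected_channels=tuple(int(i) for i in report.rejected_channels),
    )


@dataclass
class TrialAverage:
    """Channel- and trial-averaged response on a trial-relative time axis."""

    time: np.ndarray  # seconds from task onset
    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    level: Label
    n_trials: int


def hrf_average(
    series: HemodynamicSeries,
    schedule: ParadigmSchedule,
    level: "Label | str",
) -> TrialAverage:
    """Average the response to one workload level.

    Channels are averaged spatially first, then the resulting vector is
    averaged temporally over the level's trials (task plus the following
    rest period, so the full rise and return are visible).
    """
    level = Label(str(level))
    trials = _trial_windows(schedule, level)
    if not trials:
        raise ValueError(f"level {level.value} is absent from the schedule")
    spatial = {
        "hbo": series.hbo.mean(axis=0),
        "hbr": series.hbr.mean(axis=0),
        "hbt": series.hbt.mean(axis=0),
    }
    length = min((t.stop - t.start) + (r.stop - r.start) for t, r in trials)
    segments = {k: [] for k in spatial}
    for task, _rest in trials:
        start = task.start
        for k, v in spatial.items():
            segments[k].append(v[start : start + length])
    time = np.arange(length) / series.sampling_rate
    return TrialAverage(
        time=time,
        hbo=np.mean(segments["hbo"], axis=0),
        hbr=np.mean(segments["hbr"], axis=0),
        hbt=np.mean(segments["hbt"], axis=0),
        level=level,
        n_trials=len(trials),
    )


def hrf_model_substitution(
    channel: np.ndarray,
    schedule: ParadigmSchedule,
) -> tuple[np.ndarray, float]:
    """Reconstruct a noisy channel from the canonical HRF model.

    The channel is projected (least squares) onto an intercept plus the
    task reference convolved with the canonical HRF; the fitted curve and
    the HRF gain coefficient are returned.  Intended for plotting and
    diagnostics of retained-but-noisy channels, not as classifier input.
    """
    channel = np.asarray(channel, dtype=float).ravel()
    if channel.size != schedule.n_samples:
        raise ValueError("channel length does not match the schedule")
    ref = reference_signal(schedule)
    if not np.any(ref):
        raise ValueError("schedule has no task blocks: degenerate design")
    kernel = hrf_kernel(schedule.sampling_rate)
    regressor = np.convolve(ref, kernel)[: schedule.n_samples]
    design = np.column_stack([np.ones_like(regressor), regressor])
    coef, *_ = np.linalg.lstsq(design, channel, rcond=None)
    fitted = design @ coef
    return fitted, float(coef[1])
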