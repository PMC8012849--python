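"""Command translation and kinematic simulation of the exoskeleton hand.

Decoded workload states drive a five-finger tendon-driven exoskeleton: the
mild state opens the hand, the intense state closes it, and low-confidence
outputs hold the current pose ("tied").  Each finger is driven by a linear
actuator whose stroke (0 to 25.5 mm) maps through the tendon linkage to the
MCP, PIP and DIP joint angles; the map is calibrated so full stroke reaches
the design range of motion (63.1, 118.2, 63.1 degrees) with a smooth
saturating (logarithmic-like) shape, and strokes follow a minimum-jerk
profile completing in about one second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Command",
    "ExoskeletonConfig",
    "translate",
    "stroke_to_angles",
    "execute",
]

_STATE_TO_COMMAND = {"mwl1": "open", "mwl2": "close", "undecided": "tied"}
JOINTS = ("mcp", "pip", "dip")


@dataclass(frozen=True)
class Command:
    """One actuation directive with its emission time."""

    value: str  # "open" | "close" | "tied"
    timestamp: float
    fingers: "tuple[int, ...] | None" = None  # None = all five

    def __post_init__(self) -> None:
        if self.value not in ("open", "close", "tied"):
            raise ValueError(f"unknown command {self.value!r}")


@dataclass(frozen=True)
class ExoskeletonConfig:
    """Geometry and timing of the tendon-driven hand."""

    stroke_max_mm: float = 25.5
    rom_deg: tuple[float, float, float] = (63.1, 118.2, 63.1)  # MCP, PIP, DIP
    actuation_time_s: float = 1.0
    n_fingers: int = 5
    curve_k: float = 9.0  # saturation of the stroke-to-angle curve
    calibration: "Callable[[np.ndarray], np.ndarray] | None" = None

    def __post_init__(self) -> None:
        if self.stroke_max_mm <= 0 or self.actuation_time_s <= 0:
            raise ValueError("stroke_max_mm and actuation_time_s must be > 0")
        if any(r <= 0 for r in self.rom_deg):
            raise ValueError("range-of-motion angles must be > 0")
        if self.n_fingers < 1:
            raise ValueError("n_fingers must be >= 1")
        if self.curve_k <= 0:
            raise ValueError("curve_k must be > 0")


def translate(
    predictions: Iterable[str],
    timestamps: "Sequence[float] | None" = None,
    margins: "Sequence[float] | None" = None,
    confidence_threshold: float = 0.0,
) -> list[Command]:
    """Turn a stream of decoded states into de-duplicated commands.

    ``mwl1`` maps to ``open``, ``mwl2`` to ``close``; a state of
    ``undecided`` — or any state whose absolute classifier margin falls
    below ``confidence_threshold`` — maps to ``tied`` (hold the current
    pose).  Consecutive repetitions of the same command emit nothing, so
    the hand is not re-actuated while the state persists.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("prediction stream is empty")
    if timestamps is None:
        timestamps = list(range(len(predictions)))
    if len(timestamps) != len(predictions):
        raise ValueError("timestamps must align with predictions")
    if margins is not None and len(margins) != len(predictions):
        raise ValueError("margins must align with predictions")
    commands: list[Command] = []
    for i, state in enumerate(predictions):
        if state not in _STATE_TO_COMMAND:
            raise ValueError(f"unknown state token {state!r}")
        value = _STATE_TO_COMMAND[state]
        if (
            margins is not None
            and value != "tied"
            and abs(margins[i]) < confidence_threshold
        ):
            value = "tied"
        if commands and commands[-1].value == value:
            continue
        commands.append(Command(value=value, timestamp=float(timestamps[i])))
    return commands


def stroke_to_angles(
    stroke_mm: float, config: "ExoskeletonConfig | None" = None
) -> tuple[float, float, float]:
    """Map actuator stroke to (MCP, PIP, DIP) joint angles in degrees.

    A strictly monotone smooth saturating curve with exact endpoints:
    zero stroke gives the open pose (0, 0, 0) and full stroke reaches the
    configured range of motion.  A user calibration function mapping the
    normalized stroke in [0, 1] to a normalized angle in [0, 1] may replace
    the default shape.
    """
    config = config or ExoskeletonConfig()
    if not 0 <= stroke_mm <= config.stroke_max_mm:
        raise ValueError(
            f"stroke must lie in [0, {config.stroke_max_mm}] mm, got {stroke_mm}"
        )
    x = stroke_mm / config.stroke_max_mm
    if config.calibration is not None:
        shape = float(config.calibration(np.asarray(x)))
    else:
        shape = float(np.log1p(config.curve_k * x) / np.log1p(config.curve_k))
    return tuple(r * shape for r in config.rom_deg)


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def execute(
    commands: Sequence[Command],
    config: "ExoskeletonConfig | None" = None,
    dt: float = 0.05,
    settle_s: "float | None" = None,
) -> pd.DataFrame:
    """Simulate the per-finger stroke and joint-angle trajectories.

    ``open`` drives the stroke of the addressed fingers toward 0, ``close``
    toward full stroke, each along a minimum-jerk profile that completes in
    ``actuation_time_s``; ``tied`` freezes the pose at its current value.
    Returns a table with one row per time step: time, per-finger stroke and
    per-finger MCP/PIP/DIP angles.  The pose is a pure function of the
    command history, so replays are deterministic.
    """
    config = config or ExoskeletonConfig()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    commands = sorted(commands, key=lambda c: c.timestamp)
    t_end = (commands[-1].timestamp if commands else 0.0) + (
        settle_s if settle_s is not None else config.actuation_time_s
    )
    times = np.arange(0.0, t_end + dt / 2, dt)

    # Per finger: list of (t0, s0, s1) motion segments.
    segments: list[list[tuple[float, float, float]]] = [
        [(-np.inf, 0.0, 0.0)] for _ in range(config.n_fingers)
    ]

    def stroke_at(finger: int, t: float) -> float:
        t0, s0, s1 = segments[finger][-1]
        for seg in reversed(segments[finger]):
            if seg[0] <= t:
                t0, s0, s1 = seg
                break
        tau = (t - t0) / config.actuation_time_s if np.isfinite(t0) else 1.0
        return s0 + (s1 - s0) * float(_min_jerk(np.asarray(tau)))

    for cmd in commands:
        fingers = cmd.fingers if cmd.fingers is not None else range(config.n_fingers)
        for f in fingers:
            current = stroke_at(f, cmd.timestamp)
            if cmd.value == "tied":
                target = current
            elif cmd.value == "open":
                target = 0.0
            else:
                target = config.stroke_max_mm
            segments[f].append((cmd.timestamp, current, target))

    rows = []
    for t in times:
        row = {"time": t}
        for f in range(config.n_fingers):
            s = stroke_at(f, t)
            mcp, pip_, dip = stroke_to_angles(s, config)
            row[f"f{f + 1}_stroke"] = s
            row[f"f{f + 1}_mcp"] = mcp
            row[f"f{f + 1}_pip"] = pip_
            row[f"f{f + 1}_dip"] = dip
        rows.append(row)
    return pd.DataFrame(rows)
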