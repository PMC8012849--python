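"""End-to-end orchestration: simulate/load -> decode -> actuate.

``run_pipeline`` executes the full chain — simulation (or loading a
recording), MBLL inversion, zero-phase low-pass filtering, channel QC and
subject rejection, feature extraction, SVM evaluation per chromophore,
command translation and the kinematic hand simulation — persisting every
stage's output under the configured directory together with a JSON-lines
run log.  All data files are byte-deterministic for a fixed seed; only the
run log contains wall-clock timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .actuate import execute, translate
from .config import RunConfig
from .decode import EvaluationResult, evaluate_subject
from .optics import ExtinctionTable, OpticalGeometry, invert_mbll
from .paradigm import ParadigmSchedule, build_default_paradigm
from .preprocess import lowpass
from .quality import (
    ChannelQCReport,
    SubjectQCReport,
    channel_significance,
    contamination_flags,
    reject_subject,
)
from .synthesize import simulate_subject

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a pipeline run produced (None past a rejection)."""

    config: RunConfig
    schedule: ParadigmSchedule
    qc_report: ChannelQCReport
    subject_report: SubjectQCReport
    evaluation: "EvaluationResult | None"
    commands: "list | None"
    poses: "pd.DataFrame | None"
    output_dir: Path


def _geometry(config: RunConfig) -> tuple[ExtinctionTable, OpticalGeometry]:
    table = ExtinctionTable(wavelengths=tuple(config.optics.wavelengths))
    geometry = OpticalGeometry(
        path_length_cm=config.optics.path_length_cm, dpf=config.optics.dpf
    )
    return table, geometry


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline described by ``config``.

    Returns the collected stage outputs; on subject rejection the
    classifier and actuation stages are skipped and their fields are None.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_file = log_path.open("w")
    t_start = time.perf_counter()

    def log(stage: str, **info) -> None:
        entry = {
            "stage": stage,
            "elapsed_s": round(time.perf_counter() - t_start, 4),
            "seed": config.seed,
            "config_hash": config.config_hash,
            **info,
        }
        log_file.write(json.dumps(entry) + "\n")

    provenance = {"seed": config.seed, "config_hash": config.config_hash}
    table, geometry = _geometry(config)

    try:
        # --- acquire -------------------------------------------------------
        if config.input_path is None:
            schedule = build_default_paradigm(
                levels=config.paradigm.levels,
                n_trials=config.paradigm.n_trials,
                task_s=config.paradigm.task_s,
                rest_s=config.paradigm.rest_s,
                baseline_s=config.paradigm.baseline_s,
                inter_level_delay_s=config.paradigm.inter_level_delay_s,
                sampling_rate=config.paradigm.sampling_rate,
            )
            subject = config.generator.to_subject_config(config.seed)
            recording, _truth = simulate_subject(
                subject, schedule, table=table, geometry=geometry
            )
            recording.metadata.update(provenance)
            log("simulate", n_channels=recording.n_channels,
                n_samples=recording.n_samples)
        else:
            recording, schedule = nio.read_recording(config.input_path)
            recording.metadata.update(provenance)
            if schedule is None:
                schedule = build_default_paradigm(
                    levels=config.paradigm.levels,
                    n_trials=config.paradigm.n_trials,
                    task_s=config.paradigm.task_s,
                    rest_s=config.paradigm.rest_s,
                    baseline_s=config.paradigm.baseline_s,
                    inter_level_delay_s=config.paradigm.inter_level_delay_s,
                    sampling_rate=recording.sampling_rate,
                )
            log("load", path=str(config.input_path))

        ext = "snirf" if config.output_format == "snirf" else "tsv"
        nio.write_recording(
            recording, out / f"recording.{ext}", fmt=config.output_format,
            schedule=schedule,
        )
        schedule.to_events().to_csv(out / "events.tsv", sep="\t", index=False)

        # --- preprocess ----------------------------------------------------
        series = invert_mbll(recording, table=table, geometry=geometry)
        series = lowpass(
            series, cutoff_hz=config.filter.cutoff_hz, order=config.filter.order
        )
        series.metadata.update(provenance)
        nio.write_series_tsv(series, out / "hemodynamics.tsv")
        log("preprocess", cutoff_hz=config.filter.cutoff_hz)

        # --- quality control ----------------------------------------------
        qc = channel_significance(
            series, schedule, alpha=config.qc.alpha, threshold=config.qc.threshold
        )
        flags = contamination_flags(series, qc)
        subject_qc = reject_subject(qc, flags)
        qc_frame = qc.to_frame()
        qc_frame["contaminated"] = flags
        nio._write_tsv_with_header(
            out / "qc_report.tsv",
            qc_frame,
            {"format": "nirsbmi-qc", **{k: str(v) for k, v in provenance.items()}},
        )
        log(
            "qc",
            rejected_channels=[int(i) for i in qc.rejected_channels],
            contamination_fraction=subject_qc.contamination_fraction,
            retained=subject_qc.retained,
        )
        if not subject_qc.retained:
            log("abort", reason="subject rejected by QC")
            return PipelineResult(
                config=config,
                schedule=schedule,
                qc_report=qc,
                subject_report=subject_qc,
                evaluation=None,
                commands=None,
                poses=None,
                output_dir=out,
            )

        # --- decode --------------------------------------------------------
        channels = qc.passing_channels
        if channels.size == 0:
            raise RuntimeError("decode: no channel passed quality control")
        evaluation = evaluate_subject(
            series,
            schedule,
            channels=channels,
            window_s=config.features.window_s,
            step_s=config.features.step_s,
            feature_set=tuple(config.features.feature_set),
            C=config.classifier.C,
            seed=config.seed,
            by_epoch=config.classifier.by_epoch,
        )
        results = evaluation.to_frame(subject=f"seed{config.seed}")
        nio._write_tsv_with_header(
            out / "results.tsv",
            results,
            {"format": "nirsbmi-results", **{k: str(v) for k, v in provenance.items()}},
        )
        log("decode", **{f"accuracy_{k}": round(v, 2) for k, v in evaluation.accuracy.items()})

        # --- actuate -------------------------------------------------------
        truth, pred = evaluation.predictions["hbo"]
        margins = None
        commands = translate(
            list(pred),
            timestamps=np.arange(len(pred), dtype=float).tolist(),
            margins=margins,
            confidence_threshold=config.actuation.confidence_threshold,
        )
        exo = config.actuation.to_exo_config()
        poses = execute(commands, exo, dt=config.actuation.dt_s)
        cmd_frame = pd.DataFrame(
            {"timestamp": [c.timestamp for c in commands],
             "command": [c.value for c in commands]}
        )
        nio._write_tsv_with_header(
            out / "commands.tsv",
            cmd_frame,
            {"format": "nirsbmi-commands", **{k: str(v) for k, v in provenance.items()}},
        )
        nio._write_tsv_with_header(
            out / "poses.tsv",
            poses,
            {"format": "nirsbmi-poses", **{k: str(v) for k, v in provenance.items()}},
        )
        log("actuate", n_commands=len(commands))
        return PipelineResult(
            config=config,
            schedule=schedule,
            qc_report=qc,
            subject_report=subject_qc,
            evaluation=evaluation,
            commands=commands,
            poses=poses,
            output_dir=out,
        )
    except Exception as exc:
        log("error", error=str(exc), stage_type=type(exc).__name__)
        raise
    finally:
        log_file.close()
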