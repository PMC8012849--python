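"""Readers and writers for recordings, series, features and reports.

Two on-disk formats are supported for recordings: SNIRF (the HDF5-based
standard for near-infrared spectroscopy data, with the paradigm embedded as
stimulus tables) and a plain TSV dialect (a time column plus one column per
channel x wavelength, with ``# key: value`` header lines) for easy
inspection.  Every file written carries the seed and configuration hash it
was produced under.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .optics import DEFAULT_WAVELENGTHS, HemodynamicSeries, RawRecording
from .paradigm import Block, Label, ParadigmSchedule

__all__ = [
    "read_recording",
    "write_recording",
    "write_series_tsv",
    "read_series_tsv",
]


class FormatError(ValueError):
    """The file does not conform to the expected on-disk format."""


def _provenance(metadata: dict) -> dict:
    out = {"software": f"nirsbmi {__version__}"}
    for key in ("seed", "config_hash"):
        if key in metadata:
            out[key] = metadata[key]
    return out


# --------------------------------------------------------------------------
# TSV dialect


def _write_tsv_with_header(path, frame: pd.DataFrame, header: dict) -> None:
    buf = _io.StringIO()
    for k, v in header.items():
        buf.write(f"# {k}: {v}\n")
    frame.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    Path(path).write_text(buf.getvalue())


def _read_tsv_with_header(path) -> tuple[pd.DataFrame, dict]:
    header: dict = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    n_skip = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_skip += 1
        k, _, v = line[1:].partition(":")
        header[k.strip()] = v.strip()
    frame = pd.read_csv(_io.StringIO("".join(lines[n_skip:])), sep="\t")
    return frame, header


def _recording_to_tsv(recording: RawRecording, path) -> None:
    cols = {"time": np.arange(recording.n_samples) / recording.sampling_rate}
    for i, ch in enumerate(recording.channels):
        for w, wl in enumerate(recording.wavelengths):
            cols[f"{ch}_wl{wl:g}"] = recording.delta_od[i, w]
    header = {
        "format": "nirsbmi-recording",
        "sampling_rate_hz": f"{recording.sampling_rate:g}",
        "wavelengths_nm": ",".join(f"{w:g}" for w in recording.wavelengths),
        **_provenance(recording.metadata),
    }
    _write_tsv_with_header(path, pd.DataFrame(cols), header)


def _recording_from_tsv(path) -> RawRecording:
    frame, header = _read_tsv_with_header(path)
    if header.get("format") != "nirsbmi-recording":
        raise FormatError(f"{path}: missing 'format: nirsbmi-recording' header")
    try:
        fs = float(header["sampling_rate_hz"])
        wavelengths = tuple(float(w) for w in header["wavelengths_nm"].split(","))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad or missing header field ({exc})") from exc
    if len(wavelengths) != 2:
        raise FormatError(
            f"{path}: two wavelengths required, found {len(wavelengths)}"
        )
    channels = []
    for col in frame.columns:
        if col == "time":
            continue
        ch = col.rsplit("_wl", 1)[0]
        if ch not in channels:
            channels.append(ch)
    od = np.empty((len(channels), 2, len(frame)))
    for i, ch in enumerate(channels):
        for w, wl in enumerate(wavelengths):
            col = f"{ch}_wl{wl:g}"
            if col not in frame.columns:
                raise FormatError(f"{path}: missing column {col}")
            od[i, w] = frame[col].to_numpy()
    metadata = {
        k: header[k] for k in ("seed", "config_hash") if k in header
    }
    if "seed" in metadata:
        metadata["seed"] = int(metadata["seed"])
    return RawRecording(
        delta_od=od,
        sampling_rate=fs,
        wavelengths=wavelengths,
        channels=tuple(channels),
        metadata=metadata,
    )


def write_series_tsv(series: HemodynamicSeries, path) -> None:
    """Write a concentration series (uM) as TSV with provenance headers."""
    cols = {"time": np.arange(series.n_samples) / series.sampling_rate}
    for i, ch in enumerate(series.channels):
        cols[f"{ch}_hbo"] = series.hbo[i]
        cols[f"{ch}_hbr"] = series.hbr[i]
        cols[f"{ch}_hbt"] = series.hbt[i]
    header = {
        "format": "nirsbmi-series",
        "units": "micromolar",
        "sampling_rate_hz": f"{series.sampling_rate:g}",
        **_provenance(series.metadata),
    }
    _write_tsv_with_header(path, pd.DataFrame(cols), header)


def read_series_tsv(path) -> HemodynamicSeries:
    frame, header = _read_tsv_with_header(path)
    if header.get("format") != "nirsbmi-series":
        raise FormatError(f"{path}: missing 'format: nirsbmi-series' header")
    fs = float(header["sampling_rate_hz"])
    channels = []
    for col in frame.columns:
        if col.endswith("_hbo"):
            channels.append(col[: -len("_hbo")])
    hbo = np.stack([frame[f"{ch}_hbo"].to_numpy() for ch in channels])
    hbr = np.stack([frame[f"{ch}_hbr"].to_numpy() for ch in channels])
    return HemodynamicSeries(
        hbo=hbo, hbr=hbr, sampling_rate=fs, channels=tuple(channels)
    )


# --------------------------------------------------------------------------
# SNIRF (HDF5)

_STR = h5py.string_dtype(encoding="utf-8")


def _recording_to_snirf(
    recording: RawRecording, path, schedule: "ParadigmSchedule | None" = None
) -> None:
    n_ch, _, n_samp = recording.delta_od.shape
    # measurements ordered channel-major, wavelength-minor
    data = np.empty((n_samp, n_ch * 2))
    for i in range(n_ch):
        for w in range(2):
            data[:, i * 2 + w] = recording.delta_od[i, w]
    with h5py.File(path, "w", track_order=True) as f:
        def ds(group, name, value):
            group.create_dataset(name, data=value, track_times=False)

        ds(f, "formatVersion", np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        tags = {
            "SubjectID": "synthetic",
            "MeasurementDate": "unknown",
            "MeasurementTime": "unknown",
            "LengthUnit": "cm",
            "TimeUnit": "s",
            "FrequencyUnit": "Hz",
            **{k: str(v) for k, v in _provenance(recording.metadata).items()},
        }
        for k, v in tags.items():
            ds(meta, k, np.bytes_(v))
        d1 = nirs.create_group("data1")
        ds(d1, "dataTimeSeries", data)
        ds(d1, "time", np.array([0.0, 1.0 / recording.sampling_rate]))
        for m in range(n_ch * 2):
            ml = d1.create_group(f"measurementList{m + 1}")
            ch, w = divmod(m, 2)
            ds(ml, "sourceIndex", np.int32(ch + 1))
            ds(ml, "detectorIndex", np.int32(ch + 1))
            ds(ml, "wavelengthIndex", np.int32(w + 1))
            ds(ml, "dataType", np.int32(99999))  # processed dOD
            ds(ml, "dataTypeLabel", np.bytes_("dOD"))
            ds(ml, "dataTypeIndex", np.int32(1))
        probe = nirs.create_group("probe")
        ds(probe, "wavelengths", np.asarray(recording.wavelengths, dtype=float))
        pos = np.zeros((n_ch, 3))
        pos[:, 0] = np.arange(n_ch) * 3.0
        ds(probe, "sourcePos3D", pos)
        ds(probe, "detectorPos3D", pos + np.array([3.0, 0.0, 0.0]))
        if schedule is not None:
            for s, label in enumerate(("rest", "mwl1", "mwl2")):
                blocks = [b for b in schedule.blocks if b.label.value == label]
                if not blocks:
                    continue
                stim = nirs.create_group(f"stim{s + 1}")
                ds(stim, "name", np.bytes_(label))
                ds(
                    stim,
                    "data",
                    np.array([[b.onset, b.duration, 1.0] for b in blocks]),
                )


def _recording_from_snirf(path) -> tuple[RawRecording, "ParadigmSchedule | None"]:
    with h5py.File(path, "r") as f:
        if "nirs" not in f or "data1" not in f["nirs"]:
            raise FormatError(f"{path}: missing /nirs/data1 group")
        d1 = f["nirs/data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        if time.size == 2:
            fs = 1.0 / float(time[1] - time[0])
        else:
            fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = tuple(float(w) for w in np.asarray(f["nirs/probe/wavelengths"]))
        if len(wavelengths) != 2:
            raise FormatError(
                f"{path}: probe/wavelengths must list 2 wavelengths, "
                f"found {len(wavelengths)}"
            )
        mls = sorted(
            (k for k in d1 if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList") :]),
        )
        if len(mls) != data.shape[1]:
            raise FormatError(f"{path}: measurementList count does not match data")
        pairs = {}
        for col, k in enumerate(mls):
            ml = d1[k]
            src = int(np.asarray(ml["sourceIndex"]))
            det = int(np.asarray(ml["detectorIndex"]))
            wli = int(np.asarray(ml["wavelengthIndex"]))
            pairs.setdefault((src, det), {})[wli] = col
        n_ch = len(pairs)
        od = np.empty((n_ch, 2, data.shape[0]))
        for i, key in enumerate(sorted(pairs)):
            cols = pairs[key]
            if set(cols) != {1, 2}:
                raise FormatError(
                    f"{path}: channel {key} does not have both wavelengths"
                )
            od[i, 0] = data[:, cols[1]]
            od[i, 1] = data[:, cols[2]]
        metadata = {}
        meta = f["nirs"].get("metaDataTags")
        if meta is not None:
            for k in ("seed", "config_hash"):
                if k in meta:
                    v = np.asarray(meta[k]).item()
                    if isinstance(v, bytes):
                        v = v.decode()
                    metadata[k] = int(v) if k == "seed" else v
        schedule = None
        stims = sorted(k for k in f["nirs"] if k.startswith("stim"))
        if stims:
            blocks = []
            for k in stims:
                name = np.asarray(f["nirs"][k]["name"]).item()
                if isinstance(name, bytes):
                    name = name.decode()
                for onset, duration, _amp in np.asarray(f["nirs"][k]["data"]):
                    blocks.append(Block(Label(name), float(onset), float(duration)))
            blocks.sort(key=lambda b: b.onset)
            schedule = ParadigmSchedule(blocks=tuple(blocks), sampling_rate=fs)
    recording = RawRecording(
        delta_od=od,
        sampling_rate=fs,
        wavelengths=wavelengths,
        metadata=metadata,
    )
    return recording, schedule


# --------------------------------------------------------------------------
# dispatch


def _infer_format(path, fmt: "str | None") -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".snirf":
        return "snirf"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer format from extension {suffix!r}; pass format=")


def write_recording(
    recording: RawRecording,
    path,
    fmt: "str | None" = None,
    schedule: "ParadigmSchedule | None" = None,
) -> None:
    """Write a dual-wavelength recording as SNIRF or TSV."""
    fmt = _infer_format(path, fmt)
    if fmt == "snirf":
        _recording_to_snirf(recording, path, schedule=schedule)
    elif fmt == "tsv":
        _recording_to_tsv(recording, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_recording(
    path, fmt: "str | None" = None
) -> tuple[RawRecording, "ParadigmSchedule | None"]:
    """Read a recording; returns (recording, embedded schedule or None)."""
    fmt = _infer_format(path, fmt)
    if fmt == "snirf":
        return _recording_from_snirf(path)
    if fmt == "tsv":
        return _recording_from_tsv(path), None
    raise ValueError(f"unsupported format {fmt!r}")
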