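"""Readers and writers: SNIRF (HDF5) containers and a plain CSV/TSV dialect.

SNIRF is the community container for continuous-wave NIRS.  Only the
subset needed for a two-wavelength CW measurement is written: one data
block, a 3-D probe, and one stimulus group per condition.  The CSV
dialect is a wide table (``time_s`` plus one ``S{src}_D{det}_{wl}nm``
column per channel-wavelength) with events in a sidecar TSV; it exists so
test fixtures stay human-inspectable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import EventSchedule, Recording, Unit
from .montage import Montage


class SnirfFormatError(RuntimeError):
    """Raised when a container is missing required SNIRF structure."""


def _str_dataset(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(rec: Recording, path) -> None:
    """Write a raw-intensity recording as a SNIRF v1.0 container."""
    rec.require_unit(Unit.RAW_INTENSITY, "write_snirf")
    if rec.n_samples == 0:
        raise ValueError("refusing to write a zero-length recording")
    m = rec.montage
    with h5py.File(path, "w") as f:
        _str_dataset(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_dataset(meta, "SubjectID", "sim")
        _str_dataset(meta, "MeasurementDate", "unknown")
        _str_dataset(meta, "MeasurementTime", "unknown")
        _str_dataset(meta, "LengthUnit", "m")
        _str_dataset(meta, "TimeUnit", "s")
        _str_dataset(meta, "FrequencyUnit", "Hz")

        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.data.T)
        data.create_dataset("time", data=rec.times)
        for row in range(rec.data.shape[0]):
            ch = rec.row_channel(row)
            wl_index = row % 2 + 1
            s_label, d_label = m.channels[ch]
            ml = data.create_group(f"measurementList{row + 1}")
            ml.create_dataset("sourceIndex", data=m.source_labels.index(s_label) + 1)
            ml.create_dataset("detectorIndex", data=m.detector_labels.index(d_label) + 1)
            ml.create_dataset("wavelengthIndex", data=wl_index)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(m.wavelengths, dtype=float))
        probe.create_dataset("sourcePos3D", data=m.source_pos)
        probe.create_dataset("detectorPos3D", data=m.detector_pos)
        probe.create_dataset(
            "sourceLabels", data=np.array([np.bytes_(l) for l in m.source_labels])
        )
        probe.create_dataset(
            "detectorLabels", data=np.array([np.bytes_(l) for l in m.detector_labels])
        )

        for i, cond in enumerate(rec.events.condition_set, start=1):
            sub = rec.events.for_condition(cond)
            stim = nirs.create_group(f"stim{i}")
            _str_dataset(stim, "name", cond)
            stim.create_dataset(
                "data",
                data=np.column_stack([sub.onsets, sub.durations, np.ones(len(sub))]),
            )

        # ROI membership is not part of SNIRF; stored as a sidecar group
        roi = nirs.create_group("fnirsblockROI")
        for name, idx in m.roi_map.items():
            roi.create_dataset(name, data=np.asarray(idx, dtype=int))


def _decode(x) -> str:
    v = x[()] if isinstance(x, h5py.Dataset) else x
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.ndarray):
        v = v.item() if v.size == 1 else v
        if isinstance(v, bytes):
            return v.decode()
    return str(v)


def read_snirf(path) -> Recording:
    """Read a two-wavelength continuous-wave SNIRF container."""
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise SnirfFormatError(f"{path}: no /nirs group")
        nirs = f["nirs"]
        if "data1" not in nirs:
            raise SnirfFormatError(f"{path}: no /nirs/data1 block")
        data_grp = nirs["data1"]
        ts = np.asarray(data_grp["dataTimeSeries"]).T
        time = np.asarray(data_grp["time"]).ravel()
        if len(time) > 1:
            sfreq = 1.0 / float(np.median(np.diff(time)))
        else:
            sfreq = 1.0

        if "probe" not in nirs:
            raise SnirfFormatError(f"{path}: missing probe geometry")
        probe = nirs["probe"]
        wavelengths = tuple(np.asarray(probe["wavelengths"], dtype=float).ravel()[:2])
        src_pos = np.asarray(probe["sourcePos3D"], dtype=float)
        det_pos = np.asarray(probe["detectorPos3D"], dtype=float)
        if "sourceLabels" in probe:
            src_labels = [_decode(v) for v in probe["sourceLabels"][()]]
            det_labels = [_decode(v) for v in probe["detectorLabels"][()]]
        else:
            src_labels = [f"S{i + 1}" for i in range(len(src_pos))]
            det_labels = [f"D{i + 1}" for i in range(len(det_pos))]

        ml_names = sorted(
            (k for k in data_grp if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if not ml_names:
            raise SnirfFormatError(f"{path}: no measurementList entries")
        channels: list[tuple[str, str]] = []
        row_order = np.empty(len(ml_names), dtype=int)
        for row, name in enumerate(ml_names):
            ml = data_grp[name]
            s = src_labels[int(ml["sourceIndex"][()]) - 1]
            d = det_labels[int(ml["detectorIndex"][()]) - 1]
            wl_index = int(ml["wavelengthIndex"][()]) - 1
            pair = (s, d)
            if pair not in channels:
                channels.append(pair)
            row_order[2 * channels.index(pair) + wl_index] = row

        roi_map: dict[str, list[int]] = {}
        if "fnirsblockROI" in nirs:
            roi_map = {k: list(map(int, nirs["fnirsblockROI"][k][()]))
                       for k in nirs["fnirsblockROI"]}

        montage = Montage(
            source_labels=src_labels,
            source_pos=src_pos,
            detector_labels=det_labels,
            detector_pos=det_pos,
            channels=channels,
            wavelengths=wavelengths,
            roi_map=roi_map,
        )

        stim_names = sorted(
            (k for k in nirs if k.startswith("stim")),
            key=lambda k: int(k[len("stim"):]),
        )
        rows = []
        for name in stim_names:
            stim = nirs[name]
            cond = _decode(stim["name"])
            arr = np.atleast_2d(np.asarray(stim["data"], dtype=float))
            for onset, dur, *_ in arr:
                rows.append((onset, dur, cond))
        if rows:
            rows.sort(key=lambda r: r[0])
            events = EventSchedule(
                np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows], dtype=object),
            )
        else:
            warnings.warn(f"{path}: no stimulus block; events are empty", stacklevel=2)
            events = EventSchedule.empty()

    return Recording(
        data=ts[row_order],
        sfreq=sfreq,
        unit=Unit.RAW_INTENSITY,
        montage=montage,
        events=events,
    )


# --------------------------------------------------------------------------
# CSV fixture dialect
# --------------------------------------------------------------------------

def write_csv_recording(rec: Recording, path, events_path=None) -> None:
    """Write the wide-CSV fixture dialect (events in a sidecar TSV)."""
    m = rec.montage
    cols = {"time_s": rec.times}
    for row in range(rec.data.shape[0]):
        ch = rec.row_channel(row)
        s, d = m.channels[ch]
        wl = m.wavelengths[row % 2]
        si = m.source_labels.index(s) + 1
        di = m.detector_labels.index(d) + 1
        cols[f"S{si}_D{di}_{wl:g}nm"] = rec.data[row]
    pd.DataFrame(cols).to_csv(path, index=False)
    if events_path is not None:
        rec.events.to_frame().to_csv(events_path, sep="\t", index=False)


def read_csv_recording(path, montage: Montage, events_path=None) -> Recording:
    """Read the wide-CSV dialect back against a known montage."""
    df = pd.read_csv(path)
    time = df["time_s"].to_numpy()
    sfreq = 1.0 / float(np.median(np.diff(time))) if len(time) > 1 else 1.0
    rows = []
    for ch in range(montage.n_channels):
        s, d = montage.channels[ch]
        si = montage.source_labels.index(s) + 1
        di = montage.detector_labels.index(d) + 1
        for wl in montage.wavelengths:
            rows.append(df[f"S{si}_D{di}_{wl:g}nm"].to_numpy())
    if events_path is not None and Path(events_path).exists():
        ev = pd.read_csv(events_path, sep="\t")
        events = EventSchedule(
            ev["onset_s"].to_numpy(),
            ev["duration_s"].to_numpy(),
            ev["condition"].to_numpy(dtype=object),
        )
    else:
        events = EventSchedule.empty()
    return Recording(
        data=np.array(rows), sfreq=sfreq, unit=Unit.RAW_INTENSITY,
        montage=montage, events=events,
    )
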