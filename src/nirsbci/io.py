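"""Recordings, event schedules and machine-readable reports.

A :class:`Recording` is a dense time x channel matrix with a sampling rate
and a chromophore tag — either hemoglobin concentration changes (µM) already
converted from optics, or raw absorbance change at two wavelengths awaiting
conversion. An :class:`EventSchedule` lists task onsets/durations/labels in
seconds from the start of the recording.

Two on-disk formats are supported: a minimal-profile SNIRF (HDF5) with a
single continuous-wave or processed-concentration data block, and plain
delimited matrices (header row of channel ids) with a JSON sidecar carrying
the sampling rate and chromophore. All times are seconds from recording
start, sample indices are 0-based, and windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventSchedule",
    "load_recording",
    "load_events",
    "save_recording",
    "save_events",
    "write_report",
]

#: chromophore tags a Recording may carry
CHROMOPHORES = ("HbO", "HbR", "absorbance", "intensity")


class DataError(ValueError):
    """Raised for corrupt or inconsistent data files."""


@dataclass(frozen=True)
class Recording:
    """Dense multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Chromophore concentration change (µM) or raw absorbance change /
        intensity (a.u.). For dual-wavelength raw data the columns are
        ordered wavelength-major: all channels at ``wavelengths[0]`` first,
        then all channels at ``wavelengths[1]``.
    fs : float
        Sampling frequency in Hz.
    chromophore : str
        One of ``HbO``, ``HbR``, ``absorbance``, ``intensity``.
    channel_ids : tuple of str
        Ordered channel labels, one per data column.
    wavelengths : tuple of float, optional
        Wavelengths in nm (raw data only).
    montage : ndarray, shape (n_channels, 2), optional
        2-D channel coordinates in head-schematic units.
    """

    data: np.ndarray
    fs: float
    chromophore: str
    channel_ids: tuple[str, ...]
    wavelengths: tuple[float, ...] | None = None
    montage: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D time x channel, got shape {data.shape}")
        if data.shape[0] < 2 or data.shape[1] < 1:
            raise ValueError("recording needs >=2 samples and >=1 channel")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.chromophore not in CHROMOPHORES:
            raise ValueError(f"unknown chromophore {self.chromophore!r}")
        if len(self.channel_ids) != data.shape[1]:
            raise ValueError(
                f"{len(self.channel_ids)} channel_ids for {data.shape[1]} columns"
            )
        if np.isnan(data).any():
            bad = [
                self.channel_ids[i]
                for i in np.unique(np.nonzero(np.isnan(data))[1])
            ]
            raise DataError(f"NaN values in channel(s): {', '.join(bad)}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))
        if self.wavelengths is not None:
            object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        if self.montage is not None:
            m = np.asarray(self.montage, dtype=float)
            if m.shape != (data.shape[1], 2):
                raise ValueError("montage must be (n_channels, 2)")
            object.__setattr__(self, "montage", m)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray, chromophore: str | None = None) -> "Recording":
        """Copy carrying new data (same shape contract re-validated)."""
        return replace(
            self, data=data, chromophore=chromophore or self.chromophore
        )

    def subset(self, mask_or_idx) -> "Recording":
        """Channel-subset copy preserving order."""
        idx = np.arange(self.n_channels)[mask_or_idx]
        return replace(
            self,
            data=self.data[:, idx],
            channel_ids=tuple(self.channel_ids[i] for i in idx),
            montage=None if self.montage is None else self.montage[idx],
        )


@dataclass(frozen=True)
class EventSchedule:
    """Task onsets/durations/labels in seconds from recording start."""

    onsets: np.ndarray
    durations: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if onsets.shape != durations.shape or onsets.ndim != 1:
            raise ValueError("onsets and durations must be equal-length 1-D")
        if len(self.labels) != onsets.size:
            raise ValueError("one label per event required")
        if onsets.size:
            if np.any(durations <= 0):
                raise ValueError("durations must be positive")
            order = np.argsort(onsets, kind="stable")
            onsets = onsets[order]
            durations = durations[order]
            labels = tuple(self.labels[i] for i in order)
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if np.any(onsets[:-1] + durations[:-1] > onsets[1:]):
                raise ValueError("task intervals overlap")
            object.__setattr__(self, "labels", labels)
        else:
            object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def end(self) -> float:
        """End time of the last event (0 for an empty schedule)."""
        if not len(self):
            return 0.0
        return float((self.onsets + self.durations).max())

    def select(self, label: str) -> "EventSchedule":
        keep = [i for i, lab in enumerate(self.labels) if lab == label]
        return EventSchedule(
            self.onsets[keep], self.durations[keep], tuple(self.labels[i] for i in keep)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset": self.onsets, "duration": self.durations, "label": list(self.labels)}
        )


# ---------------------------------------------------------------------------
# SNIRF (minimal profile)
# ---------------------------------------------------------------------------

_SNIRF_CW = 1          # continuous-wave amplitude
_SNIRF_PROCESSED = 99999

_CHROMO_TO_LABEL = {"HbO": "HbO", "HbR": "HbR"}


def save_recording(rec: Recording, path, events: EventSchedule | None = None) -> None:
    """Write a Recording (and optional events) to disk.

    ``.snirf`` suffix selects minimal-profile SNIRF; anything else writes a
    delimited matrix with header row plus a ``<path>.meta.json`` sidecar
    (and ``<path>.events.tsv`` when events are given).
    """
    path = Path(path)
    if path.suffix == ".snirf":
        _write_snirf(rec, path, events)
    else:
        _write_delimited(rec, path, events)


def load_recording(path, format: str | None = None) -> Recording:
    """Read a Recording from SNIRF or a delimited matrix with sidecar.

    Parameters
    ----------
    path : path-like
    format : {'snirf', 'delimited'}, optional
        Inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "snirf" if path.suffix == ".snirf" else "delimited"
    if format == "snirf":
        return _read_snirf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {format!r}")


def _write_snirf(rec: Recording, path: Path, events: EventSchedule | None) -> None:
    str_t = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=str_t)
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=rec.data)
        d1.create_dataset("time", data=rec.times)
        probe = nirs.create_group("probe")
        wls = rec.wavelengths or (760.0, 850.0)
        probe.create_dataset("wavelengths", data=np.asarray(wls, dtype=float))
        if rec.montage is not None:
            # channel positions stored as sourcePos2D with 1:1 source:channel
            pos = np.column_stack([rec.montage, np.zeros(rec.n_channels)])
            probe.create_dataset("sourcePos3D", data=pos)
        n_ch = rec.n_channels
        raw = rec.chromophore in ("absorbance", "intensity")
        n_phys = n_ch // 2 if raw else n_ch
        for i in range(n_ch):
            ml = d1.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=(i % n_phys) + 1)
            ml.create_dataset("detectorIndex", data=(i % n_phys) + 1)
            ml.create_dataset("wavelengthIndex", data=(i // n_phys) + 1 if raw else 1)
            if raw:
                ml.create_dataset("dataType", data=_SNIRF_CW)
            else:
                ml.create_dataset("dataType", data=_SNIRF_PROCESSED)
                ml.create_dataset(
                    "dataTypeLabel", data=_CHROMO_TO_LABEL[rec.chromophore], dtype=str_t
                )
            ml.create_dataset("channelLabel", data=rec.channel_ids[i], dtype=str_t)
        if events is not None and len(events):
            by_label: dict[str, list[int]] = {}
            for i, lab in enumerate(events.labels):
                by_label.setdefault(lab, []).append(i)
            for s, (lab, idx) in enumerate(by_label.items(), start=1):
                g = nirs.create_group(f"stim{s}")
                g.create_dataset("name", data=lab, dtype=str_t)
                g.create_dataset(
                    "data",
                    data=np.column_stack(
                        [events.onsets[idx], events.durations[idx], np.ones(len(idx))]
                    ),
                )


def _read_snirf(path: Path) -> Recording:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DataError(f"cannot open {path} as HDF5/SNIRF: {exc}") from exc
    with f:
        if "nirs" not in f:
            raise DataError("not a SNIRF file: missing /nirs group")
        nirs = f["nirs"]
        blocks = [k for k in nirs if k.startswith("data")]
        if len(blocks) != 1:
            raise DataError(
                f"minimal SNIRF profile supports exactly one data block, found {len(blocks)}"
            )
        d1 = nirs[blocks[0]]
        data = np.asarray(d1["dataTimeSeries"], dtype=float)
        time = np.asarray(d1["time"], dtype=float)
        if time.size >= 2:
            fs = 1.0 / float(np.mean(np.diff(time)))
        else:
            raise DataError("SNIRF time vector too short to infer sampling rate")
        mls = sorted(
            (k for k in d1 if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if len(mls) != data.shape[1]:
            raise DataError("measurementList count does not match data columns")
        dtypes = {int(np.asarray(d1[k]["dataType"])) for k in mls}
        if len(dtypes) != 1:
            raise DataError("mixed dataType blocks not supported (minimal profile)")
        (dtype,) = dtypes
        if dtype == _SNIRF_CW:
            chromo = "intensity"
        elif dtype == _SNIRF_PROCESSED:
            labels = {
                _decode(np.asarray(d1[k]["dataTypeLabel"])) for k in mls if "dataTypeLabel" in d1[k]
            }
            if len(labels) != 1 or not (labels & {"HbO", "HbR"}):
                raise DataError(f"unsupported processed dataTypeLabel set {labels}")
            chromo = labels.pop()
        else:
            raise DataError(f"unsupported SNIRF dataType {dtype} (minimal profile)")
        ids = []
        for i, k in enumerate(mls):
            if "channelLabel" in d1[k]:
                ids.append(_decode(np.asarray(d1[k]["channelLabel"])))
            else:
                s = int(np.asarray(d1[k]["sourceIndex"]))
                d = int(np.asarray(d1[k]["detectorIndex"]))
                ids.append(f"S{s}-D{d}")
        wls = None
        if "probe" in nirs and "wavelengths" in nirs["probe"]:
            wls = tuple(np.asarray(nirs["probe"]["wavelengths"], dtype=float))
    return Recording(data=data, fs=fs, chromophore=chromo, channel_ids=tuple(ids), wavelengths=wls)


def _decode(x) -> str:
    v = x[()] if getattr(x, "shape", None) == () else x
    if isinstance(v, bytes):
        return v.decode()
    return str(v)


# ---------------------------------------------------------------------------
# Delimited matrices + sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _write_delimited(rec: Recording, path: Path, events: EventSchedule | None) -> None:
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    # %.17g round-trips doubles exactly; pandas' default formatter does not
    pd.DataFrame(rec.data, columns=list(rec.channel_ids)).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )
    meta = {"fs": rec.fs, "chromophore": rec.chromophore}
    if rec.wavelengths is not None:
        meta["wavelengths"] = list(rec.wavelengths)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    if events is not None:
        save_events(events, path.with_name(path.stem + ".events.tsv"))


def _read_delimited(path: Path) -> Recording:
    side = _sidecar(path)
    if not side.exists():
        raise DataError(f"delimited recording requires sidecar {side.name}")
    meta = json.loads(side.read_text())
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as load error
        raise DataError(f"cannot parse {path}: {exc}") from exc
    return Recording(
        data=df.to_numpy(dtype=float),
        fs=float(meta["fs"]),
        chromophore=meta["chromophore"],
        channel_ids=tuple(str(c) for c in df.columns),
        wavelengths=tuple(meta["wavelengths"]) if "wavelengths" in meta else None,
    )


def save_events(events: EventSchedule, path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def load_events(path) -> EventSchedule:
    """Read an event table (TSV/CSV with onset, duration, label columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = {"onset", "duration", "label"} - set(df.columns)
    if missing:
        raise DataError(f"events table missing column(s): {sorted(missing)}")
    return EventSchedule(
        onsets=df["onset"].to_numpy(dtype=float),
        durations=df["duration"].to_numpy(dtype=float),
        labels=tuple(str(x) for x in df["label"]),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if np.isnan(v):
            return None
        if np.isinf(v):
            return "inf" if v > 0 else "-inf"
        return v
    return obj


def write_report(result, path) -> None:
    """Serialize a result object to a byte-stable JSON document.

    ``result`` is any object with a ``to_report()`` method (selection
    results, evaluation reports) or a plain mapping.
    """
    payload = result.to_report() if hasattr(result, "to_report") else result
    if not isinstance(payload, dict):
        raise TypeError("report payload must be a mapping")
    text = json.dumps(_jsonable(payload), indent=1, sort_keys=True)
    Path(path).write_text(text + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
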