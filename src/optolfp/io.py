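"""Session file formats: flat binary or HDF5 plus a JSON sidecar.

Flat binary: little-endian float32, sample-major channel-interleaved
(s0c0, s0c1, s1c0, ...), with a versioned JSON sidecar carrying subject,
gain, sampling rate, trial length, event sample indices and per-event
condition labels.  HDF5 stores the same content in one container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import SessionRecording, StimCondition

SCHEMA_VERSION = 1

_SIDECAR_REQUIRED = (
    "schema_version",
    "subject_id",
    "gain_factor",
    "sampling_rate_Hz",
    "trial_length_s",
    "n_channels",
    "n_samples",
    "events",
    "conditions",
)


def _conditions_to_json(conditions: list[StimCondition]) -> list[dict]:
    return [
        {"duration_ms": c.duration_ms, "intensity_mW": c.intensity_mW}
        for c in conditions
    ]


def _conditions_from_json(items: list[dict]) -> list[StimCondition]:
    return [StimCondition(c["duration_ms"], c["intensity_mW"]) for c in items]


def write_session(session: SessionRecording, path: str | Path) -> Path:
    """Write a session; format chosen by suffix (.h5/.hdf5 -> HDF5, else binary).

    For the binary format, `path` names the .bin file and the sidecar is
    written next to it with a .json suffix.  Returns the primary path.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _write_hdf5(session, path)
    return _write_binary(session, path)


def _write_binary(session: SessionRecording, path: Path) -> Path:
    if path.suffix != ".bin":
        path = path.with_suffix(".bin")
    interleaved = np.ascontiguousarray(session.channels.T, dtype="<f4")
    interleaved.tofile(path)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": session.subject_id,
        "gain_factor": int(session.gain_factor),
        "sampling_rate_Hz": session.sampling_rate_Hz,
        "trial_length_s": session.trial_length_s,
        "n_channels": 2,
        "n_samples": int(session.n_samples),
        "dtype": "<f4",
        "layout": "sample-major-interleaved",
        "data_file": path.name,
        "events": [int(e) for e in session.events],
        "conditions": _conditions_to_json(session.conditions),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _write_hdf5(session: SessionRecording, path: Path) -> Path:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subject_id"] = session.subject_id
        f.attrs["gain_factor"] = int(session.gain_factor)
        f.attrs["sampling_rate_Hz"] = session.sampling_rate_Hz
        f.attrs["trial_length_s"] = session.trial_length_s
        f.create_dataset("channels", data=session.channels.astype("<f4"))
        f.create_dataset("events", data=session.events)
        cond = np.array(
            [(c.duration_ms, c.intensity_mW) for c in session.conditions]
        )
        f.create_dataset("conditions", data=cond)
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read a session written by write_session; validates schema and shapes."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    return _read_binary(path)


def _read_binary(path: Path) -> SessionRecording:
    if path.suffix == ".json":
        sidecar_path = path
    else:
        sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in sidecar:
            raise ValueError(f"sidecar {sidecar_path.name} missing field {key!r}")
    if sidecar["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"sidecar schema version {sidecar['schema_version']} != "
            f"supported version {SCHEMA_VERSION}"
        )
    data_path = sidecar_path.with_name(sidecar.get("data_file", path.name))
    raw = np.fromfile(data_path, dtype=sidecar.get("dtype", "<f4"))
    n_ch = sidecar["n_channels"]
    n_samples = sidecar["n_samples"]
    if raw.size != n_ch * n_samples:
        raise ValueError(
            f"binary length mismatch: {raw.size} values, expected "
            f"{n_ch} x {n_samples}"
        )
    channels = raw.reshape(n_samples, n_ch).T.astype(float)
    return SessionRecording(
        subject_id=sidecar["subject_id"],
        channels=channels,
        sampling_rate_Hz=sidecar["sampling_rate_Hz"],
        gain_factor=sidecar["gain_factor"],
        events=np.asarray(sidecar["events"], dtype=np.int64),
        conditions=_conditions_from_json(sidecar["conditions"]),
        trial_length_s=sidecar["trial_length_s"],
    )


def _read_hdf5(path: Path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"HDF5 schema version {version} != supported {SCHEMA_VERSION}"
            )
        for key in ("subject_id", "gain_factor", "sampling_rate_Hz", "trial_length_s"):
            if key not in f.attrs:
                raise ValueError(f"HDF5 file missing attribute {key!r}")
        cond = f["conditions"][()]
        return SessionRecording(
            subject_id=str(f.attrs["subject_id"]),
            channels=f["channels"][()].astype(float),
            sampling_rate_Hz=float(f.attrs["sampling_rate_Hz"]),
            gain_factor=int(f.attrs["gain_factor"]),
            events=f["events"][()].astype(np.int64),
            conditions=[StimCondition(d, i) for d, i in cond],
            trial_length_s=float(f.attrs["trial_length_s"]),
        )
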