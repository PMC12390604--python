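"""Recording storage: a plain-CSV form and an HDF5 container form.

Two interchangeable layouts carry the same data:

* CSV directory -- one file per channel named
  ``sub<subject>_<muscle>_<modality>.csv`` with header ``time_s,value`` and a
  sidecar ``...meta.json`` holding subject, muscle, modality, sampling rate
  and units.  Human-auditable; the timestamps are advisory (time is sample
  index / fs; fs always comes from metadata, never from timestamps).
* HDF5 container -- datasets at ``/sub<subject>/<muscle>/<modality>`` with the
  same metadata as attributes, plus file-level ``seed`` and ``config_hash``.

A write-then-read round trip reproduces samples bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .simulate import RawRecording

__all__ = ["write_recordings", "read_recordings"]


def _channel_stem(rec: RawRecording) -> str:
    return f"sub{rec.subject_id:03d}_{rec.muscle_id}_{rec.modality}"


def _meta(rec: RawRecording) -> dict:
    return {
        "subject_id": rec.subject_id,
        "muscle_id": rec.muscle_id,
        "modality": rec.modality,
        "fs": rec.fs,
        "units": rec.units,
        "n_samples": len(rec.samples),
    }


def write_recordings(
    path: str | Path,
    recordings: list[RawRecording],
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write recordings as a CSV directory or (``.h5``/``.hdf5`` suffix) container."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            if seed is not None:
                fh.attrs["seed"] = seed
            if config_hash is not None:
                fh.attrs["config_hash"] = config_hash
            for rec in recordings:
                ds = fh.create_dataset(
                    f"sub{rec.subject_id:03d}/{rec.muscle_id}/{rec.modality}",
                    data=rec.samples,
                )
                for k, v in _meta(rec).items():
                    ds.attrs[k] = v
        return path
    path.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        stem = _channel_stem(rec)
        t = np.arange(len(rec.samples)) / rec.fs
        np.savetxt(
            path / f"{stem}.csv",
            np.column_stack([t, rec.samples]),
            delimiter=",",
            header="time_s,value",
            comments="",
            fmt=["%.10g", "%.17g"],
        )
        (path / f"{stem}.meta.json").write_text(json.dumps(_meta(rec), sort_keys=True, indent=1))
    if seed is not None or config_hash is not None:
        (path / "store.meta.json").write_text(
            json.dumps({"seed": seed, "config_hash": config_hash}, sort_keys=True)
        )
    return path


def _validate(rec: RawRecording, origin: str) -> RawRecording:
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError(f"NaN/Inf samples in channel {origin}")
    return rec


def _read_csv_channel(csv_path: Path) -> RawRecording:
    meta_path = csv_path.with_name(csv_path.stem + ".meta.json")
    if not meta_path.exists():
        raise ValueError(f"missing metadata sidecar for channel file {csv_path.name}")
    meta = json.loads(meta_path.read_text())
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    t, values = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if len(dt) and (np.max(dt) - np.min(dt)) > 1e-6 * np.median(dt) + 1e-12:
        raise ValueError(f"non-uniform sampling in channel {csv_path.stem}")
    try:
        rec = RawRecording(
            subject_id=int(meta["subject_id"]),
            muscle_id=meta["muscle_id"],
            modality=meta["modality"],
            fs=float(meta["fs"]),
            samples=values,
            units=meta.get("units", "a.u."),
        )
    except ValueError as exc:
        raise ValueError(f"channel {csv_path.stem}: {exc}") from exc
    return _validate(rec, csv_path.stem)


def read_recordings(path: str | Path) -> list[RawRecording]:
    """Read a recording collection from either storage form.

    Sampling rates come from metadata, never from timestamps.  Missing
    metadata, non-uniform sampling or non-finite samples are rejected with the
    offending channel named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    recordings: list[RawRecording] = []
    if path.is_dir():
        for csv_path in sorted(path.glob("sub*_*.csv")):
            recordings.append(_read_csv_channel(csv_path))
    else:
        with h5py.File(path, "r") as fh:
            def visit(name, obj):
                if isinstance(obj, h5py.Dataset):
                    a = obj.attrs
                    for key in ("subject_id", "muscle_id", "modality", "fs"):
                        if key not in a:
                            raise ValueError(f"missing metadata {key!r} on channel {name}")
                    try:
                        rec = RawRecording(
                            subject_id=int(a["subject_id"]),
                            muscle_id=str(a["muscle_id"]),
                            modality=str(a["modality"]),
                            fs=float(a["fs"]),
                            samples=obj[()],
                            units=str(a.get("units", "a.u.")),
                        )
                    except ValueError as exc:
                        raise ValueError(f"channel {name}: {exc}") from exc
                    recordings.append(_validate(rec, name))

            fh.visititems(visit)
    if not recordings:
        raise ValueError(f"no channels found under {path}")
    recordings.sort(key=lambda r: (r.subject_id, r.modality, r.muscle_id))
    return recordings
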