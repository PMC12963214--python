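"""Read/write NIfTI spectral volumes, thermocouple CSV logs and YAML manifests.

Filename convention for volumes: ``sub-<s>_scan-<t>_<channel>.nii.gz`` with
channel one of ``vmi70 | hu | zeff | edw``. The channel tag lives in the
filename rather than a NIfTI header extension for portability.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import Channel, SpectralVolume, ThermocoupleTrack

_FNAME_RE = re.compile(r"sub-(?P<sub>[^_]+)_scan-(?P<scan>\d+)_(?P<channel>[a-z0-9]+)\.nii(\.gz)?$")

THERMOLOG_COLUMNS = ["sensor_id", "time_s", "temp_c"]


def volume_filename(subject, scan_index: int, channel: Channel) -> str:
    return f"sub-{subject}_scan-{scan_index:02d}_{Channel(channel).value}.nii.gz"


def parse_volume_filename(name: str) -> dict:
    m = _FNAME_RE.search(Path(name).name)
    if m is None:
        raise ValueError(f"filename {name!r} does not match sub-<s>_scan-<t>_<channel>.nii[.gz]")
    return {
        "subject": m.group("sub"),
        "scan_index": int(m.group("scan")),
        "channel": Channel(m.group("channel")),
    }


def write_volume(volume: SpectralVolume, path) -> Path:
    """Write a SpectralVolume as NIfTI-1; geometry goes into the affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    img.header.set_zooms(volume.spacing)
    # acquisition time stashed in the header's toffset field (seconds)
    img.header["toffset"] = volume.scan_time_s
    nib.save(img, str(path))
    return path


def read_volume(path, channel: Channel | None = None,
                scan_index: int | None = None,
                scan_time_s: float | None = None) -> SpectralVolume:
    """Read a NIfTI-1 file into a SpectralVolume.

    Channel and scan index are taken from the filename when it follows the
    naming convention; pass them explicitly otherwise. Rejects non-3D data
    and non-positive spacing rather than silently defaulting geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"{path} is not a readable NIfTI-1 file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    if channel is None or scan_index is None:
        meta = parse_volume_filename(path.name)
        channel = channel or meta["channel"]
        scan_index = meta["scan_index"] if scan_index is None else scan_index
    if scan_time_s is None:
        scan_time_s = float(img.header["toffset"])
    return SpectralVolume(
        channel=channel,
        data=data,
        spacing=tuple(float(z) for z in zooms),
        origin=tuple(origin),
        scan_index=int(scan_index),
        scan_time_s=scan_time_s,
    )


def write_thermolog(tracks, path) -> Path:
    """Write thermocouple tracks to CSV (``sensor_id,time_s,temp_c``).

    Values are written with Python's shortest round-trip float repr so a
    read-back reproduces them exactly.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(THERMOLOG_COLUMNS)
        for tr in tracks:
            for t, temp in zip(tr.times_s, tr.temps_c):
                w.writerow([tr.sensor_id, repr(float(t)), repr(float(temp))])
    return path


def read_thermolog(path, tip_positions: dict | None = None) -> list[ThermocoupleTrack]:
    """Read a thermocouple CSV log into tracks (one per sensor id).

    ``tip_positions`` maps sensor id -> (x, y, z) mm; sensors absent from the
    mapping get a NaN tip (statistics-only use). Track invariants (strictly
    increasing times, temperature sanity bounds) are enforced on load.
    """
    path = Path(path)
    rows: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header {THERMOLOG_COLUMNS}")
        if [h.strip() for h in header] != THERMOLOG_COLUMNS:
            raise ValueError(
                f"{path}: bad header {header!r}, expected {THERMOLOG_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            sid = row[0]
            try:
                t, temp = float(row[1]), float(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row {row!r}") from exc
            rows.setdefault(sid, []).append((t, temp))
    tracks = []
    tip_positions = tip_positions or {}
    for sid in rows:
        arr = np.asarray(rows[sid], dtype=float)
        tip = tip_positions.get(sid, np.full(3, np.nan))
        tracks.append(
            ThermocoupleTrack(sensor_id=sid, tip_mm=tip, times_s=arr[:, 0], temps_c=arr[:, 1])
        )
    return tracks


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
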