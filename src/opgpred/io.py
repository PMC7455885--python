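"""On-disk formats: NIfTI volumes/masks, line-set JSON streamlines, CSV tables.

Volumes and masks are NIfTI-1 (.nii.gz), one file per modality per
scan, RAS orientation with the spacing on the affine diagonal.
Streamlines use a small documented JSON dialect::

    {"format": "lineset-json/1", "space": "world_mm",
     "lines": [[[x, y, z], ...], ...]}

Clinical records are CSV with columns subject_id, scan_id, time_years,
logmar_od, logmar_os, radiographic_progression (0/1). Feature tables
round-trip to CSV with a sidecar JSON schema (column names, scheme,
config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .cohort import ClinicalRecord
from .features import FeatureTable
from .geometry import RegionMask, StreamlineSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_streamlines",
    "load_streamlines",
    "write_clinical_csv",
    "read_clinical_csv",
    "write_feature_table",
    "read_feature_table",
    "config_hash",
]


def _affine(spacing_mm) -> np.ndarray:
    return np.diag([*spacing_mm, 1.0])


def save_volume(volume: np.ndarray, spacing_mm, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(spacing_mm))
    nib.save(img, str(path))


def load_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float32), spacing


def save_mask(mask: RegionMask, path: Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing_mm))
    nib.save(img, str(path))


def load_mask(path: Path, label: str) -> RegionMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj)
    return RegionMask(mask=data > 0, label=label, spacing_mm=spacing)


def save_streamlines(lines: StreamlineSet, path: Path) -> None:
    payload = {
        "format": "lineset-json/1",
        "space": "world_mm",
        "lines": [np.asarray(ln).round(4).tolist() for ln in lines],
    }
    Path(path).write_text(json.dumps(payload))


def load_streamlines(path: Path) -> StreamlineSet:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "lineset-json/1":
        raise ValueError(f"{path}: not a lineset-json/1 file")
    return StreamlineSet([np.asarray(ln, dtype=float) for ln in payload["lines"]])


# ---------------------------------------------------------------------------
# clinical records


def write_clinical_csv(subjects, path: Path) -> None:
    """Flatten per-subject VA series and scan flags into the clinical CSV."""
    rows = []
    for subj in subjects:
        for k, scan in enumerate(subj.scans):
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "scan_id": k,
                    "time_years": round(scan.time_years, 4),
                    "logmar_od": subj.va_series["od"][k][1],
                    "logmar_os": subj.va_series["os"][k][1],
                    "radiographic_progression": int(subj.radiographic_flags[k]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical_csv(path: Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    records = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("time_years")
        records.append(
            ClinicalRecord(
                subject_id=str(sid),
                va_series={
                    "od": list(zip(g["time_years"], g["logmar_od"])),
                    "os": list(zip(g["time_years"], g["logmar_os"])),
                },
                radiographic_flags=[bool(v) for v in g["radiographic_progression"]],
            )
        )
    return records


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(table: FeatureTable, csv_path: Path, config: dict | None = None) -> None:
    csv_path = Path(csv_path)
    table.to_csv(csv_path)
    schema = {
        "scheme": table.scheme,
        "columns": table.columns,
        "n_rows": len(table.data),
        "labels_present": table.labels is not None,
        "package_version": __version__,
        "config_hash": config_hash(config) if config is not None else None,
    }
    csv_path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))


def read_feature_table(csv_path: Path, labels_by_subject: dict[str, str] | None = None) -> FeatureTable:
    csv_path = Path(csv_path)
    schema = json.loads(csv_path.with_suffix(".schema.json").read_text())
    df = pd.read_csv(csv_path, index_col="row_id")
    subject_ids = df.pop("subject_id").astype(str).tolist()
    labels = None
    if labels_by_subject is not None:
        labels = np.asarray([labels_by_subject[s] for s in subject_ids])
    return FeatureTable(
        data=df, scheme=schema["scheme"], subject_ids=subject_ids, labels=labels
    )


def config_hash(config) -> str:
    """Stable short hash of a config mapping or dataclass."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
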