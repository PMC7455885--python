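"""Per-region intensity features and static/dynamic feature tables.

Each (region, modality) pair yields min, max, mean, SD and K evenly
spaced distribution quantiles of the masked voxel intensities, after
linear histogram matching of every volume to a fixed per-modality
reference. Optic-nerve morphometry (volume, perimeter, thickness,
tortuosity) enters the table alongside the intensity block.

Static tables carry one row per scan. Dynamic tables carry one row per
subject: the base features of the index scan plus difference blocks
(later scan minus earlier scan) for either successive scan pairs
("dynamic 1") or all chronological pairs ("dynamic 2"). Scans are
labelled A, B, C, ... chronologically, so a delta block between the
first and second scan is named ``delta_B-A``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, EmptyRegionError, SchemaError
from .geometry import RegionMask, compute_morphology

__all__ = [
    "IntensityFeatures",
    "FeatureTable",
    "histogram_match",
    "extract_region_features",
    "scan_feature_vector",
    "assemble_static",
    "assemble_dynamic",
]

log = logging.getLogger(__name__)

MORPH_REGIONS = ("ON-L", "ON-R")  # optic-nerve masks get the morphometry block
DEFAULT_REGIONS = ("ON-L", "ON-R", "OR-L", "OR-R")


def _stat_names(n_quantiles: int) -> list[str]:
    # quantile grid k/K for k=1..K; K=10 gives deciles q10..q100 and keeps
    # the median (q50) on the grid for even K
    return ["min", "max", "mean", "sd"] + [
        f"q{round(100 * k / n_quantiles):02d}" for k in range(1, n_quantiles + 1)
    ]


def histogram_match(
    volume: np.ndarray,
    reference_volume: np.ndarray,
    outlier_low_pct: float = 1.0,
    outlier_high_pct: float = 99.0,
) -> np.ndarray:
    """Linear histogram matching after outlier exclusion.

    Voxels outside the source's [low, high] percentile band are treated
    as outliers and excluded from the fit: the affine map is determined
    entirely by the percentile pair, sending the source (P_low, P_high)
    onto the reference (P_low, P_high), and is then applied to every
    voxel (outliers included).
    """
    if not (0.0 <= outlier_low_pct < outlier_high_pct <= 100.0):
        raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
    src = np.asarray(volume, dtype=float)
    ref = np.asarray(reference_volume, dtype=float)
    if src.size == 0 or ref.size == 0:
        raise EmptyRegionError("histogram matching needs nonempty volumes")
    s_lo, s_hi = np.percentile(src, [outlier_low_pct, outlier_high_pct])
    r_lo, r_hi = np.percentile(ref, [outlier_low_pct, outlier_high_pct])
    if s_hi - s_lo <= 0:
        raise DegenerateScaleError("constant source volume: scale is undefined")
    slope = (r_hi - r_lo) / (s_hi - s_lo)
    return (src - s_lo) * slope + r_lo


@dataclass
class IntensityFeatures:
    """Per (region, modality) intensity summaries of one scan."""

    values: dict[tuple[str, str], dict[str, float]]
    n_quantiles: int

    def as_columns(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (region, modality), stats in self.values.items():
            for stat, v in stats.items():
                out[f"{region.replace('-', '_')}_{modality}_{stat}"] = v
        return out


def extract_region_features(
    scan, masks: Sequence[RegionMask], n_quantiles: int = 10
) -> IntensityFeatures:
    """Intensity distribution statistics inside each region, per modality.

    ``scan`` provides ``volumes``: a mapping modality -> 3D array. For
    every (region, modality) pair the masked voxel values yield min, max,
    mean, SD and ``n_quantiles`` evenly spaced quantiles (k/K grid).
    """
    qgrid = [k / n_quantiles for k in range(1, n_quantiles + 1)]
    names = _stat_names(n_quantiles)
    values: dict[tuple[str, str], dict[str, float]] = {}
    for region in masks:
        if not region.mask.any():
            raise EmptyRegionError(f"region {region.label!r} is empty")
        sel = region.mask
        for modality, vol in scan.volumes.items():
            v = np.asarray(vol)[sel].astype(float)
            qs = np.quantile(v, qgrid)
            stats = dict(
                zip(
                    names,
                    [float(v.min()), float(v.max()), float(v.mean()), float(v.std())]
                    + [float(q) for q in qs],
                )
            )
            values[(region.label, modality)] = stats
    return IntensityFeatures(values=values, n_quantiles=n_quantiles)


def scan_feature_vector(
    scan,
    masks: dict[str, RegionMask],
    n_quantiles: int = 10,
    regions: Sequence[str] = DEFAULT_REGIONS,
    morphology: bool = True,
    slice_axis: int = 2,
) -> dict[str, float]:
    """Full per-scan feature vector: intensity block plus ON morphometry."""
    intensity = extract_region_features(
        scan, [masks[r] for r in regions], n_quantiles=n_quantiles
    )
    out = intensity.as_columns()
    if morphology:
        for region in MORPH_REGIONS:
            if region not in masks:
                continue
            morph = compute_morphology(masks[region], slice_axis=slice_axis)
            prefix = region.replace("-", "_")
            for k, v in morph.as_dict().items():
                out[f"{prefix}_{k}"] = v
    return out


@dataclass
class FeatureTable:
    """Rows = subjects or scans, columns = named features.

    ``data`` is indexed by row id; ``subject_ids`` and ``labels`` (if
    known) align with the rows. ``scheme`` is one of ``static``,
    ``dynamic1``, ``dynamic2``.
    """

    data: pd.DataFrame
    scheme: str
    subject_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(c is None or c == "" for c in self.data.columns):
            raise SchemaError("feature table has unnamed columns")
        if len(self.subject_ids) != len(self.data):
            raise SchemaError("subject_ids must align with rows")
        if self.labels is not None and len(self.labels) != len(self.data):
            raise SchemaError("labels must align with rows")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        self.data.assign(subject_id=self.subject_ids).to_csv(path, index_label="row_id")


def _scan_letter(i: int) -> str:
    return chr(ord("A") + i)


def assemble_static(subjects: Sequence, n_quantiles: int = 10, **kwargs) -> FeatureTable:
    """One row per scan, columns = intensity + morphology features.

    Column order is fixed by the first scan's feature vector; any scan
    producing a different feature set raises :class:`SchemaError`.
    """
    rows: dict[str, dict[str, float]] = {}
    subject_ids: list[str] = []
    labels: list[str] = []
    columns: list[str] | None = None
    for subj in subjects:
        for i, scan in enumerate(subj.scans):
            vec = scan_feature_vector(scan, subj.masks[i], n_quantiles=n_quantiles, **kwargs)
            if columns is None:
                columns = list(vec)
            elif list(vec) != columns:
                raise SchemaError(
                    f"scan {subj.subject_id}:{_scan_letter(i)} yields a different feature set"
                )
            rows[f"{subj.subject_id}:{_scan_letter(i)}"] = vec
            subject_ids.append(subj.subject_id)
            labels.append(subj.group)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return FeatureTable(
        data=df, scheme="static", subject_ids=subject_ids, labels=np.asarray(labels)
    )


def assemble_dynamic(
    subjects: Sequence, scheme: str = "successive", n_quantiles: int = 10, **kwargs
) -> FeatureTable:
    """One row per subject: index-scan features plus delta blocks.

    ``scheme="successive"`` differences consecutive scan pairs only
    (s-1 blocks for s scans); ``scheme="all_pairs"`` differences every
    chronological pair (s(s-1)/2 blocks). Deltas are later minus
    earlier. Subjects with a single scan are excluded with a warning;
    included subjects must share one scan count so rows share a schema.
    """
    if scheme not in ("successive", "all_pairs"):
        raise ValueError(f"unknown dynamic scheme {scheme!r}")
    included = []
    for subj in subjects:
        if len(subj.scans) < 2:
            log.warning(
                "subject %s has %d scan(s); excluded from dynamic analysis",
                subj.subject_id,
                len(subj.scans),
            )
            continue
        included.append(subj)
    if not included:
        raise SchemaError("no subject has >= 2 scans; dynamic table is empty")
    counts = {len(s.scans) for s in included}
    if len(counts) > 1:
        raise SchemaError(
            f"dynamic tables need a uniform scan count per subject, got {sorted(counts)}"
        )
    s = counts.pop()
    if scheme == "successive":
        pairs = [(k, k + 1) for k in range(s - 1)]
    else:
        pairs = list(itertools.combinations(range(s), 2))

    rows: dict[str, dict[str, float]] = {}
    subject_ids, labels = [], []
    columns: list[str] | None = None
    for subj in included:
        vecs = [
            scan_feature_vector(scan, subj.masks[i], n_quantiles=n_quantiles, **kwargs)
            for i, scan in enumerate(subj.scans)
        ]
        base = vecs[-1]  # index scan (chronologically last)
        row = dict(base)
        for a, b in pairs:
            tag = f"delta_{_scan_letter(b)}-{_scan_letter(a)}"
            for col in base:
                row[f"{tag}_{col}"] = vecs[b][col] - vecs[a][col]
        if columns is None:
            columns = list(row)
        elif list(row) != columns:
            raise SchemaError(f"subject {subj.subject_id} yields a different feature set")
        rows[subj.subject_id] = row
        subject_ids.append(subj.subject_id)
        labels.append(subj.group)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    scheme_name = "dynamic1" if scheme == "successive" else "dynamic2"
    return FeatureTable(
        data=df, scheme=scheme_name, subject_ids=subject_ids, labels=np.asarray(labels)
    )


def n_delta_blocks(n_scans: int, scheme: str) -> int:
    """Delta-block count for a subject with ``n_scans`` chronological scans."""
    if scheme in ("successive", "dynamic1"):
        return n_scans - 1
    if scheme in ("all_pairs", "dynamic2"):
        return n_scans * (n_scans - 1) // 2
    raise ValueError(f"unknown dynamic scheme {scheme!r}")
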