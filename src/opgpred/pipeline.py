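"""End-to-end orchestration: generate -> label/select -> extract -> train.

``run_pipeline`` executes the whole study on a synthetic cohort and
writes inspectable, diffable artifacts: the echoed config, the cohort
manifest (labels, reasons, selected scans), feature CSVs for the
static/dynamic schemes, one model report per scheme with its ROC
curve, and a run log. Identical config + seed gives byte-identical
CSV/JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .cohort import apply_exclusions, label_progression, select_scans
from .errors import ConfigurationError, OpgPredError
from .features import assemble_dynamic, assemble_static, histogram_match
from .synthetic import (
    MODALITIES,
    CohortConfig,
    MultimodalScan,
    SyntheticSubject,
    generate_cohort,
)
from .model import cross_validate

__all__ = ["RunConfig", "run_pipeline", "simulate_to_disk", "load_cohort", "validate_inputs"]

log = logging.getLogger(__name__)

_COMPLETE_MARKER = "RUN_COMPLETE"


@dataclass
class RunConfig:
    """Full pipeline configuration; the seed governs every random draw."""

    outdir: Path
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_quantiles: int = 10
    outlier_low_pct: float = 1.0
    outlier_high_pct: float = 99.0
    schemes: tuple[str, ...] = ("static", "dynamic1", "dynamic2")
    svm_c: float = 1.0
    max_features: int = 10
    prescreen: int = 25  # SFS candidate pool per fold (top-N by training AUC)
    seed: int | None = None
    overwrite: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.seed is not None:
            self.cohort = dataclasses.replace(self.cohort, seed=int(self.seed))
        self.seed = self.cohort.seed
        for s in self.schemes:
            if s not in ("static", "dynamic1", "dynamic2"):
                raise ConfigurationError(f"unknown scheme {s!r}")

    @classmethod
    def from_yaml(cls, path: Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw.setdefault("outdir", ".")
        if "schemes" in raw:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(cohort=cohort, **raw)


class StageError(OpgPredError):
    """A pipeline stage failed; the message names the stage and context."""


def _stage(name: str, fn, *args, **kwargs):
    try:
        log.info("stage %s", name)
        return fn(*args, **kwargs)
    except OpgPredError as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def _windowed(subjects: list[SyntheticSubject]) -> tuple[list[SyntheticSubject], list[dict]]:
    """Apply labeling, exclusion, and scan-window rules; build the manifest."""
    manifest = []
    kept_subjects = []
    for subj in subjects:
        record = io.ClinicalRecord(
            subject_id=subj.subject_id,
            va_series=subj.va_series,
            radiographic_flags=subj.radiographic_flags,
        )
        decision, why_excl = apply_exclusions(record)
        label, reason = label_progression(record)
        times = [s.time_years for s in subj.scans]
        sel = select_scans(times, label)
        manifest.append(
            {
                "subject_id": subj.subject_id,
                "group_truth": subj.group,
                "label": label,
                "label_reason": reason,
                "inclusion": decision,
                "inclusion_reason": why_excl,
                "selected_scans": sel,
                "scan_times_years": [round(t, 4) for t in times],
            }
        )
        if decision == "exclude" or not sel:
            continue
        kept_subjects.append(
            dataclasses.replace(
                subj,
                group="case" if label == "progression" else "control",
                scans=[subj.scans[i] for i in sel],
                masks=[subj.masks[i] for i in sel],
                streamlines=[subj.streamlines[i] for i in sel],
                radiographic_flags=[subj.radiographic_flags[i] for i in sel],
            )
        )
    return kept_subjects, manifest


def _match_cohort(subjects: list[SyntheticSubject], cfg: RunConfig) -> list[SyntheticSubject]:
    """Histogram-match every volume to a fixed per-modality reference.

    The reference is the first control subject's index scan (paper-silent
    choice; fixed per run so outputs are comparable across subjects).
    """
    ref_subj = next((s for s in subjects if s.group == "control"), subjects[0])
    reference = {m: ref_subj.scans[-1].volumes[m] for m in MODALITIES}
    out = []
    for subj in subjects:
        new_scans = []
        for scan in subj.scans:
            vols = {
                m: histogram_match(
                    scan.volumes[m],
                    reference[m],
                    cfg.outlier_low_pct,
                    cfg.outlier_high_pct,
                ).astype(np.float32)
                for m in MODALITIES
            }
            new_scans.append(
                MultimodalScan(
                    volumes=vols, spacing_mm=scan.spacing_mm, time_years=scan.time_years
                )
            )
        out.append(dataclasses.replace(subj, scans=new_scans))
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, "object"]:
    """Run every stage and write all artifacts; returns reports per scheme."""
    outdir = Path(cfg.outdir)
    marker = outdir / _COMPLETE_MARKER
    if marker.exists() and not cfg.overwrite:
        raise ConfigurationError(
            f"output directory {outdir} holds a completed run; pass overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(cfg.cohort)
    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump(
            {
                "cohort": dataclasses.asdict(cfg.cohort),
                "n_quantiles": cfg.n_quantiles,
                "outlier_percentiles": [cfg.outlier_low_pct, cfg.outlier_high_pct],
                "schemes": list(cfg.schemes),
                "svm_c": cfg.svm_c,
                "max_features": cfg.max_features,
                "resolved_seed": cfg.seed,
                "config_hash": chash,
                "package_version": __version__,
            },
            sort_keys=True,
        )
    )

    subjects = _stage("simulate", generate_cohort, cfg.cohort)
    kept, manifest = _stage("label", _windowed, subjects)
    (outdir / "cohort_manifest.json").write_text(
        json.dumps(
            {"config_hash": chash, "package_version": __version__, "subjects": manifest},
            indent=2,
        )
    )
    io.write_clinical_csv(subjects, outdir / "clinical.csv")
    matched = _stage("normalize", _match_cohort, kept, cfg)

    reports = {}
    meta = dataclasses.asdict(cfg.cohort)
    for scheme in cfg.schemes:
        if scheme == "static":
            table = _stage("extract:static", assemble_static, matched, cfg.n_quantiles)
        else:
            pair_scheme = "successive" if scheme == "dynamic1" else "all_pairs"
            table = _stage(
                f"extract:{scheme}", assemble_dynamic, matched, pair_scheme, cfg.n_quantiles
            )
        io.write_feature_table(table, outdir / f"features_{scheme}.csv", config=meta)
        report = _stage(
            f"train:{scheme}",
            cross_validate,
            table,
            seed=cfg.seed,
            C=cfg.svm_c,
            max_features=cfg.max_features,
            prescreen=cfg.prescreen,
        )
        report.metadata.update({"config_hash": chash, "package_version": __version__})
        (outdir / f"report_{scheme}.json").write_text(json.dumps(report.to_dict(), indent=2))
        pd.DataFrame(
            {
                "threshold": report.roc.thresholds,
                "sensitivity": report.roc.sensitivity,
                "specificity": report.roc.specificity,
            }
        ).to_csv(outdir / f"roc_{scheme}.csv", index=False)
        reports[scheme] = report
    marker.write_text("ok\n")
    return reports


# ---------------------------------------------------------------------------
# disk cohort layout (simulate/validate/extract subcommands)


def simulate_to_disk(cfg: CohortConfig, outdir: Path) -> list[SyntheticSubject]:
    """Write a generated cohort as NIfTI volumes/masks + JSON streamlines."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = generate_cohort(cfg)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cfg) | {"config_hash": io.config_hash(cfg)})
    )
    io.write_clinical_csv(subjects, outdir / "clinical.csv")
    for subj in subjects:
        sdir = outdir / "subjects" / subj.subject_id
        for k, scan in enumerate(subj.scans):
            scandir = sdir / f"scan{k}"
            scandir.mkdir(parents=True, exist_ok=True)
            for mod in MODALITIES:
                io.save_volume(scan.volumes[mod], scan.spacing_mm, scandir / f"{mod}.nii.gz")
            for lbl, m in subj.masks[k].items():
                io.save_mask(m, scandir / f"mask_{lbl}.nii.gz")
        io.save_streamlines(subj.streamlines[0], sdir / "streamlines.json")
    return subjects


def load_cohort(cohort_dir: Path, labels: dict[str, str] | None = None) -> list[SyntheticSubject]:
    """Read a simulated cohort back from disk (inverse of simulate_to_disk)."""
    cohort_dir = Path(cohort_dir)
    records = {r.subject_id: r for r in io.read_clinical_csv(cohort_dir / "clinical.csv")}
    subjects = []
    for sdir in sorted((cohort_dir / "subjects").iterdir()):
        sid = sdir.name
        rec = records[sid]
        scandirs = sorted(sdir.glob("scan*"))
        scans, masks = [], []
        for k, scandir in enumerate(scandirs):
            vols = {}
            spacing = None
            for mod in MODALITIES:
                vols[mod], spacing = io.load_volume(scandir / f"{mod}.nii.gz")
            t = rec.va_series["od"][k][0]
            scans.append(MultimodalScan(volumes=vols, spacing_mm=spacing, time_years=t))
            masks.append(
                {
                    lbl: io.load_mask(scandir / f"mask_{lbl}.nii.gz", lbl)
                    for lbl in ("ON-L", "ON-R", "OR-L", "OR-R")
                }
            )
        if labels is not None:
            group = "case" if labels[sid] == "progression" else "control"
        else:
            group = "case" if label_progression(rec)[0] == "progression" else "control"
        streamset = io.load_streamlines(sdir / "streamlines.json")
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                group=group,
                scans=scans,
                masks=masks,
                streamlines=[streamset] * len(scans),
                va_series=rec.va_series,
                radiographic_flags=rec.radiographic_flags,
                rois={},
                fa_subject_mean=float("nan"),
            )
        )
    return subjects


def validate_inputs(cohort_dir: Path) -> pd.DataFrame:
    """Diagnostic pass over an on-disk cohort; returns a pass/fail table.

    Checks that NIfTI headers agree across modalities per scan, masks
    are binary and on the scan grid, and streamline files parse. Never
    raises; every problem becomes a failure row.
    """
    import nibabel as nib

    cohort_dir = Path(cohort_dir)
    rows = []

    def add(target, check, ok, detail=""):
        rows.append({"target": str(target), "check": check, "status": "pass" if ok else "fail", "detail": detail})

    subjects_dir = cohort_dir / "subjects"
    if not subjects_dir.is_dir():
        add(cohort_dir, "layout", False, "missing subjects/ directory")
        return pd.DataFrame(rows)
    for sdir in sorted(subjects_dir.iterdir()):
        for scandir in sorted(sdir.glob("scan*")):
            shapes, zooms = {}, {}
            for mod in MODALITIES:
                p = scandir / f"{mod}.nii.gz"
                try:
                    img = nib.load(str(p))
                    shapes[mod] = tuple(img.shape)
                    zooms[mod] = tuple(round(z, 6) for z in img.header.get_zooms()[:3])
                except Exception as exc:  # noqa: BLE001 - diagnostic mode
                    add(p, "readable", False, str(exc))
            ok = len(set(shapes.values())) <= 1 and len(set(zooms.values())) <= 1
            add(scandir, "modalities_share_grid", ok, f"shapes={set(shapes.values())}")
            for mpath in sorted(scandir.glob("mask_*.nii.gz")):
                try:
                    data = np.asarray(nib.load(str(mpath)).dataobj)
                    binary = set(np.unique(data)).issubset({0, 1})
                    on_grid = shapes and tuple(data.shape) == next(iter(shapes.values()))
                    add(mpath, "mask_binary_on_grid", bool(binary and on_grid),
                        f"values={sorted(set(np.unique(data)))[:4]}")
                except Exception as exc:  # noqa: BLE001
                    add(mpath, "readable", False, str(exc))
        spath = sdir / "streamlines.json"
        try:
            lines = io.load_streamlines(spath)
            add(spath, "streamlines_parse", lines.count > 0, f"n={lines.count}")
        except Exception as exc:  # noqa: BLE001
            add(spath, "streamlines_parse", False, str(exc))
    return pd.DataFrame(rows)
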