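"""Synthetic longitudinal multi-modal MRI cohorts with known ground truth.

The generator emulates a two-group (progression case vs. control)
surveillance-imaging cohort: each subject carries 1-3 co-registered
scans of 7 modalities (T1, T1CE, T2, FLAIR, FA, TR, RAD) on one grid,
tubular optic-nerve masks, and optic-radiation masks defined by
filtering a synthetic streamline bundle with the ``A AND B NOT C`` ROI
logic.

The fractional-anisotropy signal is hierarchical: each subject's OR
mean is drawn from its group's normal distribution (defaults follow the
reported scaled-FA group summaries, 2.38 +/- 1.79 for progressing cases
vs. 6.23 +/- 3.56 for controls), and voxel values scatter around the
subject mean with a small measurement noise. The between-subject SD is
shrunk to sqrt(sd^2 - noise_sd^2) so the pooled voxel distribution of a
group is exactly the configured normal. All intensities are truncated
at zero (scaled intensities are magnitudes).

Case subjects additionally carry a per-interval drift of the OR signal
across successive scans (FA declining toward the index scan by
default), a radiographic bulge of the optic-nerve tube on the index
scan, and/or a visual-acuity (logMAR) worsening, so that both the
dynamic features and the clinical labeling rules have a detectable
signal. Scan times are fractional years with the index scan at t=0 and
preceding scans at negative times inside a 2-year window.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError
from .features import FeatureTable
from .geometry import RegionMask, StreamlineSet, filter_streamlines, streamlines_to_mask

__all__ = [
    "MODALITIES",
    "CohortConfig",
    "MultimodalScan",
    "SyntheticSubject",
    "generate_tube_mask",
    "generate_streamlines",
    "generate_cohort",
    "make_feature_table",
    "subject_or_fa_mean",
]

MODALITIES = ("T1", "T1CE", "T2", "FLAIR", "FA", "TR", "RAD")

# arbitrary-unit background levels per modality; the absolute scale is
# irrelevant downstream because volumes are histogram-matched
_BASE_LEVEL = {"T1": 100.0, "T1CE": 110.0, "T2": 120.0, "FLAIR": 90.0,
               "FA": 12.0, "TR": 60.0, "RAD": 50.0}
_BASE_CV = 0.05  # background coefficient of variation


@dataclass
class MultimodalScan:
    """One timepoint: 7 co-registered volumes on a shared grid."""

    volumes: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float]
    time_years: float

    def __post_init__(self) -> None:
        missing = [m for m in MODALITIES if m not in self.volumes]
        if missing:
            raise ConfigurationError(f"scan is missing modalities: {missing}")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ConfigurationError(f"modalities disagree on grid shape: {shapes}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.volumes.values())).shape


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str  # "case" | "control"
    scans: list[MultimodalScan]
    masks: list[dict[str, RegionMask]]  # per scan: ON-L, ON-R, OR-L, OR-R
    streamlines: list[StreamlineSet]  # per scan (generation is per subject)
    va_series: dict[str, list[tuple[float, float]]]  # eye -> [(t_years, logMAR)]
    radiographic_flags: list[bool]
    rois: dict[str, RegionMask]  # ROI-A, ROI-B-L, ROI-B-R, ROI-C
    fa_subject_mean: float


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    FA group parameters default to the reported scaled-intensity group
    summaries (cases 2.38 +/- 1.79, controls 6.23 +/- 3.56, arbitrary
    units). ``drift_per_interval`` shifts the OR-region mean of case
    subjects between consecutive scans (signal units per interval,
    applied relative to the index scan).
    """

    n_cases: int = 19
    n_controls: int = 19
    scans_per_subject: int = 3
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    fa_mean_case: float = 2.38
    fa_sd_case: float = 1.79
    fa_mean_control: float = 6.23
    fa_sd_control: float = 3.56
    drift_per_interval: dict[str, float] = field(default_factory=lambda: {"FA": -0.5})
    noise_sd: float = 0.3
    seed: int = 0
    on_radius_mm: float = 3.0
    on_progression_factor: float = 1.5
    n_streamlines: int = 40
    decoy_fraction: float = 0.2
    scan_interval_years: float = 0.8

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        if self.n_controls < 1:
            raise ConfigurationError("n_controls must be >= 1")
        if not 1 <= self.scans_per_subject <= 3:
            raise ConfigurationError("scans_per_subject must be in 1..3")
        for name in ("fa_sd_case", "fa_sd_control", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise ConfigurationError("grid_shape needs 3 axes of >= 16 voxels")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ConfigurationError("voxel_spacing_mm must be positive")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ConfigurationError("decoy_fraction must be in [0, 1)")
        if self.scan_interval_years * (self.scans_per_subject - 1) > 2.0:
            raise ConfigurationError(
                "scan_interval_years puts scans outside the 2-year window"
            )


# ---------------------------------------------------------------------------
# geometric phantoms


def generate_tube_mask(
    grid_shape: Sequence[int],
    spacing_mm: Sequence[float],
    axis_path: np.ndarray,
    radius_mm: float,
    label: str = "tube",
) -> RegionMask:
    """Voxels whose centers lie within ``radius_mm`` of a polyline path.

    Stands in for a manually segmented tubular structure (an optic
    nerve). The path is given in world mm and must lie inside the grid.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    shape = np.asarray(grid_shape, dtype=int)
    path = np.atleast_2d(np.asarray(axis_path, dtype=float))
    if path.shape[0] < 2:
        raise GeometryError("tube path needs >= 2 points")
    if radius_mm < 0.5 * float(spacing.min()):
        raise GeometryError(
            f"tube radius {radius_mm} mm is below half the minimum spacing"
        )
    extent = shape * spacing
    if np.any(path < 0) or np.any(path >= extent):
        raise GeometryError("tube path leaves the grid")
    lo = np.maximum(np.floor((path.min(axis=0) - radius_mm) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((path.max(axis=0) + radius_mm) / spacing).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = (idx + 0.5) * spacing
    dmin = np.full(len(centers), np.inf)
    for p0, p1 in zip(path[:-1], path[1:]):
        ab = p1 - p0
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(centers - p0, axis=1)
        else:
            t = np.clip((centers - p0) @ ab / denom, 0.0, 1.0)
            proj = p0 + t[:, None] * ab
            d = np.linalg.norm(centers - proj, axis=1)
        dmin = np.minimum(dmin, d)
    inside = idx[dmin <= radius_mm]
    if inside.size == 0:
        raise GeometryError("tube mask is empty")
    mask = np.zeros(tuple(shape), dtype=bool)
    mask[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return RegionMask(mask=mask, label=label, spacing_mm=tuple(spacing))


def _voxel_centers(roi: RegionMask) -> np.ndarray:
    return (np.argwhere(roi.mask) + 0.5) * np.asarray(roi.spacing_mm)


def _hits(line: np.ndarray, roi: RegionMask) -> bool:
    from .geometry import line_voxel_indices

    idx = line_voxel_indices(line, roi.spacing_mm, roi.mask.shape)
    if idx.size == 0:
        return False
    return bool(roi.mask[idx[:, 0], idx[:, 1], idx[:, 2]].any())


def generate_streamlines(
    roi_a: RegionMask,
    roi_b: RegionMask,
    n_lines: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    decoy_fraction: float = 0.0,
    n_points: int = 10,
    bow_mm: float = 3.0,
    jitter_mm: float = 0.3,
) -> StreamlineSet:
    """Polylines from ``roi_a`` to ``roi_b`` plus decoys violating A-AND-B.

    Valid lines start at a voxel center of A, end at a voxel center of B,
    and bow gently sideways; decoys (``round(n_lines * decoy_fraction)``
    of the total) stay inside A and therefore fail the inclusion
    criteria. Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not roi_a.mask.any() or not roi_b.mask.any():
        raise GeometryError("streamline seeding needs nonempty ROIs")
    if (roi_a.mask & roi_b.mask).any():
        raise GeometryError("roi_a and roi_b must be disjoint")
    extent = np.asarray(roi_a.mask.shape) * np.asarray(roi_a.spacing_mm)
    a_centers = _voxel_centers(roi_a)
    b_centers = _voxel_centers(roi_b)
    n_decoys = int(round(n_lines * decoy_fraction))
    n_valid = n_lines - n_decoys
    t = np.linspace(0.0, 1.0, n_points)
    lines: list[np.ndarray] = []
    for _ in range(n_valid):
        p0 = a_centers[rng.integers(len(a_centers))]
        p1 = b_centers[rng.integers(len(b_centers))]
        base = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        # bow sideways, perpendicular to the chord in the xy-plane
        chord = p1 - p0
        perp = np.array([-chord[1], chord[0], 0.0])
        norm = np.linalg.norm(perp)
        perp = perp / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        amp = rng.uniform(-bow_mm, bow_mm)
        line = base + np.sin(math.pi * t)[:, None] * amp * perp[None, :]
        line[1:-1] += rng.normal(0.0, jitter_mm, size=(n_points - 2, 3))
        line = np.clip(line, 0.0, extent - 1e-6)
        line[0], line[-1] = p0, p1  # endpoints stay exactly in A and B
        lines.append(line)
    for _ in range(n_decoys):
        for _try in range(100):
            p0 = a_centers[rng.integers(len(a_centers))]
            p1 = a_centers[rng.integers(len(a_centers))]
            line = np.vstack([p0, 0.5 * (p0 + p1), p1])
            if not (_hits(line, roi_a) and _hits(line, roi_b)):
                break
        lines.append(line)
    return StreamlineSet(lines)


# ---------------------------------------------------------------------------
# cohort assembly


def _box_mask(shape, spacing, frac_lo, frac_hi, label) -> RegionMask:
    shape = np.asarray(shape, dtype=int)
    lo = np.floor(np.asarray(frac_lo) * shape).astype(int)
    hi = np.ceil(np.asarray(frac_hi) * shape).astype(int)
    mask = np.zeros(tuple(shape), dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return RegionMask(mask=mask, label=label, spacing_mm=tuple(spacing))


def _template_geometry(config: CohortConfig) -> dict:
    """Fixed anatomical layout shared by every subject."""
    shape = np.asarray(config.grid_shape)
    spacing = np.asarray(config.voxel_spacing_mm)
    extent = shape * spacing

    def on_path(xfrac: float) -> np.ndarray:
        return np.array(
            [
                [xfrac * extent[0], 0.28 * extent[1], 0.15 * extent[2]],
                [xfrac * extent[0], 0.28 * extent[1], 0.85 * extent[2]],
            ]
        )

    geo = {
        "on_path_L": on_path(0.30),
        "on_path_R": on_path(0.70),
        "roi_a": _box_mask(shape, spacing, (0.40, 0.40, 0.38), (0.60, 0.52, 0.62), "ROI-A"),
        "roi_b_L": _box_mask(shape, spacing, (0.08, 0.82, 0.30), (0.45, 0.95, 0.70), "ROI-B"),
        "roi_b_R": _box_mask(shape, spacing, (0.55, 0.82, 0.30), (0.92, 0.95, 0.70), "ROI-B"),
        "roi_c": _box_mask(shape, spacing, (0.0, 0.0, 0.90), (1.0, 1.0, 1.0), "ROI-C"),
    }
    for side in ("L", "R"):
        geo[f"on_{side}"] = generate_tube_mask(
            shape, spacing, geo[f"on_path_{side}"], config.on_radius_mm, label=f"ON-{side}"
        )
        geo[f"on_{side}_progressed"] = generate_tube_mask(
            shape,
            spacing,
            geo[f"on_path_{side}"],
            config.on_radius_mm * config.on_progression_factor,
            label=f"ON-{side}",
        )
    return geo


def _truncated_normal(rng, mean, sd, size=None) -> np.ndarray | float:
    """Normal draw truncated at 0 by clipping (intensities are magnitudes)."""
    x = np.maximum(rng.normal(mean, sd, size=size), 0.0)
    return float(x) if size is None else x


@functools.lru_cache(maxsize=64)
def _censored_normal_params(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Pre-censoring (mu, sigma) whose zero-clipped draw realizes the targets.

    The configured group mean/SD describe the *observed* (non-negative)
    intensity distribution; when the target mean sits within a few SD of
    zero, clipping would otherwise bias the realized moments upward. For
    X ~ N(mu, sigma) and Y = max(X, 0), with a = mu/sigma:

        E[Y]  = mu * Phi(a) + sigma * phi(a)
        E[Y^2] = (mu^2 + sigma^2) * Phi(a) + mu * sigma * phi(a)

    Solved for (mu, sigma) by root finding; far from zero (a > 5) the
    identity map is returned.
    """
    from scipy import optimize, stats as _st

    if target_mean / target_sd > 5.0:
        return target_mean, target_sd

    def censored_moments(params):
        mu, sigma = params
        sigma = abs(sigma)
        a = mu / sigma
        e1 = mu * _st.norm.cdf(a) + sigma * _st.norm.pdf(a)
        e2 = (mu**2 + sigma**2) * _st.norm.cdf(a) + mu * sigma * _st.norm.pdf(a)
        var = max(e2 - e1**2, 1e-12)
        return e1 - target_mean, math.sqrt(var) - target_sd

    sol = optimize.fsolve(censored_moments, x0=(target_mean, target_sd), full_output=False)
    mu, sigma = float(sol[0]), abs(float(sol[1]))
    return mu, sigma


def _case_triggers(n_cases: int) -> list[tuple[bool, bool]]:
    """(radiographic, va_decline) per case, mirroring the observed mix.

    Roughly 16:2:1 radiographic-only : both : VA-only per 19 cases; every
    case carries at least one trigger.
    """
    n_va_only = 1 if n_cases >= 10 else 0
    n_both = int(round(0.1 * n_cases))
    triggers = []
    for j in range(n_cases):
        if j < n_va_only:
            triggers.append((False, True))
        elif j < n_va_only + n_both:
            triggers.append((True, True))
        else:
            triggers.append((True, False))
    return triggers


def generate_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Generate ``n_cases + n_controls`` synthetic subjects.

    Deterministic for a fixed ``config.seed``: one root seed sequence is
    spawned into per-subject streams.
    """
    geo = _template_geometry(config)
    spacing = tuple(float(s) for s in config.voxel_spacing_mm)
    shape = tuple(int(n) for n in config.grid_shape)
    s = config.scans_per_subject
    n_total = config.n_cases + config.n_controls
    seeds = np.random.SeedSequence(config.seed).spawn(n_total)
    triggers = _case_triggers(config.n_cases)

    subjects: list[SyntheticSubject] = []
    for i in range(n_total):
        is_case = i < config.n_cases
        group = "case" if is_case else "control"
        sid = f"{group}_{i if is_case else i - config.n_cases:02d}"
        rng = np.random.default_rng(seeds[i])

        raw_lines = {}
        or_masks = {}
        all_lines: list[np.ndarray] = []
        for side in ("L", "R"):
            ls = generate_streamlines(
                geo["roi_a"],
                geo[f"roi_b_{side}"],
                config.n_streamlines,
                rng=rng,
                decoy_fraction=config.decoy_fraction,
            )
            raw_lines[side] = ls
            kept = filter_streamlines(ls, geo["roi_a"], geo[f"roi_b_{side}"], geo["roi_c"])
            or_masks[side] = streamlines_to_mask(kept, shape, spacing, label=f"OR-{side}")
            all_lines.extend(ls.lines)
        streamset = StreamlineSet(all_lines)

        group_mean = config.fa_mean_case if is_case else config.fa_mean_control
        group_sd = config.fa_sd_case if is_case else config.fa_sd_control
        sd_between = math.sqrt(
            max(group_sd**2 - config.noise_sd**2, (0.1 * group_sd) ** 2)
        )
        # subject mean from the group distribution; pre-censoring parameters
        # are moment-matched so the clipped draw realizes (mean, sd_between)
        mm_mu, mm_sd = _censored_normal_params(group_mean, sd_between)
        fa_mean = _truncated_normal(rng, mm_mu, mm_sd)

        radio, va_decline = triggers[i] if is_case else (False, False)

        times = [-(s - 1 - k) * config.scan_interval_years for k in range(s)]
        for k in range(s - 1):  # small timing jitter, order preserved
            times[k] += float(rng.uniform(-0.05, 0.05))

        or_union = or_masks["L"].mask | or_masks["R"].mask
        n_or = int(or_union.sum())
        scans: list[MultimodalScan] = []
        masks: list[dict[str, RegionMask]] = []
        for k in range(s):
            on_key = "_progressed" if (is_case and radio and k == s - 1) else ""
            scan_masks = {
                "ON-L": geo[f"on_L{on_key}"],
                "ON-R": geo[f"on_R{on_key}"],
                "OR-L": or_masks["L"],
                "OR-R": or_masks["R"],
            }
            on_union = scan_masks["ON-L"].mask | scan_masks["ON-R"].mask
            vols: dict[str, np.ndarray] = {}
            for mod in MODALITIES:
                base = _BASE_LEVEL[mod]
                vol = np.maximum(rng.normal(base, _BASE_CV * base, size=shape), 0.0)
                vol[on_union] = np.maximum(
                    rng.normal(1.15 * base, _BASE_CV * base, size=int(on_union.sum())), 0.0
                )
                drift = config.drift_per_interval.get(mod, 0.0) if is_case else 0.0
                shift = drift * (k - (s - 1))
                if mod == "FA":
                    vol[or_union] = _truncated_normal(
                        rng, fa_mean + shift, config.noise_sd, size=n_or
                    )
                else:
                    vol[or_union] = np.maximum(
                        rng.normal(0.85 * base + shift, _BASE_CV * base, size=n_or), 0.0
                    )
                vols[mod] = vol.astype(np.float32)
            scans.append(MultimodalScan(volumes=vols, spacing_mm=spacing, time_years=times[k]))
            masks.append(scan_masks)

        base_logmar = {"od": 0.1 + float(rng.uniform(0.0, 0.1)), "os": 0.05}
        va_series: dict[str, list[tuple[float, float]]] = {}
        for eye in ("od", "os"):
            series = []
            val = base_logmar[eye]
            for k in range(s):
                if k > 0:
                    val += float(rng.uniform(-0.02, 0.02))
                series.append((times[k], round(max(val, 0.0), 3)))
            if eye == "od" and va_decline:
                t_last, v_last = series[-1]
                series[-1] = (t_last, round(v_last + 0.3, 3))
            va_series[eye] = series

        flags = [False] * s
        if radio:
            flags[s - 1] = True

        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                group=group,
                scans=scans,
                masks=masks,
                streamlines=[streamset] * s,
                va_series=va_series,
                radiographic_flags=flags,
                rois={
                    "ROI-A": geo["roi_a"],
                    "ROI-B-L": geo["roi_b_L"],
                    "ROI-B-R": geo["roi_b_R"],
                    "ROI-C": geo["roi_c"],
                },
                fa_subject_mean=fa_mean,
            )
        )
    return subjects


def subject_or_fa_mean(subject: SyntheticSubject, scan_index: int = -1) -> float:
    """Measured mean FA inside the subject's optic radiations on one scan."""
    masks = subject.masks[scan_index]
    sel = masks["OR-L"].mask | masks["OR-R"].mask
    return float(subject.scans[scan_index].volumes["FA"][sel].mean())


# ---------------------------------------------------------------------------
# feature-level cohort (fast path for model experiments)


def make_feature_table(
    n_cases: int = 19,
    n_controls: int = 19,
    n_noise: int = 50,
    effect_scale: float = 1.0,
    seed: int = 0,
    fa_mean_case: float = 2.38,
    fa_sd_case: float = 1.79,
    fa_mean_control: float = 6.23,
    fa_sd_control: float = 3.56,
) -> tuple[FeatureTable, np.ndarray]:
    """Subject-level feature table: one informative OR-FA column + noise.

    The informative column draws each subject's OR-FA mean from its
    group's distribution; ``effect_scale`` rescales the group-mean
    separation about the common midpoint (2.0 doubles the effect) while
    keeping the SDs. Noise columns are standard normal. Returns the
    table and the per-row labels.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    center = 0.5 * (fa_mean_case + fa_mean_control)
    mu_case = center + effect_scale * (fa_mean_case - center)
    mu_ctrl = center + effect_scale * (fa_mean_control - center)
    x = np.concatenate(
        [
            rng.normal(mu_case, fa_sd_case, n_cases),
            rng.normal(mu_ctrl, fa_sd_control, n_controls),
        ]
    )
    n = n_cases + n_controls
    noise = rng.normal(0.0, 1.0, size=(n, n_noise))
    ids = [f"case_{j:02d}" for j in range(n_cases)] + [
        f"control_{j:02d}" for j in range(n_controls)
    ]
    labels = np.asarray(["case"] * n_cases + ["control"] * n_controls)
    data = {"OR_FA_mean": x}
    for j in range(n_noise):
        data[f"noise_{j:02d}"] = noise[:, j]
    df = pd.DataFrame(data, index=ids)
    table = FeatureTable(data=df, scheme="static", subject_ids=ids, labels=labels)
    return table, labels
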