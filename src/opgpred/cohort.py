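"""Clinical labeling and scan-selection rules for the case-control design.

Progression is defined as radiographic tumor enlargement on any
surveillance scan and/or a worsening of best-corrected visual acuity of
at least 0.2 logMAR between successive examinations in either eye
(higher logMAR = worse acuity; a config flag accepts the opposite sign
convention). Subjects with severe baseline vision loss (20/470 or
worse, a floor effect) or a prior surgical biopsy are excluded.

Scan windows mirror the surveillance design: for a case, the index
(progression) scan plus up to 3 immediately preceding scans within 2
years of it; for a control, the 3 most recent scans, each within 2
years of the most recent. Every decision carries a machine-readable
reason string for auditability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import InsufficientDataError

__all__ = [
    "SEVERE_LOSS_LOGMAR",
    "ClinicalRecord",
    "label_progression",
    "apply_exclusions",
    "select_scans",
]

log = logging.getLogger(__name__)

# 20/470 in logMAR: log10(470/20)
SEVERE_LOSS_LOGMAR = math.log10(470 / 20)

VA_WORSENING_THRESHOLD = 0.2
WINDOW_YEARS = 2.0
MAX_PRIOR_SCANS = 3


@dataclass
class ClinicalRecord:
    """Per-subject clinical data: VA series per eye, per-scan flags."""

    subject_id: str
    va_series: dict[str, list[tuple[float, float]]]  # eye -> [(time_years, logMAR)]
    radiographic_flags: list[bool]
    prior_biopsy: bool = False
    baseline_logmar: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for eye, series in self.va_series.items():
            times = [t for t, _ in series]
            if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
                raise ValueError(f"VA times for eye {eye!r} must be non-decreasing")
            if any(not math.isfinite(v) for _, v in series):
                raise ValueError(f"non-finite logMAR for eye {eye!r}")
        if not self.baseline_logmar:
            self.baseline_logmar = {
                eye: series[0][1] for eye, series in self.va_series.items() if series
            }


def label_progression(
    record: ClinicalRecord,
    worsening_is_increase: bool = True,
    va_threshold: float = VA_WORSENING_THRESHOLD,
) -> tuple[str, str]:
    """Label a subject ``progression``/``no_progression`` with a reason.

    Progression fires if any radiographic flag is set, or if any eye's
    logMAR moves by >= ``va_threshold`` in the worsening direction
    between two successive examinations (worsening = increase by
    default; set ``worsening_is_increase=False`` for the opposite
    recording convention).
    """
    has_va = any(record.va_series.get(eye) for eye in record.va_series)
    if not has_va or not record.radiographic_flags:
        raise InsufficientDataError(
            f"subject {record.subject_id}: need >= 1 VA measurement and >= 1 scan flag"
        )
    reasons = []
    if any(record.radiographic_flags):
        scan_i = record.radiographic_flags.index(True)
        reasons.append(f"radiographic_growth:scan={scan_i}")
    sign = 1.0 if worsening_is_increase else -1.0
    for eye, series in record.va_series.items():
        for (t0, v0), (t1, v1) in zip(series, series[1:]):
            # small epsilon so 0.1 -> 0.3 meets the 0.2 threshold despite
            # binary floating point (0.3 - 0.1 < 0.2 exactly)
            if sign * (v1 - v0) >= va_threshold - 1e-9:
                reasons.append(f"va_decline:eye={eye},t={t1:.2f},delta={sign * (v1 - v0):.2f}")
                break
    if reasons:
        return "progression", ";".join(reasons)
    return "no_progression", "no_trigger"


def apply_exclusions(record: ClinicalRecord) -> tuple[str, str]:
    """``include``/``exclude`` with a reason; never raises.

    Exclusion triggers: prior surgical biopsy, or baseline acuity at the
    severe-loss floor (logMAR >= log10(470/20) ~ 1.371) in the
    better-seeing eye, where worsening could no longer be observed.
    """
    if record.prior_biopsy:
        return "exclude", "prior_biopsy"
    if record.baseline_logmar:
        better = min(record.baseline_logmar.values())
        if better >= SEVERE_LOSS_LOGMAR:
            return "exclude", f"severe_baseline_vision_loss:logmar={better:.3f}"
    return "include", "eligible"


def select_scans(
    scan_times: Sequence[float],
    label: str,
    window_years: float = WINDOW_YEARS,
    max_prior: int = MAX_PRIOR_SCANS,
) -> list[int]:
    """Indices of the scans entering the analysis, chronologically ordered.

    Cases keep the index (progression) scan plus up to ``max_prior``
    immediately preceding scans within ``window_years`` of it; controls
    keep their 3 most recent scans, each within ``window_years`` of the
    most recent. An empty series yields an empty selection with a
    warning.
    """
    times = list(scan_times)
    if not times:
        log.warning("subject with no scans dropped from selection")
        return []
    order = sorted(range(len(times)), key=lambda i: times[i])
    t_index = times[order[-1]]
    if label in ("progression", "case"):
        prior = [i for i in order[:-1] if t_index - times[i] <= window_years]
        return prior[-max_prior:] + [order[-1]]
    kept = [i for i in order if t_index - times[i] <= window_years]
    return kept[-MAX_PRIOR_SCANS:]
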