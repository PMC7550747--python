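"""Construction of the age-matched normative sample.

One subject is never compared against the full control pool: controls are
first restricted to an age window around the subject (default ± 10 years,
closed interval), and volumetric measures are optionally divided by each
subject's total intracranial volume (TIV) to adjust for head size. The
retained controls' mean and sample SD per biomarker define the normative
reference used by the single-case statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import BiomarkerRecord, SubjectMeta

log = logging.getLogger(__name__)

#: Measures divided by TIV during head-size normalization.
TIV_NORMALIZED_MEASURES = frozenset(
    {"volume_mm3", "surface_area_mm2", "gm_total_mm3", "wm_total_mm3", "ventricles_mm3"}
)

#: Default half-width of the control age window, years.
DEFAULT_AGE_DEVIATION = 10.0

#: Cohorts smaller than this trigger a warning (statistics stay valid at n>=2).
MIN_CONTROLS_WARN = 5


class DegenerateCohortError(ValueError):
    """Cohort cannot support a comparison (n < 2 or zero variance)."""


@dataclass
class NormativeCohort:
    """Age-filtered control sample for one biomarker."""

    biomarker_key: tuple[str, str]
    values: list[float]
    control_ids: list[str]
    age_window: tuple[float, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(self.control_ids):
            raise ValueError("values and control_ids must align")
        if self.n < 2:
            raise DegenerateCohortError(
                f"cohort for {self.biomarker_key} has n={self.n}; need >= 2 controls"
            )

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return sum(self.values) / self.n

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1 denominator)."""
        m = self.mean
        return math.sqrt(sum((v - m) ** 2 for v in self.values) / (self.n - 1))

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0


def select_age_window(
    controls: Sequence[SubjectMeta],
    subject_age: float,
    deviation: float = DEFAULT_AGE_DEVIATION,
) -> list[SubjectMeta]:
    """Keep controls whose age lies within ``subject_age ± deviation`` (inclusive).

    Order is preserved. A warning is emitted when fewer than
    ``MIN_CONTROLS_WARN`` controls survive; zero survivors is an error telling
    the user to widen the deviation.
    """
    if deviation <= 0:
        raise ValueError(f"age deviation must be positive, got {deviation}")
    low, high = subject_age - deviation, subject_age + deviation
    retained = [c for c in controls if low <= c.age <= high]
    if not retained:
        raise ValueError(
            f"no control within age window [{low:g}, {high:g}]; widen the age deviation"
        )
    if len(retained) < MIN_CONTROLS_WARN:
        log.warning(
            "only %d controls within age window [%g, %g]; results may be unstable",
            len(retained), low, high,
        )
    return retained


def normalize_tiv(
    records: Sequence[BiomarkerRecord], meta_tiv: Mapping[str, float]
) -> list[BiomarkerRecord]:
    """Divide volumetric and surface-area records by the subject's TIV.

    Thickness, curvature and the eTIV record itself pass through unchanged.
    Applying this to already-normalized records raises rather than dividing
    twice.
    """
    out = []
    for r in records:
        if r.measure == "etiv_mm3" or r.measure not in TIV_NORMALIZED_MEASURES:
            out.append(r)
            continue
        if r.normalized:
            raise ValueError(
                f"record {r.key} for {r.subject_id} is already TIV-normalized"
            )
        tiv = meta_tiv.get(r.subject_id)
        if tiv is None or not (tiv > 0):
            raise ValueError(
                f"subject {r.subject_id} has missing or non-positive TIV ({tiv!r})"
            )
        out.append(
            BiomarkerRecord(
                subject_id=r.subject_id,
                session=r.session,
                region=r.region,
                measure=r.measure,
                value=r.value / tiv,
                normalized=True,
            )
        )
    return out


def tiv_map(records: Sequence[BiomarkerRecord]) -> dict[str, float]:
    """Extract subject -> eTIV from a record table."""
    return {r.subject_id: r.value for r in records if r.measure == "etiv_mm3"}


def build_cohort(
    control_records: Sequence[BiomarkerRecord],
    retained_controls: Sequence[SubjectMeta],
    key: tuple[str, str],
    session: int = 1,
    age_window: tuple[float, float] | None = None,
) -> NormativeCohort:
    """Assemble the normative sample for one biomarker from retained controls.

    Controls lacking the biomarker at the requested session are excluded and
    counted in a log line; fewer than 2 usable controls is an error.
    """
    region, measure = key
    by_subject = {
        r.subject_id: r
        for r in control_records
        if r.region == region and r.measure == measure and r.session == session
    }
    values, ids = [], []
    missing = 0
    normalized = False
    for c in retained_controls:
        rec = by_subject.get(c.subject_id)
        if rec is None:
            missing += 1
            continue
        values.append(rec.value)
        ids.append(c.subject_id)
        normalized = rec.normalized
    if missing:
        log.info("cohort %s: excluded %d controls lacking the biomarker", key, missing)
    if len(values) < 2:
        raise DegenerateCohortError(
            f"cohort for {key} has n={len(values)} usable controls; need >= 2"
        )
    if age_window is None:
        ages = [c.age for c in retained_controls]
        age_window = (min(ages), max(ages))
    cohort = NormativeCohort(
        biomarker_key=key,
        values=values,
        control_ids=ids,
        age_window=age_window,
        normalized=normalized,
    )
    if cohort.degenerate:
        log.warning("cohort %s has zero variance across %d controls", key, cohort.n)
    return cohort
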