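"""Disease-burden scoring, imaging-clinical correlations, and atrophy rates.

For Huntington's disease the progression index is

    disease burden = age * (CAG - 35.5)

with age in years and CAG the repeat length of the expanded allele; it is
negative below the pathological range and that is flagged, not hidden.
Associations between imaging measures (affected-voxel counts, regional
volumes) and clinical scores use Pearson correlation, optionally partialling
out the disease burden; longitudinal change is summarized as an annualized
rate (OLS slope over sessions) and compared between groups with a pooled
two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

#: CAG repeat threshold in the burden formula.
CAG_OFFSET = 35.5

MONTHS_PER_YEAR = 12.0


@dataclass
class LongitudinalSeries:
    """Repeated measurements of one biomarker for one subject."""

    subject_id: str
    biomarker_key: tuple[str, str]
    sessions: list[tuple[float, float]]  # (interval_months from baseline, value)

    def __post_init__(self) -> None:
        t = [s[0] for s in self.sessions]
        if t and (t[0] != 0 or any(b <= a for a, b in zip(t, t[1:]))):
            raise ValueError("session intervals must start at 0 and strictly increase")


@dataclass
class ClinicalRecord:
    subject_id: str
    disease_burden: float
    scores: dict[str, float] = field(default_factory=dict)


def disease_burden(age: float, cag: float) -> float:
    """Age x (CAG - 35.5). Negative for CAG below 35.5 (flagged via log)."""
    if cag is None:
        raise ValueError("CAG repeat length is required to compute disease burden")
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    burden = age * (cag - CAG_OFFSET)
    if burden < 0:
        log.warning("negative disease burden (CAG %s below %s)", cag, CAG_OFFSET)
    return burden


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-tailed p on df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def partial_correlation(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> tuple[float, float]:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), with the
    two-tailed p on df = n - 3. Equivalent to correlating the residuals of x
    and y after regressing each on z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be 1-D of equal length")
    if n < 4:
        raise ValueError("need at least 4 observations for a partial correlation")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise ValueError("covariate is collinear with x or y; partial correlation degenerate")
    r = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    df = n - 3
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def annualized_rate(series: LongitudinalSeries) -> float:
    """Change per year: OLS slope of value on time-in-years over all sessions.

    With exactly two sessions this reduces to
    (value_last - value_first) / elapsed_years.
    """
    if len(series.sessions) < 2:
        raise ValueError(f"{series.subject_id}: need >= 2 sessions for a rate")
    months = np.array([s[0] for s in series.sessions])
    values = np.array([s[1] for s in series.sessions])
    if months[-1] == months[0]:
        raise ValueError("zero elapsed time between first and last session")
    years = months / MONTHS_PER_YEAR
    slope, _ = np.polyfit(years, values, 1)
    return float(slope)


def group_rate_test(
    patient_rates: Sequence[float],
    control_rates: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, int, float]:
    """Two-sample t-test of atrophy rates between patients and controls.

    Pooled-variance Student t by default (df = n1 + n2 - 2, two-tailed);
    set ``equal_var=False`` for the Welch variant.
    """
    a = np.asarray(patient_rates, dtype=float)
    b = np.asarray(control_rates, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 rates")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() != b.mean():
            raise ValueError("zero pooled variance; t undefined")
        return 0.0, int(a.size + b.size - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = int(a.size + b.size - 2) if equal_var else int(res.df)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not math.isfinite(t):
        raise ValueError("degenerate rate samples; t undefined")
    return t, df, p
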