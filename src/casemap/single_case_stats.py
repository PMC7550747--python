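"""Single-case inference: z-scores, the Crawford-Howell modified t, and FDR.

The central statistic compares one observation x* against a small normative
sample (mean x̄, sample SD s, size n):

    t = (x* - x̄) / (s * sqrt((n + 1) / n)),   df = n - 1

which treats the case as a sample of one and remains calibrated for small n,
where the naive z-score (x* - x̄)/s referred to the normal distribution is
anti-conservative. Panels of regional biomarkers are corrected with the
Benjamini-Hochberg step-up over the panel size; significance is declared at
adjusted p < alpha (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import BiomarkerRecord, SubjectMeta
from .normative import (
    DegenerateCohortError,
    NormativeCohort,
    build_cohort,
    normalize_tiv,
    select_age_window,
    tiv_map,
)

DEFAULT_ALPHA = 0.05
DEFAULT_FDR_Q = 0.05


@dataclass
class SingleCaseResult:
    """One biomarker's comparison of the case against its normative cohort."""

    biomarker_key: tuple[str, str]
    x_star: float
    n: int
    control_mean: float
    control_sd: float
    z: float
    t: float
    df: int
    p: float
    p_adj: float
    significant: bool
    direction: str  # "below" | "above" | "none"


def z_score(x_star: float, cohort: NormativeCohort) -> float:
    """Deviation of the case from the cohort mean in control-SD units."""
    sd = cohort.sd
    if sd <= 0:
        raise DegenerateCohortError(
            f"cohort {cohort.biomarker_key} has zero SD; z-score undefined"
        )
    return (x_star - cohort.mean) / sd


def crawford_howell_t(
    x_star: float, cohort: NormativeCohort, tails: str = "two"
) -> tuple[float, int, float]:
    """Modified independent-samples t for one case vs a small control sample.

    Returns ``(t, df, p)`` with df = n - 1. ``tails`` is ``"two"`` (default),
    ``"less"`` (P(T <= t), deficit direction) or ``"greater"``.
    """
    n, sd = cohort.n, cohort.sd
    if n < 2:
        raise DegenerateCohortError("Crawford-Howell t needs at least 2 controls")
    if sd <= 0:
        raise DegenerateCohortError(
            f"cohort {cohort.biomarker_key} has zero SD; t undefined"
        )
    t = (x_star - cohort.mean) / (sd * math.sqrt((n + 1) / n))
    df = n - 1
    if tails == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tails == "less":
        p = stats.t.cdf(t, df)
    elif tails == "greater":
        p = stats.t.sf(t, df)
    else:
        raise ValueError(f"tails must be two|less|greater, got {tails!r}")
    return t, df, min(float(p), 1.0)


def bh_fdr(p_values: Sequence[float], q: float = DEFAULT_FDR_Q) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg step-up adjustment.

    Sorted ascending, adj_(i) = p_(i) * m / i, enforced monotone from the
    largest rank downward, capped at 1, restored to input order. A hypothesis
    is rejected when its adjusted p is strictly below ``q``. Ties share a
    stable sort and therefore identical adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return [], []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    rejected = p_adj < q
    return p_adj.tolist(), rejected.tolist()


def compare_roi_panel(
    subject_records: Sequence[BiomarkerRecord],
    control_records: Sequence[BiomarkerRecord],
    control_meta: Sequence[SubjectMeta],
    panel: Sequence[tuple[str, str]],
    subject_age: float,
    *,
    age_deviation: float = 10.0,
    tiv_normalize: bool = True,
    alpha: float = DEFAULT_ALPHA,
    fdr_q: float = DEFAULT_FDR_Q,
    tails: str = "two",
    session: int = 1,
) -> list[SingleCaseResult]:
    """Run the full ROI-panel comparison for one subject.

    Pipeline per panel key: age-window control selection, optional TIV
    normalization, cohort construction, z plus Crawford-Howell t; one BH-FDR
    pass across the whole panel (m = panel size). Direction is ``below`` when
    the case falls under the control mean, ``above`` when over, ``none`` at
    exact equality.
    """
    subject_ids = {r.subject_id for r in subject_records}
    if len(subject_ids) != 1:
        raise ValueError(f"subject_records must cover exactly one subject, got {subject_ids}")
    (subject_id,) = subject_ids

    panel = list(panel)
    subject_lookup = {
        r.key: r for r in subject_records if r.session == session
    }
    missing = [key for key in panel if key not in subject_lookup]
    if missing:
        raise ValueError(f"subject {subject_id} lacks panel biomarkers: {missing}")

    retained = select_age_window(
        [m for m in control_meta if m.group == "control"], subject_age, age_deviation
    )

    if tiv_normalize:
        tivs = tiv_map([*subject_records, *control_records])
        subject_records = normalize_tiv(subject_records, tivs)
        control_records = normalize_tiv(control_records, tivs)
        subject_lookup = {r.key: r for r in subject_records if r.session == session}

    window = (subject_age - age_deviation, subject_age + age_deviation)

    partial: list[tuple[tuple[str, str], float, NormativeCohort, float, float, int, float]] = []
    for key in panel:
        cohort = build_cohort(control_records, retained, key, session, age_window=window)
        x_star = subject_lookup[key].value
        z = z_score(x_star, cohort)
        t, df, p = crawford_howell_t(x_star, cohort, tails=tails)
        partial.append((key, x_star, cohort, z, t, df, p))

    p_adj, rejected = bh_fdr([row[-1] for row in partial], q=fdr_q)

    results = []
    for (key, x_star, cohort, z, t, df, p), padj in zip(partial, p_adj):
        if t == 0:
            direction = "none"
        else:
            direction = "below" if x_star < cohort.mean else "above"
        results.append(
            SingleCaseResult(
                biomarker_key=key,
                x_star=x_star,
                n=cohort.n,
                control_mean=cohort.mean,
                control_sd=cohort.sd,
                z=z,
                t=t,
                df=df,
                p=p,
                p_adj=padj,
                significant=padj < alpha,
                direction=direction,
            )
        )
    return results
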