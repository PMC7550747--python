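"""Seeded calibration and recovery studies for the single-case pipeline.

Every function here runs the package's own statistical machinery against
synthetic data with known ground truth, or against an independent oracle
(high-precision Student-t CDF, brute-force FDR, residual-regression partial
correlation), and returns scalar summaries: type-I error rates, detection
rates, worst-case numerical errors, Dice overlap, recovery correlations.
These back both the test suite and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from .clinical_longitudinal import annualized_rate, partial_correlation, pearson_r
from .normative import NormativeCohort
from .single_case_stats import bh_fdr, compare_roi_panel, crawford_howell_t, z_score
from .synthetic import SimulationConfig, simulate_cohort, simulate_gm_images, simulate_longitudinal, sphere_mask
from .voxelwise import threshold_binarize, voxelwise_single_case


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def student_t_cdf_highprec(t: float, df: int, dps: int = 30) -> float:
    """Student-t CDF from the regularized incomplete beta at ``dps`` digits.

    Evaluated with mpmath, independently of the scipy routines used by the
    implementation.
    """
    import mpmath

    with mpmath.workdps(dps):
        x = mpmath.mpf(df) / (df + mpmath.mpf(t) ** 2)
        tail = mpmath.betainc(
            mpmath.mpf(df) / 2, mpmath.mpf(1) / 2, 0, x, regularized=True
        ) / 2
        return float(tail if t < 0 else 1 - tail)


def brute_force_bh(p: list[float]) -> list[float]:
    """Step-up BH adjusted p-values straight from the definition."""
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def residual_partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial correlation via explicit residualization on the covariate."""
    z1 = np.column_stack([np.ones_like(z), z])
    rx = x - z1 @ np.linalg.lstsq(z1, x, rcond=None)[0]
    ry = y - z1 @ np.linalg.lstsq(z1, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def _cohort(values, key=("roi", "volume_mm3")) -> NormativeCohort:
    return NormativeCohort(
        biomarker_key=key,
        values=[float(v) for v in values],
        control_ids=[f"c{i}" for i in range(len(values))],
        age_window=(0.0, 120.0),
    )


# ---------------------------------------------------------------------------
# Exactness studies
# ---------------------------------------------------------------------------

def worked_single_case_example() -> dict:
    """Controls {10, 12, 14}, case 8: the hand-checkable reference comparison."""
    cohort = _cohort([10.0, 12.0, 14.0])
    t, df, p = crawford_howell_t(8.0, cohort)
    return {"t": t, "df": df, "p": p, "z": z_score(8.0, cohort)}


def crawford_howell_p_max_error(seed: int, n_cases: int = 1000) -> float:
    """Worst |p - oracle| over random (case, cohort) draws."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(2, 50))
        values = rng.normal(rng.uniform(-100, 100), rng.uniform(0.05, 30), n)
        if np.std(values, ddof=1) == 0:
            continue
        x_star = float(rng.normal(0, 60))
        t, df, p = crawford_howell_t(x_star, _cohort(values))
        cdf = student_t_cdf_highprec(t, df)
        oracle = min(2 * min(cdf, 1 - cdf), 1.0)
        worst = max(worst, abs(p - oracle))
    return worst


def bh_fdr_max_error(seed: int, n_vectors: int = 1000) -> float:
    """Worst |adjusted p - brute-force oracle| over random p-vectors with ties."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 51))
        p = rng.uniform(0, 1, m)
        if m > 2 and rng.random() < 0.5:
            p[int(rng.integers(0, m))] = p[int(rng.integers(0, m))]
        p = np.round(p, 3)
        adj, _ = bh_fdr(p.tolist())
        oracle = brute_force_bh(p.tolist())
        worst = max(worst, float(np.max(np.abs(np.array(adj) - np.array(oracle)))))
    return worst


def partial_corr_max_error(seed: int, n_triples: int = 1000) -> float:
    """Worst |r - residual-regression oracle| over random (x, y, z) triples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_triples):
        n = int(rng.integers(5, 50))
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = rng.uniform(-1, 1) * x + rng.uniform(-1, 1) * z + rng.normal(size=n)
        r, _ = partial_correlation(x, y, z)
        worst = max(worst, abs(r - residual_partial_r(x, y, z)))
    return worst


# ---------------------------------------------------------------------------
# Calibration studies
# ---------------------------------------------------------------------------

def type1_rejection_rate(
    seed: int, n_controls: int = 10, alpha: float = 0.05, reps: int = 10_000
) -> float:
    """False-positive rate of the two-tailed modified t under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        values = rng.normal(0, 1, n_controls)
        x_star = float(rng.normal(0, 1))
        _, _, p = crawford_howell_t(x_star, _cohort(values))
        rejections += p < alpha
    return rejections / reps


def naive_z_rejection_rate(
    seed: int, n_controls: int = 5, critical: float = 1.96, reps: int = 10_000
) -> float:
    """False-positive rate of |z| > critical under the null (anti-conservative)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        values = rng.normal(0, 1, n_controls)
        x_star = float(rng.normal(0, 1))
        cohort = _cohort(values)
        if cohort.sd == 0:
            continue
        rejections += abs(z_score(x_star, cohort)) > critical
    return rejections / reps


# ---------------------------------------------------------------------------
# End-to-end ROI pipeline study
# ---------------------------------------------------------------------------

def _slim_panel() -> dict:
    """12 biomarkers without age trend so an implant is exactly k control SDs."""
    keys = list(SimulationConfig().roi_panel.items())[:12]
    return {key: (mean, sd, 0.0) for key, (mean, sd, _) in keys}


def roi_panel_study(
    seed: int, reps: int = 500, effect: float = -3.0, n_controls: int = 20
) -> dict:
    """Detection and null false-alarm rates for the full ROI panel pipeline.

    Each replicate simulates a fresh cohort, implants ``effect`` control SDs
    into one ROI of the single patient, runs the complete age-window /
    Crawford-Howell / FDR pipeline, and checks whether the implanted ROI is
    flagged (adjusted p < 0.05). A matched set of null replicates (no
    implant) measures the probability of flagging any ROI at all.
    """
    panel_def = _slim_panel()
    panel = list(panel_def)
    target = panel[0]
    hits = 0
    null_any = 0
    for r in range(reps):
        for implanted in (True, False):
            config = SimulationConfig(
                seed=int(np.random.SeedSequence([seed, r, int(implanted)]).generate_state(1)[0] % 2**31),
                n_controls=n_controls,
                n_patients=1,
                # span < the 10-year matching window so all controls are retained
                age_range=(45.0, 55.0),
                roi_panel=panel_def,
                implants_roi={("pat000", target): effect} if implanted else {},
            )
            metas, records = simulate_cohort(config)
            subject = [x for x in records if x.subject_id == "pat000"]
            controls = [x for x in records if x.subject_id.startswith("ctrl")]
            age = next(m.age for m in metas if m.subject_id == "pat000")
            results = compare_roi_panel(
                subject, controls, metas, panel, age, tiv_normalize=False
            )
            if implanted:
                hit = next(x for x in results if x.biomarker_key == target)
                hits += hit.significant and hit.direction == "below"
            else:
                null_any += any(x.significant for x in results)
    return {"detection_rate": hits / reps, "null_any_flag_rate": null_any / reps}


# ---------------------------------------------------------------------------
# Voxelwise studies
# ---------------------------------------------------------------------------

def voxel_scalar_equivalence_max_error(seed: int, n_voxels: int = 100) -> float:
    """Worst |vectorized - scalar| t and p over random in-mask voxels."""
    rng = np.random.default_rng(seed)
    config = SimulationConfig(
        seed=seed, n_controls=12, n_patients=1, grid_shape=(16, 16, 16),
        image_noise_sd=0.05,
    )
    images = simulate_gm_images(config)
    controls = [images[f"ctrl{i:03d}"] for i in range(12)]
    subject = images["pat000"]
    worst = 0.0
    for tails in ("less", "two"):
        stat = voxelwise_single_case(subject, controls, tails=tails, fwhm_mm=0)
        inside = np.argwhere(stat.mask.data)
        picks = inside[rng.choice(len(inside), n_voxels, replace=False)]
        for i, j, k in picks:
            cohort = _cohort([c.data[i, j, k] for c in controls])
            t_ref, _, p_ref = crawford_howell_t(subject.data[i, j, k], cohort, tails=tails)
            worst = max(
                worst,
                abs(stat.t.data[i, j, k] - t_ref),
                abs(stat.p.data[i, j, k] - p_ref),
            )
    return worst


def voxel_null_calibration(
    seed: int,
    runs: int = 50,
    grid: int = 32,
    n_controls: int = 20,
    p_threshold: float = 0.005,
) -> dict:
    """Mean suprathreshold fraction under the voxelwise null, with its binomial SD.

    The subject is drawn from the control image distribution, so the expected
    fraction of voxels below the uncorrected threshold equals the threshold.
    """
    fractions = []
    n_mask_total = 0
    for r in range(runs):
        config = SimulationConfig(
            seed=int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31),
            n_controls=n_controls, n_patients=1,
            grid_shape=(grid, grid, grid), image_noise_sd=0.05,
        )
        images = simulate_gm_images(config)
        controls = [images[f"ctrl{i:03d}"] for i in range(n_controls)]
        stat = voxelwise_single_case(images["pat000"], controls, tails="less", fwhm_mm=0)
        binary = threshold_binarize(stat, p_threshold=p_threshold)
        n_mask = int(stat.mask.data.sum())
        n_mask_total += n_mask
        fractions.append(binary.count / n_mask)
    mean_fraction = float(np.mean(fractions))
    binom_sd = math.sqrt(p_threshold * (1 - p_threshold) / n_mask_total)
    return {
        "mean_fraction": mean_fraction,
        "expected": p_threshold,
        "binomial_sd": binom_sd,
        "n_mask_total": n_mask_total,
    }


def lesion_recovery_dice(
    seed: int,
    runs: int = 20,
    radius: float = 6.0,
    effect: float = 4.0,
    n_controls: int = 20,
    fwhm_voxels: float = 2.0,
    grid: int = 32,
) -> float:
    """Median Dice between the detected atrophy map and the implanted sphere."""
    center = (grid // 2, grid // 2, grid // 2)
    dices = []
    for r in range(runs):
        config = SimulationConfig(
            seed=int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31),
            n_controls=n_controls, n_patients=1,
            grid_shape=(grid, grid, grid), image_noise_sd=0.05,
            implants_voxel=[("pat000", center, radius, effect)],
        )
        images = simulate_gm_images(config)
        controls = [images[f"ctrl{i:03d}"] for i in range(n_controls)]
        voxel_mm = config.voxel_size[0]
        stat = voxelwise_single_case(
            images["pat000"], controls, tails="less", fwhm_mm=fwhm_voxels * voxel_mm
        )
        detected = threshold_binarize(stat, p_threshold=0.005).data.data.astype(bool)
        truth = sphere_mask((grid, grid, grid), center, radius)
        inter = np.logical_and(detected, truth).sum()
        denom = detected.sum() + truth.sum()
        dices.append(2 * inter / denom if denom else 0.0)
    return float(np.median(dices))


# ---------------------------------------------------------------------------
# Longitudinal study
# ---------------------------------------------------------------------------

def longitudinal_recovery_r(seed: int, n_subjects: int = 50) -> float:
    """Correlation between generated and recovered annualized atrophy rates.

    Rates spread uniformly over [-200, -50] units/year; each measurement gets
    Gaussian noise with SD equal to 10% of the subject's |rate|; two scans 18
    months apart.
    """
    rng = np.random.default_rng(seed)
    config = SimulationConfig(seed=seed, n_controls=0, n_patients=n_subjects)
    true_rates = {
        f"pat{i:03d}": float(rng.uniform(-200.0, -50.0)) for i in range(n_subjects)
    }
    estimated, truth = [], []
    for sid, rate in true_rates.items():
        (series,) = simulate_longitudinal(
            config, {sid: rate}, n_sessions=2, interval_months=18.0,
            noise_sd=0.1 * abs(rate),
        )
        estimated.append(annualized_rate(series))
        truth.append(rate)
    r, _ = pearson_r(estimated, truth)
    return r
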