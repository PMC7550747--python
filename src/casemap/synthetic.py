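"""Seeded synthetic cohorts: metadata, ROI biomarker tables, and GM images.

Emulates the inputs of a single-case atrophy study: an age-spread control
group, a patient group with optional implanted regional deficits (in control-
SD units), co-registered modulated gray-matter images built from a shared
template plus per-subject noise and optional focal spherical atrophy, and
longitudinal series with known annualized rates.

Determinism contract: the same seed and configuration give byte-identical
outputs, and each subject draws from an RNG stream derived from
(seed, subject index), so enlarging the cohort never reshuffles existing
subjects.

Defaults mirror a realistic normative-comparison study: 24 controls and 23
patients aged 30-65 years, CAG repeats 40-48, eTIV ~ N(1.5e6, 1.2e5) mm^3,
a bilateral basal-ganglia + ventricle ROI panel with ~5-8% coefficients of
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .clinical_longitudinal import LongitudinalSeries
from .io_formats import (
    BiomarkerRecord,
    GLOBAL_REGION,
    SubjectMeta,
    VolumeImage,
    write_biomarker_csv,
    write_subject_meta,
    write_volume,
)

#: Default ROI panel: (region, measure) -> (control mean, control sd, age slope per year).
DEFAULT_ROI_PANEL: dict[tuple[str, str], tuple[float, float, float]] = {
    ("Left-Caudate", "volume_mm3"): (3600.0, 280.0, -12.0),
    ("Right-Caudate", "volume_mm3"): (3700.0, 290.0, -12.0),
    ("Left-Putamen", "volume_mm3"): (5000.0, 380.0, -18.0),
    ("Right-Putamen", "volume_mm3"): (4900.0, 370.0, -18.0),
    ("Left-Accumbens-area", "volume_mm3"): (550.0, 70.0, -2.0),
    ("Right-Accumbens-area", "volume_mm3"): (540.0, 68.0, -2.0),
    ("Left-Lateral-Ventricle", "volume_mm3"): (9000.0, 2500.0, 120.0),
    ("Right-Lateral-Ventricle", "volume_mm3"): (8500.0, 2400.0, 120.0),
    ("lh-precentral", "thickness_mm"): (2.55, 0.12, -0.004),
    ("rh-precentral", "thickness_mm"): (2.54, 0.12, -0.004),
    ("lh-insula", "thickness_mm"): (3.0, 0.15, -0.003),
    ("rh-insula", "thickness_mm"): (3.0, 0.15, -0.003),
    ("lh-precentral", "volume_mm3"): (13000.0, 1100.0, -40.0),
    ("rh-precentral", "volume_mm3"): (12900.0, 1100.0, -40.0),
    ("lh-postcentral", "thickness_mm"): (2.05, 0.11, -0.003),
    ("rh-postcentral", "thickness_mm"): (2.04, 0.11, -0.003),
    ("lh-superiorfrontal", "thickness_mm"): (2.70, 0.13, -0.004),
    ("rh-superiorfrontal", "thickness_mm"): (2.69, 0.13, -0.004),
    ("lh-superiorparietal", "thickness_mm"): (2.20, 0.11, -0.003),
    ("rh-superiorparietal", "thickness_mm"): (2.19, 0.11, -0.003),
    ("lh-inferiorparietal", "thickness_mm"): (2.45, 0.12, -0.003),
    ("rh-inferiorparietal", "thickness_mm"): (2.44, 0.12, -0.003),
    ("lh-medialorbitofrontal", "thickness_mm"): (2.40, 0.13, -0.003),
    ("rh-medialorbitofrontal", "thickness_mm"): (2.39, 0.13, -0.003),
    ("global", "gm_total_mm3"): (650000.0, 55000.0, -1800.0),
    ("global", "wm_total_mm3"): (450000.0, 45000.0, -500.0),
}

TIV_MEAN = 1.5e6
TIV_SD = 1.2e5


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study."""

    seed: int = 0
    n_controls: int = 24
    n_patients: int = 23
    age_range: tuple[float, float] = (30.0, 65.0)
    roi_panel: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_PANEL)
    )
    #: (subject_id, biomarker key) -> shift in control-SD units.
    implants_roi: dict[tuple[str, tuple[str, str]], float] = field(default_factory=dict)
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    gm_template: str = "ellipsoid_shell"  # or "smooth_field"
    image_noise_sd: float = 0.05
    #: (subject_id, center voxel, radius in voxels, effect in noise-SD units).
    implants_voxel: list[tuple[str, tuple[int, int, int], float, float]] = field(
        default_factory=list
    )
    cag_range: tuple[int, int] = (40, 48)

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be non-negative")
        for _, center, radius, _ in self.implants_voxel:
            if radius >= min(self.grid_shape) / 2:
                raise ValueError("implant radius must be < half the smallest grid axis")
            for c, dim in zip(center, self.grid_shape):
                if not (0 <= c < dim):
                    raise ValueError(f"implant center {center} outside grid {self.grid_shape}")

    def subject_ids(self) -> list[str]:
        """Controls first, then patients; stable under cohort growth."""
        return [f"ctrl{i:03d}" for i in range(self.n_controls)] + [
            f"pat{i:03d}" for i in range(self.n_patients)
        ]


def _subject_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    # one stream per subject: cohort-size changes never reshuffle earlier subjects
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectMeta], list[BiomarkerRecord]]:
    """Draw metadata and ROI biomarker tables for controls and patients.

    Control values are Normal(mean + age_slope * (age - age midrange), sd) per
    ROI; patients are additionally shifted by ``implants_roi`` effect sizes in
    units of the control SD.
    """
    lo, hi = config.age_range
    mid = 0.5 * (lo + hi)
    metas: list[SubjectMeta] = []
    records: list[BiomarkerRecord] = []
    ids = config.subject_ids()
    for index, subject_id in enumerate(ids):
        rng = _subject_rng(config, index)
        is_patient = subject_id.startswith("pat")
        age = float(rng.uniform(lo, hi))
        sex = "f" if rng.random() < 0.5 else "m"
        cag = int(rng.integers(config.cag_range[0], config.cag_range[1] + 1)) if is_patient else None
        tiv = float(abs(rng.normal(TIV_MEAN, TIV_SD)))
        metas.append(
            SubjectMeta(
                subject_id=subject_id,
                group="patient" if is_patient else "control",
                age=age,
                sex=sex,
                cag=cag,
            )
        )
        records.append(
            BiomarkerRecord(subject_id, 1, GLOBAL_REGION, "etiv_mm3", tiv)
        )
        for key, (mean, sd, age_slope) in config.roi_panel.items():
            value = rng.normal(mean + age_slope * (age - mid), sd)
            if is_patient:
                value += config.implants_roi.get((subject_id, key), 0.0) * sd
            region, measure = key
            records.append(
                BiomarkerRecord(subject_id, 1, region, measure, float(value))
            )
    return metas, records


def _ellipsoid_shell(shape: tuple[int, int, int]) -> np.ndarray:
    # solid ellipsoid of GM-like intensity; zero background outside the "skull"
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    center = [(s - 1) / 2 for s in shape]
    semi = [0.42 * s for s in shape]
    r_out = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return np.where(r_out <= 1, 0.8, 0.0)


def _smooth_field(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0, mode="wrap")
    field_ -= field_.min()
    peak = field_.max()
    return field_ / peak if peak > 0 else field_


def template_image(config: SimulationConfig) -> VolumeImage:
    """Shared noise-free gray-matter template on the study grid."""
    affine = np.diag([*config.voxel_size, 1.0])
    if config.gm_template == "ellipsoid_shell":
        data = _ellipsoid_shell(config.grid_shape)
    elif config.gm_template == "smooth_field":
        data = _smooth_field(config.grid_shape, np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(10**6,))
        ))
    else:
        raise ValueError(f"unknown template {config.gm_template!r}")
    return VolumeImage(data=data, affine=affine)


def sphere_mask(
    shape: tuple[int, int, int], center: tuple[int, int, int], radius: float
) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2


def simulate_gm_images(config: SimulationConfig) -> dict[str, VolumeImage]:
    """Per-subject GM images: template + noise + implanted focal atrophy.

    Returns ``{subject_id: image}`` with controls first. Voxel implants
    subtract ``effect * image_noise_sd`` inside the stated sphere, clipped at
    zero intensity.
    """
    template = template_image(config)
    implants_by_subject: dict[str, list] = {}
    for subject_id, center, radius, effect in config.implants_voxel:
        implants_by_subject.setdefault(subject_id, []).append((center, radius, effect))
    images: dict[str, VolumeImage] = {}
    for index, subject_id in enumerate(config.subject_ids()):
        # offset the spawn key so image noise is independent of the ROI draws
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(index, 1))
        )
        data = template.data + rng.normal(0.0, config.image_noise_sd, config.grid_shape)
        for center, radius, effect in implants_by_subject.get(subject_id, []):
            data = data - effect * config.image_noise_sd * sphere_mask(
                config.grid_shape, center, radius
            )
        images[subject_id] = template.like(np.clip(data, 0.0, None))
    return images


def simulate_longitudinal(
    config: SimulationConfig,
    rates: dict[str, float],
    n_sessions: int = 2,
    interval_months: float = 12.0,
    baseline: float = 4000.0,
    noise_sd: float = 0.0,
    biomarker_key: tuple[str, str] = ("Left-Caudate", "volume_mm3"),
) -> list[LongitudinalSeries]:
    """Series with value = baseline + rate * years + noise per session."""
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    all_ids = config.subject_ids()
    series = []
    for subject_id, rate in rates.items():
        index = all_ids.index(subject_id) if subject_id in all_ids else hash(subject_id) % 2**16
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(index, 2))
        )
        sessions = []
        for s in range(n_sessions):
            months = s * interval_months
            value = baseline + rate * months / 12.0
            if noise_sd > 0:
                value += rng.normal(0.0, noise_sd)
            sessions.append((months, float(value)))
        series.append(
            LongitudinalSeries(subject_id=subject_id, biomarker_key=biomarker_key, sessions=sessions)
        )
    return series


def write_study(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a full synthetic study on disk (CSV tables + NIfTI images)."""
    out = Path(out_dir)
    (out / "controls").mkdir(parents=True, exist_ok=True)
    (out / "patients").mkdir(exist_ok=True)
    metas, records = simulate_cohort(config)
    meta_path = out / "meta.csv"
    bio_path = out / "biomarkers.csv"
    write_subject_meta(metas, meta_path)
    write_biomarker_csv(records, bio_path)
    paths = {"meta": meta_path, "biomarkers": bio_path}
    for subject_id, img in simulate_gm_images(config).items():
        sub = "controls" if subject_id.startswith("ctrl") else "patients"
        p = out / sub / f"{subject_id}.nii.gz"
        write_volume(img, p)
        paths[subject_id] = p
    return paths
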