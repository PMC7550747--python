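"""Readers and writers for every external format the pipeline touches.

Supported formats: FreeSurfer-dialect segmentation statistics tables
(``aseg.stats``, ``?h.aparc.stats``), long-format biomarker CSV, subject
metadata CSV, NIfTI-1 volumes, and CSV/JSON single-case result reports.

Region names are kept verbatim from the stats files (``Left-Caudate``,
``lh-precentral``); bilateral grouping is handled by the alias table in
:mod:`casemap.panels`. Voxel indexing is 0-based and world coordinates go
through the affine; images are never reoriented or resampled here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Biomarker measures carried by a record.
MEASURES = (
    "volume_mm3",
    "thickness_mm",
    "surface_area_mm2",
    "mean_curvature",
    "gm_total_mm3",
    "wm_total_mm3",
    "ventricles_mm3",
    "etiv_mm3",
)

#: ``# Measure`` names recognized in aseg.stats and their canonical measure.
ASEG_GLOBAL_MEASURES = {
    "EstimatedTotalIntraCranialVol": "etiv_mm3",
    "TotalGrayVol": "gm_total_mm3",
    "CerebralWhiteMatterVol": "wm_total_mm3",
    "VentricleChoroidVol": "ventricles_mm3",
}

#: Global-measure regions use this pseudo region name.
GLOBAL_REGION = "global"


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


@dataclass(frozen=True)
class BiomarkerRecord:
    """One (subject, session, region, measure) observation."""

    subject_id: str
    session: int
    region: str
    measure: str
    value: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise FormatError(
                f"unknown measure {self.measure!r}; allowed: {', '.join(MEASURES)}"
            )
        if self.session < 1:
            raise ValueError(f"session must be >= 1, got {self.session}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.region, self.measure)


@dataclass
class SubjectMeta:
    """Demographics and clinical metadata for one subject."""

    subject_id: str
    group: str  # "control" | "patient"
    age: float
    sex: str = "unknown"  # "f" | "m" | "unknown"
    cag: int | None = None
    session_intervals: list[float] = field(default_factory=lambda: [0.0])
    clinical_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"group must be control|patient, got {self.group!r}")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.cag is not None and self.cag < 0:
            raise ValueError("CAG repeat length cannot be negative")
        iv = self.session_intervals
        if any(t < 0 for t in iv) or any(b <= a for a, b in zip(iv, iv[1:])):
            raise ValueError("session_intervals must be non-negative and strictly increasing")


@dataclass
class VolumeImage:
    """A 3-D scalar grid with a voxel-to-world (RAS+) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "VolumeImage":
        """New image on this grid with different voxel data."""
        return VolumeImage(data=data, affine=self.affine.copy())


def check_same_grid(images: Sequence[VolumeImage], atol: float = 1e-4) -> None:
    """Raise unless all images share shape and affine (elementwise tolerance)."""
    ref = images[0]
    for i, img in enumerate(images[1:], start=1):
        if img.shape != ref.shape:
            raise ValueError(f"image {i} grid shape {img.shape} != {ref.shape}")
        if not np.allclose(img.affine, ref.affine, atol=atol):
            raise ValueError(f"image {i} affine differs from the reference affine")


# ---------------------------------------------------------------------------
# FreeSurfer stats dialect
# ---------------------------------------------------------------------------

def _split_stats_file(path: Path) -> tuple[list[tuple[int, str]], list[str], list[tuple[int, str]]]:
    """Split a stats file into measure comment lines, column headers, table rows."""
    measure_lines: list[tuple[int, str]] = []
    col_headers: list[str] = []
    rows: list[tuple[int, str]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("Measure"):
                measure_lines.append((lineno, body))
            elif body.startswith("ColHeaders"):
                col_headers = body.split()[1:]
            continue
        rows.append((lineno, line))
    return measure_lines, col_headers, rows


def _parse_measure_lines(
    measure_lines: Iterable[tuple[int, str]], subject_id: str, session: int
) -> list[BiomarkerRecord]:
    records = []
    for lineno, body in measure_lines:
        # "# Measure <name>, <short>, <description>, <value>, <unit>"
        parts = [p.strip() for p in body[len("Measure"):].split(",")]
        if len(parts) < 4:
            continue
        # the canonical name is the first or second comma field depending on
        # the segmentation version ("TotalGray, TotalGrayVol, ...")
        measure = ASEG_GLOBAL_MEASURES.get(parts[0]) or (
            ASEG_GLOBAL_MEASURES.get(parts[1]) if len(parts) > 1 else None
        )
        if measure is None:
            log.debug("ignoring unrecognized Measure line %r (line %d)", parts[0], lineno)
            continue
        try:
            value = float(parts[-2])
        except ValueError as exc:
            raise FormatError(f"non-numeric Measure value at line {lineno}: {parts[-2]!r}") from exc
        records.append(
            BiomarkerRecord(subject_id, session, GLOBAL_REGION, measure, value)
        )
    return records


def _column_indices(col_headers: list[str], required: Sequence[str], path: Path) -> dict[str, int]:
    if not col_headers:
        raise FormatError(f"{path}: no ColHeaders line found")
    idx = {}
    for col in required:
        if col not in col_headers:
            raise FormatError(f"{path}: missing required column {col!r}")
        idx[col] = col_headers.index(col)
    return idx


def _cell_float(cells: list[str], i: int, lineno: int) -> float:
    try:
        return float(cells[i])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"non-numeric value cell at line {lineno}: {cells[i] if i < len(cells) else '<missing>'!r}") from exc


def read_aseg_stats(path: str | Path, subject_id: str, session: int = 1) -> list[BiomarkerRecord]:
    """Parse an ``aseg.stats`` file into biomarker records.

    Each table row yields one ``volume_mm3`` record; recognized ``# Measure``
    header lines (eTIV, total gray, cerebral white matter, ventricles) yield
    one global record each.
    """
    path = Path(path)
    measure_lines, col_headers, rows = _split_stats_file(path)
    records = _parse_measure_lines(measure_lines, subject_id, session)
    if rows:
        idx = _column_indices(col_headers, ["SegId", "Volume_mm3", "StructName"], path)
        for lineno, line in rows:
            cells = line.split()
            region = cells[idx["StructName"]]
            value = _cell_float(cells, idx["Volume_mm3"], lineno)
            records.append(BiomarkerRecord(subject_id, session, region, "volume_mm3", value))
    _check_unique(records, path)
    return records


#: aparc table column -> measure.
_APARC_COLUMNS = {
    "SurfArea": "surface_area_mm2",
    "GrayVol": "volume_mm3",
    "ThickAvg": "thickness_mm",
    "MeanCurv": "mean_curvature",
}


def read_aparc_stats(
    path: str | Path, hemisphere: str, subject_id: str, session: int = 1
) -> list[BiomarkerRecord]:
    """Parse an ``?h.aparc.stats`` file: four measures per cortical region.

    Regions are prefixed ``lh-`` / ``rh-`` according to ``hemisphere``. If the
    file's own ``# hemi`` comment disagrees with the argument, a warning is
    logged and the argument wins.
    """
    if hemisphere not in ("lh", "rh"):
        raise ValueError(f"hemisphere must be lh|rh, got {hemisphere!r}")
    path = Path(path)
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line.startswith("#") and line.lstrip("#").strip().startswith("hemi"):
            file_hemi = line.lstrip("#").split()[-1]
            if file_hemi in ("lh", "rh") and file_hemi != hemisphere:
                log.warning(
                    "%s declares hemisphere %s but %s was requested; using %s",
                    path, file_hemi, hemisphere, hemisphere,
                )
            break
    _, col_headers, rows = _split_stats_file(path)
    required = ["StructName", *(_APARC_COLUMNS)]
    idx = _column_indices(col_headers, required, path)
    records: list[BiomarkerRecord] = []
    for lineno, line in rows:
        cells = line.split()
        region = f"{hemisphere}-{cells[idx['StructName']]}"
        for col, measure in _APARC_COLUMNS.items():
            value = _cell_float(cells, idx[col], lineno)
            records.append(BiomarkerRecord(subject_id, session, region, measure, value))
    _check_unique(records, path)
    return records


def _check_unique(records: Sequence[BiomarkerRecord], source: object) -> None:
    seen: set[tuple] = set()
    for r in records:
        k = (r.subject_id, r.session, r.region, r.measure)
        if k in seen:
            raise FormatError(f"{source}: duplicate record for {k}")
        seen.add(k)


# ---------------------------------------------------------------------------
# Long-format biomarker CSV
# ---------------------------------------------------------------------------

_BIOMARKER_COLUMNS = ["subject_id", "session", "region", "measure", "value"]


def read_biomarker_csv(path: str | Path) -> list[BiomarkerRecord]:
    """Read a long-format biomarker CSV (alternate ingestion path).

    Rows with a missing / non-numeric value are skipped with a logged warning;
    the skip count is reported in one log line so no row vanishes silently.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in _BIOMARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    has_norm = "normalized" in df.columns
    records: list[BiomarkerRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        value = pd.to_numeric(getattr(row, "value"), errors="coerce")
        if pd.isna(value):
            skipped += 1
            log.warning("skipping row with non-numeric value: %s", tuple(row))
            continue
        records.append(
            BiomarkerRecord(
                subject_id=str(row.subject_id),
                session=int(row.session),
                region=str(row.region),
                measure=str(row.measure),
                value=float(value),
                normalized=bool(getattr(row, "normalized")) if has_norm else False,
            )
        )
    if skipped:
        log.warning("%s: skipped %d of %d rows with missing values", path, skipped, len(df))
    _check_unique(records, path)
    return records


def write_biomarker_csv(records: Sequence[BiomarkerRecord], path: str | Path) -> None:
    """Write records to the long CSV format; round-trips with the reader."""
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "session": r.session,
                "region": r.region,
                "measure": r.measure,
                "value": repr(r.value),
                "normalized": r.normalized,
            }
            for r in records
        ],
        columns=[*_BIOMARKER_COLUMNS, "normalized"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Subject metadata CSV
# ---------------------------------------------------------------------------

_META_BASE = ["subject_id", "group", "age", "sex", "cag", "session_intervals"]


def read_subject_meta(path: str | Path) -> list[SubjectMeta]:
    """Read subject metadata; columns beyond the base set become clinical scores.

    ``session_intervals`` is a semicolon-separated list of months from baseline
    (optional; defaults to a single baseline session).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "group", "age"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    score_cols = [c for c in df.columns if c not in _META_BASE]
    metas = []
    for row in df.itertuples(index=False):
        cag = getattr(row, "cag", None)
        cag = None if cag is None or pd.isna(cag) else int(cag)
        intervals = [0.0]
        raw_iv = getattr(row, "session_intervals", None)
        if raw_iv is not None and not pd.isna(raw_iv):
            intervals = [float(t) for t in str(raw_iv).split(";")]
        scores = {}
        for c in score_cols:
            v = getattr(row, c)
            if not pd.isna(v):
                scores[c] = float(v)
        metas.append(
            SubjectMeta(
                subject_id=str(row.subject_id),
                group=str(row.group),
                age=float(row.age),
                sex=str(getattr(row, "sex", "unknown")),
                cag=cag,
                session_intervals=intervals,
                clinical_scores=scores,
            )
        )
    return metas


def write_subject_meta(metas: Sequence[SubjectMeta], path: str | Path) -> None:
    score_names = sorted({name for m in metas for name in m.clinical_scores})
    rows = []
    for m in metas:
        row = {
            "subject_id": m.subject_id,
            "group": m.group,
            "age": m.age,
            "sex": m.sex,
            "cag": m.cag if m.cag is not None else "",
            "session_intervals": ";".join(repr(t) for t in m.session_intervals),
        }
        for name in score_names:
            row[name] = m.clinical_scores.get(name, "")
        rows.append(row)
    pd.DataFrame(rows, columns=[*_META_BASE, *score_names]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# NIfTI-1 volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> VolumeImage:
    """Load a single-frame NIfTI-1 image (4-D with one frame is squeezed)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(
                f"{path}: {data.shape[3]} frames; split the 4-D file into 3-D volumes"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D data, got shape {data.shape}")
    return VolumeImage(data=data.astype(np.float64), affine=np.asarray(img.affine))


def write_volume(img: VolumeImage, path: str | Path, description: str = "") -> None:
    """Write a NIfTI-1 file (float32 on disk)."""
    import nibabel as nib

    nifti = nib.Nifti1Image(img.data.astype(np.float32), img.affine)
    if description:
        nifti.header["descrip"] = description.encode()[:79]
    nib.save(nifti, str(path))


# ---------------------------------------------------------------------------
# Single-case result reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "region", "measure", "n_controls", "control_mean", "control_sd",
    "z", "t", "df", "p", "p_adj", "significant", "direction",
]


def _result_row(r) -> dict:
    region, measure = r.biomarker_key
    return {
        "region": region,
        "measure": measure,
        "n_controls": r.n,
        "control_mean": r.control_mean,
        "control_sd": r.control_sd,
        "z": r.z,
        "t": r.t,
        "df": r.df,
        "p": r.p,
        "p_adj": r.p_adj,
        "significant": r.significant,
        "direction": r.direction,
    }


def write_report(results: Sequence, path: str | Path, format: str = "csv") -> None:
    """Write single-case results as CSV or JSON.

    Numeric fields are serialized with at least 10 significant digits so that
    reruns produce byte-identical tables.
    """
    rows = [_result_row(r) for r in results]
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(",".join(_REPORT_COLUMNS) + "\n")
            for row in rows:
                cells = []
                for col in _REPORT_COLUMNS:
                    v = row[col]
                    if isinstance(v, bool):
                        cells.append(str(v))
                    elif isinstance(v, float):
                        cells.append(f"{v:.12g}")
                    else:
                        cells.append(str(v))
                fh.write(",".join(cells) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"format must be csv|json, got {format!r}")


def read_report_json(path: str | Path) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise FormatError(f"{path}: expected a JSON array of result rows")
    return data
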