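"""Reading and writing thickness maps, cohort tables, and result tables.

En-face total retinal thickness maps are stored as plain CSV matrices of
micrometre values (comma separated, no header, "." decimal) with a JSON
sidecar of the same stem carrying the scan metadata: laterality (OD/OS),
nominal scan extent, optional fovea coordinates and scan quality.  Missing
pixels are empty cells.  Cohort tables are ordinary CSV files; per-eye map
files are named ``<subject_id>_<OD|OS>.csv``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LATERALITIES = ("OD", "OS")
GROUPS = ("PD", "HC")
SEXES = ("F", "M")

#: Maximum credible total retinal thickness in micrometres.
THICKNESS_MAX_UM = 1000.0

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age_years",
    "axial_length_od_mm",
    "axial_length_os_mm",
    "age_at_diagnosis",
]


class FormatError(ValueError):
    """A file is structurally unreadable (missing sidecar, bad CSV cell)."""


class ValidationError(ValueError):
    """A file parsed but violates a domain invariant."""


@dataclass
class ThicknessMap:
    """En-face total retinal thickness map over a nominally square macular scan.

    Parameters
    ----------
    values : ndarray
        Thickness in µm, shape (rows, cols).  NaN marks missing pixels.
    laterality : str
        "OD" (right eye) or "OS" (left eye).
    nominal_extent_mm : float
        Scan extent assumed by the device (6.0 mm for the macular cube).
    pixel_pitch_mm : tuple of float
        Physical (row, col) spacing between grid points.  Grid points span
        the extent inclusively, so the pitch is extent / (dim - 1).
    fovea_rc : tuple of float, optional
        Continuous (row, col) coordinates of the foveal centre.
    quality : float, optional
        Device signal-quality score on a 0-10 scale.
    """

    values: np.ndarray
    laterality: str
    nominal_extent_mm: float = 6.0
    pixel_pitch_mm: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    fovea_rc: Optional[tuple[float, float]] = None
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("thickness values must be a 2-D matrix")
        if self.laterality not in LATERALITIES:
            raise ValidationError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )
        if self.pixel_pitch_mm is None:
            nrow, ncol = self.values.shape
            self.pixel_pitch_mm = (
                self.nominal_extent_mm / (nrow - 1),
                self.nominal_extent_mm / (ncol - 1),
            )
        self.pixel_pitch_mm = (float(self.pixel_pitch_mm[0]), float(self.pixel_pitch_mm[1]))
        if not all(p > 0 for p in self.pixel_pitch_mm):
            raise ValidationError("pixel pitch must be positive in both axes")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not ((finite > 0) & (finite < THICKNESS_MAX_UM)).all():
            bad = finite[(finite <= 0) | (finite >= THICKNESS_MAX_UM)][0]
            raise ValidationError(
                f"thickness values must lie in (0, {THICKNESS_MAX_UM}) µm; found {bad}"
            )
        if np.isinf(self.values).any():
            raise ValidationError("thickness values must be finite or NaN (missing)")
        if self.fovea_rc is not None:
            r, c = self.fovea_rc
            nrow, ncol = self.values.shape
            if not (0 <= r <= nrow - 1 and 0 <= c <= ncol - 1):
                raise ValidationError(f"fovea_rc {self.fovea_rc} outside matrix bounds")
            self.fovea_rc = (float(r), float(c))
        if self.quality is not None and not 0 <= self.quality <= 10:
            raise ValidationError(f"quality must lie in [0, 10], got {self.quality}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_pitch(self, pitch: tuple[float, float]) -> "ThicknessMap":
        """Copy of the map with a new physical pixel pitch (values untouched)."""
        return replace(self, pixel_pitch_mm=pitch)


@dataclass
class SubjectRecord:
    """Clinical covariates and biometry for one study participant."""

    subject_id: str
    group: str
    sex: str
    age_years: float
    axial_length_od_mm: Optional[float] = None
    axial_length_os_mm: Optional[float] = None
    age_at_diagnosis: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"subject {self.subject_id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if not self.age_years > 0:
            raise ValidationError(f"subject {self.subject_id}: age must be positive")
        for name in ("axial_length_od_mm", "axial_length_os_mm"):
            al = getattr(self, name)
            if al is not None and not 20.0 <= al <= 30.0:
                raise ValidationError(
                    f"subject {self.subject_id}: {name}={al} outside [20, 30] mm"
                )

    def axial_length(self, laterality: str) -> Optional[float]:
        return self.axial_length_od_mm if laterality == "OD" else self.axial_length_os_mm


@dataclass
class Cohort:
    """Subjects plus their per-eye thickness maps keyed by (subject_id, laterality)."""

    subjects: list[SubjectRecord]
    maps: dict[tuple[str, str], ThicknessMap]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate subject ids: {sorted(dupes)}")
        known = set(ids)
        for sid, lat in self.maps:
            if sid not in known:
                raise ValidationError(f"map for unknown subject {sid!r}")
            if lat not in LATERALITIES:
                raise ValidationError(f"map key laterality {lat!r} invalid")

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def n_eyes(self) -> int:
        return len(self.maps)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_thickness_map(path: str | Path) -> ThicknessMap:
    """Read a CSV thickness matrix plus its JSON sidecar into a ThicknessMap.

    The pixel pitch is initialised from the sidecar's ``nominal_extent_mm``
    as extent / (dim - 1) per axis; apply the axial-length correction
    afterwards to obtain physical coordinates.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar} for {path}")
    meta = json.loads(sidecar.read_text())
    try:
        values = _read_matrix(path)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
    fovea = meta.get("fovea_rc")
    return ThicknessMap(
        values=values,
        laterality=meta.get("laterality"),
        nominal_extent_mm=float(meta.get("nominal_extent_mm", 6.0)),
        fovea_rc=tuple(fovea) if fovea is not None else None,
        quality=meta.get("quality"),
    )


def _read_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line and not rows:
                continue
            row = []
            for j, cell in enumerate(line.split(",")):
                cell = cell.strip()
                if cell == "":
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {i}, col {j}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    width = {len(r) for r in rows}
    if len(width) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(width)})")
    return np.array(rows, dtype=float)


def write_thickness_map(tmap: ThicknessMap, path: str | Path) -> None:
    """Write CSV + JSON sidecar such that :func:`read_thickness_map` inverts it."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in tmap.values:
            fh.write(",".join("" if np.isnan(v) else repr(float(v)) for v in row))
            fh.write("\n")
    meta: dict = {
        "laterality": tmap.laterality,
        "nominal_extent_mm": tmap.nominal_extent_mm,
    }
    if tmap.fovea_rc is not None:
        meta["fovea_rc"] = list(tmap.fovea_rc)
    if tmap.quality is not None:
        meta["quality"] = tmap.quality
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_cohort(table_path: str | Path, maps_dir: str | Path) -> Cohort:
    """Read a cohort CSV and every per-eye map file present in ``maps_dir``.

    Eyes whose map file ``<subject_id>_<OD|OS>.csv`` does not exist are
    logged and skipped; the cohort keeps the subject regardless.
    """
    table_path, maps_dir = Path(table_path), Path(maps_dir)
    df = pd.read_csv(table_path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{table_path}: missing columns {missing}")
    subjects = []
    for idx, row in df.iterrows():
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    sex=str(row["sex"]),
                    age_years=float(row["age_years"]),
                    axial_length_od_mm=_opt(row["axial_length_od_mm"]),
                    axial_length_os_mm=_opt(row["axial_length_os_mm"]),
                    age_at_diagnosis=_opt(row["age_at_diagnosis"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{table_path} row {idx}: {exc}") from exc
    maps: dict[tuple[str, str], ThicknessMap] = {}
    for rec in subjects:
        for lat in LATERALITIES:
            mp = maps_dir / f"{rec.subject_id}_{lat}.csv"
            if mp.exists():
                maps[(rec.subject_id, lat)] = read_thickness_map(mp)
            else:
                logger.info("no map for eye (%s, %s)", rec.subject_id, lat)
    return Cohort(subjects=subjects, maps=maps)


def write_cohort(cohort: Cohort, table_path: str | Path, maps_dir: str | Path) -> None:
    """Write the cohort table and all maps in the formats read_cohort expects."""
    maps_dir = Path(maps_dir)
    maps_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "age_years": s.age_years,
                "axial_length_od_mm": s.axial_length_od_mm,
                "axial_length_os_mm": s.axial_length_os_mm,
                "age_at_diagnosis": s.age_at_diagnosis,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(table_path, index=False)
    for (sid, lat), tmap in cohort.maps.items():
        write_thickness_map(tmap, maps_dir / f"{sid}_{lat}.csv")


def load_pd_demographics() -> pd.DataFrame:
    """Packaged Parkinson's-cohort demographics table (33 patients).

    Columns: subject_id, age_years, sex, updrs_motor (NaN where not
    documented), age_at_diagnosis, on_levodopa, age_dopa_started,
    other_medications.  Ages are at the date of imaging.
    """
    with resources.files("macula.data").joinpath("pd_demographics.csv").open() as fh:
        return pd.read_csv(fh)
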