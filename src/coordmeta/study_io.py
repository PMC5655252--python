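"""Reading, validation, and harmonisation of study and peak tables.

A coordinate-based meta-analysis starts from two plain-text inputs: a study
table (one row per included VBM study: sample sizes, demographics, clinical
scores, scanner and analysis settings) and, per study, a table of reported
peak coordinates with their statistics.  Both are TSV with the missing-value
sentinel ``NA``; the canonical column orders are given by
:data:`STUDY_COLUMNS` and :data:`PEAK_COLUMNS`.

Coordinates may be reported in MNI or Talairach space; :func:`convert_to_mni`
maps Talairach coordinates to MNI through a single fixed affine (the inverse
of the Lancaster *icbm2tal* transform for SPM-normalised data), so the
conversion is deterministic and invertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "PeakTable",
    "STUDY_COLUMNS",
    "PEAK_COLUMNS",
    "ICBM2TAL",
    "load_study_table",
    "write_study_table",
    "load_peak_tables",
    "write_peak_tables",
    "convert_to_mni",
    "summarize_availability",
    "StudyTableError",
]

NA = "NA"

STUDY_COLUMNS = [
    "study_id",
    "n_patients",
    "male_patients",
    "n_controls",
    "male_controls",
    "age_patient_mean",
    "age_patient_sd",
    "age_control_mean",
    "age_control_sd",
    "updrs3_mean",
    "updrs3_sd",
    "hy_mean",
    "hy_sd",
    "duration_mean",
    "duration_sd",
    "mmse_mean",
    "mmse_sd",
    "fab_mean",
    "fab_sd",
    "scanner_tesla",
    "software",
    "smoothing_fwhm_mm",
    "threshold_p",
    "threshold_corrected",
    "quality_score",
    "subgroup_tags",
]

PEAK_COLUMNS = ["study_id", "x", "y", "z", "space", "direction", "stat_type", "stat_value"]

SPACES = ("MNI", "Talairach")
DIRECTIONS = ("decrease", "increase")
STAT_TYPES = ("t", "z", "p_only", "unreported")

# Lancaster et al. icbm2tal affine for SPM-normalised data: maps MNI (ICBM)
# mm to Talairach mm.  Talairach coordinates are converted to MNI with its
# inverse.  Recorded here as the single documented conversion matrix.
ICBM2TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
_TAL2ICBM = np.linalg.inv(ICBM2TAL)


class StudyTableError(ValueError):
    """Malformed study or peak table (message names the offending row/column)."""


@dataclass(frozen=True)
class StudyRecord:
    """One included study's demographic, clinical, and imaging metadata."""

    study_id: str
    n_patients: int
    n_controls: int
    male_patients: Optional[int] = None
    male_controls: Optional[int] = None
    age_patient_mean: Optional[float] = None
    age_patient_sd: Optional[float] = None
    age_control_mean: Optional[float] = None
    age_control_sd: Optional[float] = None
    updrs3_mean: Optional[float] = None
    updrs3_sd: Optional[float] = None
    hy_mean: Optional[float] = None
    hy_sd: Optional[float] = None
    duration_mean: Optional[float] = None
    duration_sd: Optional[float] = None
    mmse_mean: Optional[float] = None
    mmse_sd: Optional[float] = None
    fab_mean: Optional[float] = None
    fab_sd: Optional[float] = None
    scanner_tesla: Optional[float] = None
    software: str = ""
    smoothing_fwhm_mm: Optional[float] = None
    threshold_p: Optional[float] = None
    threshold_corrected: bool = False
    quality_score: float = 0.0
    subgroup_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise StudyTableError("study_id must be non-empty")
        if self.n_patients < 1 or self.n_controls < 1:
            raise StudyTableError(f"{self.study_id}: group sizes must be >= 1")
        if self.male_patients is not None and not 0 <= self.male_patients <= self.n_patients:
            raise StudyTableError(
                f"{self.study_id}: male_patients outside [0, n_patients]"
            )
        if self.male_controls is not None and not 0 <= self.male_controls <= self.n_controls:
            raise StudyTableError(
                f"{self.study_id}: male_controls outside [0, n_controls]"
            )
        if not 0 <= self.quality_score <= 10:
            raise StudyTableError(f"{self.study_id}: quality_score outside [0, 10]")
        if self.scanner_tesla is not None and self.scanner_tesla not in (1.5, 3.0):
            raise StudyTableError(
                f"{self.study_id}: scanner_tesla must be 1.5, 3.0 or missing"
            )
        object.__setattr__(self, "subgroup_tags", frozenset(self.subgroup_tags))

    @property
    def male_ratio(self) -> Optional[float]:
        """Male proportion in the patient group, if male counts are known."""
        if self.male_patients is None:
            return None
        return self.male_patients / self.n_patients


@dataclass
class PeakTable:
    """One study's reported peak coordinates with statistics."""

    study_id: str
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.peaks, columns=PEAK_COLUMNS[1:]) if len(self.peaks) else (
            pd.DataFrame(columns=PEAK_COLUMNS[1:])
        )
        for col in ("x", "y", "z"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if len(df) and not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise StudyTableError(f"{self.study_id}: non-finite coordinate in column {col}")
        if len(df):
            bad = ~df["space"].isin(SPACES)
            if bad.any():
                raise StudyTableError(
                    f"{self.study_id}: unknown space {df.loc[bad, 'space'].iloc[0]!r}"
                )
            bad = ~df["direction"].isin(DIRECTIONS)
            if bad.any():
                raise StudyTableError(
                    f"{self.study_id}: unknown direction {df.loc[bad, 'direction'].iloc[0]!r}"
                )
            bad = ~df["stat_type"].isin(STAT_TYPES)
            if bad.any():
                raise StudyTableError(
                    f"{self.study_id}: unknown stat_type {df.loc[bad, 'stat_type'].iloc[0]!r}"
                )
        self.peaks = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.peaks)

    def mni_coordinates(self) -> np.ndarray:
        """(n, 3) peak coordinates, Talairach rows converted to MNI."""
        if not len(self):
            return np.empty((0, 3))
        xyz = self.peaks[["x", "y", "z"]].to_numpy(dtype=float)
        out = xyz.copy()
        tal = (self.peaks["space"] == "Talairach").to_numpy()
        if tal.any():
            out[tal] = np.array([convert_to_mni(p, "Talairach") for p in xyz[tal]])
        return out


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_float(raw: str, study: str, col: str) -> Optional[float]:
    if raw == NA or raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise StudyTableError(f"study {study!r}, column {col!r}: not a number: {raw!r}") from exc


def _parse_int(raw: str, study: str, col: str) -> Optional[int]:
    v = _parse_float(raw, study, col)
    if v is None:
        return None
    if v != int(v):
        raise StudyTableError(f"study {study!r}, column {col!r}: not an integer: {raw!r}")
    return int(v)


def _fmt(v) -> str:
    if v is None:
        return NA
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, frozenset) or isinstance(v, (set, list, tuple)):
        return ";".join(sorted(v)) if v else NA
    if isinstance(v, float):
        if math.isnan(v):
            return NA
        return format(v, "g")
    return str(v)


def load_study_table(path) -> List[StudyRecord]:
    """Read a study table TSV into validated :class:`StudyRecord` rows."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise StudyTableError(f"{path}: empty file (missing header)")
    header = lines[0].split("\t")
    if header != STUDY_COLUMNS:
        raise StudyTableError(
            f"{path}: header does not match the documented schema "
            f"(first mismatch at column {next((i for i, (a, b) in enumerate(zip(header, STUDY_COLUMNS)) if a != b), min(len(header), len(STUDY_COLUMNS)))})"
        )
    records: List[StudyRecord] = []
    seen = set()
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(STUDY_COLUMNS):
            raise StudyTableError(
                f"{path}: row {row_no} has {len(cells)} cells, expected {len(STUDY_COLUMNS)}"
            )
        d = dict(zip(STUDY_COLUMNS, cells))
        sid = d["study_id"]
        if sid in seen:
            raise StudyTableError(f"{path}: duplicate study_id {sid!r} at row {row_no}")
        seen.add(sid)
        corrected_raw = d["threshold_corrected"]
        if corrected_raw not in ("true", "false"):
            raise StudyTableError(
                f"study {sid!r}, column 'threshold_corrected': expected true/false, got {corrected_raw!r}"
            )
        tags = frozenset(t for t in d["subgroup_tags"].split(";") if t and t != NA)
        rec = StudyRecord(
            study_id=sid,
            n_patients=_parse_int(d["n_patients"], sid, "n_patients") or 0,
            n_controls=_parse_int(d["n_controls"], sid, "n_controls") or 0,
            male_patients=_parse_int(d["male_patients"], sid, "male_patients"),
            male_controls=_parse_int(d["male_controls"], sid, "male_controls"),
            age_patient_mean=_parse_float(d["age_patient_mean"], sid, "age_patient_mean"),
            age_patient_sd=_parse_float(d["age_patient_sd"], sid, "age_patient_sd"),
            age_control_mean=_parse_float(d["age_control_mean"], sid, "age_control_mean"),
            age_control_sd=_parse_float(d["age_control_sd"], sid, "age_control_sd"),
            updrs3_mean=_parse_float(d["updrs3_mean"], sid, "updrs3_mean"),
            updrs3_sd=_parse_float(d["updrs3_sd"], sid, "updrs3_sd"),
            hy_mean=_parse_float(d["hy_mean"], sid, "hy_mean"),
            hy_sd=_parse_float(d["hy_sd"], sid, "hy_sd"),
            duration_mean=_parse_float(d["duration_mean"], sid, "duration_mean"),
            duration_sd=_parse_float(d["duration_sd"], sid, "duration_sd"),
            mmse_mean=_parse_float(d["mmse_mean"], sid, "mmse_mean"),
            mmse_sd=_parse_float(d["mmse_sd"], sid, "mmse_sd"),
            fab_mean=_parse_float(d["fab_mean"], sid, "fab_mean"),
            fab_sd=_parse_float(d["fab_sd"], sid, "fab_sd"),
            scanner_tesla=_parse_float(d["scanner_tesla"], sid, "scanner_tesla"),
            software=d["software"] if d["software"] != NA else "",
            smoothing_fwhm_mm=_parse_float(d["smoothing_fwhm_mm"], sid, "smoothing_fwhm_mm"),
            threshold_p=_parse_float(d["threshold_p"], sid, "threshold_p"),
            threshold_corrected=corrected_raw == "true",
            quality_score=_parse_float(d["quality_score"], sid, "quality_score") or 0.0,
            subgroup_tags=tags,
        )
        records.append(rec)
    return records


def write_study_table(records: Sequence[StudyRecord], path) -> None:
    """Serialise study records in canonical TSV form (round-trip stable)."""
    lines = ["\t".join(STUDY_COLUMNS)]
    for rec in records:
        cells = []
        for col in STUDY_COLUMNS:
            v = getattr(rec, col)
            if col == "software":
                cells.append(v if v else NA)
            else:
                cells.append(_fmt(v))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_peak_tables(path, studies: Optional[Sequence[StudyRecord]] = None) -> List[PeakTable]:
    """Read peak tables from one TSV (or a directory of TSVs).

    When ``studies`` is given, every peak row must reference a known
    study_id, and the returned list covers *all* studies in their order —
    a study with no reported peaks yields an empty table (the encoding of
    "no significant differences").
    """
    path = Path(path)
    if path.is_dir():
        frames = []
        for f in sorted(path.glob("*.tsv")):
            frames.append(pd.read_csv(f, sep="\t", dtype={"study_id": str}, na_values=[NA], keep_default_na=False))
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PEAK_COLUMNS)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"study_id": str}, na_values=[NA], keep_default_na=False)
    missing_cols = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing_cols:
        raise StudyTableError(f"{path}: peak table missing columns {missing_cols}")
    for col in ("x", "y", "z"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise StudyTableError(f"{path}: non-numeric coordinate in column {col!r}") from exc
    df["stat_value"] = pd.to_numeric(df["stat_value"], errors="coerce")

    if studies is not None:
        known = {s.study_id for s in studies}
        unknown = set(df["study_id"]) - known
        if unknown:
            raise StudyTableError(
                f"{path}: peaks reference unknown study_id(s): {sorted(unknown)}"
            )
        order = [s.study_id for s in studies]
    else:
        order = list(dict.fromkeys(df["study_id"]))
    grouped = dict(tuple(df.groupby("study_id", sort=False)))
    out = []
    for sid in order:
        sub = grouped.get(sid)
        rows = sub[PEAK_COLUMNS[1:]] if sub is not None else pd.DataFrame(columns=PEAK_COLUMNS[1:])
        out.append(PeakTable(sid, rows))
    return out


def write_peak_tables(tables: Iterable[PeakTable], path) -> None:
    """Write peak tables as a single canonical TSV."""
    lines = ["\t".join(PEAK_COLUMNS)]
    for tbl in tables:
        for _, row in tbl.peaks.iterrows():
            sv = row["stat_value"]
            sv_txt = NA if sv is None or (isinstance(sv, float) and math.isnan(sv)) else format(float(sv), "g")
            lines.append(
                "\t".join(
                    [
                        tbl.study_id,
                        format(float(row["x"]), "g"),
                        format(float(row["y"]), "g"),
                        format(float(row["z"]), "g"),
                        str(row["space"]),
                        str(row["direction"]),
                        str(row["stat_type"]),
                        sv_txt,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def convert_to_mni(peak, space: str) -> np.ndarray:
    """Convert a coordinate triple to MNI mm.

    MNI input is returned unchanged; Talairach input is mapped through the
    inverse of the documented :data:`ICBM2TAL` affine.  The mapping is
    deterministic and invertible.
    """
    xyz = np.asarray(peak, dtype=float)
    if xyz.shape != (3,):
        raise ValueError("peak must be a coordinate triple")
    if space == "MNI":
        return xyz
    if space == "Talairach":
        return _TAL2ICBM[:3, :3] @ xyz + _TAL2ICBM[:3, 3]
    raise ValueError(f"unknown coordinate space {space!r}")


#: Covariates summarised by :func:`summarize_availability`: display name ->
#: attribute holding the study-level value.
AVAILABILITY_FIELDS = {
    "age": "age_patient_mean",
    "male_ratio": "male_ratio",
    "updrs3": "updrs3_mean",
    "hy": "hy_mean",
    "duration": "duration_mean",
    "mmse": "mmse_mean",
    "fab": "fab_mean",
    "scanner_tesla": "scanner_tesla",
}


def summarize_availability(studies: Sequence[StudyRecord]) -> pd.DataFrame:
    """Per-covariate reporting count and range of reported study means."""
    if not studies:
        raise ValueError("study list is empty")
    rows = []
    for name, attr in AVAILABILITY_FIELDS.items():
        vals = [getattr(s, attr) for s in studies]
        present = [v for v in vals if v is not None]
        rows.append(
            {
                "covariate": name,
                "n_reporting": len(present),
                "min": min(present) if present else np.nan,
                "max": max(present) if present else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
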