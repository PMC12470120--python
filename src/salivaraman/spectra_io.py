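"""Reading, writing and assembling Raman spectra and clinical tables.

Two on-disk spectrum dialects are supported:

``two_column_text``
    One acquisition per file: whitespace- or comma-separated
    ``(wavenumber, intensity)`` pairs, ``#``-prefixed comment lines ignored.
    Metadata (subject id, replicate index, stage) round-trips through header
    comments of the form ``# key: value``.

``csv_row``
    Matrix exchange: first row is the wavenumber axis, each subsequent row is
    one spectrum (first column a row label).

Wavenumbers are always cm^-1 and are never converted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ClinicalValidationError,
    GridMismatchError,
    LinkageError,
    SpectrumContentError,
    SpectrumParseError,
    StageError,
)

logger = logging.getLogger(__name__)

#: Pipeline stages in their only legal order.
STAGES = (
    "raw",
    "baseline_corrected",
    "aligned",
    "resampled",
    "normalized",
    "averaged",
)

GROUPS = ("OSAS", "CTR")
SMOKING_LEVELS = ("non_smoker", "smoker", "former")


@dataclass
class RamanSpectrum:
    """One Raman acquisition: an ascending wavenumber axis plus intensities.

    Parameters
    ----------
    wavenumbers : array-like
        Raman shift axis in cm^-1, strictly ascending, length >= 2.
    intensities : array-like
        Scattered intensity in arbitrary units, same length as the axis.
    subject_id : str
        Identifier of the donor; empty for anonymous spectra.
    replicate_index : int
        1-based acquisition index within the subject.
    stage : str
        Position in the preprocessing pipeline; one of :data:`STAGES`.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    subject_id: str = ""
    replicate_index: int = 1
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumContentError("axis and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise SpectrumContentError(
                f"axis length {self.wavenumbers.size} != "
                f"intensity length {self.intensities.size}"
            )
        if self.wavenumbers.size < 2:
            raise SpectrumContentError("a spectrum needs at least 2 points")
        dw = np.diff(self.wavenumbers)
        if np.any(dw == 0):
            raise SpectrumContentError("duplicate wavenumber in axis")
        if np.any(dw < 0):
            raise SpectrumContentError("wavenumber axis must be ascending")
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if self.replicate_index < 1:
            raise SpectrumContentError("replicate_index must be >= 1")

    # -- stage bookkeeping -------------------------------------------------
    def advanced(self, stage: str, wavenumbers=None, intensities=None) -> "RamanSpectrum":
        """Return a copy moved forward to `stage` with optionally new data."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise StageError(
                f"cannot move from stage {self.stage!r} to {stage!r}: "
                "stages only advance"
            )
        return replace(
            self,
            stage=stage,
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            intensities=self.intensities if intensities is None else intensities,
        )

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"expected stage in {allowed}, got {self.stage!r}"
            )

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass
class ClinicalRecord:
    """One row of the clinical covariate table.

    OSAS membership requires an apnea-hypopnea index (AHI) of at least
    5 events/h, the threshold at which the mild severity class begins.
    Optional assay columns (lactate, cortisol, SOD3) may be absent.
    """

    subject_id: str
    group: str
    age: Optional[float] = None
    sex: Optional[str] = None
    ahi: Optional[float] = None
    bmi: Optional[float] = None
    ess: Optional[int] = None
    smoking: Optional[str] = None
    lactate_uM: Optional[float] = None
    cortisol_ng_ml: Optional[float] = None
    sod3_pg_ml: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ClinicalValidationError(
                f"subject {self.subject_id!r}: unknown group {self.group!r}"
            )
        if self.ahi is not None and self.ahi < 0:
            raise ClinicalValidationError(
                f"subject {self.subject_id!r}: AHI must be >= 0"
            )
        if self.group == "OSAS" and (self.ahi is None or self.ahi < 5):
            raise ClinicalValidationError(
                f"subject {self.subject_id!r}: OSAS requires AHI >= 5 events/h"
            )
        if self.bmi is not None and self.bmi <= 0:
            raise ClinicalValidationError(
                f"subject {self.subject_id!r}: BMI must be > 0"
            )
        if self.ess is not None and not (0 <= self.ess <= 24):
            raise ClinicalValidationError(
                f"subject {self.subject_id!r}: ESS must lie in 0..24"
            )
        if self.smoking is not None and self.smoking not in SMOKING_LEVELS:
            raise ClinicalValidationError(
                f"subject {self.subject_id!r}: unknown smoking level "
                f"{self.smoking!r}"
            )
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ClinicalValidationError(
                f"subject {self.subject_id!r}: sex must be 'M' or 'F'"
            )


@dataclass
class SubjectRecord:
    """A subject: clinical covariates plus replicate (and averaged) spectra."""

    clinical: ClinicalRecord
    replicates: list = field(default_factory=list)
    averaged: Optional[RamanSpectrum] = None

    @property
    def subject_id(self) -> str:
        return self.clinical.subject_id

    @property
    def group(self) -> str:
        return self.clinical.group


@dataclass
class Cohort:
    """All subjects of a study, optionally with generator ground truth."""

    subjects: list
    grid: Optional[np.ndarray] = None
    ground_truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ClinicalValidationError("duplicate subject_id in cohort")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def by_group(self, group: str) -> list:
        return [s for s in self.subjects if s.group == group]


# ---------------------------------------------------------------------------
# spectrum I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("subject_id", "replicate_index", "stage")


def _parse_two_column(text: str, source: str) -> tuple:
    wn, it, meta = [], [], {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip()
                if key in _META_KEYS:
                    meta[key] = value.strip()
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) != 2:
            raise SpectrumParseError(
                f"{source}: line {lineno}: expected two columns, got "
                f"{len(parts)} ({stripped!r})"
            )
        try:
            wn.append(float(parts[0]))
            it.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(
                f"{source}: line {lineno}: non-numeric value ({stripped!r})"
            ) from exc
    return np.array(wn), np.array(it), meta


def read_spectrum(path, dialect: str = "two_column_text") -> RamanSpectrum:
    """Read one spectrum from `path`.

    Non-ascending axes are sorted on read with a logged warning; duplicate
    wavenumbers are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "two_column_text":
        wn, it, meta = _parse_two_column(text, str(path))
    elif dialect == "csv_row":
        frame = pd.read_csv(io.StringIO(text), index_col=0)
        if frame.shape[0] < 1:
            raise SpectrumContentError(f"{path}: no spectrum rows")
        try:
            wn = frame.columns.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise SpectrumParseError(
                f"{path}: csv_row header must be the wavenumber axis"
            ) from exc
        it = frame.iloc[0].to_numpy(dtype=float)
        meta = {"subject_id": str(frame.index[0])}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if wn.size < 2:
        raise SpectrumContentError(f"{path}: fewer than 2 points")
    if np.unique(wn).size != wn.size:
        raise SpectrumContentError(f"{path}: duplicate wavenumber")
    if np.any(np.diff(wn) < 0):
        logger.warning("%s: wavenumber axis not ascending; sorting on read", path)
        order = np.argsort(wn)
        wn, it = wn[order], it[order]

    return RamanSpectrum(
        wavenumbers=wn,
        intensities=it,
        subject_id=meta.get("subject_id", ""),
        replicate_index=int(meta.get("replicate_index", 1)),
        stage=meta.get("stage", "raw"),
    )


def write_spectrum(spectrum: RamanSpectrum, path, dialect: str = "two_column_text") -> None:
    """Write `spectrum` so that :func:`read_spectrum` reproduces it.

    Values are written with 17 significant digits, enough to round-trip
    IEEE doubles exactly.
    """
    path = Path(path)
    if dialect == "two_column_text":
        lines = [
            f"# subject_id: {spectrum.subject_id}",
            f"# replicate_index: {spectrum.replicate_index}",
            f"# stage: {spectrum.stage}",
        ]
        lines += [
            f"{w:.17g} {i:.17g}"
            for w, i in zip(spectrum.wavenumbers, spectrum.intensities)
        ]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "csv_row":
        header = ",".join(f"{w:.17g}" for w in spectrum.wavenumbers)
        row = ",".join(f"{i:.17g}" for i in spectrum.intensities)
        path.write_text(f"subject_id,{header}\n{spectrum.subject_id},{row}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_spectral_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a subjects x wavenumbers matrix (first row = axis) as CSV."""
    out = matrix.copy()
    out.columns = [f"{float(c):.10g}" for c in out.columns]
    out.to_csv(path, index_label="subject_id", float_format="%.10g")


def read_spectral_matrix(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_spectral_matrix`."""
    frame = pd.read_csv(path, index_col=0)
    frame.columns = frame.columns.astype(float)
    return frame


# ---------------------------------------------------------------------------
# clinical table I/O
# ---------------------------------------------------------------------------

_CLINICAL_FIELDS = (
    "subject_id", "group", "age", "sex", "ahi", "bmi", "ess", "smoking",
    "lactate_uM", "cortisol_ng_ml", "sod3_pg_ml",
)
_FLOAT_FIELDS = ("age", "ahi", "bmi", "lactate_uM", "cortisol_ng_ml", "sod3_pg_ml")


def read_clinical_table(path) -> list:
    """Read a clinical covariate CSV into validated :class:`ClinicalRecord` s.

    Required columns: ``subject_id`` and ``group``. Unknown columns survive in
    each record's ``extras`` dict; empty optional cells become ``None``.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "group"} - set(frame.columns)
    if missing:
        raise ClinicalValidationError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    records = []
    extra_cols = [c for c in frame.columns if c not in _CLINICAL_FIELDS]
    for _, row in frame.iterrows():
        kwargs = {"subject_id": str(row["subject_id"]), "group": str(row["group"])}
        for name in _CLINICAL_FIELDS[2:]:
            if name not in frame.columns or pd.isna(row[name]):
                continue
            value = row[name]
            if name in _FLOAT_FIELDS:
                value = float(value)
            elif name == "ess":
                value = int(value)
            else:
                value = str(value)
            kwargs[name] = value
        kwargs["extras"] = {
            c: row[c] for c in extra_cols if not pd.isna(row[c])
        }
        records.append(ClinicalRecord(**kwargs))
    ids = [r.subject_id for r in records]
    if len(ids) != len(set(ids)):
        raise ClinicalValidationError(f"{path}: duplicate subject_id")
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in _CLINICAL_FIELDS}
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def assemble_cohort(
    spectra: Iterable[RamanSpectrum],
    clinical: Sequence[ClinicalRecord],
) -> Cohort:
    """Group replicate spectra by subject and attach clinical covariates.

    Subjects are ordered by id; within a subject, replicates keep their input
    order but are renumbered contiguously from 1. A spectrum whose subject id
    is not in the clinical table raises :class:`LinkageError`.
    """
    by_id = {r.subject_id: r for r in clinical}
    buckets: dict = {sid: [] for sid in by_id}
    for spec in spectra:
        if spec.subject_id not in by_id:
            raise LinkageError(
                f"spectrum references unknown subject {spec.subject_id!r}"
            )
        buckets[spec.subject_id].append(spec)
    subjects = []
    for sid in sorted(by_id):
        reps = [
            replace(s, replicate_index=i)
            for i, s in enumerate(buckets[sid], start=1)
        ]
        subjects.append(SubjectRecord(clinical=by_id[sid], replicates=reps))
    return Cohort(subjects=subjects)


def clinical_frame(cohort: Cohort) -> pd.DataFrame:
    """Tabulate the cohort's clinical covariates (one row per subject)."""
    rows = []
    for s in cohort.subjects:
        rows.append({name: getattr(s.clinical, name) for name in _CLINICAL_FIELDS})
    return pd.DataFrame(rows).set_index("subject_id")
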