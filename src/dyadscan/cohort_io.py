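"""Cohort schema, subject records, table I/O and eligibility rules.

The cohort is a flat per-subject table (CSV/TSV, UTF-8, header row) holding
case/control status, sex, parental dementia history, parental birthplaces,
covariates and optional CSF endophenotypes.  Missing values are written with
a dedicated ``NA`` token so that a negative answer ("no") is never confused
with an unobtainable one ("unknown").

Three row-level rules live here because every downstream statistic depends
on them:

* control eligibility — controls must be strictly older than 75 years;
* dyad eligibility — subjects with both parents affected are excluded from
  univariate dyad tables (they are retained, with both indicators set, in
  the regression stages);
* the same-birthplace flag — exact string equality after normalisation
  (casefold, trim, diacritic stripping); neighbouring but distinct place
  names compare as different.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

NA_TOKEN = "NA"

STATUS_VALUES = ("case", "control")
SEX_VALUES = ("male", "female")
HISTORY_VALUES = ("yes", "no", "unknown")
PARENT_VALUES = ("father", "mother", "any")
APOE_ALLELES = ("e2", "e3", "e4")

#: onset at or below this age classifies a case as early onset (EOAD).
EOAD_MAX_ONSET = 65.0
#: controls must be strictly older than this at assessment.
CONTROL_MIN_AGE = 75.0

MANDATORY_COLUMNS = (
    "subject_id",
    "status",
    "sex",
    "age_at_assessment",
    "paternal_history",
    "maternal_history",
    "father_birthplace",
    "mother_birthplace",
)
OPTIONAL_COLUMNS = (
    "age_of_onset",
    "education",
    "year_of_birth",
    "n_siblings",
    "siblings_with_dementia",
    "apoe",
    "csf_abeta42",
    "csf_ttau",
    "csf_ptau",
    "age_at_lp",
)
COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

_FLOAT_COLUMNS = (
    "age_at_assessment",
    "age_of_onset",
    "education",
    "csf_abeta42",
    "csf_ttau",
    "csf_ptau",
    "age_at_lp",
)
_INT_COLUMNS = ("year_of_birth", "n_siblings", "siblings_with_dementia")
_POSITIVE_COLUMNS = ("csf_abeta42", "csf_ttau", "csf_ptau")


# ---------------------------------------------------------------------------
# normalisation helpers


def normalize_place(place) -> str | None:
    """Normalise a birthplace string for comparison.

    Casefolds, trims, collapses internal whitespace and strips diacritics.
    Returns ``None`` for missing/NA input.  No gazetteer logic: distinct
    names always compare as different, however close the places are.
    """
    if place is None:
        return None
    if isinstance(place, float) and np.isnan(place):
        return None
    s = str(place).strip()
    if not s or s.upper() == NA_TOKEN:
        return None
    s = unicodedata.normalize("NFKD", s)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = re.sub(r"\s+", " ", s).casefold().strip()
    return s or None


def normalize_apoe(value) -> str | None:
    """Canonicalise an APOE genotype to an ordered ``eX/eY`` pair.

    Accepts ``e3/e4``, ``E3E4``, ``3/4``, ``34`` and the epsilon glyphs.
    Raises ``ValueError`` when the value cannot be read as two alleles.
    """
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if not s or s.upper() == NA_TOKEN:
        return None
    s = s.lower().replace("ε", "e").replace("∊", "e")
    alleles = re.findall(r"[234]", s)
    if len(alleles) != 2:
        raise ValueError(f"cannot parse APOE genotype {value!r}")
    a, b = sorted(alleles)
    return f"e{a}/e{b}"


def _as_opt_float(value) -> float | None:
    if value is None:
        return None
    try:
        if np.isnan(value):  # type: ignore[arg-type]
            return None
    except TypeError:
        pass
    return float(value)


def _as_opt_int(value) -> int | None:
    f = _as_opt_float(value)
    return None if f is None else int(round(f))


# ---------------------------------------------------------------------------
# records


@dataclass
class SubjectRecord:
    """One row of the cohort table.

    ``onset_class`` is always derived from ``age_of_onset`` (early onset iff
    onset <= 65 years), never stored, so the invariant stays testable.
    """

    subject_id: str
    status: str
    sex: str
    age_at_assessment: float | None = None
    age_of_onset: float | None = None
    education: float | None = None
    year_of_birth: int | None = None
    paternal_history: str = "unknown"
    maternal_history: str = "unknown"
    father_birthplace: str | None = None
    mother_birthplace: str | None = None
    n_siblings: int | None = None
    siblings_with_dementia: int | None = None
    apoe: str | None = None
    csf_abeta42: float | None = None
    csf_ttau: float | None = None
    csf_ptau: float | None = None
    age_at_lp: float | None = None

    def validate(self) -> None:
        if self.status not in STATUS_VALUES:
            raise CohortValidationError(
                f"subject {self.subject_id}: status must be one of {STATUS_VALUES}, got {self.status!r}"
            )
        if self.sex not in SEX_VALUES:
            raise CohortValidationError(
                f"subject {self.subject_id}: sex must be one of {SEX_VALUES}, got {self.sex!r}"
            )
        for name in ("paternal_history", "maternal_history"):
            if getattr(self, name) not in HISTORY_VALUES:
                raise CohortValidationError(
                    f"subject {self.subject_id}: {name} must be one of {HISTORY_VALUES}"
                )
        if (
            self.n_siblings is not None
            and self.siblings_with_dementia is not None
            and self.siblings_with_dementia > self.n_siblings
        ):
            raise CohortValidationError(
                f"subject {self.subject_id}: siblings_with_dementia > n_siblings"
            )
        for name in _POSITIVE_COLUMNS:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise CohortValidationError(
                    f"subject {self.subject_id}: {name} must be strictly positive"
                )
        if self.apoe is not None:
            normalize_apoe(self.apoe)

    @property
    def onset_class(self) -> str | None:
        """``EOAD`` (onset <= 65), ``LOAD`` (onset >= 66) or None."""
        if self.age_of_onset is None:
            return None
        return "EOAD" if self.age_of_onset <= EOAD_MAX_ONSET else "LOAD"

    @property
    def apoe_e4_carrier(self) -> bool | None:
        if self.apoe is None:
            return None
        return "e4" in normalize_apoe(self.apoe)


@dataclass
class CohortTable:
    """An ordered cohort with provenance and a filter audit log.

    The canonical storage is a :class:`pandas.DataFrame` with the schema
    columns; ``records`` materialises :class:`SubjectRecord` objects on
    demand.  Every filter applied through :meth:`subset` is recorded in
    ``provenance["filters"]`` with its removed/retained row counts.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"cohort frame missing columns: {', '.join(missing)}")
        self.frame = self.frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        ids = self.frame["subject_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortValidationError(
                f"duplicate subject_id values: {sorted(set(dup))[:5]}"
            )
        self.provenance.setdefault("filters", [])

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_cases(self) -> int:
        return int((self.frame["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.frame["status"] == "control").sum())

    @property
    def records(self) -> list[SubjectRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            rec = SubjectRecord(
                subject_id=str(d["subject_id"]),
                status=d["status"],
                sex=d["sex"],
                age_at_assessment=_as_opt_float(d["age_at_assessment"]),
                age_of_onset=_as_opt_float(d["age_of_onset"]),
                education=_as_opt_float(d["education"]),
                year_of_birth=_as_opt_int(d["year_of_birth"]),
                paternal_history=d["paternal_history"],
                maternal_history=d["maternal_history"],
                father_birthplace=d["father_birthplace"],
                mother_birthplace=d["mother_birthplace"],
                n_siblings=_as_opt_int(d["n_siblings"]),
                siblings_with_dementia=_as_opt_int(d["siblings_with_dementia"]),
                apoe=d["apoe"],
                csf_abeta42=_as_opt_float(d["csf_abeta42"]),
                csf_ttau=_as_opt_float(d["csf_ttau"]),
                csf_ptau=_as_opt_float(d["csf_ptau"]),
                age_at_lp=_as_opt_float(d["age_at_lp"]),
            )
            out.append(rec)
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[SubjectRecord], provenance: dict | None = None
    ) -> "CohortTable":
        rows = []
        for rec in records:
            rec.validate()
            rows.append({f.name: getattr(rec, f.name) for f in _dc_fields(rec)})
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        for col in _FLOAT_COLUMNS + _INT_COLUMNS:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        return cls(frame, provenance or {})

    def subset(self, mask: Sequence[bool], filter_name: str) -> "CohortTable":
        """Return a filtered copy, logging removed/retained counts."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != len(self):
            raise ValueError("mask length does not match cohort size")
        new_frame = self.frame.loc[mask].reset_index(drop=True)
        prov = {k: v for k, v in self.provenance.items() if k != "filters"}
        prov["filters"] = list(self.provenance.get("filters", [])) + [
            {
                "filter": filter_name,
                "removed": int((~mask).sum()),
                "retained": int(mask.sum()),
            }
        ]
        return CohortTable(new_frame, prov)


# ---------------------------------------------------------------------------
# I/O


def _delimiter_for(path: Path, dialect: str | None) -> str:
    if dialect:
        return {"tsv": "\t", "csv": ",", "\t": "\t", ",": ","}.get(dialect, dialect)
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cohort(path, dialect: str | None = None) -> CohortTable:
    """Read a cohort CSV/TSV into a validated :class:`CohortTable`.

    Header matching is case-insensitive and order-free.  A missing mandatory
    column raises :class:`SchemaError` naming the column; unparseable cells
    raise :class:`CohortValidationError` carrying their row indices.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    sep = _delimiter_for(path, dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [str(c).strip().lower() for c in raw.columns]

    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    n = len(raw)
    errors: list[str] = []
    frame = pd.DataFrame(index=range(n))

    def col(name: str) -> pd.Series:
        if name in raw.columns:
            return raw[name].astype(str).str.strip()
        return pd.Series([""] * n, dtype=str)

    def missing_mask(s: pd.Series) -> pd.Series:
        return (s == "") | (s.str.upper() == NA_TOKEN)

    frame["subject_id"] = col("subject_id")
    for name, allowed in (
        ("status", STATUS_VALUES),
        ("sex", SEX_VALUES),
    ):
        s = col(name).str.lower()
        bad = ~s.isin(allowed)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(f"row {i}: invalid {name} value {raw[name].iloc[i]!r}")
        frame[name] = s

    for name in ("paternal_history", "maternal_history"):
        s = col(name).str.lower()
        s = s.mask(missing_mask(s), "unknown")
        bad = ~s.isin(HISTORY_VALUES)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(f"row {i}: invalid {name} value {raw[name].iloc[i]!r}")
        frame[name] = s

    for name in ("father_birthplace", "mother_birthplace"):
        s = col(name)
        frame[name] = s.mask(missing_mask(s), None)

    for name in _FLOAT_COLUMNS + _INT_COLUMNS:
        s = col(name)
        out = np.full(n, np.nan)
        present = ~missing_mask(s)
        for i in np.flatnonzero(present.to_numpy()):
            try:
                out[i] = float(s.iloc[i])
            except ValueError:
                errors.append(f"row {i}: unparseable {name} value {s.iloc[i]!r}")
        frame[name] = out

    apoe_raw = col("apoe")
    apoe_vals: list[str | None] = []
    for i in range(n):
        v = apoe_raw.iloc[i]
        if v == "" or v.upper() == NA_TOKEN:
            apoe_vals.append(None)
            continue
        try:
            apoe_vals.append(normalize_apoe(v))
        except ValueError:
            errors.append(f"row {i}: unparseable apoe value {v!r}")
            apoe_vals.append(None)
    frame["apoe"] = apoe_vals

    # row-level invariants
    sib_bad = (
        frame["n_siblings"].notna()
        & frame["siblings_with_dementia"].notna()
        & (frame["siblings_with_dementia"] > frame["n_siblings"])
    )
    for i in np.flatnonzero(sib_bad.to_numpy()):
        errors.append(f"row {i}: siblings_with_dementia exceeds n_siblings")
    for name in _POSITIVE_COLUMNS:
        bad = frame[name].notna() & (frame[name] <= 0)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(f"row {i}: {name} must be strictly positive")

    if errors:
        shown = "; ".join(errors[:10])
        more = f" (+{len(errors) - 10} more)" if len(errors) > 10 else ""
        raise CohortValidationError(f"{len(errors)} row error(s): {shown}{more}")

    return CohortTable(
        frame,
        provenance={"source": str(path), "rows_read": n, "filters": []},
    )


def write_cohort(cohort: CohortTable, path, dialect: str | None = None) -> None:
    """Write the cohort as CSV/TSV with ``NA`` for every missing value."""
    path = Path(path)
    sep = _delimiter_for(path, dialect)
    out = cohort.frame.copy()
    for name in _INT_COLUMNS:
        out[name] = out[name].map(
            lambda v: NA_TOKEN if pd.isna(v) else str(int(round(v)))
        )
    for name in _FLOAT_COLUMNS:
        out[name] = out[name].map(lambda v: NA_TOKEN if pd.isna(v) else repr(float(v)))
    for name in ("father_birthplace", "mother_birthplace", "apoe"):
        out[name] = out[name].map(lambda v: NA_TOKEN if v is None or pd.isna(v) else v)
    out.to_csv(path, sep=sep, index=False)


def write_filter_log(cohort: CohortTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cohort.provenance.get("filters", []), fh, indent=2)


# ---------------------------------------------------------------------------
# eligibility rules


def apply_control_eligibility(cohort: CohortTable) -> CohortTable:
    """Drop controls aged 75 or younger (cases are untouched).

    Controls with missing assessment age are also excluded; the filter log
    records the total removed.
    """
    age = cohort.frame["age_at_assessment"]
    is_control = (cohort.frame["status"] == "control").to_numpy()
    ok_age = (age.notna() & (age > CONTROL_MIN_AGE)).to_numpy()
    keep = ~is_control | ok_age
    return cohort.subset(keep, f"control_age_gt_{CONTROL_MIN_AGE:g}")


def dyad_eligible(subject: SubjectRecord, parent: str) -> str:
    """Classify a subject for a univariate dyad table.

    Returns ``exposed``, ``unexposed`` or ``excluded``.  Subjects with both
    parents affected are excluded from every univariate dyad, as is any
    subject whose relevant history is unknown.  For ``parent="any"`` both
    histories must be known and exposure means exactly one affected parent.
    Total and deterministic; the three outcomes partition any input.
    """
    if parent not in PARENT_VALUES:
        raise ValueError(f"parent must be one of {PARENT_VALUES}, got {parent!r}")
    pat, mat = subject.paternal_history, subject.maternal_history
    both_yes = pat == "yes" and mat == "yes"
    if parent == "father":
        if pat == "unknown" or both_yes:
            return "excluded"
        return "exposed" if pat == "yes" else "unexposed"
    if parent == "mother":
        if mat == "unknown" or both_yes:
            return "excluded"
        return "exposed" if mat == "yes" else "unexposed"
    if pat == "unknown" or mat == "unknown" or both_yes:
        return "excluded"
    return "exposed" if (pat == "yes") != (mat == "yes") else "unexposed"


def exposure_vector(frame: pd.DataFrame, parent: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`dyad_eligible`: ``(exposed, eligible)`` masks."""
    if parent not in PARENT_VALUES:
        raise ValueError(f"parent must be one of {PARENT_VALUES}, got {parent!r}")
    pat = frame["paternal_history"].to_numpy()
    mat = frame["maternal_history"].to_numpy()
    pat_yes, mat_yes = pat == "yes", mat == "yes"
    both_yes = pat_yes & mat_yes
    if parent == "father":
        eligible = (pat != "unknown") & ~both_yes
        exposed = pat_yes & eligible
    elif parent == "mother":
        eligible = (mat != "unknown") & ~both_yes
        exposed = mat_yes & eligible
    else:
        eligible = (pat != "unknown") & (mat != "unknown") & ~both_yes
        exposed = (pat_yes ^ mat_yes) & eligible
    return exposed, eligible


def same_town_flag(subject: SubjectRecord) -> str:
    """``same`` / ``different`` / ``unknown`` for the parental birthplaces."""
    f = normalize_place(subject.father_birthplace)
    m = normalize_place(subject.mother_birthplace)
    if f is None or m is None:
        return "unknown"
    return "same" if f == m else "different"


def same_town_vector(frame: pd.DataFrame) -> np.ndarray:
    """Vectorised :func:`same_town_flag` over the cohort frame."""
    f = frame["father_birthplace"].map(normalize_place)
    m = frame["mother_birthplace"].map(normalize_place)
    out = np.where(
        f.isna() | m.isna(),
        "unknown",
        np.where(f.to_numpy() == m.to_numpy(), "same", "different"),
    )
    return out.astype(object)


# ---------------------------------------------------------------------------
# machine-readable schema


def schema_dict() -> dict:
    """JSON-schema-style description of the cohort table."""
    props: dict[str, dict] = {
        "subject_id": {"type": "string", "description": "unique opaque id"},
        "status": {"enum": list(STATUS_VALUES)},
        "sex": {"enum": list(SEX_VALUES)},
        "age_at_assessment": {"type": "number", "unit": "years"},
        "age_of_onset": {"type": "number", "unit": "years", "nullable": True},
        "education": {"type": "number", "unit": "years", "nullable": True},
        "year_of_birth": {"type": "integer", "nullable": True},
        "paternal_history": {"enum": list(HISTORY_VALUES)},
        "maternal_history": {"enum": list(HISTORY_VALUES)},
        "father_birthplace": {"type": "string", "nullable": True},
        "mother_birthplace": {"type": "string", "nullable": True},
        "n_siblings": {"type": "integer", "nullable": True},
        "siblings_with_dementia": {"type": "integer", "nullable": True},
        "apoe": {
            "type": "string",
            "pattern": "^e[234]/e[234]$",
            "nullable": True,
        },
        "csf_abeta42": {"type": "number", "unit": "pg/mL", "nullable": True},
        "csf_ttau": {"type": "number", "unit": "pg/mL", "nullable": True},
        "csf_ptau": {"type": "number", "unit": "pg/mL", "nullable": True},
        "age_at_lp": {"type": "number", "unit": "years", "nullable": True},
    }
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "dyadscan cohort table",
        "type": "object",
        "missing_token": NA_TOKEN,
        "required": list(MANDATORY_COLUMNS),
        "properties": props,
    }
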