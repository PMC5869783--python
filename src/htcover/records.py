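"""Six-file record bundle: schemas, validation, and delimited-text I/O.

The bundle emulates an administrative outpatient dataset with six tables:
person demographics, blood-pressure screening events, service/utilization
events, diagnosis events, a hypertension registry, and follow-up BP events
(the follow-up table reuses the service schema with ``service_code =
follow_up_bp``).  Files are UTF-8 CSV with a header row and ISO-8601 dates;
all comparisons downstream are day-granular.

Invariants are validated explicitly: ``validate_bundle`` reports violation
counts per invariant, ``read_bundle`` either aborts on the first violation
(strict) or drops offending rows and counts them (permissive).  Orphan
events — rows whose ``person_id`` is absent from the persons table — are
always a violation, never silently joined.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd

SEX_VALUES = ("male", "female")
SERVICE_CODES = (
    "ht_cvd_risk_assessment",
    "lipid_panel",
    "ht_treatment_start",
    "follow_up_bp",
)
REGISTRY_CONDITIONS = ("hypertension", "other")
SBP_RANGE = (50, 300)
DBP_RANGE = (30, 200)
LIPID_FIELDS = ("total_chol", "ldl", "hdl")

_SERVICE_COLUMNS = [
    "person_id", "event_date", "service_code",
    "sbp", "dbp", "total_chol", "ldl", "hdl",
]

TABLE_COLUMNS: dict[str, list[str]] = {
    "persons": ["person_id", "birth_date", "sex", "province_code", "in_civil_registry"],
    "screenings": ["person_id", "event_date", "sbp", "dbp"],
    "services": list(_SERVICE_COLUMNS),
    "diagnoses": ["person_id", "event_date", "icd10_code"],
    "registry": ["person_id", "condition", "registration_date"],
    "followups": list(_SERVICE_COLUMNS),
}

TABLE_FILES = {name: f"{name}.csv" for name in TABLE_COLUMNS}

_DATE_COLUMNS = {
    "persons": ["birth_date"],
    "screenings": ["event_date"],
    "services": ["event_date"],
    "diagnoses": ["event_date"],
    "registry": ["registration_date"],
    "followups": ["event_date"],
}
_INT_COLUMNS = {
    "persons": ["province_code"],
    "screenings": ["sbp", "dbp"],
    "services": ["sbp", "dbp", "total_chol", "ldl", "hdl"],
    "diagnoses": [],
    "registry": [],
    "followups": ["sbp", "dbp", "total_chol", "ldl", "hdl"],
}
_BOOL_COLUMNS = {"persons": ["in_civil_registry"]}

_ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2,}(\.[0-9]+)?$")


class BundleValidationError(ValueError):
    """Raised in strict mode when a bundle violates a schema invariant."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(f"bundle failed validation: {report.nonzero()}")


def make_table(name: str, data=None) -> pd.DataFrame:
    """Build a table of the canonical schema with canonical dtypes.

    ``data`` may be a mapping of column -> array, a DataFrame, or None for
    an empty table.  Missing optional columns are filled with NA.
    """
    columns = TABLE_COLUMNS[name]
    if data is None:
        frame = pd.DataFrame({c: [] for c in columns})
    else:
        frame = pd.DataFrame(data).copy()
    for col in columns:
        if col not in frame.columns:
            frame[col] = pd.NA
    frame = frame[columns]
    return _coerce_dtypes(name, frame)


def _coerce_dtypes(name: str, frame: pd.DataFrame) -> pd.DataFrame:
    for col in _DATE_COLUMNS.get(name, []):
        frame[col] = pd.to_datetime(frame[col], errors="coerce")
    for col in _INT_COLUMNS.get(name, []):
        num = pd.to_numeric(frame[col], errors="coerce")
        num = num.where(num.isna() | (num == np.floor(num)))
        frame[col] = num.astype("Int64")
    for col in _BOOL_COLUMNS.get(name, []):
        if frame[col].dtype != "boolean":
            mapped = frame[col].map(
                {True: True, False: False, "True": True, "False": False,
                 "true": True, "false": False, "1": True, "0": False}
            )
            frame[col] = mapped.astype("boolean")
    for col in frame.columns:
        if frame[col].dtype == object or str(frame[col].dtype) == "string":
            s = frame[col].astype("string")
            frame[col] = s.where(~(s.isna() | (s == "")), pd.NA).astype(object)
    return frame


@dataclasses.dataclass
class RecordBundle:
    """In-memory holder of the six tables, each a pandas DataFrame."""

    persons: pd.DataFrame
    screenings: pd.DataFrame
    services: pd.DataFrame
    diagnoses: pd.DataFrame
    registry: pd.DataFrame
    followups: pd.DataFrame
    read_report: "ValidationReport | None" = dataclasses.field(
        default=None, compare=False, repr=False
    )

    @classmethod
    def empty(cls) -> "RecordBundle":
        return cls(**{name: make_table(name) for name in TABLE_COLUMNS})

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def tables(self):
        for name in TABLE_COLUMNS:
            yield name, getattr(self, name)

    def counts(self) -> dict[str, int]:
        return {name: len(tab) for name, tab in self.tables()}


def bundles_equal(a: RecordBundle, b: RecordBundle) -> bool:
    """Field-wise equality of two bundles, ignoring row index labels."""
    for name in TABLE_COLUMNS:
        ta = a.table(name).reset_index(drop=True)
        tb = b.table(name).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(ta, tb, check_dtype=False)
        except AssertionError:
            return False
    return True


@dataclasses.dataclass
class ValidationReport:
    """Violation counts per (table, invariant)."""

    counts: dict[str, dict[str, int]]
    rows_checked: dict[str, int]

    @property
    def total_violations(self) -> int:
        return sum(v for tab in self.counts.values() for v in tab.values())

    @property
    def is_valid(self) -> bool:
        return self.total_violations == 0

    def count(self, kind: str) -> int:
        """Total count for one invariant kind, summed across tables."""
        return sum(tab.get(kind, 0) for tab in self.counts.values())

    def nonzero(self) -> dict[str, dict[str, int]]:
        return {
            name: {k: v for k, v in tab.items() if v}
            for name, tab in self.counts.items()
            if any(tab.values())
        }


def _violation_masks(bundle: RecordBundle, province_codes) -> dict[str, pd.DataFrame]:
    """Boolean masks (rows x invariant kinds) for every table."""
    provinces = set(int(p) for p in province_codes)
    masks: dict[str, pd.DataFrame] = {}

    p = bundle.persons
    pm = pd.DataFrame(index=p.index)
    pid = p["person_id"]
    pm["missing_person_id"] = pid.isna()
    pm["duplicate_person_id"] = pid.duplicated() & pid.notna()
    pm["missing_birth_date"] = p["birth_date"].isna()
    pm["invalid_sex"] = ~p["sex"].isin(SEX_VALUES)
    pm["invalid_province"] = ~p["province_code"].isin(provinces)
    pm["invalid_registry_flag"] = p["in_civil_registry"].isna().to_numpy()
    masks["persons"] = pm

    valid_pid = set(pid.dropna()) - set(pid[pm["duplicate_person_id"]].dropna())
    # rows of persons dropped for other reasons still anchor their events;
    # orphanhood is about linkage, not about the person row's own validity
    known = set(pid.dropna())

    s = bundle.screenings
    sm = pd.DataFrame(index=s.index)
    sm["missing_person_id"] = s["person_id"].isna()
    sm["invalid_event_date"] = s["event_date"].isna()
    sm["sbp_out_of_range"] = ~s["sbp"].between(*SBP_RANGE).fillna(False).astype(bool)
    sm["dbp_out_of_range"] = ~s["dbp"].between(*DBP_RANGE).fillna(False).astype(bool)
    sm["dbp_not_below_sbp"] = (s["dbp"] >= s["sbp"]).fillna(False).astype(bool)
    sm["orphan_event"] = ~s["person_id"].isin(known) & s["person_id"].notna()
    masks["screenings"] = sm

    for name in ("services", "followups"):
        t = bundle.table(name)
        tm = pd.DataFrame(index=t.index)
        tm["missing_person_id"] = t["person_id"].isna()
        tm["invalid_event_date"] = t["event_date"].isna()
        is_fu = t["service_code"].isin(["follow_up_bp"])
        if name == "followups":
            tm["invalid_service_code"] = ~is_fu
        else:
            tm["invalid_service_code"] = ~t["service_code"].isin(SERVICE_CODES) | is_fu
        bp_present = t["sbp"].notna() & t["dbp"].notna()
        bp_absent = t["sbp"].isna() & t["dbp"].isna()
        tm["bp_fields_mismatch"] = np.where(is_fu, ~bp_present, ~bp_absent)
        bp_bad = (
            ~t["sbp"].between(*SBP_RANGE).fillna(True).astype(bool)
            | ~t["dbp"].between(*DBP_RANGE).fillna(True).astype(bool)
            | (t["dbp"] >= t["sbp"]).fillna(False).astype(bool)
        )
        tm["bp_out_of_range"] = (is_fu & bp_present & bp_bad).to_numpy()
        is_lipid = t["service_code"].isin(["lipid_panel"])
        lipids_present = t[list(LIPID_FIELDS)].notna().all(axis=1)
        lipids_absent = t[list(LIPID_FIELDS)].isna().all(axis=1)
        tm["lipid_fields_mismatch"] = np.where(is_lipid, ~lipids_present, ~lipids_absent)
        tm["orphan_event"] = ~t["person_id"].isin(known) & t["person_id"].notna()
        masks[name] = tm

    d = bundle.diagnoses
    dm = pd.DataFrame(index=d.index)
    dm["missing_person_id"] = d["person_id"].isna()
    dm["invalid_event_date"] = d["event_date"].isna()
    code = d["icd10_code"].astype("string")
    dm["invalid_icd10"] = ~code.str.match(_ICD10_PATTERN).fillna(False).astype(bool)
    dm["orphan_event"] = ~d["person_id"].isin(known) & d["person_id"].notna()
    masks["diagnoses"] = dm

    r = bundle.registry
    rm = pd.DataFrame(index=r.index)
    rm["missing_person_id"] = r["person_id"].isna()
    rm["invalid_condition"] = ~r["condition"].isin(REGISTRY_CONDITIONS)
    rm["invalid_registration_date"] = r["registration_date"].isna()
    rm["orphan_event"] = ~r["person_id"].isin(known) & r["person_id"].notna()
    masks["registry"] = rm

    _ = valid_pid
    return masks


def validate_bundle(bundle: RecordBundle, province_codes=range(1, 77)) -> ValidationReport:
    """Count invariant violations per table without modifying the bundle."""
    masks = _violation_masks(bundle, province_codes)
    counts = {
        name: {kind: int(frame[kind].sum()) for kind in frame.columns}
        for name, frame in masks.items()
    }
    rows = {name: len(frame) for name, frame in masks.items()}
    return ValidationReport(counts=counts, rows_checked=rows)


def read_bundle(
    directory_path,
    strictness: str = "strict",
    province_codes=range(1, 77),
) -> RecordBundle:
    """Read the six CSV files from ``directory_path``.

    strict: any invariant violation (including a malformed date) raises
    :class:`BundleValidationError`.  permissive: offending rows are dropped
    and counted; the counts are attached as ``bundle.read_report``.  A
    missing file is always fatal.
    """
    if strictness not in ("strict", "permissive"):
        raise ValueError(f"unknown strictness {strictness!r}")
    directory = Path(directory_path)
    tables = {}
    for name, filename in TABLE_FILES.items():
        path = directory / filename
        if not path.exists():
            raise FileNotFoundError(f"required file missing: {path}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing_cols = [c for c in TABLE_COLUMNS[name] if c not in raw.columns]
        if missing_cols:
            raise ValueError(f"{path}: missing columns {missing_cols}")
        tables[name] = make_table(name, raw)
    bundle = RecordBundle(**tables)
    masks = _violation_masks(bundle, province_codes)
    report = ValidationReport(
        counts={
            name: {kind: int(frame[kind].sum()) for kind in frame.columns}
            for name, frame in masks.items()
        },
        rows_checked={name: len(frame) for name, frame in masks.items()},
    )
    if strictness == "strict":
        if not report.is_valid:
            raise BundleValidationError(report)
        bundle.read_report = report
        return bundle
    # permissive: drop any row violating at least one invariant, then
    # recompute orphanhood against the surviving persons
    clean = {}
    for name, frame in bundle.tables():
        bad = masks[name].any(axis=1)
        clean[name] = frame.loc[~bad].reset_index(drop=True)
    cleaned = RecordBundle(**clean)
    masks2 = _violation_masks(cleaned, province_codes)
    for name, frame in list(cleaned.tables()):
        bad = masks2[name].any(axis=1)
        if bad.any():
            for kind in masks2[name].columns:
                report.counts[name][kind] = report.counts[name].get(kind, 0) + int(
                    masks2[name][kind].sum()
                )
            setattr(cleaned, name, frame.loc[~bad].reset_index(drop=True))
    cleaned.read_report = report
    return cleaned


def write_bundle(bundle: RecordBundle, directory_path) -> dict[str, Path]:
    """Write the six CSV files; returns table name -> file path.

    Output is deterministic: identical bundles serialize byte-identically.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in bundle.tables():
        out = frame.copy()
        for col in _DATE_COLUMNS.get(name, []):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        path = directory / TABLE_FILES[name]
        out.to_csv(path, index=False, na_rep="", lineterminator="\n")
        paths[name] = path
    return paths
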