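"""Patient-level clinical records for the RA / nonRA image-classification pipeline.

A :class:`PatientRecord` carries everything one first-visit rheumatology
work-up produces: demographics, seven laboratory values, symptom flags, two
visual-analog-scale (VAS) scores, and bilateral findings for the 15 hand and
wrist joint sites (wrist, MCP1-5, PIP2-5, thumb IP, DIP2-5).  Each joint
carries five channels: patient-reported symptom (a), examiner tenderness (b),
examiner swelling (c), and the OMERACT semi-quantitative ultrasound scores in
grayscale (d) and power Doppler (e), each graded 0-3.

Records serialise losslessly to a flat CSV dialect (one row per patient,
joint columns named ``J_{side}_{site}_{channel}``) and to a nested JSON
mirror.  Validation reports violations rather than raising, so malformed
rows can be rejected individually on read.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

SIDES: tuple[str, ...] = ("right", "left")
#: The 15 joint sites per hand. The thumb has MCP1 and IP but no PIP1/DIP1.
SITES: tuple[str, ...] = (
    "wrist",
    "MCP1", "MCP2", "MCP3", "MCP4", "MCP5",
    "PIP2", "PIP3", "PIP4", "PIP5",
    "IP",
    "DIP2", "DIP3", "DIP4", "DIP5",
)
JOINT_CHANNELS: tuple[str, ...] = ("a", "b", "c", "d", "e")
#: channel letter -> JointFinding attribute
CHANNEL_ATTRS = {
    "a": "symptom",
    "b": "tenderness",
    "c": "swelling",
    "d": "gs_score",
    "e": "pd_score",
}

#: Clinical (non-joint) fields in their canonical display order (squares 1-14).
CLINICAL_FIELDS: tuple[str, ...] = (
    "rf", "acpa", "esr", "onset_days", "crp", "ana", "mmp3", "wbc",
    "gender", "skin_abnormality", "body_temperature", "trunk_pain",
    "patient_vas", "doctor_vas",
)
NUMERIC_FIELDS: tuple[str, ...] = (
    "rf", "acpa", "esr", "onset_days", "crp", "ana", "mmp3", "wbc",
    "body_temperature", "patient_vas", "doctor_vas",
)
FLAG_FIELDS: tuple[str, ...] = ("skin_abnormality", "trunk_pain")

LABELS = ("RA", "nonRA")


class SchemaError(ValueError):
    """A tabular source does not match the documented record schema."""


@dataclass
class JointFinding:
    """Five channels of one joint on one side.

    symptom / tenderness / swelling are binary; gs_score and pd_score are the
    OMERACT 0-3 grayscale and power Doppler synovitis grades.
    """

    symptom: bool = False
    tenderness: bool = False
    swelling: bool = False
    gs_score: int = 0
    pd_score: int = 0


@dataclass
class PatientRecord:
    """One patient's full clinical picture, with an optional RA/nonRA label."""

    patient_id: str
    gender: str  # "male" | "female"
    body_temperature: float  # degrees Celsius
    onset_days: float  # days from symptom onset to first visit
    trunk_pain: bool
    skin_abnormality: bool
    patient_vas: float  # 0-100
    doctor_vas: float  # 0-100
    rf: float  # IU/mL
    acpa: float  # U/mL
    esr: float  # mm/hour
    crp: float  # mg/dL
    ana: float  # reciprocal titre (0, 40, 80, ...)
    mmp3: float  # ng/mL
    wbc: float  # cells/uL
    joints: dict = field(default_factory=dict)  # (side, site) -> JointFinding
    label: Optional[str] = None

    def copy(self) -> "PatientRecord":
        joints = {k: replace(v) for k, v in self.joints.items()}
        return replace(self, joints=joints)


def iter_joint_keys() -> Iterable[tuple[str, str]]:
    for side in SIDES:
        for site in SITES:
            yield side, site


def joint_field_id(side: str, site: str, channel: str) -> str:
    return f"J_{side}_{site}_{channel}"


def parse_joint_field_id(field_id: str) -> tuple[str, str, str]:
    """Split ``J_{side}_{site}_{channel}`` into its parts (raises on mismatch)."""
    parts = field_id.split("_")
    if len(parts) != 4 or parts[0] != "J":
        raise KeyError(f"not a joint field id: {field_id!r}")
    _, side, site, channel = parts
    if side not in SIDES or site not in SITES or channel not in JOINT_CHANNELS:
        raise KeyError(f"unknown joint field id: {field_id!r}")
    return side, site, channel


def all_field_ids() -> list[str]:
    """All 164 field identifiers: 14 clinical + 150 joint channels."""
    ids = list(CLINICAL_FIELDS)
    for side, site in iter_joint_keys():
        for ch in JOINT_CHANNELS:
            ids.append(joint_field_id(side, site, ch))
    return ids


def get_field(record: PatientRecord, field_id: str):
    """Raw value of a clinical field or a joint channel on a record."""
    if field_id in CLINICAL_FIELDS:
        return getattr(record, field_id)
    side, site, channel = parse_joint_field_id(field_id)
    jf = record.joints.get((side, site))
    if jf is None:
        return None
    return getattr(jf, CHANNEL_ATTRS[channel])


def set_field(record: PatientRecord, field_id: str, value) -> None:
    if field_id in CLINICAL_FIELDS:
        setattr(record, field_id, value)
        return
    side, site, channel = parse_joint_field_id(field_id)
    setattr(record.joints[(side, site)], CHANNEL_ATTRS[channel], value)


def validate_record(record: PatientRecord, allow_missing: bool = False) -> list[str]:
    """Report every invariant violation on ``record``; empty list means valid.

    Total: never raises on a structurally complete ``PatientRecord``.  With
    ``allow_missing`` a ``None`` field is tolerated (the encoder then renders
    it with the dedicated "missing" colour).
    """
    problems: list[str] = []

    def _missing(name: str) -> None:
        if not allow_missing:
            problems.append(f"{name}: missing value")

    if record.label is not None and record.label not in LABELS:
        problems.append(f"label: must be one of {LABELS}, got {record.label!r}")

    if record.gender is None:
        _missing("gender")
    elif record.gender not in ("male", "female"):
        problems.append(f"gender: must be 'male' or 'female', got {record.gender!r}")

    for name in ("rf", "acpa", "esr", "crp", "ana", "mmp3", "wbc", "onset_days",
                 "body_temperature"):
        v = getattr(record, name)
        if v is None:
            _missing(name)
        elif not isinstance(v, (int, float)) or isinstance(v, bool):
            problems.append(f"{name}: not numeric ({v!r})")
        elif v < 0:
            problems.append(f"{name}: must be nonnegative, got {v}")

    for name in ("patient_vas", "doctor_vas"):
        v = getattr(record, name)
        if v is None:
            _missing(name)
        elif not isinstance(v, (int, float)) or isinstance(v, bool):
            problems.append(f"{name}: not numeric ({v!r})")
        elif not (0 <= v <= 100):
            problems.append(f"{name}: must lie in [0, 100], got {v}")

    for name in FLAG_FIELDS:
        v = getattr(record, name)
        if v is None:
            _missing(name)
        elif not isinstance(v, bool):
            problems.append(f"{name}: must be boolean, got {v!r}")

    expected = set(iter_joint_keys())
    present = set(record.joints)
    for side, site in sorted(expected - present):
        problems.append(f"missing joint: ({side}, {site})")
    for side, site in sorted(present - expected):
        problems.append(f"unknown joint: ({side}, {site})")

    for (side, site), jf in sorted(record.joints.items()):
        if (side, site) not in expected:
            continue
        for ch in ("symptom", "tenderness", "swelling"):
            v = getattr(jf, ch)
            if v is None:
                _missing(f"J_{side}_{site}.{ch}")
            elif not isinstance(v, bool):
                problems.append(f"J_{side}_{site}.{ch}: must be boolean, got {v!r}")
        for ch in ("gs_score", "pd_score"):
            v = getattr(jf, ch)
            if v is None:
                _missing(f"J_{side}_{site}.{ch}")
            elif v not in (0, 1, 2, 3):
                problems.append(
                    f"J_{side}_{site}.{ch}: must be in {{0,1,2,3}}, got {v!r}")

    return problems


# ---------------------------------------------------------------------------
# Tabular serialization
# ---------------------------------------------------------------------------

def csv_columns() -> list[str]:
    cols = ["patient_id", "rf", "acpa", "esr", "crp", "ana", "mmp3", "wbc",
            "gender", "skin_abnormality", "body_temperature", "trunk_pain",
            "onset_days", "patient_vas", "doctor_vas", "label"]
    for side, site in iter_joint_keys():
        for ch in JOINT_CHANNELS:
            cols.append(joint_field_id(side, site, ch))
    return cols


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _record_to_row(record: PatientRecord) -> dict:
    row = {
        "patient_id": record.patient_id,
        "label": "" if record.label is None else record.label,
        "gender": "" if record.gender is None else record.gender,
    }
    for name in NUMERIC_FIELDS + FLAG_FIELDS:
        row[name] = _fmt(getattr(record, name))
    for (side, site), jf in record.joints.items():
        for ch in JOINT_CHANNELS:
            row[joint_field_id(side, site, ch)] = _fmt(getattr(jf, CHANNEL_ATTRS[ch]))
    return row


def _parse_float(text: str):
    return None if text == "" else float(text)


def _parse_flag(text: str):
    if text == "":
        return None
    if text in ("1", "true", "True"):
        return True
    if text in ("0", "false", "False"):
        return False
    raise ValueError(f"not a flag value: {text!r}")


def _row_to_record(row: dict) -> PatientRecord:
    joints = {}
    for side, site in iter_joint_keys():
        kwargs = {}
        for ch in JOINT_CHANNELS:
            raw = row[joint_field_id(side, site, ch)]
            attr = CHANNEL_ATTRS[ch]
            if attr in ("gs_score", "pd_score"):
                kwargs[attr] = None if raw == "" else int(float(raw))
            else:
                kwargs[attr] = _parse_flag(raw)
        joints[(side, site)] = JointFinding(**kwargs)
    return PatientRecord(
        patient_id=row["patient_id"],
        label=row["label"] or None,
        gender=row["gender"] or None,
        body_temperature=_parse_float(row["body_temperature"]),
        onset_days=_parse_float(row["onset_days"]),
        trunk_pain=_parse_flag(row["trunk_pain"]),
        skin_abnormality=_parse_flag(row["skin_abnormality"]),
        patient_vas=_parse_float(row["patient_vas"]),
        doctor_vas=_parse_float(row["doctor_vas"]),
        rf=_parse_float(row["rf"]),
        acpa=_parse_float(row["acpa"]),
        esr=_parse_float(row["esr"]),
        crp=_parse_float(row["crp"]),
        ana=_parse_float(row["ana"]),
        mmp3=_parse_float(row["mmp3"]),
        wbc=_parse_float(row["wbc"]),
        joints=joints,
    )


def _record_to_json_obj(record: PatientRecord) -> dict:
    obj = {"patient_id": record.patient_id, "label": record.label,
           "gender": record.gender}
    for name in NUMERIC_FIELDS + FLAG_FIELDS:
        obj[name] = getattr(record, name)
    joints: dict = {side: {} for side in SIDES}
    for (side, site), jf in record.joints.items():
        joints[side][site] = {
            "a": jf.symptom, "b": jf.tenderness, "c": jf.swelling,
            "d": jf.gs_score, "e": jf.pd_score,
        }
    obj["joints"] = joints
    return obj


def _json_obj_to_record(obj: dict) -> PatientRecord:
    joints = {}
    for side in SIDES:
        for site in SITES:
            j = obj["joints"][side][site]
            joints[(side, site)] = JointFinding(
                symptom=j["a"], tenderness=j["b"], swelling=j["c"],
                gs_score=j["d"], pd_score=j["e"])
    kwargs = {name: obj[name] for name in NUMERIC_FIELDS + FLAG_FIELDS}
    return PatientRecord(patient_id=obj["patient_id"], label=obj.get("label"),
                         gender=obj.get("gender"), joints=joints, **kwargs)


def write_records(records: list[PatientRecord], sink) -> int:
    """Write records to a CSV (default) or JSON file; returns the row count.

    Column order is fixed; floats use their shortest round-trip repr so that
    write -> read -> write is byte-identical.
    """
    path = Path(sink)
    if path.suffix.lower() == ".json":
        payload = [_record_to_json_obj(r) for r in records]
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
        return len(records)
    cols = csv_columns()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, lineterminator="\n")
        writer.writeheader()
        for record in records:
            writer.writerow(_record_to_row(record))
    return len(records)


def read_records(source, strict: bool = True) -> list[PatientRecord]:
    """Read records from the CSV or JSON dialect written by :func:`write_records`.

    Column order is irrelevant; an unknown column raises :class:`SchemaError`.
    Rows that fail validation are rejected with a logged reason (or, with
    ``strict=False``, kept if only missing values are at fault).
    """
    path = Path(source)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        candidates = [_json_obj_to_record(obj) for obj in payload]
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file, header required")
            known = set(csv_columns())
            unknown = [c for c in reader.fieldnames if c not in known]
            if unknown:
                raise SchemaError(f"{path}: unknown column(s) {unknown}")
            missing = sorted(known - set(reader.fieldnames))
            if missing:
                raise SchemaError(f"{path}: missing column(s) {missing[:5]}")
            candidates = [_row_to_record(row) for row in reader]

    records = []
    for record in candidates:
        problems = validate_record(record, allow_missing=not strict)
        if problems:
            logger.warning("rejecting record %s: %s",
                           record.patient_id, "; ".join(problems[:3]))
            continue
        records.append(record)
    return records
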