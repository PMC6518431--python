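"""Reading, validating and normalizing trial records and publication evidence.

Two registry dialects are supported: ``ctgov_json`` (one JSON object per
study mirroring ClinicalTrials.gov field names, ISO-8601 date values) and
``flat_csv`` (one row per study).  Publication evidence — one discovered
dissemination event per row — is read from CSV or JSON.

Records that fail validation are reported in an issue log, never silently
dropped; date-order inconsistencies are flagged on the record so downstream
stages can decide whether to exclude them.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from pydantic import BaseModel, Field, NonNegativeInt, ValidationError, model_validator

from ._dates import Actuality, ImpreciseDate, Precision, parse_imprecise
from .errors import ConfigurationError, SchemaError

__all__ = [
    "AffiliationRole",
    "Affiliation",
    "CompletionDate",
    "EvidenceFormat",
    "EvidenceSource",
    "Issue",
    "IssueLog",
    "OverallStatus",
    "PublicationEvidence",
    "ResponsiblePartyRole",
    "StudyType",
    "TrialRecord",
    "filter_by_affiliation",
    "normalize_identifier",
    "normalize_text",
    "read_publication_corpus",
    "read_registry_records",
    "write_publication_corpus",
    "write_registry_records",
]


class ResponsiblePartyRole(str, Enum):
    sponsor = "sponsor"
    principal_investigator = "principal_investigator"
    sponsor_investigator = "sponsor_investigator"
    unknown = "unknown"


class StudyType(str, Enum):
    interventional = "interventional"
    observational = "observational"


class OverallStatus(str, Enum):
    completed = "completed"
    terminated = "terminated"
    withdrawn = "withdrawn"
    suspended = "suspended"
    recruiting = "recruiting"
    unknown = "unknown"


class AffiliationRole(str, Enum):
    lead = "lead"
    facility = "facility"


class Affiliation(BaseModel, frozen=True):
    name: str
    role: AffiliationRole


class CompletionDate(BaseModel, frozen=True):
    """A (primary) completion date with precision and actual/estimated status."""

    date: dt.date
    precision: Precision = Precision.day
    actuality: Actuality = Actuality.actual


class EvidenceSource(str, Enum):
    registry_summary = "registry_summary"
    registry_indexed = "registry_indexed"
    pubmed_id_search = "pubmed_id_search"
    manual_search = "manual_search"


class EvidenceFormat(str, Enum):
    journal_article = "journal_article"
    summary_result = "summary_result"
    csr = "csr"
    thesis = "thesis"
    conference = "conference"
    dataset = "dataset"


class TrialRecord(BaseModel):
    """One registered clinical study with all tracked dates and parties."""

    trial_id: str = Field(min_length=1)
    sponsor_name: str
    responsible_party_role: ResponsiblePartyRole = ResponsiblePartyRole.unknown
    affiliations: Tuple[Affiliation, ...] = ()
    study_type: StudyType
    overall_status: OverallStatus
    start_date: ImpreciseDate
    registration_submitted: ImpreciseDate
    registration_posted: ImpreciseDate
    primary_completion_date: Optional[CompletionDate] = None
    completion_date: Optional[CompletionDate] = None
    summary_results_posted: Optional[ImpreciseDate] = None
    linked_publication_ids: Tuple[str, ...] = ()
    enrollment: Optional[NonNegativeInt] = None
    flags: Tuple[str, ...] = ()

    @model_validator(mode="after")
    def _flag_date_inconsistencies(self) -> "TrialRecord":
        flags = list(self.flags)
        if (
            self.registration_submitted.date > self.registration_posted.date
            and "registration_order" not in flags
        ):
            flags.append("registration_order")
        pcd, cd = self.primary_completion_date, self.completion_date
        if (
            pcd is not None
            and cd is not None
            and pcd.actuality is Actuality.actual
            and cd.actuality is Actuality.actual
            and pcd.date > cd.date
            and "completion_order" not in flags
        ):
            flags.append("completion_order")
        if tuple(flags) != self.flags:
            object.__setattr__(self, "flags", tuple(flags))
        return self

    def lead_affiliations(self) -> Tuple[str, ...]:
        return tuple(a.name for a in self.affiliations if a.role is AffiliationRole.lead)

    def facility_affiliations(self) -> Tuple[str, ...]:
        return tuple(a.name for a in self.affiliations if a.role is AffiliationRole.facility)


class PublicationEvidence(BaseModel, frozen=True):
    """One discovered dissemination event for a trial."""

    trial_id: str = Field(min_length=1)
    source: EvidenceSource
    format: EvidenceFormat
    pub_date: ImpreciseDate
    identifier: str = Field(min_length=1)
    rater_id: str = "auto"


@dataclass(frozen=True)
class Issue:
    where: str  # file/row/record context
    field: str
    message: str


class IssueLog(List[Issue]):
    def add(self, where: str, field: str, message: str) -> None:
        self.append(Issue(where=where, field=field, message=message))


_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Case-fold and collapse whitespace for deterministic substring matching."""
    return _WS_RE.sub(" ", text.strip()).casefold()


_DOI_PREFIXES = ("https://doi.org/", "http://doi.org/", "http://dx.doi.org/", "doi:")


def normalize_identifier(identifier: str) -> str:
    ident = identifier.strip()
    low = ident.casefold()
    for prefix in _DOI_PREFIXES:
        if low.startswith(prefix):
            ident = ident[len(prefix):]
            low = ident.casefold()
    return low.strip()


# ---------------------------------------------------------------------------
# flat_csv dialect
# ---------------------------------------------------------------------------

_FLAT_COLUMNS = [
    "trial_id",
    "sponsor_name",
    "responsible_party_role",
    "lead_affiliations",
    "facility_affiliations",
    "study_type",
    "overall_status",
    "start_date",
    "registration_submitted",
    "registration_posted",
    "primary_completion_date",
    "primary_completion_type",
    "completion_date",
    "completion_type",
    "summary_results_posted",
    "linked_publication_ids",
    "enrollment",
]

_LIST_SEP = ";"


def _split_list(cell: str) -> Tuple[str, ...]:
    return tuple(s.strip() for s in cell.split(_LIST_SEP) if s.strip()) if cell else ()


def _completion_from(text: str, actuality_text: str, where: str) -> Optional[CompletionDate]:
    d = parse_imprecise(text, impute="last")
    if d is None:
        return None
    actuality = Actuality(actuality_text.strip().lower()) if actuality_text.strip() else Actuality.actual
    return CompletionDate(date=d.date, precision=d.precision, actuality=actuality)


def _record_from_flat_row(row: dict, where: str) -> TrialRecord:
    affiliations = [
        Affiliation(name=n, role=AffiliationRole.lead) for n in _split_list(row.get("lead_affiliations", ""))
    ] + [
        Affiliation(name=n, role=AffiliationRole.facility)
        for n in _split_list(row.get("facility_affiliations", ""))
    ]
    enrollment = row.get("enrollment", "").strip()
    return TrialRecord(
        trial_id=row.get("trial_id", "").strip(),
        sponsor_name=row.get("sponsor_name", "").strip(),
        responsible_party_role=ResponsiblePartyRole(
            row.get("responsible_party_role", "").strip() or "unknown"
        ),
        affiliations=tuple(affiliations),
        study_type=StudyType(row.get("study_type", "").strip()),
        overall_status=OverallStatus(row.get("overall_status", "").strip() or "unknown"),
        start_date=parse_imprecise(row.get("start_date"), impute="first"),
        registration_submitted=parse_imprecise(row.get("registration_submitted"), impute="first"),
        registration_posted=parse_imprecise(row.get("registration_posted"), impute="first"),
        primary_completion_date=_completion_from(
            row.get("primary_completion_date", ""), row.get("primary_completion_type", ""), where
        ),
        completion_date=_completion_from(
            row.get("completion_date", ""), row.get("completion_type", ""), where
        ),
        summary_results_posted=parse_imprecise(row.get("summary_results_posted"), impute="last"),
        linked_publication_ids=tuple(
            normalize_identifier(i) for i in _split_list(row.get("linked_publication_ids", ""))
        ),
        enrollment=int(enrollment) if enrollment else None,
    )


def _flat_row_from_record(r: TrialRecord) -> dict:
    def iso(d: Optional[ImpreciseDate]) -> str:
        return d.isoformat() if d is not None else ""

    def iso_c(c: Optional[CompletionDate]) -> Tuple[str, str]:
        if c is None:
            return "", ""
        return ImpreciseDate(date=c.date, precision=c.precision).isoformat(), c.actuality.value

    pcd, pcd_t = iso_c(r.primary_completion_date)
    cd, cd_t = iso_c(r.completion_date)
    return {
        "trial_id": r.trial_id,
        "sponsor_name": r.sponsor_name,
        "responsible_party_role": r.responsible_party_role.value,
        "lead_affiliations": _LIST_SEP.join(r.lead_affiliations()),
        "facility_affiliations": _LIST_SEP.join(r.facility_affiliations()),
        "study_type": r.study_type.value,
        "overall_status": r.overall_status.value,
        "start_date": iso(r.start_date),
        "registration_submitted": iso(r.registration_submitted),
        "registration_posted": iso(r.registration_posted),
        "primary_completion_date": pcd,
        "primary_completion_type": pcd_t,
        "completion_date": cd,
        "completion_type": cd_t,
        "summary_results_posted": iso(r.summary_results_posted),
        "linked_publication_ids": _LIST_SEP.join(r.linked_publication_ids),
        "enrollment": "" if r.enrollment is None else str(r.enrollment),
    }


# ---------------------------------------------------------------------------
# ctgov_json dialect
# ---------------------------------------------------------------------------

_ROLE_TO_CTGOV = {
    ResponsiblePartyRole.sponsor: "Sponsor",
    ResponsiblePartyRole.principal_investigator: "Principal Investigator",
    ResponsiblePartyRole.sponsor_investigator: "Sponsor-Investigator",
    ResponsiblePartyRole.unknown: "",
}
_ROLE_FROM_CTGOV = {v: k for k, v in _ROLE_TO_CTGOV.items()}


def _record_from_ctgov(obj: dict, where: str) -> TrialRecord:
    affiliations = [
        Affiliation(name=n, role=AffiliationRole.lead)
        for n in obj.get("ResponsiblePartyInvestigatorAffiliation", [])
    ] + [
        Affiliation(name=n, role=AffiliationRole.facility) for n in obj.get("LocationFacility", [])
    ]

    def comp(date_key: str, type_key: str) -> Optional[CompletionDate]:
        d = parse_imprecise(obj.get(date_key), impute="last")
        if d is None:
            return None
        actuality = Actuality((obj.get(type_key) or "Actual").lower())
        return CompletionDate(date=d.date, precision=d.precision, actuality=actuality)

    return TrialRecord(
        trial_id=(obj.get("NCTId") or "").strip(),
        sponsor_name=(obj.get("LeadSponsorName") or "").strip(),
        responsible_party_role=_ROLE_FROM_CTGOV.get(
            obj.get("ResponsiblePartyType", ""), ResponsiblePartyRole.unknown
        ),
        affiliations=tuple(affiliations),
        study_type=StudyType((obj.get("StudyType") or "").lower()),
        overall_status=OverallStatus((obj.get("OverallStatus") or "unknown").lower()),
        start_date=parse_imprecise(obj.get("StartDate"), impute="first"),
        registration_submitted=parse_imprecise(obj.get("StudyFirstSubmitDate"), impute="first"),
        registration_posted=parse_imprecise(obj.get("StudyFirstPostDate"), impute="first"),
        primary_completion_date=comp("PrimaryCompletionDate", "PrimaryCompletionDateType"),
        completion_date=comp("CompletionDate", "CompletionDateType"),
        summary_results_posted=parse_imprecise(obj.get("ResultsFirstPostDate"), impute="last"),
        linked_publication_ids=tuple(
            normalize_identifier(i) for i in obj.get("ReferencePMID", [])
        ),
        enrollment=obj.get("EnrollmentCount"),
    )


def _ctgov_from_record(r: TrialRecord) -> dict:
    def iso(d: Optional[ImpreciseDate]) -> Optional[str]:
        return d.isoformat() if d is not None else None

    obj = {
        "NCTId": r.trial_id,
        "LeadSponsorName": r.sponsor_name,
        "ResponsiblePartyType": _ROLE_TO_CTGOV[r.responsible_party_role],
        "ResponsiblePartyInvestigatorAffiliation": list(r.lead_affiliations()),
        "LocationFacility": list(r.facility_affiliations()),
        "StudyType": r.study_type.value.capitalize(),
        "OverallStatus": r.overall_status.value.capitalize(),
        "StartDate": iso(r.start_date),
        "StudyFirstSubmitDate": iso(r.registration_submitted),
        "StudyFirstPostDate": iso(r.registration_posted),
        "ReferencePMID": list(r.linked_publication_ids),
        "EnrollmentCount": r.enrollment,
        "ResultsFirstPostDate": iso(r.summary_results_posted),
    }
    for key, comp in (
        ("PrimaryCompletionDate", r.primary_completion_date),
        ("CompletionDate", r.completion_date),
    ):
        if comp is not None:
            obj[key] = ImpreciseDate(date=comp.date, precision=comp.precision).isoformat()
            obj[key + "Type"] = comp.actuality.value.capitalize()
        else:
            obj[key] = None
            obj[key + "Type"] = None
    return obj


# ---------------------------------------------------------------------------
# public readers / writers
# ---------------------------------------------------------------------------


def read_registry_records(
    path: Union[str, Path], dialect: str
) -> Tuple[List[TrialRecord], IssueLog]:
    """Read trial records from ``path`` in the named dialect.

    Returns the validated records plus an issue log; unparseable records are
    logged and skipped, never silently dropped.
    """
    path = Path(path)
    issues = IssueLog()
    records: List[TrialRecord] = []
    if dialect == "flat_csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "trial_id" not in reader.fieldnames:
                raise SchemaError(f"{path}: not a flat_csv registry file (missing trial_id column)")
            for i, row in enumerate(reader, start=2):
                where = f"{path.name}:row {i}"
                try:
                    records.append(_record_from_flat_row(row, where))
                except (ValidationError, ValueError) as exc:
                    issues.add(where, "record", _short_error(exc))
    elif dialect == "ctgov_json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: malformed JSON at line {exc.lineno}") from None
        if isinstance(payload, dict):
            payload = payload.get("studies", [payload])
        for i, obj in enumerate(payload):
            where = f"{path.name}:study {i}"
            try:
                records.append(_record_from_ctgov(obj, where))
            except (ValidationError, ValueError) as exc:
                issues.add(where, "record", _short_error(exc))
    else:
        raise ConfigurationError(f"unknown registry dialect {dialect!r}")
    return records, issues


def _short_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "record"
        return f"{loc}: {first['msg']}"
    return str(exc)


def write_registry_records(
    records: Sequence[TrialRecord], path: Union[str, Path], dialect: str
) -> None:
    path = Path(path)
    if dialect == "flat_csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FLAT_COLUMNS)
            writer.writeheader()
            for r in records:
                writer.writerow(_flat_row_from_record(r))
    elif dialect == "ctgov_json":
        path.write_text(json.dumps([_ctgov_from_record(r) for r in records], indent=1) + "\n")
    else:
        raise ConfigurationError(f"unknown registry dialect {dialect!r}")


_CORPUS_COLUMNS = ["trial_id", "source", "format", "pub_date", "identifier", "rater_id"]


def read_publication_corpus(
    path: Union[str, Path]
) -> Tuple[List[PublicationEvidence], IssueLog]:
    """Read a publication-evidence corpus (CSV with the standard header, or JSON).

    Identifiers are normalized (case-folded, whitespace-stripped, DOI prefix
    removed); exact duplicates on (trial_id, identifier, rater_id, source)
    are collapsed with a log entry, keeping the earliest date.
    """
    path = Path(path)
    issues = IssueLog()
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise SchemaError(f"{path}: corpus JSON must be a list of objects")
        row_iter = list(enumerate(rows, start=1))
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            missing = [c for c in _CORPUS_COLUMNS if reader.fieldnames is None or c not in reader.fieldnames]
            if missing:
                raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
            row_iter = list(enumerate(reader, start=2))

    seen: dict = {}
    order: List[Tuple] = []
    for i, row in row_iter:
        where = f"{path.name}:row {i}"
        missing = [c for c in _CORPUS_COLUMNS[:5] if not str(row.get(c, "") or "").strip()]
        if missing:
            raise SchemaError(f"{where}: missing value for {', '.join(missing)}")
        try:
            ev = PublicationEvidence(
                trial_id=str(row["trial_id"]).strip(),
                source=EvidenceSource(str(row["source"]).strip()),
                format=EvidenceFormat(str(row["format"]).strip()),
                pub_date=parse_imprecise(str(row["pub_date"]), impute="last"),
                identifier=normalize_identifier(str(row["identifier"])),
                rater_id=str(row.get("rater_id", "") or "auto").strip(),
            )
        except ValueError as exc:
            raise SchemaError(f"{where}: {_short_error(exc)}") from None
        key = (ev.trial_id, ev.identifier, ev.rater_id, ev.source)
        if key in seen:
            issues.add(where, "identifier", f"duplicate of earlier row collapsed ({ev.identifier})")
            if ev.pub_date.date < seen[key].pub_date.date:
                seen[key] = ev
        else:
            seen[key] = ev
            order.append(key)
    return [seen[k] for k in order], issues


def write_publication_corpus(
    corpus: Sequence[PublicationEvidence], path: Union[str, Path]
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CORPUS_COLUMNS)
        for ev in corpus:
            writer.writerow(
                [
                    ev.trial_id,
                    ev.source.value,
                    ev.format.value,
                    ev.pub_date.isoformat(),
                    ev.identifier,
                    ev.rater_id,
                ]
            )


def filter_by_affiliation(
    records: Iterable[TrialRecord], patterns: Sequence[str]
) -> List[Tuple[TrialRecord, AffiliationRole]]:
    """Retain records whose sponsor or any affiliation matches any pattern.

    Matching is normalized case-insensitive substring matching.  The
    annotation records whether the match was on the lead side (sponsor or
    lead affiliation) or only on a recruiting facility.
    """
    if not patterns:
        raise ConfigurationError("at least one affiliation pattern is required")
    pats = [normalize_text(p) for p in patterns]
    out: List[Tuple[TrialRecord, AffiliationRole]] = []
    for r in records:
        lead_texts = [normalize_text(r.sponsor_name)] + [
            normalize_text(a) for a in r.lead_affiliations()
        ]
        if any(p in t for p in pats for t in lead_texts):
            out.append((r, AffiliationRole.lead))
            continue
        facility_texts = [normalize_text(a) for a in r.facility_affiliations()]
        if any(p in t for p in pats for t in facility_texts):
            out.append((r, AffiliationRole.facility))
    return out
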