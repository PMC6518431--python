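"""Sample construction: responsibility, eligibility filters, and
registration-timing strata (tracking variables 1-5).

Filters run in a fixed order — responsibility, study type, status,
(optional) date-consistency flags, registration policy — so each excluded
trial carries exactly one deterministic primary reason and the exclusion
flow is reproducible.  Registration timing is classified by the delay
between study start and registration, with two overrides: registration
after the resolved completion date, and registration after the trial's
first results publication (the most severe applicable class wins).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .config import RegistrationDateField, RegistrationPolicy, ResponsibilityScope, TrackingConfig
from .registry_io import TrialRecord, normalize_text
from .timeliness import resolve_completion_date

__all__ = [
    "ExclusionReason",
    "IncludedTrial",
    "RegistrationStratum",
    "ResponsibilityClass",
    "SamplingOutcome",
    "apply_sampling",
    "classify_registration_timing",
    "classify_responsibility",
]


class ResponsibilityClass(str, Enum):
    legal = "legal"  # sponsor or responsible-party PI affiliation
    cooperating = "cooperating"  # recruiting facility only
    none = "none"


class RegistrationStratum(str, Enum):
    prospective = "prospective"
    late = "late"
    retrospective = "retrospective"
    post_completion = "post_completion"
    post_publication = "post_publication"


class ExclusionReason(str, Enum):
    responsibility = "responsibility"
    study_type = "study_type"
    status = "status"
    flagged_dates = "flagged_dates"
    registration_timing = "registration_timing"
    registration_unclassifiable = "registration_unclassifiable"


def classify_responsibility(
    record: TrialRecord, institution_patterns: Sequence[str]
) -> ResponsibilityClass:
    """Is the institution legally responsible, only recruiting, or uninvolved?

    ``legal`` iff a pattern matches the sponsor name or a lead (responsible
    party / principal investigator) affiliation; ``cooperating`` iff it
    matches only a recruiting facility.  Matching is normalized
    case-insensitive substring matching.
    """
    pats = [normalize_text(p) for p in institution_patterns]
    lead_texts = [normalize_text(record.sponsor_name)] + [
        normalize_text(a) for a in record.lead_affiliations()
    ]
    if any(p in t for p in pats for t in lead_texts):
        return ResponsibilityClass.legal
    facility_texts = [normalize_text(a) for a in record.facility_affiliations()]
    if any(p in t for p in pats for t in facility_texts):
        return ResponsibilityClass.cooperating
    return ResponsibilityClass.none


def classify_registration_timing(
    record: TrialRecord,
    first_pub_date: Optional[dt.date],
    config: TrackingConfig,
    completion_date: Optional[dt.date] = None,
) -> RegistrationStratum:
    """Assign the registration-timing stratum for one trial.

    With delay ``d`` = registration − start in whole days (on imputed
    dates): prospective iff d ≤ cutoff (21 days by default, the FDAAA
    "within 21 days" allowance — ties classify into the less severe class),
    late iff cutoff < d ≤ threshold (60 days by default), retrospective
    beyond that.  Overridden by post_completion when registration falls
    after the resolved completion date, and by post_publication when it
    falls after the first results publication; the most severe class wins.
    """
    if config.registration_date_field is RegistrationDateField.submitted:
        registration = record.registration_submitted.date
    else:
        registration = record.registration_posted.date
    start = record.start_date.date
    delay_days = (registration - start).days

    if completion_date is None:
        resolved = resolve_completion_date(record, config.completion)
        completion_date = resolved[0] if resolved else None

    if first_pub_date is not None and registration > first_pub_date:
        return RegistrationStratum.post_publication
    if completion_date is not None and registration > completion_date:
        return RegistrationStratum.post_completion
    if delay_days <= config.prospective_cutoff_days:
        return RegistrationStratum.prospective
    if delay_days <= config.retrospective_threshold_days:
        return RegistrationStratum.late
    return RegistrationStratum.retrospective


@dataclass(frozen=True)
class IncludedTrial:
    record: TrialRecord
    responsibility: ResponsibilityClass
    stratum: Optional[RegistrationStratum]


@dataclass
class SamplingOutcome:
    included: List[IncludedTrial]
    excluded: List[Tuple[TrialRecord, ExclusionReason]]

    @property
    def reason_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {r.value: 0 for r in ExclusionReason}
        for _, reason in self.excluded:
            counts[reason.value] += 1
        return counts


def apply_sampling(
    records: Sequence[TrialRecord],
    institution_patterns: Sequence[str],
    config: TrackingConfig,
    first_pub_dates: Optional[Mapping[str, dt.date]] = None,
) -> SamplingOutcome:
    """Partition records into the tracked sample and an exclusion log.

    ``first_pub_dates`` maps trial IDs to the earliest accepted
    dissemination date, enabling the post-publication stratum override.
    Included trials carry their responsibility class and registration
    stratum; each excluded record carries the first failing filter.
    """
    first_pub_dates = first_pub_dates or {}
    included: List[IncludedTrial] = []
    excluded: List[Tuple[TrialRecord, ExclusionReason]] = []
    for record in records:
        responsibility = classify_responsibility(record, institution_patterns)
        if responsibility is ResponsibilityClass.none or (
            config.responsibility_scope is ResponsibilityScope.legal_only
            and responsibility is not ResponsibilityClass.legal
        ):
            excluded.append((record, ExclusionReason.responsibility))
            continue
        if record.study_type not in config.study_types:
            excluded.append((record, ExclusionReason.study_type))
            continue
        if record.overall_status not in config.statuses:
            excluded.append((record, ExclusionReason.status))
            continue
        if config.exclude_flagged and record.flags:
            excluded.append((record, ExclusionReason.flagged_dates))
            continue
        try:
            stratum: Optional[RegistrationStratum] = classify_registration_timing(
                record, first_pub_dates.get(record.trial_id), config
            )
        except (TypeError, AttributeError):
            stratum = None
        if config.registration_policy is RegistrationPolicy.prospective_only:
            if stratum is None:
                excluded.append((record, ExclusionReason.registration_unclassifiable))
                continue
            if stratum is not RegistrationStratum.prospective:
                excluded.append((record, ExclusionReason.registration_timing))
                continue
        included.append(IncludedTrial(record=record, responsibility=responsibility, stratum=stratum))
    return SamplingOutcome(included=included, excluded=excluded)
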