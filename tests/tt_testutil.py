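"""Shared factories for building records and evidence in tests."""

import datetime as dt

from trialtrack import (
    Actuality,
    Affiliation,
    AffiliationRole,
    CompletionDate,
    EvidenceFormat,
    EvidenceSource,
    ImpreciseDate,
    OverallStatus,
    Precision,
    PublicationEvidence,
    ResponsiblePartyRole,
    StudyType,
    TrialRecord,
)


def d(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def make_record(
    trial_id="NCT00000001",
    sponsor="Univ A",
    *,
    role="sponsor",
    lead=("Univ A",),
    facilities=(),
    study_type="interventional",
    status="completed",
    start="2010-01-10",
    submitted="2010-01-12",
    posted="2010-01-20",
    pcd="2011-06-01",
    pcd_actuality="actual",
    cd="2011-08-01",
    cd_actuality="actual",
    summary=None,
    linked=(),
    enrollment=None,
    month_precision=(),
) -> TrialRecord:
    def idate(s, field):
        if s is None:
            return None
        prec = Precision.month if field in month_precision else Precision.day
        return ImpreciseDate(date=d(s), precision=prec)

    def cdate(s, actuality, field):
        if s is None:
            return None
        prec = Precision.month if field in month_precision else Precision.day
        return CompletionDate(date=d(s), precision=prec, actuality=Actuality(actuality))

    affiliations = tuple(
        [Affiliation(name=n, role=AffiliationRole.lead) for n in lead]
        + [Affiliation(name=n, role=AffiliationRole.facility) for n in facilities]
    )
    return TrialRecord(
        trial_id=trial_id,
        sponsor_name=sponsor,
        responsible_party_role=ResponsiblePartyRole(role),
        affiliations=affiliations,
        study_type=StudyType(study_type),
        overall_status=OverallStatus(status),
        start_date=idate(start, "start"),
        registration_submitted=idate(submitted, "submitted"),
        registration_posted=idate(posted, "posted"),
        primary_completion_date=cdate(pcd, pcd_actuality, "pcd"),
        completion_date=cdate(cd, cd_actuality, "cd"),
        summary_results_posted=idate(summary, "summary"),
        linked_publication_ids=tuple(linked),
        enrollment=enrollment,
    )


def make_evidence(
    trial_id="NCT00000001",
    source="manual_search",
    format="journal_article",
    date="2012-01-01",
    identifier="10.1/x",
    rater="rater_a",
) -> PublicationEvidence:
    return PublicationEvidence(
        trial_id=trial_id,
        source=EvidenceSource(source),
        format=EvidenceFormat(format),
        pub_date=ImpreciseDate(date=d(date)),
        identifier=identifier,
        rater_id=rater,
    )
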