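"""Multi-source publication search over a local evidence corpus.

The search mirrors the registry-first workflow used by tracking studies:
summary results posted on the registry entry, publications the registry has
indexed (linked identifiers), a PubMed lookup of the trial's registry
number, and finally a manual (search-engine) step.  Each step is a "source"
consulted in a configurable order over an offline corpus; the incremental
yield per source is first-class output, because later, more laborious steps
are exactly what raises overall publication rates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from pydantic import BaseModel, field_validator

from ._dates import ImpreciseDate, Precision
from .errors import ContractError
from .registry_io import (
    EvidenceFormat,
    EvidenceSource,
    PublicationEvidence,
    TrialRecord,
    normalize_identifier,
)

__all__ = [
    "SearchConfig",
    "TrialEvidenceSet",
    "collect_evidence",
    "earliest_dissemination",
    "incremental_yield",
]

DEFAULT_SOURCE_ORDER = (
    EvidenceSource.registry_summary,
    EvidenceSource.registry_indexed,
    EvidenceSource.pubmed_id_search,
    EvidenceSource.manual_search,
)

DEFAULT_FORMAT_PRIORITY = (
    EvidenceFormat.journal_article,
    EvidenceFormat.summary_result,
    EvidenceFormat.csr,
    EvidenceFormat.thesis,
    EvidenceFormat.conference,
    EvidenceFormat.dataset,
)


class SearchConfig(BaseModel, frozen=True):
    """Ordered sources to consult and which dissemination formats count."""

    source_order: Tuple[EvidenceSource, ...] = DEFAULT_SOURCE_ORDER
    accepted_formats: frozenset = frozenset(
        {EvidenceFormat.journal_article, EvidenceFormat.summary_result}
    )
    format_priority: Tuple[EvidenceFormat, ...] = DEFAULT_FORMAT_PRIORITY

    @field_validator("source_order")
    @classmethod
    def _order_valid(cls, v):
        if not v:
            raise ValueError("source_order must be non-empty")
        if len(set(v)) != len(v):
            raise ValueError("source_order must not contain duplicates")
        return v

    @field_validator("accepted_formats", mode="before")
    @classmethod
    def _coerce_formats(cls, v):
        return frozenset(EvidenceFormat(x) for x in v)


@dataclass(frozen=True)
class TrialEvidenceSet:
    """Deduplicated evidence for one trial under a fixed source order."""

    trial_id: str
    evidence: Tuple[PublicationEvidence, ...]
    first_found_source: Optional[EvidenceSource]
    earliest_dissemination_date: Optional[dt.date]
    source_order: Tuple[EvidenceSource, ...]

    @property
    def found(self) -> bool:
        return self.earliest_dissemination_date is not None


def _summary_evidence(record: TrialRecord) -> Optional[PublicationEvidence]:
    if record.summary_results_posted is None:
        return None
    return PublicationEvidence(
        trial_id=record.trial_id,
        source=EvidenceSource.registry_summary,
        format=EvidenceFormat.summary_result,
        pub_date=record.summary_results_posted,
        identifier=f"ctgov-results:{record.trial_id.casefold()}",
        rater_id="auto",
    )


def collect_evidence(
    record: TrialRecord,
    corpus: Iterable[PublicationEvidence],
    config: SearchConfig,
) -> TrialEvidenceSet:
    """Consult the configured sources in order and deduplicate the findings.

    ``registry_summary`` evidence is synthesized from the record's posted
    summary-results date; ``registry_indexed`` joins the record's linked
    publication identifiers against the corpus (any source label); the
    remaining sources take corpus rows carrying their own label.  Duplicate
    identifiers keep the attribution of the earliest source in the order.
    """
    rows = [ev for ev in corpus if ev.trial_id == record.trial_id]
    linked = {normalize_identifier(i) for i in record.linked_publication_ids}

    by_identifier: Dict[str, PublicationEvidence] = {}
    first_source: Optional[EvidenceSource] = None
    for source in config.source_order:
        found_here: List[PublicationEvidence] = []
        if source is EvidenceSource.registry_summary:
            ev = _summary_evidence(record)
            if ev is not None:
                found_here.append(ev)
        elif source is EvidenceSource.registry_indexed:
            for ev in rows:
                if ev.identifier in linked:
                    found_here.append(
                        ev.model_copy(update={"source": EvidenceSource.registry_indexed})
                    )
        else:
            found_here.extend(ev for ev in rows if ev.source is source)
        for ev in sorted(found_here, key=lambda e: (e.pub_date.date, e.identifier)):
            if ev.identifier not in by_identifier:
                by_identifier[ev.identifier] = ev
        if found_here and first_source is None:
            if any(ev.format in config.accepted_formats for ev in found_here):
                first_source = source
    evidence = tuple(
        sorted(by_identifier.values(), key=lambda e: (e.pub_date.date, e.identifier))
    )
    earliest = earliest_dissemination_from(evidence, config.accepted_formats, config.format_priority)
    return TrialEvidenceSet(
        trial_id=record.trial_id,
        evidence=evidence,
        first_found_source=first_source,
        earliest_dissemination_date=earliest[0] if earliest else None,
        source_order=tuple(config.source_order),
    )


def earliest_dissemination_from(
    evidence: Sequence[PublicationEvidence],
    accepted_formats: Iterable[EvidenceFormat],
    format_priority: Sequence[EvidenceFormat] = DEFAULT_FORMAT_PRIORITY,
) -> Optional[Tuple[dt.date, EvidenceFormat]]:
    accepted = set(accepted_formats)
    candidates = [ev for ev in evidence if ev.format in accepted]
    if not candidates:
        return None
    prio = {f: i for i, f in enumerate(format_priority)}
    best = min(candidates, key=lambda e: (e.pub_date.date, prio.get(e.format, len(prio)), e.identifier))
    return best.pub_date.date, best.format


def earliest_dissemination(
    evidence_set: TrialEvidenceSet,
    accepted_formats: Iterable[EvidenceFormat],
    format_priority: Sequence[EvidenceFormat] = DEFAULT_FORMAT_PRIORITY,
) -> Optional[Tuple[dt.date, EvidenceFormat]]:
    """Earliest date over accepted-format evidence; ties broken by format priority."""
    return earliest_dissemination_from(evidence_set.evidence, accepted_formats, format_priority)


def incremental_yield(
    evidence_sets: Sequence[TrialEvidenceSet], config: SearchConfig
) -> pd.DataFrame:
    """Per-source incremental yield table.

    For each source, in order: the number of trials first found (with an
    accepted-format item) at that source, and the cumulative proportion of
    all trials found so far.  Cumulative proportions are non-decreasing and
    end at the overall found proportion.
    """
    order = tuple(config.source_order)
    for es in evidence_sets:
        if es.source_order != order:
            raise ContractError(
                f"evidence set for {es.trial_id} was built under a different source order"
            )
    n = len(evidence_sets)
    counts = {source: 0 for source in order}
    for es in evidence_sets:
        if es.first_found_source is not None:
            counts[es.first_found_source] += 1
    rows = []
    cumulative = 0
    for source in order:
        cumulative += counts[source]
        rows.append(
            {
                "source": source.value,
                "n_new": counts[source],
                "cumulative_n": cumulative,
                "cumulative_proportion": cumulative / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["source", "n_new", "cumulative_n", "cumulative_proportion"])
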