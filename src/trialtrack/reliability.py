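"""Inter-rater comparison of independently collected publication evidence.

Two trained raters searching for the same trial's publications often find
different things.  Disagreement is defined on the *identifier sets* the two
raters recorded for each trial — not on dates: two records of the same DOI
with different dates are agreement plus a date-conflict warning.  Five
mutually exclusive categories cover every case, and an explicit adjudication
rule turns the two sets into the consensus evidence used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import ConfigurationError, ContractError
from .registry_io import PublicationEvidence

__all__ = [
    "AdjudicationRule",
    "DisagreementCategory",
    "RaterComparison",
    "adjudicate",
    "compare_raters",
]


class DisagreementCategory(str, Enum):
    both_same = "both_same"
    both_none = "both_none"
    only_one_found = "only_one_found"
    different_publications = "different_publications"
    overlapping_sets = "overlapping_sets"


class AdjudicationRule(str, Enum):
    union = "union"
    intersection = "intersection"
    earliest_date = "earliest_date"


@dataclass(frozen=True)
class RaterComparison:
    trial_id: str
    category: DisagreementCategory
    raters: Tuple[str, str]
    ids_a: frozenset
    ids_b: frozenset
    evidence_a: Tuple[PublicationEvidence, ...]
    evidence_b: Tuple[PublicationEvidence, ...]
    date_conflict: bool


def _categorize(ids_a: frozenset, ids_b: frozenset) -> DisagreementCategory:
    if not ids_a and not ids_b:
        return DisagreementCategory.both_none
    if ids_a == ids_b:
        return DisagreementCategory.both_same
    if not ids_a or not ids_b:
        return DisagreementCategory.only_one_found
    if not (ids_a & ids_b):
        return DisagreementCategory.different_publications
    return DisagreementCategory.overlapping_sets


def compare_raters(
    evidence: Iterable[PublicationEvidence],
    trial_ids: Sequence[str],
    raters: Optional[Tuple[str, str]] = None,
) -> Tuple[List[RaterComparison], Dict[str, float]]:
    """Compare the two raters' identifier sets for every trial.

    ``evidence`` must be restricted to at most two rater IDs; pass ``raters``
    explicitly when fewer than two appear in the data.  Returns one
    comparison per trial plus summary proportions per category over
    ``trial_ids`` (they sum to 1).
    """
    evidence = list(evidence)
    present = sorted({ev.rater_id for ev in evidence})
    if raters is None:
        if len(present) != 2:
            raise ContractError(
                f"expected exactly two rater IDs in evidence, found {present!r}; "
                "pass raters=(a, b) explicitly"
            )
        raters = (present[0], present[1])
    else:
        extra = set(present) - set(raters)
        if extra:
            raise ContractError(f"evidence contains unexpected rater IDs {sorted(extra)!r}")
    a, b = raters

    by_trial: Dict[str, Dict[str, List[PublicationEvidence]]] = {
        t: {a: [], b: []} for t in trial_ids
    }
    for ev in evidence:
        if ev.trial_id in by_trial:
            by_trial[ev.trial_id][ev.rater_id].append(ev)

    comparisons: List[RaterComparison] = []
    counts = {c: 0 for c in DisagreementCategory}
    for trial_id in trial_ids:
        ev_a = tuple(sorted(by_trial[trial_id][a], key=lambda e: (e.pub_date.date, e.identifier)))
        ev_b = tuple(sorted(by_trial[trial_id][b], key=lambda e: (e.pub_date.date, e.identifier)))
        ids_a = frozenset(e.identifier for e in ev_a)
        ids_b = frozenset(e.identifier for e in ev_b)
        category = _categorize(ids_a, ids_b)
        shared_dates = {
            i: ({e.pub_date.date for e in ev_a if e.identifier == i},
                {e.pub_date.date for e in ev_b if e.identifier == i})
            for i in ids_a & ids_b
        }
        conflict = any(da != db for da, db in shared_dates.values())
        counts[category] += 1
        comparisons.append(
            RaterComparison(
                trial_id=trial_id,
                category=category,
                raters=(a, b),
                ids_a=ids_a,
                ids_b=ids_b,
                evidence_a=ev_a,
                evidence_b=ev_b,
                date_conflict=conflict,
            )
        )
    n = len(trial_ids)
    summary = {c.value: (counts[c] / n if n else 0.0) for c in DisagreementCategory}
    return comparisons, summary


def adjudicate(
    comparisons: Sequence[RaterComparison],
    rule: AdjudicationRule,
) -> Dict[str, List[PublicationEvidence]]:
    """Resolve the two raters' evidence into consensus evidence per trial.

    ``union`` keeps every identifier either rater found; ``intersection``
    keeps only shared identifiers; ``earliest_date`` keeps the single item
    with the earliest date across both raters (ties broken by identifier).
    For identifiers kept by union/intersection the earliest-dated instance
    is retained.
    """
    try:
        rule = AdjudicationRule(rule)
    except ValueError:
        raise ConfigurationError(f"unknown adjudication rule {rule!r}") from None

    consensus: Dict[str, List[PublicationEvidence]] = {}
    for comp in comparisons:
        pooled = list(comp.evidence_a) + list(comp.evidence_b)
        pooled.sort(key=lambda e: (e.pub_date.date, e.identifier, e.rater_id))
        if rule is AdjudicationRule.union:
            keep_ids = comp.ids_a | comp.ids_b
        elif rule is AdjudicationRule.intersection:
            keep_ids = comp.ids_a & comp.ids_b
        else:  # earliest_date: single earliest item, if any evidence exists
            consensus[comp.trial_id] = pooled[:1]
            continue
        seen: set = set()
        kept: List[PublicationEvidence] = []
        for ev in pooled:
            if ev.identifier in keep_ids and ev.identifier not in seen:
                seen.add(ev.identifier)
                kept.append(ev)
        consensus[comp.trial_id] = kept
    return consensus
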