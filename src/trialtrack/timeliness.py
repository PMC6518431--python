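"""Completion-date resolution and fixed-window publication proportions.

A trial's "completion" can be referenced to the primary completion date
(PCD, last participant examined for the primary outcome) or the later
completion date (CD, last participant's last visit, covering secondary
outcomes and adverse events).  Which reference is used, and whether
registry-estimated dates are acceptable, materially changes publication
rates; both are explicit policy knobs here.

Rates are simple proportions: the share of evaluable trials whose earliest
accepted dissemination falls within ``window_months`` calendar months of the
resolved reference date (inclusive boundary, end-of-month clamped).  Trials
whose window has not yet elapsed at the snapshot date are censored —
excluded from the denominator but always reported as a separate count.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from math import inf
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from pydantic import BaseModel

from ._dates import Actuality, add_months
from .errors import ConfigurationError
from .registry_io import CompletionDate, TrialRecord

__all__ = [
    "CompletionPolicy",
    "CompletionReference",
    "RateResult",
    "publication_rate",
    "rate_table",
    "resolve_completion_date",
]

Window = Union[int, float, None]  # None or math.inf = all-time


class CompletionReference(str, Enum):
    pcd = "pcd"
    cd = "cd"
    cd_then_pcd = "cd_then_pcd"
    pcd_then_cd = "pcd_then_cd"


class CompletionPolicy(BaseModel, frozen=True):
    """How to resolve a trial's completion reference date."""

    reference: CompletionReference = CompletionReference.cd_then_pcd
    allow_estimated: bool = False


def resolve_completion_date(
    record: TrialRecord, policy: CompletionPolicy
) -> Optional[Tuple[dt.date, str]]:
    """Return the policy's reference date and a provenance tag, or None.

    The tag names the field actually used (``"cd"``/``"pcd"``) with an
    ``"+estimated"`` suffix when an estimated date was accepted.  Absence is
    a value: the caller counts it as missing-reference.
    """

    def usable(c: Optional[CompletionDate]) -> bool:
        if c is None:
            return False
        return policy.allow_estimated or c.actuality is Actuality.actual

    candidates: List[Tuple[str, Optional[CompletionDate]]]
    ref = policy.reference
    if ref is CompletionReference.pcd:
        candidates = [("pcd", record.primary_completion_date)]
    elif ref is CompletionReference.cd:
        candidates = [("cd", record.completion_date)]
    elif ref is CompletionReference.cd_then_pcd:
        candidates = [("cd", record.completion_date), ("pcd", record.primary_completion_date)]
    else:
        candidates = [("pcd", record.primary_completion_date), ("cd", record.completion_date)]
    for tag, comp in candidates:
        if usable(comp):
            if comp.actuality is Actuality.estimated:
                tag += "+estimated"
            return comp.date, tag
    return None


def _is_all_time(window: Window) -> bool:
    return window is None or window == inf


@dataclass(frozen=True)
class RateResult:
    """One publication-rate cell with its full accounting."""

    window_months: Optional[int]  # None = all-time
    reference: str
    stratum: str
    numerator: int
    denominator: int
    censored: int
    missing_reference: int
    snapshot_date: dt.date

    @property
    def rate(self) -> Optional[float]:
        """Proportion published within the window; None when undefined (denominator 0)."""
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def undefined(self) -> bool:
        return self.denominator == 0

    def to_dict(self) -> dict:
        return {
            "window_months": self.window_months,
            "reference": self.reference,
            "stratum": self.stratum,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "censored": self.censored,
            "missing_reference": self.missing_reference,
            "snapshot_date": self.snapshot_date.isoformat(),
            "rate": self.rate,
            "undefined": self.undefined,
        }


def publication_rate(
    sample: Sequence[Tuple[TrialRecord, Optional[dt.date]]],
    policy: CompletionPolicy,
    window_months: Window,
    snapshot_date: dt.date,
    stratum: str = "all",
) -> RateResult:
    """Proportion of trials published within ``window_months`` of completion.

    ``sample`` pairs each record with its earliest accepted dissemination
    date (None when nothing was found).  A trial enters the numerator iff
    that date is on or before reference + window (calendar months).  Finite
    windows that have not elapsed at ``snapshot_date`` are censored; the
    all-time window (None or inf) uses the snapshot date as the bound with
    no censoring.
    """
    if not _is_all_time(window_months) and int(window_months) <= 0:
        raise ConfigurationError(f"window_months must be positive, got {window_months}")
    numerator = denominator = censored = missing = 0
    for record, pub_date in sample:
        resolved = resolve_completion_date(record, policy)
        if resolved is None:
            missing += 1
            continue
        reference_date, _tag = resolved
        if _is_all_time(window_months):
            bound = snapshot_date
        else:
            bound = add_months(reference_date, int(window_months))
            if bound > snapshot_date:
                censored += 1
                continue
        denominator += 1
        if pub_date is not None and pub_date <= bound:
            numerator += 1
    return RateResult(
        window_months=None if _is_all_time(window_months) else int(window_months),
        reference=policy.reference.value + ("+estimated" if policy.allow_estimated else ""),
        stratum=stratum,
        numerator=numerator,
        denominator=denominator,
        censored=censored,
        missing_reference=missing,
        snapshot_date=snapshot_date,
    )


def rate_table(
    sample: Sequence[Tuple[TrialRecord, Optional[dt.date], Optional[str]]],
    policies: Sequence[CompletionPolicy],
    windows: Sequence[Window],
    snapshot_date: dt.date,
    strata: Union[str, Sequence[str]] = "auto",
) -> List[RateResult]:
    """Full cross of (policy, window, stratum) rate cells.

    ``sample`` carries a stratum label per trial (None allowed).  With
    ``strata="auto"`` the table contains an ``"all"`` row per cell plus one
    row per stratum label present in the sample.
    """
    present = sorted({s for _, _, s in sample if s is not None})
    if strata == "auto":
        strata_list = ["all"] + present
    elif isinstance(strata, str):
        strata_list = [strata]
    else:
        strata_list = list(strata)
    out: List[RateResult] = []
    for policy in policies:
        for window in windows:
            for stratum in strata_list:
                if stratum == "all":
                    sub = [(r, p) for r, p, _ in sample]
                else:
                    sub = [(r, p) for r, p, s in sample if s == stratum]
                out.append(
                    publication_rate(sub, policy, window, snapshot_date, stratum=stratum)
                )
    return out
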