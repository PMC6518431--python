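"""The ten tracking variables as one explicit, serializable configuration.

Publication-tracking studies differ in who counts as responsible for a
trial, which study types and statuses are followed up, how retrospective
registration is handled, which completion date anchors the clock, what time
windows and dissemination formats count, where publications are searched,
and how rater disagreement is resolved.  Every one of those choices changes
the resulting rates, so all of them are explicit fields here — none is left
implicit — and every report embeds the full configuration plus its hash.
"""

from __future__ import annotations

import hashlib
import json
from enum import Enum
from pathlib import Path
from typing import List, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError
from .publication_search import SearchConfig
from .registry_io import OverallStatus, StudyType
from .reliability import AdjudicationRule
from .timeliness import CompletionPolicy

__all__ = [
    "RegistrationDateField",
    "RegistrationPolicy",
    "ResponsibilityScope",
    "TrackingConfig",
]


class ResponsibilityScope(str, Enum):
    legal_only = "legal_only"  # sponsor / principal investigator only
    all_recruiting = "all_recruiting"  # any recruiting involvement


class RegistrationPolicy(str, Enum):
    include_all = "include_all"
    prospective_only = "prospective_only"
    stratify = "stratify"


class RegistrationDateField(str, Enum):
    submitted = "submitted"
    posted = "posted"


_ALL_TIME = "all_time"


class TrackingConfig(BaseModel, frozen=True):
    """All ten tracking variables, with conventional defaults.

    Defaults: legal-and-recruiting scope stratified separately, completed
    interventional trials, 21/60-day registration cutoffs on the submission
    date, completion date (falling back to the primary completion date) as
    the clock anchor, 12/24-month and all-time windows, journal articles and
    registry summary results as accepted formats, the registry-first source
    order, and union adjudication of rater disagreements.
    """

    # 1. responsibility
    responsibility_scope: ResponsibilityScope = ResponsibilityScope.all_recruiting
    # 2. study types
    study_types: frozenset = frozenset({StudyType.interventional})
    # 3. statuses
    statuses: frozenset = frozenset({OverallStatus.completed})
    # 4. sampling source (descriptive: where the sample was drawn from)
    sampling_source: str = "registry"
    # 5. registration timing
    registration_policy: RegistrationPolicy = RegistrationPolicy.stratify
    prospective_cutoff_days: int = Field(default=21, ge=0)
    retrospective_threshold_days: int = Field(default=60, ge=0)
    registration_date_field: RegistrationDateField = RegistrationDateField.submitted
    # 6. completion date
    completion: CompletionPolicy = CompletionPolicy()
    # 7. timeliness windows (months; None = all-time)
    windows: Tuple[Optional[int], ...] = (12, 24, None)
    # 8 + 9. formats and sources
    search: SearchConfig = SearchConfig()
    # 10. inter-rater reliability
    adjudication_rule: AdjudicationRule = AdjudicationRule.union
    raters: Optional[Tuple[str, str]] = None
    # housekeeping
    exclude_flagged: bool = False

    @field_validator("study_types", mode="before")
    @classmethod
    def _coerce_types(cls, v):
        out = frozenset(StudyType(x) for x in v)
        if not out:
            raise ValueError("study_types must be non-empty")
        return out

    @field_validator("statuses", mode="before")
    @classmethod
    def _coerce_statuses(cls, v):
        out = frozenset(OverallStatus(x) for x in v)
        if not out:
            raise ValueError("statuses must be non-empty")
        return out

    @field_validator("windows", mode="before")
    @classmethod
    def _coerce_windows(cls, v):
        out = []
        for w in v:
            if w is None or w == _ALL_TIME:
                out.append(None)
            else:
                w = int(w)
                if w <= 0:
                    raise ValueError(f"window must be positive, got {w}")
                out.append(w)
        return tuple(out)

    @model_validator(mode="after")
    def _cutoffs_ordered(self) -> "TrackingConfig":
        if self.prospective_cutoff_days > self.retrospective_threshold_days:
            raise ValueError(
                "prospective_cutoff_days must not exceed retrospective_threshold_days"
            )
        return self

    # -- serialization ----------------------------------------------------

    def canonical_dict(self) -> dict:
        """JSON-safe dict with deterministic ordering of all set-valued fields."""
        return {
            "responsibility_scope": self.responsibility_scope.value,
            "study_types": sorted(t.value for t in self.study_types),
            "statuses": sorted(s.value for s in self.statuses),
            "sampling_source": self.sampling_source,
            "registration_policy": self.registration_policy.value,
            "prospective_cutoff_days": self.prospective_cutoff_days,
            "retrospective_threshold_days": self.retrospective_threshold_days,
            "registration_date_field": self.registration_date_field.value,
            "completion": {
                "reference": self.completion.reference.value,
                "allow_estimated": self.completion.allow_estimated,
            },
            "windows": [w if w is not None else _ALL_TIME for w in self.windows],
            "search": {
                "source_order": [s.value for s in self.search.source_order],
                "accepted_formats": sorted(f.value for f in self.search.accepted_formats),
                "format_priority": [f.value for f in self.search.format_priority],
            },
            "adjudication_rule": self.adjudication_rule.value,
            "raters": list(self.raters) if self.raters else None,
            "exclude_flagged": self.exclude_flagged,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "TrackingConfig":
        data = dict(data)
        if "completion" in data and isinstance(data["completion"], dict):
            data["completion"] = CompletionPolicy(**data["completion"])
        if "search" in data and isinstance(data["search"], dict):
            data["search"] = SearchConfig(**data["search"])
        if data.get("raters") is not None:
            data["raters"] = tuple(data["raters"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "TrackingConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: tracking config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.canonical_dict(), sort_keys=False))
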