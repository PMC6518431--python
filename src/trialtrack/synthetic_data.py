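"""Synthetic registries and publication corpora with known ground truth.

The generator emulates the structure a publication-tracking study meets in
the wild: registration delays spanning prospective, late, retrospective,
post-completion and post-publication strata; a Bernoulli ever-published
indicator with a lognormal (or exponential) completion-to-publication
latency; per-source discoverability (registry summary/indexed link, PubMed
ID search, manual search); two imperfect raters for the manual step; and a
fraction of month-precision dates.

One deliberate simplification keeps the closed-form oracles exact: every
dissemination artifact of a trial (journal article, registry summary, each
rater's manual find — including a wrong pick) carries the same latent
publication date.  Real corpora spread these dates out; here the collapse
makes the expected window rate simply ``p_published * F(w)`` times, when
discoverability-adjusted, the probability that at least one source finds
the publication.

All randomness flows from ``config.seed`` through a single generator, so
identical configurations yield byte-identical files.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple, Union

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats

from ._dates import Actuality, ImpreciseDate, Precision, month_end, month_start
from .errors import ConfigurationError
from .registry_io import (
    Affiliation,
    AffiliationRole,
    CompletionDate,
    EvidenceFormat,
    EvidenceSource,
    OverallStatus,
    PublicationEvidence,
    ResponsiblePartyRole,
    StudyType,
    TrialRecord,
    write_publication_corpus,
    write_registry_records,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "TrialTruth",
    "expected_rate",
    "expected_rater_categories",
    "expected_source_yields",
    "generate_registry",
    "write_outputs",
]

DAYS_PER_MONTH = 30.4375

STRATA = ("prospective", "late", "retrospective", "post_completion", "post_publication")


class SyntheticConfig(BaseModel, frozen=True):
    """Generator parameters; defaults emulate a registry cohort whose window
    rates rise from roughly 0.16 at 12 months to about 0.75 all-time, with a
    registry+PubMed yield near 0.48 and the manual step adding about 0.27.
    Illustrative study conditions, not estimates of any real dataset."""

    n_trials: int = Field(default=2000, ge=0)
    seed: int = 0
    id_offset: int = Field(default=0, ge=0)  # first trial number, for concatenable cohorts
    # study timeline
    start_min: dt.date = dt.date(2008, 1, 1)
    start_max: dt.date = dt.date(2012, 12, 31)
    duration_meanlog: float = math.log(18.0)  # months, start -> PCD
    duration_sdlog: float = 0.4
    gap_meanlog: float = math.log(2.0)  # months, PCD -> CD
    gap_sdlog: float = 0.5
    # registration-delay mixture
    stratum_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "prospective": 0.55,
            "late": 0.10,
            "retrospective": 0.25,
            "post_completion": 0.08,
            "post_publication": 0.02,
        }
    )
    # publication model
    p_published_ever: float = Field(default=0.8, ge=0.0, le=1.0)
    latency_model: Literal["lognormal", "exponential"] = "lognormal"
    latency_meanlog: float = 3.26  # months from CD; median ~26 months
    latency_sdlog: float = 0.97
    latency_rate_per_month: float = 0.0  # used by the exponential model
    # per-source discoverability
    p_registry: float = Field(default=0.5, ge=0.0, le=1.0)
    p_summary_given_registry: float = Field(default=0.5, ge=0.0, le=1.0)
    p_pubmed: float = Field(default=0.2, ge=0.0, le=1.0)
    p_manual: float = Field(default=0.86, ge=0.0, le=1.0)
    # rater model (manual step)
    rater_sensitivity: float = Field(default=0.87, ge=0.0, le=1.0)
    rater_wrong_pick: float = Field(default=0.10, ge=0.0, le=1.0)
    rater_ids: Tuple[str, str] = ("rater_a", "rater_b")
    # record noise
    month_precision_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    p_legal: float = Field(default=0.7, ge=0.0, le=1.0)
    institution: str = "University Medical Center Alpha"
    other_sponsor: str = "Pharma Beta GmbH"

    @field_validator("stratum_probs")
    @classmethod
    def _probs_valid(cls, v):
        unknown = set(v) - set(STRATA)
        if unknown:
            raise ValueError(f"unknown strata {sorted(unknown)}")
        probs = {s: float(v.get(s, 0.0)) for s in STRATA}
        if any(not 0.0 <= p <= 1.0 for p in probs.values()):
            raise ValueError("stratum probabilities must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("stratum probabilities must sum to 1")
        return probs

    @model_validator(mode="after")
    def _dates_ordered(self) -> "SyntheticConfig":
        if self.start_min > self.start_max:
            raise ValueError("start_min must not exceed start_max")
        return self


@dataclass(frozen=True)
class TrialTruth:
    """Latent per-trial ground truth, consistent with the emitted files."""

    trial_id: str
    stratum: str
    published: bool
    publication_date: Optional[str]  # ISO, None if never published
    start_date: str
    primary_completion_date: str
    completion_date: str
    registration_date: str
    registry_discoverable: bool
    registry_mode: Optional[str]  # "summary" | "indexed"
    pubmed_discoverable: bool
    manual_discoverable: bool
    first_found_source: Optional[str]  # under the default source order
    rater_found: Dict[str, Optional[str]]  # rater id -> recorded identifier
    legal_responsibility: bool


@dataclass
class SyntheticTruth:
    config: SyntheticConfig
    trials: List[TrialTruth]

    def to_dict(self) -> dict:
        return {
            "config": json.loads(self.config.model_dump_json()),
            "trials": [asdict(t) for t in self.trials],
        }


def _months_to_days(months: float) -> int:
    return max(1, int(round(months * DAYS_PER_MONTH)))


def _latency_months(config: SyntheticConfig, rng: np.random.Generator) -> float:
    if config.latency_model == "lognormal":
        return float(rng.lognormal(config.latency_meanlog, config.latency_sdlog))
    rate = config.latency_rate_per_month
    if rate <= 0.0:
        return float("inf")
    return float(rng.exponential(1.0 / rate))


def _imprecise(d: dt.date, make_month: bool, impute: str) -> ImpreciseDate:
    if not make_month:
        return ImpreciseDate(date=d, precision=Precision.day)
    stored = month_start(d.year, d.month) if impute == "first" else month_end(d.year, d.month)
    return ImpreciseDate(date=stored, precision=Precision.month)


def _true_stratum(
    start: dt.date,
    registration: dt.date,
    completion: dt.date,
    publication: Optional[dt.date],
    cutoff: int = 21,
    threshold: int = 60,
) -> str:
    if publication is not None and registration > publication:
        return "post_publication"
    if registration > completion:
        return "post_completion"
    d = (registration - start).days
    if d <= cutoff:
        return "prospective"
    if d <= threshold:
        return "late"
    return "retrospective"


def generate_registry(
    config: SyntheticConfig,
) -> Tuple[List[TrialRecord], List[PublicationEvidence], SyntheticTruth]:
    """Draw a seeded synthetic registry, evidence corpus, and ground truth.

    Emitted dates respect start ≤ PCD ≤ CD; trials in the post-publication
    stratum have registration after their latent publication date; evidence
    rows follow the per-source discoverability and two-rater model.
    """
    rng = np.random.default_rng(config.seed)
    records: List[TrialRecord] = []
    corpus: List[PublicationEvidence] = []
    truths: List[TrialTruth] = []

    start_span = (config.start_max - config.start_min).days + 1
    strata = list(STRATA)
    probs = np.array([config.stratum_probs[s] for s in strata])
    no_pub_probs = probs.copy()
    no_pub_probs[strata.index("post_publication")] = 0.0
    if no_pub_probs.sum() > 0:
        no_pub_probs = no_pub_probs / no_pub_probs.sum()

    rater_a, rater_b = config.rater_ids

    for i in range(config.n_trials):
        trial_id = f"NCT{config.id_offset + i + 1:08d}"
        doi = f"10.5555/synth.{trial_id.lower()}"

        start = config.start_min + dt.timedelta(days=int(rng.integers(0, start_span)))
        pcd = start + dt.timedelta(
            days=_months_to_days(rng.lognormal(config.duration_meanlog, config.duration_sdlog))
        )
        cd = pcd + dt.timedelta(
            days=_months_to_days(rng.lognormal(config.gap_meanlog, config.gap_sdlog))
        )

        published = bool(rng.random() < config.p_published_ever)
        publication: Optional[dt.date] = None
        if published:
            lat = _latency_months(config, rng)
            if math.isinf(lat):
                published, publication = False, None
            else:
                publication = cd + dt.timedelta(days=_months_to_days(lat))

        if published:
            intended = strata[int(rng.choice(len(strata), p=probs))]
        elif no_pub_probs.sum() > 0:
            intended = strata[int(rng.choice(len(strata), p=no_pub_probs))]
        else:  # degenerate config: everything post_publication but unpublishable
            intended = "prospective"

        if intended == "prospective":
            registration = start + dt.timedelta(days=int(rng.integers(0, 22)))
        elif intended == "late":
            registration = start + dt.timedelta(days=int(rng.integers(22, 61)))
        elif intended == "retrospective":
            dur = (cd - start).days
            delay = int(rng.integers(61, max(62, dur + 1)))
            registration = start + dt.timedelta(days=min(delay, dur))
        elif intended == "post_completion":
            registration = cd + dt.timedelta(days=int(rng.integers(30, 366)))
        else:  # post_publication; only drawn for published trials
            registration = publication + dt.timedelta(days=int(rng.integers(7, 181)))
        posted = registration + dt.timedelta(days=int(rng.integers(0, 15)))

        stratum = _true_stratum(start, registration, cd, publication)

        legal = bool(rng.random() < config.p_legal)

        # discoverability and rater coins (meaningful only when published)
        registry_disc = published and bool(rng.random() < config.p_registry)
        registry_mode: Optional[str] = None
        if registry_disc:
            registry_mode = (
                "summary" if rng.random() < config.p_summary_given_registry else "indexed"
            )
        pubmed_disc = published and bool(rng.random() < config.p_pubmed)
        manual_disc = published and bool(rng.random() < config.p_manual)
        rater_found: Dict[str, Optional[str]] = {rater_a: None, rater_b: None}
        if manual_disc:
            for rater in (rater_a, rater_b):
                if rng.random() < config.rater_sensitivity:
                    wrong = rng.random() < config.rater_wrong_pick
                    rater_found[rater] = f"{doi}-alt-{rater}" if wrong else doi

        f = config.month_precision_fraction
        start_stored = _imprecise(start, bool(rng.random() < f), "first")
        pcd_stored = _imprecise(pcd, bool(rng.random() < f), "last")
        cd_stored = _imprecise(cd, bool(rng.random() < f), "last")

        summary_posted: Optional[ImpreciseDate] = None
        linked: Tuple[str, ...] = ()
        if registry_disc and registry_mode == "summary":
            summary_posted = ImpreciseDate(date=publication, precision=Precision.day)
        if registry_disc and registry_mode == "indexed":
            linked = (doi,)
            corpus.append(
                PublicationEvidence(
                    trial_id=trial_id,
                    source=EvidenceSource.registry_indexed,
                    format=EvidenceFormat.journal_article,
                    pub_date=ImpreciseDate(date=publication),
                    identifier=doi,
                    rater_id="auto",
                )
            )
        if pubmed_disc:
            corpus.append(
                PublicationEvidence(
                    trial_id=trial_id,
                    source=EvidenceSource.pubmed_id_search,
                    format=EvidenceFormat.journal_article,
                    pub_date=ImpreciseDate(date=publication),
                    identifier=doi,
                    rater_id="auto",
                )
            )
        for rater, ident in rater_found.items():
            if ident is not None:
                corpus.append(
                    PublicationEvidence(
                        trial_id=trial_id,
                        source=EvidenceSource.manual_search,
                        format=EvidenceFormat.journal_article,
                        pub_date=ImpreciseDate(date=publication),
                        identifier=ident,
                        rater_id=rater,
                    )
                )

        if registry_mode == "summary":
            first_found: Optional[str] = EvidenceSource.registry_summary.value
        elif registry_mode == "indexed":
            first_found = EvidenceSource.registry_indexed.value
        elif pubmed_disc:
            first_found = EvidenceSource.pubmed_id_search.value
        elif any(v is not None for v in rater_found.values()):
            first_found = EvidenceSource.manual_search.value
        else:
            first_found = None

        if legal:
            sponsor = config.institution
            affiliations = (
                Affiliation(name=config.institution, role=AffiliationRole.lead),
                Affiliation(name=f"{config.institution} Hospital", role=AffiliationRole.facility),
            )
            role = ResponsiblePartyRole.sponsor
        else:
            sponsor = config.other_sponsor
            affiliations = (
                Affiliation(name=config.other_sponsor, role=AffiliationRole.lead),
                Affiliation(name=f"{config.institution} Hospital", role=AffiliationRole.facility),
            )
            role = ResponsiblePartyRole.sponsor

        records.append(
            TrialRecord(
                trial_id=trial_id,
                sponsor_name=sponsor,
                responsible_party_role=role,
                affiliations=affiliations,
                study_type=StudyType.interventional,
                overall_status=OverallStatus.completed,
                start_date=start_stored,
                registration_submitted=ImpreciseDate(date=registration),
                registration_posted=ImpreciseDate(date=posted),
                primary_completion_date=CompletionDate(
                    date=pcd_stored.date, precision=pcd_stored.precision, actuality=Actuality.actual
                ),
                completion_date=CompletionDate(
                    date=cd_stored.date, precision=cd_stored.precision, actuality=Actuality.actual
                ),
                summary_results_posted=summary_posted,
                linked_publication_ids=linked,
                enrollment=int(rng.integers(20, 500)),
            )
        )
        truths.append(
            TrialTruth(
                trial_id=trial_id,
                stratum=stratum,
                published=published,
                publication_date=publication.isoformat() if publication else None,
                start_date=start.isoformat(),
                primary_completion_date=pcd.isoformat(),
                completion_date=cd.isoformat(),
                registration_date=registration.isoformat(),
                registry_discoverable=registry_disc,
                registry_mode=registry_mode,
                pubmed_discoverable=pubmed_disc,
                manual_discoverable=manual_disc,
                first_found_source=first_found,
                rater_found=rater_found,
                legal_responsibility=legal,
            )
        )

    return records, corpus, SyntheticTruth(config=config, trials=truths)


def write_outputs(
    records: List[TrialRecord],
    corpus: List[PublicationEvidence],
    truth: SyntheticTruth,
    outdir: Union[str, Path],
) -> None:
    """Write registry flat_csv, corpus CSV, and truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_registry_records(records, outdir / "registry.csv", dialect="flat_csv")
    write_publication_corpus(corpus, outdir / "corpus.csv")
    (outdir / "truth.json").write_text(
        json.dumps(truth.to_dict(), sort_keys=True, indent=1, default=str) + "\n"
    )


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------


def _latency_cdf(config: SyntheticConfig, window_months: Optional[float]) -> float:
    if window_months is None or math.isinf(window_months):
        return 1.0
    w = float(window_months)
    if config.latency_model == "lognormal":
        dist = stats.lognorm(s=config.latency_sdlog, scale=math.exp(config.latency_meanlog))
        return float(dist.cdf(w))
    rate = config.latency_rate_per_month
    return 0.0 if rate <= 0 else 1.0 - math.exp(-rate * w)


def manual_find_probability(config: SyntheticConfig) -> float:
    """P(the manual step records anything | publication manual-discoverable)."""
    miss = (1.0 - config.rater_sensitivity) ** 2
    return 1.0 - miss


def expected_rate(
    config: SyntheticConfig,
    window_months: Optional[float],
    discoverability_adjusted: bool = False,
) -> float:
    """Expected publication rate at a CD-referenced window.

    ``p_published_ever * F(window)`` where F is the latency CDF; the
    discoverability-adjusted variant multiplies by the probability that at
    least one search source turns the publication up.
    """
    rate = config.p_published_ever * _latency_cdf(config, window_months)
    if discoverability_adjusted:
        p_manual_eff = config.p_manual * manual_find_probability(config)
        miss_all = (1 - config.p_registry) * (1 - config.p_pubmed) * (1 - p_manual_eff)
        rate *= 1.0 - miss_all
    return rate


def expected_source_yields(config: SyntheticConfig) -> Dict[str, float]:
    """Analytic per-source first-found proportions under the default order."""
    p = config.p_published_ever
    p_r, p_sgr = config.p_registry, config.p_summary_given_registry
    p_pm = config.p_pubmed
    p_m_eff = config.p_manual * manual_find_probability(config)
    return {
        EvidenceSource.registry_summary.value: p * p_r * p_sgr,
        EvidenceSource.registry_indexed.value: p * p_r * (1 - p_sgr),
        EvidenceSource.pubmed_id_search.value: p * (1 - p_r) * p_pm,
        EvidenceSource.manual_search.value: p * (1 - p_r) * (1 - p_pm) * p_m_eff,
    }


def expected_rater_categories(config: SyntheticConfig) -> Dict[str, float]:
    """Analytic disagreement-category proportions over all trials.

    With discoverable-publication probability ``pd = p_published * p_manual``,
    per-rater sensitivity ``s`` and wrong-pick probability ``q``:
    only-one-found is ``pd * 2s(1-s)`` and different-publications is
    ``pd * s^2 * q(2-q)`` (disjoint unless both raters picked correctly).
    """
    pd_ = config.p_published_ever * config.p_manual
    s, q = config.rater_sensitivity, config.rater_wrong_pick
    only_one = pd_ * 2 * s * (1 - s)
    different = pd_ * s * s * q * (2 - q)
    both_same = pd_ * s * s * (1 - q) ** 2
    return {
        "only_one_found": only_one,
        "different_publications": different,
        "both_same": both_same,
        "both_none": 1.0 - only_one - different - both_same,
        "overlapping_sets": 0.0,
    }
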