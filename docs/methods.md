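# Methods

This note documents the model behind `trialtrack`: what the pipeline
computes, the conventions it adopts where registries are ambiguous, what
the synthetic-data generator does and does not emulate, and the numerical
and design choices a maintainer would want stated.

## Pipeline model

The pipeline is a deterministic composition of four stages over a set of
registry trial records and a local publication-evidence corpus:

1. **Sampling** (tracking variables 1–5). Filters run in a fixed order —
   responsibility, study type, status, optional date-consistency flags,
   registration policy — so each excluded trial carries exactly one primary
   reason and exclusion flow diagrams are reproducible. Responsibility is
   `legal` when the institution matches the sponsor or a lead
   (responsible-party) affiliation, `cooperating` when it matches only a
   recruiting facility; with `all_recruiting` scope both are tracked and
   reports still stratify the two. Registration timing is classified from
   the delay `d = registration − start` in whole days: prospective for
   `d ≤ 21` (the FDAAA registration allowance; ties go to the less severe
   class), late for `21 < d ≤ 60`, retrospective beyond 60 days, overridden
   by post-completion (registration after the resolved completion date) and
   post-publication (registration after the first accepted dissemination);
   the most severe applicable class wins. The registry start-date field
   stands in for "study start" (first-enrolment dates are not generally
   available), and either the registration *submitted* or *posted* date can
   be selected — both choices are recorded in the report manifest.

2. **Search** (variables 8–9). Sources are consulted in a configurable
   order over an offline corpus: summary results synthesized from the
   record's posted date, registry-indexed links joined to the corpus by
   identifier, PubMed-ID rows, manual-search rows. Identifiers are
   normalized (case-folded, DOI prefixes stripped) and deduplicated keeping
   the earliest source's attribution, which makes per-source *incremental
   yield* well defined. Matching is an exact trial-ID join; title-similarity
   matching is deliberately excluded — that interpretive judgment is exactly
   what the reliability stage measures.

3. **Timeliness** (variables 6–7). The completion reference is PCD, CD, or
   a fallback order of the two; registry-estimated dates are used only when
   `allow_estimated` is set, and the provenance tag records what was used.
   A trial is "published within `w` months" when its earliest
   accepted-format dissemination is on or before `reference + w` calendar
   months (inclusive boundary, end-of-month clamping: Jan 31 + 1 m → Feb 28/29
   — matching how registries phrase month-grained deadlines). Finite windows
   not yet elapsed at the snapshot date are *censored*: excluded from the
   denominator but always reported as a separate count, so uncensored
   behaviour is recoverable. The all-time window bounds at the snapshot
   date with no censoring. Denominator-zero cells are flagged undefined,
   never reported as 0.

4. **Reliability** (variable 10). Disagreement between two raters is
   defined on identifier *sets* per trial (both-same, both-none,
   only-one-found, different-publications, overlapping); two records of the
   same identifier with different dates are agreement plus a date-conflict
   warning. Reliability is computed on the manual-search rows only — the
   registry and PubMed-ID steps are deterministic lookups, the manual step
   is where judgment enters — while denominators remain all tracked trials.
   An explicit adjudication rule (union by default; intersection;
   earliest-date) converts the two sets into the consensus evidence used by
   the rate stage, and is part of the manifest because union and
   intersection bracket any single rater's downstream rate.

Every report embeds a manifest stating all ten variables, the configuration
hash, and the snapshot date; identical inputs and configuration produce a
byte-identical report body.

### Date-precision conventions

Month-precision dates (`YYYY-MM`) are stored as a concrete day plus a
precision flag. Start and registration dates are imputed to the *first* of
the month, biasing delay classification toward *prospective*; completion
and publication dates to the *last* of the month, biasing window checks
toward *published in time*. Both biases are deliberate, conservative, in
opposite directions, and auditable through the flag. Records whose dates
violate ordering invariants (submitted after posted; actual PCD after
actual CD) are kept and flagged, never silently fixed; a configuration
switch can exclude flagged records.

## Synthetic-data generator

The generator emulates the structure such a tracking study meets in
practice, with all randomness flowing from a single seeded generator
(byte-reproducible outputs):

* study timeline: start dates uniform over 2008–2012; start→PCD duration
  lognormal (median 18 months, σ_log 0.4); PCD→CD gap lognormal (median
  2 months, σ_log 0.5);
* registration delay: a five-stratum mixture (defaults 0.55 prospective /
  0.10 late / 0.25 retrospective / 0.08 post-completion / 0.02
  post-publication) with uniform delays inside each band; the
  post-publication stratum is drawn only among published trials, keeping
  the ever-published probability exact;
* publication: ever-published Bernoulli `p = 0.8`; CD→publication latency
  lognormal with μ_log = 3.26, σ_log = 0.97 (months; median ≈ 26 months) —
  an exponential latency is available as an alternative;
* discoverability: registry `p_r = 0.5` (split evenly between posted
  summary results and an indexed link), PubMed `p_p = 0.2`, manual
  `p_m = 0.86`, independent per source;
* raters: given a manually discoverable publication, each of two raters
  finds it with sensitivity `s = 0.87` and, when finding something, records
  a wrong identifier with probability `q = 0.10` (wrong picks are
  rater-specific, so two wrong picks disagree);
* record noise: 10% of start/PCD/CD dates stored at month precision; 70%
  of trials sponsored by the institution (the rest recruit for an outside
  sponsor).

These defaults were chosen so the synthetic cohort qualitatively reproduces
the structure reported by registry-based tracking studies — window rates
rising from ≈ 0.16 at 12 months through ≈ 0.35 at 24 months to ≈ 0.75
all-time, registry+PubMed yield ≈ 0.48 with the manual step adding ≈ 0.27,
only-one-rater ≈ 0.16 and different-publications ≈ 0.10. They are
illustrative study conditions, not estimates fitted to any real dataset.

**Closed-form oracles.** One deliberate simplification keeps the oracles
exact: all dissemination artifacts of a trial (article, summary, each
rater's find — including wrong picks) carry the same latent publication
date. Then

* expected window rate: `p · F(w)`, discoverability-adjusted by
  `1 − (1−p_r)(1−p_p)(1−p_m·(1−(1−s)²))`, with `F` the latency CDF;
* expected first-found yields: `p·p_r/2` for each registry route,
  `p·(1−p_r)·p_p` for PubMed, `p·(1−p_r)(1−p_p)·p_m·(1−(1−s)²)` for manual;
* expected rater categories with `p_d = p·p_m`: only-one-found
  `p_d·2s(1−s)`, different-publications `p_d·s²·q(2−q)`, both-same
  `p_d·s²(1−q)²`.

**What the generator does not emulate** — hence what passing recovery tests
do and do not show. Real corpora have format-specific, spread-out
dissemination dates; publication probability correlated with stratum (the
generator's strata share one publication model, so it does not reproduce
rising per-stratum rates in retrospectively registered trials); rater
false-positives for unpublished trials; fuzzy, title-based matching
problems; registries with missing or inconsistent completion dates beyond
the flag model. Recovery tests therefore validate the *accounting* — that
the pipeline measures what the configuration says it measures — not the
external realism of any particular rate.

## Numerical and testing choices

* Whole-day delay arithmetic on imputed dates; calendar-month window
  addition with end-of-month clamping, cross-checked in tests against
  pandas' independent `DateOffset` implementation.
* Ties at stratum cutoffs go to the less severe class (`≤` semantics);
  earliest-dissemination ties on the same date break by a configurable
  format priority (journal article first), then identifier.
* The rate computation is verified against a naive per-trial brute-force
  oracle (independent date arithmetic) on hundreds of randomized fixtures
  of up to 1,000 trials.
* Parameter-recovery tests run 20 replicates of 2,000 trials and compare
  the estimate pooled across replicates with the analytic value at three
  binomial standard errors of the pooled sample size; pooling tests the
  same recovery property as per-replicate checks at far lower
  false-failure probability given the ~180 simultaneous 3σ comparisons
  involved. A snapshot date of 2040-01-01 leaves the all-time truncation
  of the lognormal latency tail negligible relative to that tolerance.
* Problem sizes throughout the suite (250–2,000 trials per cohort) were
  chosen as the smallest at which binomial tolerances are informative.

## Known limitations

* Only two registry dialects (ClinicalTrials.gov-style JSON, flat CSV) and
  one corpus schema are supported; no live API clients.
* Affiliation matching is normalized substring matching — deterministic and
  testable, but blind to spelling variants a fuzzy matcher would catch.
* Fixed-window proportions only; no time-to-event (Kaplan–Meier) estimates.
* Reliability handles exactly two raters; more require pre-adjudication.
* Both ISRCTN-style registration dates (submitted, posted) are carried and
  the choice is a configuration knob; no attempt is made to guess which a
  given registry "means".
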