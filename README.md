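# trialtrack

Tracking whether — and how timely — registered clinical studies publish
their results.

Meta-research groups, registries and transparency dashboards repeatedly ask
the same question of an academic institution or company: *of the trials you
ran, how many published results, and how fast?* The answer depends heavily
on ten methodological choices made along the way: who counts as responsible
for a trial (legal sponsor/PI vs any recruiting site), which study types and
statuses are followed up, where the sample is drawn from, how retrospective
registration is handled, which completion date anchors the clock, what time
window counts as "timely", which dissemination formats count, where
publications are searched, and how disagreements between raters are
resolved. Two studies that differ in a single one of these knobs can report
very different "publication rates" for the same institution.

`trialtrack` makes every one of those ten tracking variables an explicit,
serializable configuration field, runs the full pipeline deterministically,
and embeds the complete configuration (plus its hash) in every report — so
a benchmark is always interpretable and reproducible.

## The quantities computed

For a tracked sample of trials, the central estimate is a fixed-window
publication proportion

```
rate(w) = #{ trials : t_pub ≤ t_ref + w } / #{ evaluable trials }
```

where `t_ref` is the completion reference — the primary completion date
(PCD, last participant examined for the primary outcome) or the later
completion date (CD, last participant's last visit) — `t_pub` is the
earliest accepted dissemination (journal article, registry summary result,
CSR, …) found by an ordered multi-source search, and `w` is a window in
calendar months (or all-time). Trials whose window has not elapsed at the
snapshot date are censored and reported separately; undefined rates
(denominator 0) are flagged, never silently zero.

Around that sit:

* **registration-timing strata** — prospective (registration ≤ 21 days
  after start, the FDAAA allowance), late (22–60 days), retrospective
  (> 60 days), post-completion, and post-publication (registered after the
  first results publication, which makes the stratum's publication rate
  100% by definition);
* **incremental search yield** — how many trials are first found by each
  successive source (registry summary results, registry-indexed links,
  PubMed lookup of the registry number, manual searching);
* **inter-rater reliability** — per-trial comparison of two independent
  raters' identifier sets (same / one-found-only / different publications /
  overlapping / none), with explicit union / intersection / earliest-date
  adjudication.

A seeded synthetic-registry generator with known ground truth and
closed-form expected rates (`p_published · F(w)`, discoverability-adjusted)
makes every stage testable by parameter recovery without any external data.

## Worked example

```python
import datetime as dt
import trialtrack as tt

cfg = tt.SyntheticConfig(n_trials=300, seed=1)          # synthetic cohort
records, corpus, truth = tt.generate_registry(cfg)

model = tt.TrialTracker(records, corpus, cfg.institution)
results = model.fit(snapshot_date=dt.date(2040, 1, 1))
print(results.summary())
```

```
                  Clinical Study Publication Tracking
========================================================================
Institution: University Medical Center Alpha
Snapshot: 2040-01-01    Config hash: 22c8ecfe9e58
Sample flow: 300 records -> 300 tracked
------------------------------------------------------------------------
Publication rates
reference        windowstratum                num   den  cens     rate
cd_then_pcd         12m  all                   48   300     0    0.160
cd_then_pcd         24m  all                  107   300     0    0.357
cd_then_pcd    all-time  all                  221   300     0    0.737
cd_then_pcd    all-time  post_publication       2     2     0    1.000
...
------------------------------------------------------------------------
Search yield by source (first found)
  registry_summary          69 new   cumulative 0.230
  registry_indexed          44 new   cumulative 0.377
  pubmed_id_search          23 new   cumulative 0.453
  manual_search             85 new   cumulative 0.737
------------------------------------------------------------------------
Inter-rater reliability (manual search, raters ['rater_a', 'rater_b'])
  both_none                 0.337
  both_same                 0.457
  different_publications    0.080
  only_one_found            0.127
  date conflicts: 0
========================================================================
```

Reading this: 16% of the 300 tracked trials had results disseminated within
12 months of the completion date, 36% within 24 months, 74% ever; the
registry and PubMed steps together located publications for 45% of trials
and the manual step raised that to 74%; the two simulated raters found a
publication only-one-of-them for 13% of trials and different publications
for 8%. `results.rate_table`, `results.yield_table`, `results.reliability`
and `results.manifest` expose the same numbers as data;
`results.plot_rates()` draws the window profile; `model.fit_grid([...])`
runs a sensitivity grid over configuration variants.

The same pipeline is scriptable from the shell:

```sh
trialtrack simulate --seed 1 --n-trials 300 --out sim/
trialtrack track --registry sim/registry.csv --corpus sim/corpus.csv \
    --institution "University Medical Center Alpha" \
    --snapshot 2040-01-01 --out report/
```

Real registry extracts are read with
`TrialTracker.from_files(..., dialect="ctgov_json")` (one JSON object per
study, ClinicalTrials.gov field names) or `dialect="flat_csv"`; dates may be
day- (`YYYY-MM-DD`) or month-precision (`YYYY-MM`), with month-precision
start/registration dates imputed to the first of the month and
completion/publication dates to the last (both benefit-of-the-doubt
directions, flagged for audit).

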