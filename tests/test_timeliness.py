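"""Completion-date resolution and windowed publication rates.

The rate computation is checked against an independently written
brute-force oracle that resolves references and adds calendar months with
pandas rather than the package's own date arithmetic.
"""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from tt_testutil import d, make_record

from trialtrack import (
    CompletionPolicy,
    ConfigurationError,
    publication_rate,
    rate_table,
    resolve_completion_date,
)


class TestResolveCompletionDate:
    def test_fallback_to_pcd_when_cd_absent(self):
        record = make_record(cd=None, pcd="2012-05-10")
        policy = CompletionPolicy(reference="cd_then_pcd")
        assert resolve_completion_date(record, policy) == (d("2012-05-10"), "pcd")

    def test_estimated_pcd_rejected_unless_allowed(self):
        record = make_record(cd=None, pcd="2012-05-10", pcd_actuality="estimated")
        strict = CompletionPolicy(reference="pcd", allow_estimated=False)
        lax = CompletionPolicy(reference="pcd", allow_estimated=True)
        assert resolve_completion_date(record, strict) is None
        assert resolve_completion_date(record, lax) == (d("2012-05-10"), "pcd+estimated")

    def test_cd_policy_picks_cd_when_both_present(self):
        record = make_record(pcd="2012-05-10", cd="2012-08-10")
        assert resolve_completion_date(record, CompletionPolicy(reference="cd")) == (
            d("2012-08-10"),
            "cd",
        )


def _oracle_rate(sample, policy, window_months, snapshot):
    """Naive per-trial loop with pandas month arithmetic (independent path)."""
    num = den = cens = 0
    for record, pub in sample:
        fields = {
            "pcd": record.primary_completion_date,
            "cd": record.completion_date,
        }
        order = {"pcd": ["pcd"], "cd": ["cd"], "cd_then_pcd": ["cd", "pcd"],
                 "pcd_then_cd": ["pcd", "cd"]}[policy.reference.value]
        ref = None
        for name in order:
            c = fields[name]
            if c is not None and (policy.allow_estimated or c.actuality.value == "actual"):
                ref = c.date
                break
        if ref is None:
            continue
        if window_months is None:
            bound = snapshot
        else:
            bound = (pd.Timestamp(ref) + pd.DateOffset(months=window_months)).date()
            if bound > snapshot:
                cens += 1
                continue
        den += 1
        if pub is not None and pub <= bound:
            num += 1
    return num, den, cens


def _random_sample(rng, n):
    sample = []
    for i in range(n):
        cd_date = dt.date(2009, 1, 1) + dt.timedelta(days=int(rng.integers(0, 2500)))
        pcd_date = cd_date - dt.timedelta(days=int(rng.integers(0, 300)))
        has_cd = rng.random() < 0.9
        has_pcd = rng.random() < 0.9
        record = make_record(
            trial_id=f"NCT{i:08d}",
            start=(pcd_date - dt.timedelta(days=400)).isoformat(),
            submitted=(pcd_date - dt.timedelta(days=390)).isoformat(),
            posted=(pcd_date - dt.timedelta(days=380)).isoformat(),
            pcd=pcd_date.isoformat() if has_pcd else None,
            pcd_actuality="estimated" if rng.random() < 0.2 else "actual",
            cd=cd_date.isoformat() if has_cd else None,
            cd_actuality="estimated" if rng.random() < 0.2 else "actual",
        )
        pub = None
        if rng.random() < 0.7:
            pub = cd_date + dt.timedelta(days=int(rng.integers(-30, 2000)))
        sample.append((record, pub))
    return sample


def test_rate_equals_brute_force_on_random_fixtures():
    """200 random fixtures of up to 1,000 trials match the naive per-trial count."""
    rng = np.random.default_rng(42)
    policies = [CompletionPolicy(reference=r, allow_estimated=bool(a))
                for r in ["pcd", "cd", "cd_then_pcd", "pcd_then_cd"] for a in (0, 1)]
    for k in range(200):
        n = int(rng.integers(1, 60)) if k < 198 else 1000
        sample = _random_sample(rng, n)
        policy = policies[int(rng.integers(0, len(policies)))]
        window = [6, 12, 24, 36, None][int(rng.integers(0, 5))]
        snapshot = dt.date(2012, 1, 1) + dt.timedelta(days=int(rng.integers(0, 4000)))
        result = publication_rate(sample, policy, window, snapshot)
        num, den, cens = _oracle_rate(sample, policy, window, snapshot)
        assert (result.numerator, result.denominator, result.censored) == (num, den, cens)
        assert result.missing_reference == len(sample) - den - cens


def test_rate_monotone_in_window():
    rng = np.random.default_rng(7)
    sample = _random_sample(rng, 300)
    policy = CompletionPolicy(reference="cd_then_pcd")
    snapshot = dt.date(2040, 1, 1)
    rates = [publication_rate(sample, policy, w, snapshot).rate for w in [6, 12, 24, 48, None]]
    assert all(a <= b for a, b in zip(rates, rates[1:]))


def test_cd_reference_rate_at_least_pcd_rate_when_cd_later():
    """With CD ≥ PCD per record, the CD-anchored window can only be more generous."""
    rng = np.random.default_rng(8)
    sample = [(r, p) for r, p in _random_sample(rng, 500)
              if r.completion_date is not None and r.primary_completion_date is not None]
    snapshot = dt.date(2040, 1, 1)
    for window in (12, 24):
        cd_rate = publication_rate(sample, CompletionPolicy(reference="cd", allow_estimated=True),
                                   window, snapshot).rate
        pcd_rate = publication_rate(sample, CompletionPolicy(reference="pcd", allow_estimated=True),
                                    window, snapshot).rate
        assert cd_rate >= pcd_rate


def test_censoring_excludes_unelapsed_windows():
    record = make_record(cd="2015-06-01")
    snapshot = d("2016-01-01")
    result = publication_rate([(record, d("2015-08-01"))],
                              CompletionPolicy(reference="cd"), 12, snapshot)
    assert result.censored == 1
    assert result.denominator == 0
    assert result.undefined and result.rate is None  # flagged, not NaN


def test_all_time_window_never_censors():
    record = make_record(cd="2015-06-01")
    result = publication_rate([(record, d("2015-08-01"))],
                              CompletionPolicy(reference="cd"), None, d("2016-01-01"))
    assert result.censored == 0
    assert result.rate == 1.0


def test_nonpositive_window_rejected():
    with pytest.raises(ConfigurationError):
        publication_rate([], CompletionPolicy(), 0, d("2016-01-01"))


class TestRateTable:
    def test_shape_is_full_cross(self):
        sample = [(make_record(), None, None)]
        cells = rate_table(sample, [CompletionPolicy()], [12, 24, None], d("2040-01-01"))
        assert len(cells) == 3  # no strata present -> "all" only

    def test_post_publication_stratum_rate_is_one(self):
        sample = []
        for i in range(5):
            record = make_record(trial_id=f"NCT{i:08d}", cd="2011-08-01",
                                 submitted="2013-05-01", posted="2013-05-03")
            sample.append((record, d("2013-01-01"), "post_publication"))
        cells = rate_table(sample, [CompletionPolicy()], [None], d("2040-01-01"))
        cell = next(c for c in cells if c.stratum == "post_publication")
        assert cell.rate == 1.0
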