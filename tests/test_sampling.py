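"""Sampling filters, responsibility classes, and registration-timing strata."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tt_testutil import d, make_record

from trialtrack import (
    ExclusionReason,
    RegistrationStratum,
    ResponsibilityClass,
    TrackingConfig,
    apply_sampling,
    classify_registration_timing,
    classify_responsibility,
)


class TestResponsibility:
    def test_sponsor_match_is_legal(self):
        record = make_record(sponsor="Univ A", lead=())
        assert classify_responsibility(record, ["Univ A"]) is ResponsibilityClass.legal

    def test_pi_affiliation_match_is_legal(self):
        record = make_record(sponsor="Pharma X", lead=("Univ A Dept of Cardiology",))
        assert classify_responsibility(record, ["univ a"]) is ResponsibilityClass.legal

    def test_facility_only_is_cooperating(self):
        record = make_record(sponsor="Pharma X", lead=("Pharma X",),
                             facilities=("Univ A Hospital",))
        assert classify_responsibility(record, ["Univ A"]) is ResponsibilityClass.cooperating

    def test_absent_everywhere_is_none(self):
        record = make_record(sponsor="Pharma X", lead=("Pharma X",))
        assert classify_responsibility(record, ["Univ A"]) is ResponsibilityClass.none


class TestRegistrationTiming:
    config = TrackingConfig()

    @pytest.mark.parametrize(
        "delay_days, expected",
        [
            (0, RegistrationStratum.prospective),
            (21, RegistrationStratum.prospective),  # tie goes to the less severe class
            (22, RegistrationStratum.late),
            (40, RegistrationStratum.late),
            (60, RegistrationStratum.late),
            (61, RegistrationStratum.retrospective),
            (90, RegistrationStratum.retrospective),
        ],
    )
    def test_delay_bands(self, delay_days, expected):
        start = d("2010-01-10")
        record = make_record(
            start="2010-01-10",
            submitted=(start + dt.timedelta(days=delay_days)).isoformat(),
            posted=(start + dt.timedelta(days=delay_days + 5)).isoformat(),
            cd="2012-08-01",
            pcd="2012-06-01",
        )
        assert classify_registration_timing(record, None, self.config) is expected

    def test_registration_after_completion_is_post_completion(self):
        record = make_record(submitted="2012-01-01", posted="2012-01-05",
                             cd="2011-08-01")
        assert (
            classify_registration_timing(record, None, self.config)
            is RegistrationStratum.post_completion
        )

    def test_registration_after_first_publication_wins_over_everything(self):
        record = make_record(submitted="2012-01-01", posted="2012-01-05", cd="2011-08-01")
        assert (
            classify_registration_timing(record, d("2011-12-22"), self.config)
            is RegistrationStratum.post_publication
        )

    def test_posted_date_field_shifts_classification(self):
        config = TrackingConfig(registration_date_field="posted")
        record = make_record(start="2010-01-10", submitted="2010-01-25", posted="2010-03-20")
        assert classify_registration_timing(record, None, self.config) is RegistrationStratum.prospective
        assert classify_registration_timing(record, None, config) is RegistrationStratum.retrospective


def _mixed_records():
    records = []
    for i in range(10):
        study_type = "observational" if i < 3 else "interventional"
        records.append(
            make_record(trial_id=f"NCT{i:08d}", study_type=study_type)
        )
    return records


class TestApplySampling:
    def test_study_type_filter_counts(self):
        config = TrackingConfig(study_types={"interventional"})
        outcome = apply_sampling(_mixed_records(), ["Univ A"], config)
        assert len(outcome.included) == 7
        assert len(outcome.excluded) == 3
        assert all(r is ExclusionReason.study_type for _, r in outcome.excluded)

    def test_withdrawn_excluded_when_only_completed_tracked(self):
        config = TrackingConfig(statuses={"completed"})
        record = make_record(status="withdrawn")
        outcome = apply_sampling([record], ["Univ A"], config)
        assert outcome.included == []
        assert outcome.excluded[0][1] is ExclusionReason.status

    def test_all_recruiting_scope_keeps_cooperating_sites(self):
        record = make_record(sponsor="Pharma X", lead=("Pharma X",),
                             facilities=("Univ A Hospital",))
        wide = apply_sampling([record], ["Univ A"], TrackingConfig(responsibility_scope="all_recruiting"))
        narrow = apply_sampling([record], ["Univ A"], TrackingConfig(responsibility_scope="legal_only"))
        assert len(wide.included) == 1
        assert wide.included[0].responsibility is ResponsibilityClass.cooperating
        assert narrow.included == []
        assert narrow.excluded[0][1] is ExclusionReason.responsibility

    def test_prospective_only_equals_stratify_restricted(self, small_cohort):
        _, records, _, _ = small_cohort
        institution = [records[0].sponsor_name]
        strat = apply_sampling(records, ["University Medical Center Alpha"],
                               TrackingConfig(registration_policy="stratify"))
        prosp = apply_sampling(records, ["University Medical Center Alpha"],
                               TrackingConfig(registration_policy="prospective_only"))
        expected = {
            it.record.trial_id
            for it in strat.included
            if it.stratum is RegistrationStratum.prospective
        }
        assert {it.record.trial_id for it in prosp.included} == expected

    @settings(max_examples=40, derandomize=True)
    @given(
        st.sets(st.sampled_from(["completed", "terminated", "withdrawn", "suspended"]), min_size=1),
        st.sets(st.sampled_from(["interventional", "observational"]), min_size=1),
        st.sampled_from(["legal_only", "all_recruiting"]),
        st.sampled_from(["include_all", "prospective_only", "stratify"]),
    )
    def test_conservation_for_every_config(self, statuses, types, scope, policy):
        """Included + excluded partitions the input, with one reason each."""
        records = [
            make_record(trial_id=f"NCT{i:08d}",
                        sponsor="Univ A" if i % 3 else "Pharma X",
                        lead=("Univ A",) if i % 3 else ("Pharma X",),
                        facilities=("Univ A Clinic",) if i % 2 else (),
                        status=["completed", "terminated", "withdrawn"][i % 3],
                        study_type=["interventional", "observational"][i % 2])
            for i in range(12)
        ]
        config = TrackingConfig(statuses=statuses, study_types=types,
                                responsibility_scope=scope, registration_policy=policy)
        outcome = apply_sampling(records, ["Univ A"], config)
        assert len(outcome.included) + len(outcome.excluded) == len(records)
        included_ids = {it.record.trial_id for it in outcome.included}
        excluded_ids = {r.trial_id for r, _ in outcome.excluded}
        assert not included_ids & excluded_ids

    def test_widening_filters_never_shrinks_sample(self, small_cohort):
        _, records, _, _ = small_cohort
        pats = ["University Medical Center Alpha"]
        narrow = TrackingConfig(statuses={"completed"}, responsibility_scope="legal_only")
        wide = TrackingConfig(statuses={"completed", "terminated", "withdrawn", "suspended"},
                              responsibility_scope="all_recruiting")
        n_narrow = len(apply_sampling(records, pats, narrow).included)
        n_wide = len(apply_sampling(records, pats, wide).included)
        assert n_wide >= n_narrow
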