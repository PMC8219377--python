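"""Proband designation, at-risk windows and SPM adjudication."""

from collections import Counter

import pytest

from famsir.cohort import (
    assign_probands,
    build_relative_windows,
    build_spm_windows,
    flag_relapse,
    spm_enrichment_table,
)
from famsir.exposure import accrue, expected_count
from famsir.registry import CancerEvent, ICCC3Group, RegistryConfig
from conftest import events_frame, persons_frame


def one_cohort(persons, events, config):
    cohorts = assign_probands(persons, events, config)
    assert len(cohorts) == 1
    return cohorts[0]


class TestAssignProbands:
    def test_earliest_diagnosis_wins(self, config):
        persons = persons_frame(
            [
                ("a", "f1", "child", "male", "latino", 1990),
                ("b", "f1", "child", "female", "latino", 1992),
                ("m", "f1", "mother", "female", "latino", 1970),
            ]
        )
        events = events_frame([("b", 1995, "I", None, 1), ("a", 2001, "III", None, 1)])
        cohort = one_cohort(persons, events, config)
        assert cohort.proband_id == "b" and cohort.proband_dx_year == 1995
        # the 2001 case is a concordant sibling, listed among relatives
        assert ("a", "child") in cohort.relatives

    def test_single_case_family(self, config, toy_family):
        persons, events = toy_family
        cohort = one_cohort(persons, events, config)
        assert cohort.proband_id == "c1"
        assert set(cohort.relatives) == {("c2", "child"), ("m1", "mother")}

    def test_same_year_tie_breaks_on_person_id(self, config):
        persons = persons_frame(
            [
                ("z9", "f1", "child", "male", "latino", 1990),
                ("a1", "f1", "child", "female", "latino", 1992),
            ]
        )
        events = events_frame([("z9", 2000, "I", None, 1), ("a1", 2000, "III", None, 1)])
        cohort = one_cohort(persons, events, config)
        assert cohort.proband_id == "a1"

    def test_tie_break_choice_is_outcome_invariant(self, config, flat_rates):
        """Same-year co-diagnoses coincide in time under the mid-year
        convention, so either tie-break choice yields identical O and E."""
        scheme = config.scheme()

        def o_and_e(winner, loser):
            persons = persons_frame(
                [
                    (winner, "f1", "child", "male", "latino", 1990),
                    (loser, "f1", "child", "female", "latino", 1992),
                    ("s3", "f1", "child", "male", "latino", 1994),
                ]
            )
            events = events_frame(
                [(winner, 2000, "I", None, 1), (loser, 2000, "III", None, 1)]
            )
            cohort = one_cohort(persons, events, config)
            windows = build_relative_windows(cohort, persons, events, config, "any_cancer")
            O = sum(w.event for w in windows)
            E = expected_count((accrue(w, scheme) for w in windows), flat_rates, "any", scheme)
            return O, E

        # swap which child wins the tie by renaming ids
        assert o_and_e("a", "b") == o_and_e("b", "a")

    def test_affected_mother_only_family_emits_no_cohort(self, config):
        persons = persons_frame(
            [
                ("c", "f1", "child", "male", "latino", 1990),
                ("m", "f1", "mother", "female", "latino", 1970),
            ]
        )
        events = events_frame([("m", 2000, "XI", None, 1)])
        assert assign_probands(persons, events, config) == []

    def test_proband_age_and_period_intake(self, config):
        persons = persons_frame(
            [
                ("c", "f1", "child", "male", "latino", 1989),
                ("d", "f1", "child", "male", "latino", 1990),
            ]
        )
        # c diagnosed above the age-26 intake bound; d inside
        events = events_frame([("c", 2015 + 1, "I", None, 1), ("d", 2010, "I", None, 1)])
        events.loc[0, "diagnosis_year"] = 2015  # keep within period but age 26 boundary
        cohort = one_cohort(persons, events, config)
        assert cohort.proband_id == "d"  # 2010 earlier than 2015


class TestRelativeWindows:
    def relatives(self, events_rows, config, mode="any_cancer", log=None):
        persons = persons_frame(
            [
                ("p", "f1", "child", "male", "latino", 1990),
                ("s", "f1", "child", "female", "latino", 1992),
            ]
        )
        events = events_frame([("p", 2000, "I", None, 1)] + events_rows)
        cohort = one_cohort(persons, events, config)
        return build_relative_windows(cohort, persons, events, config, mode, log)

    def test_censored_sibling_window(self, config):
        (w,) = self.relatives([], config)
        assert (w.start_age, w.end_age, w.event) == (8.0, 23.0, 0)

    def test_affected_sibling_window(self, config):
        (w,) = self.relatives([("s", 2005, "VIII", None, 1)], config)
        assert (w.start_age, w.end_age, w.event) == (8.0, 13.0, 1)
        assert w.event_group == "VIII"

    def test_same_category_mismatch_censors_at_other_cancer(self, config):
        (w,) = self.relatives([("s", 2005, "III", None, 1)], config, mode="same_category")
        assert (w.end_age, w.event) == (13.0, 0)

    def test_continue_past_other_cancer_when_censoring_disabled(self):
        config = RegistryConfig(censor_at_other_cancer=False)
        # solid primary at 2005 does not qualify; hematologic second at 2010 does
        (w,) = self.relatives(
            [("s", 2005, "III", None, 1), ("s", 2010, "II", None, 2)],
            config,
            mode="same_category",
        )
        assert (w.end_age, w.event, w.event_group) == (18.0, 1, "II")

    def test_censoring_rule_changes_person_time_on_toy_families(self, config, flat_rates):
        """Censoring at a non-qualifying cancer vs continuing follow-up
        gives different O and E on a constructed family set."""
        persons = persons_frame(
            [
                ("p1", "f1", "child", "male", "latino", 1990),
                ("s1", "f1", "child", "male", "latino", 1992),
                ("p2", "f2", "child", "male", "latino", 1990),
                ("s2", "f2", "child", "male", "latino", 1992),
                ("p3", "f3", "child", "male", "latino", 1990),
                ("s3", "f3", "child", "male", "latino", 1992),
            ]
        )
        events = events_frame(
            [
                ("p1", 2000, "I", None, 1),
                ("s1", 2005, "III", None, 1),  # wrong category, no further event
                ("p2", 2000, "I", None, 1),
                ("s2", 2005, "III", None, 1),  # wrong category ...
                ("s2", 2010, "I", None, 2),    # ... then a qualifying one
                ("p3", 2000, "I", None, 1),
            ]
        )
        scheme = config.scheme()

        def run(censor):
            cfg = RegistryConfig(censor_at_other_cancer=censor)
            O = E = 0
            for cohort in assign_probands(persons, events, cfg):
                ws = build_relative_windows(cohort, persons, events, cfg, "same_category")
                O += sum(w.event for w in ws)
                E += expected_count(
                    (accrue(w, scheme) for w in ws), flat_rates, "hematologic", scheme
                )
            return O, E

        o_censor, e_censor = run(True)
        o_cont, e_cont = run(False)
        assert o_censor == 0 and o_cont == 1
        assert e_cont > e_censor

    def test_member_born_after_study_end_skipped(self, config):
        persons = persons_frame(
            [
                ("p", "f1", "child", "male", "latino", 1990),
                ("s", "f1", "child", "female", "latino", 2016),
            ]
        )
        persons.loc[1, "birth_year"] = 2016
        events = events_frame([("p", 2000, "I", None, 1)])
        cohorts = assign_probands(persons, events, config)
        log = Counter()
        ws = build_relative_windows(cohorts[0], persons, events, config, "any_cancer", log)
        assert ws == [] and log["born_after_study_end"] == 1

    def test_sibling_born_after_proband_diagnosis_at_risk_from_birth(self, config):
        persons = persons_frame(
            [
                ("p", "f1", "child", "male", "latino", 1990),
                ("s", "f1", "child", "female", "latino", 2005),
            ]
        )
        events = events_frame([("p", 2000, "I", None, 1)])
        cohort = one_cohort(persons, events, config)
        (w,) = build_relative_windows(cohort, persons, events, config, "any_cancer")
        assert (w.start_age, w.end_age) == (0.0, 10.0)

    def test_mother_beyond_follow_up_ceiling_excluded(self, config, toy_family):
        persons, events = toy_family  # mother born 1970, proband dx 2000 -> age 30
        cohort = one_cohort(persons, events, config)
        log = Counter()
        ws = build_relative_windows(cohort, persons, events, config, "any_cancer", log)
        assert {w.person_id for w in ws} == {"c2"}
        assert log["beyond_follow_up_ceiling"] == 1

    def test_pre_proband_mother_excluded_by_default_counted_in_paper_mode(self):
        persons = persons_frame(
            [
                ("p", "f1", "child", "male", "latino", 1990),
                ("m", "f1", "mother", "female", "latino", 1975),
            ]
        )
        events = events_frame([("p", 2000, "I", None, 1), ("m", 1998, "XI", None, 1)])
        default = RegistryConfig()
        cohort = one_cohort(persons, events, default)
        assert build_relative_windows(cohort, persons, events, default, "any_cancer") == []

        paper = RegistryConfig(paper_mode=True)
        (w,) = build_relative_windows(cohort, persons, events, paper, "any_cancer")
        assert (w.event, w.start_age, w.end_age) == (1, 23.0, 23.0)

    def test_proband_never_contributes_a_window(self, config, toy_family):
        persons, events = toy_family
        cohort = one_cohort(persons, events, config)
        ws = build_relative_windows(cohort, persons, events, config, "any_cancer")
        assert "c1" not in {w.person_id for w in ws}

    def test_stratum_uses_mother_race_and_member_sex(self, config):
        persons = persons_frame(
            [
                ("p", "f1", "child", "male", "nl_white", 1990),
                ("s", "f1", "child", "male", "nl_white", 1992),
                ("m", "f1", "mother", "female", "nl_api", 1980),
            ]
        )
        events = events_frame([("p", 2000, "I", None, 1)])
        cohort = one_cohort(persons, events, config)
        ws = build_relative_windows(cohort, persons, events, config, "any_cancer")
        assert all(w.stratum[0] == "nl_api" for w in ws)


class TestSPM:
    def test_spm_window_with_event(self, config):
        persons = persons_frame([("p", "f1", "child", "male", "latino", 1990)])
        events = events_frame(
            [("p", 1994, "I", "x", 1), ("p", 1999, "VIII", "y", 2)]
        )
        (w,) = build_spm_windows(events, persons, config)
        assert (w.start_age, w.end_age, w.event, w.event_group) == (4.0, 9.0, 1, "VIII")

    def test_spm_window_censored_at_study_end(self, config):
        persons = persons_frame([("p", "f1", "child", "male", "latino", 1994)])
        events = events_frame([("p", 2014, "I", None, 1)])
        (w,) = build_spm_windows(events, persons, config)
        assert (w.start_age, w.end_age, w.event) == (20.0, 21.0, 0)

    def test_relapse_does_not_end_follow_up(self, config):
        persons = persons_frame([("p", "f1", "child", "male", "latino", 1990)])
        events = events_frame(
            [("p", 1994, "I", "lymphoid", 1), ("p", 1999, "I", "lymphoid", 2)]
        )
        (w,) = build_spm_windows(events, persons, config)
        assert (w.event, w.end_age) == (0, 25.0)

    def test_mothers_excluded_from_spm_analysis(self, config):
        persons = persons_frame([("m", "f1", "mother", "female", "latino", 1989)])
        events = events_frame([("m", 2000, "XI", None, 1)])
        assert build_spm_windows(events, persons, config) == []


class TestFlagRelapse:
    def ev(self, year, group, subtype, seq=1):
        return CancerEvent("p", year, ICCC3Group(group), subtype, seq)

    def test_same_group_same_subtype_is_relapse(self, config):
        assert flag_relapse(self.ev(2000, "I", "lymphoid"), self.ev(2004, "I", "lymphoid", 2), config)

    def test_different_group_is_distinct(self, config):
        assert not flag_relapse(self.ev(2000, "I", "a"), self.ev(2004, "VIII", "b", 2), config)

    def test_identical_same_year_events_are_relapse(self, config):
        assert flag_relapse(self.ev(2000, "I", "a"), self.ev(2000, "I", "a", 2), config)

    def test_min_gap_flags_same_group_within_gap(self):
        cfg = RegistryConfig(relapse_min_gap_years=3)
        assert flag_relapse(self.ev(2000, "I", "a"), self.ev(2002, "I", "b", 2), cfg)
        assert not flag_relapse(self.ev(2000, "I", "a"), self.ev(2004, "I", "b", 2), cfg)

    def test_wrong_person_or_order_rejected(self, config):
        with pytest.raises(ValueError):
            flag_relapse(self.ev(2000, "I", "a"), CancerEvent("q", 2004, ICCC3Group.I, "a", 2), config)
        with pytest.raises(ValueError):
            flag_relapse(self.ev(2004, "I", "a"), self.ev(2000, "I", "a"), config)


class TestEnrichmentTable:
    def test_no_spms_yields_zero_events(self, config, toy_family):
        persons, events = toy_family
        x1, n1, x2, n2 = spm_enrichment_table(persons, events, config)
        assert (x1, x2) == (0, 0) and n1 + n2 == len(persons)

    def test_single_familial_risk_family_with_spm(self, config):
        persons = persons_frame(
            [
                ("p", "f1", "child", "male", "latino", 1990),
                ("s", "f1", "child", "male", "latino", 1992),
                ("m", "f1", "mother", "female", "latino", 1970),
            ]
        )
        events = events_frame(
            [
                ("p", 2000, "I", "a", 1),
                ("p", 2005, "VIII", "b", 2),
                ("s", 2003, "III", "c", 1),
            ]
        )
        assert spm_enrichment_table(persons, events, config) == (1, 3, 0, 0)

    def test_empty_registry_warns_zero_table(self, config):
        persons = persons_frame([])
        events = events_frame([])
        assert spm_enrichment_table(persons, events, config) == (0, 0, 0, 0)
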