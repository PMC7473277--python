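"""Event extraction, era dispatch, case resolution and source breakdowns."""
from __future__ import annotations

import pandas as pd
import pytest

import ecohort as ec
from ecohort.codelist import CodeListError, System, normalize_code


def _gp(rows):
    return pd.DataFrame(rows, columns=["person_id", "event_date", "code"]).assign(
        event_date=lambda d: pd.to_datetime(d.event_date))


def _hosp(rows):
    return pd.DataFrame(rows, columns=["person_id", "admission_date", "codes"]).assign(
        admission_date=lambda d: pd.to_datetime(d.admission_date))


def _mort(rows):
    return pd.DataFrame(rows, columns=["person_id", "death_date", "cause_codes"]).assign(
        death_date=lambda d: pd.to_datetime(d.death_date))


EMPTY_GP, EMPTY_HOSP, EMPTY_MORT = _gp([]), _hosp([]), _mort([])


class TestExtractConditionEvents:
    def test_multi_code_episode_yields_only_matches(self, tiny_codelist):
        hosp = _hosp([(1, "2005-03-01", "F001;I10")])
        ev = ec.extract_condition_events(EMPTY_GP, hosp, EMPTY_MORT, tiny_codelist)
        assert len(ev) == 1
        row = ev.iloc[0]
        assert (row.code, row.source, row.condition, row.category) == \
            ("F001", "HOSP", "dementia", "AD")
        assert row.event_date == pd.Timestamp("2005-03-01")

    def test_gp_event_prefix_match(self, tiny_codelist):
        gp = _gp([(1, "2006-07-01", "Eu021")])
        ev = ec.extract_condition_events(gp, EMPTY_HOSP, EMPTY_MORT, tiny_codelist)
        assert ev.source.tolist() == ["GP"]
        assert ev.category.tolist() == [""]

    def test_era_dispatch_for_mortality_codes(self, tiny_codelist):
        """A 1999 death is matched under ICD-9; the same token on a
        post-cutover death is treated as ICD-10 and does not match the
        ICD-9 entry."""
        mort = _mort([(1, "1999-06-01", "2904"), (2, "2003-06-01", "2904")])
        ev = ec.extract_condition_events(EMPTY_GP, EMPTY_HOSP, mort, tiny_codelist)
        assert ev.person_id.tolist() == [1]
        assert ev.system.tolist() == ["ICD9"]

    def test_non_cohort_persons_dropped(self, tiny_codelist):
        gp = _gp([(1, "2006-07-01", "Eu02"), (99, "2006-07-01", "Eu02")])
        ev = ec.extract_condition_events(gp, EMPTY_HOSP, EMPTY_MORT,
                                         tiny_codelist, cohort_ids={1})
        assert set(ev.person_id) == {1}

    def test_unparseable_tokens_skipped_with_log(self, tiny_codelist, caplog):
        gp = _gp([(1, "2006-07-01", "Eu02z00"),   # over-long Read token
                  (1, "2006-07-02", "Eu02")])
        with caplog.at_level("WARNING"):
            ev = ec.extract_condition_events(gp, EMPTY_HOSP, EMPTY_MORT, tiny_codelist)
        assert len(ev) == 1
        assert any("unparseable" in r.message for r in caplog.records)


class TestAscertainDementia:
    def _events(self, rows):
        return pd.DataFrame(rows, columns=["person_id", "event_date", "system",
                                           "code", "source", "condition",
                                           "category"]).assign(
            event_date=lambda d: pd.to_datetime(d.event_date))

    def test_diagnosis_is_first_code_of_any_kind(self):
        # earliest code is all-cause in hospital; subtype arrives later in GP
        ev = self._events([
            (1, "2005-03-01", "ICD10", "F03", "HOSP", "dementia", ""),
            (1, "2006-07-01", "READ2", "Eu00", "GP", "dementia", "AD")])
        asc = ec.ascertain_dementia(ev).iloc[0]
        assert asc.diagnosis_date == pd.Timestamp("2005-03-01")
        assert asc.first_source == "HOSP"
        assert asc.subtypes == "AD"
        assert asc.sources_ever == "GP|HOSP"

    def test_subtypes_are_non_exclusive_union(self):
        ev = self._events([
            (1, "2005-01-01", "ICD10", "F00", "HOSP", "dementia", "AD"),
            (1, "2009-01-01", "ICD10", "F01", "DEATH", "dementia", "VaD")])
        asc = ec.ascertain_dementia(ev).iloc[0]
        assert asc.subtypes == "AD|VaD"

    def test_mortality_only_case(self):
        ev = self._events([(1, "2010-02-03", "ICD10", "F03", "DEATH",
                            "dementia", "")])
        asc = ec.ascertain_dementia(ev).iloc[0]
        assert bool(asc.all_cause) and asc.first_source == "DEATH"
        assert asc.diagnosis_date == pd.Timestamp("2010-02-03")

    def test_same_date_tie_broken_by_priority(self):
        ev = self._events([
            (1, "2005-01-01", "ICD10", "F03", "HOSP", "dementia", ""),
            (1, "2005-01-01", "READ2", "Eu02", "GP", "dementia", "")])
        assert ec.ascertain_dementia(ev).iloc[0].first_source == "GP"
        flipped = ec.ascertain_dementia(ev, tie_break=("DEATH", "HOSP", "GP"))
        assert flipped.iloc[0].first_source == "HOSP"

    def test_subtype_implies_case_over_pipeline_output(self, built_clean):
        asc = built_clean.ascertainments
        has_subtype = asc.subtypes.str.len() > 0
        assert asc.loc[has_subtype, "all_cause"].all()
        assert asc.loc[asc.all_cause, "diagnosis_date"].notna().all()
        assert asc.loc[asc.all_cause, "first_source"].isin(["GP", "HOSP", "DEATH"]).all()


class TestBruteForceOracle:
    def test_diagnosis_dates_match_per_person_scan(self, sim_clean, dementia_list):
        """Independent oracle: for >= 1,000 synthetic persons, scan every raw
        record per person with per-entry matching and compare dates/subtypes."""
        n_oracle = 1500
        ids = set(sim_clean.demographics.person_id[:n_oracle])
        cutover = pd.Timestamp("2001-01-01")

        expected: dict[int, dict] = {}

        def note(pid, date, cats):
            rec = expected.setdefault(pid, {"date": date, "subtypes": set()})
            rec["date"] = min(rec["date"], date)
            rec["subtypes"] |= {c for c in cats if c}

        def brute_match(raw, system):
            try:
                code = normalize_code(raw, system)
            except CodeListError:
                return None
            cats = {e.category for e in dementia_list.entries if e.matches(code)
                    and e.condition == "dementia"}
            has = any(e.matches(code) and e.condition == "dementia"
                      for e in dementia_list.entries)
            return cats if has else None

        for r in sim_clean.gp_events.itertuples():
            if r.person_id in ids:
                cats = brute_match(r.code, System.READ2)
                if cats is not None:
                    note(r.person_id, r.event_date, cats)
        for r in sim_clean.hospital_episodes.itertuples():
            if r.person_id in ids:
                for tok in str(r.codes).split(";"):
                    cats = brute_match(tok, System.ICD10)
                    if cats is not None:
                        note(r.person_id, r.admission_date, cats)
        for r in sim_clean.mortality.itertuples():
            if r.person_id in ids:
                system = System.ICD9 if r.death_date < cutover else System.ICD10
                for tok in str(r.cause_codes).split(";"):
                    cats = brute_match(tok, system)
                    if cats is not None:
                        note(r.person_id, r.death_date, cats)

        ev = ec.extract_condition_events(
            sim_clean.gp_events, sim_clean.hospital_episodes, sim_clean.mortality,
            dementia_list, cohort_ids=ids)
        asc = ec.ascertain_dementia(ev).set_index("person_id")

        assert set(asc.index) == set(expected)
        for pid, exp in expected.items():
            assert asc.loc[pid, "diagnosis_date"] == exp["date"], pid
            got = set(filter(None, asc.loc[pid, "subtypes"].split("|")))
            assert got == exp["subtypes"], pid

    def test_full_recording_recovers_truth_exactly(self, dementia_list):
        """With no dirty data and every source recording with probability 1,
        ascertained subtype sets equal the ground truth exactly and every
        true case is found."""
        cfg = ec.SimConfig(n_participants=3000, seed=17,
                           p_record_source={"GP": 1.0, "HOSP": 1.0, "DEATH": 1.0},
                           p_wdsd_only_death=0.0)
        tabs = ec.generate_population(cfg)
        gt = tabs.ground_truth.set_index("person_id")
        ev = ec.extract_condition_events(tabs.gp_events, tabs.hospital_episodes,
                                         tabs.mortality, dementia_list)
        asc = ec.ascertain_dementia(ev).set_index("person_id")
        true_cases = gt.index[gt.true_dementia == 1]
        assert set(asc.index) == set(true_cases)
        for pid in true_cases:
            assert asc.loc[pid, "subtypes"] == gt.loc[pid, "true_subtypes"]
            # onset-to-code delays are positive: first code never precedes onset
            assert asc.loc[pid, "diagnosis_date"] >= gt.loc[pid, "true_onset_date"]


class TestComorbidities:
    def test_only_matching_codes_produce_events(self, sim_clean, comorbidity_lists):
        tables = ec.extract_comorbidity_tables(
            sim_clean.gp_events, sim_clean.hospital_episodes, sim_clean.mortality,
            comorbidity_lists)
        assert set(tables) == set(comorbidity_lists)
        hyp = tables["hypertension"]
        assert len(hyp) > 0
        assert (hyp.condition == "hypertension").all()

    def test_empty_codelist_collection_gives_empty_map(self, sim_clean):
        assert ec.extract_comorbidity_tables(
            sim_clean.gp_events, sim_clean.hospital_episodes,
            sim_clean.mortality, {}) == {}

    def test_per_condition_equals_single_multilist_pass(self, sim_clean,
                                                        comorbidity_lists):
        """Equivalence oracle: running each list separately gives the same
        tables as one pass with all entries concatenated, split afterwards."""
        per = ec.extract_comorbidity_tables(
            sim_clean.gp_events, sim_clean.hospital_episodes, sim_clean.mortality,
            comorbidity_lists)
        combined = ec.CodeList("combined", tuple(
            e for cl in comorbidity_lists.values() for e in cl.entries))
        allev = ec.extract_condition_events(
            sim_clean.gp_events, sim_clean.hospital_episodes, sim_clean.mortality,
            combined)
        for name, table in per.items():
            split = allev.loc[allev.condition == name].reset_index(drop=True)
            lhs = table.sort_values(list(table.columns)).reset_index(drop=True)
            rhs = split.sort_values(list(split.columns)).reset_index(drop=True)
            pd.testing.assert_frame_equal(lhs, rhs)


class TestFirstSourceBreakdown:
    def _asc(self, rows):
        return pd.DataFrame(rows, columns=["person_id", "all_cause",
                                           "diagnosis_date", "subtypes",
                                           "first_source", "sources_ever"])

    def test_fractions_and_mortality_only(self):
        asc = self._asc([(1, True, None, "", "GP", "GP"),
                         (2, True, None, "", "GP", "GP|HOSP"),
                         (3, True, None, "", "HOSP", "HOSP"),
                         (4, True, None, "", "DEATH", "DEATH")])
        out = ec.first_source_breakdown(asc)
        assert out["first_fractions"] == {"GP": 0.5, "HOSP": 0.25, "DEATH": 0.25}
        assert out["mortality_only_count"] == 1
        assert sum(out["first_fractions"].values()) == pytest.approx(1.0)

    def test_single_source_cohort(self):
        asc = self._asc([(i, True, None, "", "GP", "GP") for i in range(3)])
        out = ec.first_source_breakdown(asc)
        assert out["first_fractions"]["GP"] == 1.0

    def test_zero_cases_reports_absent_fractions(self):
        out = ec.first_source_breakdown(self._asc([]))
        assert out["n_cases"] == 0
        assert out["first_fractions"] is None
        assert out["mortality_only_fraction"] is None
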