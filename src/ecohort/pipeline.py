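"""End-to-end cohort construction: clean -> include -> phenotype -> tables.

The stage order is fixed — demographics cleaning, mortality cleaning,
birth-window inclusion, linkage flagging, dementia phenotyping, diagnosis-
date validation, comorbidity extraction, table assembly — because the
per-rule exclusion counts depend on it: a person failing two rules is
attributed to the first rule applied.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cleaning, eligibility, phenotyping, tables
from .codelist import CodeList
from .simulate import SimTables

log = logging.getLogger(__name__)

__all__ = ["PipelineParams", "BuildResult", "build_cohort", "summarize",
           "write_build_outputs", "write_summaries"]


@dataclass
class PipelineParams:
    """Every tunable study constant of the construction pipeline."""

    birth_window: tuple = eligibility.BIRTH_WINDOW
    admin_end: pd.Timestamp = eligibility.ADMIN_END
    dob_min: pd.Timestamp = cleaning.DOB_MIN
    death_valid_window: tuple = cleaning.DEATH_VALID_WINDOW
    dementia_valid_window: tuple = cleaning.DEMENTIA_VALID_WINDOW
    linkage_threshold: float = 0.95
    gap_censoring: bool = False
    tie_break: tuple = phenotyping.DEFAULT_TIE_BREAK
    icd9_cutover: pd.Timestamp = pd.Timestamp("2001-01-01")

    def replace(self, **kw) -> "PipelineParams":
        return dataclasses.replace(self, **kw)


@dataclass
class BuildResult:
    """All artifacts of one cohort build."""

    n_input: int
    members: pd.DataFrame
    demographics_table: pd.DataFrame
    dementia_events: pd.DataFrame
    ascertainments: pd.DataFrame
    comorbidity_tables: dict[str, pd.DataFrame]
    flow: pd.DataFrame
    exclusion_log: cleaning.ExclusionLog
    mortality_log: cleaning.ExclusionLog
    resolved_deaths: pd.DataFrame = field(repr=False, default=None)


def build_cohort(
    tables_in: SimTables,
    dementia_list: CodeList,
    comorbidity_lists: dict[str, CodeList] | None = None,
    params: PipelineParams | None = None,
) -> BuildResult:
    """Run the full construction pipeline on linked input tables."""
    p = params or PipelineParams()
    n_input = len(tables_in.demographics)

    demo, clean_log = cleaning.clean_demographics(tables_in.demographics, p.dob_min)
    kept_mort, resolved_deaths, mort_log = cleaning.clean_mortality(
        tables_in.mortality, demo, p.death_valid_window)

    members, incl_log = eligibility.apply_inclusion(
        demo, resolved_deaths, p.birth_window, p.admin_end, p.gap_censoring)
    members = eligibility.flag_linkage(
        members, tables_in.linkage_quality, p.linkage_threshold)

    member_ids = set(members["person_id"])
    events = phenotyping.extract_condition_events(
        tables_in.gp_events, tables_in.hospital_episodes, kept_mort,
        dementia_list, member_ids, p.icd9_cutover)
    asc = phenotyping.ascertain_dementia(events, p.tie_break)
    asc, excluded_ids, dem_log = cleaning.validate_dementia_dates(
        asc, p.dementia_valid_window)

    members = members.loc[~members["person_id"].isin(excluded_ids)].reset_index(drop=True)
    events = events.loc[~events["person_id"].isin(excluded_ids)].reset_index(drop=True)
    member_ids = set(members["person_id"])

    comorb = phenotyping.extract_comorbidity_tables(
        tables_in.gp_events, tables_in.hospital_episodes, kept_mort,
        comorbidity_lists or {}, member_ids, p.icd9_cutover)

    exclusion_log = cleaning.ExclusionLog()
    exclusion_log.extend(clean_log)
    exclusion_log.extend(incl_log)
    # only members who reached the dementia-date rule count as excluded there
    dem_excluded = excluded_ids  # already restricted to ascertained persons
    exclusion_log.steps.append(("invalid_dementia_date",
                                len(member_ids) + len(dem_excluded), len(dem_excluded)))
    exclusion_log.ids["invalid_dementia_date"] = frozenset(dem_excluded)

    flow_steps = [(rule, len(exclusion_log.ids[rule]))
                  for rule, _, _ in exclusion_log.steps]
    flow = tables.flow_diagram(n_input, flow_steps, len(members))

    demographics_table = tables.build_demographics_table(members, asc)
    log.info("stage=build_cohort input=%d members=%d cases=%d",
             n_input, len(members), int(demographics_table["dementia_flag"].sum()))
    return BuildResult(
        n_input=n_input,
        members=members,
        demographics_table=demographics_table,
        dementia_events=events,
        ascertainments=asc,
        comorbidity_tables=comorb,
        flow=flow,
        exclusion_log=exclusion_log,
        mortality_log=mort_log,
        resolved_deaths=resolved_deaths,
    )


def summarize(demographics_table: pd.DataFrame,
              ascertainments: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Compute every results summary from the built tables."""
    t = demographics_table
    cases = t.loc[t["dementia_flag"].astype(bool)]

    strata_frames = []
    for population, df in (("whole_cohort", t), ("dementia_cases", cases)):
        for stratifier in tables.STRATIFIERS:
            s = tables.stratified_person_years(df, stratifier)
            frame = s.to_frame()
            frame.insert(0, "population", population)
            frame["percent"] = [
                tables.proportion_percent(int(nn), s.total_n) if s.total_n else 0
                for nn in frame["n"]]
            strata_frames.append(frame)
    table1 = pd.concat(strata_frames, ignore_index=True)

    breakdown = tables.subtype_breakdown(ascertainments).to_frame()

    src = phenotyping.first_source_breakdown(ascertainments)
    fu = tables.followup_summaries(t)
    overlap_rows = []
    for s in phenotyping.SOURCES:
        overlap_rows.append((
            f"ever_{s}",
            int(round((fu["source_ever_fractions"] or {}).get(s, 0) * src["n_cases"]))
            if fu["source_ever_fractions"] else 0,
            (fu["source_ever_fractions"] or {}).get(s, "")
            if fu["source_ever_fractions"] else "",
        ))
        overlap_rows.append((
            f"first_{s}", src["first_counts"][s],
            src["first_fractions"][s] if src["first_fractions"] else ""))
    overlap_rows.append(("mortality_only", src["mortality_only_count"],
                         src["mortality_only_fraction"]
                         if src["mortality_only_fraction"] is not None else ""))
    source_overlap = pd.DataFrame(overlap_rows, columns=["measure", "n", "fraction"])

    followup = pd.DataFrame([
        ("n_cases", fu["n_cases"]),
        ("median_follow_up_years", fu["median_follow_up_years"]),
        ("n_entered_before_60", fu["n_entered_before_60"]),
        ("median_follow_up_entered_before_60",
         fu["median_follow_up_entered_before_60"]),
        ("died_fraction", fu["died_fraction"]),
    ], columns=["measure", "value"])

    return {
        "summary_table1": table1,
        "subtype_breakdown": breakdown,
        "source_overlap": source_overlap,
        "followup_summary": followup,
    }


def write_build_outputs(result: BuildResult, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, date_format="%Y-%m-%d")
    result.demographics_table.to_csv(directory / "demographics_table.csv", **kw)
    result.dementia_events.to_csv(directory / "dementia_events.csv", **kw)
    result.ascertainments.to_csv(directory / "ascertainment.csv", **kw)
    for name, df in result.comorbidity_tables.items():
        df.to_csv(directory / f"events_{name}.csv", **kw)
    result.flow.to_csv(directory / "flow_diagram.csv", index=False)
    result.exclusion_log.write(directory / "exclusions.csv")


def write_summaries(summaries: dict[str, pd.DataFrame], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in summaries.items():
        df.to_csv(directory / f"{name}.csv", index=False)
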