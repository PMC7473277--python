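"""Cohort tables and stratified summaries.

Assembles the one-row-per-participant demographics table (entry/exit,
follow-up, dementia and subtype flags, linkage flag) and the standard
results summaries of a routine-data cohort description: counts and
person-years stratified by sex, deprivation quintile and birth decade;
the non-exclusive dementia subtype breakdown; source-of-ascertainment
overlap; median follow-up; and the exclusion flow table.

Printed-percentage convention: nearest integer, half away from zero.
Median convention: lower median for even counts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotyping import SOURCES

__all__ = [
    "StratifiedSummary",
    "SubtypeBreakdown",
    "FlowError",
    "STRATIFIERS",
    "BIRTH_DECADES",
    "SUBTYPE_CATEGORIES",
    "proportion_percent",
    "birth_decade",
    "build_demographics_table",
    "stratified_person_years",
    "subtype_breakdown",
    "followup_summaries",
    "flow_diagram",
]

STRATIFIERS = ("sex", "deprivation_quintile", "birth_decade")
#: Decade bins as conventionally printed; note the first spans 11 years.
BIRTH_DECADES = ("1900-1910", "1911-1920", "1921-1930",
                 "1931-1940", "1941-1950", "1951-1960")
SUBTYPE_CATEGORIES = ("AD", "VaD", "DLB", "FTD")

MISSING_LABEL = "Missing"


class FlowError(RuntimeError):
    """Exclusion accounting does not close."""


def proportion_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer, half away from zero."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if not (0 <= numerator <= denominator):
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def birth_decade(dob) -> str:
    """Decade stratum label for a date of birth (inclusive bin edges)."""
    year = pd.Timestamp(dob).year
    if year < 1900:
        return "<1900"
    if 1900 <= year <= 1910:
        return "1900-1910"
    if year > 1960:
        return ">1960"
    start = 1911 + ((year - 1911) // 10) * 10
    return f"{start}-{start + 9}"


def _lower_median(values) -> float | None:
    vals = sorted(values)
    if not vals:
        return None
    return vals[(len(vals) - 1) // 2]


def build_demographics_table(
    members: pd.DataFrame,
    ascertainments: pd.DataFrame,
) -> pd.DataFrame:
    """One row per cohort member with dementia flags merged in.

    Case fields (diagnosis date, subtypes, first source) are blank for
    non-cases.  An ascertainment for a person who is not a member signals a
    mis-ordered pipeline and raises.
    """
    member_ids = set(members["person_id"])
    stray = set(ascertainments["person_id"]) - member_ids
    if stray:
        sample = sorted(stray)[:5]
        raise ValueError(
            f"ascertainments for {len(stray)} non-member person id(s), e.g. {sample}")
    table = members.merge(ascertainments, on="person_id", how="left")
    table["dementia_flag"] = table["all_cause"].eq(True)
    table["subtype_flag"] = table["subtypes"].fillna("").astype(str).str.len() > 0
    table = table.drop(columns=["all_cause"])
    for col in ("subtypes", "first_source", "sources_ever"):
        table[col] = table[col].fillna("")
    table["diagnosis_date"] = pd.to_datetime(table["diagnosis_date"])
    cols = ["person_id", "dob", "sex", "deprivation_quintile",
            "entry_date", "exit_date", "death_date", "follow_up_years",
            "dementia_flag", "subtype_flag", "diagnosis_date", "subtypes",
            "first_source", "sources_ever", "linkage_flag"]
    return table[cols]


@dataclass
class StratifiedSummary:
    """Per-stratum counts and person-years for one stratifier."""

    stratifier: str
    table: pd.DataFrame  # columns: stratum, n, person_years
    total_n: int
    total_person_years: float

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "stratifier", self.stratifier)
        return out


def _stratum_labels(df: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "sex":
        s = df["sex"].astype(str)
        return s.where(s.str.len() > 0, MISSING_LABEL)
    if stratifier == "deprivation_quintile":
        q = df["deprivation_quintile"]
        return pd.Series(
            [MISSING_LABEL if pd.isna(v) else str(int(v)) for v in q], index=df.index)
    if stratifier == "birth_decade":
        return df["dob"].map(birth_decade)
    raise ValueError(f"unknown stratifier {stratifier!r}; expected one of {STRATIFIERS}")


def stratified_person_years(df: pd.DataFrame, stratifier: str) -> StratifiedSummary:
    """Counts and person-years per stratum (whole cohort or case subset)."""
    labels = _stratum_labels(df, stratifier)
    grouped = df.groupby(labels.rename("stratum"), sort=False).agg(
        n=("person_id", "size"), person_years=("follow_up_years", "sum"))
    if stratifier == "sex":
        order = ["F", "M", MISSING_LABEL]
    elif stratifier == "deprivation_quintile":
        order = [str(i) for i in range(1, 6)] + [MISSING_LABEL]
    else:
        order = list(BIRTH_DECADES)
    extra = [s for s in grouped.index if s not in order]
    grouped = grouped.reindex(order + extra, fill_value=0)
    table = grouped.reset_index()
    return StratifiedSummary(
        stratifier=stratifier,
        table=table,
        total_n=int(len(df)),
        total_person_years=float(df["follow_up_years"].sum()),
    )


@dataclass
class SubtypeBreakdown:
    """Non-exclusive dementia subtype counts among all-cause cases."""

    n_all_cause: int
    n_subtyped: int
    category_counts: dict[str, int]
    n_AD_and_VaD: int
    category_percents: dict[str, int]  # of n_subtyped, nearest integer

    def to_frame(self) -> pd.DataFrame:
        rows = [("all_cause", self.n_all_cause, ""),
                ("any_subtype", self.n_subtyped,
                 proportion_percent(self.n_subtyped, self.n_all_cause)
                 if self.n_all_cause else "")]
        for cat in SUBTYPE_CATEGORIES:
            rows.append((cat, self.category_counts.get(cat, 0),
                         self.category_percents.get(cat, "")))
        rows.append(("AD_and_VaD", self.n_AD_and_VaD,
                     proportion_percent(self.n_AD_and_VaD, self.n_subtyped)
                     if self.n_subtyped else ""))
        return pd.DataFrame(rows, columns=["category", "n", "percent"])


def subtype_breakdown(ascertainments: pd.DataFrame) -> SubtypeBreakdown:
    """Subtype counts over cases; categories are non-exclusive, so counts can
    sum to more than the number of subtyped persons.  Percentages use the
    subtyped persons as denominator."""
    cases = ascertainments.loc[ascertainments["all_cause"].astype(bool)]
    subtype_sets = [set(s.split("|")) if s else set()
                    for s in cases["subtypes"].fillna("")]
    n_all = len(cases)
    n_subtyped = sum(1 for s in subtype_sets if s)
    counts = {cat: sum(1 for s in subtype_sets if cat in s)
              for cat in SUBTYPE_CATEGORIES}
    n_mixed = sum(1 for s in subtype_sets if {"AD", "VaD"} <= s)
    percents = ({cat: proportion_percent(c, n_subtyped)
                 for cat, c in counts.items()} if n_subtyped else {})
    return SubtypeBreakdown(n_all, n_subtyped, counts, n_mixed, percents)


def followup_summaries(demographics_table: pd.DataFrame) -> dict:
    """Follow-up summaries among cases.

    * median follow-up (lower median);
    * count and median follow-up of cases whose entry preceded their 60th
      birthday (strict: entry_date < dob + 60 years);
    * fraction of cases dying during follow-up (death present and <= exit);
    * fraction of cases ever identified in each source.

    Medians are absent (None), not zero, when there are no cases.
    """
    t = demographics_table
    cases = t.loc[t["dementia_flag"].astype(bool)]
    n = len(cases)
    out: dict = {"n_cases": n}
    out["median_follow_up_years"] = _lower_median(cases["follow_up_years"])
    if n:
        sixty = cases["dob"] + pd.DateOffset(years=60)
        young = cases.loc[cases["entry_date"] < sixty]
        out["n_entered_before_60"] = int(len(young))
        out["median_follow_up_entered_before_60"] = _lower_median(
            young["follow_up_years"])
        died = cases["death_date"].notna() & (cases["death_date"] <= cases["exit_date"])
        out["died_fraction"] = float(died.mean())
        out["source_ever_fractions"] = {
            src: float(cases["sources_ever"].str.contains(src, regex=False).mean())
            for src in SOURCES}
    else:
        out.update({"n_entered_before_60": 0,
                    "median_follow_up_entered_before_60": None,
                    "died_fraction": None, "source_ever_fractions": None})
    return out


def flow_diagram(initial_count: int, steps, final_count: int) -> pd.DataFrame:
    """Ordered flow table: each step's output = previous count - exclusions.

    ``steps`` is an iterable of (rule, excluded_count).  Raises
    :class:`FlowError` if the accounting does not reproduce ``final_count``.
    """
    rows = []
    n = int(initial_count)
    for rule, excluded in steps:
        excluded = int(excluded)
        rows.append((rule, n, excluded, n - excluded))
        n -= excluded
    if n != int(final_count):
        raise FlowError(
            f"flow does not close: {initial_count} - exclusions = {n}, "
            f"but final cohort has {final_count}")
    return pd.DataFrame(rows, columns=["step", "n_in", "n_excluded", "n_out"])
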