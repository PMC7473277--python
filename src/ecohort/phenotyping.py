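"""Code-list phenotyping across linked clinical sources.

Scans primary-care events (Read v2), hospital episodes (ICD-10) and
mortality cause codes (ICD-9 before the coding cutover, ICD-10 after)
against a code list and emits one condition event per matching
(record, condition, category) pair.  Per-person case status is then
resolved: a person is an all-cause case if they have at least one matching
code in any source, the diagnosis date is the date of the *first* code of
any kind (all-cause or subtype), subtype flags are the union of subtype
categories over all events, and the first-identifying source is the source
of the earliest event (same-date ties broken by a fixed, configurable
priority, default GP > hospital > death certificate).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .codelist import CodeList, CodeListError, CodeMatcher, System, normalize_code

log = logging.getLogger(__name__)

__all__ = [
    "SOURCES",
    "DEFAULT_TIE_BREAK",
    "extract_condition_events",
    "ascertain_dementia",
    "extract_comorbidity_tables",
    "first_source_breakdown",
]

SOURCES = ("GP", "HOSP", "DEATH")
DEFAULT_TIE_BREAK = ("GP", "HOSP", "DEATH")

EVENT_COLUMNS = ["person_id", "event_date", "system", "code",
                 "source", "condition", "category"]


def _match_unique(raw_codes, system: System, matcher: CodeMatcher):
    """Map each unique raw token to its normalized value and matches.

    Returns (mapping raw -> list of (value, condition, category)), and the
    count of unparseable tokens (skipped, logged by the caller).
    """
    mapping: dict[str, list[tuple[str, str, str]]] = {}
    n_bad = 0
    for raw in raw_codes:
        try:
            code = normalize_code(raw, system)
        except CodeListError:
            n_bad += 1
            mapping[raw] = []
            continue
        mapping[raw] = [(code.value, cond, cat) for cond, cat in matcher.match(code)]
    return mapping, n_bad


def _explode(df, raw_col, system_col_or_value, source, matcher, date_col):
    rows = []
    if isinstance(system_col_or_value, System):
        systems = pd.Series([system_col_or_value] * len(df), index=df.index)
    else:
        systems = df[system_col_or_value]
    for system in {System(s) for s in systems}:
        sub = df.loc[systems == system]
        mapping, n_bad = _match_unique(sub[raw_col].unique(), system, matcher)
        for rec in sub.itertuples(index=False):
            raw = getattr(rec, raw_col)
            for value, cond, cat in mapping[raw]:
                rows.append((rec.person_id, getattr(rec, date_col),
                             system.value, value, source, cond, cat))
        if n_bad:
            log.warning("source=%s system=%s skipped %d unparseable code token(s)",
                        source, system.value, n_bad)
    return rows


def extract_condition_events(
    gp_events: pd.DataFrame,
    hospital_episodes: pd.DataFrame,
    mortality: pd.DataFrame,
    codelist: CodeList,
    cohort_ids=None,
    icd9_cutover=pd.Timestamp("2001-01-01"),
) -> pd.DataFrame:
    """Build the condition event table for one code list.

    GP events are dated at the event date, hospital episodes at admission,
    mortality at the death date.  Mortality cause codes are matched as ICD-9
    when the death precedes the cutover date, ICD-10 on/after it.
    Unparseable code tokens are skipped with a logged count.
    """
    matcher = CodeMatcher(codelist)
    cutover = pd.Timestamp(icd9_cutover)

    def _filter(df):
        if cohort_ids is None:
            return df
        return df.loc[df["person_id"].isin(cohort_ids)]

    rows = []
    gp = _filter(gp_events)
    rows += _explode(gp.rename(columns={"event_date": "date"}),
                     "code", System.READ2, "GP", matcher, "date")

    hosp = _filter(hospital_episodes).copy()
    if len(hosp):
        hosp = hosp.rename(columns={"admission_date": "date"})
        hosp["codes"] = hosp["codes"].astype(str).str.split(";")
        hosp = hosp.explode("codes").rename(columns={"codes": "code"})
        hosp = hosp.loc[hosp["code"].astype(str).str.len() > 0]
        rows += _explode(hosp, "code", System.ICD10, "HOSP", matcher, "date")

    mort = _filter(mortality).copy()
    if len(mort):
        mort = mort.rename(columns={"death_date": "date"})
        mort["cause_codes"] = mort["cause_codes"].astype(str).str.split(";")
        mort = mort.explode("cause_codes").rename(columns={"cause_codes": "code"})
        mort = mort.loc[mort["code"].astype(str).str.len() > 0]
        mort["system"] = np.where(mort["date"] < cutover,
                                  System.ICD9.value, System.ICD10.value)
        rows += _explode(mort, "code", "system", "DEATH", matcher, "date")

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events["person_id"] = events["person_id"].astype(np.int64)
    events["event_date"] = pd.to_datetime(events["event_date"]).astype("datetime64[ns]")
    for col in ("system", "code", "source", "condition", "category"):
        events[col] = events[col].astype(object)
    events = events.sort_values(
        ["person_id", "event_date", "source", "condition", "category", "code"],
        kind="mergesort").reset_index(drop=True)
    return events


def ascertain_dementia(
    events: pd.DataFrame,
    tie_break: tuple = DEFAULT_TIE_BREAK,
    condition: str | None = None,
) -> pd.DataFrame:
    """Resolve per-person case status from one condition's event table.

    diagnosis_date = earliest event of any kind; subtypes = union of
    non-empty categories over all events anywhere, any time; first_source =
    source of the earliest event, same-date ties broken by ``tie_break``
    priority order; sources_ever = every source with at least one event.
    """
    if condition is not None:
        events = events.loc[events["condition"] == condition]
    elif len(events) and events["condition"].nunique() > 1:
        raise ValueError("events span multiple conditions; pass condition=...")
    if not len(events):
        return pd.DataFrame(columns=["person_id", "all_cause", "diagnosis_date",
                                     "subtypes", "first_source", "sources_ever"])
    rank = {s: i for i, s in enumerate(tie_break)}
    ev = events.copy()
    ev["_rank"] = ev["source"].map(rank)
    ev = ev.sort_values(["person_id", "event_date", "_rank"], kind="mergesort")

    first = ev.groupby("person_id", as_index=True).first()
    subtypes = ev.groupby("person_id")["category"].agg(
        lambda c: "|".join(sorted({x for x in c if x})))
    sources = ev.groupby("person_id")["source"].agg(
        lambda s: "|".join(sorted(set(s))))

    out = pd.DataFrame({
        "person_id": first.index,
        "all_cause": True,
        "diagnosis_date": first["event_date"].to_numpy(),
        "subtypes": subtypes.reindex(first.index).to_numpy(),
        "first_source": first["source"].to_numpy(),
        "sources_ever": sources.reindex(first.index).to_numpy(),
    }).reset_index(drop=True)
    out["diagnosis_date"] = pd.to_datetime(out["diagnosis_date"])
    return out


def extract_comorbidity_tables(
    gp_events: pd.DataFrame,
    hospital_episodes: pd.DataFrame,
    mortality: pd.DataFrame,
    codelists,
    cohort_ids=None,
    icd9_cutover=pd.Timestamp("2001-01-01"),
) -> dict[str, pd.DataFrame]:
    """One event table per code list, same format as the dementia table.

    ``codelists`` is a mapping name -> :class:`CodeList` (or an iterable of
    code lists, keyed by their names).
    """
    if not hasattr(codelists, "items"):
        codelists = {cl.name: cl for cl in codelists}
    return {
        name: extract_condition_events(gp_events, hospital_episodes, mortality,
                                       cl, cohort_ids, icd9_cutover)
        for name, cl in codelists.items()
    }


def first_source_breakdown(ascertainments: pd.DataFrame) -> dict:
    """Counts and fractions of cases by first-identifying source, plus the
    count identified *only* on the death certificate.  With zero cases the
    fractions are reported as absent (None)."""
    cases = ascertainments.loc[ascertainments["all_cause"].astype(bool)]
    n = len(cases)
    counts = {src: int((cases["first_source"] == src).sum()) for src in SOURCES}
    mortality_only = int((cases["sources_ever"] == "DEATH").sum())
    fractions = ({src: counts[src] / n for src in SOURCES} if n else None)
    return {
        "n_cases": n,
        "first_counts": counts,
        "first_fractions": fractions,
        "mortality_only_count": mortality_only,
        "mortality_only_fraction": (mortality_only / n) if n else None,
    }
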