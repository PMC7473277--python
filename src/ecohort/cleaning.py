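"""Data-cleaning exclusions with full accounting.

Routine-data extracts contain records that cannot be right: births before
the registration system existed, death dates outside the plausible data
window, registration spells with no start date, and diagnosis codes dated
outside the study window.  Each rule here drops (or invalidates) records
and logs (rule, examined, excluded) so a study flow diagram can account for
every person, and a person failing two rules is attributed to the first
rule applied.

All window boundaries are strict: "before 1/1/1900" excludes 1899-12-31 but
keeps 1900-01-01, and likewise for the death and diagnosis windows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .spells import parse_spells

log = logging.getLogger(__name__)

__all__ = [
    "ExclusionLog",
    "DOB_MIN",
    "DEATH_VALID_WINDOW",
    "DEMENTIA_VALID_WINDOW",
    "clean_demographics",
    "clean_mortality",
    "validate_dementia_dates",
]

DOB_MIN = pd.Timestamp("1900-01-01")
DEATH_VALID_WINDOW = (pd.Timestamp("1980-01-01"), pd.Timestamp("2020-01-01"))
DEMENTIA_VALID_WINDOW = (pd.Timestamp("1900-01-01"), pd.Timestamp("2018-01-01"))


@dataclass
class ExclusionLog:
    """Ordered record of (rule, examined, excluded) with per-rule id sets."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    ids: dict[str, frozenset] = field(default_factory=dict)

    def add(self, rule: str, examined: int, excluded_ids) -> None:
        excluded = frozenset(excluded_ids)
        if len(excluded) > examined:
            raise ValueError(f"rule {rule!r}: excluded {len(excluded)} > examined {examined}")
        self.steps.append((rule, examined, len(excluded)))
        self.ids[rule] = excluded
        log.info("stage=%s examined=%d excluded=%d", rule, examined, len(excluded))

    def extend(self, other: "ExclusionLog") -> None:
        for rule, examined, _ in other.steps:
            self.steps.append((rule, examined, len(other.ids[rule])))
            self.ids[rule] = other.ids[rule]

    @property
    def total_excluded(self) -> int:
        return sum(n for _, _, n in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "examined", "excluded"])

    def write(self, path: str | Path) -> None:
        """Write ``exclusions.csv`` plus a per-rule excluded-id list."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        rows = [(rule, pid) for rule, idset in self.ids.items()
                for pid in sorted(idset)]
        pd.DataFrame(rows, columns=["rule", "person_id"]).to_csv(
            path.with_name(path.stem + "_ids.csv"), index=False)


def clean_demographics(
    demographics: pd.DataFrame,
    dob_min: pd.Timestamp = DOB_MIN,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop persons with an impossible date of birth or no usable GP
    registration start date.  Rule order: date of birth first, so a person
    failing both is counted under the birth-date rule only."""
    logx = ExclusionLog()
    demo = demographics

    bad_dob = demo["dob"].isna() | (demo["dob"] < pd.Timestamp(dob_min))
    logx.add("dob_before_1900", len(demo), demo.loc[bad_dob, "person_id"])
    demo = demo.loc[~bad_dob]

    def _missing_registration(serialized: str) -> bool:
        spells = parse_spells(serialized)
        return (not spells) or any(start is None for start, _ in spells)

    bad_reg = demo["gp_spells"].map(_missing_registration)
    logx.add("missing_gp_registration", len(demo), demo.loc[bad_reg, "person_id"])
    demo = demo.loc[~bad_reg]

    return demo.reset_index(drop=True), logx


def clean_mortality(
    mortality: pd.DataFrame,
    demographics: pd.DataFrame,
    valid_window: tuple = DEATH_VALID_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Discard mortality records (with their cause codes) whose death date is
    outside the valid window, then resolve one death date per person:
    mortality record if a valid one exists, else the demographic-register
    (WDSD) death date, else absent.

    Returns (kept mortality records, resolved deaths, log).  The log counts
    *records*; the id set holds the persons whose records were dropped.  Two
    conflicting valid records for one person keep the earlier date with a
    warning.
    """
    lo, hi = (pd.Timestamp(valid_window[0]), pd.Timestamp(valid_window[1]))
    logx = ExclusionLog()
    mort = mortality

    invalid = mort["death_date"].isna() | (mort["death_date"] < lo) | (mort["death_date"] > hi)
    dropped_ids = mort.loc[invalid, "person_id"]
    logx.steps.append(("death_date_out_of_range", len(mort), int(invalid.sum())))
    logx.ids["death_date_out_of_range"] = frozenset(dropped_ids)
    log.info("stage=death_date_out_of_range examined=%d excluded=%d",
             len(mort), int(invalid.sum()))
    kept = mort.loc[~invalid]

    if len(kept):
        per_person = kept.groupby("person_id")["death_date"]
        n_conflicts = int((per_person.nunique() > 1).sum())
        if n_conflicts:
            log.warning("conflicting mortality death dates for %d person(s); "
                        "keeping the earlier date", n_conflicts)
        earliest = per_person.transform("min")
        kept = kept.loc[kept["death_date"] == earliest]
        kept = kept.drop_duplicates(subset=["person_id", "death_date"])
        resolved_mort = kept.groupby("person_id", as_index=False)["death_date"].min()
    else:
        resolved_mort = pd.DataFrame(columns=["person_id", "death_date"])

    resolved = demographics[["person_id"]].merge(resolved_mort, on="person_id", how="left")
    resolved["death_date"] = pd.to_datetime(resolved["death_date"])
    if "wdsd_death_date" in demographics.columns:
        wdsd = demographics.set_index("person_id")["wdsd_death_date"]
        fallback = pd.to_datetime(resolved["person_id"].map(wdsd))
        resolved["death_date"] = resolved["death_date"].fillna(fallback)

    return kept.reset_index(drop=True), resolved, logx


def validate_dementia_dates(
    ascertainments: pd.DataFrame,
    valid_window: tuple = DEMENTIA_VALID_WINDOW,
) -> tuple[pd.DataFrame, frozenset, ExclusionLog]:
    """Exclude *participants* whose dementia diagnosis date falls outside the
    valid window — such codes cannot be distinguished from data errors, so
    the person leaves the cohort entirely, not just the case group."""
    lo, hi = (pd.Timestamp(valid_window[0]), pd.Timestamp(valid_window[1]))
    logx = ExclusionLog()
    asc = ascertainments
    is_case = asc["all_cause"].astype(bool)
    bad = is_case & asc["diagnosis_date"].notna() & (
        (asc["diagnosis_date"] < lo) | (asc["diagnosis_date"] > hi))
    excluded = frozenset(asc.loc[bad, "person_id"])
    logx.add("invalid_dementia_date", len(asc), excluded)
    return asc.loc[~bad].reset_index(drop=True), excluded, logx
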