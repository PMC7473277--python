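"""Cohort eligibility, entry/exit dates and person-years of follow-up.

Eligibility is a birth window (inclusive at both ends): participants born
between the window start and end.  The upper bound encodes the requirement
that a participant's 60th birthday falls within follow-up.  Entry is the
first GP registration date; exit is the earliest of de-registration, death,
and the administrative end of data.  Follow-up is (exit - entry) in days
divided by 365.25, the standard epidemiological year length.

Gaps between registration spells count as follow-up by default (entry and
exit define a single interval); ``gap_censoring=True`` instead sums only the
time covered by spells.

Low-quality record linkage (< threshold probabilistic match on any dataset)
sets a flag; it never excludes.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cleaning import ExclusionLog
from .spells import parse_spells

log = logging.getLogger(__name__)

__all__ = [
    "BIRTH_WINDOW",
    "ADMIN_END",
    "DAYS_PER_YEAR",
    "apply_inclusion",
    "person_years",
    "flag_linkage",
]

BIRTH_WINDOW = (pd.Timestamp("1900-01-01"), pd.Timestamp("1958-01-01"))
ADMIN_END = pd.Timestamp("2018-01-31")
DAYS_PER_YEAR = 365.25


def person_years(entry, exit) -> float | np.ndarray:
    """Follow-up years between entry and exit: (exit - entry in days)/365.25."""
    entry = pd.to_datetime(entry)
    exit = pd.to_datetime(exit)
    if isinstance(entry, pd.Timestamp):
        days = (exit - entry).days
        if days < 0:
            raise ValueError(f"entry {entry.date()} after exit {exit.date()}")
        return days / DAYS_PER_YEAR
    days = (exit - entry).dt.days if hasattr(exit - entry, "dt") else (exit - entry).days
    if (np.asarray(days) < 0).any():
        raise ValueError("entry after exit for some persons")
    return np.asarray(days) / DAYS_PER_YEAR


def apply_inclusion(
    demographics: pd.DataFrame,
    resolved_deaths: pd.DataFrame,
    birth_window: tuple = BIRTH_WINDOW,
    admin_end: pd.Timestamp = ADMIN_END,
    gap_censoring: bool = False,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the birth-window criterion and derive entry/exit/follow-up.

    ``resolved_deaths`` is the per-person death-date table from
    :func:`ecohort.cleaning.clean_mortality`.  Persons whose entry would fall
    after their exit are excluded and logged as ``zero_follow_up``.
    """
    lo, hi = pd.Timestamp(birth_window[0]), pd.Timestamp(birth_window[1])
    admin_end = pd.Timestamp(admin_end)
    logx = ExclusionLog()

    demo = demographics
    out_of_window = (demo["dob"] < lo) | (demo["dob"] > hi)
    logx.add("outside_birth_window", len(demo), demo.loc[out_of_window, "person_id"])
    demo = demo.loc[~out_of_window]

    deaths = dict(zip(resolved_deaths["person_id"], resolved_deaths["death_date"]))

    rows = []
    dropped: list = []
    for rec in demo.itertuples(index=False):
        spells = parse_spells(rec.gp_spells)
        starts = [s for s, _ in spells if s is not None]
        entry = min(starts)
        reg_exit = admin_end if any(e is None for _, e in spells) else max(
            e for _, e in spells)
        death = deaths.get(rec.person_id, pd.NaT)
        exit_date = min(reg_exit, admin_end)
        if pd.notna(death):
            exit_date = min(exit_date, death)
        if entry > exit_date:
            dropped.append(rec.person_id)
            continue
        if gap_censoring:
            fu_days = 0
            for s, e in spells:
                a = max(s, entry)
                b = min(e if e is not None else admin_end, exit_date)
                if b > a:
                    fu_days += (b - a).days
            fu = fu_days / DAYS_PER_YEAR
        else:
            fu = (exit_date - entry).days / DAYS_PER_YEAR
        rows.append((rec.person_id, rec.dob, rec.sex, rec.deprivation_quintile,
                     entry, exit_date, death if pd.notna(death) else pd.NaT, fu))
    logx.add("zero_follow_up", len(demo), dropped)

    members = pd.DataFrame(rows, columns=[
        "person_id", "dob", "sex", "deprivation_quintile",
        "entry_date", "exit_date", "death_date", "follow_up_years"])
    if len(members):
        members["deprivation_quintile"] = members["deprivation_quintile"].astype("Int64")
        for col in ("dob", "entry_date", "exit_date", "death_date"):
            members[col] = pd.to_datetime(members[col])
    log.info("stage=apply_inclusion members=%d", len(members))
    return members.reset_index(drop=True), logx


def flag_linkage(
    members: pd.DataFrame,
    linkage_quality: pd.DataFrame,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Set ``linkage_flag`` where any dataset link has match probability
    strictly below the threshold.  Flag only — never an exclusion."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"linkage threshold must be in (0, 1], got {threshold}")
    low = linkage_quality.loc[
        linkage_quality["match_probability"] < threshold, "person_id"]
    members = members.copy()
    members["linkage_flag"] = members["person_id"].isin(set(low))
    return members
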