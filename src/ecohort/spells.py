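"""GP registration spell serialization.

A person's registration history is a list of (start, end) date pairs.  In
the delimited tables it is one field: spells joined by ``;``, start and end
joined by ``:``, empty date = missing (an empty end means the spell is open,
i.e. still registered at the administrative end of follow-up).
"""
from __future__ import annotations

import pandas as pd

Spell = tuple[pd.Timestamp | None, pd.Timestamp | None]


def parse_spells(serialized: str) -> list[Spell]:
    """Parse the spell field; '' (or NaN) means no recorded spell."""
    if serialized is None or (isinstance(serialized, float) and pd.isna(serialized)):
        return []
    s = str(serialized).strip()
    if not s:
        return []
    out: list[Spell] = []
    for part in s.split(";"):
        if not part:
            continue
        a, _, b = part.partition(":")
        start = pd.Timestamp(a) if a else None
        end = pd.Timestamp(b) if b else None
        out.append((start, end))
    return out


def format_spells(spells: list[Spell]) -> str:
    parts = []
    for start, end in spells:
        a = "" if start is None else str(pd.Timestamp(start).date())
        b = "" if end is None else str(pd.Timestamp(end).date())
        parts.append(f"{a}:{b}")
    return ";".join(parts)
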