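"""Clinical code lists and cross-system code matching.

UK routine healthcare data mix three coding systems: hospital episodes are
coded in ICD-10, causes of death in ICD-9 (before 2001) or ICD-10, and
primary-care events in Read version 2.  A *code list* is the standard
phenotyping device: a set of (system, pattern) rules, each either an exact
code or a chapter prefix, labelled with the clinical condition it identifies
and, optionally, a sub-category (here: dementia subtypes AD, VaD, DLB, FTD).

Normalisation conventions
-------------------------
* ICD-9 / ICD-10: dots are formatting only (``F00.1`` == ``F001``) and
  matching is case-insensitive, so values are upper-cased with dots removed.
* Read v2 is case-sensitive (``Eu02`` and ``EU02`` are different concepts)
  and codes are at most five characters, conventionally padded with trailing
  dots (``Eu02.``); padding is stripped, case preserved.  Longer code+term
  strings are rejected rather than truncated.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

log = logging.getLogger(__name__)

__all__ = [
    "System",
    "MatchMode",
    "CodeListError",
    "ClinicalCode",
    "CodeListEntry",
    "CodeList",
    "CodeMatcher",
    "normalize_code",
    "load_codelist",
    "match_code",
    "dementia_categories",
    "builtin_codelist",
    "BUILTIN_CODELISTS",
]


class System(str, Enum):
    """Coding system of a clinical code."""

    ICD9 = "ICD9"
    ICD10 = "ICD10"
    READ2 = "READ2"


class MatchMode(str, Enum):
    """How a code-list pattern recognises codes: exact value or prefix."""

    EXACT = "exact"
    PREFIX = "prefix"


class CodeListError(ValueError):
    """Raised for malformed codes or code-list files."""


READ2_MAX_LEN = 5

#: Fixture code lists shipped with the package (illustrative, not the
#: validated research lists; users supply their own in the same format).
BUILTIN_CODELISTS = (
    "dementia",
    "hypertension",
    "diabetes",
    "stroke",
    "ever_smoking",
    "obesity",
    "atrial_fibrillation",
)

CODELIST_COLUMNS = ("system", "pattern", "match_mode", "condition", "category")


@dataclass(frozen=True)
class ClinicalCode:
    """A normalized coded clinical concept."""

    system: System
    value: str


def normalize_code(raw: str, system: System | str) -> ClinicalCode:
    """Return the canonical :class:`ClinicalCode` for a raw code string.

    Raises :class:`CodeListError` for empty, over-long (Read v2) or
    non-alphanumeric values.
    """
    try:
        system = System(system)
    except ValueError:
        raise CodeListError(f"unknown coding system: {system!r}") from None
    s = str(raw).strip()
    if not s:
        raise CodeListError(f"empty clinical code for system {system.value}: {raw!r}")
    if system is System.READ2:
        value = s.rstrip(".")
        if not value:
            raise CodeListError(f"Read v2 code is all padding: {raw!r}")
        if len(value) > READ2_MAX_LEN:
            raise CodeListError(
                f"Read v2 code longer than {READ2_MAX_LEN} characters: {raw!r}"
            )
    else:
        value = s.replace(".", "").upper()
    if not (value.isascii() and value.isalnum()):
        raise CodeListError(f"invalid characters in {system.value} code: {raw!r}")
    return ClinicalCode(system, value)


@dataclass(frozen=True)
class CodeListEntry:
    """One rule of a code list: pattern + match mode + condition label."""

    system: System
    pattern: str
    match_mode: MatchMode
    condition: str
    category: str = ""

    def matches(self, code: ClinicalCode) -> bool:
        if code.system is not self.system:
            return False
        if self.match_mode is MatchMode.EXACT:
            return code.value == self.pattern
        return code.value.startswith(self.pattern)


@dataclass(frozen=True)
class CodeList:
    """A named, ordered collection of code-list entries."""

    name: str
    entries: tuple[CodeListEntry, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        if not self.entries:
            raise CodeListError(f"code list {self.name!r} has no entries")
        seen: dict[tuple, MatchMode] = {}
        for e in self.entries:
            key = (e.system, e.pattern, e.condition, e.category)
            if key in seen:
                if seen[key] is not e.match_mode:
                    raise CodeListError(
                        f"code list {self.name!r}: conflicting match modes for "
                        f"{e.system.value} {e.pattern!r} ({e.condition}/{e.category})"
                    )
                raise CodeListError(
                    f"code list {self.name!r}: duplicate entry "
                    f"{e.system.value} {e.pattern!r} ({e.condition}/{e.category})"
                )
            seen[key] = e.match_mode

    @property
    def conditions(self) -> set[str]:
        return {e.condition for e in self.entries}


def load_codelist(path: str | Path, name: str | None = None) -> CodeList:
    """Load a code list from delimited text.

    Format: comma-separated, UTF-8, header
    ``system,pattern,match_mode,condition,category`` (empty category allowed).
    Rows are normalized; exact duplicates collapse to one with a logged
    warning; unknown tokens or missing columns raise :class:`CodeListError`
    with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise CodeListError(f"code list file not found: {path}")
    entries: list[CodeListEntry] = []
    seen: dict[tuple, int] = {}
    n_dupes = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        missing = set(CODELIST_COLUMNS) - set(header)
        if missing:
            raise CodeListError(
                f"{path}: missing column(s) {sorted(missing)}; "
                f"expected header {','.join(CODELIST_COLUMNS)}"
            )
        for rownum, row in enumerate(reader, start=2):
            try:
                system = System(row["system"].strip())
            except ValueError:
                raise CodeListError(
                    f"{path}:{rownum}: unknown system {row['system']!r}"
                ) from None
            try:
                mode = MatchMode(row["match_mode"].strip().lower())
            except ValueError:
                raise CodeListError(
                    f"{path}:{rownum}: unknown match_mode {row['match_mode']!r}"
                ) from None
            try:
                code = normalize_code(row["pattern"], system)
            except CodeListError as exc:
                raise CodeListError(f"{path}:{rownum}: {exc}") from None
            condition = row["condition"].strip()
            if not condition:
                raise CodeListError(f"{path}:{rownum}: empty condition label")
            category = (row.get("category") or "").strip()
            key = (system, code.value, mode, condition, category)
            if key in seen:
                n_dupes += 1
                log.warning(
                    "%s:%d: duplicate of row %d collapsed (%s %s)",
                    path, rownum, seen[key], system.value, code.value,
                )
                continue
            seen[key] = rownum
            entries.append(CodeListEntry(system, code.value, mode, condition, category))
    if n_dupes:
        log.warning("%s: collapsed %d duplicate row(s)", path, n_dupes)
    return CodeList(name=name or path.stem, entries=tuple(entries))


class CodeMatcher:
    """Indexed matcher over one code list.

    Exact entries go into a hash map; prefix entries are scanned per system.
    Semantically identical to a brute-force scan over all entries, which the
    test suite uses as the independent oracle.
    """

    def __init__(self, codelist: CodeList) -> None:
        self.codelist = codelist
        self._exact: dict[tuple[System, str], set[tuple[str, str]]] = {}
        self._prefix: dict[System, list[tuple[str, str, str]]] = {}
        for e in codelist.entries:
            if e.match_mode is MatchMode.EXACT:
                self._exact.setdefault((e.system, e.pattern), set()).add(
                    (e.condition, e.category)
                )
            else:
                self._prefix.setdefault(e.system, []).append(
                    (e.pattern, e.condition, e.category)
                )

    def match(self, code: ClinicalCode) -> set[tuple[str, str]]:
        out = set(self._exact.get((code.system, code.value), ()))
        for pattern, condition, category in self._prefix.get(code.system, ()):
            if code.value.startswith(pattern):
                out.add((condition, category))
        return out

    def match_value(self, system: System | str, value: str) -> set[tuple[str, str]]:
        return self.match(ClinicalCode(System(system), value))


def match_code(code: ClinicalCode, codelist: CodeList) -> set[tuple[str, str]]:
    """Return the set of ``(condition, category)`` pairs recognising ``code``.

    Empty set means no match.  Order of code-list entries never matters.
    """
    return CodeMatcher(codelist).match(code)


def dementia_categories(codelist: CodeList, condition: str = "dementia") -> set[str]:
    """Distinct non-empty subtype categories declared for ``condition``."""
    return {e.category for e in codelist.entries if e.condition == condition and e.category}


def builtin_codelist(name: str) -> CodeList:
    """Load one of the fixture code lists shipped with the package."""
    if name not in BUILTIN_CODELISTS:
        raise CodeListError(
            f"unknown built-in code list {name!r}; available: {BUILTIN_CODELISTS}"
        )
    ref = resources.files("ecohort") / "codelists" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return load_codelist(path, name=name)
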