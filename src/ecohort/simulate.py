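"""Synthetic linked healthcare tables with known ground truth.

Generates the five linked tables a routine-data dementia cohort is built
from — demographics (with GP registration spells and a demographic-register
death date), primary-care events (Read v2), hospital episodes (ICD-10),
mortality records (ICD-9 before the coding cutover, ICD-10 after) and
per-person per-dataset linkage-quality scores — plus a ground-truth table of
true disease states for recovery testing.

The disease model is deliberately simple but carries the statistical
structure the downstream analysis assumes:

* dementia onset follows an exponential-in-age hazard,
  ``h(a) = h60 * 2**((a - 60) / doubling)``, with no onset before age 40;
* subtypes are drawn as *sets* (AD, VaD, mixed AD+VaD, DLB, FTD, or
  all-cause only), so subtype categories are non-exclusive by construction;
* each source (GP, hospital, death certificate) records a true case with its
  own probability and a positive onset-to-first-code delay;
* post-diagnosis mortality is high (configurable, default 79% dying before
  the administrative end of follow-up);
* causes of death switch from ICD-9 to ICD-10 coding at the cutover date;
* optional "dirty" records reproduce the defects real extracts contain:
  impossible birth dates, out-of-range death dates, missing GP registration
  dates, and dementia codes with invalid dates.

All randomness flows from ``SimConfig.seed``; identical configs give
byte-identical output tables.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codelist import ClinicalCode, CodeList, CodeMatcher, System, builtin_codelist

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SimTables",
    "generate_population",
    "inject_dirty_records",
    "simulate",
    "write_tables",
    "read_tables",
    "code_catalog",
]

LN2 = float(np.log(2.0))
DAYS_PER_YEAR = 365.25

SUBTYPE_SETS: dict[str, frozenset[str]] = {
    "none": frozenset(),
    "AD": frozenset({"AD"}),
    "VaD": frozenset({"VaD"}),
    "AD+VaD": frozenset({"AD", "VaD"}),
    "DLB": frozenset({"DLB"}),
    "FTD": frozenset({"FTD"}),
}

SOURCES = ("GP", "HOSP", "DEATH")
DIRTY_KINDS = (
    "dob_before_1900",
    "death_out_of_range",
    "missing_gp_registration",
    "invalid_dementia_date",
)
LINKAGE_DATASETS = ("WLGP", "PEDW", "ADDE", "WDSD")

# Non-dementia filler codes; anything that would match the dementia list is
# filtered out again at run time as a safety net.
_READ2_NOISE = ("H33z", "22K4", "246A", "9N19", "bd3j", "G20", "C109", "G573z",
                "1371", "137R", "C380", "G66z")
_ICD10_NOISE = ("J45", "M545", "K21", "N39", "I10", "E119", "I48", "I639", "E66")
_ICD9_CAUSE_NOISE = ("4149", "1629", "486", "431", "4019")
_ICD10_CAUSE_NOISE = ("I251", "C349", "J189", "I64", "I10")


class SimConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


def _date(x) -> np.datetime64:
    return np.datetime64(str(pd.Timestamp(x).date()), "D")


@dataclass
class SimConfig:
    """Parameters of the synthetic linked-data generator.

    Probabilities are per-person (or per-link) Bernoulli rates;
    ``p_record_source`` entries are the unconditional target fractions of
    true cases identified in each dataset; delays/scales are in years.
    """

    n_participants: int = 20_000
    birth_window: tuple = ("1895-01-01", "1975-01-01")
    admin_end: str = "2018-01-31"
    baseline_hazard_60: float = 0.002
    hazard_doubling_years: float = 6.0
    subtype_profile: dict = field(default_factory=lambda: {
        "none": 0.40, "AD": 0.305, "VaD": 0.215,
        "AD+VaD": 0.065, "DLB": 0.01, "FTD": 0.005,
    })
    p_record_source: dict = field(default_factory=lambda: {
        "GP": 0.61, "HOSP": 0.78, "DEATH": 0.40,
    })
    record_delay_scale: dict = field(default_factory=lambda: {"GP": 1.0, "HOSP": 1.5})
    p_death_after_dx: float = 0.79
    post_dx_survival_scale: float = 3.5
    p_wdsd_only_death: float = 0.07
    icd9_cutover: str = "2001-01-01"
    background_hazard_60: float = 0.025
    background_doubling_years: float = 8.0
    registration_window: tuple = ("1991-01-01", "2000-01-01")
    hospital_data_start: str = "1991-04-01"
    p_deregistration: float = 0.12
    p_second_spell: float = 0.05
    p_female: float = 0.52
    sex_missing_rate: float = 0.0005
    deprivation_missing_rate: float = 0.02
    gp_noise_rate: float = 3.0
    hosp_noise_rate: float = 0.6
    dirty_rates: dict = field(default_factory=lambda: {k: 0.0 for k in DIRTY_KINDS})
    p_low_linkage: float = 0.02
    seed: int = 0
    codelist: str = "dementia"

    def validate(self) -> None:
        if int(self.n_participants) <= 0:
            raise SimConfigError("n_participants must be positive")
        if _date(self.birth_window[0]) >= _date(self.birth_window[1]):
            raise SimConfigError("birth_window start must precede end")
        probs = {
            "p_death_after_dx": self.p_death_after_dx,
            "p_wdsd_only_death": self.p_wdsd_only_death,
            "p_deregistration": self.p_deregistration,
            "p_second_spell": self.p_second_spell,
            "p_female": self.p_female,
            "sex_missing_rate": self.sex_missing_rate,
            "deprivation_missing_rate": self.deprivation_missing_rate,
            "p_low_linkage": self.p_low_linkage,
        }
        for src in SOURCES:
            if src not in self.p_record_source:
                raise SimConfigError(f"p_record_source missing source {src!r}")
            probs[f"p_record_source[{src}]"] = self.p_record_source[src]
        for kind, rate in self.dirty_rates.items():
            if kind not in DIRTY_KINDS:
                raise SimConfigError(f"unknown dirty_rates key {kind!r}")
            probs[f"dirty_rates[{kind}]"] = rate
        for name, p in probs.items():
            if not (0.0 <= float(p) <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1], got {p}")
        unknown = set(self.subtype_profile) - set(SUBTYPE_SETS)
        if unknown:
            raise SimConfigError(f"unknown subtype_profile keys {sorted(unknown)}")
        total = float(sum(self.subtype_profile.values()))
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"subtype_profile must sum to 1, got {total}")
        if any(v < 0 for v in self.subtype_profile.values()):
            raise SimConfigError("subtype_profile probabilities must be >= 0")
        for par in ("baseline_hazard_60", "hazard_doubling_years",
                    "background_hazard_60", "background_doubling_years",
                    "post_dx_survival_scale", "gp_noise_rate", "hosp_noise_rate"):
            if float(getattr(self, par)) <= 0 and par not in ("gp_noise_rate", "hosp_noise_rate"):
                raise SimConfigError(f"{par} must be positive")
            if float(getattr(self, par)) < 0:
                raise SimConfigError(f"{par} must be >= 0")
        for src in ("GP", "HOSP"):
            if float(self.record_delay_scale.get(src, -1)) <= 0:
                raise SimConfigError(f"record_delay_scale[{src}] must be positive")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SimConfigError(f"unknown SimConfig field(s): {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        for name in ("birth_window", "registration_window"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg


@dataclass
class SimTables:
    """The generated linked tables (pandas DataFrames)."""

    demographics: pd.DataFrame
    gp_events: pd.DataFrame
    hospital_episodes: pd.DataFrame
    mortality: pd.DataFrame
    linkage_quality: pd.DataFrame
    ground_truth: pd.DataFrame

    def copy(self) -> "SimTables":
        return SimTables(**{f.name: getattr(self, f.name).copy()
                            for f in dataclasses.fields(self)})


def _gompertz_age(rng, hazard60: float, doubling: float, floor_age) -> np.ndarray:
    """Sample event ages from h(a) = hazard60 * 2**((a-60)/doubling), a >= floor."""
    b = LN2 / doubling
    floor_age = np.asarray(floor_age, dtype=float)
    e = rng.exponential(1.0, size=floor_age.shape if floor_age.ndim else None)
    e = np.atleast_1d(e)
    return 60.0 + np.log(b * e / hazard60 + np.exp(b * (floor_age - 60.0))) / b


def _trunc_exp_days(rng, scale_years: float, upper_days: np.ndarray) -> np.ndarray:
    """Exponential delays (days) truncated to [0, upper_days]."""
    upper = np.maximum(np.asarray(upper_days, dtype=float), 0.0)
    scale = scale_years * DAYS_PER_YEAR
    u = rng.random(len(upper))
    cdf = -np.expm1(-upper / scale)
    return np.floor(-scale * np.log1p(-u * cdf)).astype(np.int64)


def code_catalog(codelist: CodeList) -> dict[tuple[System, str], list[str]]:
    """Concrete example code values per (system, category) for one condition list.

    For each entry, candidate values (the pattern itself plus short
    extensions for prefix entries) are kept only if matching them against
    the *full* list yields exactly the entry's category (subtypes) or no
    non-empty category at all (all-cause), so generated events can never
    encode an unintended subtype.
    """
    matcher = CodeMatcher(codelist)
    catalog: dict[tuple[System, str], list[str]] = {}
    for entry in codelist.entries:
        candidates = [entry.pattern]
        if entry.match_mode.value == "prefix":
            suffixes = "0123z" if entry.system is System.READ2 else "012389"
            limit = 5 if entry.system is System.READ2 else 6
            candidates += [entry.pattern + c for c in suffixes
                           if len(entry.pattern) + 1 <= limit]
        for cand in candidates:
            pairs = matcher.match(ClinicalCode(entry.system, cand))
            if {cond for cond, _ in pairs} != {entry.condition}:
                continue
            nonempty = {cat for _, cat in pairs if cat}
            ok = nonempty == {entry.category} if entry.category else not nonempty
            if ok:
                bucket = catalog.setdefault((entry.system, entry.category), [])
                if cand not in bucket:
                    bucket.append(cand)
    return catalog


def _pick(rng, seq):
    return seq[int(rng.integers(0, len(seq)))]


def generate_population(config: SimConfig) -> SimTables:
    """Generate clean linked tables (no dirty records) with ground truth."""
    config.validate()
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 11])
    n = int(config.n_participants)
    ids = np.arange(1, n + 1, dtype=np.int64)

    birth0, birth1 = _date(config.birth_window[0]), _date(config.birth_window[1])
    admin = _date(config.admin_end)
    reg0, reg1 = (_date(config.registration_window[0]),
                  _date(config.registration_window[1]))
    hosp_start = _date(config.hospital_data_start)
    cutover = _date(config.icd9_cutover)

    dob = birth0 + rng.integers(0, int((birth1 - birth0) / np.timedelta64(1, "D")) + 1,
                                n).astype("timedelta64[D]")

    sex = np.where(rng.random(n) < config.p_female, "F", "M").astype(object)
    sex[rng.random(n) < config.sex_missing_rate] = ""
    quintile = rng.integers(1, 6, n).astype(float)
    quintile[rng.random(n) < config.deprivation_missing_rate] = np.nan

    # GP registration: adults registering during the digital-records era.
    reg_lo = np.maximum(dob + np.timedelta64(int(16 * DAYS_PER_YEAR), "D"), reg0)
    reg_lo = np.minimum(reg_lo, reg1)
    span = ((reg1 - reg_lo) / np.timedelta64(1, "D")).astype(np.int64)
    reg = reg_lo + (rng.random(n) * (span + 1)).astype(np.int64).astype("timedelta64[D]")
    reg_age = ((reg - dob) / np.timedelta64(1, "D")).astype(float) / DAYS_PER_YEAR
    admin_age = ((admin - dob) / np.timedelta64(1, "D")).astype(float) / DAYS_PER_YEAR

    # Background (non-dementia) death age, conditioned on surviving to registration.
    bg_death_age = _gompertz_age(rng, config.background_hazard_60,
                                 config.background_doubling_years, reg_age)
    # Dementia onset age: no onset before 40, and left-truncated at
    # registration (participants are dementia-free when they enter, so all
    # cases are incident during follow-up).
    onset_age = _gompertz_age(rng, config.baseline_hazard_60,
                              config.hazard_doubling_years,
                              np.maximum(40.0, reg_age))
    is_case = onset_age < np.minimum(bg_death_age, admin_age)
    onset = dob + np.round(onset_age * DAYS_PER_YEAR).astype(np.int64).astype("timedelta64[D]")

    # Deaths. Cases die before admin_end with p_death_after_dx; non-cases per
    # the background hazard.
    died = np.zeros(n, dtype=bool)
    death = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")

    noncase = ~is_case
    bg_death = dob + np.round(bg_death_age * DAYS_PER_YEAR).astype(np.int64).astype("timedelta64[D]")
    nc_dies = noncase & (bg_death <= admin)
    died[nc_dies] = True
    death[nc_dies] = np.maximum(bg_death[nc_dies], reg[nc_dies] + np.timedelta64(1, "D"))

    case_idx = np.flatnonzero(is_case)
    case_dies = rng.random(len(case_idx)) < config.p_death_after_dx
    ci = case_idx[case_dies]
    base = np.maximum(onset[ci], reg[ci]) + np.timedelta64(1, "D")
    upper = ((admin - base) / np.timedelta64(1, "D")).astype(np.int64)
    delay = _trunc_exp_days(rng, config.post_dx_survival_scale, upper)
    death[ci] = base + delay.astype("timedelta64[D]")
    died[ci] = True

    # Exit bound for event generation (death, else administrative end).
    exit_ev = np.where(died, death, admin).astype("datetime64[D]")

    # De-registration for non-case survivors only; second (gap) spells for a
    # small fraction of them to exercise gap-censoring.
    alive_noncase = noncase & ~died
    dereg = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    do_dereg = alive_noncase & (rng.random(n) < config.p_deregistration)
    span_d = ((admin - reg) / np.timedelta64(1, "D")).astype(np.int64)
    dereg_off = (rng.random(n) * np.maximum(span_d - 1, 1)).astype(np.int64) + 1
    dereg[do_dereg] = (reg + dereg_off.astype("timedelta64[D]"))[do_dereg]
    exit_ev = np.minimum(exit_ev, np.where(do_dereg, dereg, admin).astype("datetime64[D]"))

    two_spells = alive_noncase & ~do_dereg & (rng.random(n) < config.p_second_spell)

    def _fmt(d) -> str:
        return "" if np.isnat(d) else str(d.astype("datetime64[D]"))

    spells = []
    gap_lo = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    gap_hi = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    for i in range(n):
        if two_spells[i]:
            total = int((admin - reg[i]) / np.timedelta64(1, "D"))
            if total > 400:
                a = reg[i] + np.timedelta64(int(total * 0.4), "D")
                b = reg[i] + np.timedelta64(int(total * 0.5), "D")
                gap_lo[i], gap_hi[i] = a, b
                spells.append(f"{_fmt(reg[i])}:{_fmt(a)};{_fmt(b)}:")
                continue
        end = dereg[i] if do_dereg[i] else np.datetime64("NaT")
        spells.append(f"{_fmt(reg[i])}:{_fmt(end)}")
    spells = np.asarray(spells, dtype=object)

    wdsd_death = death.copy()  # demographic register knows all deaths

    # Mortality records: most deaths get a certificate record; a small
    # fraction are known only to the demographic register.
    has_mort_record = died & (rng.random(n) >= config.p_wdsd_only_death)

    # Per-source dementia recording.
    p = config.p_record_source
    p_known_death = config.p_death_after_dx * (1.0 - config.p_wdsd_only_death)
    p_death_code = min(1.0, p["DEATH"] / p_known_death) if p_known_death > 0 else 0.0
    has_gp = is_case & (rng.random(n) < p["GP"])
    has_hosp = is_case & (rng.random(n) < p["HOSP"])
    has_death_code = is_case & has_mort_record & (rng.random(n) < p_death_code)

    # Subtype sets per case.
    keys = sorted(SUBTYPE_SETS)
    weights = np.array([config.subtype_profile.get(k, 0.0) for k in keys])
    weights = weights / weights.sum()
    subtype_draw = rng.choice(len(keys), size=n, p=weights)
    true_subtypes = [sorted(SUBTYPE_SETS[keys[subtype_draw[i]]]) if is_case[i] else []
                     for i in range(n)]

    # Dementia event dates per source (positive truncated-exponential delays,
    # clipped into each source's observable window).
    gp_base = np.maximum(onset, reg)
    gp_upper = ((exit_ev - gp_base) / np.timedelta64(1, "D")).astype(np.int64)
    gp_date = gp_base + _trunc_exp_days(rng, config.record_delay_scale["GP"],
                                        gp_upper).astype("timedelta64[D]")
    hosp_base = np.maximum(onset, hosp_start)
    hosp_upper = ((exit_ev - hosp_base) / np.timedelta64(1, "D")).astype(np.int64)
    hosp_date = hosp_base + _trunc_exp_days(rng, config.record_delay_scale["HOSP"],
                                            hosp_upper).astype("timedelta64[D]")

    # Concrete codes from the configured code list.
    catalog = code_catalog(builtin_codelist(config.codelist)
                           if isinstance(config.codelist, str) else config.codelist)
    dem_matcher = CodeMatcher(builtin_codelist(config.codelist)
                              if isinstance(config.codelist, str) else config.codelist)

    def _clean_noise(pool, system):
        return [c for c in pool
                if not dem_matcher.match(ClinicalCode(system, c.upper().replace(".", "")
                                                      if system is not System.READ2 else c))]

    read_noise = _clean_noise(_READ2_NOISE, System.READ2)
    icd10_noise = _clean_noise(_ICD10_NOISE, System.ICD10)
    icd9_cause = _clean_noise(_ICD9_CAUSE_NOISE, System.ICD9)
    icd10_cause = _clean_noise(_ICD10_CAUSE_NOISE, System.ICD10)

    def _code_for(system: System, category: str) -> str:
        options = catalog.get((system, category))
        if not options:  # no concrete code for this (system, category)
            options = catalog[(system, "")]
        return _pick(rng, options)

    gp_rows: list[tuple[int, np.datetime64, str]] = []
    hosp_rows: list[tuple[int, np.datetime64, str]] = []
    mort_codes: dict[int, list[str]] = {}

    for i in case_idx:
        recorded = [s for s, flag in (("GP", has_gp[i]), ("HOSP", has_hosp[i]),
                                      ("DEATH", has_death_code[i])) if flag]
        if not recorded:
            continue
        # each true subtype is coded in one recorded source
        per_source: dict[str, list[str]] = {s: [] for s in recorded}
        for cat in true_subtypes[i]:
            per_source[recorded[int(rng.integers(0, len(recorded)))]].append(cat)
        death_sys = (System.ICD9 if died[i] and death[i] < cutover else System.ICD10)
        for src in recorded:
            cats = per_source[src] or [""]
            if src == "GP":
                for cat in cats:
                    gp_rows.append((ids[i], gp_date[i], _code_for(System.READ2, cat)))
            elif src == "HOSP":
                codes = [_code_for(System.ICD10, cat) for cat in cats]
                if rng.random() < 0.3:
                    codes.append(_pick(rng, icd10_noise))
                hosp_rows.append((ids[i], hosp_date[i], ";".join(codes)))
            else:
                mort_codes[int(ids[i])] = [_code_for(death_sys, cat) for cat in cats]

    # Noise events (non-dementia codes) for all persons.
    def _noise_events(rate, base_dates, upper_dates, pool):
        counts = rng.poisson(rate, n)
        owners = np.repeat(np.arange(n), counts)
        if len(owners) == 0:
            return np.empty(0, np.int64), np.empty(0, "datetime64[D]"), []
        spans = ((upper_dates - base_dates) / np.timedelta64(1, "D")).astype(np.int64)
        spans = np.maximum(spans, 0)
        offs = (rng.random(len(owners)) * (spans[owners] + 1)).astype(np.int64)
        dates = base_dates[owners] + offs.astype("timedelta64[D]")
        codes = [_pick(rng, pool) for _ in range(len(owners))]
        return ids[owners], dates, codes

    gp_noise_ids, gp_noise_dates, gp_noise_codes = _noise_events(
        config.gp_noise_rate, reg, exit_ev, read_noise)
    # keep GP events out of registration gaps (two-spell persons)
    if len(gp_noise_ids):
        pos = gp_noise_ids - 1  # ids are 1..n
        lo, hi = gap_lo[pos], gap_hi[pos]
        in_gap = ~np.isnat(lo) & (gp_noise_dates > lo) & (gp_noise_dates < hi)
        gp_noise_dates = np.where(in_gap, hi, gp_noise_dates)
    hb = np.maximum(reg, hosp_start)
    hosp_noise_ids, hosp_noise_dates, hosp_noise_codes = _noise_events(
        config.hosp_noise_rate, hb, np.maximum(exit_ev.astype("datetime64[D]"), hb),
        icd10_noise)

    gp_events = pd.DataFrame({
        "person_id": np.concatenate([np.array([r[0] for r in gp_rows], np.int64),
                                     gp_noise_ids]),
        "event_date": pd.to_datetime(np.concatenate(
            [np.array([r[1] for r in gp_rows], "datetime64[D]"), gp_noise_dates])),
        "code": [r[2] for r in gp_rows] + list(gp_noise_codes),
    })
    hosp = pd.DataFrame({
        "person_id": np.concatenate([np.array([r[0] for r in hosp_rows], np.int64),
                                     hosp_noise_ids]),
        "admission_date": pd.to_datetime(np.concatenate(
            [np.array([r[1] for r in hosp_rows], "datetime64[D]"), hosp_noise_dates])),
        "codes": [r[2] for r in hosp_rows] + list(hosp_noise_codes),
    })

    mort_ids = ids[has_mort_record]
    mort_dates = death[has_mort_record]
    mort_rows = []
    for pid, d in zip(mort_ids, mort_dates):
        base_pool = icd9_cause if d < cutover else icd10_cause
        codes = list(mort_codes.get(int(pid), [])) + [_pick(rng, base_pool)]
        mort_rows.append((int(pid), d, ";".join(codes)))
    mortality = pd.DataFrame(mort_rows, columns=["person_id", "death_date", "cause_codes"])
    mortality["person_id"] = mortality["person_id"].astype(np.int64)
    mortality["death_date"] = pd.to_datetime(mortality["death_date"])

    lq_person = np.repeat(ids, len(LINKAGE_DATASETS))
    lq_ds = np.tile(np.array(LINKAGE_DATASETS, object), n)
    low = rng.random(len(lq_person)) < config.p_low_linkage
    q = np.where(low, 0.5 + 0.449 * rng.random(len(lq_person)),
                 0.95 + 0.05 * rng.random(len(lq_person)))
    linkage = pd.DataFrame({
        "person_id": lq_person,
        "dataset": lq_ds,
        "match_probability": np.round(q, 4),
    })

    demographics = pd.DataFrame({
        "person_id": ids,
        "dob": pd.to_datetime(dob),
        "sex": sex,
        "deprivation_quintile": pd.array(
            [int(v) if not np.isnan(v) else None for v in quintile], dtype="Int64"),
        "gp_spells": spells,
        "wdsd_death_date": pd.to_datetime(wdsd_death),
    })

    ground_truth = pd.DataFrame({
        "person_id": ids,
        "true_dementia": is_case.astype(np.int8),
        "true_onset_date": pd.to_datetime(
            np.where(is_case, onset, np.datetime64("NaT", "D"))),
        "true_subtypes": ["|".join(true_subtypes[i]) for i in range(n)],
        "dirty_flags": [""] * n,
    })

    def _sorted(df, cols):
        df = df.sort_values(cols, kind="mergesort").reset_index(drop=True)
        for col in df.columns:
            if df[col].dtype.kind == "M":
                df[col] = df[col].astype("datetime64[ns]")
        return df

    return SimTables(
        demographics=_sorted(demographics, ["person_id"]),
        gp_events=_sorted(gp_events, ["person_id", "event_date", "code"]),
        hospital_episodes=_sorted(hosp, ["person_id", "admission_date", "codes"]),
        mortality=_sorted(mortality, ["person_id", "death_date"]),
        linkage_quality=_sorted(linkage, ["person_id", "dataset"]),
        ground_truth=_sorted(ground_truth, ["person_id"]),
    )


def inject_dirty_records(tables: SimTables, config: SimConfig
                         ) -> tuple[SimTables, dict[str, int]]:
    """Inject the configured data defects; returns new tables + counts.

    Defect assignment is disjoint across defect types (one permutation of
    persons, binomially sized slices), so every excluded person can be
    attributed to exactly one injected defect.  Each injection is recorded in
    ``ground_truth.dirty_flags``.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 29])
    t = tables.copy()
    demo = t.demographics
    n = len(demo)
    person_ids = demo["person_id"].to_numpy()

    rates = {k: float(config.dirty_rates.get(k, 0.0)) for k in DIRTY_KINDS}
    counts = {k: int(rng.binomial(n, r)) if r > 0 else 0 for k, r in rates.items()}
    while sum(counts.values()) > n:  # pathological rates; trim largest
        kmax = max(counts, key=counts.get)
        counts[kmax] -= 1
    perm = rng.permutation(person_ids)
    assigned: dict[str, np.ndarray] = {}
    pos = 0
    for kind in DIRTY_KINDS:
        assigned[kind] = perm[pos:pos + counts[kind]]
        pos += counts[kind]

    flags = dict(zip(t.ground_truth["person_id"], t.ground_truth["dirty_flags"]))

    def _flag(pid, kind):
        cur = flags.get(pid, "")
        flags[pid] = f"{cur}|{kind}" if cur else kind

    idx = {pid: i for i, pid in enumerate(person_ids)}

    # dob before 1900
    for pid in assigned["dob_before_1900"]:
        day = int(rng.integers(0, 7300))  # 1880..1899
        demo.loc[demo.index[idx[pid]], "dob"] = (
            pd.Timestamp("1880-01-01") + pd.Timedelta(days=day))
        _flag(pid, "dob_before_1900")

    # death date outside [1980-01-01, 2020-01-01]
    mort = t.mortality
    extra_rows = []
    for pid in assigned["death_out_of_range"]:
        if rng.random() < 0.5:
            bad = pd.Timestamp("1950-01-01") + pd.Timedelta(days=int(rng.integers(0, 9000)))
        else:
            bad = pd.Timestamp("2020-01-02") + pd.Timedelta(days=int(rng.integers(0, 1500)))
        hit = mort["person_id"] == pid
        if hit.any():
            mort.loc[hit, "death_date"] = bad
        else:
            extra_rows.append({"person_id": pid, "death_date": bad,
                               "cause_codes": "R99" if bad.year > 2000 else "7999"})
        _flag(pid, "death_out_of_range")
    if extra_rows:
        mort = pd.concat([mort, pd.DataFrame(extra_rows)], ignore_index=True)
        mort["person_id"] = mort["person_id"].astype(np.int64)
        t.mortality = mort.sort_values(["person_id", "death_date"],
                                       kind="mergesort").reset_index(drop=True)

    # missing GP registration dates
    for j, pid in enumerate(assigned["missing_gp_registration"]):
        row = demo.index[idx[pid]]
        if j % 2 == 0:
            demo.loc[row, "gp_spells"] = ""          # no spell at all
        else:
            old = str(demo.loc[row, "gp_spells"])
            end = old.split(";")[0].partition(":")[2]
            demo.loc[row, "gp_spells"] = f":{end}"   # spell missing its start
        _flag(pid, "missing_gp_registration")

    # dementia code with an invalid (pre-1900) date -> earliest code invalid
    dem_list = builtin_codelist(config.codelist) if isinstance(config.codelist, str) \
        else config.codelist
    allcause = code_catalog(dem_list).get((System.READ2, ""), ["Eu020"])
    bad_gp = []
    for pid in assigned["invalid_dementia_date"]:
        day = int(rng.integers(0, 1000))
        bad_gp.append({
            "person_id": pid,
            "event_date": pd.Timestamp("1897-01-01") + pd.Timedelta(days=day),
            "code": allcause[int(rng.integers(0, len(allcause)))],
        })
        _flag(pid, "invalid_dementia_date")
    if bad_gp:
        gp = pd.concat([t.gp_events, pd.DataFrame(bad_gp)], ignore_index=True)
        gp["person_id"] = gp["person_id"].astype(np.int64)
        t.gp_events = gp.sort_values(["person_id", "event_date", "code"],
                                     kind="mergesort").reset_index(drop=True)

    t.ground_truth["dirty_flags"] = [flags.get(pid, "")
                                     for pid in t.ground_truth["person_id"]]
    return t, counts


def simulate(config: SimConfig) -> SimTables:
    """Generate a population and apply the configured dirty-record injection."""
    tables = generate_population(config)
    if any(v > 0 for v in config.dirty_rates.values()):
        tables, _ = inject_dirty_records(tables, config)
    return tables


_DATE_COLS = {
    "demographics": ["dob", "wdsd_death_date"],
    "gp_events": ["event_date"],
    "hospital_episodes": ["admission_date"],
    "mortality": ["death_date"],
    "linkage_quality": [],
    "ground_truth": ["true_onset_date"],
}
_STR_COLS = {
    "demographics": ["sex", "gp_spells"],
    "gp_events": ["code"],
    "hospital_episodes": ["codes"],
    "mortality": ["cause_codes"],
    "linkage_quality": ["dataset"],
    "ground_truth": ["true_subtypes", "dirty_flags"],
}


def write_tables(tables: SimTables, directory: str | Path) -> None:
    """Write all six tables as CSV (ISO dates, empty field = missing)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _DATE_COLS:
        df = getattr(tables, name)
        df.to_csv(directory / f"{name}.csv", index=False, date_format="%Y-%m-%d")


def read_tables(directory: str | Path, require_ground_truth: bool = False) -> SimTables:
    """Read tables written by :func:`write_tables`; round-trips exactly."""
    directory = Path(directory)
    frames = {}
    for name, date_cols in _DATE_COLS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            if name == "ground_truth" and not require_ground_truth:
                frames[name] = pd.DataFrame(
                    columns=["person_id", "true_dementia", "true_onset_date",
                             "true_subtypes", "dirty_flags"])
                continue
            raise FileNotFoundError(f"missing input table: {path}")
        dtype: dict = {"person_id": np.int64}
        if name == "demographics":
            dtype["deprivation_quintile"] = "Int64"
        if name == "ground_truth":
            dtype["true_dementia"] = np.int8
        try:
            df = pd.read_csv(path, dtype=dtype, parse_dates=date_cols)
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"malformed table file {path}: {exc}") from None
        for col in _STR_COLS[name]:
            if col in df.columns:
                df[col] = df[col].fillna("").astype(object)
        for col in date_cols:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).astype("datetime64[ns]")
        frames[name] = df
    return SimTables(**frames)
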