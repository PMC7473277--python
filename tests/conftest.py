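"""Shared fixtures: fixture code lists and session-scoped synthetic cohorts.

The large simulations are generated once per session.  Their configuration
matches the study conditions the recovery checks assume: clean runs use a
birth window identical to the eligibility window (so exclusions cannot
interact with recovery denominators) and a diagnosis-date validity window
ending at the administrative end of follow-up.
"""
from __future__ import annotations

import pandas as pd
import pytest

import ecohort as ec

ADMIN_END = pd.Timestamp("2018-01-31")


def recovery_sim_config(**overrides) -> ec.SimConfig:
    base = dict(
        n_participants=20_000,
        birth_window=("1900-01-01", "1958-01-01"),
        seed=20_2601,
    )
    base.update(overrides)
    return ec.SimConfig(**base)


def recovery_params() -> ec.PipelineParams:
    return ec.PipelineParams(
        dementia_valid_window=(pd.Timestamp("1900-01-01"), ADMIN_END))


@pytest.fixture(scope="session")
def dementia_list() -> ec.CodeList:
    return ec.builtin_codelist("dementia")


@pytest.fixture(scope="session")
def comorbidity_lists() -> dict[str, ec.CodeList]:
    return {n: ec.builtin_codelist(n)
            for n in ec.BUILTIN_CODELISTS if n != "dementia"}


@pytest.fixture(scope="session")
def sim_clean() -> ec.SimTables:
    """20k persons, no dirty records, birth window == eligibility window."""
    return ec.generate_population(recovery_sim_config())


@pytest.fixture(scope="session")
def built_clean(sim_clean, dementia_list) -> ec.BuildResult:
    return ec.build_cohort(sim_clean, dementia_list, params=recovery_params())


@pytest.fixture(scope="session")
def sim_dirty() -> ec.SimTables:
    """20k persons with 5% of each dirty-record defect injected."""
    cfg = recovery_sim_config(
        seed=20_2602,
        dirty_rates={k: 0.05 for k in
                     ("dob_before_1900", "death_out_of_range",
                      "missing_gp_registration", "invalid_dementia_date")})
    return ec.simulate(cfg)


@pytest.fixture(scope="session")
def built_dirty(sim_dirty, dementia_list) -> ec.BuildResult:
    return ec.build_cohort(sim_dirty, dementia_list, params=recovery_params())


def make_tiny_codelist() -> ec.CodeList:
    """A small hand-built list exercising both match modes and categories."""
    E = ec.CodeListEntry
    S, M = ec.System, ec.MatchMode
    return ec.CodeList("dementia_tiny", (
        E(S.ICD10, "F00", M.PREFIX, "dementia", "AD"),
        E(S.ICD10, "F01", M.PREFIX, "dementia", "VaD"),
        E(S.ICD10, "F03", M.PREFIX, "dementia", ""),
        E(S.ICD9, "290", M.PREFIX, "dementia", ""),
        E(S.ICD9, "3310", M.EXACT, "dementia", "AD"),
        E(S.READ2, "Eu02", M.PREFIX, "dementia", ""),
        E(S.READ2, "Eu02z", M.EXACT, "dementia", "VaD"),
    ))


@pytest.fixture()
def tiny_codelist() -> ec.CodeList:
    return make_tiny_codelist()
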