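"""Run configuration: one YAML file driving simulate, build and summarize.

Layout (all keys optional; defaults reproduce the documented study
constants)::

    sim:                      # SimConfig fields
      n_participants: 20000
      seed: 1
    pipeline:                 # PipelineParams fields
      birth_window: ["1900-01-01", "1958-01-01"]
      admin_end: "2018-01-31"
      linkage_threshold: 0.95
    codelists:
      dementia: "builtin:dementia"
      comorbidities: ["builtin:hypertension", "builtin:diabetes", ...]
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .codelist import BUILTIN_CODELISTS, CodeList, builtin_codelist, load_codelist
from .pipeline import PipelineParams
from .simulate import SimConfig

__all__ = ["RunConfig", "ConfigError", "load_run_config", "resolve_codelist"]

DEFAULT_COMORBIDITIES = tuple(f"builtin:{n}" for n in BUILTIN_CODELISTS if n != "dementia")


class ConfigError(ValueError):
    """Invalid run configuration."""


def resolve_codelist(spec: str) -> CodeList:
    """Resolve ``builtin:<name>`` or a file path to a loaded code list."""
    if spec.startswith("builtin:"):
        return builtin_codelist(spec.split(":", 1)[1])
    return load_codelist(spec)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    dementia_codelist: str = "builtin:dementia"
    comorbidity_codelists: tuple = DEFAULT_COMORBIDITIES

    def dementia_list(self) -> CodeList:
        return resolve_codelist(self.dementia_codelist)

    def comorbidity_lists(self) -> dict[str, CodeList]:
        lists = [resolve_codelist(s) for s in self.comorbidity_codelists]
        return {cl.name: cl for cl in lists}


def _pipeline_from_dict(d: dict) -> PipelineParams:
    known = {f.name for f in dataclasses.fields(PipelineParams)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown pipeline field(s): {sorted(unknown)}")
    kw = dict(d)
    for key in ("admin_end", "dob_min", "icd9_cutover"):
        if key in kw:
            kw[key] = pd.Timestamp(kw[key])
    for key in ("birth_window", "death_valid_window", "dementia_valid_window"):
        if key in kw:
            kw[key] = tuple(pd.Timestamp(x) for x in kw[key])
    if "tie_break" in kw:
        kw["tie_break"] = tuple(kw["tie_break"])
    return PipelineParams(**kw)


def load_run_config(path: str | Path | None = None) -> RunConfig:
    """Load a run configuration; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = set(raw) - {"sim", "pipeline", "codelists"}
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    sim = SimConfig.from_dict(raw.get("sim") or {})
    pipe = _pipeline_from_dict(raw.get("pipeline") or {})
    cl = raw.get("codelists") or {}
    return RunConfig(
        sim=sim,
        pipeline=pipe,
        dementia_codelist=cl.get("dementia", "builtin:dementia"),
        comorbidity_codelists=tuple(cl.get("comorbidities", DEFAULT_COMORBIDITIES)),
    )
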