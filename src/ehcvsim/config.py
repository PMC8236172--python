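"""Run configuration loading and result export.

Configs are YAML (or JSON) files validated against a strict schema:
unknown keys are rejected with a closest-match suggestion, defaults are
filled in (2009-2032 horizon, weekly steps), and the fixture/scenario
references are resolved to package objects.  Every run writes a
manifest alongside its outputs: config hash, scenario name, fixture
provenance summary, software version and timestamp.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .bands import WEEKS_PER_YEAR
from .engine import SimulationConfig, SimulationOutput
from .errors import ValidationError
from .fixtures import FixtureBundle, hk_anchor_fixture
from .policy import BUILTIN_SCENARIOS, ScenarioSpec, get_scenario


class RunConfig(BaseModel, extra="forbid"):
    """Schema of a run configuration file."""

    fixture_path: str = "hk_anchored"
    scenario_name: str = "baseline"
    scenario_path: str | None = None
    start_year: int = 2009
    end_year: int = 2032
    dt_weeks: float = 1.0
    output_path: str = "results"
    log_level: str = "INFO"
    seed: int = Field(default=0, description="used only by synthetic fixture generation")

    @field_validator("dt_weeks")
    @classmethod
    def _dt_divides_year(cls, v: float) -> float:
        steps = WEEKS_PER_YEAR / v if v > 0 else 0
        if v <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ValueError(f"dt_weeks must be a positive divisor of {WEEKS_PER_YEAR}, got {v}")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON config file.

    Unknown keys raise with a did-you-mean suggestion against the known
    schema fields.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config root must be a mapping, got {type(raw).__name__}")
    known = set(RunConfig.model_fields)
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValidationError(f"unknown config key {key!r}{suffix}")
    try:
        return RunConfig(**raw)
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def resolve_fixture(cfg: RunConfig) -> FixtureBundle:
    if cfg.fixture_path == "hk_anchored":
        return hk_anchor_fixture()
    return FixtureBundle.load(cfg.fixture_path)


def resolve_scenario(cfg: RunConfig, name: str | None = None) -> ScenarioSpec:
    if cfg.scenario_path is not None and name is None:
        data = yaml.safe_load(Path(cfg.scenario_path).read_text())
        return ScenarioSpec(
            name=data["name"], events=tuple((e["year"], e["attribute"], e["value"]) for e in data.get("events", []))
        )
    return get_scenario(name or cfg.scenario_name)


def to_simulation_config(cfg: RunConfig, scenario: ScenarioSpec | None = None) -> SimulationConfig:
    return SimulationConfig(
        fixture=resolve_fixture(cfg),
        scenario=scenario if scenario is not None else resolve_scenario(cfg),
        start_year=cfg.start_year,
        end_year=cfg.end_year,
        dt=cfg.dt_weeks,
    )


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    output: SimulationOutput,
    path: str | Path,
    cfg: RunConfig | None = None,
    comparisons: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the annual-records CSV, optional comparisons CSV, and manifest.

    Currency columns are exported as rounded integers; a read-back of
    the CSV reproduces the exported values exactly.
    """
    from . import __version__

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    records = output.records.copy()
    records["expenditure_hkd"] = records["expenditure_hkd"].round().astype("int64")
    csv_path = outdir / f"{output.scenario}_annual.csv"
    records.to_csv(csv_path, index=False)
    paths = {"records": csv_path}

    if comparisons is not None and len(comparisons):
        cmp_path = outdir / "comparisons.csv"
        comparisons.to_csv(cmp_path, index=False)
        paths["comparisons"] = cmp_path

    fixture_prov = {}
    if cfg is not None:
        fixture_prov = resolve_fixture(cfg).provenance
    manifest = {
        "scenario": output.scenario,
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "fixture_provenance": fixture_prov,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    manifest_path = outdir / f"{output.scenario}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
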