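"""Scenario configuration: schema, TOML round-trip, multi-seed runs.

A scenario file is TOML with an ``[engine]`` block (time step, iteration
count, seed), exactly one scenario block (``[sir]``, ``[spheroid]`` or
``[pyramidal]``) and an optional ``[output]`` block.  Validation is
strict: unknown keys are rejected so typos fail loudly, probabilities
must lie in [0, 1] and lengths/rates must be positive.

``run_scenario`` executes ``repeats`` independent runs with consecutive
seeds (base, base+1, ...), writes one CSV per seed plus a summary CSV
with mean/min/max per column across seeds.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    """Scenario configuration failed validation."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EngineConfig(_StrictModel):
    time_step: float = Field(1.0, gt=0)
    n_iterations: int = Field(100, ge=0)
    rng_seed: int = 0


class SirConfig(_StrictModel):
    disease: Optional[Literal["measles", "influenza"]] = None
    n_total: int = Field(2010, gt=0)
    n_infected_initial: int = Field(10, gt=0)
    infection_radius: float = Field(8.0, gt=0)
    p_infection: float = Field(0.5, ge=0, le=1)
    p_recovery: float = Field(0.125, ge=0, le=1)
    max_step: float = Field(25.0, ge=0)
    box_side: float = Field(100.0, gt=0)


class SpheroidConfig(_StrictModel):
    n_initial_cells: int = Field(2000, gt=0)
    volume_growth_rate: float = Field(30.0, gt=0)
    division_diameter: float = Field(14.0, gt=0)
    migration_sigma: float = Field(0.5, ge=0)
    p_apoptosis: float = Field(0.0, ge=0, le=1)
    initial_diameter: float = Field(10.0, gt=0)
    cadence_hours: float = Field(24.0, gt=0)


class PyramidalConfig(_StrictModel):
    n_cells: int = Field(1, gt=0)


class OutputConfig(_StrictModel):
    out_dir: str = "out"
    collection_frequency: int = Field(1, ge=1)


class ScenarioConfig(_StrictModel):
    scenario: Literal["sir", "spheroid", "pyramidal"]
    engine: EngineConfig = Field(default_factory=EngineConfig)
    sir: Optional[SirConfig] = None
    spheroid: Optional[SpheroidConfig] = None
    pyramidal: Optional[PyramidalConfig] = None
    output: OutputConfig = Field(default_factory=OutputConfig)

    @model_validator(mode="after")
    def _exactly_one_block(self) -> "ScenarioConfig":
        blocks = {"sir": self.sir, "spheroid": self.spheroid,
                  "pyramidal": self.pyramidal}
        present = [k for k, v in blocks.items() if v is not None]
        if not present:
            # fill the named scenario's block with defaults
            setattr(self, self.scenario, {"sir": SirConfig, "spheroid": SpheroidConfig,
                                          "pyramidal": PyramidalConfig}[self.scenario]())
        elif present != [self.scenario]:
            raise ValueError(f"scenario is {self.scenario!r} but blocks "
                             f"{present} are present; exactly the matching "
                             "block is allowed")
        return self


def load_config(path) -> ScenarioConfig:
    """Parse and validate a TOML scenario file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    try:
        return ScenarioConfig(**data)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise ConfigError(f"invalid scenario config {path}: offending keys: "
                          f"{keys}\n{exc}") from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def serialize_config(config: ScenarioConfig) -> str:
    """Emit the config as TOML; ``load`` of the result reproduces it."""
    data = config.model_dump(exclude_none=True)
    lines = []
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for section, body in data.items():
        if not isinstance(body, dict):
            continue
        lines.append("")
        lines.append(f"[{section}]")
        for k, v in body.items():
            if v is not None:
                lines.append(f"{k} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _run_sir(config: ScenarioConfig, seed: int) -> pd.DataFrame:
    from . import epi

    c = config.sir
    if c.disease is not None:
        params = epi.disease_abm_template(c.disease, box_side=c.box_side,
                                          dt=config.engine.time_step)
    else:
        params = epi.SirAbmParams(
            n_total=c.n_total, n_infected_initial=c.n_infected_initial,
            infection_radius=c.infection_radius, p_infection=c.p_infection,
            p_recovery=c.p_recovery, max_step=c.max_step, box_side=c.box_side,
            dt=config.engine.time_step)
    run = epi.run_sir_abm(params, config.engine.n_iterations, seed)
    frame = run.to_dataframe()
    frame.insert(0, "iteration", np.arange(len(frame)))
    return frame


def _run_spheroid(config: ScenarioConfig, seed: int) -> pd.DataFrame:
    from . import onco

    c = config.spheroid
    params = onco.TumorCellParams(
        volume_growth_rate=c.volume_growth_rate,
        division_diameter=c.division_diameter,
        migration_sigma=c.migration_sigma, p_apoptosis=c.p_apoptosis,
        initial_diameter=c.initial_diameter)
    sim = onco.build_spheroid_simulation(c.n_initial_cells, params, seed=seed,
                                         time_step=config.engine.time_step)
    frame = onco.spheroid_growth_curve(sim, config.engine.n_iterations,
                                       cadence_hours=c.cadence_hours)
    frame.insert(0, "iteration",
                 (frame["t"] / config.engine.time_step).round().astype(int))
    return frame


def _run_pyramidal(config: ScenarioConfig, seed: int) -> pd.DataFrame:
    from . import neuro

    sim, somas = neuro.build_pyramidal_simulation(
        config.pyramidal.n_cells, seed=seed,
        time_step=config.engine.time_step)
    sim.run(config.engine.n_iterations)
    frames = []
    for cell_id, soma in enumerate(somas):
        per_tree = neuro.morphometrics(neuro.extract_morphology(sim, soma))
        per_tree.insert(0, "cell_id", cell_id)
        frames.append(per_tree)
    return pd.concat(frames, ignore_index=True)


_RUNNERS = {"sir": _run_sir, "spheroid": _run_spheroid, "pyramidal": _run_pyramidal}


def summarize_runs(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Row-wise mean/min/max per numeric column across per-seed tables."""
    base = frames[0]
    out = {}
    key_cols = [c for c in ("iteration", "cell_id", "tree_kind", "t") if c in base.columns]
    for col in key_cols:
        out[col] = base[col]
    for col in base.columns:
        if col in key_cols or not pd.api.types.is_numeric_dtype(base[col]):
            continue
        stacked = np.stack([f[col].to_numpy(float) for f in frames])
        out[f"{col}_mean"] = stacked.mean(axis=0)
        out[f"{col}_min"] = stacked.min(axis=0)
        out[f"{col}_max"] = stacked.max(axis=0)
    return pd.DataFrame(out)


def run_scenario(config: ScenarioConfig, seed: int | None = None,
                 repeats: int = 1, out_dir=None) -> dict:
    """Run ``repeats`` seeds (base, base+1, ...) and aggregate.

    Returns ``{"runs": [frames], "summary": frame, "seeds": [...]}`` and,
    if ``out_dir`` is given, writes ``run_seed<N>.csv`` per seed plus
    ``summary.csv``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    base_seed = config.engine.rng_seed if seed is None else seed
    seeds = [base_seed + k for k in range(repeats)]
    runner = _RUNNERS[config.scenario]
    frames = [runner(config, s) for s in seeds]
    summary = summarize_runs(frames)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s, frame in zip(seeds, frames):
            frame.to_csv(out_dir / f"run_seed{s}.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        (out_dir / "scenario.toml").write_text(serialize_config(config))
    return {"runs": frames, "summary": summary, "seeds": seeds}
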