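"""Pipeline configuration: strict, validated, YAML-backed.

A single global seed deterministically derives every per-stage substream
so WT-vs-mutant comparisons are noise-matched.  Unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .landscape import LandscapeSpec


class ConfigError(ValueError):
    pass


class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    n_runs: int = Field(10, ge=1)     # independent runs per genotype
    temperature: float = Field(1.0, ge=0)
    friction: float = Field(0.5, gt=0)
    timestep: float = Field(0.02, gt=0)
    n_steps: int = Field(20_000, ge=1)
    save_stride: int = Field(20, ge=1)


class MetadSettings(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    initial_height: float = Field(0.3, gt=0)
    width: float = Field(0.75, gt=0)
    deposition_interval: int = Field(300, ge=1)
    tempered: bool = True
    bias_factor: float = Field(10.0, gt=1)


class AnalysisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    dissociation_threshold: float = Field(30.0, gt=0)
    dissociation_persistence: int = Field(1, ge=1)
    snapshot_stride: int = Field(10, ge=1)
    contact_cutoff: float = Field(7.0, gt=0)


class KineticsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    washout_t_half: float = Field(9.41, gt=0)      # h
    washout_times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    washout_noise_sd: float = Field(2.0, ge=0)     # % of control
    pk_t_half: float = Field(6.65, gt=0)           # h
    pk_c0: float = Field(1000.0, gt=0)
    pk_times: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0)
    pk_noise_sd: float = Field(0.02, ge=0)         # log-scale (multiplicative)
    ic50: float = Field(6.4, gt=0)                 # nM
    hill: float = 1.0
    dr_concs: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0)
    dr_noise_sd: float = Field(2.0, ge=0)
    pretreat_grid: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
    pkpd_kon: float = Field(0.01, gt=0)            # 1/(nM·h)
    pkpd_c0: float = Field(100.0, gt=0)            # nM
    pkpd_duration: float = Field(48.0, gt=0)       # h
    slow_t_half: float = Field(9.41, gt=0)         # dissociation t1/2 contrast
    fast_t_half: float = Field(0.98, gt=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    wt_landscape: LandscapeSpec = LandscapeSpec()
    mutant_landscape: LandscapeSpec = LandscapeSpec(genotype="M124V")
    simulation: SimulationSettings = SimulationSettings()
    metad: MetadSettings = MetadSettings()
    analysis: AnalysisSettings = AnalysisSettings()
    kinetics: KineticsSettings = KineticsSettings()
    output_dir: str = "results/pipeline"


def substream_seeds(global_seed: int, n: int, stage: str) -> list[int]:
    """Deterministic per-stage child seeds (< 2**31) from the global seed."""
    import zlib

    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode()) % (2**31)])
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration (strict keys)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        # re-raise with field paths spelled out for the caller
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {details}") from exc


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )
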