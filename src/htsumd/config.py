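"""Run configuration: a single validated, serialisable bundle of every
tunable the pipeline exposes.  Unknown keys are rejected at load time and a
load -> dump -> load round trip is the identity, so the config hash stored
in a screen report pins the exact conditions of a run."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pydantic
import yaml

from .analysis import ClusterParams
from .energetics import EnergyModel, HBondCriteria
from .engine import SuMDConfig
from .errors import ConfigError
from .screen import ScreenConfig


class RunConfig(pydantic.BaseModel):
    """Flat, file-friendly view of :class:`~htsumd.screen.ScreenConfig`."""

    model_config = pydantic.ConfigDict(extra="forbid")

    # system preparation
    min_separation: float = pydantic.Field(50.0, gt=0)
    electrostatic_cutoff: float = pydantic.Field(9.0, gt=0)
    padding: float = pydantic.Field(13.0, gt=0)
    salt_molar: float = pydantic.Field(0.1, ge=0)
    # supervised loop
    step_ps: float = pydantic.Field(300.0, gt=0)
    checkpoints: int = pydantic.Field(5, ge=2)
    substeps: int = pydantic.Field(12, ge=1)
    max_consecutive_rejections: int = pydantic.Field(20, ge=1)
    supervision_off_distance: float = pydantic.Field(5.0, gt=0)
    max_accepted_steps: int = pydantic.Field(200, ge=1)
    replicas: int = pydantic.Field(3, ge=1)
    # clustering
    eps: float = pydantic.Field(1.5, gt=0)
    min_samples: int = pydantic.Field(10, ge=1)
    # H-bond criteria & hydrophobic switch
    hbond_distance: float = pydantic.Field(3.0, gt=0)
    hbond_angle: float = pydantic.Field(120.0, gt=0, le=180)
    hyd_r_on: float = pydantic.Field(4.5, gt=0)
    hyd_r_off: float = pydantic.Field(6.0, gt=0)
    # consensus
    min_occupancy: float = pydantic.Field(10.0, ge=0, le=100)
    decile_fraction: float = pydantic.Field(0.10, gt=0, le=1)
    policy: str = "extended"
    # NMR thresholds
    mixture_first: float = pydantic.Field(0.35, gt=0)
    mixture_discard: float = pydantic.Field(0.25, gt=0)
    fstd_cutoff: float = pydantic.Field(50.0, gt=0)
    # seeds
    base_seed: int = pydantic.Field(0, ge=0, lt=2**31)

    @pydantic.model_validator(mode="after")
    def _cross_checks(self):
        if self.min_separation < self.electrostatic_cutoff:
            raise ValueError("min_separation below electrostatic cutoff")
        if self.hyd_r_off <= self.hyd_r_on:
            raise ValueError("hyd_r_off must exceed hyd_r_on")
        if self.mixture_first <= self.mixture_discard:
            raise ValueError("mixture_first must exceed mixture_discard")
        return self

    def to_screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            sumd=SuMDConfig(
                step_ps=self.step_ps, checkpoints=self.checkpoints,
                substeps=self.substeps,
                max_consecutive_rejections=self.max_consecutive_rejections,
                supervision_off_distance=self.supervision_off_distance,
                max_accepted_steps=self.max_accepted_steps,
                replicas=self.replicas, base_seed=self.base_seed),
            cluster=ClusterParams(eps=self.eps, min_samples=self.min_samples),
            model=EnergyModel(cutoff=self.electrostatic_cutoff),
            hbond=HBondCriteria(max_da_distance=self.hbond_distance,
                                min_dha_angle=self.hbond_angle),
            min_separation=self.min_separation,
            electrostatic_cutoff=self.electrostatic_cutoff,
            min_occupancy=self.min_occupancy,
            decile_fraction=self.decile_fraction, policy=self.policy)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()


def load_config(path_or_text) -> RunConfig:
    """Load a YAML or JSON configuration with strict field validation."""
    text = str(path_or_text)
    try:
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
    except OSError:
        pass
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    try:
        return RunConfig(**data)
    except pydantic.ValidationError as exc:
        raise ConfigError(str(exc)) from None


def dump_config(config: RunConfig, path=None) -> str:
    text = yaml.safe_dump(config.model_dump(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
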