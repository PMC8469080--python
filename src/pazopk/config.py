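"""Configuration handling: YAML <-> dataclasses, seed substreams."""
from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, replace

import yaml

from .cohort import CohortDesign
from .model import PopulationParameters
from .saem import CovariateCandidate, SaemSettings

__all__ = ["PipelineConfig", "load_config", "save_config", "seed_for"]


def seed_for(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    seed: int = 1
    design: CohortDesign = field(default_factory=CohortDesign)
    parameters: PopulationParameters = field(
        default_factory=PopulationParameters.reference)
    fit: SaemSettings = field(default_factory=SaemSettings)
    fit_enabled: bool = True
    fit_covariates: list = field(default_factory=lambda: [
        CovariateCandidate("v", "ASAT", "power")])
    stepwise_enabled: bool = False
    stepwise_candidates: list = field(default_factory=list)
    vpc_replicates: int = 1000
    npde_replicates: int = 1000
    vpc_bins: int = 8
    target_auc: float = 750.0
    trough_criterion: float = 20.5
    threshold_grid: tuple = (250.0, 1500.0, 50.0)  # start, stop, step
    loo_enabled: bool = False
    bootstrap_iterations: int = 100

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = replace(self, seed=seed)
        cfg.design = replace(cfg.design, seed=seed_for(seed, "simulate"))
        cfg.fit = replace(cfg.fit, seed=seed_for(seed, "fit"))
        return cfg


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list) and isinstance(f.default, tuple):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    if "design" in data:
        d = data.pop("design")
        for key in ("tdm_visit_counts", "rich_schedule", "dose_menu",
                    "dose_probs", "tdm_time_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        cfg.design = _build(CohortDesign, d)
    if "parameters" in data:
        cfg.parameters = _build(PopulationParameters, data.pop("parameters"))
    if "fit" in data:
        cfg.fit = _build(SaemSettings, data.pop("fit"))
    for key in ("fit_covariates", "stepwise_candidates"):
        if key in data:
            items = data.pop(key)
            setattr(cfg, key, [
                c if isinstance(c, CovariateCandidate)
                else CovariateCandidate(**c) for c in items])
    for k, v in data.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key: {k}")
        if k == "threshold_grid":
            v = tuple(v)
        setattr(cfg, k, v)
    return cfg
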