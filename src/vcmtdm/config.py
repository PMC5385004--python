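"""YAML-backed run configuration.

Everything a clinician-analyst might need to change lives here: the
population PK parameterization (the shipped constants are a documented
stand-in, since commercial TDM software does not publish its model), the
serum-creatinine floor, the eligibility window, screening thresholds,
declared near-duplicate covariate pairs, and the sampler settings.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .glmm import McmcSettings
from .pk import PopulationPKModel

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class RunConfig:
    pop: PopulationPKModel = field(default_factory=PopulationPKModel)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    scr_floor: float = 0.6                       # mg/dL
    trough_window: tuple[float, float] = (3.0, 5.0)  # days
    rho_threshold: float = 0.2                   # |Spearman rho| screen
    duplicate_pairs: tuple[tuple[str, str], ...] = (("bun_adjscr", "bun_scr"),)
    auto_duplicate_rho: float = 0.9
    large_deviation_threshold: float = 10.0      # μg/mL
    signed_large_deviation: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a config file, overriding defaults key by key.

    Top-level blocks: ``pop`` (population PK model fields), ``mcmc``
    (sampler settings), and scalar options matching :class:`RunConfig`
    field names.
    """
    if path is None:
        return default_config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pop_kwargs = raw.pop("pop", {}) or {}
    if "omega" in pop_kwargs:
        pop_kwargs["omega"] = dict(pop_kwargs["omega"])
    if "clcr_range" in pop_kwargs:
        pop_kwargs["clcr_range"] = tuple(pop_kwargs["clcr_range"])
    mcmc_kwargs = raw.pop("mcmc", {}) or {}
    scalars = {}
    for key in ("scr_floor", "rho_threshold", "auto_duplicate_rho",
                "large_deviation_threshold", "signed_large_deviation"):
        if key in raw:
            scalars[key] = raw.pop(key)
    if "trough_window" in raw:
        scalars["trough_window"] = tuple(raw.pop("trough_window"))
    if "duplicate_pairs" in raw:
        scalars["duplicate_pairs"] = tuple(tuple(p) for p in raw.pop("duplicate_pairs"))
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return RunConfig(pop=PopulationPKModel(**pop_kwargs),
                     mcmc=McmcSettings(**mcmc_kwargs), **scalars)
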