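"""Pipeline configuration: one validated set of tunables, YAML-loadable.

Defaults are the analysis settings used throughout the package: a beta-value
cutoff of 0.1 when finding regions, permutation p < 0.01 downstream, a
+/- 2 kb promoter window around the TSS and a 0.5 log2 expression cutoff.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import yaml

log = logging.getLogger("lscsig")


class ConfigError(ValueError):
    pass


@dataclass
class Config:
    # DMR caller
    delta_cutoff: float = 0.1       # min |smoothed group difference|, beta units
    maxgap: int = 500               # bp; probes further apart start a new cluster
    smooth_window: int = 1000       # bp half-window of the running-mean smoother
    n_permutations: int = 250
    min_probes: int = 1
    p_cutoff: float = 0.01          # permutation p threshold downstream
    fwer_cutoff: float = 0.1        # for the cross-progenitor DMR panel
    # signature integration
    promoter_window: int = 2000     # bp around TSS
    expr_cutoff: float = 0.5        # min |log2 ratio| of differential expression
    # identity classifier
    sd_floor: float = 0.01          # lower bound on per-DMR reference sd
    # randomness
    seed: int = 0

    def validate(self) -> "Config":
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.delta_cutoff <= 0:
            raise ConfigError("delta_cutoff must be > 0")
        if not (0 < self.p_cutoff <= 1) or not (0 < self.fwer_cutoff <= 1):
            raise ConfigError("p_cutoff/fwer_cutoff must be in (0, 1]")
        if self.maxgap < 0 or self.smooth_window < 0:
            raise ConfigError("maxgap/smooth_window must be >= 0")
        if self.promoter_window < 0:
            raise ConfigError("promoter_window must be >= 0")
        if self.expr_cutoff < 0:
            raise ConfigError("expr_cutoff must be >= 0")
        if self.sd_floor <= 0:
            raise ConfigError("sd_floor must be > 0")
        if self.min_probes < 1:
            raise ConfigError("min_probes must be >= 1")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None, overrides: dict | None = None) -> Config:
    """Load a YAML/JSON config; unknown keys are rejected, defaults filled.

    The full resolved parameter set is echoed to the package logger so every
    run records its tunables and seed.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = Config(**data).validate()
    log.info("config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg
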