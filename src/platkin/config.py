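"""Run configuration shared by the CLI and the analysis drivers.

A flat YAML key-value file; command-line flags override file values,
and the defaults reproduce the study conditions: 298.15 K, 55.5 M
water, 1 mM Pt complex / 5 mM monosaccharide / 1 mM chloride.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

from .constants import KineticConstants
from .microkin import AssocPolicy

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    temperature: float = 298.15          # K
    water_conc: float = 55.5             # mol/L, clamped solvent
    complex_conc: float = 0.001          # mol/L initial Pt complex
    saccharide_conc: float = 0.005       # mol/L initial monosaccharide
    chloride_conc: float = 0.001         # mol/L initial free chloride
    k_assoc: float = 1e9                 # M^-1 s^-1 barrierless policy
    rtol: float = 1e-9
    atol: float = 1e-15
    seed: int = 0
    initial: dict[str, float] = field(default_factory=dict)  # explicit overrides

    def constants(self) -> KineticConstants:
        return KineticConstants(temperature=self.temperature,
                                water_conc=self.water_conc)

    def assoc_policy(self) -> AssocPolicy:
        return AssocPolicy(k_assoc=self.k_assoc)

    def override(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def load_config(path: Optional[str]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path!r} must be a key-value mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
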