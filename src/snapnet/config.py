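"""Declarative run configuration: one YAML file with per-module sections.

Sections mirror the module configs (``prior``, ``sampler``, ``pt``,
``model``, ``run``); command-line flags override file values.  Configs
serialize losslessly (round-trip identity) and are hash-stamped into run
outputs for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .parallel_tempering import PTConfig
from .priors import PriorConfig
from .rate_samplers import HMCConfig
from .nonparametric_gibbs import SamplerSettings

__all__ = ["RunConfig", "ConfigError", "ABLATIONS"]

ABLATIONS = ("full", "fixed_proposals", "no_pt")

_RATE_NAMES = {"k", "beta", "gamma"}


class ConfigError(ValueError):
    """Malformed run configuration; message lists the offending keys."""


@dataclass
class ModelSection:
    L: int = 10
    truncation: int | None = None
    nonparametric: bool = True
    fixed_rates: dict = field(default_factory=dict)


@dataclass
class RunSection:
    total_sweeps: int = 1000
    seed: int = 0
    output_dir: str = "runs"
    ablation: str = "full"
    record_ladder: bool = False


@dataclass
class RunConfig:
    prior: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    hmc: HMCConfig = field(default_factory=HMCConfig)
    pt: PTConfig = field(default_factory=PTConfig)
    model: ModelSection = field(default_factory=ModelSection)
    run: RunSection = field(default_factory=RunSection)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad = [k for k in self.model.fixed_rates if k not in _RATE_NAMES]
        if bad:
            raise ConfigError(f"fixed_rates keys must name real rates; got {bad}")
        if self.run.ablation not in ABLATIONS:
            raise ConfigError(
                f"run.ablation must be one of {ABLATIONS}; got {self.run.ablation!r}"
            )
        if self.prior.L != self.model.L:
            raise ConfigError("prior.L and model.L must agree")
        self.sampler.hmc = self.hmc

    def apply_ablation(self) -> None:
        """Translate the ablation name into sampler/ensemble settings."""
        if self.run.ablation == "fixed_proposals":
            self.sampler.mode = "fixed"
            self.sampler.use_hmc = False
        elif self.run.ablation == "no_pt":
            self.pt.n_chains = 1

    def to_dict(self) -> dict:
        d = {
            "prior": asdict(self.prior),
            "sampler": {
                k: v for k, v in asdict(self.sampler).items() if k != "hmc"
            },
            "hmc": {
                k: (v.tolist() if hasattr(v, "tolist") else v)
                for k, v in asdict(self.hmc).items()
            },
            "pt": asdict(self.pt),
            "model": asdict(self.model),
            "run": asdict(self.run),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"prior", "sampler", "hmc", "pt", "model", "run"}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config sections: {sorted(bad)}")

        def build(section, factory):
            payload = dict(d.get(section, {}))
            valid = set(factory().__dict__)
            unknown = set(payload) - valid
            if unknown:
                raise ConfigError(
                    f"unknown keys in section {section!r}: {sorted(unknown)}"
                )
            try:
                return factory(**payload)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid section {section!r}: {exc}") from exc

        return cls(
            prior=build("prior", PriorConfig),
            sampler=build("sampler", SamplerSettings),
            hmc=build("hmc", HMCConfig),
            pt=build("pt", PTConfig),
            model=build("model", ModelSection),
            run=build("run", RunSection),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def digest(self) -> str:
        """Stable short hash of the fully-resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
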