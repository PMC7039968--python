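"""Experiment configuration: a YAML file whose keys mirror the library.

Layout::

    network:            # NetworkParams fields, one-to-one
      n_pns: 50
      kc_threshold: 119
    experiment:
      name: simulate    # simulate | learn | fixed-drive | sweep | grid | analytic
      n_iterations: 100
      # experiment-specific arguments (control, learning_rate, variant, ...)
    output_dir: results/run1
    seed: 1
    log_level: info

Unknown keys are rejected with the offending key named, and the fully
resolved configuration is echoed into every output directory so a run can
be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .circuit import NetworkParams

__all__ = ["ExperimentConfig", "load_config"]

_NETWORK_FIELDS = {f.name for f in dataclasses.fields(NetworkParams)}
_TOP_LEVEL_KEYS = {"network", "experiment", "output_dir", "seed", "log_level"}


@dataclass
class ExperimentConfig:
    network: NetworkParams = field(default_factory=NetworkParams)
    experiment_name: str = "simulate"
    experiment_args: dict = field(default_factory=dict)
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "info"

    def resolved(self) -> dict:
        """Plain-dict form, written alongside every run's outputs."""
        return {
            "network": self.network.to_dict(),
            "experiment": {"name": self.experiment_name,
                           **self.experiment_args},
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "log_level": self.log_level,
        }


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML experiment configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown configuration key "
                         f"{sorted(unknown)[0]!r}")
    net_raw = raw.get("network", {}) or {}
    bad = set(net_raw) - _NETWORK_FIELDS
    if bad:
        raise ValueError(f"{path}: unknown network key {sorted(bad)[0]!r}")
    exp_raw = dict(raw.get("experiment", {}) or {})
    name = exp_raw.pop("name", "simulate")
    return ExperimentConfig(
        network=NetworkParams(**net_raw),
        experiment_name=name,
        experiment_args=exp_raw,
        output_dir=raw.get("output_dir", "results"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "info")),
    )
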