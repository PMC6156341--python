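"""Run configuration: one YAML file bundling model, data, optimizer and profile settings.

Schema (all concentrations μM; omitted blocks fall back to the defaults shown):

.. code-block:: yaml

    model: raf_equilibrium          # registered model id
    model_options: {K1: 0.04, K2: 20.0, R_tot: 50.0}
    quant_data: data/occupancy.csv  # optional
    constraints: data/labels.csv    # optional
    search_space:
      K3: {bounds: [1.0e-4, 1.0e4]}           # scale: linear (default) | log10
      K5: {bounds: [1.0e-4, 1.0e4]}
    optimizer:
      method: de                    # de | scatter_search
      max_iterations: 1000
      strategy: best1exp
    profile:
      threshold: 0.15
      replicates: 1
      parameters:
        K3: {range: [1.0e2, 1.0e5], points: 100, scale: log10}
    seed: 1
    output_dir: out
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import yaml

from .optimize import SearchSpace
from .raf import RafEquilibriumAdapter

__all__ = ["RunConfig", "ConfigError", "MODEL_REGISTRY", "load_config"]


class ConfigError(ValueError):
    """The run configuration is malformed or references missing files."""


def _make_raf(options: Mapping[str, Any]) -> RafEquilibriumAdapter:
    opts = dict(options)
    R_tot = float(opts.pop("R_tot", 50.0))
    fixed = {"K1": 0.04, "K2": 20.0, "K3": 4000.0, "K5": 0.1}
    fixed.update({k: float(v) for k, v in opts.items()})
    return RafEquilibriumAdapter(fixed, R_tot=R_tot)


#: model id -> adapter factory taking the ``model_options`` mapping
MODEL_REGISTRY: dict[str, Callable[[Mapping[str, Any]], Any]] = {
    "raf_equilibrium": _make_raf,
}


@dataclass
class RunConfig:
    model: str
    model_options: dict = field(default_factory=dict)
    quant_data: str | None = None
    constraints: str | None = None
    search_space: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    seed: int | None = None
    output_dir: str = "out"
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self):
        if self.model not in MODEL_REGISTRY:
            raise ConfigError(
                f"unknown model {self.model!r}; registered: {sorted(MODEL_REGISTRY)}")
        for attr in ("quant_data", "constraints"):
            p = getattr(self, attr)
            if p is not None and not (self.base_dir / p).exists():
                raise ConfigError(f"{attr} file not found: {self.base_dir / p}")

    def make_adapter(self):
        return MODEL_REGISTRY[self.model](self.model_options)

    def make_space(self) -> SearchSpace:
        if not self.search_space:
            raise ConfigError("config has no search_space block")
        bounds, scales = {}, {}
        for name, spec in self.search_space.items():
            lo, hi = spec["bounds"]
            bounds[name] = (float(lo), float(hi))
            if spec.get("scale", "linear") != "linear":
                scales[name] = spec["scale"]
        return SearchSpace(bounds=bounds, scales=scales)

    def profile_grids(self) -> tuple[dict[str, np.ndarray], dict[str, str]]:
        grids, scales = {}, {}
        for name, spec in self.profile.get("parameters", {}).items():
            lo, hi = (float(v) for v in spec["range"])
            n = int(spec.get("points", 100))
            scale = spec.get("scale", "linear")
            grids[name] = np.logspace(np.log10(lo), np.log10(hi), n) \
                if scale == "log10" else np.linspace(lo, hi, n)
            scales[name] = scale
        return grids, scales

    def path(self, rel: str | None) -> Path | None:
        return None if rel is None else self.base_dir / rel

    def digest(self) -> str:
        """Short content hash of the configuration, embedded in every output."""
        payload = {k: v for k, v in self.__dict__.items() if k != "base_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    if not isinstance(raw, dict) or "model" not in raw:
        raise ConfigError(f"{path} must be a mapping with at least a 'model' key")
    known = {f.name for f in RunConfig.__dataclass_fields__.values()} - {"base_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(base_dir=path.parent, **raw)
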