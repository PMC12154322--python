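"""Run configuration: YAML serialization with strict validation.

A :class:`RunConfig` bundles everything a pipeline run needs — sigmoid
trajectory parameters per biomarker, the CI model parameters, the age-band
registry, threshold tables, the noise model, the root seed and generator
settings.  Loading rejects unknown keys at every level so typos fail fast;
``dump(load(text))`` round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from .ci import CIParams
from .cohort import BIOMARKERS
from .sigmoid import NoiseSpec, SigmoidParams
from .zones import AgeBand, ThresholdTable

__all__ = ["RunConfig", "load_config", "dump_config", "default_config"]

_TOP_KEYS = {
    "seed",
    "tau_coupling",
    "n_per_age",
    "age_range",
    "noise",
    "sigmoid",
    "ci",
    "bands",
    "thresholds",
    "window",
    "paths",
}


def _check_keys(d: Mapping, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {context}")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    tau_coupling: float = -0.5
    n_per_age: int = 5
    age_range: tuple[int, int] = (31, 60)
    noise_kind: str = "additive-gaussian"
    sigmoid_params: Mapping[str, SigmoidParams] = field(default_factory=dict)
    noise_scales: Mapping[str, float] = field(default_factory=dict)
    ci_params: Optional[CIParams] = None
    registry: tuple[AgeBand, ...] = ()
    thresholds: tuple[ThresholdTable, ...] = ()
    window_range: tuple[float, float] = (31.0, 70.0)
    window_step: float = 0.1
    input_path: Optional[str] = None
    out_dir: str = "."

    @property
    def noise(self) -> NoiseSpec:
        return NoiseSpec(kind=self.noise_kind, scale=1.0, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "tau_coupling": self.tau_coupling,
            "n_per_age": self.n_per_age,
            "age_range": list(self.age_range),
            "noise": {"kind": self.noise_kind},
            "sigmoid": {
                name: {
                    "L": p.L,
                    "k": p.k,
                    "x0": p.x0,
                    "noise_sd": float(self.noise_scales.get(name, 0.0)),
                }
                for name, p in self.sigmoid_params.items()
            },
            "ci": self.ci_params.to_dict() if self.ci_params else None,
            "bands": [
                {
                    "lower": float(b.lower),
                    "upper": float(b.upper),
                    "gamma": float(b.gamma),
                    "delta": float(b.delta),
                    "display": [[float(v) for v in r] for r in b.display],
                }
                for b in self.registry
            ],
            "thresholds": [
                {
                    "age_group": t.age_group,
                    "lower": float(t.lower),
                    "upper": float(t.upper),
                    "direction": dict(t.direction),
                    "rows": {
                        b: {cat: [float(v) for v in rng] for cat, rng in rows.items()}
                        for b, rows in t.rows.items()
                    },
                }
                for t in self.thresholds
            ],
            "window": {"lower": self.window_range[0], "upper": self.window_range[1],
                       "step": self.window_step},
            "paths": {"input": self.input_path, "out_dir": self.out_dir},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        _check_keys(d, _TOP_KEYS, "config")
        cfg = default_config()
        if "seed" in d:
            cfg.seed = int(d["seed"])
        if "tau_coupling" in d:
            cfg.tau_coupling = float(d["tau_coupling"])
        if "n_per_age" in d:
            cfg.n_per_age = int(d["n_per_age"])
        if "age_range" in d:
            lo, hi = d["age_range"]
            cfg.age_range = (int(lo), int(hi))
        if "noise" in d:
            _check_keys(d["noise"], {"kind"}, "config.noise")
            cfg.noise_kind = str(d["noise"]["kind"])
        if "sigmoid" in d:
            params, scales = {}, {}
            for name, block in d["sigmoid"].items():
                if name not in BIOMARKERS:
                    raise ValueError(f"unknown biomarker {name!r} in config.sigmoid")
                _check_keys(block, {"L", "k", "x0", "noise_sd"}, f"config.sigmoid.{name}")
                params[name] = SigmoidParams(
                    L=float(block["L"]), k=float(block["k"]), x0=float(block["x0"])
                )
                scales[name] = float(block.get("noise_sd", 0.0))
            cfg.sigmoid_params = params
            cfg.noise_scales = scales
        if "ci" in d and d["ci"] is not None:
            _check_keys(d["ci"], {"alpha", "beta", "terms"}, "config.ci")
            for name, term in d["ci"]["terms"].items():
                if name not in BIOMARKERS:
                    raise ValueError(f"unknown biomarker {name!r} in config.ci.terms")
                _check_keys(term, {"w", "k", "m"}, f"config.ci.terms.{name}")
            cfg.ci_params = CIParams.from_dict(d["ci"])
        if "bands" in d:
            bands = []
            for b in d["bands"]:
                _check_keys(b, {"lower", "upper", "gamma", "delta", "display"}, "config.bands[]")
                display = tuple(tuple(float(v) for v in r) for r in b.get("display", []))
                if len(display) != 3:
                    raise ValueError("each band needs 3 display ranges")
                bands.append(
                    AgeBand(
                        lower=float(b["lower"]), upper=float(b["upper"]),
                        gamma=float(b["gamma"]), delta=float(b["delta"]),
                        display=display,
                    )
                )
            cfg.registry = tuple(bands)
        if "thresholds" in d:
            tabs = []
            for t in d["thresholds"]:
                _check_keys(
                    t, {"age_group", "lower", "upper", "direction", "rows"},
                    "config.thresholds[]",
                )
                rows = {
                    b: {cat: tuple(float(v) for v in rng) for cat, rng in block.items()}
                    for b, block in t["rows"].items()
                }
                tabs.append(
                    ThresholdTable(
                        age_group=str(t["age_group"]), lower=float(t["lower"]),
                        upper=float(t["upper"]), rows=rows,
                        direction=dict(t["direction"]),
                    )
                )
            cfg.thresholds = tuple(tabs)
        if "window" in d:
            _check_keys(d["window"], {"lower", "upper", "step"}, "config.window")
            cfg.window_range = (float(d["window"]["lower"]), float(d["window"]["upper"]))
            cfg.window_step = float(d["window"].get("step", 0.1))
        if "paths" in d and d["paths"] is not None:
            _check_keys(d["paths"], {"input", "out_dir"}, "config.paths")
            cfg.input_path = d["paths"].get("input")
            cfg.out_dir = d["paths"].get("out_dir") or "."
        return cfg


def default_config() -> RunConfig:
    """Configuration carrying the package defaults."""
    from .defaults import (
        DEFAULT_CI_PARAMS,
        DEFAULT_NOISE_SCALES,
        DEFAULT_REGISTRY,
        DEFAULT_SIGMOID_PARAMS,
        DEFAULT_TAU_COUPLING,
        DEFAULT_THRESHOLDS,
    )

    return RunConfig(
        seed=0,
        tau_coupling=DEFAULT_TAU_COUPLING,
        sigmoid_params=dict(DEFAULT_SIGMOID_PARAMS),
        noise_scales=dict(DEFAULT_NOISE_SCALES),
        ci_params=DEFAULT_CI_PARAMS,
        registry=DEFAULT_REGISTRY,
        thresholds=DEFAULT_THRESHOLDS,
    )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return default_config()
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig) -> str:
    """Serialize a configuration to YAML text."""
    return yaml.safe_dump(config.to_dict(), sort_keys=False)
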