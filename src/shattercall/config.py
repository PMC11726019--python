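"""Run configuration: YAML/JSON parsing, aliases, range validation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import DetectorParams
from .simulate import ShatterSimConfig

__all__ = ["RunConfig", "validate_config", "load_config_file"]

#: accepted shorthand -> canonical field
PARAM_ALIASES = {
    "min_run": "min_panel_run",
    "min_ccf": "min_segment_ccf",
    "max_size_ratio": "uniformity_max_ratio",
    "clonal_cutoff": "clonal_ccf_cutoff",
}

SIM_ALIASES = {
    "k": "n_breakpoints",
    "r": "retention_prob",
    "p": "purity",
    "sigma": "noise_sd",
    "a": "ecdna_copies",
}


@dataclass
class RunConfig:
    """Validated configuration for a detector or simulator run."""

    params: DetectorParams = field(default_factory=DetectorParams)
    sim: ShatterSimConfig = field(default_factory=ShatterSimConfig)
    seed: int = 0
    out_prefix: str = "shattercall"
    log_level: str = "INFO"

    def manifest(self) -> dict:
        from . import __version__

        return {
            "version": __version__,
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
            "sim": _sim_dict(self.sim),
            "out_prefix": self.out_prefix,
        }


def _sim_dict(sim: ShatterSimConfig) -> dict:
    d = dataclasses.asdict(sim)
    if d.get("region") is not None:
        d["region"] = list(d["region"])
    return d


def _apply(section: dict, cls, aliases: dict[str, str], label: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    resolved = {}
    unknown = []
    for key, value in section.items():
        canon = aliases.get(key.lower(), key)
        if canon not in fields:
            unknown.append(key)
            continue
        resolved[canon] = value
    if unknown:
        raise ValueError(f"unknown {label} key(s): {', '.join(sorted(unknown))}")
    if "region" in resolved and resolved["region"] is not None:
        resolved["region"] = tuple(resolved["region"])
    try:
        return cls(**resolved)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid {label} configuration: {exc}") from exc


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse and validate a YAML/JSON config; fill defaults.

    Sections: ``params`` (detector thresholds), ``sim`` (simulator), plus
    top-level ``seed``, ``out_prefix``, ``log_level``.  Unknown keys are
    rejected with a message naming them; out-of-range values name the
    offending field.
    """
    if raw is None or raw == "":
        data: dict = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known_top = {"params", "sim", "seed", "out_prefix", "log_level"}
    unknown = [k for k in data if k not in known_top]
    if unknown:
        raise ValueError(f"unknown config section(s)/key(s): {', '.join(sorted(unknown))}")
    params = _apply(data.get("params") or {}, DetectorParams, PARAM_ALIASES, "detector")
    sim = _apply(data.get("sim") or {}, ShatterSimConfig, SIM_ALIASES, "simulator")
    seed = int(data.get("seed", 0))
    if "seed" in data:
        sim = dataclasses.replace(sim, seed=seed)
    return RunConfig(
        params=params,
        sim=sim,
        seed=seed,
        out_prefix=str(data.get("out_prefix", "shattercall")),
        log_level=str(data.get("log_level", "INFO")),
    )


def load_config_file(path: str | Path | None) -> RunConfig:
    if path is None:
        return validate_config(None)
    text = Path(path).read_text(encoding="utf-8")
    return validate_config(text)


def write_manifest(config: RunConfig, prefix: str | Path) -> Path:
    """Write the run manifest (config + seed + version) next to the outputs."""
    path = Path(f"{prefix}.manifest.json")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(config.manifest(), fh, indent=1)
        fh.write("\n")
    return path
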