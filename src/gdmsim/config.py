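"""Run configuration: YAML file + CLI overrides, and output manifests."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import yaml

from .errors import ValidationError
from .label_processes import DEFAULT_FN_RATE, DEFAULT_FP_RATE


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on besides the code itself."""

    n_patients: int = 37651
    seed: int = 0
    target_prevalence: float = 0.105
    dip_2020: bool = True
    fn_rate: float = DEFAULT_FN_RATE
    fp_rate: float = DEFAULT_FP_RATE
    test_fraction: float = 0.3
    exclude_years: tuple = (2020,)
    grid_max_level: float = 0.9
    grid_step: float = 0.1
    n_boot: int = 2000
    report_precision: int = 2

    def override(self, **kwargs) -> "RunConfig":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        if "exclude_years" in updates:
            updates["exclude_years"] = tuple(updates["exclude_years"])
        return replace(self, **updates)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["exclude_years"] = list(out["exclude_years"])
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must map keys to values")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "exclude_years" in raw:
            raw["exclude_years"] = tuple(raw["exclude_years"])
        return cls(**raw)


def _package_version() -> str:
    try:
        return version("gdmsim")
    except PackageNotFoundError:
        return "unknown"


def write_manifest(outdir, config: RunConfig, extra: dict | None = None) -> Path:
    """Drop a manifest with the config, its hash, and the package version."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "package_version": _package_version(),
    }
    if extra:
        payload.update(extra)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path
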