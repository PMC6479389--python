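"""Scenario configuration, file I/O helpers and run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .engine import CohortConfig
from .mortality import ERRParams

__all__ = ["ScenarioConfig", "write_manifest"]


@dataclass
class ScenarioConfig:
    """One reproducible run: input paths, model settings and dialect switches."""

    base_table: str = "base_table.csv"
    mortality: str = "mortality.csv"
    intentions: str = "intentions.csv"
    cohort_sizes: str = "cohort_sizes.csv"

    initial_size: float = 1_000_000.0
    start_age: int = 13
    end_age: int = 103
    hazard_timing: str = "destination"

    err_current: float = 0.09
    err_former: float = 0.04

    would_be_smoker: float = 0.01
    would_be_quitter: float = 0.05
    use_rounded_deltas: bool = False

    uncertainty: bool = True
    n_draws: int = 10_000
    rate_sd: float = 0.02
    seed: int = 0

    ax_fraction: float = 0.5

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            initial_size=self.initial_size,
            start_age=self.start_age,
            end_age=self.end_age,
            hazard_timing=self.hazard_timing,
        )

    def err_params(self) -> ERRParams:
        return ERRParams(self.err_current, self.err_former)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def resolve(self, name: str, base_dir: Path | None = None) -> Path:
        p = Path(getattr(self, name))
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        if not p.exists():
            raise FileNotFoundError(f"config references missing file: {p}")
        return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seed, inputs) -> Path:
    """Write a run manifest: config echo, seed, library versions, checksums."""
    import numpy, pandas, scipy, statsmodels  # noqa: E401

    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "tobcohort": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "input_sha256": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
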