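"""Run configuration (YAML) and the reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .curves import CANDIDATE_FAMILIES


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    weather: str | None = None
    sensor: str | None = None
    metadata: str | None = None
    outdir: str = "rndvi_out"
    tbase_c: float = 10.0
    include_transplant_day: bool = True
    grouping: str = "by_yield_level_and_type"
    per_cultivar_norm: bool = False
    ndvi_max_override: dict | None = None
    stage_bins: dict[str, list[float]] | None = None
    families: list[str] = field(default_factory=lambda: list(CANDIDATE_FAMILIES))
    seed: int = 0
    #: design block for the simulate command: noise_sd, replicates,
    #: cultivars (names known to the reference tables), n_rates, ...
    design: dict = field(default_factory=dict)

    def require_paths(self) -> None:
        missing = [
            name
            for name in ("weather", "sensor", "metadata")
            if getattr(self, name) is None or not Path(getattr(self, name)).exists()
        ]
        if missing:
            raise FileNotFoundError(
                f"config is missing or points to nonexistent input(s): {missing}"
            )


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def write_manifest(outdir, config: RunConfig, command: str, **extra) -> Path:
    """Record config hash, seed and versions so a run can be reproduced."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": asdict(config),
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "rndvi_version": __version__,
        **extra,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
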