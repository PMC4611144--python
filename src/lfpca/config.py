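"""Run configuration and manifests.

A single structured YAML file drives the command-line pipeline; CLI flags
override file values.  Every output directory receives a ``manifest.json``
recording the inputs, parameters, seed and stage order, sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    """Configuration shared by the pipeline subcommands."""

    # inputs
    images: list = field(default_factory=list)
    mask: str | None = None
    design: str | None = None
    covariates: str | None = None
    # phantom overrides (passed through to PhantomParams)
    phantom: dict = field(default_factory=dict)
    # preprocessing
    fwhm_mm: float | None = None
    recenter_times: bool = True
    # LFPCA truncation
    n_x: float | int = 0.9
    n_w: float | int = 0.9
    max_components: int = 10
    # VBM
    fdr_q: float = 0.05
    cluster_min_extent: int = 21
    connectivity: str = "full"
    # reproducibility
    seed: int = 0
    outdir: str = "lfpca_out"

    def validate_inputs(self) -> None:
        """Check referenced paths exist before any computation starts."""
        for path in [self.mask, self.design, self.covariates, *self.images]:
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input path does not exist: {path}")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus CLI overrides.

    Flag overrides win over file values; ``None`` overrides are ignored.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        values.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)


def write_manifest(outdir, *, command: str, config: RunConfig,
                   stages: list, extra: dict | None = None) -> Path:
    """Write manifest.json describing a finished run."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": stages,
        "finished_utc": _time.strftime("%Y-%m-%dT%H:%M:%SZ", _time.gmtime()),
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
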