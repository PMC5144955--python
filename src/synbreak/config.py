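"""Run configuration: documented defaults for every analysis threshold,
YAML round-trip, and a reproducibility manifest written next to outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .collinearity import KB_PER_BAND

logger = logging.getLogger("synbreak")


@dataclass
class RunConfig:
    """Analysis-wide knobs with their documented defaults.

    * ``min_run`` -- concordant markers required on each side of a profile
      transition before a breakpoint is called (2: one discordant marker
      never calls a breakpoint).
    * ``nearby_threshold`` -- gene distance within which two distinct
      breakpoints on a common reference order count as "nearby" (a reused
      fragile region rather than a shared breakpoint).
    * ``min_tract_len`` -- minimum poly(dA:dT) run length in bp (6).
    * ``bin_size`` -- tumbling window for tract density profiles in bp (100).
    * ``kb_per_band`` -- physical distance per consensus fingerprint band
      (1.5 kb/band).
    """

    seed: int = 0
    min_run: int = 2
    nearby_threshold: int = 5
    min_tract_len: int = 6
    bin_size: int = 100
    kb_per_band: float = KB_PER_BAND
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def log_thresholds(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))

    def write_manifest(self, out_dir: Union[str, Path]) -> Path:
        """Record config, seed and package version alongside the outputs."""
        from . import __version__

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"config": dataclasses.asdict(self), "version": __version__}
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return path
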