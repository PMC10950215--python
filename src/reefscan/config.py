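"""Pipeline configuration and run manifests.

A pipeline run is described by a flat TOML file with one section per stage
(``scene``, ``preprocess``, ``annotate``, ``model``, ``survey``, ``stats``)
plus a ``master_seed`` and output directory.  Every stage derives its own
seed deterministically from the master seed and its stage name, so no stage
draws randomness outside its derived seed.  Each stage appends an entry to a
JSON run manifest recording input/output file hashes, the seed, the config
snapshot and elapsed time — re-running a deterministic stage with identical
inputs reproduces identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["PipelineConfig", "RunManifest", "stage_seed", "sha256_file"]

STAGES = ("scene", "preprocess", "annotate", "model", "survey", "stats")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration; round-trips its raw TOML dict."""

    master_seed: int = 0
    output_dir: Path = Path("reefscan_out")
    version: str = "1"
    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        sections = {k: dict(v) for k, v in raw.items() if isinstance(v, dict)}
        return cls(
            master_seed=int(raw.get("master_seed", 0)),
            output_dir=Path(raw.get("output_dir", "reefscan_out")),
            version=str(raw.get("version", "1")),
            sections=sections,
        )

    def stage(self, name: str) -> dict[str, Any]:
        return dict(self.sections.get(name, {}))

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)

    def snapshot(self) -> dict[str, Any]:
        return {
            "master_seed": self.master_seed,
            "output_dir": str(self.output_dir),
            "version": self.version,
            "sections": self.sections,
        }


@dataclass
class RunManifest:
    """Append-only JSON record of pipeline stages."""

    path: Path
    entries: list[dict[str, Any]] = field(default_factory=list)

    @classmethod
    def open(cls, path: str | Path) -> "RunManifest":
        path = Path(path)
        entries = json.loads(path.read_text()) if path.exists() else []
        return cls(path, entries)

    def record(self, stage: str, *, seed: int, config: dict[str, Any],
               inputs: list[str | Path] = (), outputs: list[str | Path] = (),
               started: float | None = None) -> None:
        now = time.time()
        self.entries.append({
            "stage": stage,
            "seed": seed,
            "timestamp": now,
            "elapsed_s": round(now - started, 3) if started else None,
            "config": config,
            "inputs": {str(p): sha256_file(p) for p in inputs},
            "outputs": {str(p): sha256_file(p) for p in outputs},
        })
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.entries, indent=1))
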