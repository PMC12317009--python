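"""Pipeline configuration: one seed, per-stage parameters, stable round trips."""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the demo pipeline in one serialisable record.

    Defaults mirror the mapping protocol: 16-px GLI windows, 100 depth
    bins, block sizes 12-24 with alpha 0.001, a 40% MPM threshold, a 0.2
    probability threshold for coordinate assignment, and 10 000
    permutations. All randomness derives from ``seed`` via per-stage
    spawned generators.
    """
    seed: int = 0
    gli_window_px: int = 16
    depth_bins: int = 100
    n_traverses: int = 162
    block_range: tuple[int, int] = (12, 24)
    alpha: float = 0.001
    min_support: int | None = None
    merge_window: int = 3
    mpm_threshold: float = 0.4
    neighbourhood: int = 26
    assign_threshold: float = 0.2
    n_perm: int = 10_000
    noise_sd: float = 0.03
    n_subjects: int = 10
    jitter_mm: float = 2.0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        self.block_range = tuple(self.block_range)  # type: ignore[assignment]
        if self.gli_window_px < 2:
            raise ValueError("gli_window_px must be >= 2")
        if self.depth_bins < 10:
            raise ValueError("depth_bins must be >= 10")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.mpm_threshold <= 1.0:
            raise ValueError("mpm_threshold must lie in [0, 1]")
        if not 0.0 <= self.assign_threshold <= 1.0:
            raise ValueError("assign_threshold must lie in [0, 1]")
        if self.neighbourhood not in (6, 18, 26):
            raise ValueError("neighbourhood must be 6, 18 or 26")
        if self.n_perm < 1000:
            raise ValueError("n_perm must be >= 1000")
        if self.block_range[0] < 2 or self.block_range[1] < self.block_range[0]:
            raise ValueError("invalid block_range")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        tag = zlib.crc32(stage.encode("utf-8"))
        ss = np.random.SeedSequence([self.seed, tag])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_range"] = list(self.block_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)
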