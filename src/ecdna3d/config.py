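"""Run configuration: defaults < config file < CLI flags."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .reconstruct import FitConfig


@dataclass
class RunConfig:
    resolution: int = 5000
    gamma: float | str = "auto"        # 'auto' => 0.05 * Ne, or a fixed float
    n_restarts: int = 5
    max_rounds: int = 1000
    convergence_eps: float = 1e-4
    q_threshold: float = 0.05
    distance_model: str = "circ"       # 'ref' | 'circ' | 'spatial'
    mode: str = "consensus"            # 'consensus' | 'ensemble'
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("resolution", "n_restarts", "max_rounds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("convergence_eps", "q_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma != "auto":
            self.gamma = float(self.gamma)
            if self.gamma < 0:
                raise ValueError("gamma must be non-negative or 'auto'")
        if self.distance_model not in ("ref", "circ", "spatial"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build from defaults, then a JSON config file, then keyword overrides
        (CLI flags); override values of None are ignored."""
        values: dict = {}
        if path is not None:
            raw = json.loads(Path(path).read_text())
            known = {f.name for f in fields(cls)}
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def as_dict(self) -> dict:
        return asdict(self)

    def hashable_dict(self) -> dict:
        """Config content that determines results — excludes output_dir so
        identical runs in different directories hash identically."""
        d = asdict(self)
        d.pop("output_dir")
        return d

    def fit_config(self) -> FitConfig:
        return FitConfig(
            n_restarts=self.n_restarts,
            max_rounds=self.max_rounds,
            convergence_eps=self.convergence_eps,
            gamma=None if self.gamma == "auto" else float(self.gamma),
            mode=self.mode,
        )
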