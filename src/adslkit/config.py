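"""Flat key/value run configuration with validation.

A run is reproducible from a single YAML file of scalar keys; every
CLI flag overrides the config key of the same name. Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

STAGES = ("behavior", "metabolomics", "popgen", "simulate")


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    K: number of earliest eligible visits scored per cage-day.
    B: permutation count for shuffled-label nulls.
    alpha: two-tailed significance level.
    bonferroni_family: family size m for Bonferroni adjustment
        (0 = use the number of days tested).
    window_bp / step_bp: sliding-window geometry in base pairs.
    Ne: diploid effective population size for scaled selection
        coefficients and simulations.
    """

    stage: str = "behavior"
    events_path: str | None = None
    roster_path: str | None = None
    metabolite_path: str | None = None
    vcf_path: str | None = None
    region: str | None = None
    K: int = 10
    B: int = 1000
    alpha: float = 0.05
    bonferroni_family: int = 0
    onset: float = 0.0
    rewarded_corners: tuple[int, ...] = (1, 2, 3, 4)
    window_bp: int = 10_000
    step_bp: int = 2_000
    Ne: int = 10_000
    s: float = 0.0
    theta: float = 1.0
    n_days: int = 9
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bonferroni_family < 0:
            raise ValueError("bonferroni_family must be >= 0")
        if self.step_bp < 1 or self.window_bp < self.step_bp:
            raise ValueError("require window_bp >= step_bp >= 1")
        if self.Ne < 1:
            raise ValueError("Ne must be a positive integer")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword arguments (e.g. CLI flags) override keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "rewarded_corners" in raw:
            raw["rewarded_corners"] = tuple(raw["rewarded_corners"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
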