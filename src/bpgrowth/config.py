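"""Run configuration: one YAML-serializable object bundling the grid,
annealer, thresholds and prognosis settings for a reproducible run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .fitting import AnnealConfig
from .landscape import GridSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full analysis run needs, with reproducible defaults.

    ``fast_factor`` divides the annealing step budgets (1 = the full
    reference budgets); thresholds are the near-optimality levels and
    ``cutoffs`` the prognosis segment ends in days.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    thresholds: tuple[float, ...] = (0.01, 0.05, 0.10)
    cutoffs: tuple[float, ...] = (65, 76, 87, 98, 107)
    seed: int | None = None
    fast_factor: float = 1.0
    outdir: str = "bpgrowth_out"

    def __post_init__(self):
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        if self.fast_factor <= 0:
            raise ValueError("fast_factor must be positive")

    def effective_anneal(self) -> AnnealConfig:
        cfg = self.anneal.with_seed(self.seed) if self.seed is not None \
            else self.anneal
        if self.fast_factor != 1.0:
            cfg = cfg.scaled(self.fast_factor)
        return cfg

    def to_yaml(self, path) -> None:
        doc = {
            "grid": asdict(self.grid),
            "anneal": asdict(self.anneal),
            "thresholds": list(self.thresholds),
            "cutoffs": list(self.cutoffs),
            "seed": self.seed,
            "fast_factor": self.fast_factor,
            "outdir": self.outdir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kw = {}
        if "grid" in doc:
            kw["grid"] = GridSpec(**doc["grid"])
        if "anneal" in doc:
            kw["anneal"] = AnnealConfig(**doc["anneal"])
        for key in ("thresholds", "cutoffs"):
            if key in doc:
                kw[key] = tuple(doc[key])
        for key in ("seed", "fast_factor", "outdir"):
            if key in doc:
                kw[key] = doc[key]
        kw.update(overrides)
        return cls(**kw)
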