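"""Pipeline configuration: one human-editable YAML file covering every stage.

Defaults are the working values of the whole pipeline: 100 bp flank
isolation, a 0.30–0.70 frequency window, 120 bp maximum product, GC < 60%,
Tm 55–62 °C, structure scan over K = 2–10, core fraction 0.20.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .kasp import DesignConstraints
from .screening import FilterThresholds


@dataclass
class PipelineConfig:
    seed: int = 0
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    design: DesignConstraints = field(default_factory=DesignConstraints)
    k_range: tuple[int, int] = (2, 10)
    n_restarts: int = 10
    core_fraction: float = 0.20
    core_objective: str = "EN"
    enforce_coverage: bool = True
    # synthetic-panel defaults: the study-scale conditions
    n_pops: int = 8
    n_samples: int = 280
    n_loci: int = 32
    admix_alpha: float = 0.05
    freq_prior: tuple[float, float] = (0.2, 0.2)
    missing_rate: float = 0.02

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["thresholds"] = asdict(self.thresholds)
        data["design"] = asdict(self.design)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in data:
            t = data["thresholds"]
            if "freq_window" in t:
                t["freq_window"] = tuple(t["freq_window"])
            data["thresholds"] = FilterThresholds(**t)
        if "design" in data:
            d = data["design"]
            for key in ("tm_range", "primer_len"):
                if key in d:
                    d[key] = tuple(d[key])
            data["design"] = DesignConstraints(**d)
        for key in ("k_range", "freq_prior"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
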