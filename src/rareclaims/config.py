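"""Run configuration: every analysis is fully determined by config + inputs."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field


class SimulateConfig(BaseModel):
    n_diseases: int = 200
    archetype_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "Congenital": 0.2,
            "Childhood": 0.2,
            "Acquired": 0.2,
            "Elderly": 0.2,
            "Flat": 0.2,
        }
    )
    prevalence_log_range: tuple[float, float] = (-6.0, -3.0)
    years: list[int] = Field(default_factory=lambda: list(range(2009, 2019)))
    churn: float = 0.0
    population_total: float = 126_000_000
    unmatched_fraction: float = 0.1
    discordant_fraction: float = 0.1


class AnalyzeConfig(BaseModel):
    cube: str = "cube.tsv"
    population: str = "population.tsv"
    annotations: str | None = "annotations.tsv"
    reference_year: int = 2018
    disclosure_threshold: int = 10
    rounding_base: int = 10
    ten_year_source: str = "rounded"  # or "coarsened"
    k_candidates: list[int] = Field(default_factory=lambda: list(range(2, 9)))
    min_total: float = 50
    case_gap_threshold: int = 2
    figures: bool = True


class HarmonizeConfig(BaseModel):
    vocab_a: str = "vocab_a.tsv"
    vocab_b: str = "vocab_b.tsv"
    truth: str | None = "truth.tsv"
    min_shared_tokens: int = 2


class RunConfig(BaseModel):
    """Top-level configuration; the seed drives every source of randomness."""

    seed: int = 0
    out_dir: str = "output"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    analyze: AnalyzeConfig = Field(default_factory=AnalyzeConfig)
    harmonize: HarmonizeConfig = Field(default_factory=HarmonizeConfig)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
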