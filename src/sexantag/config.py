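"""Structured configuration: TOML/YAML files mapped onto dataclasses.

A single config file with sections ``[model]``, ``[mating]``,
``[locus_sim]``, ``[genome_sim]`` and ``[sampling]`` parameterizes every
stage of the pipeline; any section may be omitted, in which case the
scenario defaults apply.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any

import yaml

from .genome_sim import GenomeSimConfig
from .locus_sim import LocusSimConfig
from .model import FitnessScheme, MateChoiceMatrix
from .sampling import SubsampleDesign

__all__ = ["load_config", "PipelineConfig"]


def _read(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


class PipelineConfig:
    """Parsed pipeline configuration with stage-level accessors."""

    def __init__(self, raw: dict[str, Any]):
        self.raw = raw

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls(_read(path))

    @property
    def stages(self) -> list[str]:
        default = ["equilibrium-scan", "locus-sim", "genome-sim",
                   "sampling-analysis"]
        return list(self.raw.get("stages", default))

    def scheme(self) -> FitnessScheme:
        sec = self.raw.get("model", {})
        return FitnessScheme(
            s=float(sec.get("s", 0.1)),
            alpha=float(sec.get("alpha", 1.0)),
            hf=float(sec.get("hf", 0.5)),
            hm=float(sec.get("hm", 0.5)),
        )

    def mating(self) -> MateChoiceMatrix:
        sec = self.raw.get("mating", {})
        return MateChoiceMatrix(
            m1=float(sec.get("m1", 1.0)),
            m2=float(sec.get("m2", 1.0)),
            m3=float(sec.get("m3", 1.0)),
        )

    def model_options(self) -> dict:
        sec = self.raw.get("model", {})
        return {
            "generations": int(sec.get("generations", 100)),
            "p0": float(sec.get("p0", 0.5)),
        }

    def locus_sim(self, seed: int | None = None) -> LocusSimConfig:
        sec = self.raw.get("locus_sim", {})
        return LocusSimConfig(
            n=int(sec.get("n", 20_000)),
            scheme=self.scheme(),
            mating=self.mating(),
            p0=float(sec.get("p0", self.model_options()["p0"])),
            generations=int(sec.get("generations", 50)),
            pairs=sec.get("pairs"),
            replicates=int(sec.get("replicates", 10)),
            seed=sec.get("seed", seed),
        )

    def genome_sim(
        self, neutral: bool = False, seed: int | None = None
    ) -> GenomeSimConfig:
        sec = dict(self.raw.get("genome_sim", {}))
        return GenomeSimConfig(
            carrying_capacity=int(sec.get("carrying_capacity", 10_000)),
            genome_length=float(sec.get("genome_length", 1e8)),
            recombination_rate=float(sec.get("recombination_rate", 1e-8)),
            mutation_rate=float(sec.get("mutation_rate", 1e-10)),
            steps=int(sec.get("steps", 1_000)),
            replicates=int(sec.get("replicates", 5)),
            neutral=bool(sec.get("neutral", neutral)),
            effect_sd=float(sec.get("effect_sd", 0.01)),
            seed=sec.get("seed", seed),
        )

    def sampling_designs(self, seed: int | None = None) -> list[SubsampleDesign]:
        sec = self.raw.get("sampling", {})
        sizes = sec.get("n_per_sex", [50, 25])
        estimator = sec.get("estimator", "eq4")
        reps = int(sec.get("replicates", 100))
        return [
            SubsampleDesign(
                n_female=int(n), n_male=int(n), estimator=estimator,
                replicates=reps, seed=seed,
            )
            for n in sizes
        ]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML or YAML pipeline configuration file."""
    return PipelineConfig.from_file(path)
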