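"""End-to-end pipeline: equilibrium scan, simulations, sampling analysis.

Ties the stages together behind a single root seed, writing TSV/JSON
artifacts plus a run manifest, and provides the miniature fixture
populations used by the test suite.  All numeric TSV output is written at
full double precision because the quantities of interest span 1e-5 to 0.7.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .equilibrium import equilibria_to_dataframe, find_equilibria, stability_bounds
from .genome_sim import GenomeSimConfig, GenomeSimResult, run_genome_sim
from .locus_sim import simulate_locus
from .model import FitnessScheme, MateChoiceMatrix
from .sampling import subsample_fst

__all__ = ["RunManifest", "run_pipeline", "generate_fixtures",
           "equilibrium_scan"]

log = logging.getLogger("sexantag")


@dataclass
class RunManifest:
    """Record of a pipeline run: config, seeds, outputs, timing."""

    seed: int | None
    version: str = __version__
    config: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    wall_clock_s: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def equilibrium_scan(
    s_values: np.ndarray,
    alpha_values: np.ndarray,
    hf: float = 0.5,
    hm: float = 0.5,
    mating: MateChoiceMatrix | None = None,
) -> pd.DataFrame:
    """Interior-equilibrium classification over an (s, alpha) grid.

    For each grid point, reports whether a stable interior equilibrium
    exists, its A1 frequency, and the closed-form alpha bounds for the
    additive random-mating case.
    """
    rows = []
    for s in s_values:
        lo, hi = stability_bounds(float(s))
        for alpha in alpha_values:
            scheme = FitnessScheme(float(s), float(alpha), hf=hf, hm=hm)
            interior = [
                r for r in find_equilibria(scheme, mating, n_grid=7)
                if not r.fixation
            ]
            stable = [r for r in interior if r.stable]
            rows.append(
                {
                    "s": float(s),
                    "alpha": float(alpha),
                    "alpha_low": lo,
                    "alpha_high": hi,
                    "n_interior": len(interior),
                    "stable_interior": bool(stable),
                    "pA1": stable[0].p_a1 if stable else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _stage_equilibrium(cfg: PipelineConfig, outdir: Path, seed) -> dict:
    scheme = cfg.scheme()
    mating = cfg.mating()
    eqs = find_equilibria(scheme, mating)
    df = equilibria_to_dataframe(eqs)
    path = outdir / "equilibria.tsv"
    _write_tsv(df, path)
    summary = outdir / "equilibria.json"
    with open(summary, "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=2)
    log.info("equilibrium-scan: %d fixed points (%d interior)",
             len(df), int((~df.fixation).sum()))
    return {"equilibria_tsv": str(path), "equilibria_json": str(summary)}

def _stage_locus_sim(cfg: PipelineConfig, outdir: Path, seed) -> dict:
    sim_cfg = cfg.locus_sim(seed=seed)
    result = simulate_locus(sim_cfg)
    path = outdir / "locus_sim.tsv"
    _write_tsv(result.to_dataframe(), path)
    summary = pd.DataFrame(
        {
            "generation": np.arange(result.pf.shape[1]),
            "mean_pA1_female": np.nanmean(result.pf, axis=0),
            "sd_pA1_female": np.nanstd(result.pf, axis=0),
            "mean_pA1_male": np.nanmean(result.pm, axis=0),
            "sd_pA1_male": np.nanstd(result.pm, axis=0),
        }
    )
    spath = outdir / "locus_sim_summary.tsv"
    _write_tsv(summary, spath)
    log.info("locus-sim: N=%d, %d replicates, %d generations, %d extinct",
             sim_cfg.n, sim_cfg.replicates, sim_cfg.generations,
             int(result.extinct.sum()))
    return {"locus_sim_tsv": str(path), "locus_sim_summary_tsv": str(spath)}


def _genome_outputs(res: GenomeSimResult, outdir: Path, label: str) -> dict:
    outs = {}
    for i, rep in enumerate(res.replicates):
        path = outdir / f"genome_{label}_rep{i}_loci.tsv"
        _write_tsv(rep.per_locus, path)
        outs[f"{label}_rep{i}_loci"] = str(path)
    summary = {
        "label": label,
        "mean_fst": res.mean_fst(),
        "mean_load": res.mean_load(),
        "mean_segregating": res.mean_segregating(),
        "pooled_snps_above_10pct": res.pooled_common_snps(0.10),
        "census_final": [int(r.census[-1]) for r in res.replicates],
        "extinct": [bool(r.extinct) for r in res.replicates],
    }
    spath = outdir / f"genome_{label}_summary.json"
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=2)
    outs[f"{label}_summary"] = str(spath)
    log.info("genome-sim[%s]: mean FST=%.3g, load=%.3g, %d SNPs>10%%",
             label, summary["mean_fst"], summary["mean_load"],
             summary["pooled_snps_above_10pct"])
    return outs


def _stage_genome(cfg: PipelineConfig, outdir: Path, seed) -> dict:
    outs = {}
    ss = np.random.SeedSequence(seed).spawn(2)
    for label, neutral, child in (
        ("antagonistic", False, ss[0]), ("neutral", True, ss[1])
    ):
        gcfg = cfg.genome_sim(neutral=neutral,
                              seed=int(child.generate_state(1)[0] % 2**31))
        res = run_genome_sim(gcfg)
        outs.update(_genome_outputs(res, outdir, label))
        outs[f"_{label}_result"] = res  # in-memory handoff to sampling stage
    return outs


def _stage_sampling(cfg: PipelineConfig, outdir: Path, seed,
                    genome_outputs: dict) -> dict:
    outs = {}
    rows = []
    for label in ("antagonistic", "neutral"):
        res = genome_outputs.get(f"_{label}_result")
        if res is None:
            continue
        for design in cfg.sampling_designs(seed=seed):
            for i, rep in enumerate(res.replicates):
                if rep.population.n_individuals == 0:
                    continue
                sub = subsample_fst(rep.population, design)
                rows.append({"scenario": label, "replicate": i,
                             **sub.summary()})
    df = pd.DataFrame(rows)
    path = outdir / "sampling_summary.tsv"
    _write_tsv(df, path)
    outs["sampling_summary_tsv"] = str(path)
    return outs


def run_pipeline(
    cfg: PipelineConfig, outdir: str | Path, seed: int | None = None
) -> RunManifest:
    """Execute the configured stages in order, writing all artifacts.

    Stage failure is recorded in the manifest and later stages that do not
    depend on the failed one still run.  Identical config and seed produce
    identical numeric outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config=cfg.raw)
    genome_outs: dict = {}
    stage_fns = {
        "equilibrium-scan": lambda: _stage_equilibrium(cfg, outdir, seed),
        "locus-sim": lambda: _stage_locus_sim(cfg, outdir, seed),
        "genome-sim": lambda: _stage_genome(cfg, outdir, seed),
        "sampling-analysis": lambda: _stage_sampling(
            cfg, outdir, seed, genome_outs
        ),
    }
    for stage in cfg.stages:
        fn = stage_fns.get(stage)
        if fn is None:
            raise ValueError(f"unknown stage: {stage}")
        t0 = time.perf_counter()
        try:
            outs = fn()
        except Exception as exc:  # record partial completion
            log.error("stage %s failed: %s", stage, exc)
            manifest.outputs[stage] = {"error": str(exc)}
            continue
        if stage == "genome-sim":
            genome_outs = outs
            outs = {k: v for k, v in outs.items() if not k.startswith("_")}
        manifest.outputs[stage] = outs
        manifest.stages_completed.append(stage)
        manifest.wall_clock_s[stage] = round(time.perf_counter() - t0, 3)
    manifest.write(outdir / "manifest.json")
    return manifest


def generate_fixtures(seed: int = 1, outdir: str | Path | None = None):
    """Miniature deterministic datasets for tests and examples.

    A small antagonistic and neutral population pair (K=200, 50 steps,
    mutation rate scaled up so a handful of loci segregate) plus a
    deterministic trajectory table.  Optionally writes them under
    ``outdir``; always returns them in memory.
    """
    from .model import GenotypeFrequencies, iterate

    ss = np.random.SeedSequence(seed).spawn(2)
    pops = {}
    for label, neutral, child in (
        ("antagonistic", False, ss[0]), ("neutral", True, ss[1])
    ):
        cfg = GenomeSimConfig(
            carrying_capacity=200,
            genome_length=1e6,
            recombination_rate=1e-8,
            mutation_rate=5e-8,
            steps=50,
            replicates=1,
            neutral=neutral,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        pops[label] = run_genome_sim(cfg).replicates[0]

    traj = iterate(
        GenotypeFrequencies.hardy_weinberg(0.5), FitnessScheme(0.1), steps=50
    ).to_dataframe()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, rep in pops.items():
            _write_tsv(rep.per_locus, outdir / f"fixture_{label}_loci.tsv")
        _write_tsv(traj, outdir / "fixture_trajectory.tsv")
    return pops, traj
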