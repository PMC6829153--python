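"""Stochastic single-locus simulator with drift, selection and mate choice.

Finite-population counterpart of the deterministic recursion: each
generation every individual survives with probability equal to its sex- and
genotype-specific viability, surviving genotype frequencies of the two sexes
are crossed into a mate-pairing distribution weighted by the mate-choice
matrix, a fixed number of mating pairs is sampled with replacement from that
distribution, and each pair contributes one offspring by independent random
choice of one allele per parent (sex assigned by a fair coin).

All replicates are advanced in lock-step with vectorized numpy sampling;
the per-genotype binomial draws are distributionally identical to
per-individual Bernoulli survival and per-pair categorical sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FitnessScheme, MateChoiceMatrix

__all__ = ["LocusSimConfig", "LocusSimResult", "simulate_locus"]

# offspring genotype distribution for each (male genotype, female genotype)
# pair: random choice of one allele per parent
_GAMETE_P = np.array([1.0, 0.5, 0.0])  # P(transmit A1 | genotype)


def _offspring_dists() -> np.ndarray:
    out = np.empty((3, 3, 3))
    for gm in range(3):
        for gf in range(3):
            am, af = _GAMETE_P[gm], _GAMETE_P[gf]
            out[gm, gf] = [
                am * af,
                am * (1 - af) + (1 - am) * af,
                (1 - am) * (1 - af),
            ]
    return out


_OFFSPRING = _offspring_dists()


@dataclass(frozen=True)
class LocusSimConfig:
    """Configuration of the stochastic single-locus simulation."""

    n: int  # diploid population size (zygotes per generation)
    scheme: FitnessScheme
    mating: MateChoiceMatrix = field(default_factory=MateChoiceMatrix.random_mating)
    p0: float = 0.5  # initial A1 frequency (zygotes drawn from HW)
    initial_counts: np.ndarray | None = None  # optional (2, 3) sex-by-genotype
    generations: int = 100
    pairs: int | None = None  # mating pairs sampled per generation; default n
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("population size must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.pairs is not None and self.pairs <= 0:
            raise ValueError("pairs must be positive")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")


@dataclass
class LocusSimResult:
    """Per-generation, per-replicate output of the single-locus simulation.

    ``pf``/``pm`` are post-selection adult A1 frequencies (NaN once a
    replicate is extinct), ``zygote_counts`` the sex-by-genotype zygote
    counts at the start of each generation, ``extinct`` flags replicates in
    which one sex died out.
    """

    pf: np.ndarray  # (replicates, generations+1)
    pm: np.ndarray
    zygote_counts: np.ndarray  # (replicates, generations+1, 2, 3)
    extinct: np.ndarray  # (replicates,) bool

    @property
    def p_zygote(self) -> np.ndarray:
        """Zygotic A1 frequency per replicate and generation."""
        total = self.zygote_counts.sum(axis=(2, 3))
        a1 = (
            2 * self.zygote_counts[..., 0] + self.zygote_counts[..., 1]
        ).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            return a1 / (2.0 * total)

    def to_dataframe(self) -> pd.DataFrame:
        reps, gens = self.pf.shape
        rep_idx = np.repeat(np.arange(reps), gens)
        gen_idx = np.tile(np.arange(gens), reps)
        counts = self.zygote_counts.reshape(reps * gens, 6)
        df = pd.DataFrame(
            {
                "replicate": rep_idx,
                "generation": gen_idx,
                "pA1_zygote": self.p_zygote.ravel(),
                "pA1_female": self.pf.ravel(),
                "pA1_male": self.pm.ravel(),
            }
        )
        for i, name in enumerate(
            ["f_11", "f_12", "f_22", "m_11", "m_12", "m_22"]
        ):
            df[f"count_{name}"] = counts[:, i]
        return df


def _initial_counts(cfg: LocusSimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.initial_counts is not None:
        counts = np.asarray(cfg.initial_counts, dtype=np.int64)
        if counts.shape != (2, 3):
            raise ValueError("initial_counts must have shape (2, 3)")
        return np.broadcast_to(counts, (cfg.replicates, 2, 3)).copy()
    q = 1.0 - cfg.p0
    hw = np.array([cfg.p0**2, 2 * cfg.p0 * q, q * q])
    geno = rng.multinomial(cfg.n, hw, size=cfg.replicates)
    females = rng.binomial(geno, 0.5)
    return np.stack([females, geno - females], axis=1).astype(np.int64)


def simulate_locus(cfg: LocusSimConfig) -> LocusSimResult:
    """Run the stochastic single-locus simulation for all replicates.

    Identical configuration and seed give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    reps, gens = cfg.replicates, cfg.generations
    n_pairs = cfg.pairs if cfg.pairs is not None else cfg.n
    M = cfg.mating.matrix

    pf = np.full((reps, gens + 1), np.nan)
    pm = np.full((reps, gens + 1), np.nan)
    zygotes = np.zeros((reps, gens + 1, 2, 3), dtype=np.int64)
    extinct = np.zeros(reps, dtype=bool)

    counts = _initial_counts(cfg, rng)  # (reps, 2, 3) sex-by-genotype zygotes
    w = np.stack([cfg.scheme.wf, cfg.scheme.wm])  # (2, 3), rows female/male

    for t in range(gens + 1):
        zygotes[:, t] = counts

        # viability selection: binomial survival per sex-genotype class
        adults = rng.binomial(counts, w[None, :, :])
        alive = ~extinct
        sex_totals = adults.sum(axis=2)  # (reps, 2)
        newly_dead = alive & (sex_totals.min(axis=1) == 0)
        extinct |= newly_dead
        alive = ~extinct

        a1_f = 2 * adults[:, 0, 0] + adults[:, 0, 1]
        a1_m = 2 * adults[:, 1, 0] + adults[:, 1, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            pf_t = a1_f / (2.0 * sex_totals[:, 0])
            pm_t = a1_m / (2.0 * sex_totals[:, 1])
        pf[alive, t] = pf_t[alive]
        pm[alive, t] = pm_t[alive]

        if t == gens:
            break

        # mate-pairing distribution: outer product of surviving male and
        # female genotype frequencies, weighted elementwise by M
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_f = adults[:, 0, :] / sex_totals[:, 0, None]
            freq_m = adults[:, 1, :] / sex_totals[:, 1, None]
        pair_w = freq_m[:, :, None] * freq_f[:, None, :] * M[None, :, :]
        pair_tot = pair_w.sum(axis=(1, 2))
        dead_now = alive & (pair_tot <= 0)
        extinct |= dead_now
        alive = ~extinct
        safe_tot = np.where(pair_tot > 0, pair_tot, 1.0)
        pair_p = (pair_w / safe_tot[:, None, None]).reshape(reps, 9)
        pair_p[~alive] = np.tile(np.eye(9)[0], (int((~alive).sum()), 1))

        pair_counts = rng.multinomial(n_pairs, pair_p)  # (reps, 9)

        # one offspring per sampled pair: genotype by parental allele draws
        offspring = np.zeros((reps, 3), dtype=np.int64)
        for cell in range(9):
            gm, gf = divmod(cell, 3)
            offspring += rng.multinomial(
                pair_counts[:, cell], _OFFSPRING[gm, gf]
            )
        # rescale brood to n zygotes if pairs != n (one offspring per pair)
        if n_pairs != cfg.n:
            total = offspring.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                probs = offspring / total
            probs[total.ravel() == 0] = np.array([1.0, 0, 0])
            offspring = rng.multinomial(cfg.n, probs)

        daughters = rng.binomial(offspring, 0.5)
        counts = np.stack([daughters, offspring - daughters], axis=1)
        counts[~alive] = 0

    return LocusSimResult(pf=pf, pm=pm, zygote_counts=zygotes, extinct=extinct)
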