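"""Forward-time individual-based simulation of genome-wide antagonism.

Synthetic-data generator emulating a population of ~10,000 diploids with a
100 Mb genome, per-nucleotide recombination rate 1e-8 and mutation rate
1e-10, evolving for 1,000 time steps with overlapping generations.  Every
mutation is sexually antagonistic: beneficial in a randomly chosen sex and
detrimental in the other, with per-sex effect magnitudes drawn independently
from a half-Gaussian of scale 0.01 and per-sex dominance drawn uniformly on
[0, 1].  A matched neutral control draws the same mutational process but
forces all selection coefficients to zero.

Each time step, Poisson(K) offspring are produced by random mother-father
pairs, then every individual (adult or newborn) survives with probability
``min(1, w * K / N)`` where ``w`` is its multiplicative own-sex fitness and
``N`` the pre-survival census — a simple density regulation that keeps the
census fluctuating around the carrying capacity ``K``.

Coordinates are continuous (infinite sites); no reference sequence exists.
Loci fixed in the population are folded into per-sex baseline fitness
constants (they still contribute to genetic load), and lost loci are pruned,
so the live matrix holds segregating loci only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .stats import multilocus_load

__all__ = [
    "GenomeSimConfig",
    "balanced_load",
    "LocusEffects",
    "PopulationState",
    "ReplicateResult",
    "GenomeSimResult",
    "run_genome_sim",
    "draw_effects",
    "new_mutations",
    "recombine",
    "recombine_with_breakpoints",
    "individual_fitness",
]


@dataclass(frozen=True)
class GenomeSimConfig:
    """Scenario parameters for the genome-wide simulation."""

    carrying_capacity: int = 10_000
    genome_length: float = 1e8
    recombination_rate: float = 1e-8  # per nucleotide per gamete
    mutation_rate: float = 1e-10  # per nucleotide per gamete
    steps: int = 1_000
    replicates: int = 5
    neutral: bool = False
    effect_sd: float = 0.01  # scale of the per-sex Gaussian effect draws
    balanced_threshold: float = 0.10  # derived-allele frequency bound for
    # the intermediate-frequency (balanced) class used in the load statistic
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 1:
            raise ValueError("carrying capacity must exceed 1")
        if min(self.recombination_rate, self.mutation_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if self.genome_length <= 0 or self.steps < 0 or self.replicates < 1:
            raise ValueError("invalid genome length / steps / replicates")


@dataclass
class LocusEffects:
    """Columnar table of segregating mutations (one entry per locus)."""

    position: np.ndarray
    s_f: np.ndarray
    s_m: np.ndarray
    h_f: np.ndarray
    h_m: np.ndarray
    origin: np.ndarray  # time step at which the mutation arose

    def __len__(self) -> int:
        return len(self.position)

    def take(self, idx: np.ndarray) -> "LocusEffects":
        return LocusEffects(
            *(getattr(self, f)[idx] for f in
              ("position", "s_f", "s_m", "h_f", "h_m", "origin"))
        )

    @classmethod
    def empty(cls) -> "LocusEffects":
        z = np.empty(0)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
                   np.empty(0, dtype=np.int64))

    @classmethod
    def concatenate(cls, a: "LocusEffects", b: "LocusEffects") -> "LocusEffects":
        return cls(
            *(np.concatenate([getattr(a, f), getattr(b, f)]) for f in
              ("position", "s_f", "s_m", "h_f", "h_m", "origin"))
        )


@dataclass
class PopulationState:
    """Final-step adult population with its segregating-locus table."""

    sex: np.ndarray  # (N,) uint8, 0 = female, 1 = male
    age: np.ndarray  # (N,) steps survived since birth
    haplotypes: np.ndarray  # (2N, L) uint8, rows 2i/2i+1 belong to individual i
    loci: LocusEffects

    @property
    def n_individuals(self) -> int:
        return len(self.sex)

    @property
    def genotypes(self) -> np.ndarray:
        """(N, L) derived-allele dosage matrix."""
        return (
            self.haplotypes[0::2].astype(np.int16)
            + self.haplotypes[1::2]
        ).astype(np.uint8)

    def sex_frequency_table(self) -> pd.DataFrame:
        """Per-locus derived-allele frequencies overall and by sex."""
        geno = self.genotypes
        fem = self.sex == 0
        n_f, n_m = int(fem.sum()), int((~fem).sum())
        cnt_f = geno[fem].sum(axis=0, dtype=np.int64)
        cnt_m = geno[~fem].sum(axis=0, dtype=np.int64)
        freq_f = cnt_f / (2.0 * max(n_f, 1))
        freq_m = cnt_m / (2.0 * max(n_m, 1))
        freq = (cnt_f + cnt_m) / (2.0 * (n_f + n_m))
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = (freq_m - freq_f) ** 2 / (4.0 * freq * (1.0 - freq))
        return pd.DataFrame(
            {
                "position": self.loci.position,
                "s_f": self.loci.s_f,
                "s_m": self.loci.s_m,
                "h_f": self.loci.h_f,
                "h_m": self.loci.h_m,
                "count_f": cnt_f,
                "count_m": cnt_m,
                "freq_f": freq_f,
                "freq_m": freq_m,
                "freq_total": freq,
                "fst_eq4": fst,
            }
        )


@dataclass
class ReplicateResult:
    """Output of one replicate of the genome simulation."""

    population: PopulationState
    per_locus: pd.DataFrame
    load: float
    census: np.ndarray  # adults after survival, per step
    segregating: np.ndarray  # segregating loci per step
    load_trajectory: np.ndarray | None = None
    #: per-sex summaries of final adult log fitness (diagnostics):
    #: mean/max own-sex log fitness and the fixed-locus baselines
    fitness_summary: dict | None = None
    extinct: bool = False

    @property
    def n_segregating(self) -> int:
        return len(self.population.loci)


@dataclass
class GenomeSimResult:
    config: GenomeSimConfig
    replicates: list[ReplicateResult] = field(default_factory=list)

    def mean_fst(self) -> float:
        """Mean whole-population per-locus FST across replicates."""
        vals = [
            np.nanmean(r.per_locus["fst_eq4"].to_numpy())
            for r in self.replicates
            if len(r.per_locus)
        ]
        return float(np.mean(vals)) if vals else float("nan")

    def mean_load(self) -> float:
        return float(np.mean([r.load for r in self.replicates]))

    def mean_segregating(self) -> float:
        return float(np.mean([r.n_segregating for r in self.replicates]))

    def pooled_common_snps(self, threshold: float = 0.10) -> int:
        """Loci above a derived-allele-frequency threshold, pooled."""
        return int(
            sum(
                (r.per_locus["freq_total"].to_numpy() > threshold).sum()
                for r in self.replicates
            )
        )


def draw_effects(
    n: int, cfg: GenomeSimConfig, rng: np.random.Generator, origin: int = 0
) -> LocusEffects:
    """Draw per-sex selection and dominance for ``n`` new mutations.

    A favored sex is chosen fairly per mutation; each sex's magnitude is an
    independent half-Gaussian draw of scale ``effect_sd``, signed + in the
    favored sex and - in the other.  Dominance is uniform per sex.  Neutral
    runs force both selection coefficients to zero (dominance still drawn).
    """
    mag_f = np.abs(rng.normal(0.0, cfg.effect_sd, n))
    mag_m = np.abs(rng.normal(0.0, cfg.effect_sd, n))
    female_favored = rng.integers(0, 2, n).astype(bool)
    s_f = np.where(female_favored, mag_f, -mag_f)
    s_m = np.where(female_favored, -mag_m, mag_m)
    if cfg.neutral:
        s_f = np.zeros(n)
        s_m = np.zeros(n)
    return LocusEffects(
        position=rng.uniform(0.0, cfg.genome_length, n),
        s_f=s_f,
        s_m=s_m,
        h_f=rng.uniform(0.0, 1.0, n),
        h_m=rng.uniform(0.0, 1.0, n),
        origin=np.full(n, origin, dtype=np.int64),
    )


def new_mutations(
    haplotype: np.ndarray,
    loci: LocusEffects,
    cfg: GenomeSimConfig,
    rng: np.random.Generator,
    origin: int = 0,
) -> tuple[np.ndarray, LocusEffects]:
    """Add Poisson(mu * genome length) new mutations to a single gamete.

    Returns the extended haplotype vector and locus table (new sites
    appended in position-sorted order).  Infinite-sites: every mutation is
    a new locus; collisions have probability zero at these rates.
    """
    n_new = rng.poisson(cfg.mutation_rate * cfg.genome_length)
    if n_new == 0:
        return haplotype.copy(), loci
    eff = draw_effects(n_new, cfg, rng, origin)
    merged = LocusEffects.concatenate(loci, eff)
    hap = np.concatenate([haplotype, np.ones(n_new, dtype=haplotype.dtype)])
    order = np.argsort(merged.position, kind="stable")
    return hap[order], merged.take(order)


def recombine_with_breakpoints(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions: np.ndarray,
    breakpoints: np.ndarray,
    start: int = 0,
) -> np.ndarray:
    """Reference gamete construction for given crossover breakpoints.

    The gamete copies ``hap_a`` (``start=0``) or ``hap_b`` up to the first
    breakpoint, then alternates.  Loci must be position-sorted.
    """
    haps = (np.asarray(hap_a), np.asarray(hap_b))
    seg = start + np.searchsorted(np.sort(breakpoints), positions, side="left")
    choose = seg % 2
    return np.where(choose == 0, haps[0], haps[1]).astype(hap_a.dtype)


def recombine(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions: np.ndarray,
    cfg: GenomeSimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete: Poisson(r * genome length) uniform crossovers."""
    n_co = rng.poisson(cfg.recombination_rate * cfg.genome_length)
    bps = rng.uniform(0.0, cfg.genome_length, n_co)
    start = int(rng.integers(0, 2))
    return recombine_with_breakpoints(hap_a, hap_b, positions, bps, start)


def individual_fitness(
    genotype: np.ndarray, s: np.ndarray, h: np.ndarray
) -> float:
    """Viability of one individual in one sex, clamped to [0, 1].

    Multiplicative across loci with per-locus genotype fitnesses
    ``(1, 1 + h*s, 1 + s)`` for dosage 0/1/2 of the derived allele.
    """
    genotype = np.asarray(genotype)
    w = 1.0
    het = genotype == 1
    hom = genotype == 2
    if het.any():
        w *= float(np.prod(1.0 + h[het] * s[het]))
    if hom.any():
        w *= float(np.prod(1.0 + s[hom]))
    return float(min(max(w, 0.0), 1.0))


def _sorted_per_gamete_breakpoints(
    n_gametes: int, rate: float, length: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform crossover positions, sorted within each gamete.

    Returns the flat breakpoint array and the (n_gametes+1,) offsets.
    Sorting uses a composite key so one global sort handles all gametes.
    """
    n_co = rng.poisson(rate * length, n_gametes)
    offsets = np.zeros(n_gametes + 1, dtype=np.int64)
    np.cumsum(n_co, out=offsets[1:])
    total = int(offsets[-1])
    bps = rng.uniform(0.0, length, total)
    gamete_of = np.repeat(np.arange(n_gametes), n_co)
    keys = np.sort(gamete_of * length + bps)
    return keys - gamete_of * length, offsets


def _run_one(cfg: GenomeSimConfig, rng: np.random.Generator) -> ReplicateResult:
    """One replicate of the overlapping-generations loop.

    The haplotype state is CSR-sparse: each haplotype row is the sorted
    list of locus ids it carries (ids ordered by genomic position), which
    keeps the per-step cost proportional to carried mutations rather than
    to individuals x segregating loci.
    """
    K = cfg.carrying_capacity
    glen = cfg.genome_length

    sex = rng.integers(0, 2, K).astype(np.uint8)
    age = np.zeros(K, dtype=np.int64)
    logw = np.zeros(K)
    idx = np.empty(0, dtype=np.int64)  # CSR column ids, 2 rows per individual
    ptr = np.zeros(2 * K + 1, dtype=np.int64)
    loci = LocusEffects.empty()

    # per-sex log-fitness every individual implicitly carries from fixed
    # loci, and the corresponding per-locus optimal-genotype log-fitness:
    # their difference is the inescapable deficit fixation leaves behind
    base_logw = np.zeros(2)  # female, male
    base_opt = np.zeros(2)

    census = np.zeros(cfg.steps, dtype=np.int64)
    segregating = np.zeros(cfg.steps, dtype=np.int64)
    load_traj = np.zeros(cfg.steps)
    extinct = False

    for step in range(cfg.steps):
        females = np.flatnonzero(sex == 0)
        males = np.flatnonzero(sex == 1)
        n_off = int(rng.poisson(K))
        if len(females) == 0 or len(males) == 0:
            extinct = True
            census[step:] = len(sex)
            segregating[step:] = len(loci)
            break

        n_adults = len(sex)
        n_loci = len(loci)
        rowlens = np.diff(ptr)

        # --- reproduction: one gamete from each parent of a random pair
        mothers = rng.choice(females, n_off)
        fathers = rng.choice(males, n_off)
        child_counts = np.zeros(2 * n_off, dtype=np.int64)
        lane_bufs = []
        for lane, parents in ((0, mothers), (1, fathers)):
            row0 = (2 * parents).astype(np.int64)
            upper = rowlens[row0] + rowlens[row0 + 1]
            ptr_upper = np.zeros(n_off + 1, dtype=np.int64)
            np.cumsum(upper, out=ptr_upper[1:])
            buf = np.empty(int(ptr_upper[-1]), dtype=np.int64)
            counts = np.zeros(n_off, dtype=np.int64)
            if n_loci:
                bp_flat, bp_off = _sorted_per_gamete_breakpoints(
                    n_off, cfg.recombination_rate, glen, rng
                )
                _kernels.transmit_sparse(
                    idx, ptr, loci.position, row0,
                    rng.integers(0, 2, n_off).astype(np.uint8),
                    bp_flat, bp_off, buf, ptr_upper, counts,
                )
            child_counts[lane::2] = counts
            lane_bufs.append((buf, ptr_upper, counts))

        child_ptr = np.zeros(2 * n_off + 1, dtype=np.int64)
        np.cumsum(child_counts, out=child_ptr[1:])
        child_idx = np.empty(int(child_ptr[-1]), dtype=np.int64)
        for lane, (buf, ptr_upper, counts) in enumerate(lane_bufs):
            _kernels.compact_rows(
                buf, ptr_upper, counts, child_idx, child_ptr[lane::2].copy()
            )

        # --- new mutations: fresh locus ids appended to carrier gametes
        eff_new = draw_effects(
            rng.poisson(cfg.mutation_rate * glen * 2 * n_off),
            cfg, rng, origin=step,
        )
        n_new = len(eff_new)
        dirty = np.zeros(2 * (n_adults + n_off), dtype=bool)
        if n_new:
            mut_rows = np.sort(rng.integers(0, 2 * n_off, n_new))
            new_cols = n_loci + np.arange(n_new, dtype=np.int64)
            child_idx = np.insert(child_idx, child_ptr[mut_rows + 1], new_cols)
            shift = np.zeros(2 * n_off + 1, dtype=np.int64)
            np.cumsum(np.bincount(mut_rows, minlength=2 * n_off),
                      out=shift[1:])
            child_ptr = child_ptr + shift
            child_counts = np.diff(child_ptr)
            dirty[2 * n_adults + mut_rows] = True
        loci = LocusEffects.concatenate(loci, eff_new)

        # --- offspring sex and fitness
        sex_off = rng.integers(0, 2, n_off).astype(np.uint8)
        logw_off = np.zeros(n_off)
        if not cfg.neutral and len(loci) and n_off:
            _kernels.log_fitness_sparse(
                child_idx, child_ptr, 0, n_off, sex_off,
                np.log1p(loci.h_f * loci.s_f), np.log1p(loci.s_f),
                np.log1p(loci.h_m * loci.s_m), np.log1p(loci.s_m),
                logw_off,
            )
            logw_off += base_logw[sex_off]

        n_tot = n_adults + n_off
        sex_all = np.concatenate([sex, sex_off])
        age_all = np.concatenate([age, np.zeros(n_off, dtype=np.int64)])
        logw_all = np.concatenate([logw, logw_off])
        idx_all = np.concatenate([idx, child_idx])
        ptr_all = np.concatenate([ptr, ptr[-1] + child_ptr[1:]])

        # --- viability + density regulation: P(survive) = min(1, w K / N)
        if cfg.neutral:
            p_surv = min(1.0, K / n_tot)
            keep = rng.random(n_tot) < p_surv
        else:
            keep = rng.random(n_tot) < np.minimum(
                1.0, np.exp(logw_all) * (K / n_tot)
            )
        if not keep.any() or not (sex_all[keep] == 0).any() or not (
            sex_all[keep] == 1
        ).any():
            extinct = True
        keep_hap = np.repeat(keep, 2)
        hap_lens = np.diff(ptr_all)
        entry_keep = np.repeat(keep_hap, hap_lens)
        idx = idx_all[entry_keep]
        kept_lens = hap_lens[keep_hap]
        ptr = np.zeros(len(kept_lens) + 1, dtype=np.int64)
        np.cumsum(kept_lens, out=ptr[1:])
        sex = sex_all[keep]
        age = age_all[keep] + 1
        logw = logw_all[keep]
        dirty = dirty[keep_hap]
        if extinct:
            census[step:] = len(sex)
            segregating[step:] = len(loci)
            break

        # --- column bookkeeping: prune lost, fold fixed into baselines
        n_hap = 2 * len(sex)
        cnt = np.bincount(idx, minlength=len(loci))
        fixed = cnt == n_hap
        alive_cols = (cnt > 0) & ~fixed
        if fixed.any():
            base_logw[0] += float(np.log1p(loci.s_f[fixed]).sum())
            base_logw[1] += float(np.log1p(loci.s_m[fixed]).sum())
            base_opt[0] += float(_best_genotype_log(
                loci.s_f[fixed], loci.h_f[fixed]).sum())
            base_opt[1] += float(_best_genotype_log(
                loci.s_m[fixed], loci.h_m[fixed]).sum())
            entry_alive = alive_cols[idx]
            idx = idx[entry_alive]
            # every surviving haplotype carries each fixed locus exactly once
            ptr = ptr - np.arange(len(ptr), dtype=np.int64) * int(fixed.sum())
        alive_idx = np.flatnonzero(alive_cols)
        order = alive_idx[np.argsort(loci.position[alive_idx], kind="stable")]
        old2new = np.full(len(loci), -1, dtype=np.int64)
        old2new[order] = np.arange(len(order))
        idx = old2new[idx]
        loci = loci.take(order)
        # rows that gained a brand-new locus id may now be unsorted after
        # position renumbering; all other rows stay sorted
        for r in np.flatnonzero(dirty):
            idx[ptr[r]:ptr[r + 1]].sort()

        census[step] = len(sex)
        segregating[step] = len(loci)
        load_traj[step] = _load_from_counts(
            cfg, loci, cnt[order] / float(n_hap)
        )

    pop = _to_population(sex, age, idx, ptr, loci)
    per_locus = pop.sex_frequency_table()

    fem = sex == 0
    summary = {
        "mean_logw_f": float(logw[fem].mean()) if fem.any() else float("nan"),
        "mean_logw_m": float(logw[~fem].mean()) if (~fem).any() else float("nan"),
        "max_logw_f": float(logw[fem].max()) if fem.any() else float("nan"),
        "max_logw_m": float(logw[~fem].max()) if (~fem).any() else float("nan"),
        "base_logw_f": float(base_logw[0]),
        "base_logw_m": float(base_logw[1]),
        "fixed_deficit_f": float(base_opt[0] - base_logw[0]),
        "fixed_deficit_m": float(base_opt[1] - base_logw[1]),
    }
    if not cfg.neutral and fem.any() and (~fem).any():
        # classical alternative: shortfall below the fittest realized
        # individual of each sex (cutoff-free, but sensitive to the
        # population's fitness variance rather than to the balanced class)
        summary["load_realized"] = multilocus_load(
            np.exp(logw[fem] - logw[fem].max()),
            np.exp(logw[~fem] - logw[~fem].max()),
        )

    return ReplicateResult(
        population=pop,
        per_locus=per_locus,
        load=_final_load(cfg, pop),
        census=census,
        segregating=segregating,
        load_trajectory=load_traj,
        fitness_summary=summary,
        extinct=extinct,
    )


def _to_population(sex, age, idx, ptr, loci) -> PopulationState:
    """Materialize the sparse haplotype state as a dense population."""
    hap = np.zeros((2 * len(sex), len(loci)), dtype=np.uint8)
    if len(loci) and len(idx):
        rows = np.repeat(np.arange(2 * len(sex)), np.diff(ptr))
        hap[rows, idx] = 1
    return PopulationState(sex=sex, age=age, haplotypes=hap, loci=loci)

def _best_genotype_log(s: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Per-locus log viability of the best genotype in one sex."""
    return np.maximum(0.0, np.maximum(np.log1p(h * s), np.log1p(s)))


def balanced_load(
    genotype_freqs: np.ndarray,
    s_f: np.ndarray,
    s_m: np.ndarray,
    h_f: np.ndarray,
    h_m: np.ndarray,
) -> float:
    """Multiplicative aggregation of the single-locus load across loci.

    ``genotype_freqs`` has shape (loci, 3): frequencies of derived-allele
    dosage 0/1/2.  Per locus and sex, the mean viability is compared with
    the best genotype of that sex (the single-locus load with the optimum
    normalized to one); per-sex loads combine multiplicatively across loci
    and the population load averages the two sexes.

    The caller restricts the input to intermediate-frequency loci: for a
    rare mutation the optimal genotype is absent from the population and
    the single-locus reference point is unattainable, so including rare
    loci would count phantom load that no individual could avoid.
    """
    g0, g1, g2 = genotype_freqs.T
    log_tot = np.zeros(2)
    for k, (s, h) in enumerate(((s_f, h_f), (s_m, h_m))):
        het = 1.0 + h * s
        hom = 1.0 + s
        wbar = g0 + g1 * het + g2 * hom
        best = np.maximum(1.0, np.maximum(het, hom))
        log_tot[k] = float(np.log(wbar / best).sum())
    return 1.0 - 0.5 * float(np.exp(log_tot).sum())


def _load_from_counts(
    cfg: GenomeSimConfig,
    loci: LocusEffects,
    freq: np.ndarray,
) -> float:
    """Hardy-Weinberg approximation of the balanced load from allele
    frequencies (used for the per-step trajectory; the final-state load
    uses exact genotype frequencies)."""
    if cfg.neutral:
        return 0.0
    keep = freq > cfg.balanced_threshold
    if not keep.any():
        return 0.0
    p = freq[keep]
    q = 1.0 - p
    genotype_freqs = np.stack([q * q, 2 * p * q, p * p], axis=1)
    return balanced_load(
        genotype_freqs, loci.s_f[keep], loci.s_m[keep],
        loci.h_f[keep], loci.h_m[keep],
    )


def _final_load(cfg: GenomeSimConfig, pop: PopulationState) -> float:
    """Balanced-polymorphism load from exact final genotype frequencies."""
    if cfg.neutral:
        return 0.0
    if len(pop.loci) == 0 or pop.n_individuals == 0:
        return 0.0 if pop.n_individuals else float("nan")
    geno = pop.genotypes
    freq = geno.sum(axis=0, dtype=np.int64) / (2.0 * pop.n_individuals)
    keep = freq > cfg.balanced_threshold
    if not keep.any():
        return 0.0
    g = geno[:, keep]
    genotype_freqs = np.stack(
        [(g == 0).mean(0), (g == 1).mean(0), (g == 2).mean(0)], axis=1
    )
    loci = pop.loci
    return balanced_load(
        genotype_freqs, loci.s_f[keep], loci.s_m[keep],
        loci.h_f[keep], loci.h_m[keep],
    )


def run_genome_sim(cfg: GenomeSimConfig) -> GenomeSimResult:
    """Run all replicates of the configured genome-wide scenario.

    Each replicate consumes an independent child seed of ``cfg.seed``, so
    results are reproducible and replicates are exchangeable.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    result = GenomeSimResult(config=cfg)
    for child in seeds:
        result.replicates.append(_run_one(cfg, np.random.default_rng(child)))
    return result
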