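"""Within-generation divergence and load statistics.

Sex-specific viability selection perturbs adult allele frequencies in
opposite directions each generation.  The resulting divergence is measured
with a male-female fixation index

    FST = (pm - pf)^2 / (4 (p11 + p12/2) (p22 + p12/2)),

the genome-wide sampling estimator of Weir & Cockerham (1984), the
population inbreeding coefficient FIS (sign convention: heterozygote excess
is *positive*, the negative of the classical 1 - Hobs/Hexp), and the genetic
load L = 1 - (w̄m + w̄f)/2, the average over sexes of the shortfall of mean
viability below the sex's optimal genotype.

Monomorphic loci have an undefined FST/FIS and yield NaN; callers exclude
them from distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FitnessScheme, GenotypeFrequencies, SexAlleleFrequencies

__all__ = [
    "SexCountTable",
    "male_female_fst",
    "fis",
    "load",
    "multilocus_load",
    "weir_cockerham_fst",
    "weir_cockerham_fst_counts",
    "hudson_fst_counts",
]


def male_female_fst(
    p: GenotypeFrequencies | np.ndarray,
    sexfreqs: SexAlleleFrequencies | tuple[float, float],
) -> float:
    """Population male-female FST from zygote frequencies and adult sex freqs.

    The denominator ``4 (p11 + p12/2)(p22 + p12/2)`` is the total
    heterozygosity ``4 p q`` of the zygote pool; returns NaN when the locus
    is monomorphic.
    """
    arr = p.as_array() if isinstance(p, GenotypeFrequencies) else np.asarray(p)
    pf, pm = (
        (sexfreqs.pf, sexfreqs.pm)
        if isinstance(sexfreqs, SexAlleleFrequencies)
        else sexfreqs
    )
    denom = 4.0 * (arr[0] + 0.5 * arr[1]) * (arr[2] + 0.5 * arr[1])
    if denom <= 0.0:
        return float("nan")
    return float((pm - pf) ** 2 / denom)


def fis(p: GenotypeFrequencies | np.ndarray) -> float:
    """Inbreeding coefficient; positive values mean heterozygote excess.

    ``FIS = p12 / (2 (p11 + p12/2)(p22 + p12/2)) - 1``; NaN for a
    monomorphic locus.  Note this is the negative of the classical
    ``1 - Hobs/Hexp`` convention.
    """
    arr = p.as_array() if isinstance(p, GenotypeFrequencies) else np.asarray(p)
    denom = 2.0 * (arr[0] + 0.5 * arr[1]) * (arr[2] + 0.5 * arr[1])
    if denom <= 0.0:
        return float("nan")
    return float(arr[1] / denom - 1.0)


def load(p: GenotypeFrequencies | np.ndarray, scheme: FitnessScheme) -> float:
    """Single-locus genetic load ``L = 1 - (w̄m + w̄f)/2``.

    ``w̄f = p · wf`` and ``w̄m = p · wm`` are the zygote-frequency-weighted
    mean relative viabilities; since each sex's optimal genotype has
    viability one, L is the average over sexes of the per-sex load (equal
    sex ratio assumed).
    """
    arr = p.as_array() if isinstance(p, GenotypeFrequencies) else np.asarray(p)
    wbar_f = float(arr @ scheme.wf)
    wbar_m = float(arr @ scheme.wm)
    return 1.0 - 0.5 * (wbar_m + wbar_f)


def multilocus_load(
    rel_viability_f: np.ndarray, rel_viability_m: np.ndarray
) -> float:
    """Genome-wide load from per-individual relative viabilities.

    Each individual's relative viability is its multiplicative fitness
    across loci normalized to its sex's realized optimum (the fittest
    individual of that sex); the load is one minus the average over sexes
    of the mean relative viability, mirroring the single-locus definition
    of load as the shortfall of mean fitness below the maximum.
    """
    rel_viability_f = np.asarray(rel_viability_f, dtype=float)
    rel_viability_m = np.asarray(rel_viability_m, dtype=float)
    if rel_viability_f.size == 0 or rel_viability_m.size == 0:
        return float("nan")
    return 1.0 - 0.5 * (rel_viability_f.mean() + rel_viability_m.mean())


@dataclass(frozen=True)
class SexCountTable:
    """Per-sex diploid sample sizes and A1 allele counts at one locus."""

    n_female: int
    n_male: int
    count_female: int
    count_male: int

    def __post_init__(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("need at least one diploid per sex")
        if not 0 <= self.count_female <= 2 * self.n_female:
            raise ValueError("female allele count exceeds 2 x diploid count")
        if not 0 <= self.count_male <= 2 * self.n_male:
            raise ValueError("male allele count exceeds 2 x diploid count")


def weir_cockerham_fst_counts(
    n_female, n_male, count_female, count_male
) -> np.ndarray:
    """Vectorized Weir-Cockerham theta-hat for the two sexes as demes.

    Variance-components estimator ``a / (a + b)`` with the sampled alleles
    as units (sample sizes ``2 n``); designed to be unbiased under neutral
    binomial sampling, so negative point estimates occur and are meaningful.
    With equal per-sex sample sizes this is exactly Hudson's estimator.
    Monomorphic samples give NaN.
    """
    n1 = 2.0 * np.asarray(n_female, dtype=float)
    n2 = 2.0 * np.asarray(n_male, dtype=float)
    p1 = np.asarray(count_female, dtype=float) / n1
    p2 = np.asarray(count_male, dtype=float) / n2

    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / (a + b)
    poly = (pbar > 0) & (pbar < 1)
    return np.where(poly, theta, np.nan)


def weir_cockerham_fst(table: SexCountTable) -> float:
    """Weir-Cockerham theta-hat between females and males at one locus."""
    return float(
        weir_cockerham_fst_counts(
            table.n_female, table.n_male, table.count_female, table.count_male
        )
    )


def hudson_fst_counts(n_female, n_male, count_female, count_male) -> np.ndarray:
    """Hudson's FST estimator on allele counts (cross-check companion)."""
    c1 = 2.0 * np.asarray(n_female, dtype=float)
    c2 = 2.0 * np.asarray(n_male, dtype=float)
    p1 = np.asarray(count_female, dtype=float) / c1
    p2 = np.asarray(count_male, dtype=float) / c2
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (c1 - 1)
        - p2 * (1 - p2) / (c2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)
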