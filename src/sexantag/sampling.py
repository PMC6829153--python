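"""Sampling variance of male-female FST estimated from finite samples.

Whole-population male-female FST under either neutrality or genome-wide
antagonism is of order 1e-5 to 1e-4, but estimates from samples of tens of
individuals per sex carry a sampling floor of roughly ``1/(4 n)`` per sex
(binomial noise in each sex's allele frequency), orders of magnitude larger.
This module quantifies that inflation: repeated subsampling of a simulated
population, sex-label randomization, Kolmogorov-Smirnov comparison of FST
distributions, and the correlation between per-locus whole-population and
subsampled FST.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genome_sim import PopulationState
from .stats import weir_cockerham_fst_counts

__all__ = ["SubsampleDesign", "SubsampleResult", "subsample_fst",
           "compare_distributions", "correlate_true_vs_sampled"]


@dataclass(frozen=True)
class SubsampleDesign:
    """One subsampling protocol for male-female FST estimation."""

    n_female: int
    n_male: int
    estimator: str = "eq4"  # "eq4" (population formula) or "wc"
    replicates: int = 100
    randomize_sex: bool = False  # draw groups ignoring recorded sex
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("need at least one individual per group")
        if self.estimator not in ("eq4", "wc"):
            raise ValueError("estimator must be 'eq4' or 'wc'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SubsampleResult:
    """Per-draw, per-locus FST estimates from repeated subsampling.

    ``values`` has shape (replicates, loci) with NaN at loci monomorphic in
    a given draw; summaries exclude those.
    """

    design: SubsampleDesign
    values: np.ndarray

    @property
    def pooled(self) -> np.ndarray:
        """All non-NaN per-locus estimates pooled across draws."""
        v = self.values.ravel()
        return v[~np.isnan(v)]

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values))

    @property
    def per_draw_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=1)

    def per_locus_means(self) -> np.ndarray:
        """Mean estimate per locus across draws (NaN if never polymorphic)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def summary(self) -> dict:
        pooled = self.pooled
        return {
            "n_female": self.design.n_female,
            "n_male": self.design.n_male,
            "estimator": self.design.estimator,
            "randomize_sex": self.design.randomize_sex,
            "replicates": self.design.replicates,
            "mean": self.mean,
            "sd": self.sd,
            "max": float(pooled.max()) if pooled.size else float("nan"),
        }


def subsample_fst(
    pop: PopulationState, design: SubsampleDesign
) -> SubsampleResult:
    """Estimate per-locus male-female FST from repeated random subsamples.

    Each draw takes ``n_female``/``n_male`` individuals without replacement
    from each sex (or, with ``randomize_sex``, from the whole population
    ignoring sex) and computes either the population FST formula on sample
    frequencies, ``(pm - pf)^2 / (4 p q)`` with ``p`` the pooled sample
    frequency, or the Weir-Cockerham estimator.  Loci monomorphic in the
    sample are NaN.
    """
    geno = pop.genotypes
    if geno.shape[1] == 0:
        raise ValueError("population has no segregating loci")
    females = np.flatnonzero(pop.sex == 0)
    males = np.flatnonzero(pop.sex == 1)
    rng = np.random.default_rng(design.seed)
    nf, nm = design.n_female, design.n_male

    if design.randomize_sex:
        everyone = np.arange(pop.n_individuals)
        if nf + nm > len(everyone):
            raise ValueError("subsample exceeds population size")
    else:
        if nf > len(females) or nm > len(males):
            raise ValueError("subsample exceeds available individuals per sex")

    out = np.empty((design.replicates, geno.shape[1]))
    for r in range(design.replicates):
        if design.randomize_sex:
            both = rng.choice(everyone, nf + nm, replace=False)
            grp_f, grp_m = both[:nf], both[nf:]
        else:
            grp_f = rng.choice(females, nf, replace=False)
            grp_m = rng.choice(males, nm, replace=False)
        cnt_f = geno[grp_f].sum(axis=0, dtype=np.int64)
        cnt_m = geno[grp_m].sum(axis=0, dtype=np.int64)
        if design.estimator == "wc":
            out[r] = weir_cockerham_fst_counts(nf, nm, cnt_f, cnt_m)
        else:
            pf = cnt_f / (2.0 * nf)
            pm = cnt_m / (2.0 * nm)
            p = (cnt_f + cnt_m) / (2.0 * (nf + nm))
            with np.errstate(divide="ignore", invalid="ignore"):
                fst = (pm - pf) ** 2 / (4.0 * p * (1.0 - p))
            out[r] = np.where((p > 0) & (p < 1), fst, np.nan)
    return SubsampleResult(design=design, values=out)


def compare_distributions(d1, d2) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of FST collections.

    Returns ``(D, p)`` using the asymptotic distribution.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    d1 = d1[~np.isnan(d1)]
    d2 = d2[~np.isnan(d2)]
    if d1.size == 0 or d2.size == 0:
        raise ValueError("cannot compare empty FST collections")
    res = sps.ks_2samp(d1, d2, method="asymp")
    return float(res.statistic), float(res.pvalue)


def correlate_true_vs_sampled(
    true_fst: np.ndarray, sampled_fst: np.ndarray
) -> float:
    """Pearson correlation of whole-population and subsampled per-locus FST.

    Loci with NaN in either input (monomorphic) are dropped; fewer than
    three shared polymorphic loci is an error.
    """
    true_fst = np.asarray(true_fst, dtype=float)
    sampled_fst = np.asarray(sampled_fst, dtype=float)
    if true_fst.shape != sampled_fst.shape:
        raise ValueError("per-locus FST vectors must be aligned")
    ok = ~np.isnan(true_fst) & ~np.isnan(sampled_fst)
    if ok.sum() < 3:
        raise ValueError("need at least three shared polymorphic loci")
    return float(sps.pearsonr(true_fst[ok], sampled_fst[ok]).statistic)
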