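"""Deterministic single-generation dynamics of a sexually antagonistic locus.

One autosomal locus with two alleles: A1 is beneficial in females, A2 in
males.  Each generation begins with identical zygotic genotype frequencies in
the two sexes; sex-specific viability selection then perturbs adult genotype
frequencies in opposite directions, adults mate with frequencies weighted by a
mate-choice matrix, and meiotic segregation rebuilds a common zygote pool.

Relative viabilities of A1A1 : A1A2 : A2A2 are ``1 : 1-hf*sf : 1-sf`` in
females and ``1-sm : 1-hm*sm : 1`` in males, with ``sm = s`` and
``sf = alpha*s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FitnessScheme",
    "GenotypeFrequencies",
    "MateChoiceMatrix",
    "SexAlleleFrequencies",
    "Trajectory",
    "NoViableMatingsError",
    "post_selection_freqs",
    "next_generation",
    "iterate",
]

_FREQ_TOL = 1e-12

# offspring-segregation projectors: beta picks the A1 gamete share of each
# genotype, gamma the A2 share; beta + gamma = I
_BETA = np.diag([1.0, 0.5, 0.0])
_GAMMA = np.diag([0.0, 0.5, 1.0])


class NoViableMatingsError(ValueError):
    """All fitness-weighted mating frequencies are zero."""


@dataclass(frozen=True)
class FitnessScheme:
    """Per-sex selection and dominance coefficients for one locus.

    Parameters
    ----------
    s : float
        Selection strength in males, ``0 <= s < 1`` (``sm = s``).
    alpha : float
        Ratio of female to male selection (``sf = alpha * s``).
    hf, hm : float
        Dominance coefficients in females and males, each in ``[0, 1]``.
    """

    s: float
    alpha: float = 1.0
    hf: float = 0.5
    hm: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.s < 1.0:
            raise ValueError(f"s must be in [0, 1), got {self.s}")
        if not 0.0 <= self.sf < 1.0:
            raise ValueError(f"sf = alpha*s = {self.sf} must be in [0, 1)")
        for name in ("hf", "hm"):
            h = getattr(self, name)
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {h}")

    @property
    def sm(self) -> float:
        return self.s

    @property
    def sf(self) -> float:
        return self.alpha * self.s

    @property
    def wf(self) -> np.ndarray:
        """Female viabilities of (A1A1, A1A2, A2A2)."""
        return np.array([1.0, 1.0 - self.hf * self.sf, 1.0 - self.sf])

    @property
    def wm(self) -> np.ndarray:
        """Male viabilities of (A1A1, A1A2, A2A2)."""
        return np.array([1.0 - self.sm, 1.0 - self.hm * self.sm, 1.0])

    def swapped(self) -> "FitnessScheme":
        """The sex-swapped scheme (sf<->sm, hf<->hm) under allele relabeling.

        Swapping sex roles *and* allele labels A1<->A2 maps trajectories of
        the original scheme onto reversed-triple trajectories of this one.
        """
        if self.alpha == 0 or self.s == 0:
            return FitnessScheme(self.sf, 1.0, hf=self.hm, hm=self.hf)
        return FitnessScheme(self.sf, self.sm / self.sf, hf=self.hm, hm=self.hf)


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Zygotic frequencies of genotypes (A1A1, A1A2, A2A2)."""

    p11: float
    p12: float
    p22: float

    def __post_init__(self) -> None:
        total = self.p11 + self.p12 + self.p22
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies sum to {total}, not 1")
        if min(self.p11, self.p12, self.p22) < -_FREQ_TOL:
            raise ValueError(f"negative genotype frequency in {self}")

    @classmethod
    def from_array(cls, p: np.ndarray) -> "GenotypeFrequencies":
        p = np.asarray(p, dtype=float)
        # defensive renormalization: clip FP dust and rescale
        p = np.clip(p, 0.0, None)
        return cls(*(p / p.sum()))

    @classmethod
    def hardy_weinberg(cls, p_a1: float) -> "GenotypeFrequencies":
        """Hardy-Weinberg proportions at A1 frequency ``p_a1``."""
        q = 1.0 - p_a1
        return cls(p_a1 * p_a1, 2.0 * p_a1 * q, q * q)

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p22])

    @property
    def p_a1(self) -> float:
        """Zygotic frequency of the female-beneficial allele A1."""
        return self.p11 + 0.5 * self.p12


@dataclass(frozen=True)
class MateChoiceMatrix:
    """Relative mating-frequency weights with three-fold symmetry.

    Expands to the 3x3 matrix ``M`` (rows: male genotype, columns: female
    genotype) with ``m1`` on the diagonal, ``m2`` adjacent off-diagonal and
    ``m3`` in the corners.  Weights are relative: ``M`` and ``c*M`` give
    identical dynamics because the reproduction recursion normalizes by the
    total mating frequency.
    """

    m1: float = 1.0
    m2: float = 1.0
    m3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.m1, self.m2, self.m3) < 0:
            raise ValueError("mate-choice weights must be nonnegative")
        if max(self.m1, self.m2, self.m3) <= 0:
            raise ValueError("at least one mate-choice weight must be positive")

    @classmethod
    def random_mating(cls) -> "MateChoiceMatrix":
        return cls(1.0, 1.0, 1.0)

    @classmethod
    def assortative_by_genotype(cls, strength: float) -> "MateChoiceMatrix":
        """Like genotypes mate more often (m1 > m2 = m3); strength > 1."""
        return cls(strength, 1.0, 1.0)

    @classmethod
    def assortative_by_fitness(cls, strength: float) -> "MateChoiceMatrix":
        """Opposite homozygotes mate more often (m3 > m2 = m1); strength > 1."""
        return cls(1.0, 1.0, strength)

    @property
    def matrix(self) -> np.ndarray:
        m1, m2, m3 = self.m1, self.m2, self.m3
        return np.array([[m1, m2, m3], [m2, m1, m2], [m3, m2, m1]])


@dataclass(frozen=True)
class SexAlleleFrequencies:
    """Post-selection adult allele and genotype frequencies by sex."""

    pf: float
    pm: float
    #: post-selection genotype frequency triples (A1A1, A1A2, A2A2)
    female_genotypes: tuple = field(default=None, compare=False)
    male_genotypes: tuple = field(default=None, compare=False)


def post_selection_freqs(
    p: GenotypeFrequencies, scheme: FitnessScheme
) -> SexAlleleFrequencies:
    """Adult (post-viability-selection) allele frequencies in each sex.

    Females: ``pf = (p11 + p12*(1-hf*sf)/2) / (p11 + p12*(1-hf*sf) + p22*(1-sf))``
    and symmetrically for males with the male viabilities.

    Raises
    ------
    ValueError
        If all fitness-weighted genotype frequencies in a sex are zero.
    """
    arr = p.as_array()
    out = {}
    for sex, w in (("f", scheme.wf), ("m", scheme.wm)):
        weighted = arr * w
        total = weighted.sum()
        if total <= 0.0:
            raise ValueError(
                f"no surviving {'females' if sex == 'f' else 'males'}: "
                "all fitness-weighted genotype frequencies are zero"
            )
        adult = weighted / total
        out[sex] = (adult[0] + 0.5 * adult[1], tuple(adult))
    return SexAlleleFrequencies(
        pf=out["f"][0],
        pm=out["m"][0],
        female_genotypes=out["f"][1],
        male_genotypes=out["m"][1],
    )


def _fitness_weighted_pairings(
    scheme: FitnessScheme, M: MateChoiceMatrix
) -> np.ndarray:
    """F = diag(wm) @ M @ diag(wf): fitness-weighted mate-pairing weights."""
    return scheme.wm[:, None] * M.matrix * scheme.wf[None, :]


def next_generation(
    p: GenotypeFrequencies,
    scheme: FitnessScheme,
    M: MateChoiceMatrix | None = None,
) -> GenotypeFrequencies:
    """Zygotic genotype frequencies in the next generation.

    With ``F = diag(wm) M diag(wf)``, ``beta = diag(1, 1/2, 0)`` and
    ``gamma = diag(0, 1/2, 1)``::

        p11' = p^T beta F beta p / p^T F p
        p22' = p^T gamma F gamma p / p^T F p
        p12' = 1 - p11' - p22'

    Raises
    ------
    NoViableMatingsError
        If ``p^T F p = 0`` (no fitness-weighted matings possible).
    """
    if M is None:
        M = MateChoiceMatrix.random_mating()
    vec = p.as_array()
    F = _fitness_weighted_pairings(scheme, M)
    denom = vec @ F @ vec
    if denom <= 0.0:
        raise NoViableMatingsError(
            "total fitness-weighted mating frequency is zero"
        )
    bp = _BETA @ vec
    gp = _GAMMA @ vec
    p11 = bp @ F @ bp / denom
    p22 = gp @ F @ gp / denom
    return GenotypeFrequencies.from_array(np.array([p11, 1.0 - p11 - p22, p22]))


@dataclass
class Trajectory:
    """Deterministic trajectory of the recursion.

    ``genotypes[t]`` are zygotic frequencies at generation ``t``;
    ``pf[t]``/``pm[t]`` the adult post-selection A1 frequencies of that
    generation.
    """

    genotypes: np.ndarray  # (steps+1, 3)
    pf: np.ndarray
    pm: np.ndarray

    @property
    def p_a1(self) -> np.ndarray:
        return self.genotypes[:, 0] + 0.5 * self.genotypes[:, 1]

    def final(self) -> GenotypeFrequencies:
        return GenotypeFrequencies.from_array(self.genotypes[-1])

    def to_dataframe(self) -> pd.DataFrame:
        g = self.genotypes
        return pd.DataFrame(
            {
                "generation": np.arange(len(g)),
                "p11": g[:, 0],
                "p12": g[:, 1],
                "p22": g[:, 2],
                "pA1": self.p_a1,
                "pf": self.pf,
                "pm": self.pm,
            }
        )


def iterate(
    p0: GenotypeFrequencies,
    scheme: FitnessScheme,
    M: MateChoiceMatrix | None = None,
    steps: int = 100,
) -> Trajectory:
    """Apply the recursion ``steps`` times, recording adult sex frequencies."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if M is None:
        M = MateChoiceMatrix.random_mating()
    genotypes = np.empty((steps + 1, 3))
    pf = np.empty(steps + 1)
    pm = np.empty(steps + 1)
    p = p0
    for t in range(steps + 1):
        genotypes[t] = p.as_array()
        sf = post_selection_freqs(p, scheme)
        pf[t], pm[t] = sf.pf, sf.pm
        if t < steps:
            p = next_generation(p, scheme, M)
    return Trajectory(genotypes=genotypes, pf=pf, pm=pm)
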