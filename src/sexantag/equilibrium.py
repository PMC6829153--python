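"""Fixed points of the two-sex recursion and their stability.

Under random mating and additive effects the interior equilibrium has the
closed form ``p̂_A1 = 1/2 - (1-alpha)/(2 s alpha)``, valid (and stable) for
``1/(1+s) < alpha < 1/(1-s)``.  Away from that special case the fixed-point
condition is a fifth-order polynomial with no useful closed form, so interior
equilibria are located numerically from a dense multi-start search over the
genotype-frequency simplex, and stability is read off the spectral radius of
a finite-difference Jacobian of the two free coordinates (p11, p22).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import (
    FitnessScheme,
    GenotypeFrequencies,
    MateChoiceMatrix,
    next_generation,
)

__all__ = [
    "EquilibriumResult",
    "additive_equilibrium",
    "stability_bounds",
    "dominance_stability_rule",
    "find_equilibria",
    "classify_stability",
    "equilibria_to_dataframe",
]

_INTERIOR_TOL = 1e-10
_DEDUP_TOL = 1e-8
_FIXED_POINT_TOL = 1e-10
_JACOBIAN_STEP = 1e-6
_STABILITY_MARGIN = 1e-9


@dataclass(frozen=True)
class EquilibriumResult:
    """A fixed point of the recursion with its local stability."""

    frequencies: GenotypeFrequencies
    stable: bool
    leading_eigenvalue: float
    fixation: bool = False

    @property
    def p_a1(self) -> float:
        return self.frequencies.p_a1


def additive_equilibrium(s: float, alpha: float) -> float:
    """Closed-form interior A1 equilibrium frequency (random mating, additive).

    ``p̂ = 1/2 - (1-alpha) / (2 s alpha)``.  The caller must check the result
    lies in (0, 1) for biological validity.
    """
    if s <= 0 or alpha <= 0:
        raise ValueError("additive equilibrium requires s > 0 and alpha > 0")
    return 0.5 - (1.0 - alpha) / (2.0 * s * alpha)


def stability_bounds(s: float) -> tuple[float, float]:
    """Bounds on alpha for a valid stable additive polymorphism.

    A polymorphism is maintained iff ``1/(1+s) < alpha < 1/(1-s)``: when
    selection is weak the window collapses to alpha = 1, i.e. approximately
    equal selection in the two sexes is required.
    """
    if not 0 < s < 1:
        raise ValueError("s must be in (0, 1)")
    return 1.0 / (1.0 + s), 1.0 / (1.0 - s)


def dominance_stability_rule(hf: float, hm: float) -> bool:
    """Stability of the symmetric-selection equilibrium by dominance.

    At alpha = 1 under random mating, the interior equilibrium is stable
    when ``hf + hm <= 1``: the mean fitness of homozygotes must not exceed
    that of heterozygotes.  Sums above one favor the locally deleterious
    allele in each sex, destabilizing the polymorphism.  The rule is the
    weak-selection boundary: at finite ``s`` it is a sufficient condition,
    with the exact (Jacobian) boundary sitting slightly above one (near
    1.04 at s = 0.1).
    """
    if not (0 <= hf <= 1 and 0 <= hm <= 1):
        raise ValueError("dominance coefficients must lie in [0, 1]")
    return hf + hm <= 1.0


def _free_coords_map(
    xy: np.ndarray, scheme: FitnessScheme, M: MateChoiceMatrix
) -> np.ndarray:
    """One recursion step expressed on the free coordinates (p11, p22)."""
    p11, p22 = xy
    p = GenotypeFrequencies.from_array(
        np.array([p11, 1.0 - p11 - p22, p22])
    )
    nxt = next_generation(p, scheme, M)
    return np.array([nxt.p11, nxt.p22])


def _jacobian(
    xy: np.ndarray, scheme: FitnessScheme, M: MateChoiceMatrix
) -> np.ndarray:
    """Central-difference Jacobian of the (p11, p22) update map."""
    J = np.empty((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = _JACOBIAN_STEP
        hi = _free_coords_map(xy + step, scheme, M)
        lo = _free_coords_map(xy - step, scheme, M)
        J[:, j] = (hi - lo) / (2.0 * _JACOBIAN_STEP)
    return J


def _spectral_radius(
    p: GenotypeFrequencies, scheme: FitnessScheme, M: MateChoiceMatrix
) -> float:
    """Spectral radius of the linearized (p11, p22) map at a fixed point.

    Boundary fixed points (fixation states) are evaluated at a point nudged
    slightly into the simplex interior: the map is smooth there, while
    central differences straddling the boundary would hit the defensive
    clipping and return garbage.
    """
    xy = np.array([p.p11, p.p22])
    if min(p.p11, p.p12, p.p22) < 1e-7:
        center = np.array([0.25, 0.25])
        xy = xy * (1.0 - 1e-4) + center * 1e-4
    eigvals = np.linalg.eigvals(_jacobian(xy, scheme, M))
    return float(np.abs(eigvals).max())


def classify_stability(
    eq: GenotypeFrequencies | EquilibriumResult,
    scheme: FitnessScheme,
    M: MateChoiceMatrix | None = None,
) -> EquilibriumResult:
    """Classify a fixed point as stable/unstable by its numeric Jacobian.

    Stability means the spectral radius of the linearized (p11, p22) map is
    below one (with a small margin against FP noise).  Raises ``ValueError``
    if the input is not actually a fixed point of the recursion.
    """
    if M is None:
        M = MateChoiceMatrix.random_mating()
    p = eq.frequencies if isinstance(eq, EquilibriumResult) else eq
    nxt = next_generation(p, scheme, M)
    resid = np.abs(nxt.as_array() - p.as_array()).max()
    if resid > 100 * _FIXED_POINT_TOL:
        raise ValueError(f"not a fixed point (residual {resid:.2e})")
    rho = _spectral_radius(p, scheme, M)
    return EquilibriumResult(
        frequencies=p,
        stable=rho < 1.0 - _STABILITY_MARGIN,
        leading_eigenvalue=rho,
        fixation=max(p.p11, p.p22) > 1.0 - 1e-9,
    )


def interior_equilibrium(
    scheme: FitnessScheme,
    M: MateChoiceMatrix | None = None,
    x0: np.ndarray | None = None,
) -> EquilibriumResult | None:
    """Fast single-start interior fixed point, or None if the solver
    leaves the simplex interior.

    Suited to parameter scans where at most one interior equilibrium is
    expected (e.g. random mating); ``find_equilibria`` is the exhaustive
    multi-start search.
    """
    if M is None:
        M = MateChoiceMatrix.random_mating()
    if x0 is None:
        x0 = np.array([0.25, 0.25])

    def residual(xy: np.ndarray) -> np.ndarray:
        p11 = min(max(xy[0], 0.0), 1.0)
        p22 = min(max(xy[1], 0.0), 1.0)
        return _free_coords_map(np.array([p11, p22]), scheme, M) - np.array(
            [p11, p22]
        )

    # retry ladder: the caller's seed, Hardy-Weinberg seeds across the
    # frequency range, and iteration-polished variants (a few recursion
    # steps pull starts into the attracting neighborhood of a stable
    # equilibrium and sharpen near-boundary cases)
    seeds = [np.asarray(x0, dtype=float)]
    for pa in (0.5, 0.2, 0.8, 0.05, 0.95):
        seeds.append(np.array([pa * pa, (1 - pa) * (1 - pa)]))
    polished = []
    for seed in seeds[:3]:
        xy = seed.copy()
        try:
            for _ in range(60):
                xy = _free_coords_map(xy, scheme, M)
        except Exception:
            continue
        polished.append(xy)
    for xy in seeds + polished:
        sol = root(residual, xy, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        p11, p22 = sol.x
        p12 = 1.0 - p11 - p22
        if min(p11, p22, p12) <= _INTERIOR_TOL:
            continue
        if np.abs(residual(sol.x)).max() > _FIXED_POINT_TOL:
            continue
        p = GenotypeFrequencies.from_array(np.array([p11, p12, p22]))
        return classify_stability(p, scheme, M)
    return None


def _seed_points(n_grid: int = 21) -> np.ndarray:
    """Simplex grid over (p11, p22) plus Hardy-Weinberg curve seeds."""
    seeds = []
    grid = np.linspace(0.01, 0.99, n_grid)
    for a in grid:
        for b in grid:
            if a + b < 0.999:
                seeds.append((a, b))
    for pa in np.linspace(0.02, 0.98, 25):
        seeds.append((pa * pa, (1 - pa) * (1 - pa)))
    return np.array(seeds)


def find_equilibria(
    scheme: FitnessScheme,
    M: MateChoiceMatrix | None = None,
    n_grid: int = 21,
) -> list[EquilibriumResult]:
    """All fixed points of the recursion: fixation states plus interior ones.

    Interior equilibria (all three genotype frequencies above 1e-10) are
    found by a multi-start Newton-type root search over the (p11, p22)
    simplex, de-duplicated at 1e-8.  The two fixation states are always
    included, flagged with ``fixation=True``.  An empty interior set is a
    valid outcome (e.g. alpha outside the stability bounds).
    """
    if M is None:
        M = MateChoiceMatrix.random_mating()

    results: list[EquilibriumResult] = []
    for p_fix in (GenotypeFrequencies(1, 0, 0), GenotypeFrequencies(0, 0, 1)):
        rho = _spectral_radius(p_fix, scheme, M)
        results.append(
            EquilibriumResult(
                frequencies=p_fix,
                stable=rho < 1.0 - _STABILITY_MARGIN,
                leading_eigenvalue=rho,
                fixation=True,
            )
        )

    def residual(xy: np.ndarray) -> np.ndarray:
        p11, p22 = xy
        p12 = 1.0 - p11 - p22
        if min(p11, p22, p12) < -0.2 or max(p11, p22) > 1.2:
            return np.array([10.0, 10.0])  # push solver back to the simplex
        p11 = min(max(p11, 0.0), 1.0)
        p22 = min(max(p22, 0.0), 1.0)
        return _free_coords_map(np.array([p11, p22]), scheme, M) - np.array(
            [p11, p22]
        )

    found: list[np.ndarray] = []
    for seed in _seed_points(n_grid):
        sol = root(residual, seed, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        p11, p22 = sol.x
        p12 = 1.0 - p11 - p22
        if min(p11, p22, p12) <= _INTERIOR_TOL:
            continue  # boundary/fixation, already handled
        if np.abs(residual(sol.x)).max() > _FIXED_POINT_TOL:
            continue
        if any(np.abs(f - sol.x).max() < _DEDUP_TOL for f in found):
            continue
        found.append(sol.x.copy())

    for xy in found:
        p = GenotypeFrequencies.from_array(
            np.array([xy[0], 1.0 - xy[0] - xy[1], xy[1]])
        )
        results.append(classify_stability(p, scheme, M))
    return results


def equilibria_to_dataframe(results: list[EquilibriumResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        p = r.frequencies
        rows.append(
            {
                "p11": p.p11,
                "p12": p.p12,
                "p22": p.p22,
                "pA1": p.p_a1,
                "stable": r.stable,
                "leading_eigenvalue": r.leading_eigenvalue,
                "fixation": r.fixation,
            }
        )
    return pd.DataFrame(rows)
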