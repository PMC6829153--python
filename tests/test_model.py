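"""Core recursion: selection, mate-choice reproduction, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexantag.model import (
    FitnessScheme,
    GenotypeFrequencies,
    MateChoiceMatrix,
    NoViableMatingsError,
    iterate,
    next_generation,
    post_selection_freqs,
)

schemes = st.builds(
    FitnessScheme,
    s=st.floats(0.0, 0.9),
    alpha=st.floats(0.05, 1.1),
    hf=st.floats(0.0, 1.0),
    hm=st.floats(0.0, 1.0),
)
genotype_triples = st.tuples(
    st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.01, 1.0)
).map(lambda t: GenotypeFrequencies.from_array(np.array(t)))
matings = st.builds(
    MateChoiceMatrix,
    m1=st.floats(0.1, 5.0),
    m2=st.floats(0.1, 5.0),
    m3=st.floats(0.1, 5.0),
)


class TestFitnessScheme:
    def test_viability_vectors(self):
        sch = FitnessScheme(s=0.2, alpha=1.5, hf=0.25, hm=0.75)
        assert sch.sm == 0.2
        assert sch.sf == pytest.approx(0.3)
        np.testing.assert_allclose(sch.wf, [1.0, 1 - 0.25 * 0.3, 1 - 0.3])
        np.testing.assert_allclose(sch.wm, [1 - 0.2, 1 - 0.75 * 0.2, 1.0])

    @pytest.mark.parametrize(
        "kwargs", [{"s": 1.0}, {"s": -0.1}, {"s": 0.5, "alpha": 2.5},
                   {"s": 0.1, "hf": 1.5}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FitnessScheme(**kwargs)


class TestPostSelectionFreqs:
    def test_additive_example(self, additive_scheme):
        # hand evaluation: pf = (0.25 + 0.25*0.95)/0.95
        sf = post_selection_freqs(
            GenotypeFrequencies(0.25, 0.5, 0.25), additive_scheme
        )
        assert sf.pf == pytest.approx(0.51315789473684, abs=1e-10)
        assert sf.pm == pytest.approx(0.48684210526316, abs=1e-10)

    def test_no_selection_leaves_frequencies(self):
        sf = post_selection_freqs(
            GenotypeFrequencies(0.25, 0.5, 0.25), FitnessScheme(0.0)
        )
        assert sf.pf == pytest.approx(0.5) and sf.pm == pytest.approx(0.5)

    def test_fixed_allele(self, additive_scheme):
        sf = post_selection_freqs(GenotypeFrequencies(1, 0, 0), additive_scheme)
        assert sf.pf == 1.0 and sf.pm == 1.0

    def test_adult_genotype_triples_normalized(self, additive_scheme):
        sf = post_selection_freqs(
            GenotypeFrequencies(0.2, 0.3, 0.5), additive_scheme
        )
        assert sum(sf.female_genotypes) == pytest.approx(1.0, abs=1e-12)
        assert sum(sf.male_genotypes) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(p=genotype_triples, scheme=schemes)
    def test_selection_favors_a1_in_females(self, p, scheme):
        sf = post_selection_freqs(p, scheme)
        assert sf.pf >= p.p_a1 - 1e-12
        assert sf.pm <= p.p_a1 + 1e-12


def _mating_table_oracle(p, scheme, M):
    """Brute-force 9-mating-pair enumeration of the next zygote pool."""
    vec = p.as_array()
    F = scheme.wm[:, None] * M.matrix * scheme.wf[None, :]
    seg = np.array([1.0, 0.5, 0.0])  # P(transmit A1) per genotype
    out = np.zeros(3)
    total = 0.0
    for gm in range(3):
        for gf in range(3):
            w = vec[gm] * F[gm, gf] * vec[gf]
            total += w
            am, af = seg[gm], seg[gf]
            out[0] += w * am * af
            out[1] += w * (am * (1 - af) + (1 - am) * af)
            out[2] += w * (1 - am) * (1 - af)
    return out / total


class TestNextGeneration:
    def test_neutral_hw_fixed_point(self, hw_half):
        nxt = next_generation(hw_half, FitnessScheme(0.0))
        np.testing.assert_allclose(nxt.as_array(), hw_half.as_array(),
                                   atol=1e-14)

    def test_hw_reached_in_one_generation(self):
        nxt = next_generation(
            GenotypeFrequencies(0.5, 0.0, 0.5), FitnessScheme(0.0)
        )
        np.testing.assert_allclose(nxt.as_array(), [0.25, 0.5, 0.25],
                                   atol=1e-14)

    def test_symmetric_selection_preserves_half_frequency(
        self, additive_scheme, hw_half
    ):
        nxt = next_generation(hw_half, additive_scheme)
        assert nxt.p_a1 == pytest.approx(0.5, abs=1e-14)
        oracle = _mating_table_oracle(
            hw_half, additive_scheme, MateChoiceMatrix.random_mating()
        )
        np.testing.assert_allclose(nxt.as_array(), oracle, atol=1e-12)

    @settings(max_examples=150, deadline=None)
    @given(p=genotype_triples, scheme=schemes, M=matings)
    def test_matches_mating_table_enumeration(self, p, scheme, M):
        nxt = next_generation(p, scheme, M)
        np.testing.assert_allclose(
            nxt.as_array(), _mating_table_oracle(p, scheme, M), atol=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(p=genotype_triples, scheme=schemes, M=matings,
           c=st.floats(0.1, 10.0))
    def test_mate_choice_scale_invariance(self, p, scheme, M, c):
        scaled = MateChoiceMatrix(c * M.m1, c * M.m2, c * M.m3)
        np.testing.assert_allclose(
            next_generation(p, scheme, M).as_array(),
            next_generation(p, scheme, scaled).as_array(),
            atol=1e-12,
        )

    @settings(max_examples=50, deadline=None)
    @given(p=genotype_triples, scheme=schemes, M=matings)
    def test_output_is_a_distribution(self, p, scheme, M):
        nxt = next_generation(p, scheme, M)
        arr = nxt.as_array()
        assert abs(arr.sum() - 1.0) < 1e-12
        assert (arr >= 0).all()

    @settings(max_examples=50, deadline=None)
    @given(p=genotype_triples, scheme=schemes, M=matings)
    def test_sex_and_allele_swap_symmetry(self, p, scheme, M):
        # swapping sex roles and allele labels maps trajectories exactly
        nxt = next_generation(p, scheme, M).as_array()
        p_sw = GenotypeFrequencies(p.p22, p.p12, p.p11)
        nxt_sw = next_generation(p_sw, scheme.swapped(), M).as_array()
        np.testing.assert_allclose(nxt, nxt_sw[::-1], atol=1e-12)

    @pytest.mark.parametrize(
        "p", [GenotypeFrequencies(1, 0, 0), GenotypeFrequencies(0, 0, 1)]
    )
    def test_fixation_states_are_fixed_points(self, p):
        scheme = FitnessScheme(0.6, 1.2, hf=0.9, hm=0.1)
        M = MateChoiceMatrix(2.0, 0.5, 3.0)
        np.testing.assert_allclose(
            next_generation(p, scheme, M).as_array(), p.as_array(), atol=1e-14
        )

    def test_no_viable_matings_raises(self):
        # m1=m2=0, m3>0 pairs only opposite homozygotes; with only A1A1
        # present there are no viable matings
        with pytest.raises(NoViableMatingsError):
            next_generation(
                GenotypeFrequencies(1, 0, 0),
                FitnessScheme(0.0),
                MateChoiceMatrix(0.0, 0.0, 1.0),
            )


def _kidwell_allele_recursion(pf, pm, scheme, steps):
    """Random-mating allele-frequency recursion (random union of gametes)."""
    out = []
    for _ in range(steps):
        p_z = 0.5 * (pf + pm)
        het = pf * (1 - pm) + pm * (1 - pf)
        p = np.array([pf * pm, het, (1 - pf) * (1 - pm)])
        wf_bar = p @ scheme.wf
        wm_bar = p @ scheme.wm
        pf = (p[0] + 0.5 * p[1] * scheme.wf[1]) / wf_bar
        pm = (p[0] * scheme.wm[0] + 0.5 * p[1] * scheme.wm[1]) / wm_bar
        out.append((p_z, pf, pm))
    return np.array(out)


class TestIterate:
    def test_zero_steps(self, additive_scheme, hw_half):
        traj = iterate(hw_half, additive_scheme, steps=0)
        assert traj.genotypes.shape == (1, 3)
        np.testing.assert_allclose(traj.genotypes[0], hw_half.as_array())

    def test_symmetric_selection_converges_to_half(self, additive_scheme):
        traj = iterate(
            GenotypeFrequencies.hardy_weinberg(0.9), additive_scheme,
            steps=20_000,
        )
        assert traj.p_a1[-1] == pytest.approx(0.5, abs=1e-8)

    def test_asymmetric_selection_fixes_the_favored_allele(self):
        # alpha above the upper stability bound: selection is stronger in
        # females, so the female-beneficial allele rises monotonically to
        # fixation; below the lower bound it is lost symmetrically
        up = iterate(
            GenotypeFrequencies.hardy_weinberg(0.5),
            FitnessScheme(0.1, 1.5), steps=3000,
        )
        assert (np.diff(up.p_a1) >= -1e-12).all()
        assert up.p_a1[-1] == pytest.approx(1.0, abs=1e-6)
        down = iterate(
            GenotypeFrequencies.hardy_weinberg(0.5),
            FitnessScheme(0.1, 1 / 1.5), steps=3000,
        )
        assert (np.diff(down.p_a1) <= 1e-12).all()
        assert down.p_a1[-1] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("draw", range(20))
    def test_kidwell_random_mating_equivalence(self, draw):
        """With an all-ones mate-choice matrix the genotype recursion must
        reproduce the classic adult-allele-frequency recursion exactly."""
        rng = np.random.default_rng(draw)
        scheme = FitnessScheme(
            s=rng.uniform(0.01, 0.8),
            alpha=rng.uniform(0.5, 1.2),
            hf=rng.uniform(0, 1),
            hm=rng.uniform(0, 1),
        )
        p0f, p0m = rng.uniform(0.05, 0.95, 2)
        # start both recursions from the zygote pool of random gamete union
        p = GenotypeFrequencies(
            p0f * p0m, p0f * (1 - p0m) + p0m * (1 - p0f),
            (1 - p0f) * (1 - p0m),
        )
        traj = iterate(p, scheme, steps=100)
        oracle = _kidwell_allele_recursion(p0f, p0m, scheme, steps=101)
        np.testing.assert_allclose(traj.p_a1, oracle[:, 0], atol=1e-12)
        np.testing.assert_allclose(traj.pf, oracle[:, 1], atol=1e-12)
        np.testing.assert_allclose(traj.pm, oracle[:, 2], atol=1e-12)

    def test_neutral_random_mating_preserves_allele_frequency(self):
        traj = iterate(
            GenotypeFrequencies.hardy_weinberg(0.3), FitnessScheme(0.0),
            steps=50,
        )
        np.testing.assert_allclose(traj.p_a1, 0.3, atol=1e-12)
        np.testing.assert_allclose(traj.pf, traj.pm, atol=1e-14)

    def test_trajectory_dataframe_columns(self, additive_scheme, hw_half):
        df = iterate(hw_half, additive_scheme, steps=3).to_dataframe()
        assert list(df.columns) == [
            "generation", "p11", "p12", "p22", "pA1", "pf", "pm"
        ]
        assert len(df) == 4
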