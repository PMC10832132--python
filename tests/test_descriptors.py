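import numpy as np
import pytest

from protofun._aadata import ALPHABET, CTD_GROUPS
from protofun.descriptors import (
    DescriptorError,
    DescriptorSpec,
    assemble_descriptor_vector,
    compute_aac,
    compute_apaac,
    compute_autocorrelation,
    compute_conjoint_triad,
    compute_ctd,
    compute_paac,
    compute_qso,
)

from .conftest import random_sequence
from . import oracles


class TestAAC:
    def test_single_letter_sequence(self):
        v = compute_aac("AAAA")
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_uniform_four_letters(self):
        v = compute_aac("ACDE")
        assert np.allclose(v[:4], 0.25) and v[4:].sum() == 0

    def test_long_random_sums_to_one(self, rng):
        v = compute_aac(random_sequence(rng, 1000))
        assert abs(v.sum() - 1.0) < 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(DescriptorError):
            compute_aac("")


class TestPseudoAAC:
    def test_lambda_zero_reduces_to_aac(self, rng):
        seq = random_sequence(rng, 80)
        assert np.allclose(compute_paac(seq, 0, 0.05), compute_aac(seq))
        assert np.allclose(compute_apaac(seq, 0, 0.05), compute_aac(seq))

    def test_constant_sequence_has_zero_correlations(self):
        seq = "A" * 50
        v = compute_paac(seq, 5, 0.05)
        assert np.allclose(v[20:], 0.0)
        assert np.allclose(v[:20], compute_aac(seq))

    def test_sums_to_one_and_nonnegative(self, rng):
        v = compute_paac(random_sequence(rng, 120), 30, 0.05)
        assert abs(v.sum() - 1.0) < 1e-12 and (v >= 0).all()

    def test_too_short_sequence_rejected(self):
        with pytest.raises(DescriptorError):
            compute_paac("ACDEF", lam=10)

    @pytest.mark.parametrize("trial", range(5))
    def test_paac_matches_literal_reference(self, rng, trial):
        seq = random_sequence(rng, int(rng.integers(50, 150)))
        ours = compute_paac(seq, 30, 0.05)
        ref = oracles.paac_reference(seq, 30, 0.05)
        assert np.allclose(ours, ref, atol=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_apaac_matches_literal_reference(self, rng, trial):
        seq = random_sequence(rng, int(rng.integers(50, 150)))
        ours = compute_apaac(seq, 30, 0.05)
        assert len(ours) == 80
        assert np.allclose(ours, oracles.apaac_reference(seq, 30, 0.05), atol=1e-9)


class TestAutocorrelation:
    def test_shape_under_defaults(self, rng):
        v = compute_autocorrelation(random_sequence(rng, 100))
        assert v.shape == (3 * 8 * 30,)

    def test_constant_sequence_moran_zero_by_convention(self):
        v = compute_autocorrelation("A" * 40, max_lag=3)
        moran = v[8 * 3: 16 * 3]
        assert np.allclose(moran, 0.0)

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_direct_summation(self, rng, trial):
        from protofun._aadata import AUTOCORRELATION_SCALES

        seq = random_sequence(rng, 60)
        name = list(AUTOCORRELATION_SCALES)[trial]
        scale = AUTOCORRELATION_SCALES[name]
        v = compute_autocorrelation(seq, {name: scale}, max_lag=2)
        mb, moran, geary = oracles.autocorrelation_reference(seq, scale, 2)
        assert np.allclose(v, mb + moran + geary, atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(DescriptorError):
            compute_autocorrelation("ACD", max_lag=5)


class TestCTD:
    def test_total_length(self, rng):
        assert compute_ctd(random_sequence(rng, 50)).shape == (147,)

    def test_single_class_sequence(self):
        # "RKEDQN" is exactly class 1 of the hydrophobicity grouping
        v = compute_ctd("RKEDQN")
        assert np.allclose(v[0:3], [1.0, 0.0, 0.0])  # composition
        assert np.allclose(v[3:6], 0.0)  # no transitions

    def test_alternating_two_class_transitions(self):
        # A (neutral, class 2) and C (hydrophobic, class 3) alternate:
        # all 5 adjacent pairs are 2<->3 transitions
        v = compute_ctd("ACACAC")
        assert v[5] == pytest.approx(1.0)  # pair (2,3) fraction
        assert v[3] == v[4] == 0.0

    def test_distribution_block_of_uniform_class(self):
        groups = {"hydrophobicity": CTD_GROUPS["hydrophobicity"]}
        v = compute_ctd("RRRR", groups)
        # class-1 distribution: first/25/50/75/100% at positions 1,1,2,3,4 of 4
        assert np.allclose(v[6:11], [0.25, 0.25, 0.5, 0.75, 1.0])

    def test_too_short_rejected(self):
        with pytest.raises(DescriptorError):
            compute_ctd("A")


class TestConjointTriad:
    def test_length_three_has_single_unit_entry(self):
        v = compute_conjoint_triad("ARC")
        assert v.sum() == 1.0 and (v == 1.0).sum() == 1

    def test_homopolymer(self):
        v = compute_conjoint_triad("AAAAA")
        assert v[0] == 1.0  # cluster(A)=0 -> triad (0,0,0)

    def test_shape_and_oracle(self, rng):
        seq = random_sequence(rng, 40)
        v = compute_conjoint_triad(seq)
        assert v.shape == (343,)
        assert np.allclose(v, oracles.conjoint_triad_reference(seq), atol=1e-12)


class TestQSO:
    def test_constant_sequence_zero_couplings(self):
        # zero-diagonal distance matrices: all couplings vanish
        v = compute_qso("A" * 22, max_lag=21)
        assert np.allclose(v[:42], 0.0)

    def test_default_class_length(self, rng):
        assert compute_qso(random_sequence(rng, 60)).shape == (124,)

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_literal_reference(self, rng, trial):
        seq = random_sequence(rng, 100)
        ours = compute_qso(seq, 21, 0.1)
        assert np.allclose(ours, oracles.qso_reference(seq, 21, 0.1), atol=1e-9)


class TestAssembledVector:
    def test_default_total_length(self, rng):
        v = assemble_descriptor_vector(random_sequence(rng, 120))
        assert v.values.shape == (1484,)

    def test_aac_only_spec(self, rng):
        spec = DescriptorSpec(classes=("aac",))
        assert assemble_descriptor_vector(random_sequence(rng, 10), spec).values.shape == (20,)

    def test_deterministic(self, rng):
        seq = random_sequence(rng, 90)
        a = assemble_descriptor_vector(seq).values
        b = assemble_descriptor_vector(seq).values
        assert (a == b).all()

    def test_minimum_length_enforced_with_class_name(self, rng):
        with pytest.raises(DescriptorError):
            assemble_descriptor_vector(random_sequence(rng, 20))

    def test_composition_blocks_nonnegative(self, rng):
        spec = DescriptorSpec()
        v = assemble_descriptor_vector(random_sequence(rng, 150), spec).values
        for cls in ("aac", "paac", "molecular_interaction_triad"):
            assert (v[spec.slices[cls]] >= 0).all()

    def test_shuffling_changes_order_blocks_but_not_aac(self, rng):
        spec = DescriptorSpec()
        seq = random_sequence(rng, 150)
        shuffled = "".join(rng.permutation(list(seq)))
        a = assemble_descriptor_vector(seq, spec).values
        b = assemble_descriptor_vector(shuffled, spec).values
        assert np.allclose(a[spec.slices["aac"]], b[spec.slices["aac"]])
        for cls in ("autocorrelation", "qso"):
            assert not np.allclose(a[spec.slices[cls]], b[spec.slices[cls]])
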