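import edlib
import numpy as np
import pytest

from its2delimit.core import AnnotatedSequence, Msa, SecondaryStructure
from its2delimit.distances import (
    EditCosts,
    SaturationError,
    _edit_dp,
    ab_matrix,
    af_matrix,
    base_pair_distance,
    empirical_frequencies,
    f84_rate_components,
    f84_transition_probabilities,
    pairwise_seq_distance,
    structure_edit_distance,
)


def struct(db, sid="s"):
    return SecondaryStructure.from_dotbracket(sid, db)


class TestStructureEditDistance:
    def test_identity_is_zero(self):
        a = struct("(((...)))")
        assert structure_edit_distance(a, a) == 0

    def test_hand_example(self):
        assert structure_edit_distance(struct("(((...)))"), struct("((.....))")) == 2

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(50):
            dbs = []
            for _k in range(3):
                n = int(rng.integers(1, 25))
                dbs.append("".join(rng.choice(list("()."), size=n)))
            a, b, c = (SecondaryStructure("x", d, frozenset()) for d in dbs)
            dab = structure_edit_distance(a, b)
            assert dab == structure_edit_distance(b, a)
            assert dab <= structure_edit_distance(a, c) + structure_edit_distance(c, b)

    def test_own_dp_agrees_with_edlib(self, rng):
        for _ in range(60):
            x = "".join(rng.choice(list("()."), size=int(rng.integers(1, 30))))
            y = "".join(rng.choice(list("()."), size=int(rng.integers(1, 30))))
            assert _edit_dp(x, y, EditCosts()) == edlib.align(
                x, y, task="distance"
            )["editDistance"]

    def test_custom_costs(self):
        costs = EditCosts(substitution=3.0, indel=1.0)
        # substitution is dominated by delete+insert at cost 2
        assert structure_edit_distance(struct("(((...)))"),
                                       struct("((.....))"), costs) == 4


class TestBasePairDistance:
    def test_identity(self):
        a = struct("(((...)))")
        assert base_pair_distance(a, a) == 0

    def test_examples(self):
        assert base_pair_distance(struct("(((...)))"), struct("((.....))")) == 1
        assert base_pair_distance(struct("........."), struct("(((...)))")) == 3

    def test_unequal_lengths_direct_user_elsewhere(self):
        with pytest.raises(ValueError, match="structure_edit_distance"):
            base_pair_distance(struct("()"), struct("(...)"))


class TestAfMatrix:
    def test_identical_structures_zero(self):
        m = af_matrix([struct("(((...)))", "a"), struct("(((...)))", "b")])
        assert np.all(m.values == 0)

    def test_matches_pairwise_calls(self):
        sts = [struct("(((...)))", "a"), struct("((.....))", "b"),
               struct(".........", "c")]
        m = af_matrix(sts)
        for i in range(3):
            for j in range(3):
                assert m.values[i, j] == structure_edit_distance(sts[i], sts[j])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            af_matrix([struct("()...", "a"), struct("()...", "a")])

    def test_bit_stable_across_runs(self, small_family):
        m1 = af_matrix(small_family.true_structures)
        m2 = af_matrix(small_family.true_structures)
        assert np.array_equal(m1.values, m2.values)


class TestSubstitutionModels:
    def test_identical_rows_zero_under_all_models(self):
        row = "ACGUACGUAC" * 10
        for model in ("jc69", "k80", "f84"):
            assert pairwise_seq_distance(row, row, model) == 0.0

    def test_jc69_closed_form(self):
        # 30% mismatches: d = -0.75 ln(1 - 0.4)
        a = "A" * 100
        b = "A" * 70 + "G" * 30
        assert pairwise_seq_distance(a, b, "jc69") == pytest.approx(0.383119, abs=1e-6)

    def test_jc69_monotone_in_p(self):
        prev = -1.0
        for k in range(0, 70, 7):
            a = "A" * 100
            b = "C" * k + "A" * (100 - k)
            d = pairwise_seq_distance(a, b, "jc69")
            assert d > prev
            prev = d

    def test_saturation_raises(self):
        a = "A" * 10
        b = "C" * 8 + "A" * 2
        with pytest.raises(SaturationError):
            pairwise_seq_distance(a, b, "jc69")

    def test_zero_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_seq_distance("--NN", "AC--", "jc69")

    def test_pairwise_deletion_of_gapped_sites(self):
        # gap columns are excluded, so p is 1/4 not 2/6
        a = "ACGU-A"
        b = "ACGA-A"  # one mismatch among five comparable sites? U->A at pos 3
        d_full = pairwise_seq_distance("ACGUA", "ACGAA", "jc69")
        assert pairwise_seq_distance(a, b, "jc69") == pytest.approx(d_full)

    def test_k80_separates_transitions(self):
        # P = 0.2 transitions (A<->G), Q = 0.05 transversions
        n = 100
        a = "A" * 40 + "C" * 40 + "G" * 10 + "U" * 10
        b = "G" * 20 + "A" * 20 + "C" * 35 + "A" * 5 + "G" * 10 + "U" * 10
        P = sum(
            (x, y) in {("A", "G"), ("G", "A"), ("C", "U"), ("U", "C")}
            for x, y in zip(a, b)
        ) / n
        Q = sum(x != y for x, y in zip(a, b)) / n - P
        assert (P, Q) == (pytest.approx(0.2), pytest.approx(0.05))
        d_jc = pairwise_seq_distance(a, b, "jc69")
        d_k80 = pairwise_seq_distance(a, b, "k80")
        # transition-rich data: K80 corrects more than JC69
        assert d_k80 > d_jc


class TestF84:
    def test_reduces_to_jc_at_uniform_frequencies(self):
        # ratio 0.5 with uniform frequencies switches off the within-group
        # process, leaving the equal-input (JC) model
        a = "ACGU" * 25
        b = "ACGU" * 20 + "CAGU" * 5
        d_jc = pairwise_seq_distance(a, b, "jc69")
        d_f84 = pairwise_seq_distance(
            a, b, "f84", ts_tv_ratio=0.5, freqs=np.array([0.25] * 4)
        )
        assert d_f84 == pytest.approx(d_jc, abs=1e-6)

    def test_transition_probabilities_are_stochastic_and_reversible(self):
        freqs = np.array([0.3, 0.2, 0.3, 0.2])
        g, w = f84_rate_components(freqs, 2.0)
        P = f84_transition_probabilities(0.7, freqs, g, w)
        assert np.allclose(P.sum(axis=1), 1.0)
        flux = freqs[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_rate_scaled_to_substitutions_per_site(self):
        freqs = np.array([0.3, 0.2, 0.3, 0.2])
        g, w = f84_rate_components(freqs, 2.0)
        t = 1e-5
        P = f84_transition_probabilities(t, freqs, g, w)
        total_rate = (1.0 - (freqs * np.diag(P)).sum()) / t
        assert total_rate == pytest.approx(1.0, rel=1e-3)

    def test_ml_distance_agrees_with_grid_search(self, rng):
        # independent oracle: coarse-to-fine scan of the same likelihood
        a = "".join(rng.choice(list("ACGU"), size=300, p=[0.3, 0.2, 0.3, 0.2]))
        b = list(a)
        idx = rng.choice(300, size=45, replace=False)
        for i in idx:
            b[i] = rng.choice([c for c in "ACGU" if c != a[i]])
        b = "".join(b)
        freqs = np.array([0.3, 0.2, 0.3, 0.2])
        d = pairwise_seq_distance(a, b, "f84", ts_tv_ratio=2.0, freqs=freqs)

        from its2delimit.distances import encode_row

        x, y = encode_row(a), encode_row(b)
        counts = np.zeros((4, 4))
        np.add.at(counts, (x, y), 1.0)
        counts = 0.5 * (counts + counts.T)
        g, w = f84_rate_components(freqs, 2.0)

        def loglik(t):
            P = f84_transition_probabilities(t, freqs, g, w)
            return (counts * np.log(freqs[:, None] * P + 1e-300)).sum()

        grid = np.linspace(1e-4, 2.0, 20001)
        t_grid = grid[np.argmax([loglik(t) for t in grid])]
        assert d == pytest.approx(t_grid, abs=2e-4)


class TestAbMatrix:
    def test_identical_rows_all_zero(self):
        msa = Msa([AnnotatedSequence(f"s{i}", "ACGUACGUAC") for i in range(3)])
        assert np.all(ab_matrix(msa, "jc69").values == 0)

    def test_matches_pairwise_calls(self):
        msa = Msa(
            [
                AnnotatedSequence("a", "ACGUACGUACGU"),
                AnnotatedSequence("b", "ACGAACGUACGU"),
                AnnotatedSequence("c", "ACGAACGCACGU"),
            ]
        )
        m = ab_matrix(msa, "jc69")
        for i, ri in enumerate(msa.rows):
            for j, rj in enumerate(msa.rows):
                if i < j:
                    assert m.values[i, j] == pytest.approx(
                        pairwise_seq_distance(ri.residues, rj.residues, "jc69")
                    )

    def test_saturated_pair_listed_or_capped(self):
        msa = Msa(
            [
                AnnotatedSequence("ok1", "ACGUACGUAC"),
                AnnotatedSequence("far", "CAUCCAUCCA"),
            ]
        )
        with pytest.raises(SaturationError, match="ok1/far"):
            ab_matrix(msa, "jc69")
        m = ab_matrix(msa, "jc69", cap=5.0)
        assert m.values[0, 1] == 5.0

    def test_family_matrix_satisfies_invariants(self, small_family):
        m = ab_matrix(small_family.msa())
        m.validate()

    def test_empirical_frequencies_sum_to_one(self, small_family):
        f = empirical_frequencies(small_family.msa())
        assert f.sum() == pytest.approx(1.0)
        assert np.all(f > 0)
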