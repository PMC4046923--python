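import numpy as np
import pytest

from ccalign.matrices import (
    Block,
    CompositionVector,
    adjust_matrix,
    build_register_matrices,
    compute_composition,
    compute_register_weights,
    matrix_relative_entropy,
)
from .oracles import pair_counts_oracle, relative_entropy_oracle


class TestComposition:
    def test_empty_sequence_returns_background(self, base_matrix):
        c = compute_composition("", pseudo_mass=20)
        assert np.allclose(c.freq, base_matrix.bg_row)
        assert c.n_obs == 0

    def test_no_pseudocount_degenerates(self):
        c = compute_composition("AAAA", pseudo_mass=0)
        assert c.freq[0] == 1.0 and c.freq[1:].sum() == 0

    def test_uniform_pseudocount_arithmetic(self):
        bg = CompositionVector(freq=np.full(20, 0.05))
        c = compute_composition("ACDE", pseudo_mass=20, background=bg)
        assert c.freq[0] == pytest.approx(2 / 24)  # (1 + 20*0.05) / (4 + 20)

    def test_x_excluded_from_counts(self):
        with_x = compute_composition("ACDEXXXX")
        without = compute_composition("ACDE")
        assert np.allclose(with_x.freq, without.freq)
        assert with_x.n_obs == 4


class TestRelativeEntropy:
    def test_blosum62_value(self, base_matrix):
        h = matrix_relative_entropy(base_matrix.joint_q, base_matrix.bg_row,
                                    base_matrix.bg_col)
        assert round(h, 2) == 0.70

    def test_independence_gives_zero(self):
        c = np.full(4, 0.25)
        assert matrix_relative_entropy(np.outer(c, c), c, c) == pytest.approx(0.0)

    def test_two_letter_toy(self):
        q = np.array([[0.4, 0.1], [0.1, 0.4]])
        c = np.array([0.5, 0.5])
        expected = 0.8 * np.log2(1.6) + 0.2 * np.log2(0.4)
        h = matrix_relative_entropy(q, c, c)
        assert h == pytest.approx(expected)
        assert round(h, 3) == 0.278

    def test_agrees_with_double_loop(self, base_matrix):
        h = matrix_relative_entropy(base_matrix.joint_q, base_matrix.bg_row,
                                    base_matrix.bg_col)
        assert h == pytest.approx(
            relative_entropy_oracle(base_matrix.joint_q, base_matrix.bg_row,
                                    base_matrix.bg_col), abs=1e-12)


class TestAdjustment:
    def test_background_compositions_recover_base(self, base_matrix):
        c = CompositionVector(freq=base_matrix.bg_row.copy())
        adj = adjust_matrix(base_matrix, c, c)
        assert adj.converged
        assert (adj.scores == base_matrix.scores).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_constraints_hold_for_biased_compositions(self, base_matrix, seed):
        rng = np.random.default_rng(seed)
        c1 = CompositionVector(freq=rng.dirichlet(30 * base_matrix.bg_row))
        c2 = CompositionVector(freq=rng.dirichlet(30 * base_matrix.bg_row))
        adj = adjust_matrix(base_matrix, c1, c2)
        assert adj.converged
        assert np.abs(adj.joint_q.sum(axis=1) - c1.freq).max() < 1e-6
        assert np.abs(adj.joint_q.sum(axis=0) - c2.freq).max() < 1e-6
        assert abs(adj.rel_entropy_bits - base_matrix.rel_entropy_bits) < 1e-6

    def test_idempotent_in_distribution(self, base_matrix):
        rng = np.random.default_rng(3)
        c1 = CompositionVector(freq=rng.dirichlet(30 * base_matrix.bg_row))
        c2 = CompositionVector(freq=rng.dirichlet(30 * base_matrix.bg_row))
        once = adjust_matrix(base_matrix, c1, c2)
        twice = adjust_matrix(once, c1, c2)
        assert np.abs(twice.joint_q - once.joint_q).max() < 1e-6

    def test_log_odds_validity(self, base_matrix):
        rng = np.random.default_rng(4)
        c1 = CompositionVector(freq=rng.dirichlet(40 * base_matrix.bg_row))
        c2 = CompositionVector(freq=rng.dirichlet(40 * base_matrix.bg_row))
        adj = adjust_matrix(base_matrix, c1, c2)
        lod = adj.log_odds
        assert (adj.joint_q * lod).sum() > 0  # expected score under q positive
        assert (np.outer(c1.freq, c2.freq) * lod).sum() < 0  # under background negative

    def test_proline_scores_higher_for_proline_poor_regions(self, base_matrix):
        # coiled coils nearly exclude the helix-breaker proline; matrices
        # adjusted to proline-poor compositions raise the proline scores
        # relative to the full-length adjustment
        P = 14  # index of proline
        full = base_matrix.bg_row.copy()
        cc = full.copy()
        cc[P] *= 0.15
        cc /= cc.sum()
        m_full = adjust_matrix(base_matrix, CompositionVector(freq=full),
                               CompositionVector(freq=full))
        m_cc = adjust_matrix(base_matrix, CompositionVector(freq=cc),
                             CompositionVector(freq=cc))
        assert m_cc.log_odds[P, P] > m_full.log_odds[P, P]
        assert m_cc.scores[P, P] >= m_full.scores[P, P]

    def test_rejects_zero_composition(self, base_matrix):
        freq = np.zeros(20)
        freq[0] = 1.0
        with pytest.raises(ValueError, match="strictly positive"):
            adjust_matrix(base_matrix, CompositionVector(freq=freq),
                          CompositionVector(freq=freq))


class TestRegisterWeights:
    ENTROPIES = {"AD": 0.45, "EG": 0.32, "BCF": 0.28}

    def test_median_scheme(self):
        w = compute_register_weights(self.ENTROPIES, "median")
        assert w["AD"] == pytest.approx(0.45 / 0.32, abs=1e-3)
        assert w["EG"] == pytest.approx(1.0)
        assert w["BCF"] == pytest.approx(0.875)

    def test_blosum_scheme(self):
        w = compute_register_weights(self.ENTROPIES, "blosum", h_background=0.70)
        assert w["AD"] == pytest.approx(0.643, abs=1e-3)
        assert w["EG"] == pytest.approx(0.457, abs=1e-3)
        assert w["BCF"] == pytest.approx(0.400, abs=1e-3)

    def test_equal_entropies_give_unit_weights(self):
        h = {"AD": 0.4, "EG": 0.4, "BCF": 0.4}
        for scheme in ("median", "off"):
            assert all(v == pytest.approx(1.0)
                       for v in compute_register_weights(h, scheme).values())

    def test_invalid_entropy_rejected(self):
        with pytest.raises(ValueError):
            compute_register_weights({"AD": 0.0, "EG": 0.3, "BCF": 0.3}, "median")


class TestRegisterMatrices:
    def test_identical_sequences_insufficient_counts(self):
        block = Block(name="b", sequences=["L", "L"], registers="a")
        with pytest.raises(ValueError, match="insufficient counts"):
            build_register_matrices([block])

    def test_toy_counts_match_oracle(self):
        # two dissimilar sequences (below clustering identity), one column
        # per register group
        block = Block(name="b", sequences=["LKS", "IET"], registers="aeb")
        ms = build_register_matrices([block], min_pairs=0.5, pseudo_pairs=1e-9)
        oracle_ad = pair_counts_oracle(["L", "I"])
        q = ms["AD"].joint_q
        li = ("L", "I")
        from ccalign.seq import AA_INDEX
        assert q[AA_INDEX["L"], AA_INDEX["I"]] == pytest.approx(
            oracle_ad[li] / sum(oracle_ad.values()), abs=1e-6)

    def test_row_order_invariance(self):
        from ccalign.simulate import make_register_blocks

        blocks = make_register_blocks(n_blocks=2, seed=5)
        perm = [Block(name=b.name, sequences=list(reversed(b.sequences)),
                      registers=b.registers) for b in blocks]
        m1 = build_register_matrices(blocks)
        m2 = build_register_matrices(perm)
        for g in m1:
            assert np.allclose(m1[g].joint_q, m2[g].joint_q)

    def test_shipped_fixture_entropy_ordering(self):
        from ccalign.io import read_blocks
        from importlib import resources

        path = resources.files("ccalign.data").joinpath("cc_blocks.txt")
        ms = build_register_matrices(read_blocks(str(path)))
        h = {g: m.rel_entropy_bits for g, m in ms.items()}
        assert h["AD"] > h["EG"] > h["BCF"]
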