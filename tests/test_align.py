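import numpy as np
import pytest

from ccalign.align import (
    AlignParams,
    align,
    align_pair,
    align_score,
    bit_score,
    build_matrix_set,
    select_matrix,
)
from ccalign.matrices import MatrixSet
from ccalign.search import _plain_set
from ccalign.seq import AA_ORDER
from .conftest import make_protein
from .oracles import local_align_oracle

PLAIN = AlignParams(mode="plain", gap_open=10, gap_extend=1, adjust=False)


def encode(seq):
    return np.array([AA_ORDER.index(c) for c in seq])


class TestBitScore:
    def test_zero_raw(self):
        assert bit_score(0, 0.267, 0.041) == pytest.approx(4.61, abs=0.01)

    def test_closed_form(self):
        assert bit_score(50, 0.267, 0.041) == pytest.approx(23.87, abs=0.01)

    def test_monotone(self):
        assert bit_score(10) < bit_score(11) < bit_score(50)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            bit_score(10, lam=0.0)


class TestSelectMatrix:
    def make_set(self, base):
        return MatrixSet(m_cc=base, m_noncc=base, m_full=base,
                         m_group={g: base for g in ("AD", "EG", "BCF")},
                         bonus=1)

    def test_both_noncc(self, base_matrix):
        tag, bonus = select_matrix(False, False, "-", "-", 0.1, 0.1,
                                   self.make_set(base_matrix), "ccalignx")
        assert tag == "NONCC" and not bonus

    def test_mixed_uses_full(self, base_matrix):
        tag, _ = select_matrix(True, False, "a", "-", 0.9, 0.1,
                               self.make_set(base_matrix), "ccalign")
        assert tag == "MIXED"

    def test_more_confident_register_wins(self, base_matrix):
        tag, bonus = select_matrix(True, True, "a", "e", 0.95, 0.90,
                                   self.make_set(base_matrix), "ccalignx")
        assert tag == "AD" and not bonus

    def test_equal_registers_get_bonus(self, base_matrix):
        tag, bonus = select_matrix(True, True, "d", "d", 0.9, 0.9,
                                   self.make_set(base_matrix), "ccalignx")
        assert tag == "AD" and bonus

    def test_ccalign_mode_ignores_registers(self, base_matrix):
        tag, bonus = select_matrix(True, True, "d", "d", 0.9, 0.9,
                                   self.make_set(base_matrix), "ccalign")
        assert tag == "CC" and not bonus


class TestPlainAlignment:
    def test_known_pair_matches_oracle(self, base_matrix):
        A = make_protein("q", "HEAGAWGHEE")
        B = make_protein("s", "PAWHEAE")
        aln = align(A, B, _plain_set(base_matrix), PLAIN)
        expected = local_align_oracle(encode("HEAGAWGHEE"), encode("PAWHEAE"),
                                      base_matrix.scores, 10, 1)
        assert aln.raw_score == expected == 17

    def test_no_positive_pair_gives_empty_alignment(self, base_matrix):
        A = make_protein("q", "WWWW")
        B = make_protein("s", "PPPP")  # W-P scores -4
        aln = align(A, B, _plain_set(base_matrix), PLAIN)
        assert aln.is_empty and aln.raw_score == 0

    def test_all_x_sequence_gives_empty_alignment(self, base_matrix):
        A = make_protein("q", "XXXXXX")
        B = make_protein("s", "ACDEFG")
        aln = align(A, B, _plain_set(base_matrix), PLAIN)
        assert aln.raw_score == 0

    def test_oracle_equivalence_on_random_pairs(self, base_matrix):
        # reduced 4-letter alphabet, short sequences, exhaustive oracle
        rng = np.random.default_rng(42)
        letters = "AWLE"
        for _ in range(60):
            la, lb = rng.integers(3, 9, size=2)
            sa = "".join(rng.choice(list(letters), la))
            sb = "".join(rng.choice(list(letters), lb))
            aln = align(make_protein("a", sa), make_protein("b", sb),
                        _plain_set(base_matrix), PLAIN)
            expected = local_align_oracle(encode(sa), encode(sb),
                                          base_matrix.scores, 10, 1)
            assert aln.raw_score == expected, (sa, sb)

    def test_score_recomputable_from_traceback(self, base_matrix):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sa = "".join(rng.choice(list(AA_ORDER), 30))
            sb = "".join(rng.choice(list(AA_ORDER), 25))
            A, B = make_protein("a", sa), make_protein("b", sb)
            aln = align(A, B, _plain_set(base_matrix), PLAIN)
            if aln.is_empty:
                continue
            # recompute: substitution scores of aligned pairs minus gap costs
            subst = sum(int(base_matrix.scores[AA_ORDER.index(sa[p.q_pos - 1]),
                                               AA_ORDER.index(sb[p.s_pos - 1])])
                        for p in aln.pairs)
            gap_cost = 0
            for prev, cur in zip(aln.pairs, aln.pairs[1:]):
                dq = cur.q_pos - prev.q_pos - 1
                ds = cur.s_pos - prev.s_pos - 1
                for g in (dq, ds):
                    if g > 0:
                        gap_cost += 10 + g  # open + len * extend
            assert aln.raw_score == subst - gap_cost

    def test_unalignable_padding_does_not_change_score(self, base_matrix):
        A = make_protein("q", "HEAGAWGHEE")
        B = make_protein("s", "PAWHEAE")
        s0 = align_score(A, B, _plain_set(base_matrix), PLAIN)
        A2 = make_protein("q", "HEAGAWGHEE" + "X" * 8)
        B2 = make_protein("s", "X" * 5 + "PAWHEAE")
        assert align_score(A2, B2, _plain_set(base_matrix), PLAIN) == s0


def cc_pair(divergence_seed=0):
    """A register-annotated coiled-coil homolog pair."""
    rng = np.random.default_rng(divergence_seed)
    core = "LAELKELAELKELAELKELAELKELAELKE"  # abcdefg-ish hydrophobic repeat
    reg = ("abcdefg" * 10)[:len(core)]
    tail = "GSTPNDGSTPND"
    seq_a = core + tail
    seq_b = core[:len(core)] + tail  # identical homolog
    prob = np.concatenate([np.full(len(core), 0.95), np.full(len(tail), 0.05)])
    regs = reg + "-" * len(tail)
    A = make_protein("a", seq_a, prob, regs)
    B = make_protein("b", seq_b, prob, regs)
    return A, B


class TestCoiledCoilModes:
    def test_bonus_raises_score_by_count(self):
        A, B = cc_pair()
        p1 = AlignParams(mode="ccalignx", bonus=2, weights_scheme="off")
        p0 = AlignParams(mode="ccalignx", bonus=0, weights_scheme="off")
        a1 = align(A, B, build_matrix_set(A, B, p1), p1)
        a0 = align(A, B, build_matrix_set(A, B, p0), p0)
        assert a1.n_bonus > 0
        assert a1.raw_score - a0.raw_score == 2 * a1.n_bonus

    def test_no_cc_annotation_equals_plain_full_matrix(self, base_matrix):
        rng = np.random.default_rng(5)
        sa = "".join(rng.choice(list(AA_ORDER), 40))
        sb = "".join(rng.choice(list(AA_ORDER), 35))
        A = make_protein("a", sa)  # cc_prob all zero
        B = make_protein("b", sb)
        pcc = AlignParams(mode="ccalign")
        mset = build_matrix_set(A, B, pcc)
        s_cc = align_score(A, B, mset, pcc)
        # plain mode scored with the same full-length adjusted matrix
        plain_params = AlignParams(mode="plain", adjust=False)
        s_plain = align_score(A, B, _plain_set(mset.m_full), plain_params)
        assert s_cc == s_plain

    def test_score_symmetry_under_symmetric_configuration(self, base_matrix):
        A, B = cc_pair()
        params = AlignParams(mode="ccalignx", weights_scheme="median")
        # symmetric matrices: identical sequences -> c1 == c2
        mset = build_matrix_set(A, B, params)
        s_ab = align_score(A, B, mset, params)
        s_ba = align_score(B, A, mset, params)
        assert s_ab == s_ba

    def test_align_pair_convenience(self):
        A, B = cc_pair()
        aln = align_pair(A, B, AlignParams(mode="ccalign"))
        assert aln.raw_score > 0
        assert aln.q_start >= 1 and aln.s_start >= 1
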