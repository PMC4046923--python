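import numpy as np
import pytest

from ccalign.benchmark import (
    GoldStandard,
    compare_methods,
    evaluate,
    make_artificial,
)
from .conftest import make_protein


def cc_protein(pid, length, cc_intervals):
    prob = np.full(length, 0.05)
    reg = np.full(length, "-", dtype="<U1")
    for s, e in cc_intervals:
        prob[s - 1:e] = 0.95
        for k, i in enumerate(range(s - 1, e)):
            reg[i] = "abcdefg"[k % 7]
    seq = "".join("LAEKVSN"[i % 7] for i in range(length))
    return make_protein(pid, seq, prob, reg)


class TestMakeArtificial:
    def test_window_arithmetic(self):
        p = cc_protein("p", 300, [(60, 120)])
        art = make_artificial(p, 50)
        assert len(art) == 161  # residues 10..170

    def test_linker_longer_than_flanks_keeps_whole_protein(self):
        p = cc_protein("p", 100, [(40, 60)])
        art = make_artificial(p, 200)
        assert art.residues == p.residues

    def test_overlapping_windows_merge_without_duplication(self):
        p = cc_protein("p", 200, [(50, 60), (70, 80)])
        art = make_artificial(p, 20)
        # windows [30,80] and [50,100] merge into [30,100]
        assert len(art) == 71

    def test_annotations_travel_with_residues(self):
        p = cc_protein("p", 300, [(60, 120)])
        art = make_artificial(p, 10)
        assert len(art.cc_prob) == len(art) == 81  # window [50, 130]
        # ten linker residues flank the 61-residue coiled-coil domain
        assert (art.cc_prob[:10] < 0.8).all()
        assert (art.cc_prob[10:71] >= 0.8).all()
        assert (art.cc_prob[71:] < 0.8).all()

    def test_non_cc_protein_rejected(self):
        p = make_protein("p", "ACDEFGHIKL")
        with pytest.raises(ValueError, match="not a coiled-coil"):
            make_artificial(p, 10)


def best_hits_from(scores_correct):
    """Build best-hit dicts: list of (query, subject, score, is_correct)."""
    gold_pairs = []
    hits = {}
    for q, s, score, ok in scores_correct:
        hits[q] = (s, score)
        if ok:
            gold_pairs.append((q, s))
    return hits, gold_pairs


class TestEvaluate:
    def test_all_correct_gives_zero_fdr_and_full_recall(self):
        rows = [(f"q{i}", f"s{i}", 100.0 - i, True) for i in range(12)]
        hits, gold_pairs = best_hits_from(rows)
        curve = evaluate(GoldStandard.from_pairs(gold_pairs), hits, 0.05)
        assert (curve.fdr[curve.n_predictions >= 10] == 0).all()
        assert curve.recall_at_fdr == 1.0

    def test_all_wrong_gives_zero_recall(self):
        gold = GoldStandard.from_pairs([(f"q{i}", f"t{i}") for i in range(12)])
        hits = {f"q{i}": (f"w{i}", 50.0 + i) for i in range(12)}
        curve = evaluate(gold, hits, 0.05)
        assert curve.recall_at_fdr == 0.0

    def test_hand_constructed_five_percent_point(self):
        # 20 predictions: 19 correct at scores 100..82 except one wrong at 90
        rows = []
        score = 100.0
        for i in range(19):
            rows.append((f"q{i}", f"s{i}", score, True))
            score -= 1.0
        rows.append(("qw", "wrong", 90.5, False))
        hits, gold_pairs = best_hits_from(rows[:19])
        hits["qw"] = ("wrong", 90.5)
        gold = GoldStandard.from_pairs(gold_pairs + [("qw", "true_partner")])
        curve = evaluate(gold, hits, 0.05)
        # loosest threshold: all 20 predictions, fdr = 1/20 = 0.05
        assert curve.fdr[-1] == pytest.approx(0.05)
        assert curve.recall_at_fdr == pytest.approx(19 / 20)

    def test_step_curve_and_monotone_recall_in_alpha(self):
        rng = np.random.default_rng(0)
        rows = [(f"q{i}", f"s{i}", float(rng.integers(20, 90)),
                 bool(rng.random() < 0.7)) for i in range(40)]
        hits, gold_pairs = best_hits_from(rows)
        gold_pairs += [(f"q{i}", f"u{i}") for i, r in enumerate(rows) if not r[3]]
        gold = GoldStandard.from_pairs(gold_pairs)
        assert (np.diff(evaluate(gold, hits, 0.05).n_predictions) >= 0).all()
        recalls = [evaluate(gold, hits, a).recall_at_fdr
                   for a in (0.01, 0.05, 0.2, 0.5, 1.0)]
        assert all(r2 >= r1 for r1, r2 in zip(recalls, recalls[1:]))

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            GoldStandard(pairs=set())


class TestCompareMethods:
    def gold_and_hits(self):
        rows = [(f"q{i}", f"s{i}", 100.0 - i, i % 3 != 0) for i in range(15)]
        hits, gold_pairs = best_hits_from(rows)
        gold_pairs += [(f"q{i}", f"v{i}") for i in range(0, 15, 3)]
        return GoldStandard.from_pairs(gold_pairs), hits

    def test_duplicated_method_gives_identical_rows(self):
        gold, hits = self.gold_and_hits()
        df = compare_methods({"m1": hits, "m2": dict(hits)}, gold)
        assert df.loc[0, "recall_at_fdr"] == df.loc[1, "recall_at_fdr"]

    def test_oracle_method_reaches_full_recall(self):
        gold, hits = self.gold_and_hits()
        oracle = {q: (sorted(gold.orthologs_of[q])[0], 99.0)
                  for q in hits if q in gold.orthologs_of}
        # pad to the same universe
        for q in hits:
            oracle.setdefault(q, ("none", 0.0))
        df = compare_methods({"oracle": oracle}, gold)
        assert df.loc[0, "recall_at_fdr"] == 1.0

    def test_differing_universes_rejected(self):
        gold, hits = self.gold_and_hits()
        other = dict(hits)
        other.pop("q0")
        with pytest.raises(ValueError, match="universe"):
            compare_methods({"m1": hits, "m2": other}, gold)
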