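import itertools
import math

import numpy as np
import pytest

from mirtol import (
    RunConfig,
    TargetPrediction,
    filter_predictions,
    hypergeom_upper_tail,
    overtargeting_scan,
    pair_expression,
    prioritize,
)
from mirtol.diffexpr import DiffExprRecord
from mirtol.integration import OverTargetResult, PairingRecord


def de(fid, log2fc, sig=True):
    direction = "none" if not sig else ("up" if log2fc > 0 else "down")
    return DiffExprRecord(fid, log2fc, 2.0, 0.001 if sig else 0.6,
                          0.01 if sig else 0.9, direction, sig)


class TestHypergeomUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(100, 10, 5, 0) == 1.0

    def test_worked_example_matches_literal_enumeration(self):
        # draw 4 of 20 with 5 marked; count draws containing >= 3 marked
        hits = sum(
            1 for draw in itertools.combinations(range(20), 4)
            if sum(1 for x in draw if x < 5) >= 3
        )
        total = math.comb(20, 4)
        assert (hits, total) == (155, 4845)
        assert hypergeom_upper_tail(20, 5, 4, 3) == pytest.approx(hits / total, abs=1e-12)

    def test_saturated_k_matches_product_formula(self):
        # k = min(n, K) = n: single-term tail C(K,n)/C(N,n)
        N, K, n = 5000, 40, 4
        expected = math.comb(K, n) / math.comb(N, n)
        assert hypergeom_upper_tail(N, K, n, n) == pytest.approx(expected, rel=1e-9)

    def test_monotone_nonincreasing_in_k(self):
        N, K, n = 300, 40, 25
        tails = [hypergeom_upper_tail(N, K, n, k) for k in range(0, min(n, K) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_invalid_counts_are_hard_errors(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 11, 5, 2)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 4, 5)  # k > min(n, K)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 11, 2)


class TestPairExpression:
    MIRNA = [de("miR-202-5p", 4.0723), de("miR-505", 1.1166), de("miR-27a", -0.369)]
    MRNA = [de("Dlgap1", -1.0), de("Sap25", 1.0), de("Serpini1", -1.0),
            de("FlatGene", 0.1, sig=False)]

    def test_opposite_directions_negatively_correlated(self):
        preds = [TargetPrediction("miR-202-5p", "Dlgap1", -1.2131)]
        (rec,) = pair_expression(self.MIRNA, self.MRNA, preds)
        assert rec.pairing_class == "negatively_correlated"
        assert rec.mirna_direction == "up" and rec.mrna_direction == "down"

    def test_same_direction_positively_correlated(self):
        preds = [TargetPrediction("miR-505", "Sap25", -1.2974)]
        (rec,) = pair_expression(self.MIRNA, self.MRNA, preds)
        assert rec.pairing_class == "positively_correlated"

    def test_weak_score_excluded_by_cutoff(self):
        preds = [TargetPrediction("miR-202-5p", "Dlgap1", -0.05)]
        assert pair_expression(self.MIRNA, self.MRNA, preds) == []

    def test_non_significant_partner_excluded(self):
        preds = [TargetPrediction("miR-202-5p", "FlatGene", -1.0)]
        assert pair_expression(self.MIRNA, self.MRNA, preds) == []

    def test_unknown_feature_skipped_with_warning(self, caplog):
        preds = [TargetPrediction("miR-999", "NoSuchGene", -1.0)]
        with caplog.at_level("WARNING", logger="mirtol"):
            assert pair_expression(self.MIRNA, self.MRNA, preds) == []
        assert "absent" in caplog.text

    def test_case_insensitive_id_matching(self):
        preds = [TargetPrediction("MIR-505", "SAP25", -1.2974)]
        (rec,) = pair_expression(self.MIRNA, self.MRNA, preds)
        assert rec.mirna_id == "miR-505" and rec.mrna_id == "Sap25"

    def test_partition_and_order_invariance(self):
        preds = [
            TargetPrediction("miR-202-5p", "Dlgap1", -1.2131),
            TargetPrediction("miR-505", "Sap25", -1.2974),
            TargetPrediction("miR-505", "Serpini1", -0.8085),
            TargetPrediction("miR-27a", "Serpini1", -1.9421),
        ]
        out = pair_expression(self.MIRNA, self.MRNA, preds)
        classes = {r.pairing_class for r in out}
        assert classes <= {"negatively_correlated", "positively_correlated"}
        out_rev = pair_expression(
            list(reversed(self.MIRNA)), list(reversed(self.MRNA)),
            list(reversed(preds)),
        )
        assert out == out_rev  # sorted output, order-invariant

    def test_strict_mode_requires_phastcons(self):
        cfg = RunConfig(strict_phastcons=True)
        preds = [
            TargetPrediction("miR-505", "Sap25", -1.2, 0.9),   # passes
            TargetPrediction("miR-505", "Serpini1", -1.2, 0.2),  # fails score
            TargetPrediction("miR-202-5p", "Dlgap1", -1.2, None),  # missing fails
        ]
        out = pair_expression(self.MIRNA, self.MRNA, preds, cfg)
        assert [(r.mirna_id, r.mrna_id) for r in out] == [("miR-505", "Sap25")]

    def test_filter_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        preds = [
            TargetPrediction(f"m{i}", f"g{i}", float(rng.uniform(-1.5, 0.0)))
            for i in range(100)
        ]
        sizes = [
            len(filter_predictions(preds, RunConfig(mirsvr_cutoff=c)))
            for c in (-0.05, -0.10, -0.30, -0.60, -1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestOvertargetingScan:
    def test_single_tested_mirna_q_equals_p(self):
        de_mirna = [de("miR-1", 2.0)]
        de_mrna = [de(f"g{i}", 1.0 if i < 5 else 0.0, sig=i < 5) for i in range(50)]
        preds = [TargetPrediction("miR-1", f"g{i}", -0.5) for i in range(10)]
        (res,) = overtargeting_scan(de_mirna, de_mrna, preds)
        assert res.q == pytest.approx(res.p)
        assert (res.N, res.K, res.n, res.k) == (50, 5, 10, 5)

    def test_mirna_without_predictions_excluded(self):
        de_mirna = [de("miR-1", 2.0), de("miR-2", 2.0)]
        de_mrna = [de("g0", 1.0)]
        preds = [TargetPrediction("miR-1", "g0", -0.5)]
        results = overtargeting_scan(de_mirna, de_mrna, preds)
        assert [r.mirna_id for r in results] == ["miR-1"]

    def test_predicted_universe_shrinks_N(self):
        de_mirna = [de("miR-1", 2.0)]
        de_mrna = [de(f"g{i}", 1.0, sig=i < 3) for i in range(30)]
        preds = [TargetPrediction("miR-1", f"g{i}", -0.5) for i in range(8)]
        (assay,) = overtargeting_scan(de_mirna, de_mrna, preds,
                                      config=RunConfig(universe="assay"))
        (restricted,) = overtargeting_scan(de_mirna, de_mrna, preds,
                                           config=RunConfig(universe="predicted"))
        assert assay.N == 30 and restricted.N == 8
        assert restricted.K <= assay.K

    def test_planted_hub_flagged(self, planted_study, config):
        from mirtol import call_de

        s = planted_study
        de_m = call_de(s["mirna"], s["design"], config, strain="susceptible")
        de_g = call_de(s["mrna"], s["design"], config, strain="susceptible")
        results = overtargeting_scan(de_m, de_g, s["predictions"], config=config)
        hub = next(r for r in results if r.mirna_id == s["truth"].hub_id)
        assert hub.raw_significant
        assert hub.n == 100  # 15 planted + 85 extra hub predictions


class TestPrioritize:
    def _ot(self, mid, q):
        return OverTargetResult(mid, 1000, 80, 10, 3, q, q)

    def _pairing(self, mid, gid, svr):
        return PairingRecord(mid, gid, "up", "down", 2.0, svr, None,
                             "negatively_correlated")

    def test_dominant_candidate_ranked_first(self):
        pairings = [self._pairing("hub", f"g{i}", -1.4) for i in range(5)]
        pairings += [self._pairing("other", "g9", -0.5)]
        ranked = prioritize(pairings, [self._ot("hub", 0.01), self._ot("other", 0.5)])
        assert ranked[0].mirna_id == "hub" and ranked[0].rank == 1

    def test_identical_candidates_tie_broken_lexicographically(self):
        pairings = [self._pairing("mirB", "g1", -1.0), self._pairing("mirA", "g2", -1.0)]
        ranked = prioritize(pairings, [])
        assert [r.mirna_id for r in ranked] == ["mirA", "mirB"]

    def test_strain_specific_breaks_residual_ties(self):
        pairings = [self._pairing("mirB", "g1", -1.0), self._pairing("mirA", "g2", -1.0)]
        ranked = prioritize(pairings, [], strain_specific_ids=["mirB"])
        assert [r.mirna_id for r in ranked] == ["mirB", "mirA"]
        assert ranked[0].strain_specific

    def test_deterministic_and_complete_ranks(self):
        rng = np.random.default_rng(4)
        pairings = [
            self._pairing(f"m{i}", f"g{j}", float(rng.uniform(-1.5, -0.1)))
            for i in range(10) for j in range(int(rng.integers(1, 5)))
        ]
        ots = [self._ot(f"m{i}", float(rng.uniform(0, 1))) for i in range(10)]
        r1 = prioritize(pairings, ots)
        r2 = prioritize(list(reversed(pairings)), list(reversed(ots)))
        assert r1 == r2
        assert sorted(c.rank for c in r1) == list(range(1, len(r1) + 1))
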