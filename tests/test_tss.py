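"""TSS detection rule, merging, filtering and classification."""

import numpy as np
import pytest

from bactmap import tss
from bactmap.core_io import GeneAnnotation, StrandedSignal
from bactmap.tss import (Candidate, TssParams, classify_tss,
                         detect_candidate_tss, flag_false_positives,
                         merge_alternative_tss, remove_stable_rna_tss)


def signal_from(plus=None, minus=None, length=None):
    plus = np.asarray(plus if plus is not None else [], dtype=np.int64)
    minus = np.asarray(minus if minus is not None else [], dtype=np.int64)
    n = length or max(len(plus), len(minus))
    sig = StrandedSignal(n)
    sig.read_starts["+"][:len(plus)] = plus
    sig.read_starts["-"][:len(minus)] = minus
    return sig


class TestDetection:
    @pytest.mark.parametrize("prev,x,expected", [
        (2, 20, True),     # 20 > 14 and 20/2 = 10 > 5
        (10, 40, False),   # 40/10 = 4 is not > 5
        (10, 44, False),   # ratio 4.4, boundary check
        (10, 51, True),    # ratio 5.1
        (0, 15, True),     # zero previous counts as passing
        (0, 14, False),    # x must exceed T
    ])
    def test_threshold_and_ratio_rule(self, prev, x, expected):
        sig = signal_from(plus=[0, 0, prev, x, 0, 0])
        pos = detect_candidate_tss(sig, TssParams())["+"]
        assert (3 in pos) is expected

    def test_minus_strand_previous_is_right_neighbour(self):
        sig = signal_from(minus=[0, 0, 20, 2, 0], length=5)
        pos = detect_candidate_tss(sig, TssParams())["-"]
        assert pos.tolist() == [2]

    def test_minus_strand_output_sorted_5prime_to_3prime(self):
        sig = signal_from(minus=[0, 20, 0, 0, 30, 0], length=6)
        pos = detect_candidate_tss(sig, TssParams())["-"]
        assert pos.tolist() == [4, 1]       # decreasing coordinates on '-'

    def test_all_zeros_gives_no_candidates(self):
        sig = signal_from(plus=np.zeros(50), minus=np.zeros(50))
        cand = detect_candidate_tss(sig, TssParams())
        assert len(cand["+"]) == 0 and len(cand["-"]) == 0

    def test_raising_T_never_adds_candidates(self):
        rng = np.random.default_rng(3)
        sig = signal_from(plus=rng.poisson(4, 2000))
        prev = None
        for T in (5, 10, 20, 40):
            pos = set(detect_candidate_tss(
                sig, TssParams(T=T))["+"].tolist())
            if prev is not None:
                assert pos <= prev
            prev = pos


class TestMerging:
    def test_strongest_wins_and_absorbs(self):
        sig = signal_from(plus=np.zeros(200))
        sig.read_starts["+"][100] = 50
        sig.read_starts["+"][101] = 30
        merged = merge_alternative_tss({"+": np.array([100, 101]),
                                        "-": np.array([])}, sig, TssParams())
        (c,) = merged
        assert c.position == 100 and c.merged_positions == (101,)

    def test_tie_breaks_to_5prime_most(self):
        sig = signal_from(plus=np.zeros(200), minus=np.zeros(200))
        for p in (100, 101):
            sig.read_starts["+"][p] = 30
            sig.read_starts["-"][p] = 30
        merged = merge_alternative_tss({"+": np.array([100, 101]),
                                        "-": np.array([100, 101])},
                                       sig, TssParams())
        by_strand = {c.strand: c for c in merged}
        assert by_strand["+"].position == 100       # lowest coordinate
        assert by_strand["-"].position == 101       # highest coordinate

    def test_isolated_candidate_unchanged(self):
        sig = signal_from(plus=np.zeros(50))
        sig.read_starts["+"][10] = 40
        merged = merge_alternative_tss({"+": np.array([10]),
                                        "-": np.array([])}, sig, TssParams())
        assert merged[0].position == 10 and merged[0].merged_positions == ()


GENES = [
    GeneAnnotation("cds1", 1000, 1600, "+", "CDS"),
    GeneAnnotation("trna1", 3000, 3080, "+", "tRNA"),
    GeneAnnotation("rrna1", 5000, 5300, "+", "rRNA"),
    GeneAnnotation("cds2", 7000, 7600, "-", "CDS"),
]


class TestStableRnaRemoval:
    @pytest.mark.parametrize("pos,strand,stable", [
        (2980, "+", True),      # 20 nt upstream of the tRNA
        (5100, "+", True),      # inside the rRNA, sense
        (950, "+", False),      # near a CDS only
        (5100, "-", False),     # antisense to the rRNA is not a stable start
    ])
    def test_partition(self, pos, strand, stable):
        cand = [Candidate(pos, strand, 50)]
        kept, removed = remove_stable_rna_tss(cand, GENES, TssParams())
        assert (len(removed) == 1) is stable


class TestFalsePositiveFilter:
    def make_signal(self):
        return signal_from(plus=np.zeros(10000), minus=np.zeros(10000))

    def test_sharp_isolated_peak_kept(self):
        sig = self.make_signal()
        sig.read_starts["+"][200] = 60          # far from any TLS -> in scope
        sig.read_starts["+"][190:211] += 1
        cand = [Candidate(200, "+", 61)]
        kept, flagged = flag_false_positives(cand, sig, GENES, TssParams())
        assert kept and not flagged

    def test_peak_riding_plateau_in_cds_flagged(self):
        sig = self.make_signal()
        sig.read_starts["+"][1100:1130] = 110
        cand = [Candidate(1110, "+", 120)]
        kept, flagged = flag_false_positives(cand, sig, GENES, TssParams())
        assert not kept and flagged[0][1] == pytest.approx(120 / 110, rel=.01)

    def test_candidate_close_to_tls_out_of_scope(self):
        sig = self.make_signal()
        # 50 nt upstream of cds1's TLS, modest read count, flat surroundings
        sig.read_starts["+"][940:961] = 40
        cand = [Candidate(950, "+", 40)]
        kept, flagged = flag_false_positives(cand, sig, GENES, TssParams())
        assert kept and not flagged


class TestClassification:
    @pytest.mark.parametrize("pos,strand,category,gene,utr", [
        (1000, "+", "gene_assigned", "cds1", 0),     # on the TLS: leaderless
        (970, "+", "gene_assigned", "cds1", 30),
        (7620, "-", "gene_assigned", "cds2", 21),    # '-' TLS at 7599
        (1200, "-", "antisense", None, None),        # inside cds1, other strand
        (1700, "+", "intergenic", None, None),       # 1300 nt from trna1
        (7100, "-", "intragenic", None, None),       # inside cds2, sense, far
    ])
    def test_categories(self, pos, strand, category, gene, utr):
        (rec,) = classify_tss([Candidate(pos, strand, 50)], GENES, TssParams())
        assert rec.category == category
        assert rec.assigned_gene == gene
        if utr is not None:
            assert rec.utr_length == utr

    def test_max_utr_limits_assignment(self):
        # 600 nt upstream of the TLS exceeds max_utr=500 -> intergenic
        (far,) = classify_tss([Candidate(400, "+", 50)], GENES, TssParams())
        assert far.category == "intergenic"
        # 450 nt upstream is within range -> assigned
        (near,) = classify_tss([Candidate(550, "+", 50)], GENES, TssParams())
        assert near.category == "gene_assigned" and near.utr_length == 450

    def test_multiplicity_single_vs_multiple(self):
        recs = classify_tss([Candidate(970, "+", 50),
                             Candidate(940, "+", 20),
                             Candidate(7620, "-", 30)], GENES, TssParams())
        mult = {r.position: r.multiplicity for r in recs}
        assert mult[970] == "multiple" and mult[940] == "multiple"
        assert mult[7620] == "single"

    def test_categories_partition_retained_set(self, tss_result):
        for r in tss_result.records:
            assert r.category in tss.CATEGORIES
            assert not r.flags


class TestLedger:
    def test_ledger_balances_on_synthetic_run(self, tss_result):
        L = tss_result.ledger
        assert L["detected"] == (L["retained"] + L["merged_away"]
                                 + L["stable_rna"] + L["false_positive"])

    def test_ledger_balances_on_random_signals(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            sig = signal_from(plus=rng.poisson(2.0, 8000),
                              minus=rng.poisson(2.0, 8000))
            result = tss.call_tss(sig, GENES, TssParams(T=6, R=2))
            result.check_ledger()       # raises on imbalance
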