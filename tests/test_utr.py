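"""5'-UTR lengths, leaderless statistics, purine profile, RBS spacing and
regulatory-region matching."""

import numpy as np
import pytest

from bactmap import utr
from bactmap.core_io import GeneAnnotation, GenomeSequence, reverse_complement
from bactmap.tss import TssRecord
from bactmap.utr import (UtrRecord, compute_utr_lengths,
                         leaderless_codon_usage, load_rfam_fixture,
                         match_regulatory_predictions, purine_profile,
                         rbs_spacing_stats, rfam_observed_intervals,
                         utr_histogram)


def assigned(pos, strand, gene, reads=10):
    return TssRecord(position=pos, strand=strand, read_starts=reads,
                     category="gene_assigned", assigned_gene=gene)


class TestComputeUtrLengths:
    def make_genome(self):
        rng = np.random.default_rng(8)
        seq = list(rng.choice(list("ACGT"), 300))
        seq[100:103] = "ATG"                    # plus-strand TLS at 100
        seq[197:200] = list(reverse_complement("GTG"))  # minus TLS at 199
        genome = GenomeSequence("t", "".join(seq))
        genes = [GeneAnnotation("gp", 100, 160, "+"),
                 GeneAnnotation("gm", 140, 200, "-")]
        return genome, genes

    def test_leaderless_utr(self):
        genome, genes = self.make_genome()
        (rec,) = compute_utr_lengths([assigned(100, "+", "gp")], genes, genome)
        assert rec.utr_length == 0 and rec.utr_seq == ""
        assert rec.start_codon == "ATG"

    def test_plus_strand_coordinates(self):
        genome, genes = self.make_genome()
        (rec,) = compute_utr_lengths([assigned(70, "+", "gp")], genes, genome)
        assert rec.utr_length == 30
        assert rec.utr_seq == genome.seq[70:100]

    def test_minus_strand_reverse_complemented(self):
        genome, genes = self.make_genome()
        (rec,) = compute_utr_lengths([assigned(229, "-", "gm")], genes, genome)
        assert rec.utr_length == 30
        assert rec.utr_seq == reverse_complement(genome.seq[200:230])
        assert rec.start_codon == "GTG"

    def test_strand_oracle_on_random_fixtures(self):
        """UTR length always equals the strand-aware TSS-TLS distance."""
        genome, genes = self.make_genome()
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = int(rng.integers(0, 60))
            strand = "+" if rng.random() < .5 else "-"
            if strand == "+":
                rec = compute_utr_lengths([assigned(100 - d, "+", "gp")],
                                          genes, genome)[0]
            else:
                rec = compute_utr_lengths([assigned(199 + d, "-", "gm")],
                                          genes, genome)[0]
            assert rec.utr_length == d == len(rec.utr_seq)

    def test_unique_mode_one_row_per_gene(self):
        genome, genes = self.make_genome()
        records = [assigned(70, "+", "gp", reads=50),
                   assigned(60, "+", "gp", reads=90),
                   assigned(229, "-", "gm", reads=10)]
        out = compute_utr_lengths(records, genes, genome, unique=True)
        assert len(out) == 2
        gp = next(r for r in out if r.gene_id == "gp")
        assert gp.tss_position == 60            # the strongest TSS wins

    def test_non_assigned_records_ignored(self):
        genome, genes = self.make_genome()
        rec = TssRecord(position=10, strand="+", read_starts=5,
                        category="intergenic")
        assert compute_utr_lengths([rec], genes, genome) == []


def utr_of(length, seq=None, codon="ATG", gene="g"):
    return UtrRecord(gene_id=gene, tss_position=0, strand="+",
                     utr_length=length, utr_seq=seq or "A" * length,
                     start_codon=codon)


class TestHistogram:
    def test_binning(self):
        counts = utr_histogram([utr_of(0), utr_of(0), utr_of(3), utr_of(7)])
        assert counts["leaderless"] == 2
        assert counts["1-5"] == 1 and counts["6-10"] == 1

    def test_upper_edge_inclusive(self):
        counts = utr_histogram([utr_of(5), utr_of(6)])
        assert counts["1-5"] == 1 and counts["6-10"] == 1

    def test_counts_conserve_input_size(self):
        rng = np.random.default_rng(5)
        utrs = [utr_of(int(v)) for v in rng.integers(0, 120, 200)]
        assert utr_histogram(utrs).sum() == 200

    def test_empty_input(self):
        assert utr_histogram([]).sum() == 0


class TestLeaderlessCodonUsage:
    def test_fractions(self):
        usage = leaderless_codon_usage([utr_of(0, codon="ATG"),
                                        utr_of(0, codon="ATG"),
                                        utr_of(0, codon="GTG"),
                                        utr_of(25)])
        assert usage["ATG"] == pytest.approx(2 / 3)
        assert usage["GTG"] == pytest.approx(1 / 3)
        assert usage.sum() == pytest.approx(1.0)

    def test_all_atg(self):
        usage = leaderless_codon_usage([utr_of(0)] * 4)
        assert usage["ATG"] == 1.0

    def test_empty_subset(self):
        assert leaderless_codon_usage([utr_of(30)]).empty

    def test_planted_ratio_recovered_within_binomial_ci(self):
        import scipy.stats as st
        rng = np.random.default_rng(7)
        n = 200
        codons = rng.choice(["ATG", "GTG"], size=n, p=[.79, .21])
        usage = leaderless_codon_usage([utr_of(0, codon=c) for c in codons])
        lo, hi = st.binom.interval(0.95, n, 0.79)
        assert lo / n <= usage["ATG"] <= hi / n


class TestPurineProfile:
    def test_all_purines(self):
        prof = purine_profile([utr_of(25, seq="A" * 25)] * 3)
        assert prof.shape == (20,) and (prof == 1.0).all()

    def test_single_utr_binary_fractions(self):
        prof = purine_profile([utr_of(20, seq="ACGT" * 5)])
        assert set(prof.tolist()) <= {0.0, 1.0}

    def test_short_utrs_excluded(self):
        with pytest.raises(ValueError):
            purine_profile([utr_of(10)])

    def test_planted_rbs_gives_local_maximum_near_minus_11(self):
        """AGGAG ending 9 nt before the codon peaks within -13..-8."""
        rng = np.random.default_rng(21)
        utrs = []
        for _ in range(100):
            seq = list(rng.choice(list("CT"), 30))       # pyrimidine floor
            seq[30 - 14:30 - 9] = "AGGAG"                # positions -14..-10
            utrs.append(utr_of(30, seq="".join(seq)))
        prof = purine_profile(utrs)
        peak = int(np.argmax(prof)) - 20                 # position rel. codon
        assert -14 <= peak <= -8
        window = prof[20 - 13:20 - 7]
        assert window.max() > prof.mean()


class TestRbsSpacing:
    def test_strictly_between_convention(self):
        # a motif whose last base sits 8 nt before the A of ATG leaves the 7
        # bases at -7..-1 strictly between motif and codon: spacer 7
        stats = rbs_spacing_stats([7])
        assert stats["mean"] == 7

    def test_identical_spacers_sd_zero(self):
        stats = rbs_spacing_stats([6, 6, 6, 6])
        assert stats["sd"] == 0.0

    def test_planted_normal_spacing_recovered(self):
        rng = np.random.default_rng(3)
        spacers = np.clip(np.round(rng.normal(7.7, 2.7, 500)), 4, 12)
        stats = rbs_spacing_stats(spacers.astype(int))
        assert abs(stats["mean"] - 7.7) <= 0.3
        assert stats["histogram"].sum() == 500


class TestRegulatoryMatching:
    def test_fixture_yields_13_observed(self):
        fixture = load_rfam_fixture()
        assert len(fixture) == 16
        out = match_regulatory_predictions(fixture,
                                           rfam_observed_intervals(fixture))
        assert (out["matched"] == "observed").sum() == 13
        assert (out["matched"] == "not_observed").sum() == 3
        # the rows with no recorded observation are exactly the unmatched ones
        assert (out["matched"] == out["rnaseq"]).all()

    def test_overlap_on_reversed_minus_strand_span(self):
        import pandas as pd
        preds = pd.DataFrame([{"name": "x", "pred_start": 66442,
                               "pred_end": 66279, "strand": "-"}])
        out = match_regulatory_predictions(preds, [(66438, 66198, "-")])
        assert out["matched"].iloc[0] == "observed"

    def test_zero_overlap_not_observed(self):
        import pandas as pd
        preds = pd.DataFrame([{"name": "x", "pred_start": 100,
                               "pred_end": 200, "strand": "+"}])
        out = match_regulatory_predictions(preds, [(300, 400, "+")])
        assert out["matched"].iloc[0] == "not_observed"

    def test_strand_mismatch_not_observed(self):
        import pandas as pd
        preds = pd.DataFrame([{"name": "x", "pred_start": 100,
                               "pred_end": 200, "strand": "+"}])
        out = match_regulatory_predictions(preds, [(100, 200, "-")])
        assert out["matched"].iloc[0] == "not_observed"
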