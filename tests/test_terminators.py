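"""Terminator parsing, selection and 3'-end verdict logic."""

import numpy as np
import pandas as pd
import pytest

from bactmap.core_io import FormatError, StrandedSignal
from bactmap.operons import OperonStructure
from bactmap.terminators import (REGIONS, TerminatorPrediction,
                                 determine_transcript_end,
                                 parse_terminator_predictions,
                                 select_terminators_for_units,
                                 summarize_end_regions)


def plus_terminator(base=100, stem=8, loop=5, tail=8, unit="u"):
    s1 = (base, base + stem)
    lp = (s1[1], s1[1] + loop)
    s2 = (lp[1], lp[1] + stem)
    tl = (s2[1], s2[1] + tail)
    return TerminatorPrediction(unit_id=unit, strand="+", stem1=s1, loop=lp,
                                stem2=s2, tail=tl)


def minus_terminator(base=100, stem=8, loop=5, tail=8, unit="u"):
    # transcription right-to-left: stem1 has the highest coordinates
    tl = (base, base + tail)
    s2 = (tl[1], tl[1] + stem)
    lp = (s2[1], s2[1] + loop)
    s1 = (lp[1], lp[1] + stem)
    return TerminatorPrediction(unit_id=unit, strand="-", stem1=s1, loop=lp,
                                stem2=s2, tail=tl)


def row_from(t):
    row = {"unit_id": t.unit_id, "strand": t.strand}
    for part in REGIONS:
        lo, hi = getattr(t, part)
        if t.strand == "+":
            row[f"{part}_start"], row[f"{part}_end"] = lo + 1, hi
        else:
            row[f"{part}_start"], row[f"{part}_end"] = hi, lo + 1
    return row


class TestParsing:
    def test_well_formed_rows_round_trip(self, tmp_path):
        t_plus, t_minus = plus_terminator(unit="a"), minus_terminator(unit="b")
        p = tmp_path / "t.tsv"
        pd.DataFrame([row_from(t_plus), row_from(t_minus)]).to_csv(
            p, sep="\t", index=False)
        back = parse_terminator_predictions(p)
        assert back == [t_plus, t_minus]

    def test_unequal_stems_rejected_with_row(self, tmp_path):
        row = row_from(plus_terminator())
        row["stem2_end"] -= 2
        p = tmp_path / "t.tsv"
        pd.DataFrame([row]).to_csv(p, sep="\t", index=False)
        with pytest.raises(FormatError, match="row 2"):
            parse_terminator_predictions(p)

    def test_non_contiguous_subspans_rejected(self):
        with pytest.raises(FormatError, match="contiguous"):
            TerminatorPrediction(unit_id="u", strand="+",
                                 stem1=(100, 108), loop=(110, 115),
                                 stem2=(115, 123), tail=(123, 131))

    def test_minus_strand_transcription_direction(self):
        t = minus_terminator()
        bases = t.bases_5to3()
        positions = [p for p, _ in bases]
        assert positions[0] > positions[-1]          # decreasing coordinates
        assert bases[0][1] == "stem1" and bases[-1][1] == "tail"

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        pd.DataFrame([{"unit_id": "u", "strand": "+"}]).to_csv(
            p, sep="\t", index=False)
        with pytest.raises(FormatError, match="missing columns"):
            parse_terminator_predictions(p)


def operon(genes, cls="primary_operon"):
    return OperonStructure(genes=genes, strand="+", cls=cls)


class TestSelection:
    OPS = [operon(("g1", "g2", "g3")), operon(("m1",), "monocistronic"),
           operon(("u1",), "unassigned")]

    def pick(self, unit):
        return select_terminators_for_units([plus_terminator(unit=unit)],
                                            self.OPS)

    def test_operon_last_gene_kept(self):
        assert len(self.pick("g3")) == 1

    def test_operon_internal_gene_dropped(self):
        assert self.pick("g2") == []

    def test_monocistronic_kept(self):
        assert len(self.pick("m1")) == 1

    def test_unassigned_gene_dropped(self):
        assert self.pick("u1") == []

    def test_unknown_unit_skipped_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            assert self.pick("nope") == []
        assert "unknown unit" in caplog.text


def coverage_for(term, upstream=50, drop_at=None, profile=None, length=400):
    """Plus-strand coverage: `upstream` until `drop_at`, then 0; or an
    explicit per-base profile across the terminator."""
    sig = StrandedSignal(length)
    cov = sig.coverage["+"]
    lo, hi = term.extent
    cov[:drop_at if drop_at is not None else hi + 20] = upstream
    if drop_at is not None:
        cov[drop_at:] = 0
    if profile is not None:
        cov[lo:lo + len(profile)] = profile
    return sig


class TestVerdicts:
    def test_clear_end_in_stem1(self):
        term = plus_terminator()
        sig = coverage_for(term, upstream=50, profile=[50, 50, 8] + [8] * 26)
        v = determine_transcript_end(sig, term)
        assert v.status == "clear_end"
        assert v.end_position == term.stem1[0] + 2     # 50/8 = 6.25 >= 5
        assert v.region == "stem1" and v.upstream_mean == 50

    def test_insufficient_coverage_below_11(self):
        term = plus_terminator()
        sig = coverage_for(term, upstream=7)
        v = determine_transcript_end(sig, term)
        assert v.status == "insufficient_coverage"
        assert v.end_position is None

    def test_upstream_mean_exactly_11_is_sufficient(self):
        term = plus_terminator()
        sig = coverage_for(term, upstream=11, drop_at=term.stem1[0])
        assert determine_transcript_end(sig, term).status == "clear_end"

    def test_gradual_decline_without_fivefold_drop(self):
        term = plus_terminator()
        profile = np.linspace(50, 30, 29).astype(int)   # never a 5x drop
        sig = coverage_for(term, upstream=50, profile=profile)
        v = determine_transcript_end(sig, term)
        assert v.status == "gradual_decrease" and v.region is None

    def test_first_hit_semantics_vs_reverse_scan(self):
        term = plus_terminator()
        # two qualifying bases: position 3 of stem1 and everything after tail
        profile = [50, 50, 50, 2] + [50] * 10 + [2] * 15
        sig = coverage_for(term, upstream=50, profile=profile)
        first = determine_transcript_end(sig, term, scan="first")
        last = determine_transcript_end(sig, term, scan="last")
        assert first.end_position == term.stem1[0] + 3
        assert last.end_position > first.end_position
        # oracle: first-hit must equal the minimum of all qualifying bases
        qualifying = [p for p, _ in term.bases_5to3()
                      if 50 / max(int(sig.coverage['+'][p]), 1) >= 5]
        assert first.end_position == min(qualifying)
        assert last.end_position == max(qualifying)

    def test_zero_coverage_base_counts_as_one(self):
        term = plus_terminator()
        sig = coverage_for(term, upstream=50, drop_at=term.stem1[0] + 1)
        v = determine_transcript_end(sig, term)
        assert v.end_position == term.stem1[0] + 1

    def test_minus_strand_scan_direction(self):
        term = minus_terminator()
        sig = StrandedSignal(400)
        cov = sig.coverage["-"]
        lo, hi = term.extent
        cov[term.stem1[1] - 3:] = 50                 # covered into stem1
        v = determine_transcript_end(sig, term)
        assert v.status == "clear_end"
        assert v.end_position == term.stem1[1] - 4
        assert v.region == "stem1"

    def test_out_of_bounds_rejected(self):
        term = plus_terminator(base=390)
        with pytest.raises(ValueError, match="bounds"):
            determine_transcript_end(StrandedSignal(400), term)


class TestSummary:
    def make(self, statuses_regions):
        from bactmap.terminators import EndVerdict
        return [EndVerdict(unit_id=f"u{i}", status=s, region=r,
                           end_position=0 if s == "clear_end" else None)
                for i, (s, r) in enumerate(statuses_regions)]

    def test_region_fractions(self):
        vs = self.make([("clear_end", "stem1"), ("clear_end", "stem1"),
                        ("clear_end", "loop")])
        summ = summarize_end_regions(vs)
        assert summ["region_fractions"]["stem1"] == pytest.approx(2 / 3)
        assert summ["region_fractions"]["loop"] == pytest.approx(1 / 3)
        assert sum(summ["region_fractions"].values()) == pytest.approx(1.0)

    def test_statuses_partition_input(self):
        vs = self.make([("clear_end", "stem1"),
                        ("insufficient_coverage", None),
                        ("gradual_decrease", None)])
        summ = summarize_end_regions(vs)
        assert sum(summ["status_counts"].values()) == summ["n"] == 3

    def test_empty_input_zeros(self):
        summ = summarize_end_regions([])
        assert summ["n"] == 0
        assert all(v == 0 for v in summ["status_counts"].values())
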