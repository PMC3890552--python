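"""Novel-transcript calling from whole-transcriptome coverage.

Maximal per-strand runs of coverage above a background threshold that do
not overlap an annotated same-strand feature are called as novel
transcripts and classified by genomic context (intragenic > antisense >
intergenic).  Novel TSSs without an automatic coverage call seed additional
``tss_derived`` calls extended downstream at a lower threshold.  Intergenic
calls are annotated with their longest open reading frame and, unless the
ORF starts at the transcript 5' end (leaderless), an upstream RBS score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import STRANDS, GeneAnnotation, GenomeSequence, StrandedSignal
from .motifs import MotifHit, MotifModel
from .refine import OrfCall, scan_orfs

#: canonical Shine-Dalgarno PWM used when no learned RBS model is supplied
_DEFAULT_RBS = "AGGAG"


@dataclass
class TranscriptCall:
    start: int                    # genomic, 0-based half-open [start, end)
    end: int
    strand: str
    source: str                   # coverage_scan | tss_derived
    cls: str = ""                 # antisense | intergenic | intragenic
    tss_position: int | None = None
    longest_orf: OrfCall | None = None
    rbs_hit: MotifHit | None = None
    leaderless: bool = False
    end_reported: bool = True     # False for intragenic calls

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def _runs_above(cov: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = cov > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(cov))
    return list(zip(starts, ends))


def call_coverage_transcripts(coverage: StrandedSignal,
                              annotation: Sequence[GeneAnnotation],
                              T_cov: float = 14, min_len: int = 50,
                              ) -> list[TranscriptCall]:
    """Maximal runs with coverage > ``T_cov`` outside same-strand features.

    Runs overlapping an annotated gene on the same strand are discarded
    (their signal belongs to a known transcript); runs shorter than
    ``min_len`` nt are dropped.
    """
    calls = []
    for strand in STRANDS:
        genes = [g for g in annotation if g.strand == strand]
        for lo, hi in _runs_above(coverage.coverage[strand], T_cov):
            if hi - lo < min_len:
                continue
            if any(g.start < hi and g.end > lo for g in genes):
                continue
            calls.append(TranscriptCall(start=lo, end=hi, strand=strand,
                                        source="coverage_scan"))
    return calls


def _context_class(five_prime: int, span: tuple[int, int] | None, strand: str,
                   annotation: Sequence[GeneAnnotation]) -> str:
    """intragenic (start inside a sense gene) > antisense (overlapping an
    opposite-strand gene) > intergenic."""
    if any(g.strand == strand and g.contains(five_prime) for g in annotation):
        return "intragenic"
    lo, hi = span if span is not None else (five_prime, five_prime + 1)
    if any(g.strand != strand and g.start < hi and g.end > lo
           for g in annotation):
        return "antisense"
    return "intergenic"


def _extend_from_tss(position: int, strand: str, cov: np.ndarray,
                     T_low: float) -> tuple[int, int]:
    """Extent [lo, hi) from a TSS, extended 3' while coverage > T_low."""
    if strand == "+":
        hi = position + 1
        while hi < len(cov) and cov[hi] > T_low:
            hi += 1
        return position, hi
    lo = position
    while lo > 0 and cov[lo - 1] > T_low:
        lo -= 1
    return lo, position + 1


def classify_novel_transcripts(calls: Sequence[TranscriptCall],
                               novel_tss: Sequence,
                               annotation: Sequence[GeneAnnotation],
                               coverage: StrandedSignal,
                               T_low: float = 5) -> list[TranscriptCall]:
    """Classify coverage calls and add tss_derived calls for novel TSSs.

    Novel TSSs (antisense / intergenic / intragenic) not contained in any
    existing same-strand call seed a new call extended downstream while
    coverage exceeds ``T_low``.  The 3' ends of intragenic calls are not
    reported -- their signal merges with the host gene's transcript.
    """
    out: list[TranscriptCall] = []
    for c in calls:
        c.cls = _context_class(c.five_prime, (c.start, c.end), c.strand,
                               annotation)
        out.append(c)
    for r in novel_tss:
        if getattr(r, "category", "") not in ("antisense", "intergenic",
                                              "intragenic"):
            continue
        covered = any(c.strand == r.strand and c.start <= r.position < c.end
                      for c in calls)
        if covered:
            for c in out:
                if (c.strand == r.strand and c.start <= r.position < c.end
                        and c.tss_position is None):
                    c.tss_position = r.position
            continue
        lo, hi = _extend_from_tss(r.position, r.strand,
                                  coverage.coverage[r.strand], T_low)
        call = TranscriptCall(start=lo, end=hi, strand=r.strand,
                              source="tss_derived", cls=r.category,
                              tss_position=r.position,
                              end_reported=r.category != "intragenic")
        out.append(call)
    return out


def _rbs_pwm(model: MotifModel | None) -> tuple[np.ndarray, np.ndarray, int]:
    if model is not None:
        return model.pwm, model.background, model.width
    width = len(_DEFAULT_RBS)
    pwm = np.full((width, 4), 0.1)
    for i, c in enumerate(_DEFAULT_RBS):
        pwm[i, "ACGT".index(c)] = 0.7
    return pwm, np.full(4, 0.25), width


def annotate_intergenic_orf_rbs(call: TranscriptCall, genome: GenomeSequence,
                                rbs_model: MotifModel | None = None,
                                min_orf_len: int = 30) -> TranscriptCall:
    """Attach the longest ORF and an RBS score to an intergenic call.

    The RBS is scored as the best log-odds window within the 20 nt upstream
    of the ORF start (within the transcript).  An ORF starting at the
    transcript 5' end is flagged leaderless and gets no RBS search.
    """
    if call.cls != "intergenic":
        raise ValueError("ORF/RBS annotation applies to intergenic calls")
    seq = genome.subseq(call.start, call.end, call.strand)
    orfs = [o for o in scan_orfs(seq, "+") if o.length >= min_orf_len]
    if not orfs:
        call.longest_orf = None
        return call
    orf = orfs[0]
    call.longest_orf = orf
    if orf.start == 0:
        call.leaderless = True
        return call
    pwm, background, width = _rbs_pwm(rbs_model)
    lo = max(orf.start - 20, 0)
    window = seq[lo:orf.start]
    if len(window) < width:
        return call
    enc = np.array(["ACGT".index(c) for c in window])
    best_score, best_off = -np.inf, 0
    log_odds = np.log2(pwm) - np.log2(background)
    for j in range(len(window) - width + 1):
        s = float(log_odds[np.arange(width), enc[j:j + width]].sum())
        if s > best_score:
            best_score, best_off = s, j
    call.rbs_hit = MotifHit(seq_index=0, offset=lo + best_off,
                            score=best_score,
                            spacer=orf.start - (lo + best_off + width))
    return call


def transcripts_frame(calls: Sequence[TranscriptCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        # the 3' coordinate is withheld for intragenic calls
        if c.strand == "+":
            start_out, end_out = c.start + 1, c.end if c.end_reported else ""
        else:
            start_out = c.start + 1 if c.end_reported else ""
            end_out = c.end
        rows.append({
            "start": start_out, "end": end_out,
            "strand": c.strand, "source": c.source, "class": c.cls,
            "tss": c.tss_position + 1 if c.tss_position is not None else "",
            "longest_orf_len": c.longest_orf.length if c.longest_orf else "",
            "rbs_score": f"{c.rbs_hit.score:.2f}" if c.rbs_hit else "",
            "leaderless": c.leaderless})
    return pd.DataFrame(rows)
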