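"""Transcript 3'-end determination at predicted rho-independent terminators.

An intrinsic terminator is a G+C-rich hairpin (stem1-loop-stem2) followed by
a T-tail.  Predictions (e.g. derived from TransTermHP output) are consumed
as a tab-separated table of per-element genomic sub-spans ordered in
transcription direction.  For monocistronic genes and the last gene of each
primary operon, the whole-transcriptome coverage is interrogated: the mean
coverage of the 5 bases immediately upstream of stem1 must reach
``min_mean`` (else the end is insufficiently covered), and the transcript
end is the first terminator base, scanning 5' to 3', at which that upstream
mean divided by the base's coverage reaches ``ratio`` -- otherwise the
profile is a gradual decrease.  Clear ends are attributed to the
sub-element containing them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core_io import FormatError, StrandedSignal

REGIONS = ("stem1", "loop", "stem2", "tail")
STATUSES = ("clear_end", "insufficient_coverage", "gradual_decrease")


@dataclass(frozen=True)
class TerminatorPrediction:
    """Sub-spans as 0-based half-open genomic intervals.

    The elements are contiguous and ordered stem1 -> loop -> stem2 -> tail
    along the transcription direction (decreasing coordinates on '-'); the
    two stems have equal lengths.
    """

    unit_id: str
    strand: str
    stem1: tuple[int, int]
    loop: tuple[int, int]
    stem2: tuple[int, int]
    tail: tuple[int, int]

    def __post_init__(self) -> None:
        s1, lp, s2, tl = self.stem1, self.loop, self.stem2, self.tail
        if (s1[1] - s1[0]) != (s2[1] - s2[0]):
            raise FormatError(f"{self.unit_id}: unequal stem lengths")
        if self.strand == "+":
            ok = s1[1] == lp[0] and lp[1] == s2[0] and s2[1] == tl[0]
        else:
            ok = lp[1] == s1[0] and s2[1] == lp[0] and tl[1] == s2[0]
        if not ok:
            raise FormatError(f"{self.unit_id}: sub-spans not contiguous in "
                              "transcription order")

    def bases_5to3(self) -> list[tuple[int, str]]:
        """(genomic position, region) for every terminator base, 5' to 3'."""
        out = []
        for region in REGIONS:
            lo, hi = getattr(self, region)
            pos = range(lo, hi) if self.strand == "+" else range(hi - 1, lo - 1, -1)
            out.extend((p, region) for p in pos)
        return out

    @property
    def extent(self) -> tuple[int, int]:
        coords = [c for r in REGIONS for c in getattr(self, r)]
        return min(coords), max(coords)


@dataclass(frozen=True)
class EndVerdict:
    unit_id: str
    status: str
    end_position: int | None = None    # 0-based
    region: str | None = None
    upstream_mean: float = 0.0


def _span_from_row(row, part: str, strand: str) -> tuple[int, int]:
    a = int(row[f"{part}_start"])
    b = int(row[f"{part}_end"])
    lo, hi = (a, b) if a <= b else (b, a)
    if strand == "+" and a > b:
        raise FormatError(f"{part}: plus-strand span given in reverse")
    return lo - 1, hi       # 1-based inclusive -> 0-based half-open


def parse_terminator_predictions(path: str | Path) -> list[TerminatorPrediction]:
    """Read the prediction table; malformed rows abort with their number.

    Expected columns: unit_id, strand, and {stem1,loop,stem2,tail}_{start,end}
    with 1-based inclusive coordinates ordered in transcription direction.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"unit_id", "strand"} | {
        f"{p}_{e}" for p in REGIONS for e in ("start", "end")}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    predictions = []
    for i, row in frame.iterrows():
        try:
            predictions.append(TerminatorPrediction(
                unit_id=str(row["unit_id"]), strand=row["strand"],
                stem1=_span_from_row(row, "stem1", row["strand"]),
                loop=_span_from_row(row, "loop", row["strand"]),
                stem2=_span_from_row(row, "stem2", row["strand"]),
                tail=_span_from_row(row, "tail", row["strand"])))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
    return predictions


def select_terminators_for_units(predictions: Sequence[TerminatorPrediction],
                                 operons: Sequence) -> list[TerminatorPrediction]:
    """Keep predictions trailing monocistronic genes or the last gene of a
    primary operon; unknown unit ids are skipped with a warning."""
    import logging
    eligible: set[str] = set()
    known: set[str] = set()
    for op in operons:
        known.update(op.genes)
        if op.cls == "monocistronic":
            eligible.add(op.genes[0])
        elif op.cls == "primary_operon":
            eligible.add(op.genes[-1])
    kept = []
    for p in predictions:
        if p.unit_id not in known:
            logging.getLogger(__name__).warning(
                "terminator for unknown unit %r skipped", p.unit_id)
            continue
        if p.unit_id in eligible:
            kept.append(p)
    return kept


def determine_transcript_end(coverage: StrandedSignal,
                             terminator: TerminatorPrediction,
                             min_mean: float = 11.0,
                             ratio: float = 5.0,
                             scan: str = "first") -> EndVerdict:
    """Apply the upstream-mean / drop-ratio rule to one terminator.

    ``scan`` selects whether the first (default) or last qualifying base in
    transcription direction is reported.  Zero-coverage bases count as
    coverage 1 so the ratio stays finite.
    """
    cov = coverage.coverage[terminator.strand]
    lo, hi = terminator.extent
    if lo < 0 or hi > len(cov):
        raise ValueError("terminator outside genome bounds")
    if terminator.strand == "+":
        a, b = terminator.stem1[0] - 5, terminator.stem1[0]
    else:
        a, b = terminator.stem1[1], terminator.stem1[1] + 5
    upstream = cov[max(a, 0):max(b, 0)]
    upstream_mean = float(upstream.mean()) if upstream.size else 0.0
    if upstream_mean < min_mean:
        return EndVerdict(unit_id=terminator.unit_id,
                          status="insufficient_coverage",
                          upstream_mean=upstream_mean)
    qualifying = [(p, region) for p, region in terminator.bases_5to3()
                  if upstream_mean / max(int(cov[p]), 1) >= ratio]
    if not qualifying:
        return EndVerdict(unit_id=terminator.unit_id,
                          status="gradual_decrease",
                          upstream_mean=upstream_mean)
    pos, region = qualifying[0] if scan == "first" else qualifying[-1]
    return EndVerdict(unit_id=terminator.unit_id, status="clear_end",
                      end_position=pos, region=region,
                      upstream_mean=upstream_mean)


def summarize_end_regions(verdicts: Sequence[EndVerdict]) -> dict:
    """Counts per status plus region fractions over clear ends."""
    status_counts = {s: 0 for s in STATUSES}
    region_counts = {r: 0 for r in REGIONS}
    for v in verdicts:
        status_counts[v.status] += 1
        if v.status == "clear_end":
            region_counts[v.region] += 1
    n_clear = status_counts["clear_end"]
    region_fracs = {r: (region_counts[r] / n_clear if n_clear else 0.0)
                    for r in REGIONS}
    return {"n": len(verdicts), "status_counts": status_counts,
            "region_counts": region_counts, "region_fractions": region_fracs}


def verdicts_frame(verdicts: Sequence[EndVerdict]) -> pd.DataFrame:
    return pd.DataFrame([{
        "unit_id": v.unit_id, "status": v.status,
        "end_position": v.end_position + 1 if v.end_position is not None else "",
        "region": v.region or "", "upstream_mean": round(v.upstream_mean, 3)}
        for v in verdicts])
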