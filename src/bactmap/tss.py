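"""Transcription start site calling from 5'-enriched read-start tracks.

A position qualifies as a TSS candidate when its read-start count exceeds a
background threshold ``T`` and rises at least ``R``-fold over the position
immediately 5' of it.  Candidates within one base of each other are merged
(keeping the strongest), starts of stable-RNA genes are set aside, sites
without a sharp local accumulation are flagged as false positives, and the
remainder is classified by genomic context: assigned to a gene, intragenic,
antisense, or intergenic.

The accounting ledger (detected = retained + merged-away + stable-RNA +
false-positive) is carried through and re-checked by the pipeline report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import STRANDS, GeneAnnotation, StrandedSignal

ASSIGNABLE_KINDS = ("CDS", "ncRNA")
STABLE_KINDS = ("rRNA", "tRNA")

CATEGORIES = ("gene_assigned", "antisense", "intragenic", "intergenic")


@dataclass(frozen=True)
class TssParams:
    """Detection and filtering thresholds.

    ``T`` and ``R`` are the read-start height and step-ratio thresholds; the
    false-positive filter applies to candidates far (> ``fp_distance`` nt)
    from the next gene start or inside coding regions with more than
    ``fp_reads`` read starts, and demands a local prominence of at least
    ``fp_prominence`` over the mean signal in a +/- ``fp_window`` nt window.
    """

    T: int = 14
    R: float = 5.0
    merge_window: int = 1
    max_utr: int = 500
    fp_distance: int = 300
    fp_reads: int = 100
    fp_prominence: float = 3.0
    fp_window: int = 10

    def __post_init__(self) -> None:
        for name in ("T", "R", "merge_window", "max_utr", "fp_distance",
                     "fp_reads", "fp_prominence", "fp_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TssParams.{name} must be positive")


@dataclass(frozen=True)
class TssRecord:
    """A called start site (+1 base), 0-based internally."""

    position: int
    strand: str
    read_starts: int
    category: str = ""
    assigned_gene: str | None = None
    utr_length: int | None = None
    multiplicity: str = ""            # single | multiple, gene_assigned only
    merged_positions: tuple[int, ...] = ()
    flags: frozenset[str] = frozenset()
    prominence: float | None = None


# ---------------------------------------------------------------------------
# Detection and merging
# ---------------------------------------------------------------------------

def detect_candidate_tss(starts: StrandedSignal, params: TssParams,
                         ) -> dict[str, np.ndarray]:
    """Flag positions with x_i > T and a >R-fold rise over the 5' neighbour.

    On the minus strand the "previous" position is i+1.  A zero previous
    count passes the ratio test (an isolated peak is the clearest start).
    Output is sorted 5' to 3' per strand.
    """
    out: dict[str, np.ndarray] = {}
    for s in STRANDS:
        x = np.asarray(starts.read_starts[s], dtype=np.int64)
        if x.size == 0:
            raise ValueError("empty read-start track")
        prev = np.empty_like(x)
        if s == "+":
            prev[0] = 0
            prev[1:] = x[:-1]
        else:
            prev[-1] = 0
            prev[:-1] = x[1:]
        hits = (x > params.T) & ((prev == 0) | (x > params.R * prev))
        pos = np.flatnonzero(hits)
        out[s] = pos if s == "+" else pos[::-1]
    return out


@dataclass(frozen=True)
class Candidate:
    position: int
    strand: str
    read_starts: int
    merged_positions: tuple[int, ...] = ()


def merge_alternative_tss(candidates: dict[str, np.ndarray],
                          starts: StrandedSignal, params: TssParams,
                          ) -> list[Candidate]:
    """Collapse candidates within ``merge_window`` nt to the strongest one.

    Ties go to the 5'-most position.  Absorbed positions are recorded on the
    surviving candidate.
    """
    merged: list[Candidate] = []
    for s in STRANDS:
        pos = np.sort(np.asarray(candidates[s]))
        x = starts.read_starts[s]
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[j] <= params.merge_window:
                j += 1
            cluster = pos[i:j + 1]
            counts = x[cluster]
            best = counts.max()
            winners = cluster[counts == best]
            # 5'-most: lowest coordinate on '+', highest on '-'
            keep = int(winners.min() if s == "+" else winners.max())
            absorbed = tuple(int(p) for p in cluster if p != keep)
            merged.append(Candidate(position=keep, strand=s,
                                    read_starts=int(x[keep]),
                                    merged_positions=absorbed))
            i = j + 1
    merged.sort(key=lambda c: (c.strand, c.position))
    return merged


# ---------------------------------------------------------------------------
# Genomic-context helpers
# ---------------------------------------------------------------------------

class _GeneIndex:
    """Sorted per-strand TLS arrays for nearest-downstream-gene queries."""

    def __init__(self, genes: Sequence[GeneAnnotation]) -> None:
        self.genes = list(genes)
        self._by_strand: dict[str, tuple[np.ndarray, list[GeneAnnotation]]] = {}
        for s in STRANDS:
            sub = [g for g in self.genes if g.strand == s]
            # sort by TLS along the transcription direction
            sub.sort(key=lambda g: g.tls, reverse=(s == "-"))
            tls = np.array([g.tls for g in sub], dtype=np.int64)
            self._by_strand[s] = (tls, sub)

    def nearest_downstream_gene(self, position: int, strand: str,
                                ) -> tuple[GeneAnnotation | None, int]:
        """The same-strand gene whose TLS is closest at or downstream of
        ``position`` in transcription direction, with its distance in nt."""
        tls, sub = self._by_strand[strand]
        if len(sub) == 0:
            return None, -1
        if strand == "+":
            k = int(np.searchsorted(tls, position, side="left"))
            if k == len(sub):
                return None, -1
            return sub[k], int(tls[k] - position)
        # '-' strand: tls sorted descending; downstream means tls <= position
        k = int(np.searchsorted(-tls, -position, side="left"))
        if k == len(sub):
            return None, -1
        return sub[k], int(position - tls[k])

    def genes_containing(self, position: int) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.contains(position)]


def _assignment(index: _GeneIndex, position: int, strand: str, max_utr: int,
                ) -> tuple[GeneAnnotation | None, int]:
    """Gene a TSS would be assigned to under the leaderless/UTR rule.

    Returns (gene, utr_length) or (None, -1).  Choosing the nearest
    downstream TLS makes the "no other TLS strictly between" requirement
    automatic.
    """
    gene, dist = index.nearest_downstream_gene(position, strand)
    if gene is None or dist > max_utr:
        return None, -1
    return gene, dist


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def remove_stable_rna_tss(candidates: Sequence[Candidate],
                          annotation: Sequence[GeneAnnotation],
                          params: TssParams,
                          ) -> tuple[list[Candidate], list[Candidate]]:
    """Partition candidates into (kept, stable_rna).

    A candidate assignable to an rRNA/tRNA gene, or lying inside one in
    sense orientation, belongs to a stable-RNA transcript.
    """
    index = _GeneIndex(annotation)
    kept, stable = [], []
    for c in candidates:
        gene, _ = _assignment(index, c.position, c.strand, params.max_utr)
        in_stable_sense = any(
            g.is_stable_rna and g.strand == c.strand
            for g in index.genes_containing(c.position))
        if (gene is not None and gene.is_stable_rna) or in_stable_sense:
            stable.append(c)
        else:
            kept.append(c)
    return kept, stable


def flag_false_positives(candidates: Sequence[Candidate],
                         starts: StrandedSignal,
                         annotation: Sequence[GeneAnnotation],
                         params: TssParams,
                         ) -> tuple[list[Candidate], list[tuple[Candidate, float]]]:
    """Partition candidates into (kept, false_positive-with-prominence).

    In-scope candidates (far from the next gene start, or inside a coding
    region with a high read-start count) must rise ``fp_prominence``-fold
    over the mean signal in the surrounding window; the prominence of every
    flagged candidate is reported for audit.
    """
    index = _GeneIndex(annotation)
    kept, flagged = [], []
    for c in candidates:
        _, dist = index.nearest_downstream_gene(c.position, c.strand)
        far = dist < 0 or dist > params.fp_distance
        in_cds_high = c.read_starts > params.fp_reads and any(
            g.kind == "CDS" and g.strand == c.strand
            for g in index.genes_containing(c.position))
        if not (far or in_cds_high):
            kept.append(c)
            continue
        x = starts.read_starts[c.strand]
        lo = max(0, c.position - params.fp_window)
        hi = min(len(x), c.position + params.fp_window + 1)
        window = np.concatenate((x[lo:c.position], x[c.position + 1:hi]))
        mean = float(window.mean()) if window.size else 0.0
        prominence = float("inf") if mean == 0 else c.read_starts / mean
        if prominence >= params.fp_prominence:
            kept.append(c)
        else:
            flagged.append((c, prominence))
    return kept, flagged


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_tss(candidates: Sequence[Candidate],
                 annotation: Sequence[GeneAnnotation],
                 params: TssParams) -> list[TssRecord]:
    """Assign each retained candidate one of the four context categories.

    Precedence: gene_assigned (on a TLS, or within ``max_utr`` nt upstream
    of the nearest same-strand TLS) > intragenic (inside a sense gene) >
    antisense (inside an opposite-strand gene) > intergenic.  Per-gene
    multiplicity is single/multiple over the assigned TSSs.
    """
    index = _GeneIndex(annotation)
    records: list[TssRecord] = []
    per_gene: dict[str, int] = {}
    for c in candidates:
        gene, utr = _assignment(index, c.position, c.strand, params.max_utr)
        if gene is not None and gene.kind in ASSIGNABLE_KINDS:
            records.append(TssRecord(
                position=c.position, strand=c.strand,
                read_starts=c.read_starts, category="gene_assigned",
                assigned_gene=gene.gene_id, utr_length=utr,
                merged_positions=c.merged_positions))
            per_gene[gene.gene_id] = per_gene.get(gene.gene_id, 0) + 1
            continue
        containing = index.genes_containing(c.position)
        if any(g.strand == c.strand for g in containing):
            category = "intragenic"
        elif containing:
            category = "antisense"
        else:
            category = "intergenic"
        records.append(TssRecord(
            position=c.position, strand=c.strand, read_starts=c.read_starts,
            category=category, merged_positions=c.merged_positions))
    out = []
    for r in records:
        if r.category == "gene_assigned":
            mult = "single" if per_gene[r.assigned_gene] == 1 else "multiple"
            r = replace(r, multiplicity=mult)
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class TssResult:
    """Retained records plus the filtered-out sets and the ledger."""

    records: list[TssRecord]
    stable_rna: list[TssRecord] = field(default_factory=list)
    false_positive: list[TssRecord] = field(default_factory=list)
    ledger: dict[str, int] = field(default_factory=dict)

    def check_ledger(self) -> None:
        L = self.ledger
        if L["detected"] != (L["retained"] + L["merged_away"]
                             + L["stable_rna"] + L["false_positive"]):
            raise AssertionError(f"TSS ledger does not balance: {L}")


def call_tss(starts: StrandedSignal, annotation: Sequence[GeneAnnotation],
             params: TssParams | None = None) -> TssResult:
    """Run detection, merging, filtering and classification end to end."""
    params = params or TssParams()
    candidates = detect_candidate_tss(starts, params)
    n_detected = sum(len(v) for v in candidates.values())
    merged = merge_alternative_tss(candidates, starts, params)
    n_merged_away = n_detected - len(merged)
    merged, stable = remove_stable_rna_tss(merged, annotation, params)
    merged, flagged = flag_false_positives(merged, starts, annotation, params)
    records = classify_tss(merged, annotation, params)
    result = TssResult(
        records=records,
        stable_rna=[TssRecord(position=c.position, strand=c.strand,
                              read_starts=c.read_starts,
                              merged_positions=c.merged_positions,
                              flags=frozenset({"stable_rna"}))
                    for c in stable],
        false_positive=[TssRecord(position=c.position, strand=c.strand,
                                  read_starts=c.read_starts,
                                  merged_positions=c.merged_positions,
                                  flags=frozenset({"false_positive"}),
                                  prominence=p)
                        for c, p in flagged],
        ledger={"detected": n_detected,
                "merged_away": n_merged_away,
                "stable_rna": len(stable),
                "false_positive": len(flagged),
                "retained": len(records)})
    result.check_ledger()
    return result


def tss_frame(result: TssResult) -> pd.DataFrame:
    """All calls (retained and filtered) as a 1-based report table."""
    rows = []
    for r in result.records + result.stable_rna + result.false_positive:
        rows.append({
            "position": r.position + 1, "strand": r.strand,
            "read_starts": r.read_starts, "category": r.category,
            "gene": r.assigned_gene or "", "utr_length":
                r.utr_length if r.utr_length is not None else "",
            "multiplicity": r.multiplicity,
            "flags": ",".join(sorted(r.flags)),
            "merged_positions": ",".join(str(p + 1)
                                         for p in r.merged_positions),
            "prominence": "" if r.prominence is None
                          else f"{r.prominence:.3f}"})
    return pd.DataFrame(rows)
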