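"""5'-UTR characterization, leaderless statistics and RBS spacing.

The 5'-UTR is the stretch of a transcript from the TSS to the first base of
the start codon; a length of zero defines a leaderless mRNA.  This module
computes UTR lengths and sequences for gene-assigned TSSs, bins their length
distribution, summarizes leaderless start-codon usage, derives the purine
(G/A) enrichment profile over the 20 bases preceding the start codon, and
compares externally predicted cis-regulatory regions (riboswitches, RNA
thermometers) against observed transcript extents.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, GenomeSequence

PURINES = frozenset("AG")
CANONICAL_STARTS = ("ATG", "GTG", "CTG", "TTG")


@dataclass(frozen=True)
class UtrRecord:
    gene_id: str
    tss_position: int          # 0-based +1 position
    strand: str
    utr_length: int
    utr_seq: str
    start_codon: str
    read_starts: int = 0

    @property
    def leaderless(self) -> bool:
        return self.utr_length == 0


def compute_utr_lengths(tss_records: Sequence, annotation: Sequence[GeneAnnotation],
                        genome: GenomeSequence,
                        unique: bool = False,
                        unique_rule: str = "strongest") -> list[UtrRecord]:
    """UTR records for gene-assigned TSSs.

    ``unique=True`` keeps one UTR per gene for the RBS/purine analyses; the
    default rule keeps the TSS with the most read starts (alternatives:
    ``shortest`` / ``longest`` UTR).
    """
    by_gene = {g.gene_id: g for g in annotation}
    records: list[UtrRecord] = []
    for r in tss_records:
        if r.category != "gene_assigned":
            continue
        gene = by_gene[r.assigned_gene]
        if gene.strand == "+":
            length = gene.tls - r.position
            seq = genome.seq[r.position:gene.tls]
            codon = genome.seq[gene.tls:gene.tls + 3]
        else:
            length = r.position - gene.tls
            seq = genome.subseq(gene.tls + 1, r.position + 1, "-")
            codon = genome.subseq(gene.tls - 2, gene.tls + 1, "-")
        if length < 0:
            raise ValueError(f"negative UTR length for {gene.gene_id}; "
                             "TSS assignment is inconsistent")
        records.append(UtrRecord(gene_id=gene.gene_id, tss_position=r.position,
                                 strand=gene.strand, utr_length=length,
                                 utr_seq=seq, start_codon=codon,
                                 read_starts=r.read_starts))
    if not unique:
        return records
    chosen: dict[str, UtrRecord] = {}
    for rec in records:
        prev = chosen.get(rec.gene_id)
        if prev is None:
            chosen[rec.gene_id] = rec
            continue
        if unique_rule == "strongest":
            better = rec.read_starts > prev.read_starts
        elif unique_rule == "shortest":
            better = rec.utr_length < prev.utr_length
        elif unique_rule == "longest":
            better = rec.utr_length > prev.utr_length
        else:
            raise ValueError(f"unknown unique_rule {unique_rule!r}")
        if better:
            chosen[rec.gene_id] = rec
    return list(chosen.values())


def utr_histogram(utrs: Sequence[UtrRecord]) -> pd.Series:
    """Length distribution: a leaderless bin, then 5-nt bins (1-5, 6-10, ...).

    The upper bin edge is inclusive (length 5 falls in 1-5); counts sum to
    the input size.
    """
    lengths = [u.utr_length for u in utrs]
    n_bins = max((length + 4) // 5 for length in lengths) if lengths else 0
    labels = ["leaderless"] + [f"{5 * k + 1}-{5 * k + 5}" for k in range(n_bins)]
    counts = pd.Series(0, index=labels, dtype=int)
    for length in lengths:
        key = "leaderless" if length == 0 else f"{5 * ((length - 1) // 5) + 1}" \
            f"-{5 * ((length - 1) // 5) + 5}"
        counts[key] += 1
    return counts


def leaderless_codon_usage(utrs: Sequence[UtrRecord]) -> pd.Series:
    """Start-codon fractions over the leaderless subset (empty if none).

    Codons outside the canonical four are kept as their own keys so that
    anomalies remain visible.
    """
    codons = [u.start_codon for u in utrs if u.leaderless]
    if not codons:
        return pd.Series(dtype=float)
    counts = pd.Series(codons).value_counts()
    return counts / counts.sum()


def purine_profile(utrs: Sequence[UtrRecord]) -> np.ndarray:
    """Per-position purine fraction over the final 20 UTR bases.

    Positions run -20..-1 relative to the first base of the start codon;
    only UTRs of length >= 20 qualify, trimmed to their final 20 nt.
    """
    windows = [u.utr_seq[-20:] for u in utrs if u.utr_length >= 20]
    if not windows:
        raise ValueError("no UTRs of length >= 20")
    arr = np.array([[c in PURINES for c in w] for w in windows], dtype=float)
    return arr.mean(axis=0)


def rbs_spacing_stats(spacers: Iterable[int]) -> dict:
    """Distribution, mean and population SD of RBS-to-start-codon spacers.

    A spacer counts the nt strictly between the motif 3' end and the first
    base of the start codon.
    """
    arr = np.asarray(list(spacers), dtype=float)
    if arr.size == 0:
        return {"n": 0, "mean": float("nan"), "sd": float("nan"),
                "histogram": pd.Series(dtype=int)}
    hist = pd.Series(arr.astype(int)).value_counts().sort_index()
    return {"n": int(arr.size), "mean": float(arr.mean()),
            "sd": float(arr.std()),          # population SD
            "histogram": hist}


# ---------------------------------------------------------------------------
# Regulatory-region predictions vs observed transcripts
# ---------------------------------------------------------------------------

def _normalize(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive, possibly 5'->3' reversed -> (lo, hi) inclusive."""
    return (start, end) if start <= end else (end, start)


def match_regulatory_predictions(predictions: pd.DataFrame,
                                 observed: Sequence[tuple[int, int, str]],
                                 min_overlap_frac: float = 0.0,
                                 ) -> pd.DataFrame:
    """Mark each predicted regulatory span observed / not_observed.

    A prediction is observed when a same-strand transcript or 5'-UTR
    interval overlaps it by more than ``min_overlap_frac`` of the predicted
    span (strictly positive overlap is always required).  Coordinates are
    1-based inclusive; minus-strand spans may be given 5'->3'.
    """
    out = predictions.copy()
    verdicts = []
    for _, row in out.iterrows():
        lo, hi = _normalize(int(row["pred_start"]), int(row["pred_end"]))
        span = hi - lo + 1
        hit = False
        for ostart, oend, ostrand in observed:
            if ostrand != row["strand"]:
                continue
            olo, ohi = _normalize(int(ostart), int(oend))
            overlap = min(hi, ohi) - max(lo, olo) + 1
            if overlap > 0 and overlap >= min_overlap_frac * span:
                hit = True
                break
        verdicts.append("observed" if hit else "not_observed")
    out["matched"] = verdicts
    return out


def load_rfam_fixture() -> pd.DataFrame:
    """Packaged table of 16 externally predicted regulatory regions with the
    transcript intervals observed for 13 of them (synthetic stand-ins are
    not used here; these are published genome coordinates)."""
    with resources.files("bactmap.data").joinpath("table2_rfam.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def rfam_observed_intervals(fixture: pd.DataFrame,
                            ) -> list[tuple[int, int, str]]:
    """Observed transcript intervals recorded alongside the predictions."""
    rows = fixture.dropna(subset=["obs_start", "obs_end"])
    return [(int(r.obs_start), int(r.obs_end), r.strand)
            for r in rows.itertuples()]
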