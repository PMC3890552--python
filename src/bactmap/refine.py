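"""Correction of annotated translational start codons using TSS evidence.

A TSS mapping inside a gene body, downstream of the annotated start, either
sits exactly on an in-frame start codon (the gene is re-annotated as a
leaderless mRNA starting there) or a new start codon is searched downstream
of the TSS, in frame with the annotated stop.  Start codons are ATG, GTG,
CTG and TTG; stops are TGA, TAA and TAG.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import GeneAnnotation, GenomeSequence, reverse_complement

START_CODONS = frozenset({"ATG", "GTG", "CTG", "TTG"})
STOP_CODONS = frozenset({"TGA", "TAA", "TAG"})


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame in forward-genome coordinates [start, end).

    ``end - start`` includes the stop codon and is divisible by 3; for
    minus-strand calls the reading direction is right to left.
    """

    start: int
    end: int
    strand: str
    start_codon: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class StartCorrection:
    gene_id: str
    old_tls: int
    new_tls: int
    mode: str                       # leaderless | new_downstream_start
    alternatives: tuple[int, ...] = ()


def scan_orfs(seq: str, strand: str = "+",
              start_set: frozenset[str] = START_CODONS,
              stop_set: frozenset[str] = STOP_CODONS) -> list[OrfCall]:
    """All ORFs on one strand of ``seq``, sorted by length descending.

    Each stop-bounded frame segment contributes an ORF from its 5'-most
    start codon; internal alternative starts are also reported as separate
    (shorter) calls.  ORFs without an in-sequence stop codon are not
    reported.  Coordinates always refer to the forward sequence.
    """
    seq = seq.upper()
    n = len(seq)
    work = seq if strand == "+" else reverse_complement(seq)
    calls: list[OrfCall] = []
    for frame in range(3):
        starts_pending: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = work[i:i + 3]
            if codon in stop_set:
                for s in starts_pending:
                    a, b = s, i + 3
                    if strand == "-":
                        a, b = n - (i + 3), n - s
                    calls.append(OrfCall(start=a, end=b, strand=strand,
                                         start_codon=work[s:s + 3]))
                starts_pending = []
            elif codon in start_set:
                starts_pending.append(i)
    calls.sort(key=lambda c: (-c.length, c.start))
    return calls


def refine_start_codon(tss_position: int, gene: GeneAnnotation,
                       genome: GenomeSequence) -> StartCorrection | None:
    """Re-annotate a gene start from a TSS inside its body.

    If the TSS lies exactly on a start codon in frame with the annotated
    stop, the gene is leaderless and starts at the TSS.  Otherwise the
    5'-most in-frame start codon strictly downstream of the TSS (and
    upstream of the stop) becomes the corrected start; all other candidate
    starts are reported for audit.  Returns ``None`` when no in-frame start
    codon exists.
    """
    if not gene.contains(tss_position):
        raise ValueError("TSS does not lie within the gene body")

    # distance from the annotated TLS along the transcription direction
    if gene.strand == "+":
        offset = tss_position - gene.start
        glen = gene.end - gene.start
        sense = genome.seq[gene.start:gene.end]
    else:
        offset = gene.end - 1 - tss_position
        glen = gene.end - gene.start
        sense = reverse_complement(genome.seq[gene.start:gene.end])
    if offset <= 0:
        raise ValueError("TSS must lie downstream of the annotated start")

    def to_genomic(local: int) -> int:
        return gene.start + local if gene.strand == "+" else gene.end - 1 - local

    in_frame = offset % 3 == 0
    codon_at_tss = sense[offset:offset + 3]
    if in_frame and codon_at_tss in START_CODONS:
        return StartCorrection(gene_id=gene.gene_id, old_tls=gene.tls,
                               new_tls=tss_position, mode="leaderless")

    # first in-frame start strictly downstream of the TSS that can reach the
    # annotated stop (an internal in-frame stop voids any earlier candidate)
    candidates: list[int] = []
    for local in range(0, glen - 3, 3):
        codon = sense[local:local + 3]
        if codon in STOP_CODONS:
            candidates = []
        elif codon in START_CODONS and local > offset:
            candidates.append(local)
    if not candidates:
        return None
    best = candidates[0]
    return StartCorrection(gene_id=gene.gene_id, old_tls=gene.tls,
                           new_tls=to_genomic(best),
                           mode="new_downstream_start",
                           alternatives=tuple(to_genomic(c)
                                              for c in candidates[1:]))


def refine_genes(tss_records, annotation, genome) -> list[StartCorrection]:
    """Apply start-codon refinement to every intragenic sense TSS.

    ``tss_records`` are retained TSS calls; only those inside a CDS on the
    same strand, downstream of its annotated start, are considered.
    """
    by_gene = {g.gene_id: g for g in annotation}
    corrections = []
    for r in tss_records:
        for gene in by_gene.values():
            if (gene.kind == "CDS" and gene.strand == r.strand
                    and gene.contains(r.position) and r.position != gene.tls):
                if gene.strand == "+" and r.position <= gene.start:
                    continue
                if gene.strand == "-" and r.position >= gene.end - 1:
                    continue
                corr = refine_start_codon(r.position, gene, genome)
                if corr is not None:
                    corrections.append(corr)
    return corrections
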