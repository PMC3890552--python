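"""Operon assembly from junction-spanning combined read pairs.

Two same-strand neighbouring genes belong to the same primary operon when
at least ``T_pairs`` combined mate-pair fragments overlap both gene bodies.
Maximal chains of such junctions form primary operons (requiring a TSS at
the first gene in transcription order); genes in no chain are monocistronic
when expressed, otherwise unassigned.  Internal gene-assigned TSSs split
primary operons into sub-operons (suffixes of the gene chain).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import STRANDS, AlignedFragment, GeneAnnotation, StrandedSignal


@dataclass(frozen=True)
class JunctionCount:
    upstream_gene: str
    downstream_gene: str
    strand: str
    n_pairs: int


@dataclass
class OperonStructure:
    genes: tuple[str, ...]              # transcription order
    strand: str
    cls: str                            # primary_operon | monocistronic | unassigned
    primary_tss: int | None = None
    internal_tss: tuple[tuple[str, int], ...] = ()
    sub_operons: tuple[tuple[str, ...], ...] = ()
    flags: frozenset[str] = frozenset()


def _strand_ordered(annotation: Sequence[GeneAnnotation],
                    strand: str) -> list[GeneAnnotation]:
    """Genes of one strand in transcription order."""
    sub = [g for g in annotation if g.strand == strand]
    sub.sort(key=lambda g: g.start, reverse=(strand == "-"))
    return sub


def junction_pair_counts(fragments: Sequence[AlignedFragment],
                         annotation: Sequence[GeneAnnotation],
                         ) -> list[JunctionCount]:
    """Count fragments overlapping both genes of every same-strand
    neighbouring pair (>= 1 nt into each gene body)."""
    counts: list[JunctionCount] = []
    for strand in STRANDS:
        genes = _strand_ordered(annotation, strand)
        frags = [f for f in fragments if f.strand == strand]
        starts = np.array([f.start for f in frags], dtype=np.int64)
        ends = np.array([f.end for f in frags], dtype=np.int64)
        for up, down in zip(genes, genes[1:]):
            lo_gene, hi_gene = (up, down) if up.start <= down.start else (down, up)
            n = int(np.count_nonzero(
                (starts < lo_gene.end) & (ends > lo_gene.start)
                & (starts < hi_gene.end) & (ends > hi_gene.start))
            ) if len(frags) else 0
            counts.append(JunctionCount(upstream_gene=up.gene_id,
                                        downstream_gene=down.gene_id,
                                        strand=strand, n_pairs=n))
    return counts


def _mean_gene_coverage(gene: GeneAnnotation, coverage: StrandedSignal) -> float:
    return float(coverage.coverage[gene.strand][gene.start:gene.end].mean())


def assemble_operons(junctions: Sequence[JunctionCount],
                     tss_records: Sequence,
                     annotation: Sequence[GeneAnnotation],
                     coverage: StrandedSignal,
                     T_pairs: int = 15,
                     min_cov: float = 1.0) -> list[OperonStructure]:
    """Chain junctions with >= ``T_pairs`` supporting fragments into operons.

    Every annotated gene ends up in exactly one structure: a primary operon
    chain, a monocistronic transcript (mean gene-body coverage >=
    ``min_cov``) or unassigned.  Chains whose first gene lacks an assigned
    TSS are kept as primary operons flagged ``no_primary_tss`` rather than
    silently dropped.
    """
    junc = {(j.upstream_gene, j.downstream_gene): j.n_pairs for j in junctions}
    tss_by_gene: dict[str, list] = {}
    for r in tss_records:
        if getattr(r, "category", "") == "gene_assigned":
            tss_by_gene.setdefault(r.assigned_gene, []).append(r)

    operons: list[OperonStructure] = []
    for strand in STRANDS:
        genes = _strand_ordered(annotation, strand)
        chain: list[GeneAnnotation] = []

        def flush(chain: list[GeneAnnotation]) -> None:
            if not chain:
                return
            if len(chain) == 1:
                g = chain[0]
                covered = _mean_gene_coverage(g, coverage) >= min_cov
                own = tss_by_gene.get(g.gene_id, [])
                operons.append(OperonStructure(
                    genes=(g.gene_id,), strand=strand,
                    cls="monocistronic" if covered else "unassigned",
                    primary_tss=(max(own, key=lambda r: r.read_starts).position
                                 if own else None)))
                return
            first = chain[0]
            first_tss = tss_by_gene.get(first.gene_id, [])
            primary = None
            flags: set[str] = set()
            if first_tss:
                primary = max(first_tss, key=lambda r: r.read_starts).position
            else:
                flags.add("no_primary_tss")
            internal = tuple(
                (g.gene_id, r.position)
                for g in chain[1:]
                for r in sorted(tss_by_gene.get(g.gene_id, []),
                                key=lambda r: r.position))
            op = OperonStructure(
                genes=tuple(g.gene_id for g in chain), strand=strand,
                cls="primary_operon", primary_tss=primary,
                internal_tss=internal, flags=frozenset(flags))
            operons.append(define_suboperons(op))

        for g in genes:
            if not chain:
                chain = [g]
                continue
            n = junc.get((chain[-1].gene_id, g.gene_id), 0)
            if n >= T_pairs:
                chain.append(g)
            else:
                flush(chain)
                chain = [g]
        flush(chain)
    return operons


def define_suboperons(operon: OperonStructure) -> OperonStructure:
    """Fill sub-operons: each internal-TSS-bearing gene k starts the suffix
    (k..last); one sub-operon per distinct gene."""
    if operon.cls != "primary_operon":
        raise ValueError("sub-operons are defined for primary operons only")
    seen: list[str] = []
    for gene_id, _pos in operon.internal_tss:
        if gene_id not in seen:
            seen.append(gene_id)
    subs = tuple(operon.genes[operon.genes.index(g):] for g in seen
                 if operon.genes.index(g) >= 1)
    operon.sub_operons = subs
    return operon


def operon_size_histogram(operons: Sequence[OperonStructure]) -> pd.Series:
    """Gene-count distribution over primary operons (monocistronic and
    unassigned singletons excluded)."""
    sizes = [len(o.genes) for o in operons if o.cls == "primary_operon"]
    return pd.Series(sizes).value_counts().sort_index() if sizes \
        else pd.Series(dtype=int)


def operons_frame(operons: Sequence[OperonStructure]) -> pd.DataFrame:
    rows = []
    for o in operons:
        rows.append({
            "genes": ",".join(o.genes), "strand": o.strand, "class": o.cls,
            "primary_tss": o.primary_tss + 1 if o.primary_tss is not None else "",
            "internal_tss": ",".join(f"{g}:{p + 1}" for g, p in o.internal_tss),
            "sub_operons": ";".join(",".join(s) for s in o.sub_operons),
            "flags": ",".join(sorted(o.flags))})
    return pd.DataFrame(rows)


def junctions_frame(junctions: Sequence[JunctionCount]) -> pd.DataFrame:
    return pd.DataFrame([{"upstream_gene": j.upstream_gene,
                          "downstream_gene": j.downstream_gene,
                          "strand": j.strand, "n_pairs": j.n_pairs}
                         for j in junctions])
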