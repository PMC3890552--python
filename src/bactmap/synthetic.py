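"""Toy genomes with a planted transcriptional architecture.

The generator lays out transcription units (operons, monocistronic genes,
stable-RNA genes and novel transcripts) along a single chromosome, plants
sigma-A promoter elements (-10 ``TAnnnT``, -35 ``ttgnca``), Shine-Dalgarno
sites (``AGGAG``) and rho-independent terminators at spacings drawn from the
ranges observed in bacterial primary-transcriptome data, and then simulates
the two sequencing libraries the pipeline consumes:

* a 5'-enriched library as sharp Poisson read-start peaks at every planted
  TSS over a low Poisson background, and
* a whole-transcriptome library as 200-500 nt mate-pair fragments sampled
  along each transcript, clipped to the transcript extent so that coverage is
  plateau-shaped with an abrupt drop at the planted 3' end.

Every planted feature is recorded, so downstream stages can be scored
against exact ground truth.  The same seed always yields bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    STRANDS,
    AlignedFragment,
    GeneAnnotation,
    GenomeSequence,
    StrandedSignal,
    build_signal_tracks,
    fragments_to_mates,
    reverse_complement,
    write_alignments_bed6,
    write_annotation_gff3,
    write_genome_fasta,
    write_signal_tracks,
)

BASES = "ACGT"
START_CODONS = ("ATG", "GTG", "CTG", "TTG")
STOP_CODONS = ("TGA", "TAA", "TAG")
NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)

MINUS10_CONSENSUS = "TANNNT"
MINUS35_CONSENSUS = "TTGNCA"
RBS_CONSENSUS = "AGGAG"

#: terminator sub-element widths (nt): stem1, loop, stem2, T-tail
TERM_WIDTHS = (8, 5, 8, 8)

#: default mix of planted 3'-end drop locations over the four sub-elements
TERM_REGION_PROBS = {"stem1": 0.72, "loop": 0.18, "stem2": 0.08, "tail": 0.02}


class PlacementError(RuntimeError):
    """Raised when the requested architecture does not fit the genome."""


@dataclass(frozen=True)
class PlantedTss:
    """A planted +1 position with its role in the architecture."""

    position: int          # 0-based genomic coordinate of the +1 base
    strand: str
    kind: str              # primary | internal | mono | stable_rna |
    #                        novel_intergenic | novel_antisense | novel_intragenic
    gene_id: str = ""      # gene the TSS belongs to ("" for novel)
    utr_length: int | None = None
    transcript_id: str = ""


@dataclass(frozen=True)
class PlantedMotif:
    """Genomic span of a planted motif instance (0-based half-open)."""

    start: int
    end: int
    strand: str
    consensus: str
    anchor: int            # TSS position or TLS position the spacer refers to
    spacer: int            # nt strictly between motif 3' end and the anchor
    tss_position: int | None = None
    gene_id: str = ""


@dataclass(frozen=True)
class PlantedTerminator:
    """A rho-independent terminator with a planted transcript-end drop."""

    unit_id: str           # gene the terminator trails (last gene of its unit)
    strand: str
    stem1: tuple[int, int]
    loop: tuple[int, int]
    stem2: tuple[int, int]
    tail: tuple[int, int]
    end_position: int      # first uncovered base in transcription direction
    region: str            # sub-element containing end_position


@dataclass(frozen=True)
class PlantedTranscript:
    """Genomic extent [start, end) of one simulated transcript."""

    transcript_id: str
    start: int
    end: int
    strand: str
    tss_position: int


@dataclass(frozen=True)
class OperonTruth:
    operon_id: str
    gene_ids: tuple[str, ...]      # transcription order
    strand: str
    primary_tss: int
    internal_tss: tuple[tuple[str, int], ...] = ()   # (gene_id, position)

    @property
    def sub_operons(self) -> tuple[tuple[str, ...], ...]:
        subs = []
        for gene_id, _pos in self.internal_tss:
            k = self.gene_ids.index(gene_id)
            if k >= 1:
                subs.append(self.gene_ids[k:])
        return tuple(subs)


@dataclass(frozen=True)
class NovelTruth:
    transcript_id: str
    start: int
    end: int
    strand: str
    cls: str               # intergenic | antisense | intragenic
    tss_position: int | None


@dataclass
class ArchitectureSpec:
    """Fully resolved layout of a toy transcriptome architecture."""

    genome_length: int
    seed: int
    genes: list[GeneAnnotation] = field(default_factory=list)
    tss: list[PlantedTss] = field(default_factory=list)
    promoters: list[PlantedMotif] = field(default_factory=list)   # -10 and -35
    rbs: list[PlantedMotif] = field(default_factory=list)
    terminators: list[PlantedTerminator] = field(default_factory=list)
    transcripts: list[PlantedTranscript] = field(default_factory=list)
    operons: list[OperonTruth] = field(default_factory=list)
    novel: list[NovelTruth] = field(default_factory=list)
    alt_tss: list[tuple[int, str]] = field(default_factory=list)
    fp_sites: list[tuple[int, int, str]] = field(default_factory=list)  # span+strand

    @property
    def true_tss_positions(self) -> set[tuple[int, str]]:
        """Planted TSSs a correct caller should retain (stable RNA excluded)."""
        return {(t.position, t.strand) for t in self.tss
                if t.kind != "stable_rna"}


@dataclass
class GroundTruth:
    """The planted architecture as flat tables keyed like pipeline outputs."""

    tss_table: pd.DataFrame
    operon_table: pd.DataFrame
    transcript_table: pd.DataFrame
    terminator_end_table: pd.DataFrame


# ---------------------------------------------------------------------------
# Architecture construction
# ---------------------------------------------------------------------------

def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


class _Block:
    """One transcription unit built in local (transcript) coordinates.

    Local coordinate 0 is the 5'-most planted element of the block; all
    features are laid out downstream and later mirrored onto the genome for
    minus-strand units.
    """

    def __init__(self) -> None:
        self.span = 0
        self.tss_local: list[dict] = []
        self.genes_local: list[dict] = []
        self.motifs_local: list[dict] = []
        self.terminator_local: dict | None = None
        self.transcripts_local: list[dict] = []


def _sample_utr(rng: np.random.Generator, leaderless: bool) -> int:
    return 0 if leaderless else int(rng.integers(20, 46))


def _sample_rbs_spacer(rng: np.random.Generator) -> int:
    return int(np.clip(round(rng.normal(7.7, 2.7)), 4, 12))


def _build_unit(rng: np.random.Generator, gene_lengths: Sequence[int],
                gene_ids: Sequence[str], *, kinds: Sequence[str] | None = None,
                leaderless: bool = False, internal_after: Sequence[int] = (),
                with_promoter: bool = True,
                term_region: str = "stem1") -> _Block:
    """Lay out one transcription unit in local coordinates."""
    blk = _Block()
    cursor = 0
    utr = _sample_utr(rng, leaderless)
    kinds = kinds or ["CDS"] * len(gene_lengths)

    def plant_promoter(tss_local: int) -> None:
        sp10 = int(rng.integers(3, 12))        # -10 spacer, 3..11 nt
        m10 = (tss_local - sp10 - 6, tss_local - sp10)
        gap = int(rng.integers(16, 20))        # -10/-35 gap, 16..19 nt
        m35 = (m10[0] - gap - 6, m10[0] - gap)
        blk.motifs_local.append({"span": m10, "consensus": MINUS10_CONSENSUS,
                                 "anchor": tss_local, "spacer": sp10,
                                 "tss_local": tss_local})
        blk.motifs_local.append({"span": m35, "consensus": MINUS35_CONSENSUS,
                                 "anchor": m10[0], "spacer": gap,
                                 "tss_local": tss_local})

    def plant_rbs(tls_local: int, gene_id: str) -> None:
        spacer = _sample_rbs_spacer(rng)
        span = (tls_local - spacer - len(RBS_CONSENSUS), tls_local - spacer)
        blk.motifs_local.append({"span": span, "consensus": RBS_CONSENSUS,
                                 "anchor": tls_local, "spacer": spacer,
                                 "gene_id": gene_id})

    # promoter extent reserved before the primary TSS
    promoter_extent = 42 if with_promoter else 0
    tss_local = cursor + promoter_extent
    if with_promoter:
        plant_promoter(tss_local)
    blk.tss_local.append({"local": tss_local, "kind": "primary",
                          "utr": utr, "gene_index": 0})
    cursor = tss_local + utr
    if with_promoter and not leaderless and kinds[0] == "CDS":
        plant_rbs(cursor, gene_ids[0])

    for j, (glen, gid, kind) in enumerate(zip(gene_lengths, gene_ids, kinds)):
        if j > 0:
            gap = 80 if j in internal_after else 50
            next_start = cursor + gap
            if j in internal_after:
                int_utr = 25
                itss = next_start - int_utr
                plant_promoter(itss)
                blk.tss_local.append({"local": itss, "kind": "internal",
                                      "utr": int_utr, "gene_index": j})
                if kind == "CDS":
                    plant_rbs(next_start, gid)
            cursor = next_start
        blk.genes_local.append({"start": cursor, "end": cursor + glen,
                                "id": gid, "kind": kind})
        cursor += glen

    # terminator 10 nt after the last gene
    t0 = cursor + 10
    w1, wl, w2, wt = TERM_WIDTHS
    stem1 = (t0, t0 + w1)
    loop = (stem1[1], stem1[1] + wl)
    stem2 = (loop[1], loop[1] + w2)
    tail = (stem2[1], stem2[1] + wt)
    spans = {"stem1": stem1, "loop": loop, "stem2": stem2, "tail": tail}
    rspan = spans[term_region]
    end_local = int(rng.integers(rspan[0], rspan[1]))
    blk.terminator_local = {"stem1": stem1, "loop": loop, "stem2": stem2,
                            "tail": tail, "end_local": end_local,
                            "region": term_region,
                            "unit_id": gene_ids[-1]}
    blk.span = tail[1]
    # transcripts: one per TSS, all ending at the planted drop
    for t in blk.tss_local:
        blk.transcripts_local.append({"start": t["local"], "end": end_local,
                                      "tss_local": t["local"]})
    return blk


def _place_block(spec: ArchitectureSpec, blk: _Block, origin: int, strand: str,
                 unit_name: str) -> None:
    """Map a local block onto genome coordinates and record ground truth."""
    span = blk.span

    def pt(local: int) -> int:
        return origin + local if strand == "+" else origin + span - 1 - local

    def iv(a: int, b: int) -> tuple[int, int]:
        if strand == "+":
            return origin + a, origin + b
        return origin + span - b, origin + span - a

    gene_by_index: dict[int, GeneAnnotation] = {}
    for j, g in enumerate(blk.genes_local):
        s, e = iv(g["start"], g["end"])
        ann = GeneAnnotation(gene_id=g["id"], start=s, end=e, strand=strand,
                             kind=g["kind"])
        spec.genes.append(ann)
        gene_by_index[j] = ann

    tss_records: list[PlantedTss] = []
    for t in blk.tss_local:
        gene = gene_by_index[t["gene_index"]]
        kind = t["kind"]
        if gene.is_stable_rna:
            kind = "stable_rna"
        elif kind == "primary" and len(blk.genes_local) == 1:
            kind = "mono"
        rec = PlantedTss(position=pt(t["local"]), strand=strand, kind=kind,
                         gene_id=gene.gene_id, utr_length=t["utr"],
                         transcript_id=unit_name)
        tss_records.append(rec)
        spec.tss.append(rec)

    for m in blk.motifs_local:
        s, e = iv(*m["span"])
        spec_list = spec.rbs if m["consensus"] == RBS_CONSENSUS else spec.promoters
        spec_list.append(PlantedMotif(
            start=s, end=e, strand=strand, consensus=m["consensus"],
            anchor=pt(m["anchor"]) if strand == "+" else pt(m["anchor"]),
            spacer=m["spacer"],
            tss_position=pt(m["tss_local"]) if "tss_local" in m else None,
            gene_id=m.get("gene_id", "")))

    term = blk.terminator_local
    spec.terminators.append(PlantedTerminator(
        unit_id=term["unit_id"], strand=strand,
        stem1=iv(*term["stem1"]), loop=iv(*term["loop"]),
        stem2=iv(*term["stem2"]), tail=iv(*term["tail"]),
        end_position=pt(term["end_local"]), region=term["region"]))

    for k, tr in enumerate(blk.transcripts_local):
        s, e = iv(tr["start"], tr["end"])
        spec.transcripts.append(PlantedTranscript(
            transcript_id=f"{unit_name}.t{k}", start=s, end=e, strand=strand,
            tss_position=pt(tr["tss_local"])))

    if len(blk.genes_local) > 1:
        internal = tuple(
            (gene_by_index[t["gene_index"]].gene_id, r.position)
            for t, r in zip(blk.tss_local, tss_records) if t["kind"] == "internal")
        primary = next(r.position for t, r in zip(blk.tss_local, tss_records)
                       if t["kind"] == "primary")
        spec.operons.append(OperonTruth(
            operon_id=unit_name,
            gene_ids=tuple(gene_by_index[j].gene_id
                           for j in range(len(blk.genes_local))),
            strand=strand, primary_tss=primary, internal_tss=internal))


DEFAULT_OPERON_SIZES = (3, 2, 4, 2, 3, 2, 2, 3)
DEFAULT_N_MONO = 11


def build_architecture(seed: int = 0, genome_length: int = 50_000,
                       operon_sizes: Sequence[int] = DEFAULT_OPERON_SIZES,
                       n_mono: int = DEFAULT_N_MONO,
                       with_stable_rna: bool = True,
                       with_novel: bool = True,
                       with_alt_tss: bool = True,
                       with_fp_site: bool = True,
                       term_region_probs: dict[str, float] | None = None,
                       ) -> ArchitectureSpec:
    """Construct the default toy architecture, fully resolved and seeded.

    Eight operons (with internal TSSs in every other one), eleven
    monocistronic genes, one tRNA and one rRNA unit, one intergenic, one
    antisense and one intragenic novel transcript, one alternative-TSS
    satellite peak and one planted false-positive site.
    """
    rng = _rng(seed)
    spec = ArchitectureSpec(genome_length=genome_length, seed=seed)
    probs = term_region_probs or TERM_REGION_PROBS
    region_names = list(probs)
    region_p = np.array([probs[r] for r in region_names], dtype=float)
    region_p = region_p / region_p.sum()

    def draw_region() -> str:
        return region_names[int(rng.choice(len(region_names), p=region_p))]

    def gene_len() -> int:
        return int(rng.integers(100, 201)) * 3       # 300..600, multiple of 3

    cursor = 800
    gene_counter = 0
    special_hosts: dict[str, GeneAnnotation] = {}

    def advance(blk: _Block, strand: str, name: str) -> None:
        nonlocal cursor
        if cursor + blk.span + 800 > spec.genome_length:
            raise PlacementError("architecture does not fit the genome; "
                                 "increase genome_length")
        _place_block(spec, blk, cursor, strand, name)
        cursor += blk.span + int(rng.integers(550, 801))

    n_leaderless_target = 8
    leaderless_flags = [True] * n_leaderless_target
    leaderless_flags += [False] * (len(operon_sizes) + n_mono
                                   - n_leaderless_target)
    rng.shuffle(leaderless_flags)

    unit_index = 0
    # -- operons ------------------------------------------------------------
    for k, size in enumerate(operon_sizes):
        ids = []
        lens = []
        for _ in range(size):
            ids.append(f"g{gene_counter:03d}")
            lens.append(gene_len())
            gene_counter += 1
        # the first three operons host the antisense / intragenic / FP plants
        strand = "+" if k < 3 else ("+" if rng.random() < 0.5 else "-")
        if k == 0:
            lens[0] = max(lens[0], 600)
        if k in (1, 2):
            lens[-1] = max(lens[-1], 600)
        internal_after = (1,) if k % 2 == 0 else ()
        blk = _build_unit(rng, lens, ids, leaderless=leaderless_flags[unit_index],
                          internal_after=internal_after,
                          term_region=draw_region())
        advance(blk, strand, f"op{k}")
        if k == 0:
            special_hosts["antisense"] = next(
                g for g in spec.genes if g.gene_id == ids[0])
        elif k == 1:
            special_hosts["intragenic"] = next(
                g for g in spec.genes if g.gene_id == ids[-1])
        elif k == 2:
            special_hosts["fp"] = next(
                g for g in spec.genes if g.gene_id == ids[-1])
        unit_index += 1

    # -- monocistronic genes -------------------------------------------------
    for _ in range(n_mono):
        gid = f"g{gene_counter:03d}"
        gene_counter += 1
        strand = "+" if rng.random() < 0.5 else "-"
        blk = _build_unit(rng, [gene_len()], [gid],
                          leaderless=leaderless_flags[unit_index],
                          term_region=draw_region())
        advance(blk, strand, gid)
        unit_index += 1

    # -- stable RNA genes ----------------------------------------------------
    if with_stable_rna:
        for kind, length in (("tRNA", 81), ("rRNA", 300)):
            gid = f"{kind.lower()}{gene_counter:03d}"
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            blk = _build_unit(rng, [length], [gid], kinds=[kind],
                              leaderless=False, with_promoter=False,
                              term_region=draw_region())
            advance(blk, strand, gid)

    # -- novel intergenic transcript ------------------------------------------
    if with_novel:
        strand = "+" if rng.random() < 0.5 else "-"
        length = 300
        if cursor + length + 840 > spec.genome_length:
            raise PlacementError("architecture does not fit the genome")
        if strand == "+":
            tss = cursor
            lo, hi = cursor, cursor + length
        else:
            tss = cursor + length - 1
            lo, hi = cursor, cursor + length
        spec.tss.append(PlantedTss(position=tss, strand=strand,
                                   kind="novel_intergenic",
                                   transcript_id="novel_ig"))
        spec.transcripts.append(PlantedTranscript(
            transcript_id="novel_ig", start=lo, end=hi, strand=strand,
            tss_position=tss))
        spec.novel.append(NovelTruth(transcript_id="novel_ig", start=lo,
                                     end=hi, strand=strand, cls="intergenic",
                                     tss_position=tss))
        cursor += length + int(rng.integers(550, 801))

        # antisense transcript inside the first operon's first gene ('+')
        host = special_hosts["antisense"]
        lo, hi = host.start + 100, host.start + 400
        spec.tss.append(PlantedTss(position=hi - 1, strand="-",
                                   kind="novel_antisense",
                                   transcript_id="novel_as"))
        spec.transcripts.append(PlantedTranscript(
            transcript_id="novel_as", start=lo, end=hi, strand="-",
            tss_position=hi - 1))
        spec.novel.append(NovelTruth(transcript_id="novel_as", start=lo,
                                     end=hi, strand="-", cls="antisense",
                                     tss_position=hi - 1))

        # intragenic TSS deep inside the last gene of the second operon ('+')
        host = special_hosts["intragenic"]
        pos = host.start + 30
        spec.tss.append(PlantedTss(position=pos, strand="+",
                                   kind="novel_intragenic",
                                   transcript_id="novel_intra"))
        spec.novel.append(NovelTruth(transcript_id="novel_intra", start=pos,
                                     end=host.end, strand="+",
                                     cls="intragenic", tss_position=pos))

    # -- alternative-TSS satellite and planted false-positive site -----------
    if with_alt_tss and spec.operons:
        # a weaker satellite peak 1 nt 5' of the first operon's primary TSS;
        # the simulator boosts the primary so both pass the step-ratio test
        # and merging keeps the stronger, 3'-side position
        spec.alt_tss.append((spec.operons[0].primary_tss,
                             spec.operons[0].strand))
    if with_fp_site:
        host = special_hosts.get("fp")
        if host is not None:
            spec.fp_sites.append((host.start + 60, host.start + 100, "+"))

    spec.genes.sort(key=lambda g: g.start)
    return spec


# ---------------------------------------------------------------------------
# Sequence rendering
# ---------------------------------------------------------------------------

def _degrade(motif: str, rng: np.random.Generator, identity: float = 0.9) -> str:
    """Render a consensus with per-base identity; N positions are random."""
    out = []
    for c in motif.upper():
        if c == "N" or rng.random() > identity:
            out.append(BASES[rng.integers(4)])
        else:
            out.append(c)
    return "".join(out)


def _gc_rich_stem(rng: np.random.Generator, width: int) -> str:
    return "".join(rng.choice(list("GCGCGCAT"), size=width))


def synthesize_genome(spec: ArchitectureSpec,
                      motif_identity: float = 0.9,
                      ) -> tuple[GenomeSequence, list[GeneAnnotation]]:
    """Render the genome sequence for a resolved architecture.

    CDS bodies are frames of non-stop codons opened by a start codon and
    closed by a stop codon; promoter/RBS consensus strings are planted with
    the given per-base identity; terminator stems are reverse-complement
    palindromes with G+C-rich stems and a T-tail on the coding strand.
    """
    rng = _rng(spec.seed + 1)
    seq = rng.choice(list(BASES), size=spec.genome_length)

    def write(start: int, s: str, strand: str) -> None:
        if strand == "-":
            s = reverse_complement(s)
        seq[start:start + len(s)] = list(s)

    leaderless = {t.gene_id for t in spec.tss
                  if t.kind in ("primary", "mono", "internal")
                  and t.utr_length == 0}
    for g in spec.genes:
        if g.kind != "CDS":
            continue
        n_codons = (g.end - g.start) // 3
        if g.gene_id in leaderless:
            start_codon = "ATG" if rng.random() < 0.79 else "GTG"
        else:
            start_codon = str(rng.choice(START_CODONS, p=[.6, .25, .08, .07]))
        body = "".join(rng.choice(NON_STOP_CODONS, size=n_codons - 2))
        stop = str(rng.choice(STOP_CODONS))
        write(g.start, start_codon + body + stop, g.strand)

    for m in spec.promoters + spec.rbs:
        write(m.start, _degrade(m.consensus, rng, motif_identity), m.strand)

    for t in spec.terminators:
        lo = min(t.stem1[0], t.tail[0])
        stem = _gc_rich_stem(rng, t.stem1[1] - t.stem1[0])
        loop = "".join(rng.choice(list(BASES), size=t.loop[1] - t.loop[0]))
        tail = "T" * (t.tail[1] - t.tail[0])
        local = stem + loop + reverse_complement(stem) + tail
        write(lo, local, t.strand)

    genome = GenomeSequence(name=f"toy_{spec.seed}", seq="".join(seq))
    return genome, list(spec.genes)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def simulate_primary_starts(spec: ArchitectureSpec,
                            lam_tss: float = 60.0,
                            lam_bg: float = 0.2,
                            lam_alt: float = 20.0,
                            lam_alt_boost: float = 200.0,
                            lam_fp: float = 150.0,
                            seed: int | None = None) -> StrandedSignal:
    """Simulate the 5'-enriched library's read-start track.

    Every planted TSS receives a Poisson(``lam_tss``) peak on top of an
    independent Poisson(``lam_bg``) background.  Each alternative-TSS pair
    is a weak Poisson(``lam_alt``) satellite 1 nt 5' of its primary peak,
    whose own height is raised by ``lam_alt_boost`` so that both clear the
    step-ratio test and the merge step keeps the primary.  Planted
    false-positive sites are broad Poisson(``lam_fp``) plateaus with no
    sharp edge relative to their surroundings.
    """
    rng = _rng(spec.seed + 2 if seed is None else seed)
    signal = StrandedSignal(spec.genome_length)
    for s in STRANDS:
        if lam_bg > 0:
            signal.read_starts[s] = rng.poisson(lam_bg, spec.genome_length)
        else:
            signal.read_starts[s] = np.zeros(spec.genome_length, dtype=np.int64)
    for t in spec.tss:
        signal.read_starts[t.strand][t.position] += rng.poisson(lam_tss)
    for pos, strand in spec.alt_tss:
        satellite = pos - 1 if strand == "+" else pos + 1
        signal.read_starts[strand][satellite] += rng.poisson(lam_alt)
        signal.read_starts[strand][pos] += rng.poisson(lam_alt_boost)
    for lo, hi, strand in spec.fp_sites:
        signal.read_starts[strand][lo:hi] += rng.poisson(lam_fp, hi - lo)
    return signal


def simulate_whole_fragments(spec: ArchitectureSpec,
                             rate: float = 0.2,
                             bg_rate: float = 0.01,
                             frag_range: tuple[int, int] = (200, 500),
                             seed: int | None = None,
                             ) -> list[AlignedFragment]:
    """Simulate combined mate-pair fragments of the whole-transcriptome library.

    Per transcript, Poisson(rate x length) fragments with lengths uniform in
    ``frag_range`` are placed uniformly and clipped to the transcript extent,
    so junction-spanning fragments connect operon genes and no fragment
    extends past the planted 3' end.  A low genome-wide background fragment
    rate models unassigned transcription.
    """
    rng = _rng(spec.seed + 3 if seed is None else seed)
    lo_len, hi_len = frag_range
    fragments: list[AlignedFragment] = []
    counter = 0
    for tr in spec.transcripts:
        tlen = tr.end - tr.start
        if tlen < 26:
            raise ValueError(f"transcript {tr.transcript_id} shorter than a read")
        n = rng.poisson(rate * tlen)
        if n == 0:
            continue
        lengths = rng.integers(lo_len, hi_len + 1, size=n)
        starts = rng.integers(tr.start - lengths + 1, tr.end, size=n)
        for s, L in zip(starts, lengths):
            a = max(int(s), tr.start)
            b = min(int(s) + int(L), tr.end)
            if b - a < 26:
                continue
            fragments.append(AlignedFragment(start=a, end=b, strand=tr.strand,
                                             is_pair=True, source_reads=2,
                                             name=f"sim{counter}"))
            counter += 1
    if bg_rate > 0:
        n_bg = rng.poisson(bg_rate * spec.genome_length * 2)
        for _ in range(n_bg):
            L = int(rng.integers(lo_len, hi_len + 1))
            s = int(rng.integers(0, spec.genome_length - L))
            strand = "+" if rng.random() < 0.5 else "-"
            fragments.append(AlignedFragment(start=s, end=s + L, strand=strand,
                                             is_pair=True, source_reads=2,
                                             name=f"bg{counter}"))
            counter += 1
    return fragments


# ---------------------------------------------------------------------------
# Ground truth export and dataset writing
# ---------------------------------------------------------------------------

def export_ground_truth(spec: ArchitectureSpec) -> GroundTruth:
    """Flatten the planted architecture into 1-based result-style tables."""
    tss_rows = [{"position": t.position + 1, "strand": t.strand,
                 "kind": t.kind, "gene_id": t.gene_id,
                 "utr_length": t.utr_length if t.utr_length is not None else "",
                 "leaderless": t.utr_length == 0,
                 "transcript_id": t.transcript_id}
                for t in spec.tss]
    op_rows = []
    for op in spec.operons:
        op_rows.append({
            "operon_id": op.operon_id, "genes": ",".join(op.gene_ids),
            "strand": op.strand, "primary_tss": op.primary_tss + 1,
            "internal_tss": ",".join(f"{g}:{p + 1}" for g, p in op.internal_tss),
            "sub_operons": ";".join(",".join(s) for s in op.sub_operons)})
    tr_rows = [{"transcript_id": n.transcript_id, "start": n.start + 1,
                "end": n.end, "strand": n.strand, "class": n.cls,
                "tss": n.tss_position + 1 if n.tss_position is not None else ""}
               for n in spec.novel]
    term_rows = [{"unit_id": t.unit_id, "strand": t.strand,
                  "stem1_start": t.stem1[0] + 1, "stem1_end": t.stem1[1],
                  "end_position": t.end_position + 1, "region": t.region}
                 for t in spec.terminators]
    return GroundTruth(tss_table=pd.DataFrame(tss_rows),
                       operon_table=pd.DataFrame(op_rows),
                       transcript_table=pd.DataFrame(tr_rows),
                       terminator_end_table=pd.DataFrame(term_rows))


def terminator_predictions_frame(spec: ArchitectureSpec) -> pd.DataFrame:
    """Terminator predictions in the consumed TSV layout (1-based inclusive,
    sub-spans ordered in transcription direction)."""
    rows = []
    for t in spec.terminators:
        row = {"unit_id": t.unit_id, "strand": t.strand}
        for part in ("stem1", "loop", "stem2", "tail"):
            lo, hi = getattr(t, part)
            if t.strand == "+":
                row[f"{part}_start"], row[f"{part}_end"] = lo + 1, hi
            else:
                row[f"{part}_start"], row[f"{part}_end"] = hi, lo + 1
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_terminator_panel(n: int, seed: int,
                              region_probs: dict[str, float] | None = None,
                              upstream_cov: int = 50,
                              genome_length_per_unit: int = 400,
                              ):
    """Signal-level panel of ``n`` plus-strand terminators with planted drops.

    Returns ``(predictions_frame, coverage, truth_frame, genome_length)``
    where coverage is a per-strand dict of vectors.  Used for calibrating and
    testing 3'-end verdict statistics at a chosen region mix without building
    a full genome.
    """
    rng = _rng(seed)
    probs = region_probs or TERM_REGION_PROBS
    names = list(probs)
    p = np.array([probs[r] for r in names], dtype=float)
    p /= p.sum()
    w1, wl, w2, wt = TERM_WIDTHS
    length = n * genome_length_per_unit
    cov = {s: np.zeros(length, dtype=np.int64) for s in STRANDS}
    pred_rows, truth_rows = [], []
    for i in range(n):
        base = i * genome_length_per_unit + 100
        stem1 = (base, base + w1)
        loop = (stem1[1], stem1[1] + wl)
        stem2 = (loop[1], loop[1] + w2)
        tail = (stem2[1], stem2[1] + wt)
        spans = {"stem1": stem1, "loop": loop, "stem2": stem2, "tail": tail}
        region = names[int(rng.choice(len(names), p=p))]
        lo, hi = spans[region]
        end = int(rng.integers(lo, hi))
        cov["+"][base - 60:end] = upstream_cov
        pred_rows.append({"unit_id": f"u{i}", "strand": "+",
                          "stem1_start": stem1[0] + 1, "stem1_end": stem1[1],
                          "loop_start": loop[0] + 1, "loop_end": loop[1],
                          "stem2_start": stem2[0] + 1, "stem2_end": stem2[1],
                          "tail_start": tail[0] + 1, "tail_end": tail[1]})
        truth_rows.append({"unit_id": f"u{i}", "end_position": end + 1,
                           "region": region})
    return (pd.DataFrame(pred_rows), cov, pd.DataFrame(truth_rows), length)


@dataclass
class SyntheticDataset:
    """A rendered architecture plus both simulated libraries."""

    spec: ArchitectureSpec
    genome: GenomeSequence
    annotation: list[GeneAnnotation]
    primary_starts: StrandedSignal
    fragments: list[AlignedFragment]
    whole_signal: StrandedSignal
    truth: GroundTruth


def make_dataset(seed: int = 0, **kwargs) -> SyntheticDataset:
    """Build, render and simulate the default architecture in one call."""
    sim_kwargs = {k: kwargs.pop(k) for k in ("lam_tss", "lam_bg", "rate",
                                             "bg_rate") if k in kwargs}
    spec = build_architecture(seed=seed, **kwargs)
    genome, annotation = synthesize_genome(spec)
    starts = simulate_primary_starts(
        spec, **{k: v for k, v in sim_kwargs.items()
                 if k in ("lam_tss", "lam_bg")})
    fragments = simulate_whole_fragments(
        spec, **{k: v for k, v in sim_kwargs.items()
                 if k in ("rate", "bg_rate")})
    whole = build_signal_tracks(fragments, spec.genome_length)
    truth = export_ground_truth(spec)
    return SyntheticDataset(spec=spec, genome=genome, annotation=annotation,
                            primary_starts=starts, fragments=fragments,
                            whole_signal=whole, truth=truth)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset in the exact formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"genome": out / "genome.fasta",
             "annotation": out / "annotation.gff3",
             "alignments": out / "whole_library.bed",
             "terminators": out / "terminator_predictions.tsv"}
    write_genome_fasta(ds.genome, paths["genome"])
    write_annotation_gff3(ds.annotation, paths["annotation"], ds.genome.name)
    write_alignments_bed6(fragments_to_mates(ds.fragments),
                          paths["alignments"], ds.genome.name)
    terminator_predictions_frame(ds.spec).to_csv(paths["terminators"],
                                                 sep="\t", index=False)
    write_signal_tracks(ds.primary_starts, out, ds.genome.name, "primary")
    write_signal_tracks(ds.whole_signal, out, ds.genome.name, "whole")
    for name, frame in (("tss", ds.truth.tss_table),
                        ("operons", ds.truth.operon_table),
                        ("transcripts", ds.truth.transcript_table),
                        ("terminator_ends", ds.truth.terminator_end_table)):
        p = out / f"truth_{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    return paths
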