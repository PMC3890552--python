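"""Standard-format I/O and strand-specific signal tracks.

All coordinates are handled internally as 0-based half-open intervals on a
single chromosome; file formats keep their native conventions (GFF3 1-based
inclusive, BED/bedGraph 0-based half-open) and report tables use 1-based
positions so that they can be compared directly against genome-browser views.

The two per-strand signal types are

* ``read_starts`` -- the number of sequenced fragments whose 5'-most
  transcribed base lies at each position (the ``x_i`` statistic used for TSS
  detection), and
* ``coverage`` -- the number of fragments covering each base (``c_i``), used
  for operon assembly, novel-transcript calling and 3'-end mapping.

Mate pairs from a paired-end library are merged into single fragments
spanning the outer extent of the two reads (a "combined pair of reads"),
provided both mates map to the same strand within 1 kb of each other.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")
VALID_BASES = frozenset("ACGT")

#: feature types accepted from GFF3 and their internal kind
_KIND_MAP = {
    "CDS": "CDS",
    "gene": "CDS",  # plain gene records are treated as coding
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "ncRNA": "ncRNA",
}

#: read length of the trimmed sequencing reads (nt)
READ_LENGTH = 26

#: maximum outer span allowed when combining mate pairs (nt)
MAX_PAIR_SPAN = 1000


class FormatError(ValueError):
    """Raised when an input file violates its documented contract."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single-chromosome genome over the strict {A,C,G,T} alphabet."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise FormatError("zero-length genome record")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(f"non-ACGT characters in genome: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end) on the given strand (reverse-complemented for '-')."""
        s = self.seq[max(start, 0):max(end, 0)]
        if strand == "-":
            s = reverse_complement(s)
        return s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneAnnotation:
    """An annotated feature with a strand-aware translational start (TLS)."""

    gene_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"{self.gene_id}: end <= start")
        if self.strand not in STRANDS:
            raise FormatError(f"{self.gene_id}: strand {self.strand!r} not in +/-")

    @property
    def tls(self) -> int:
        """First base of the start codon: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def is_stable_rna(self) -> bool:
        return self.kind in ("rRNA", "tRNA")

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class AlignedFragment:
    """A mapped fragment: a single read or a combined mate pair."""

    start: int
    end: int
    strand: str
    is_pair: bool = False
    source_reads: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError("fragment end <= start")
        if self.strand not in STRANDS:
            raise FormatError(f"fragment strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the 5'-most transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


class StrandedSignal:
    """Per-strand, per-position read-start and coverage vectors."""

    def __init__(self, length: int,
                 read_starts: dict[str, np.ndarray] | None = None,
                 coverage: dict[str, np.ndarray] | None = None) -> None:
        self.length = int(length)
        self.read_starts = read_starts or {
            s: np.zeros(self.length, dtype=np.int64) for s in STRANDS}
        self.coverage = coverage or {
            s: np.zeros(self.length, dtype=np.int64) for s in STRANDS}
        for track in (self.read_starts, self.coverage):
            for s in STRANDS:
                if len(track[s]) != self.length:
                    raise ValueError("track length mismatch")
                if (track[s] < 0).any():
                    raise ValueError("negative signal values")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StrandedSignal):
            return NotImplemented
        return self.length == other.length and all(
            np.array_equal(self.read_starts[s], other.read_starts[s])
            and np.array_equal(self.coverage[s], other.coverage[s])
            for s in STRANDS)


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> GenomeSequence:
    """Read a single-record FASTA genome; the sequence is uppercased.

    Multi-record files are rejected (single-chromosome model).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise FormatError(f"{path}: multi-record FASTA not supported "
                          f"({len(records)} records)")
    rec = records[0]
    return GenomeSequence(name=rec.id, seq=str(rec.seq).upper())


def write_genome_fasta(genome: GenomeSequence, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_annotation_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (1-based inclusive -> 0-based half-open).

    Unknown feature types are skipped with a warning; output is sorted by
    start coordinate.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneAnnotation] = []
    skipped: set[str] = set()
    for feat in db.all_features():
        kind = _KIND_MAP.get(feat.featuretype)
        if kind is None:
            skipped.add(feat.featuretype)
            continue
        if feat.end < feat.start:
            raise FormatError(f"{path}: feature with end < start at line for "
                              f"{feat.id}")
        if feat.strand not in STRANDS:
            raise FormatError(f"{path}: strand {feat.strand!r} for {feat.id}")
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneAnnotation(gene_id=gid, start=feat.start - 1,
                                    end=feat.end, strand=feat.strand,
                                    kind=kind))
    for ft in sorted(skipped):
        logger.warning("skipping unknown GFF3 feature type %r", ft)
    genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return genes


def write_annotation_gff3(genes: Sequence[GeneAnnotation], path: str | Path,
                          seqid: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: g.start):
            fh.write(f"{seqid}\tbactmap\t{g.kind}\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t0\tID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# BED6 alignments and mate-pair combination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MateInterval:
    """One aligned read; ``name`` may carry a /1 or /2 mate suffix."""

    name: str
    start: int
    end: int
    strand: str


@dataclass
class CombineResult:
    """Fragments after mate combination, plus discard accounting."""

    fragments: list[AlignedFragment] = field(default_factory=list)
    n_discarded_span: int = 0
    n_discarded_strand: int = 0


def read_alignments_bed6(path: str | Path) -> list[MateInterval]:
    mates = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            _, start, end, name, _, strand = parts[:6]
            mates.append(MateInterval(name=name, start=int(start),
                                      end=int(end), strand=strand))
    return mates


def _mate_key(name: str) -> tuple[str, bool]:
    """Return (pair key, is_mate_suffixed) stripping a /1 or /2 suffix."""
    if name.endswith(("/1", "/2")):
        return name[:-2], True
    return name, False


def combine_mate_pairs(mates: Iterable[MateInterval],
                       max_span: int = MAX_PAIR_SPAN) -> CombineResult:
    """Merge mate pairs into fragments spanning the outer read extent.

    Pairs whose outer span exceeds ``max_span`` are discarded, as are pairs
    mapping to different strands; unmatched mates are retained as single-read
    fragments.
    """
    groups: dict[str, list[MateInterval]] = defaultdict(list)
    singles: list[MateInterval] = []
    for m in mates:
        key, suffixed = _mate_key(m.name)
        if suffixed:
            groups[key].append(m)
        else:
            singles.append(m)

    result = CombineResult()
    for key in groups:
        grp = groups[key]
        if len(grp) == 1:
            singles.append(grp[0])
            continue
        if len(grp) > 2:
            raise FormatError(f"more than two mates named {key!r}")
        a, b = grp
        if a.strand != b.strand:
            result.n_discarded_strand += 1
            continue
        start, end = min(a.start, b.start), max(a.end, b.end)
        if end - start > max_span:
            result.n_discarded_span += 1
            continue
        result.fragments.append(AlignedFragment(
            start=start, end=end, strand=a.strand, is_pair=True,
            source_reads=2, name=key))
    if result.n_discarded_strand:
        logger.warning("discarded %d mate pairs on different strands",
                       result.n_discarded_strand)
    for m in singles:
        result.fragments.append(AlignedFragment(
            start=m.start, end=m.end, strand=m.strand, is_pair=False,
            source_reads=1, name=_mate_key(m.name)[0]))
    result.fragments.sort(key=lambda f: (f.strand, f.start, f.end))
    return result


def fragments_to_mates(fragments: Iterable[AlignedFragment],
                       read_length: int = READ_LENGTH) -> list[MateInterval]:
    """Represent fragments as outer mate reads (inverse of combination).

    Fragments shorter than one read length cannot be represented and raise.
    """
    mates = []
    for i, f in enumerate(fragments):
        name = f.name or f"frag{i}"
        if f.length < read_length:
            raise ValueError(f"fragment {name} shorter than read length")
        if f.is_pair or f.length > read_length:
            mates.append(MateInterval(f"{name}/1", f.start,
                                      min(f.start + read_length, f.end),
                                      f.strand))
            mates.append(MateInterval(f"{name}/2",
                                      max(f.end - read_length, f.start),
                                      f.end, f.strand))
        else:
            mates.append(MateInterval(name, f.start, f.end, f.strand))
    return mates


def write_alignments_bed6(mates: Iterable[MateInterval],
                          path: str | Path, seqid: str) -> None:
    with open(path, "w") as fh:
        for m in mates:
            fh.write(f"{seqid}\t{m.start}\t{m.end}\t{m.name}\t0\t{m.strand}\n")


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def build_signal_tracks(fragments: Iterable[AlignedFragment],
                        genome_length: int) -> StrandedSignal:
    """Count per-position read starts and coverage, per strand.

    ``read_starts[strand][p]`` counts fragments whose 5'-most transcribed
    base is ``p``; coverage increments every base of every fragment.  The
    result is independent of fragment order.
    """
    signal = StrandedSignal(genome_length)
    by_strand: dict[str, list[AlignedFragment]] = {s: [] for s in STRANDS}
    for f in fragments:
        if f.start < 0 or f.end > genome_length:
            raise ValueError(f"fragment [{f.start},{f.end}) out of bounds for "
                             f"genome of length {genome_length}")
        by_strand[f.strand].append(f)
    for s in STRANDS:
        frags = by_strand[s]
        if not frags:
            continue
        starts = np.fromiter((f.start for f in frags), dtype=np.int64)
        ends = np.fromiter((f.end for f in frags), dtype=np.int64)
        five = starts if s == "+" else ends - 1
        np.add.at(signal.read_starts[s], five, 1)
        diff = np.zeros(genome_length + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        signal.coverage[s] = np.cumsum(diff[:-1])
    return signal


def write_bedgraph(values: np.ndarray, path: str | Path, seqid: str) -> None:
    """Write an integer per-base vector as run-length-encoded bedGraph.

    Zero runs are omitted, so an all-zero track produces an empty body.
    """
    values = np.asarray(values)
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        # run boundaries wherever the value changes
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(values)]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{seqid}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str | Path, genome_length: int) -> np.ndarray:
    """Read a bedGraph file back into a per-base integer vector.

    Overlapping intervals are rejected (each base may be described once).
    """
    values = np.zeros(genome_length, dtype=np.int64)
    prev_end = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            _, start, end, val = line.split("\t")
            start, end = int(start), int(end)
            if end <= start or start < 0 or end > genome_length:
                raise FormatError(f"{path}:{lineno}: bad interval")
            if start < prev_end:
                raise FormatError(
                    f"{path}:{lineno}: overlapping or unsorted intervals")
            values[start:end] = int(float(val))
            prev_end = end
    return values


_TRACK_FILES = {
    ("read_starts", "+"): "starts.plus.bedgraph",
    ("read_starts", "-"): "starts.minus.bedgraph",
    ("coverage", "+"): "coverage.plus.bedgraph",
    ("coverage", "-"): "coverage.minus.bedgraph",
}


def write_signal_tracks(signal: StrandedSignal, out_dir: str | Path,
                        seqid: str, prefix: str = "tracks") -> list[Path]:
    """Write the four per-strand bedGraph files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (track, strand), suffix in _TRACK_FILES.items():
        arr = getattr(signal, track)[strand]
        p = out_dir / f"{prefix}.{suffix}"
        write_bedgraph(arr, p, seqid)
        paths.append(p)
    return paths


def read_signal_tracks(out_dir: str | Path, genome_length: int,
                       prefix: str = "tracks") -> StrandedSignal:
    out_dir = Path(out_dir)
    signal = StrandedSignal(genome_length)
    for (track, strand), suffix in _TRACK_FILES.items():
        p = out_dir / f"{prefix}.{suffix}"
        getattr(signal, track)[strand] = read_bedgraph(p, genome_length)
    return signal
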