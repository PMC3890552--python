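"""End-to-end orchestration and the accounting report.

Stages: simulate (optional) -> signal tracks -> TSS calling -> gene-start
refinement -> 5'-UTR/RBS statistics -> motif discovery -> operon assembly ->
novel-transcript calling -> terminator 3'-ends -> summary report.  Every
stage writes a plain TSV, the run configuration is serialized next to the
outputs, and the TSS accounting ledger (detected = retained + merged +
stable-RNA + false-positive) is re-checked when the report is written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core_io, motifs, operons, refine, synthetic, terminators, transcripts, tss, utr

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs, outputs and stage parameters of one pipeline run."""

    out_dir: str = "bactmap_out"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate is False)
    genome: str | None = None
    annotation: str | None = None
    alignments: str | None = None
    starts_prefix: str | None = None      # bedGraph prefix for the 5' library
    terminator_predictions: str | None = None
    # stage parameters
    tss_params: dict = field(default_factory=dict)
    max_pair_span: int = 1000
    t_pairs: int = 15
    min_cov: float = 1.0
    t_cov: float = 14.0
    min_transcript_len: int = 50
    t_low: float = 5.0
    term_min_mean: float = 11.0
    term_ratio: float = 5.0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    config: RunConfig
    genome: core_io.GenomeSequence
    annotation: list
    tss_result: tss.TssResult
    corrections: list
    utrs_all: list
    utrs_unique: list
    minus10: motifs.PromoterSearch
    minus35: motifs.PromoterSearch
    rbs: motifs.PromoterSearch | None
    rbs_stats: dict
    operon_structures: list
    transcript_calls: list
    verdicts: list
    end_summary: dict
    report: dict
    truth: synthetic.GroundTruth | None = None
    dataset: synthetic.SyntheticDataset | None = None


def tss_ledger_retained(detected: int, merged_away: int, stable_rna: int,
                        false_positive: int) -> int:
    """Retained TSS count implied by the filtering ledger."""
    return detected - merged_away - stable_rna - false_positive


def write_summary_report(result_dir: Path, *, ledger: dict,
                         category_counts: dict, utr_histogram,
                         leaderless_fraction: float, operon_classes: dict,
                         novel_classes: dict, end_summary: dict,
                         extras: dict | None = None) -> dict:
    """Assemble and write the accounting report; imbalances are fatal."""
    implied = tss_ledger_retained(ledger["detected"], ledger["merged_away"],
                                  ledger["stable_rna"],
                                  ledger["false_positive"])
    if implied != ledger["retained"]:
        raise AssertionError(f"TSS ledger does not balance: {ledger}")
    if sum(category_counts.values()) != ledger["retained"]:
        raise AssertionError("TSS categories do not partition the retained set")
    report = {
        "tss_ledger": ledger,
        "tss_categories": category_counts,
        "utr_histogram": {str(k): int(v) for k, v in utr_histogram.items()},
        "leaderless_fraction": leaderless_fraction,
        "operon_classes": operon_classes,
        "novel_transcript_classes": novel_classes,
        "terminator_summary": {
            "status_counts": end_summary["status_counts"],
            "region_fractions": end_summary["region_fractions"]},
    }
    if extras:
        report.update(extras)
    with open(result_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage, writing one TSV per stage plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    dataset = None
    truth = None
    if config.simulate:
        dataset = synthetic.make_dataset(seed=config.seed)
        data_dir = out / "data"
        synthetic.write_dataset(dataset, data_dir)
        genome = dataset.genome
        annotation = dataset.annotation
        starts = dataset.primary_starts
        fragments = dataset.fragments
        whole = dataset.whole_signal
        term_path = data_dir / "terminator_predictions.tsv"
        truth = dataset.truth
    else:
        for name in ("genome", "annotation", "alignments", "starts_prefix",
                     "terminator_predictions"):
            if getattr(config, name) is None:
                raise ValueError(f"missing required input --{name.replace('_', '-')}")
        genome = core_io.read_genome_fasta(config.genome)
        annotation = core_io.read_annotation_gff3(config.annotation)
        mates = core_io.read_alignments_bed6(config.alignments)
        combined = core_io.combine_mate_pairs(mates, config.max_pair_span)
        fragments = combined.fragments
        whole = core_io.build_signal_tracks(fragments, genome.length)
        starts_dir = Path(config.starts_prefix).parent
        starts = core_io.read_signal_tracks(starts_dir, genome.length,
                                            Path(config.starts_prefix).name)
        term_path = Path(config.terminator_predictions)

    # --- TSS calling -------------------------------------------------------
    params = tss.TssParams(**config.tss_params)
    tss_result = tss.call_tss(starts, annotation, params)
    tss.tss_frame(tss_result).to_csv(out / "tss.tsv", sep="\t", index=False)

    # --- gene-start refinement --------------------------------------------
    corrections = refine.refine_genes(tss_result.records, annotation, genome)
    with open(out / "start_corrections.tsv", "w") as fh:
        fh.write("gene_id\told_tls\tnew_tls\tmode\talternatives\n")
        for c in corrections:
            alts = ",".join(str(a + 1) for a in c.alternatives)
            fh.write(f"{c.gene_id}\t{c.old_tls + 1}\t{c.new_tls + 1}\t"
                     f"{c.mode}\t{alts}\n")

    # --- 5'-UTRs and RBS ---------------------------------------------------
    utrs_all = utr.compute_utr_lengths(tss_result.records, annotation, genome)
    utrs_unique = utr.compute_utr_lengths(tss_result.records, annotation,
                                          genome, unique=True)
    hist = utr.utr_histogram(utrs_all)
    hist.rename("count").to_csv(out / "utr_histogram.tsv", sep="\t")
    codon_usage = utr.leaderless_codon_usage(utrs_all)
    codon_usage.rename("fraction").to_csv(out / "leaderless_codons.tsv",
                                          sep="\t")
    try:
        profile = utr.purine_profile(utrs_unique)
        np.savetxt(out / "purine_profile.tsv", profile[None, :],
                   delimiter="\t", fmt="%.4f")
    except ValueError:
        profile = None

    # --- motif discovery ---------------------------------------------------
    m10 = motifs.find_minus10(tss_result.records, genome, seed=config.seed)
    m35 = motifs.find_minus35(m10, seed=config.seed + 1)
    try:
        rbs = motifs.find_rbs_sites(utrs_unique, seed=config.seed + 2)
        rbs_spacers = [h.spacer for h in rbs.hits.values()]
    except ValueError:
        rbs, rbs_spacers = None, []
    rbs_stats = utr.rbs_spacing_stats(rbs_spacers)
    with open(out / "motifs.json", "w") as fh:
        json.dump({
            "minus10": {"consensus": m10.model.consensus,
                        "n_hits": len(m10.hits),
                        "n_windows": len(m10.windows),
                        "ic": [round(float(v), 4) for v in m10.model.ic]},
            "minus35": ({"consensus": m35.model.consensus,
                         "n_hits": len(m35.hits)} if m35.model else None),
            "rbs": ({"consensus": rbs.model.consensus,
                     "n_hits": len(rbs.hits),
                     "spacing_mean": rbs_stats["mean"],
                     "spacing_sd": rbs_stats["sd"]} if rbs else None),
        }, fh, indent=2)

    # --- operons -----------------------------------------------------------
    junctions = operons.junction_pair_counts(fragments, annotation)
    operons.junctions_frame(junctions).to_csv(out / "junctions.tsv", sep="\t",
                                              index=False)
    structures = operons.assemble_operons(junctions, tss_result.records,
                                          annotation, whole,
                                          T_pairs=config.t_pairs,
                                          min_cov=config.min_cov)
    operons.operons_frame(structures).to_csv(out / "operons.tsv", sep="\t",
                                             index=False)

    # --- novel transcripts -------------------------------------------------
    calls = transcripts.call_coverage_transcripts(
        whole, annotation, T_cov=config.t_cov,
        min_len=config.min_transcript_len)
    novel_tss = [r for r in tss_result.records
                 if r.category in ("antisense", "intergenic", "intragenic")]
    calls = transcripts.classify_novel_transcripts(calls, novel_tss,
                                                   annotation, whole,
                                                   T_low=config.t_low)
    for c in calls:
        if c.cls == "intergenic":
            transcripts.annotate_intergenic_orf_rbs(
                c, genome, rbs.model if rbs else None)
    transcripts.transcripts_frame(calls).to_csv(out / "transcripts.tsv",
                                                sep="\t", index=False)

    # --- terminator 3' ends ------------------------------------------------
    predictions = terminators.parse_terminator_predictions(term_path)
    selected = terminators.select_terminators_for_units(predictions,
                                                        structures)
    verdicts = [terminators.determine_transcript_end(
        whole, t, min_mean=config.term_min_mean, ratio=config.term_ratio)
        for t in selected]
    terminators.verdicts_frame(verdicts).to_csv(out / "terminator_ends.tsv",
                                                sep="\t", index=False)
    end_summary = terminators.summarize_end_regions(verdicts)

    # --- report ------------------------------------------------------------
    category_counts = {c: 0 for c in tss.CATEGORIES}
    for r in tss_result.records:
        category_counts[r.category] += 1
    n_lless = sum(1 for u in utrs_all if u.leaderless)
    operon_classes: dict[str, int] = {}
    for s in structures:
        operon_classes[s.cls] = operon_classes.get(s.cls, 0) + 1
    novel_classes: dict[str, int] = {}
    for c in calls:
        novel_classes[c.cls] = novel_classes.get(c.cls, 0) + 1
    report = write_summary_report(
        out, ledger=tss_result.ledger, category_counts=category_counts,
        utr_histogram=hist,
        leaderless_fraction=n_lless / len(utrs_all) if utrs_all else 0.0,
        operon_classes=operon_classes, novel_classes=novel_classes,
        end_summary=end_summary,
        extras={"n_start_corrections": len(corrections),
                "n_sub_operons": sum(len(s.sub_operons) for s in structures),
                "seed": config.seed})

    manifest = {"seed": config.seed, "stages": sorted(
        p.name for p in out.iterdir() if p.suffix in (".tsv", ".json"))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        config=config, genome=genome, annotation=annotation,
        tss_result=tss_result, corrections=corrections, utrs_all=utrs_all,
        utrs_unique=utrs_unique, minus10=m10, minus35=m35, rbs=rbs,
        rbs_stats=rbs_stats, operon_structures=structures,
        transcript_calls=calls, verdicts=verdicts, end_summary=end_summary,
        report=report, truth=truth, dataset=dataset)
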