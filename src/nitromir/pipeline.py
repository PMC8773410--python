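"""End-to-end orchestration: reads -> tags -> annotation -> discovery ->
differential expression -> targets -> KOG summary.

One flat configuration drives every stage; identical config + inputs give
byte-identical outputs.  Each stage logs its counts to stderr and writes
its table into the output directory, and read accounting is asserted at
every stage boundary.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import annotation, de, hairpin, kog, tags
from .seq_utils import read_fasta
from .synthetic import DEFAULT_ADAPTOR3


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat run configuration; every threshold has the analysis default."""

    reads_a: str = ""
    reads_b: str = ""
    genome: str = ""
    ref_rrna: str = ""
    ref_trna: str = ""
    ref_snrna: str = ""
    ref_snorna: str = ""
    ref_known_mirna: str = ""
    transcripts: str = ""
    kog_map: str = ""
    outdir: str = "nitromir_out"
    adaptor3: str = DEFAULT_ADAPTOR3
    min_len: int = 18
    max_len: int = 30
    quality_floor: float = 20.0
    max_mismatches: int = 1
    min_tag_count: int = 5
    flank: int = 150
    mfe_ceiling: float = -18.0
    fc_threshold: float = 1.0
    alpha: float = 0.05
    alpha_strong: float = 0.01
    min_tpm: float = 1.0
    max_target_score: float = 4.0
    seed_score_max: float = 2.5
    mfe_ratio: float = 0.75
    seed: int = 0
    verbose: bool = True

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values: Dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                k, v = (s.strip() for s in line.split("=", 1))
                values[k] = v
        kwargs = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values.pop(f.name)
            if f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            elif f.type in ("bool", bool):
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw
        if values:
            raise ValueError(f"unknown config keys: {sorted(values)}")
        return cls(**kwargs)


@dataclass
class RunReport:
    accounting: pd.DataFrame
    class_counts: pd.Series
    known_profile: pd.DataFrame
    novel_candidates: pd.DataFrame
    de_table: pd.DataFrame
    target_hits: pd.DataFrame
    kog_by_category: Optional[pd.DataFrame]
    kog_by_class: Optional[pd.DataFrame]
    stage_log: List[str]


def _log(cfg: RunConfig, log: List[str], stage: str, msg: str) -> None:
    line = f"[nitromir:{stage}] {msg}"
    log.append(line)
    if cfg.verbose:
        print(line, file=sys.stderr)


def run_all(config: RunConfig) -> RunReport:
    """Run every stage in fixed order, writing all intermediates.

    Raises PipelineError naming the failing stage.
    """
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: List[str] = []

    # ---- tag processing ---------------------------------------------------
    stage = "tag_processing"
    try:
        clean_a, stats_a = tags.trim_and_filter(
            cfg.reads_a, cfg.adaptor3, cfg.min_len, cfg.max_len, cfg.quality_floor
        )
        clean_b, stats_b = tags.trim_and_filter(
            cfg.reads_b, cfg.adaptor3, cfg.min_len, cfg.max_len, cfg.quality_floor
        )
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc
    if not clean_a or not clean_b:
        raise PipelineError(stage, "no clean reads survived trimming in at least one library")
    stats_a.check_conservation()
    stats_b.check_conservation()
    tag_pair = tags.collapse_pair(clean_a, clean_b)
    counts_a = {t.sequence: t.count_a for t in tag_pair if t.count_a}
    counts_b = {t.sequence: t.count_b for t in tag_pair if t.count_b}
    acc_a, acc_b = tags.library_overlap(
        counts_a, counts_b, raw_reads=(stats_a.raw_reads, stats_b.raw_reads)
    )
    n1, n2 = stats_a.clean_reads, stats_b.clean_reads
    accounting = pd.DataFrame(
        [
            dict(library="a", **stats_a.as_dict(), unique_tags=acc_a.unique_tags,
                 common_tags=acc_a.common_tags, specific_tags=acc_a.specific_tags),
            dict(library="b", **stats_b.as_dict(), unique_tags=acc_b.unique_tags,
                 common_tags=acc_b.common_tags, specific_tags=acc_b.specific_tags),
        ]
    )
    accounting.to_csv(out / "accounting.tsv", sep="\t", index=False)
    for lib, hist_tags in (("a", counts_a), ("b", counts_b)):
        tags.length_histogram(hist_tags, "unique").to_csv(
            out / f"length_histogram_{lib}.tsv", sep="\t"
        )
    _log(cfg, log, stage, f"clean reads a={n1} b={n2}, unique tags={len(tag_pair)}")

    # ---- annotation -------------------------------------------------------
    stage = "annotation"
    try:
        refsets = [
            annotation.ReferenceSet.from_fasta(name, path)
            for name, path in (
                ("rRNA", cfg.ref_rrna), ("tRNA", cfg.ref_trna),
                ("snRNA", cfg.ref_snrna), ("snoRNA", cfg.ref_snorna),
                ("known_miRNA", cfg.ref_known_mirna),
            )
            if path
        ]
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc
    classes, class_counts = annotation.classify_all(
        {t.sequence: t.total for t in tag_pair}, refsets
    )
    known_ref = next((r for r in refsets if r.name == "known_miRNA"), None)
    known_profile = (
        annotation.known_mirna_table(counts_a, counts_b, known_ref, (n1, n2))
        if known_ref is not None
        else pd.DataFrame()
    )
    class_counts.to_csv(out / "class_counts.tsv", sep="\t")
    known_profile.to_csv(out / "known_profile.tsv", sep="\t", index=False)
    _log(cfg, log, stage, f"class counts: {class_counts.to_dict()}")

    # ---- hairpin discovery ------------------------------------------------
    stage = "hairpin_discovery"
    try:
        genome = read_fasta(cfg.genome)
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc
    unannotated = [t for t in tag_pair if classes[t.sequence] == annotation.UNANNOTATED]
    candidates, rejections = hairpin.discover_novel(
        unannotated, genome,
        min_count=cfg.min_tag_count, max_mismatches=cfg.max_mismatches,
        mfe_ceiling=cfg.mfe_ceiling, flank=cfg.flank,
    )
    cand_table = hairpin.candidates_to_table(candidates)
    cand_table.to_csv(out / "novel_candidates.tsv", sep="\t", index=False)
    (out / "novel_candidates.gff3").write_text(hairpin.candidates_to_gff3(candidates))
    _log(cfg, log, stage,
         f"{len(unannotated)} unannotated tags -> {len(candidates)} candidates, "
         f"{len(rejections)} rejections")

    # ---- differential expression -----------------------------------------
    stage = "differential_expression"
    de_inputs = [
        de.DEInput(str(r.mirna_id), int(r.count_a), int(r.count_b), n1, n2)
        for r in known_profile.itertuples()
    ] + [de.DEInput(c.id, c.count_a, c.count_b, n1, n2) for c in candidates]
    try:
        de_table = de.run_de(
            de_inputs, fc_threshold=cfg.fc_threshold, alpha=cfg.alpha,
            alpha_strong=cfg.alpha_strong, min_tpm=cfg.min_tpm,
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    n_sig = int(de_table.label.isin([de.LABEL_WEAK, de.LABEL_STRONG]).sum()) if len(de_table) else 0
    _log(cfg, log, stage, f"{len(de_table)} features tested, {n_sig} significant")

    # ---- target prediction ------------------------------------------------
    stage = "target_prediction"
    target_hits = pd.DataFrame()
    kog_by_category = kog_by_class = None
    if cfg.transcripts:
        from . import targets as targets_mod

        try:
            transcripts = read_fasta(cfg.transcripts)
        except (OSError, ValueError) as exc:
            raise PipelineError(stage, str(exc)) from exc
        responsive = set(
            de_table[de_table.label.isin([de.LABEL_WEAK, de.LABEL_STRONG,
                                          de.LABEL_A_ONLY, de.LABEL_B_ONLY])].feature_id
        )
        seqs = {}
        for r in known_profile.itertuples():
            if r.mirna_id in responsive:
                seqs[str(r.mirna_id)] = str(r.sequence)
        for c in candidates:
            if c.id in responsive:
                seqs[c.id] = c.mature
        hits, unique_genes = targets_mod.scan_transcriptome(
            seqs, transcripts, max_score=cfg.max_target_score,
            seed_score_max=cfg.seed_score_max, mfe_ratio_min=cfg.mfe_ratio,
        )
        target_hits = pd.DataFrame(
            [
                dict(
                    mirna_id=h.alignment.mirna_id, gene_id=h.alignment.transcript_id,
                    site_start=h.alignment.site_start,
                    score=h.alignment.mismatch_score, mfe_ratio=h.mfe_ratio,
                )
                for h in hits
            ],
            columns=["mirna_id", "gene_id", "site_start", "score", "mfe_ratio"],
        )
        target_hits.to_csv(out / "target_hits.tsv", sep="\t", index=False)
        _log(cfg, log, stage,
             f"{len(seqs)} responsive miRNAs x {len(transcripts)} transcripts -> "
             f"{len(target_hits)} hits, {len(unique_genes)} unique genes")

        # ---- functional annotation ----------------------------------------
        stage = "function_annotation"
        if cfg.kog_map and unique_genes:
            try:
                assignments, unmapped = kog.assign_kog(unique_genes, cfg.kog_map)
            except ValueError as exc:
                raise PipelineError(stage, str(exc)) from exc
            if assignments:
                kog_by_category, kog_by_class = kog.summarize_categories(assignments)
                kog_by_category.to_csv(out / "kog_by_category.tsv", sep="\t", index=False)
                kog_by_class.to_csv(out / "kog_by_class.tsv", sep="\t", index=False)
            _log(cfg, log, stage,
                 f"{len(assignments)} KOG assignments, {len(unmapped)} genes unmapped")

    (out / "stage_log.txt").write_text("\n".join(log) + "\n")
    return RunReport(
        accounting=accounting,
        class_counts=class_counts,
        known_profile=known_profile,
        novel_candidates=cand_table,
        de_table=de_table,
        target_hits=target_hits,
        kog_by_category=kog_by_category,
        kog_by_class=kog_by_class,
        stage_log=log,
    )
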