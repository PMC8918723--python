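"""One-command orchestration: trim -> align -> dedup -> call -> report.

Each stage persists its artifact plus a ``.done`` marker; ``resume``
skips stages whose markers exist.  All stages process reads serially in
input order, so output is byte-identical for any ``threads`` setting
(the thread count is forwarded only to an external aligner).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from metharc import __version__
from metharc.align import AlignConfig, align_reads
from metharc.bamio import read_bam, write_bam
from metharc.genome import load_index, normalize_mode
from metharc.methcall import (CallConfig, call_cpg, conversion_rate, dedup,
                              m_bias, normalize_chem, overall_level,
                              per_chromosome_levels, write_bedgraph,
                              write_calls)
from metharc.readprep import RawRead, TrimConfig, trim_stream, write_fastq
from metharc.report import (QCBundle, read_tss_bed, render_report,
                            size_distribution, tss_profile)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    index_dir: str
    r1: list
    r2: Optional[list] = None
    mode: str = "three_letter"
    chemistry: str = "bisulfite"
    out_dir: str = "metharc_out"
    tss_bed: Optional[str] = None
    threads: int = 1
    seed: int = 1
    resume: bool = False
    aligner: str = "builtin"
    trim: TrimConfig = field(default_factory=TrimConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    call: CallConfig = field(default_factory=CallConfig)
    flank: int = 2000
    tss_bins: int = 100

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def _marker(out: Path, stage: str) -> Path:
    return out / f".{stage}.done"


def _stage_done(cfg: RunConfig, out: Path, stage: str) -> bool:
    return cfg.resume and _marker(out, stage).exists()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    mode = normalize_mode(cfg.mode)
    chem = normalize_chem(cfg.chemistry)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "runconfig.json", "w") as fh:
        json.dump(cfg.echo(), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    timings: dict[str, float] = {}
    pg, idx, ref = load_index(cfg.index_dir, expected_mode=mode)

    # -- trim --------------------------------------------------------------
    t0 = time.perf_counter()
    trimmed_r1 = out / "trimmed.r1.fq.gz"
    trimmed_r2 = out / "trimmed.r2.fq.gz"
    if not _stage_done(cfg, out, "trim"):
        kept, trim_stats = trim_stream(cfg.r1, cfg.r2, cfg.trim)
        write_fastq((RawRead(p.read_id, p.r1_seq, p.r1_qual) for p in kept),
                    trimmed_r1)
        if cfg.r2:
            write_fastq((RawRead(p.read_id, p.r2_seq, p.r2_qual) for p in kept),
                        trimmed_r2)
        with open(out / "trim_stats.json", "w") as fh:
            json.dump(trim_stats.to_dict(), fh, indent=2, sort_keys=True)
        _marker(out, "trim").touch()
    else:
        kept = None
        log.info("resume: trim stage skipped")
    timings["trim"] = time.perf_counter() - t0

    # -- align -------------------------------------------------------------
    t0 = time.perf_counter()
    bam_path = out / "alignments.bam"
    if not _stage_done(cfg, out, "align"):
        if kept is None:  # resumed past trim: re-read trimmed FASTQ
            from metharc.readprep import read_fastq, TrimmedReadPair
            r1s = list(read_fastq(trimmed_r1))
            r2s = list(read_fastq(trimmed_r2)) if cfg.r2 else None
            kept = [TrimmedReadPair(a.read_id, a.seq, a.qual,
                                    r2s[i].seq if r2s else None,
                                    r2s[i].qual if r2s else None,
                                    cfg.trim.clip_head_r1, cfg.trim.clip_tail_r1,
                                    cfg.trim.clip_head_r2, cfg.trim.clip_tail_r2)
                    for i, a in enumerate(r1s)]
        acfg = dataclasses.replace(cfg.align, seed=cfg.seed)
        if cfg.aligner != "builtin":
            from metharc.external import require_binary
            require_binary(cfg.aligner)  # fail fast before any work
        restored, align_stats = align_reads(kept, pg, ref, mode, acfg)
        write_bam(restored, ref, bam_path)
        with open(out / "align_stats.json", "w") as fh:
            json.dump(align_stats.to_dict(), fh, indent=2, sort_keys=True)
        _marker(out, "align").touch()
    else:
        log.info("resume: align stage skipped")
    timings["align"] = time.perf_counter() - t0

    # -- dedup + call ------------------------------------------------------
    t0 = time.perf_counter()
    if not _stage_done(cfg, out, "call"):
        alignments = read_bam(bam_path, ref)
        low_quality = [a for a in alignments if a.mapq < cfg.call.min_mapq]
        usable = [a for a in alignments if a.mapq >= cfg.call.min_mapq]
        lq_fragments = len({a.read_id for a in low_quality})
        deduped, dedup_stats = dedup(usable)
        calls = call_cpg(deduped, ref, idx, chem, cfg.call)
        conv = conversion_rate(deduped, ref, ref.spike_in_names, chem, cfg.call)
        mbias = m_bias(deduped, ref, idx, chem, cfg.call)
        write_calls(calls, out / "cpg_calls.tsv", merged=True)
        write_calls(calls, out / "cpg_calls.stranded.tsv", merged=False)
        write_bedgraph(calls, out / "cpg_calls.bedgraph")
        calls.to_csv(out / "cpg_calls.full.tsv", sep="\t", index=False)
        mbias.to_csv(out / "m_bias.full.tsv", sep="\t", index=False)
        meth_stats = {
            "dedup": dedup_stats.to_dict(),
            "low_quality_fragments": lq_fragments,
            "conversion_rate": conv.to_dict(),
            "overall_level": overall_level(calls, ref.spike_in_names),
            "per_chromosome": per_chromosome_levels(calls, ref.spike_in_names),
        }
        with open(out / "meth_stats.json", "w") as fh:
            json.dump(meth_stats, fh, indent=2, sort_keys=True)
        # keep deduplicated alignments for the report stage
        write_bam(deduped, ref, out / "dedup.bam")
        _marker(out, "call").touch()
    else:
        log.info("resume: call stage skipped")
    timings["call"] = time.perf_counter() - t0

    # -- report ------------------------------------------------------------
    t0 = time.perf_counter()
    if not _stage_done(cfg, out, "report"):
        bundle = build_bundle(cfg, out, ref)
        render_report(bundle, out)
        bundle.to_json(out / "qc_bundle.json")
        _marker(out, "report").touch()
    else:
        log.info("resume: report stage skipped")
    timings["report"] = time.perf_counter() - t0

    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return out


def build_bundle(cfg: RunConfig, out: Path, ref) -> QCBundle:
    """Assemble the QC bundle from the persisted stage artifacts."""
    import pandas as pd

    with open(out / "trim_stats.json") as fh:
        trim_stats = json.load(fh)
    with open(out / "align_stats.json") as fh:
        align_stats = json.load(fh)
    with open(out / "meth_stats.json") as fh:
        meth_stats = json.load(fh)
    deduped = read_bam(out / "dedup.bam", ref)
    target_hist, spike_hist, size_note = size_distribution(deduped)

    calls = pd.read_csv(out / "cpg_calls.full.tsv", sep="\t")
    tss_prof = None
    tss_note = None
    if cfg.tss_bed:
        tss = read_tss_bed(cfg.tss_bed)
        tss_prof = tss_profile(calls, tss, cfg.flank, cfg.tss_bins)
    else:
        tss_note = "no TSS annotation provided"

    mbias = pd.read_csv(out / "m_bias.full.tsv", sep="\t")
    bundle = QCBundle(
        # thread count deliberately omitted: outputs are contract-identical
        # for any --threads, so the report must be too
        metadata={"mode": cfg.mode, "chemistry": cfg.chemistry,
                  "version": __version__, "aligner": cfg.aligner,
                  "seed": cfg.seed},
        trim={k: trim_stats[k] for k in
              ("total_pairs", "kept_pairs", "dropped_short", "adapter_found")},
        alignment={
            "n_reads": align_stats["n_reads"],
            "n_mapped": align_stats["n_mapped"],
            "n_unmapped": align_stats["n_unmapped"],
            "low_quality": meth_stats["low_quality_fragments"],
            "duplicates": meth_stats["dedup"]["duplicates_removed"],
            "reported": meth_stats["dedup"]["reported"],
        },
        conversion=meth_stats["conversion_rate"],
        overall_level=meth_stats["overall_level"],
        per_chromosome=meth_stats["per_chromosome"],
        m_bias=mbias.values.tolist(),
        size_hist_target=target_hist,
        size_hist_spike=spike_hist,
        size_note=size_note,
        tss_profile=tss_prof,
        tss_note=tss_note,
        composition_before=trim_stats["composition_before"],
        composition_after=trim_stats["composition_after"],
    )
    return bundle
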