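"""Coordinate-sorted BAM output and input for restored alignments.

The header names ORIGINAL chromosomes only; pseudo-genome bookkeeping
travels in tags: ``XS:Z`` bisulfite strand (OT/OB), ``XO:Z`` pseudo-
chromosome of origin is recoverable from XS + chromosome, ``XH:i`` head
cycles clipped upstream (needed to place CpG observations on their
original sequencing cycle).  Sorting happens in-process with a total
order (tid, pos, name, flag) so identical inputs give byte-identical
files, and the @PG line carries no timestamp.
"""

from __future__ import annotations

from typing import Iterable

import pysam

from metharc import __version__ as _version
from metharc.align import RestoredAlignment, reference_span
from metharc.genome import CRICK_SUFFIX, ReferenceGenome


def _flag(aln: RestoredAlignment, mate_reverse: bool) -> int:
    flag = 0
    if aln.paired:
        flag |= 0x1 | 0x2  # only proper pairs are emitted
        flag |= 0x40 if aln.mate == 1 else 0x80
        if mate_reverse:
            flag |= 0x20
    if aln.reverse:
        flag |= 0x10
    return flag


def write_bam(alignments: Iterable[RestoredAlignment], ref: ReferenceGenome,
              path) -> None:
    names = list(ref.chromosomes)
    tid = {name: i for i, name in enumerate(names)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(ref.chromosomes[n])} for n in names],
        "PG": [{"ID": "metharc", "PN": "metharc", "VN": _version}],
    }
    ordered = sorted(alignments,
                     key=lambda a: (tid[a.chrom], a.pos, a.read_id, a.mate))
    mate_reverse = {(a.read_id, a.mate): a.reverse for a in ordered}
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for aln in ordered:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.reference_id = tid[aln.chrom]
            seg.reference_start = aln.pos
            seg.mapping_quality = aln.mapq
            seg.cigarstring = aln.cigar
            seg.query_sequence = aln.seq
            seg.query_qualities = pysam.qualitystring_to_array(aln.qual)
            other = mate_reverse.get((aln.read_id, 3 - aln.mate), False)
            seg.flag = _flag(aln, other)
            if aln.paired:
                seg.next_reference_id = tid[aln.chrom]
                seg.next_reference_start = aln.mate_pos
                seg.template_length = aln.tlen
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
                seg.template_length = 0
            pseudo = aln.chrom if aln.bs_strand == "OT" else aln.chrom + CRICK_SUFFIX
            seg.set_tags([("XS", aln.bs_strand, "Z"),
                          ("XO", pseudo, "Z"),
                          ("XH", aln.clip_head, "i")])
            out.write(seg)


def read_bam(path, ref: ReferenceGenome) -> list[RestoredAlignment]:
    """Load restored alignments back from BAM (coordinate order preserved)."""
    out: list[RestoredAlignment] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for seg in bam:
            if seg.is_unmapped:
                continue
            paired = seg.is_paired
            aln = RestoredAlignment(
                read_id=seg.query_name,
                mate=2 if seg.is_read2 else 1,
                chrom=seg.reference_name,
                pos=seg.reference_start,
                cigar=seg.cigarstring,
                mapq=seg.mapping_quality,
                bs_strand=seg.get_tag("XS"),
                seq=seg.query_sequence,
                qual=pysam.qualities_to_qualitystring(seg.query_qualities),
                reverse=seg.is_reverse,
                fragment_len=abs(seg.template_length) if paired else 0,
                is_spike_in=seg.reference_name in ref.spike_in_names,
                paired=paired,
                mate_pos=seg.next_reference_start if paired else -1,
                tlen=seg.template_length,
                clip_head=seg.get_tag("XH") if seg.has_tag("XH") else 0,
            )
            out.append(aln)
    return out
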