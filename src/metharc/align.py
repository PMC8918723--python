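"""Single-pass alignment against the pseudo-genome and coordinate restoration.

Reads are letter-converted with mate-specific rules (directional library:
R1 reads the chemistry-converted strand, R2 its complement), aligned once
against the combined Watson+Crick pseudo-genome, and the resulting hits
are lifted back to original Watson coordinates with the bisulfite strand
of origin (OT = fragment from Watson, OB = from Crick) and the original,
unconverted bases.

The builtin aligner is a deterministic exact-seed / ungapped-extension
test aligner: seeds of length k are taken from the read start at a fixed
stride, candidate loci are scored by mismatch count, and only a unique
best-scoring locus is reported (ties are ambiguous).  Because the
pseudo-genome carries both strands, a legitimate converted read always
matches some pseudo-chromosome in forward orientation; for single-end
data reverse-orientation hits are therefore chemically inconsistent and
rejected, which is exactly how the single-pass design assigns strand.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from metharc.genome import (CRICK, FOUR_LETTER, THREE_LETTER, WATSON,
                            CpGIndex, PseudoGenome, ReferenceGenome,
                            normalize_mode)
from metharc.readprep import TrimmedReadPair
from metharc.utils import revcomp

OT = "OT"
OB = "OB"

MAPQ_UNIQUE = 42
MAPQ_AMBIGUOUS = 0

# ---------------------------------------------------------------------------
# CIGAR helpers

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_OPS = set("MDN=X")
_QUERY_OPS = set("MIS=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"bad CIGAR: {cigar!r}")
    return ops


def reference_span(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in _REF_OPS)


def query_span(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in _QUERY_OPS)


def reverse_cigar(cigar: str) -> str:
    return "".join(f"{n}{op}" for n, op in reversed(parse_cigar(cigar)))


# ---------------------------------------------------------------------------
# read-side conversion

C2T = "C2T"
G2A = "G2A"
C2T_CPG = "C2T_cpg_only"
G2A_CPG = "G2A_cpg_only"


@dataclass
class ConvertedRead:
    read_id: str
    mate: int
    converted_seq: str
    original_seq: str
    qual: str
    rule: str


def convert_read(seq: str, qual: str, read_id: str, mate: int, mode) -> ConvertedRead:
    """Mate-specific letter conversion of a trimmed read.

    three_letter: mate 1 C->T, mate 2 G->A (everywhere).
    four_letter: mate 1 C->T only before G; mate 2 G->A only after C.
    Terminal bases with unknowable context are preserved.
    """
    mode = normalize_mode(mode)
    if mate == 1:
        if mode == THREE_LETTER:
            conv, rule = seq.replace("C", "T"), C2T
        else:
            conv, rule = seq.replace("CG", "TG"), C2T_CPG
    elif mate == 2:
        if mode == THREE_LETTER:
            conv, rule = seq.replace("G", "A"), G2A
        else:
            conv, rule = seq.replace("CG", "CA"), G2A_CPG
    else:
        raise ValueError(f"mate must be 1 or 2, got {mate}")
    return ConvertedRead(read_id, mate, conv, seq, qual, rule)


# ---------------------------------------------------------------------------
# alignment records

@dataclass
class PseudoAlignment:
    read_id: str
    mate: int
    pseudo_chrom: str
    pseudo_pos: int  # 0-based leftmost on the pseudo-chromosome
    cigar: str
    mapq: int = MAPQ_UNIQUE
    reverse_flag: bool = False  # read aligned as its reverse complement
    is_multi: bool = False
    n_mismatch: int = 0


@dataclass
class RestoredAlignment:
    """Alignment lifted to original Watson coordinates."""

    read_id: str
    mate: int
    chrom: str
    pos: int  # 0-based leftmost on Watson
    cigar: str
    mapq: int
    bs_strand: str  # OT | OB
    seq: str  # original bases, Watson orientation
    qual: str
    reverse: bool = False  # SAM reverse-strand flag
    fragment_len: int = 0  # 0 for single-end
    is_spike_in: bool = False
    paired: bool = False
    mate_pos: int = -1
    tlen: int = 0
    clip_head: int = 0  # head cycles removed upstream (for M-bias cycles)

    @property
    def end(self) -> int:
        return self.pos + reference_span(self.cigar)


@dataclass
class AlignStats:
    n_reads: int = 0
    n_mapped: int = 0
    n_multi: int = 0
    n_unmapped: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class EvalMetrics:
    mapping_efficiency: float
    mapping_accuracy: float
    n_reads: int
    n_mapped: int
    n_correct: int
    accuracy_defined: bool = True


# ---------------------------------------------------------------------------
# builtin aligner

@dataclass
class AlignConfig:
    k: int = 16
    seed_stride: int = 4
    mismatch_rate: float = 0.04  # max mismatches = ceil(rate * read length)
    max_insert: int = 1000
    unique_only: bool = True
    random_tie: bool = False
    seed: int = 0
    max_seed_hits: int = 256


class BuiltinAligner:
    """Exact-seed, ungapped-extension aligner over the pseudo-genome."""

    def __init__(self, pg: PseudoGenome, cfg: Optional[AlignConfig] = None):
        self.cfg = cfg or AlignConfig()
        self.pg = pg
        self.names: list[str] = list(pg.pseudo_chromosomes)
        self.seqs: list[str] = [pg.pseudo_chromosomes[n] for n in self.names]
        k = self.cfg.k
        index: dict[str, list[tuple[int, int]]] = {}
        for cid, seq in enumerate(self.seqs):
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos:pos + k], []).append((cid, pos))
        self.index = index

    def max_mismatch(self, length: int) -> int:
        return int(-(-self.cfg.mismatch_rate * length // 1))  # ceil

    def candidates(self, seq: str) -> list[tuple[int, int, int]]:
        """All loci with mismatches <= budget, as (mismatches, cid, pos)."""
        cfg = self.cfg
        k = cfg.k
        n = len(seq)
        if n < k:
            return []
        cap = self.max_mismatch(n)
        starts: set[tuple[int, int]] = set()
        for off in range(0, n - k + 1, cfg.seed_stride):
            kmer = seq[off:off + k]
            if "N" in kmer:
                continue
            hits = self.index.get(kmer)
            if hits is None or len(hits) > cfg.max_seed_hits:
                continue
            for cid, pos in hits:
                if pos >= off:
                    starts.add((cid, pos - off))
        out = []
        for cid, start in starts:
            ref = self.seqs[cid]
            if start + n > len(ref):
                continue
            mm = _count_mismatches(ref, start, seq, cap)
            if mm <= cap:
                out.append((mm, cid, start))
        return out

    # -- single-end -------------------------------------------------------
    def align_single(self, conv: ConvertedRead,
                     rng: Optional[random.Random] = None) -> Optional[PseudoAlignment]:
        """Forward-orientation-only alignment of a converted single-end read.

        Reverse-orientation matches are never searched: with both strands in
        the pseudo-genome they cannot arise from a real library molecule.
        """
        cands = self.candidates(conv.converted_seq)
        if not cands:
            return None
        best = min(c[0] for c in cands)
        top = [c for c in cands if c[0] == best]
        cigar = f"{len(conv.converted_seq)}M"
        if len(top) > 1:
            if self.cfg.random_tie and rng is not None:
                mm, cid, pos = top[rng.randrange(len(top))]
                return PseudoAlignment(conv.read_id, 1, self.names[cid], pos,
                                       cigar, MAPQ_AMBIGUOUS, False, True, mm)
            return PseudoAlignment(conv.read_id, 1, "*", -1, cigar,
                                   MAPQ_AMBIGUOUS, False, True, best)
        mm, cid, pos = top[0]
        return PseudoAlignment(conv.read_id, 1, self.names[cid], pos, cigar,
                               MAPQ_UNIQUE, False, False, mm)

    # -- paired-end -------------------------------------------------------
    def align_pair(self, conv1: ConvertedRead, conv2: ConvertedRead,
                   rng: Optional[random.Random] = None
                   ) -> Optional[tuple[PseudoAlignment, PseudoAlignment]]:
        """FR-orientation paired alignment on a single pseudo-chromosome.

        R1 is searched forward; R2 is searched as the reverse complement of
        its converted sequence (directional chemistry fixes both orientations).
        """
        q1 = conv1.converted_seq
        q2 = revcomp(conv2.converted_seq)
        c1 = self.candidates(q1)
        if not c1:
            return None
        c2 = self.candidates(q2)
        if not c2:
            return None
        len1, len2 = len(q1), len(q2)
        pairs = []
        by_chrom: dict[int, list[tuple[int, int]]] = {}
        for mm, cid, pos in c2:
            by_chrom.setdefault(cid, []).append((mm, pos))
        for mm1, cid, p1 in c1:
            for mm2, p2 in by_chrom.get(cid, ()):
                flen = p2 + len2 - p1
                if p2 >= p1 and 0 < flen <= self.cfg.max_insert:
                    pairs.append((mm1 + mm2, cid, p1, p2, mm1, mm2))
        if not pairs:
            return None
        best = min(p[0] for p in pairs)
        top = [p for p in pairs if p[0] == best]
        multi = len(top) > 1
        if multi and not (self.cfg.random_tie and rng is not None):
            a1 = PseudoAlignment(conv1.read_id, 1, "*", -1, f"{len1}M",
                                 MAPQ_AMBIGUOUS, False, True, 0)
            a2 = PseudoAlignment(conv2.read_id, 2, "*", -1, f"{len2}M",
                                 MAPQ_AMBIGUOUS, True, True, 0)
            return a1, a2
        choice = top[rng.randrange(len(top))] if multi else top[0]
        _, cid, p1, p2, mm1, mm2 = choice
        mapq = MAPQ_AMBIGUOUS if multi else MAPQ_UNIQUE
        name = self.names[cid]
        a1 = PseudoAlignment(conv1.read_id, 1, name, p1, f"{len1}M",
                             mapq, False, multi, mm1)
        a2 = PseudoAlignment(conv2.read_id, 2, name, p2, f"{len2}M",
                             mapq, True, multi, mm2)
        return a1, a2


def _count_mismatches(ref: str, start: int, seq: str, cap: int) -> int:
    if ref[start:start + len(seq)] == seq:
        return 0
    mm = 0
    for i, c in enumerate(seq):
        if ref[start + i] != c:
            mm += 1
            if mm > cap:
                return mm
    return mm


# ---------------------------------------------------------------------------
# restoration

def restore_alignment(pa: PseudoAlignment, pg: PseudoGenome, ref: ReferenceGenome,
                      original_seq: str, qual: str, clip_head: int = 0,
                      paired: bool = False) -> RestoredAlignment:
    """Lift a pseudo-genome alignment back to Watson coordinates.

    Watson-origin pseudo-chromosomes keep position and CIGAR; Crick-origin
    ones mirror the position (pos = L - pseudo_pos - span), reverse the
    CIGAR element-wise and flip the orientation.  The reported sequence is
    always the ORIGINAL (unconverted) bases in Watson orientation.
    """
    if pa.pseudo_chrom not in pg.origin:
        raise KeyError(f"unknown pseudo-chromosome: {pa.pseudo_chrom}")
    o = pg.origin[pa.pseudo_chrom]
    span = reference_span(pa.cigar)
    if o.strand == WATSON:
        pos = pa.pseudo_pos
        cigar = pa.cigar
        reverse = pa.reverse_flag
        bs_strand = OT
    else:
        pos = o.length - pa.pseudo_pos - span
        if pos < 0:
            raise ValueError(
                f"restored position negative for {pa.read_id}: corrupt index?")
        cigar = reverse_cigar(pa.cigar)
        reverse = not pa.reverse_flag
        bs_strand = OB
    if reverse:
        seq_watson = revcomp(original_seq)
        qual_watson = qual[::-1]
    else:
        seq_watson = original_seq
        qual_watson = qual
    return RestoredAlignment(
        read_id=pa.read_id, mate=pa.mate, chrom=o.chrom, pos=pos,
        cigar=cigar, mapq=pa.mapq, bs_strand=bs_strand,
        seq=seq_watson, qual=qual_watson, reverse=reverse,
        is_spike_in=o.chrom in ref.spike_in_names, paired=paired,
        clip_head=clip_head)


# ---------------------------------------------------------------------------
# whole-dataset driver

def align_reads(pairs: Sequence[TrimmedReadPair], pg: PseudoGenome,
                ref: ReferenceGenome, mode, cfg: Optional[AlignConfig] = None,
                aligner: Optional[BuiltinAligner] = None
                ) -> tuple[list[RestoredAlignment], AlignStats]:
    """Convert, align and restore a stream of trimmed read pairs."""
    mode = normalize_mode(mode)
    if pg.mode != mode:
        raise ValueError(f"index mode {pg.mode} != requested mode {mode}")
    cfg = cfg or AlignConfig()
    aligner = aligner or BuiltinAligner(pg, cfg)
    stats = AlignStats()
    restored: list[RestoredAlignment] = []
    for serial, pair in enumerate(pairs):
        rng = random.Random(((cfg.seed & 0x7FFFFFFF) << 20) ^ serial) \
            if cfg.random_tie else None
        if pair.single_end:
            stats.n_reads += 1
            conv = convert_read(pair.r1_seq, pair.r1_qual, pair.read_id, 1, mode)
            pa = aligner.align_single(conv, rng)
            if pa is None or (pa.is_multi and cfg.unique_only) or pa.pseudo_chrom == "*":
                if pa is not None and pa.is_multi:
                    stats.n_multi += 1
                stats.n_unmapped += 1
                continue
            stats.n_mapped += 1
            restored.append(restore_alignment(pa, pg, ref, conv.original_seq,
                                              conv.qual, pair.clip_head_r1))
        else:
            stats.n_reads += 2
            conv1 = convert_read(pair.r1_seq, pair.r1_qual, pair.read_id, 1, mode)
            conv2 = convert_read(pair.r2_seq, pair.r2_qual, pair.read_id, 2, mode)
            hit = aligner.align_pair(conv1, conv2, rng)
            if hit is None or (hit[0].is_multi and cfg.unique_only) \
                    or hit[0].pseudo_chrom == "*":
                if hit is not None and hit[0].is_multi:
                    stats.n_multi += 2
                stats.n_unmapped += 2
                continue
            pa1, pa2 = hit
            r1 = restore_alignment(pa1, pg, ref, conv1.original_seq, conv1.qual,
                                   pair.clip_head_r1, paired=True)
            r2 = restore_alignment(pa2, pg, ref, conv2.original_seq, conv2.qual,
                                   pair.clip_head_r2, paired=True)
            frag_start = min(r1.pos, r2.pos)
            frag_end = max(r1.end, r2.end)
            flen = frag_end - frag_start
            for a, b in ((r1, r2), (r2, r1)):
                a.fragment_len = flen
                a.mate_pos = b.pos
                a.tlen = flen if a.pos <= b.pos else -flen
            if r1.pos == r2.pos:  # fully-overlapping pair: sign by mate order
                r1.tlen, r2.tlen = flen, -flen
            stats.n_mapped += 2
            restored.extend((r1, r2))
    return restored, stats


# ---------------------------------------------------------------------------
# truth evaluation (simulator interchange contract: id = r<i>:chrom:start:end:strand)

def parse_truth_id(read_id: str) -> tuple[str, int, int, str]:
    parts = read_id.rsplit(":", 4)
    if len(parts) != 5 or parts[4] not in ("W", "C"):
        raise ValueError(f"read ID carries no truth tag: {read_id!r}")
    return parts[1], int(parts[2]), int(parts[3]), parts[4]


def evaluate_against_truth(alignments: Iterable[RestoredAlignment],
                           n_total_reads: int, tolerance: int = 0) -> EvalMetrics:
    """Mapping efficiency (mapped / raw reads) and accuracy (correct / mapped).

    An alignment is correct when its restored chromosome, bisulfite strand
    and leftmost Watson position match the simulator truth within
    ``tolerance`` bp.  The expected position depends on mate and strand:
    an OT fragment has R1 at the fragment start and R2 ending at the
    fragment end; an OB fragment mirrors this.
    """
    n_mapped = 0
    n_correct = 0
    n_untagged = 0
    for aln in alignments:
        try:
            chrom, start, end, strand = parse_truth_id(aln.read_id)
        except ValueError:
            n_untagged += 1
            continue
        n_mapped += 1
        exp_strand = OT if strand == "W" else OB
        span = reference_span(aln.cigar)
        if (strand == "W") == (aln.mate == 1):
            exp_pos = start
        else:
            exp_pos = end - span
        if (aln.chrom == chrom and aln.bs_strand == exp_strand
                and abs(aln.pos - exp_pos) <= tolerance):
            n_correct += 1
    if n_untagged:
        import logging
        logging.getLogger(__name__).warning(
            "%d alignments lacked truth tags and were excluded", n_untagged)
    efficiency = n_mapped / n_total_reads if n_total_reads else 0.0
    if n_mapped:
        return EvalMetrics(efficiency, n_correct / n_mapped,
                           n_total_reads, n_mapped, n_correct)
    return EvalMetrics(efficiency, 0.0, n_total_reads, 0, 0,
                       accuracy_defined=False)
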