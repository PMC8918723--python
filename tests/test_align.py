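"""Read conversion, builtin alignment, restoration and truth evaluation."""

import pytest

from metharc.align import (OB, OT, AlignConfig, BuiltinAligner,
                           EvalMetrics, PseudoAlignment, align_reads,
                           convert_read, evaluate_against_truth,
                           parse_cigar, reference_span, restore_alignment,
                           reverse_cigar)
from metharc.genome import (ReferenceGenome, build_pseudo_genome)
from metharc.readprep import TrimmedReadPair
from metharc.utils import revcomp

Q = "I"


@pytest.mark.parametrize("seq,mate,mode,expected", [
    ("ACCGT", 1, "three_letter", "ATTGT"),
    ("AGGCT", 2, "three_letter", "AAACT"),
    ("ACGGT", 2, "four_letter", "ACAGT"),  # only G after C converts
    ("ACCGT", 1, "four_letter", "ACTGT"),
    ("GACGT", 2, "four_letter", "GACAT"),  # leading G preserved
    ("ACGC", 1, "four_letter", "ATGC"),    # terminal C preserved
])
def test_convert_read_rules(seq, mate, mode, expected):
    conv = convert_read(seq, Q * len(seq), "r", mate, mode)
    assert conv.converted_seq == expected
    assert conv.original_seq == seq
    assert len(conv.converted_seq) == len(seq)


# -- CIGAR helpers ----------------------------------------------------------

def test_cigar_reversal_and_spans():
    assert reverse_cigar("3M1D4M") == "4M1D3M"
    assert reference_span("3M1D4M") == 8
    assert reference_span(reverse_cigar("3M1D4M")) == 8
    assert reference_span("5M2I5M") == 10
    with pytest.raises(ValueError):
        parse_cigar("10X3")


# -- builtin aligner --------------------------------------------------------

def _random_ref(length=4000, seed=3):
    import numpy as np
    rng = np.random.default_rng(seed)
    return ReferenceGenome({"chr1": "".join(
        np.array(list("ACGT"))[rng.integers(0, 4, length)])})


def test_planted_exact_read_single_end():
    ref = _random_ref()
    pg = build_pseudo_genome(ref, "3")
    aligner = BuiltinAligner(pg)
    seq = pg.pseudo_chromosomes["chr1"][100:150]  # verbatim pseudo sequence
    conv = convert_read(seq, Q * 50, "r", 1, "3")
    pa = aligner.align_single(conv)
    assert (pa.pseudo_chrom, pa.pseudo_pos, pa.cigar, pa.mapq) == \
        ("chr1", 100, "50M", 42)
    assert not pa.reverse_flag and not pa.is_multi


def test_duplicated_locus_reports_ambiguous():
    base = _random_ref(2000, seed=5).chromosomes["chr1"]
    dup = base[:500] + base[100:200] + base[500:]  # segment planted twice
    ref = ReferenceGenome({"chr1": dup})
    pg = build_pseudo_genome(ref, "3")
    aligner = BuiltinAligner(pg)
    seq = dup[110:170]
    conv = convert_read(seq, Q * len(seq), "r", 1, "3")
    pa = aligner.align_single(conv)
    assert pa.is_multi and pa.mapq == 0


def test_single_end_never_reverse():
    """Forward-only search: a read matching only as revcomp stays unmapped."""
    ref = _random_ref(3000, seed=9)
    pg = build_pseudo_genome(ref, "3")
    aligner = BuiltinAligner(pg)
    # revcomp of a CONVERTED watson segment is not a legitimate library read
    bad = revcomp(pg.pseudo_chromosomes["chr1"][500:560])
    pa = aligner.align_single(convert_read(bad, Q * 60, "r", 1, "3"))
    assert pa is None or pa.reverse_flag is False


# -- restoration ------------------------------------------------------------

def make_pg(seq, mode="3"):
    ref = ReferenceGenome({"chrT": seq})
    return ref, build_pseudo_genome(ref, mode)


def test_restore_watson_is_identity():
    ref, pg = make_pg("ACGTACGTACGT")
    pa = PseudoAlignment("r", 1, "chrT", 7, "5M")
    aln = restore_alignment(pa, pg, ref, "ACGTA", Q * 5)
    assert (aln.chrom, aln.pos, aln.bs_strand, aln.cigar) == ("chrT", 7, OT, "5M")
    assert aln.seq == "ACGTA" and not aln.reverse


def test_restore_crick_mirrors_position():
    ref, pg = make_pg("ACGTACGTAC")  # L = 10
    pa = PseudoAlignment("r", 1, "chrT#rev", 2, "4M")
    aln = restore_alignment(pa, pg, ref, "TTTT", Q * 4)
    assert (aln.chrom, aln.pos, aln.bs_strand) == ("chrT", 4, OB)
    assert aln.reverse  # crick-origin R1 is reverse on Watson
    assert aln.seq == revcomp("TTTT")


def test_restore_crick_reverses_indel_cigar():
    ref, pg = make_pg("A" * 20)
    pa = PseudoAlignment("r", 1, "chrT#rev", 3, "3M1D4M")
    aln = restore_alignment(pa, pg, ref, "ACGTAAA", Q * 7)
    assert aln.cigar == "4M1D3M"
    assert reference_span(aln.cigar) == 8
    assert aln.pos == 20 - 3 - 8


def test_restore_negative_position_is_fatal():
    ref, pg = make_pg("ACGTA")
    pa = PseudoAlignment("r", 1, "chrT#rev", 3, "4M")
    with pytest.raises(ValueError, match="negative"):
        restore_alignment(pa, pg, ref, "ACGT", Q * 4)


def test_restore_indel_consistent_with_watson_walk():
    """Crick restoration of a deletion read matches a base-by-base walk
    of the restored CIGAR over the original Watson sequence."""
    watson = "AATTCCGGATCGATCGGCTA"
    ref, pg = make_pg(watson)
    L = len(watson)
    # construct a crick-space read: crick bases 5..8 and 10..13 (1bp deletion)
    crick = revcomp(watson)
    read_crick = crick[5:8] + crick[9:13]
    pa = PseudoAlignment("r", 1, "chrT#rev", 5, "3M1D4M")
    aln = restore_alignment(pa, pg, ref, read_crick, Q * len(read_crick))
    # walk the restored cigar over Watson comparing to the restored read
    rp, qp = aln.pos, 0
    for n, op in parse_cigar(aln.cigar):
        if op == "M":
            assert watson[rp:rp + n] == aln.seq[qp:qp + n]
            rp += n
            qp += n
        elif op == "D":
            rp += n


# -- paired-end driver ------------------------------------------------------

def test_pe_driver_round_trip_error_free(aligned_bisulfite):
    cfg, ref, truth, idx, restored, stats = aligned_bisulfite
    metrics = evaluate_against_truth(restored, stats.n_reads)
    assert metrics.mapping_efficiency >= 0.99
    assert metrics.mapping_accuracy >= 0.999  # sequencing errors only
    # all records carry mate pairing and consistent fragment bookkeeping
    for aln in restored[:50]:
        assert aln.fragment_len > 0 and aln.paired
        assert aln.chrom in ref.chromosomes


def test_pe_mates_share_strand_and_chrom(aligned_bisulfite):
    _, _, _, _, restored, _ = aligned_bisulfite
    by_id = {}
    for aln in restored:
        by_id.setdefault(aln.read_id, []).append(aln)
    for group in by_id.values():
        assert len(group) == 2
        assert group[0].chrom == group[1].chrom
        assert group[0].bs_strand == group[1].bs_strand
        assert group[0].fragment_len == group[1].fragment_len


def test_mode_mismatch_is_fatal():
    ref = _random_ref(2000)
    pg = build_pseudo_genome(ref, "4")
    with pytest.raises(ValueError, match="mode"):
        align_reads([], pg, ref, "3")


# -- truth evaluation -------------------------------------------------------

def _fake_aln(read_id, chrom, pos, strand, mate=1, span=10):
    from metharc.align import RestoredAlignment
    return RestoredAlignment(read_id, mate, chrom, pos, f"{span}M", 42,
                             strand, "A" * span, Q * span)


def test_evaluate_metrics_arithmetic():
    alns = [_fake_aln(f"r{i}:chr1:100:200:W", "chr1", 100, OT) for i in range(9)]
    m = evaluate_against_truth(alns, n_total_reads=10)
    assert m.mapping_efficiency == pytest.approx(0.9)
    assert m.mapping_accuracy == 1.0
    assert (m.n_reads, m.n_mapped, m.n_correct) == (10, 9, 9)


def test_evaluate_zero_mapped_flagged():
    m = evaluate_against_truth([], n_total_reads=5)
    assert m.mapping_efficiency == 0.0
    assert m.mapping_accuracy == 0.0
    assert not m.accuracy_defined


def test_evaluate_mate_and_strand_positioning():
    # OB fragment: mate1 maps at end - span, mate2 at start
    ok1 = _fake_aln("r0:chr1:50:150:C", "chr1", 140, OB, mate=1)
    ok2 = _fake_aln("r0:chr1:50:150:C", "chr1", 50, OB, mate=2)
    bad = _fake_aln("r1:chr1:50:150:C", "chr1", 50, OB, mate=1)
    m = evaluate_against_truth([ok1, ok2, bad], n_total_reads=4)
    assert m.n_correct == 2


# -- external aligner adapter ----------------------------------------------

def test_external_missing_binary_is_actionable(monkeypatch):
    import shutil
    from metharc.external import ExternalAlignerError, require_binary
    monkeypatch.setattr(shutil, "which", lambda name: None)
    with pytest.raises(ExternalAlignerError, match="builtin"):
        require_binary("bowtie2")


def test_external_sam_flag_decoding():
    from metharc.external import parse_sam_line
    line = "r1\t16\tchr1#rev\t101\t42\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + Q * 50
    pa = parse_sam_line(line)
    assert pa.reverse_flag is True
    assert pa.pseudo_pos == 100 and pa.pseudo_chrom == "chr1#rev"
    assert parse_sam_line("r2\t4\t*\t0\t0\t*\t*\t0\t0\tA\tI") is None


@pytest.mark.skipif(
    __import__("shutil").which("bowtie2") is None
    or __import__("shutil").which("bowtie2-build") is None,
    reason="bowtie2 not on PATH")
def test_external_concordance_with_builtin(tmp_path, sim_bisulfite):
    """Same dataset through builtin vs bowtie2: >=99% identical restored loci."""
    import subprocess

    from metharc.external import external_align
    from metharc.readprep import RawRead, write_fastq

    cfg, ref, truth, r1, r2 = sim_bisulfite
    pg = build_pseudo_genome(ref, "3")
    fa = tmp_path / "pseudo.fa"
    with open(fa, "w") as fh:
        for name, seq in pg.pseudo_chromosomes.items():
            fh.write(f">{name}\n{seq}\n")
    subprocess.run(["bowtie2-build", "-q", str(fa), str(tmp_path / "idx")],
                   check=True, capture_output=True)
    conv1, conv2 = [], []
    for a, b in zip(r1, r2):
        conv1.append(RawRead(a.read_id,
                             convert_read(a.seq, a.qual, a.read_id, 1, "3").converted_seq,
                             a.qual))
        conv2.append(RawRead(b.read_id,
                             convert_read(b.seq, b.qual, b.read_id, 2, "3").converted_seq,
                             b.qual))
    write_fastq(conv1, tmp_path / "c1.fq")
    write_fastq(conv2, tmp_path / "c2.fq")
    ext = {}
    for pa in external_align(tmp_path / "c1.fq", tmp_path / "idx", "bowtie2",
                             tmp_path / "c2.fq"):
        if pa.mapq >= 20:
            aln = restore_alignment(pa, pg, ref, "A" * 10, Q * 10)
            ext[(pa.read_id, pa.mate)] = (aln.chrom, aln.pos, aln.bs_strand)
    from metharc.readprep import TrimConfig, trim_pair
    kept = [p for p in (trim_pair(a, b, TrimConfig()) for a, b in zip(r1, r2)) if p]
    restored, _ = align_reads(kept, pg, ref, "3")
    both = concordant = 0
    for aln in restored:
        key = (aln.read_id, aln.mate)
        if key in ext:
            both += 1
            concordant += ext[key] == (aln.chrom, aln.pos, aln.bs_strand)
    assert both > 0
    assert concordant / both >= 0.99
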