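"""Duplicate removal, CpG calling semantics, conversion rate and M-bias."""

import numpy as np
import pytest

from metharc.align import OB, OT, RestoredAlignment
from metharc.genome import ReferenceGenome, build_cpg_index
from metharc.methcall import (CallConfig, call_cpg, conversion_rate, dedup,
                              m_bias, overall_level, per_chromosome_levels)

Q = "I"  # Q40


def aln(read_id, chrom, pos, seq, *, mate=1, strand=OT, qual=None, paired=True,
        mate_pos=None, frag=None, reverse=False, mapq=42, clip_head=0):
    n = len(seq)
    return RestoredAlignment(
        read_id=read_id, mate=mate, chrom=chrom, pos=pos, cigar=f"{n}M",
        mapq=mapq, bs_strand=strand, seq=seq, qual=qual or Q * n,
        reverse=reverse, fragment_len=frag or n, paired=paired,
        mate_pos=mate_pos if mate_pos is not None else pos, clip_head=clip_head)


@pytest.fixture
def ref10():
    # CpG at position 2 (C) / 3 (G)
    return ReferenceGenome({"chrT": "AACGTTACGT"})


@pytest.fixture
def idx10(ref10):
    return build_cpg_index(ref10)


# -- dedup ------------------------------------------------------------------

def _pe_fragment(rid, chrom, start, end, strand, qual_char=Q):
    n = 10
    a = aln(rid, chrom, start, "A" * n, mate=1, strand=strand,
            qual=qual_char * n, frag=end - start, mate_pos=end - n)
    b = aln(rid, chrom, end - n, "A" * n, mate=2, strand=strand,
            qual=qual_char * n, frag=end - start, mate_pos=start)
    return [a, b]


def test_dedup_counts_shared_keys():
    frags = (_pe_fragment("a", "chrT", 100, 250, OT)
             + _pe_fragment("b", "chrT", 100, 250, OT)
             + _pe_fragment("c", "chrT", 300, 450, OT))
    frags.sort(key=lambda x: x.pos)
    kept, stats = dedup(frags)
    assert stats.input_fragments == 3
    assert stats.duplicates_removed == 1
    assert stats.reported == 2


def test_dedup_opposite_strands_both_kept():
    frags = (_pe_fragment("a", "chrT", 100, 250, OT)
             + _pe_fragment("b", "chrT", 100, 250, OB))
    frags.sort(key=lambda x: x.pos)
    _, stats = dedup(frags)
    assert stats.duplicates_removed == 0 and stats.reported == 2


def test_dedup_keeps_highest_quality_copy():
    lo = _pe_fragment("low", "chrT", 100, 250, OT, qual_char="#")
    hi = _pe_fragment("high", "chrT", 100, 250, OT, qual_char=Q)
    frags = sorted(lo + hi, key=lambda x: x.pos)
    kept, _ = dedup(frags)
    assert {a.read_id for a in kept} == {"high"}


def test_dedup_known_multiplicities_and_idempotence():
    rng = np.random.default_rng(4)
    frags = []
    expected_dups = 0
    for i in range(100):
        k = int(rng.integers(1, 6))
        expected_dups += k - 1
        start = 20 * i
        for copy in range(k):
            frags.extend(_pe_fragment(f"f{i}c{copy}", "chrT", start,
                                      start + 150, OT))
    frags.sort(key=lambda x: x.pos)
    kept, stats = dedup(frags)
    assert stats.duplicates_removed == expected_dups
    kept2, stats2 = dedup(kept)
    assert stats2.duplicates_removed == 0
    assert [a.read_id for a in kept2] == [a.read_id for a in kept]


def test_dedup_unsorted_input_is_fatal():
    frags = _pe_fragment("a", "chrT", 300, 450, OT) \
        + _pe_fragment("b", "chrT", 100, 250, OT)
    with pytest.raises(ValueError, match="sorted"):
        dedup(frags)


def test_dedup_single_end_keyed_by_position():
    a = aln("a", "chrT", 100, "A" * 10, paired=False, frag=0)
    b = aln("b", "chrT", 100, "A" * 10, paired=False, frag=0)
    c = aln("c", "chrT", 101, "A" * 10, paired=False, frag=0)
    _, stats = dedup([a, b, c])
    assert stats.duplicates_removed == 1 and stats.reported == 2


# -- call_cpg ---------------------------------------------------------------

def test_bisulfite_pileup_counts(ref10, idx10):
    # three OT single-end reads covering the CpG C at position 2: C, C, T
    reads = [aln(f"r{i}", "chrT", 0, s, paired=False)
             for i, s in enumerate(["AACGTTACGT", "AACGTTACGT", "AATGTTACGT"])]
    calls = call_cpg(reads, ref10, idx10, "bisulfite")
    row = calls.iloc[0]
    assert (row.meth, row.unmeth) == (2, 1)
    assert row.beta == pytest.approx(2 / 3)


def test_taps_pileup_inverted(ref10, idx10):
    reads = [aln(f"r{i}", "chrT", 0, s, paired=False)
             for i, s in enumerate(["AACGTTACGT", "AACGTTACGT", "AATGTTACGT"])]
    calls = call_cpg(reads, ref10, idx10, "taps")
    row = calls.iloc[0]
    assert (row.meth, row.unmeth) == (1, 2)
    assert row.beta == pytest.approx(1 / 3)


def test_strand_resolved_bookkeeping(ref10, idx10):
    ot = aln("a", "chrT", 0, "AACGTTACGT", paired=False, strand=OT)  # C at 2
    ob = aln("b", "chrT", 0, "AACATTACGT", paired=False, strand=OB)  # A at 3
    calls = call_cpg([ot, ob], ref10, idx10, "bisulfite")
    row = calls.iloc[0]
    assert (row.meth, row.unmeth) == (1, 1)
    assert (row.meth_watson, row.unmeth_watson) == (1, 0)
    assert (row.meth_crick, row.unmeth_crick) == (0, 1)


def test_chemistry_duality_on_identical_input(aligned_bisulfite):
    cfg, ref, truth, idx, restored, stats = aligned_bisulfite
    deduped, _ = dedup(sorted(restored, key=lambda a: (a.chrom, a.pos)))
    bs = call_cpg(deduped, ref, idx, "bisulfite")
    tp = call_cpg(deduped, ref, idx, "taps")
    assert len(bs) == len(tp)
    assert (bs["meth"] == tp["unmeth"]).all()
    assert (bs["unmeth"] == tp["meth"]).all()
    assert (bs["meth_watson"] == tp["unmeth_watson"]).all()


def test_pe_overlap_counted_once(ref10, idx10):
    # both mates of one fragment cover the CpG; only one observation counts
    a = aln("p", "chrT", 0, "AACGTTACGT", mate=1, strand=OT)
    b = aln("p", "chrT", 0, "AATGTTACGT", mate=2, strand=OT, reverse=True)
    calls = call_cpg([a, b], ref10, idx10, "bisulfite")
    row = calls.iloc[0]
    assert row.meth + row.unmeth == 1
    assert row.meth == 1  # tie on quality: mate 1's C wins


def test_low_quality_bases_and_mapq_skipped(ref10, idx10):
    lowq = aln("a", "chrT", 0, "AACGTTACGT", paired=False, qual="#" * 10)
    lowmapq = aln("b", "chrT", 0, "AACGTTACGT", paired=False, mapq=5)
    calls = call_cpg([lowq, lowmapq], ref10, idx10, "bisulfite")
    assert calls.empty


def test_chemistry_must_be_explicit(ref10, idx10):
    with pytest.raises(ValueError, match="chemistry"):
        call_cpg([], ref10, idx10, None)


def test_count_conservation(aligned_bisulfite):
    """Total per-site counts equal total contributed observations."""
    cfg, ref, truth, idx, restored, stats = aligned_bisulfite
    deduped, _ = dedup(sorted(restored, key=lambda a: (a.chrom, a.pos)))
    calls = call_cpg(deduped, ref, idx, "bisulfite")
    from metharc.methcall import _fragment_observations
    n_obs = sum(1 for _ in _fragment_observations(deduped, idx.site_sets(),
                                                  CallConfig()))
    assert (calls["meth"] + calls["unmeth"]).sum() == n_obs
    assert (calls["meth"] == calls["meth_watson"] + calls["meth_crick"]).all()


# -- conversion rate --------------------------------------------------------

def test_conversion_rate_arithmetic():
    # lambda chromosome with isolated cytosines; 98 T reads and 2 C reads
    lam = "AT" * 5 + "CA" + "AT" * 5  # single C at position 10
    ref = ReferenceGenome({"lambda": lam}, frozenset(["lambda"]))
    reads = []
    for i in range(98):
        reads.append(aln(f"t{i}", "lambda", 8, "ATTA", paired=False))  # T at 10
    for i in range(2):
        reads.append(aln(f"c{i}", "lambda", 8, "ATCA", paired=False))  # C at 10
    rate = conversion_rate(reads, ref, ["lambda"], "bisulfite")
    assert rate.estimable
    assert rate.rate == pytest.approx(0.98)
    assert rate.total_count == 100


def test_conversion_rate_zero_coverage_flagged():
    ref = ReferenceGenome({"lambda": "ACGT" * 10}, frozenset(["lambda"]))
    rate = conversion_rate([], ref, ["lambda"], "bisulfite")
    assert not rate.estimable and rate.rate is None


def test_conversion_rate_taps_counts_retained():
    lam = "AT" * 5 + "CA" + "AT" * 5
    ref = ReferenceGenome({"lambda": lam}, frozenset(["lambda"]))
    reads = [aln("a", "lambda", 8, "ATCA", paired=False),   # retained C
             aln("b", "lambda", 8, "ATTA", paired=False)]   # converted T
    rate = conversion_rate(reads, ref, ["lambda"], "taps")
    assert rate.rate == pytest.approx(0.5)


def test_conversion_rate_context_breakdown():
    lam = "AACGAA" + "AACTAA"  # CpG C at 2; non-CpG C at 8
    ref = ReferenceGenome({"lambda": lam}, frozenset(["lambda"]))
    reads = [aln("a", "lambda", 0, "AATGAAAATTAA", paired=False)]  # both converted
    rate = conversion_rate(reads, ref, ["lambda"], "bisulfite")
    assert rate.cpg_total == 1 and rate.cpg_rate == 1.0
    assert rate.total_count == 2


# -- M-bias -----------------------------------------------------------------

def test_mbias_reverse_read_cycle_attribution():
    """Hand-built two-read case: forward vs reverse cycle bookkeeping."""
    ref = ReferenceGenome({"chrT": "AACGTTACGT"})
    idx = build_cpg_index(ref)  # CpGs at 2 and 7
    fwd = aln("f", "chrT", 0, "AACGTTACGT", paired=False)  # observes 2 at qpos 2
    rev = aln("r", "chrT", 0, "AACGTTACGT", paired=False, reverse=True)
    table = m_bias([fwd, rev], ref, idx, "bisulfite")
    cycles = dict(((int(r.mate), int(r.cycle)), (int(r.meth), int(r.unmeth)))
                  for r in table.itertuples(index=False))
    # forward read: qpos 2 -> cycle 3, qpos 7 -> cycle 8; the reverse read
    # counts from its 3'-most aligned base: qpos 2 -> cycle 8, qpos 7 -> cycle 3.
    # Both reads observe methylated Cs, so each cycle collects one from each.
    assert cycles[(1, 3)] == (2, 0) and cycles[(1, 8)] == (2, 0)
    assert set(cycles) == {(1, 3), (1, 8)}


def test_mbias_head_clip_offsets_cycles():
    ref = ReferenceGenome({"chrT": "AACGTTACGT"})
    idx = build_cpg_index(ref)
    r = aln("f", "chrT", 0, "AACGTTACGT", paired=False, clip_head=2)
    table = m_bias([r], ref, idx, "bisulfite")
    assert set(table["cycle"]) == {5, 10}  # shifted by the clipped cycles


def test_mbias_constructed_artifact_at_read2_head(ref10, idx10):
    # every mate-2 cycle-1 observation unmethylated, mate-1 50/50
    reads = []
    for i in range(10):
        meth = "AACGTTACGT" if i % 2 == 0 else "AATGTTACGT"
        reads.append(aln(f"a{i}", "chrT", 0, meth, mate=1, paired=False))
    for i in range(10):
        # reverse-oriented mate 2 whose watson 3'-most base is the CpG C:
        # seq covers positions 0..3 so qpos 2 is read cycle 2 from the 3' end
        reads.append(aln(f"b{i}", "chrT", 1, "ATG", mate=2, paired=False,
                         reverse=True))
    table = m_bias(reads, ref10, idx10, "bisulfite")
    m2 = table[table["mate"] == 2]
    assert (m2["level"] == 0).all()
    m1 = table[table["mate"] == 1]
    assert m1["level"].iloc[0] == pytest.approx(0.5)


# -- per-chromosome levels --------------------------------------------------

def test_per_chromosome_levels_and_conservation():
    import pandas as pd
    calls = pd.DataFrame({
        "chrom": ["chr1"] * 2 + ["chr2"] + ["lambda"],
        "pos": [2, 10, 5, 3],
        "meth": [4, 6, 5, 0],
        "unmeth": [12, 18, 5, 10],
    })
    levels = per_chromosome_levels(calls, spike_in_names=["lambda"])
    assert levels["chr1"] == pytest.approx(0.25)
    assert levels["chr2"] == pytest.approx(0.5)
    assert "lambda" not in levels
    total = overall_level(calls, ["lambda"])
    cov = {"chr1": 40, "chr2": 10}
    weighted = sum(levels[c] * cov[c] for c in levels) / sum(cov.values())
    assert total == pytest.approx(weighted)


def test_zero_coverage_chromosome_omitted():
    import pandas as pd
    calls = pd.DataFrame({"chrom": ["chr1"], "pos": [1],
                          "meth": [0], "unmeth": [0]})
    assert per_chromosome_levels(calls) == {}
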