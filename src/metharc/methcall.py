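"""PCR-duplicate removal and per-CpG methylation calling.

Chemistry semantics.  Both chemistries are read out at CpG sites from the
Watson-oriented alignment sequence: an OT (Watson-origin) fragment shows
C or T at the Watson C of a CpG, an OB (Crick-origin) fragment shows G or
A at the Watson G (the Crick C).  A retained base (C/G) means the
cytosine survived the chemistry, a converted base (T/A) means it was
deaminated/reduced:

* bisulfite — unmethylated C converts, so retained = methylated;
* TAPS      — METHYLATED C converts, so retained = unmethylated.

Overlapping mates of a pair observe the same molecule, so at any site
covered by both mates only the higher-quality base is counted (tie:
mate 1).  Spike-in conversion rates are estimated from ALL cytosines of
the designated spike-in chromosomes (both strands, every context) as the
fraction of observations behaving as the chemistry predicts for
unmethylated input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from metharc.align import OB, OT, RestoredAlignment, parse_cigar
from metharc.genome import CpGIndex, ReferenceGenome

BISULFITE = "bisulfite"
TAPS = "taps"
_CHEMS = {"bs": BISULFITE, BISULFITE: BISULFITE, "taps": TAPS, TAPS: TAPS}


def normalize_chem(chem) -> str:
    if chem is None:
        raise ValueError("chemistry must be given explicitly: 'bisulfite' or 'taps'")
    try:
        return _CHEMS[chem]
    except KeyError:
        raise ValueError(f"unknown chemistry: {chem!r}") from None


@dataclass
class CallConfig:
    min_base_qual: int = 20
    min_mapq: int = 20
    phred_offset: int = 33


@dataclass
class DedupStats:
    input_fragments: int = 0
    duplicates_removed: int = 0
    reported: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class ConversionRate:
    spike_in_name: str
    converted_count: int = 0
    total_count: int = 0
    cpg_converted: int = 0
    cpg_total: int = 0
    estimable: bool = False

    @property
    def rate(self) -> Optional[float]:
        return self.converted_count / self.total_count if self.estimable else None

    @property
    def cpg_rate(self) -> Optional[float]:
        return self.cpg_converted / self.cpg_total if self.cpg_total else None

    @property
    def non_cpg_rate(self) -> Optional[float]:
        n = self.total_count - self.cpg_total
        return (self.converted_count - self.cpg_converted) / n if n else None

    def to_dict(self) -> dict:
        return {
            "spike_in_name": self.spike_in_name,
            "converted_count": self.converted_count,
            "total_count": self.total_count,
            "rate": self.rate,
            "cpg_rate": self.cpg_rate,
            "non_cpg_rate": self.non_cpg_rate,
            "estimable": self.estimable,
        }


# ---------------------------------------------------------------------------
# fragment grouping

class Fragment(NamedTuple):
    read_id: str
    chrom: str
    start: int
    end: int
    bs_strand: str
    paired: bool
    sum_qual: int
    alignments: tuple

    @property
    def key(self) -> tuple:
        if self.paired:
            return (self.chrom, self.start, self.end, self.bs_strand)
        return (self.chrom, self.start, self.bs_strand)


def _check_sorted(alignments: Sequence[RestoredAlignment]) -> None:
    last: dict[str, int] = {}
    order: list[str] = []
    for aln in alignments:
        if aln.chrom not in last:
            if order and aln.chrom in order:
                raise ValueError("alignment stream is not coordinate-sorted")
            order.append(aln.chrom)
            last[aln.chrom] = aln.pos
        else:
            if order[-1] != aln.chrom or aln.pos < last[aln.chrom]:
                raise ValueError("alignment stream is not coordinate-sorted")
            last[aln.chrom] = aln.pos


def group_fragments(alignments: Sequence[RestoredAlignment]) -> list[Fragment]:
    """Group mates into fragments, preserving first-encounter order."""
    by_id: dict[str, list[RestoredAlignment]] = {}
    order: list[str] = []
    for aln in alignments:
        if aln.read_id not in by_id:
            order.append(aln.read_id)
        by_id.setdefault(aln.read_id, []).append(aln)
    out = []
    for rid in order:
        group = tuple(sorted(by_id[rid], key=lambda a: a.mate))
        start = min(a.pos for a in group)
        end = max(a.end for a in group)
        sq = sum(ord(c) for a in group for c in a.qual)
        out.append(Fragment(rid, group[0].chrom, start, end,
                            group[0].bs_strand, group[0].paired, sq, group))
    return out


def dedup(alignments: Sequence[RestoredAlignment]
          ) -> tuple[list[RestoredAlignment], DedupStats]:
    """Remove PCR duplicates from a coordinate-sorted alignment stream.

    Fragments sharing (chrom, start, end, strand) for paired data or
    (chrom, pos, strand) for single-end are duplicates; the copy with the
    highest summed base quality is kept (ties: first encountered).
    """
    _check_sorted(alignments)
    fragments = group_fragments(alignments)
    best: dict[tuple, Fragment] = {}
    order: list[tuple] = []
    for frag in fragments:
        key = frag.key
        if key not in best:
            best[key] = frag
            order.append(key)
        elif frag.sum_qual > best[key].sum_qual:
            best[key] = frag
    kept_ids = {best[k].read_id for k in order}
    kept = [a for a in alignments if a.read_id in kept_ids]
    stats = DedupStats(
        input_fragments=len(fragments),
        duplicates_removed=len(fragments) - len(order),
        reported=len(order),
    )
    return kept, stats


# ---------------------------------------------------------------------------
# observation extraction

class _Obs(NamedTuple):
    chrom: str
    site: int        # Watson C position of the CpG
    strand: str      # OT | OB (which strand's cytosine was read)
    retained: bool   # True: C/G observed; False: T/A observed
    qual: int
    mate: int
    cycle: int       # 1-based original sequencing cycle


def _walk_matches(aln: RestoredAlignment):
    """Yield (ref_pos, query_pos) for every aligned (M/=/X) base."""
    rp, qp = aln.pos, 0
    for n, op in parse_cigar(aln.cigar):
        if op in "M=X":
            for i in range(n):
                yield rp + i, qp + i
            rp += n
            qp += n
        elif op in "DN":
            rp += n
        elif op in "IS":
            qp += n


def _cycle_of(aln: RestoredAlignment, qpos: int) -> int:
    base = (len(aln.seq) - 1 - qpos) if aln.reverse else qpos
    return base + aln.clip_head + 1


def _alignment_observations(aln: RestoredAlignment, cpg_set: frozenset[int],
                            cfg: CallConfig) -> list[_Obs]:
    obs = []
    offset = cfg.phred_offset
    for rp, qp in _walk_matches(aln):
        if aln.bs_strand == OT:
            if rp not in cpg_set:
                continue
            site = rp
            base = aln.seq[qp]
            retained = base == "C"
            informative = base in "CT"
        else:
            if rp - 1 not in cpg_set:
                continue
            site = rp - 1
            base = aln.seq[qp]
            retained = base == "G"
            informative = base in "GA"
        q = ord(aln.qual[qp]) - offset
        if not informative or q < cfg.min_base_qual:
            continue
        obs.append(_Obs(aln.chrom, site, aln.bs_strand, retained, q,
                        aln.mate, _cycle_of(aln, qp)))
    return obs


def _fragment_observations(alignments: Sequence[RestoredAlignment],
                           site_sets: dict[str, frozenset[int]],
                           cfg: CallConfig) -> Iterable[_Obs]:
    """Per-fragment CpG observations with mate-overlap resolution."""
    usable = [a for a in alignments if a.mapq >= cfg.min_mapq]
    for frag in group_fragments(usable):
        cpg_set = site_sets.get(frag.chrom)
        if not cpg_set:
            continue
        chosen: dict[int, _Obs] = {}
        for aln in frag.alignments:
            for ob in _alignment_observations(aln, cpg_set, cfg):
                prev = chosen.get(ob.site)
                # overlap: higher base quality wins, tie goes to mate 1
                if prev is None or ob.qual > prev.qual or \
                        (ob.qual == prev.qual and ob.mate < prev.mate):
                    chosen[ob.site] = ob
        yield from chosen.values()


def _is_meth(retained: bool, chem: str) -> bool:
    return retained if chem == BISULFITE else not retained


# ---------------------------------------------------------------------------
# public operations

CALL_COLUMNS = ["chrom", "pos", "meth", "unmeth", "beta",
                "meth_watson", "unmeth_watson", "meth_crick", "unmeth_crick"]


def call_cpg(alignments: Sequence[RestoredAlignment], ref: ReferenceGenome,
             idx: CpGIndex, chem, cfg: Optional[CallConfig] = None) -> pd.DataFrame:
    """Per-CpG methylated/unmethylated counts, strand-resolved and merged.

    Returns a DataFrame (CALL_COLUMNS) sorted by (chrom, pos) in reference
    order, containing only covered sites.  ``beta`` = meth/(meth+unmeth).
    """
    chem = normalize_chem(chem)
    cfg = cfg or CallConfig()
    site_sets = idx.site_sets()
    counts: dict[tuple[str, int], list[int]] = {}
    for ob in _fragment_observations(alignments, site_sets, cfg):
        row = counts.setdefault((ob.chrom, ob.site), [0, 0, 0, 0])
        meth = _is_meth(ob.retained, chem)
        col = (0 if meth else 1) if ob.strand == OT else (2 if meth else 3)
        row[col] += 1
    chrom_order = {c: i for i, c in enumerate(ref.chromosomes)}
    records = []
    for (chrom, pos), (mw, uw, mc, uc) in sorted(
            counts.items(), key=lambda kv: (chrom_order[kv[0][0]], kv[0][1])):
        meth, unmeth = mw + mc, uw + uc
        records.append((chrom, pos, meth, unmeth, meth / (meth + unmeth),
                        mw, uw, mc, uc))
    return pd.DataFrame(records, columns=CALL_COLUMNS)


def conversion_rate(alignments: Sequence[RestoredAlignment], ref: ReferenceGenome,
                    spike_in_names: Iterable[str], chem,
                    cfg: Optional[CallConfig] = None) -> ConversionRate:
    """Spike-in conversion rate over all cytosines of both strands.

    The rate is the fraction of cytosine observations behaving as the
    chemistry predicts for unmethylated DNA: converted (T/A) under
    bisulfite, retained (C/G) under TAPS.
    """
    chem = normalize_chem(chem)
    cfg = cfg or CallConfig()
    spike_in_names = [n for n in spike_in_names if n in ref.chromosomes]
    result = ConversionRate(spike_in_name=",".join(spike_in_names) or "none")
    if not spike_in_names:
        return result
    c_sets = {n: frozenset(i for i, b in enumerate(ref.chromosomes[n]) if b == "C")
              for n in spike_in_names}
    g_sets = {n: frozenset(i for i, b in enumerate(ref.chromosomes[n]) if b == "G")
              for n in spike_in_names}
    offset = cfg.phred_offset
    behaved = 0
    total = 0
    cpg_behaved = 0
    cpg_total = 0
    for aln in alignments:
        if aln.chrom not in c_sets or aln.mapq < cfg.min_mapq:
            continue
        seq = ref.chromosomes[aln.chrom]
        cs, gs = c_sets[aln.chrom], g_sets[aln.chrom]
        for rp, qp in _walk_matches(aln):
            base = aln.seq[qp]
            if ord(aln.qual[qp]) - offset < cfg.min_base_qual:
                continue
            if aln.bs_strand == OT and rp in cs:
                if base not in "CT":
                    continue
                converted = base == "T"
                is_cpg = rp + 1 < len(seq) and seq[rp + 1] == "G"
            elif aln.bs_strand == OB and rp in gs:
                if base not in "GA":
                    continue
                converted = base == "A"
                is_cpg = rp >= 1 and seq[rp - 1] == "C"
            else:
                continue
            well_behaved = converted if chem == BISULFITE else not converted
            total += 1
            behaved += well_behaved
            if is_cpg:
                cpg_total += 1
                cpg_behaved += well_behaved
    result.converted_count = behaved
    result.total_count = total
    result.cpg_converted = cpg_behaved
    result.cpg_total = cpg_total
    result.estimable = total > 0
    return result


def m_bias(alignments: Sequence[RestoredAlignment], ref: ReferenceGenome,
           idx: CpGIndex, chem, cfg: Optional[CallConfig] = None) -> pd.DataFrame:
    """Methylation level per mate per original sequencing cycle.

    Cycles are 1-based positions on the read AS SEQUENCED, so reverse-
    oriented alignments count from their 3'-most aligned base backwards
    and upstream head-clipping shifts cycles by the clipped amount.
    """
    chem = normalize_chem(chem)
    cfg = cfg or CallConfig()
    site_sets = idx.site_sets()
    counts: dict[tuple[int, int], list[int]] = {}
    for ob in _fragment_observations(alignments, site_sets, cfg):
        row = counts.setdefault((ob.mate, ob.cycle), [0, 0])
        row[0 if _is_meth(ob.retained, chem) else 1] += 1
    records = [(mate, cycle, m, u, m / (m + u))
               for (mate, cycle), (m, u) in sorted(counts.items())]
    return pd.DataFrame(records, columns=["mate", "cycle", "meth", "unmeth", "level"])


def per_chromosome_levels(calls: pd.DataFrame,
                          spike_in_names: Iterable[str] = ()) -> dict[str, float]:
    """Coverage-weighted methylation level per chromosome (spike-ins excluded).

    Chromosomes with zero covered CpGs are omitted.
    """
    skip = set(spike_in_names)
    out: dict[str, float] = {}
    if calls.empty:
        return out
    for chrom, sub in calls.groupby("chrom", sort=False):
        if chrom in skip:
            continue
        denom = (sub["meth"] + sub["unmeth"]).sum()
        if denom > 0:
            out[chrom] = float(sub["meth"].sum() / denom)
    return out


def overall_level(calls: pd.DataFrame, spike_in_names: Iterable[str] = ()) -> Optional[float]:
    skip = set(spike_in_names)
    sub = calls[~calls["chrom"].isin(skip)] if not calls.empty else calls
    if sub.empty:
        return None
    denom = (sub["meth"] + sub["unmeth"]).sum()
    return float(sub["meth"].sum() / denom) if denom else None


def write_calls(calls: pd.DataFrame, path, merged: bool = True) -> None:
    """Write calls as BED-like TSV (0-based start, half-open end)."""
    with open(path, "w") as out:
        if merged:
            out.write("#chrom\tstart\tend\tbeta\tmeth\tunmeth\tstrand\n")
            for row in calls.itertuples(index=False):
                out.write(f"{row.chrom}\t{row.pos}\t{row.pos + 2}\t"
                          f"{row.beta:.4f}\t{row.meth}\t{row.unmeth}\t+\n")
        else:
            out.write("#chrom\tstart\tend\tbeta\tmeth\tunmeth\tstrand\n")
            for row in calls.itertuples(index=False):
                wt = row.meth_watson + row.unmeth_watson
                ct = row.meth_crick + row.unmeth_crick
                if wt:
                    out.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t"
                              f"{row.meth_watson / wt:.4f}\t"
                              f"{row.meth_watson}\t{row.unmeth_watson}\t+\n")
                if ct:
                    out.write(f"{row.chrom}\t{row.pos + 1}\t{row.pos + 2}\t"
                              f"{row.meth_crick / ct:.4f}\t"
                              f"{row.meth_crick}\t{row.unmeth_crick}\t-\n")


def write_bedgraph(calls: pd.DataFrame, path) -> None:
    with open(path, "w") as out:
        out.write('track type=bedGraph name="CpG methylation"\n')
        for row in calls.itertuples(index=False):
            out.write(f"{row.chrom}\t{row.pos}\t{row.pos + 2}\t{row.beta:.4f}\n")
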