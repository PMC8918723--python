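"""FASTQ preprocessing: adapter removal, quality trimming, cycle clipping.

Trimming order per mate:

1. 3' adapter search — the adapter prefix is matched against every read
   suffix, requiring an 8 nt exact seed (or the full overlap when shorter),
   at most 10% mismatches over the matched span, and an overlap of at
   least 3 nt at the read end; the leftmost acceptable hit wins.
2. 3' quality trimming with the running-sum method: walking from the 3'
   end, accumulate ``threshold - q``; the read is cut at the position
   maximising the sum (the standard BWA-style rule).
3. Head/tail cycle clipping of exactly the configured counts, intended
   for end-repair artifacts that survive adapter removal.

Pairs where either mate falls below the minimum length are dropped whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from metharc.utils import open_text

#: Illumina TruSeq adapter read-through sequences
DEFAULT_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
DEFAULT_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"


@dataclass
class RawRead:
    read_id: str
    seq: str
    qual: str


@dataclass
class TrimConfig:
    adapter_r1: str = DEFAULT_ADAPTER_R1
    adapter_r2: str = DEFAULT_ADAPTER_R2
    min_qual: int = 20
    min_len: int = 36
    clip_head_r1: int = 0
    clip_tail_r1: int = 0
    clip_head_r2: int = 0
    clip_tail_r2: int = 0
    adapter_seed: int = 8
    adapter_max_mismatch_frac: float = 0.10
    adapter_min_overlap: int = 3
    phred_offset: int = 33


@dataclass
class TrimmedReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: Optional[str] = None
    r2_qual: Optional[str] = None
    clip_head_r1: int = 0
    clip_tail_r1: int = 0
    clip_head_r2: int = 0
    clip_tail_r2: int = 0

    @property
    def single_end(self) -> bool:
        return self.r2_seq is None


@dataclass
class TrimStats:
    total_pairs: int = 0
    kept_pairs: int = 0
    dropped_short: int = 0
    adapter_found: int = 0
    composition_before: dict = field(default_factory=dict)
    composition_after: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "kept_pairs": self.kept_pairs,
            "dropped_short": self.dropped_short,
            "adapter_found": self.adapter_found,
            "composition_before": {m: t.to_dict(orient="list")
                                   for m, t in self.composition_before.items()},
            "composition_after": {m: t.to_dict(orient="list")
                                  for m, t in self.composition_after.items()},
        }


def find_adapter(seq: str, adapter: str, seed: int = 8,
                 max_mismatch_frac: float = 0.10, min_overlap: int = 3) -> int:
    """Return the read position where the 3' adapter starts, or len(seq).

    A candidate at position i matches adapter[:len(seq)-i] against seq[i:];
    the first ``seed`` bases of the overlap must match exactly and the
    whole overlap may contain at most ``max_mismatch_frac`` mismatches.
    """
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        span = min(n - i, len(adapter))
        if span < min_overlap:
            break
        seed_len = min(seed, span)
        if seq[i:i + seed_len] != adapter[:seed_len]:
            continue
        mm = sum(a != b for a, b in zip(seq[i:i + span], adapter[:span]))
        if mm <= max_mismatch_frac * span:
            return i
    return n


def quality_trim_point(qual: str, threshold: int = 20, phred_offset: int = 33) -> int:
    """BWA-style running-sum 3' trim point: keep qual[:point]."""
    best_pos = len(qual)
    best_sum = 0
    running = 0
    for i in range(len(qual) - 1, -1, -1):
        running += threshold - (ord(qual[i]) - phred_offset)
        if running < 0:
            break
        if running > best_sum:
            best_sum = running
            best_pos = i
    return best_pos


def _trim_mate(seq: str, qual: str, adapter: str, cfg: TrimConfig,
               clip_head: int, clip_tail: int) -> tuple[str, str, bool]:
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    cut = find_adapter(seq, adapter, cfg.adapter_seed,
                       cfg.adapter_max_mismatch_frac, cfg.adapter_min_overlap)
    had_adapter = cut < len(seq)
    seq, qual = seq[:cut], qual[:cut]
    qcut = quality_trim_point(qual, cfg.min_qual, cfg.phred_offset)
    seq, qual = seq[:qcut], qual[:qcut]
    end = len(seq) - clip_tail
    seq, qual = seq[clip_head:max(clip_head, end)], qual[clip_head:max(clip_head, end)]
    return seq, qual, had_adapter


def trim_pair(r1: RawRead, r2: Optional[RawRead], cfg: TrimConfig) -> Optional[TrimmedReadPair]:
    """Trim one read pair (or single read); None when dropped as too short."""
    s1, q1, a1 = _trim_mate(r1.seq, r1.qual, cfg.adapter_r1, cfg,
                            cfg.clip_head_r1, cfg.clip_tail_r1)
    if r2 is None:
        if len(s1) < cfg.min_len:
            return None
        return TrimmedReadPair(r1.read_id, s1, q1,
                               clip_head_r1=cfg.clip_head_r1,
                               clip_tail_r1=cfg.clip_tail_r1)
    s2, q2, a2 = _trim_mate(r2.seq, r2.qual, cfg.adapter_r2, cfg,
                            cfg.clip_head_r2, cfg.clip_tail_r2)
    if len(s1) < cfg.min_len or len(s2) < cfg.min_len:
        return None
    pair = TrimmedReadPair(r1.read_id, s1, q1, s2, q2,
                           cfg.clip_head_r1, cfg.clip_tail_r1,
                           cfg.clip_head_r2, cfg.clip_tail_r2)
    pair._adapter_found = a1 or a2  # transient bookkeeping for the driver
    return pair


def base_composition(seqs: Iterable[str]) -> pd.DataFrame:
    """Per-cycle fraction of A/C/G/T/N among reads covering each cycle.

    Returns a DataFrame indexed by 1-based cycle with columns A,C,G,T,N;
    empty input yields an empty frame.
    """
    letters = "ACGTN"
    counts: list[np.ndarray] = []
    for seq in seqs:
        if len(seq) > len(counts):
            counts.extend(np.zeros(5, dtype=np.int64) for _ in range(len(seq) - len(counts)))
        for c, base in enumerate(seq):
            counts[c][letters.index(base) if base in letters else 4] += 1
    if not counts:
        return pd.DataFrame(columns=list(letters))
    mat = np.vstack(counts).astype(float)
    totals = mat.sum(axis=1, keepdims=True)
    frac = mat / np.where(totals == 0, 1, totals)
    return pd.DataFrame(frac, columns=list(letters),
                        index=pd.RangeIndex(1, len(counts) + 1, name="cycle"))


# ---------------------------------------------------------------------------
# FASTQ streaming

class FastqFormatError(RuntimeError):
    pass


def read_fastq(paths) -> Iterator[RawRead]:
    """Stream reads from one or more (possibly gzipped) FASTQ files."""
    if isinstance(paths, (str, bytes)) or not isinstance(paths, (list, tuple)):
        paths = [paths]
    for path in paths:
        with open_text(path) as fh:
            record_no = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                record_no += 1
                seq = fh.readline().rstrip("\n")
                plus = fh.readline()
                qual = fh.readline().rstrip("\n")
                if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                    raise FastqFormatError(
                        f"malformed FASTQ record {record_no} in {path}")
                yield RawRead(header[1:].split()[0].rstrip("\n"), seq, qual)


def write_fastq(reads: Iterable[RawRead], path) -> None:
    with open_text(path, "wt") as out:
        for r in reads:
            out.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def trim_stream(r1_paths, r2_paths, cfg: TrimConfig):
    """Trim a whole dataset; returns (kept pairs list, TrimStats)."""
    reads1 = list(read_fastq(r1_paths))
    reads2 = list(read_fastq(r2_paths)) if r2_paths else None
    if reads2 is not None and len(reads1) != len(reads2):
        raise FastqFormatError("R1/R2 files contain different numbers of reads")

    stats = TrimStats()
    stats.composition_before = {"r1": base_composition(r.seq for r in reads1)}
    if reads2 is not None:
        stats.composition_before["r2"] = base_composition(r.seq for r in reads2)

    kept: list[TrimmedReadPair] = []
    for i, r1 in enumerate(reads1):
        r2 = reads2[i] if reads2 is not None else None
        if r2 is not None and r1.read_id.split("/")[0] != r2.read_id.split("/")[0]:
            raise FastqFormatError(
                f"mate ID mismatch at record {i + 1}: {r1.read_id} vs {r2.read_id}")
        stats.total_pairs += 1
        pair = trim_pair(r1, r2, cfg)
        if pair is None:
            stats.dropped_short += 1
            continue
        stats.kept_pairs += 1
        if getattr(pair, "_adapter_found", False):
            stats.adapter_found += 1
        kept.append(pair)

    stats.composition_after = {"r1": base_composition(p.r1_seq for p in kept)}
    if reads2 is not None:
        stats.composition_after["r2"] = base_composition(p.r2_seq for p in kept)
    return kept, stats
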