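"""Truth-tagged read simulator for bisulfite and TAPS libraries.

Generates an i.i.d.-uniform ACGT genome (optionally with an unmethylated
lambda-like spike-in chromosome), assigns every CpG a truth methylation
probability, and emits directional paired-end or single-end reads whose
IDs encode the originating fragment (``r<i>:chrom:start:end:strand``,
strand W = Watson/OT, C = Crick/OB) so that mapping efficiency and
accuracy can be measured exactly.

Chemistry model per template-strand cytosine:

* bisulfite — an unmethylated C reads as T with probability
  ``conversion_rate``; a methylated C reads as T only with probability
  ``inverse_failure``.
* TAPS — inverted: a METHYLATED CpG C reads as T with probability
  ``conversion_rate``, an unmethylated CpG C with probability
  ``inverse_failure``; non-CpG cytosines are untouched.

Non-CpG cytosines are simulated fully unmethylated (mammalian-like
default).  Fragments shorter than the read length read through into the
sequencing adapter.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from metharc.genome import ReferenceGenome, build_cpg_index
from metharc.readprep import DEFAULT_ADAPTER_R1, DEFAULT_ADAPTER_R2, RawRead
from metharc.utils import revcomp

BASES = "ACGT"
LAMBDA_NAME = "lambda"


@dataclass
class SimConfig:
    seed: int = 1
    genome_length: int = 100_000
    n_chromosomes: int = 1
    n_fragments: int = 10_000
    read_len: int = 100
    paired: bool = True
    frag_mu: float = 167.0
    frag_sigma: float = 30.0
    min_frag: int = 30
    meth_beta: Optional[float] = None  # constant truth; None -> bimodal draw
    chemistry: str = "bisulfite"
    conversion_rate: float = 0.995
    inverse_failure: float = 0.005
    error_rate: float = 0.001
    spike_in: bool = False
    spike_in_length: int = 5_000
    spike_in_fraction: float = 0.1  # fraction of fragments drawn from spike-in
    ct_rich: bool = False
    ct_min_fraction: float = 0.7
    ct_window: int = 200
    base_quality: int = 37
    r2_head_unmeth_cycles: int = 0  # emulate end-repair artifact at R2 head
    adapter_r1: str = DEFAULT_ADAPTER_R1
    adapter_r2: str = DEFAULT_ADAPTER_R2


def simulate_genome(cfg: SimConfig) -> tuple[ReferenceGenome, pd.DataFrame]:
    """Random genome plus a per-CpG truth table (chrom, pos, beta).

    Without a constant ``meth_beta``, truth values are drawn from a
    bimodal mixture (70% Beta(8,2) high, 30% Beta(2,8) low) resembling
    the methylome of a somatic mammalian tissue.  Spike-in CpGs have
    truth 0 (fully unmethylated control).

    The background is i.i.d. uniform ACGT, overlaid with occasional
    400 bp pyrimidine- or purine-skewed blocks (one per ~8 kb, base
    probabilities 0.4/0.4/0.1/0.1) emulating the CT-rich stretches that
    surround regulatory elements in real genomes; GC content stays 0.5
    in expectation.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms: dict[str, str] = {}
    per = cfg.genome_length // cfg.n_chromosomes
    letters = np.array(list(BASES))
    for i in range(cfg.n_chromosomes):
        arr = letters[rng.integers(0, 4, per)]
        block = 400
        for _ in range(max(1, per // 8000)):
            if per <= block:
                break
            start = int(rng.integers(0, per - block))
            if rng.random() < 0.5:  # pyrimidine-skewed (CT-rich on Watson)
                probs = [0.1, 0.4, 0.1, 0.4]  # A C G T
            else:  # purine-skewed (CT-rich on Crick)
                probs = [0.4, 0.1, 0.4, 0.1]
            arr[start:start + block] = letters[
                rng.choice(4, size=block, p=probs)]
        chroms[f"chr{i + 1}"] = "".join(arr)
    spike = frozenset()
    if cfg.spike_in:
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, cfg.spike_in_length)])
        chroms[LAMBDA_NAME] = seq
        spike = frozenset([LAMBDA_NAME])
    ref = ReferenceGenome(chroms, spike)
    idx = build_cpg_index(ref)
    records = []
    for chrom, positions in idx.sites.items():
        n = len(positions)
        if chrom in spike:
            betas = np.zeros(n)
        elif cfg.meth_beta is not None:
            betas = np.full(n, float(cfg.meth_beta))
        else:
            high = rng.random(n) < 0.7
            betas = np.where(high, rng.beta(8, 2, n), rng.beta(2, 8, n))
        for p, b in zip(positions, betas):
            records.append((chrom, int(p), float(b)))
    truth = pd.DataFrame(records, columns=["chrom", "pos", "beta"])
    return ref, truth


def find_ct_rich_windows(seq: str, min_fraction: float = 0.7,
                         window: int = 200, strand: str = "watson"
                         ) -> list[tuple[int, int]]:
    """Merged Watson-coordinate intervals of C+T-rich windows.

    Windows of ``window`` bp at stride window/2 qualify when the fraction
    of C+T on the requested strand (G+A on Watson for the Crick strand)
    reaches ``min_fraction``; overlapping qualifying windows are merged.
    """
    letters = "CT" if strand == "watson" else "GA"
    stride = max(1, window // 2)
    hits = []
    for start in range(0, max(1, len(seq) - window + 1), stride):
        sub = seq[start:start + window]
        if len(sub) < window:
            break
        frac = sum(sub.count(c) for c in letters) / window
        if frac >= min_fraction:
            hits.append((start, start + window))
    merged: list[tuple[int, int]] = []
    for start, end in hits:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def _convert_template(template: str, next_base: str, truth_beta, chrom: str,
                      start: int, flen: int, strand: str, cfg: SimConfig,
                      rng: np.random.Generator) -> str:
    """Apply per-molecule methylation draws and chemistry to one template.

    ``template`` is the fragment sequence 5'->3' on the sampled strand;
    ``next_base`` is the genomic base just past its 3' end (context for
    the terminal C), or "" at a chromosome boundary.
    """
    taps = cfg.chemistry == "taps"
    out = list(template)
    ext = template + next_base
    for i, b in enumerate(template):
        if b != "C":
            continue
        is_cpg = i + 1 < len(ext) and ext[i + 1] == "G"
        if is_cpg:
            if strand == "W":
                site = start + i
            else:
                site = start + flen - 1 - i - 1  # Watson C of the Crick CpG
            beta = truth_beta.get((chrom, site), 0.0)
            methylated = rng.random() < beta
        else:
            methylated = False
        if taps:
            if not is_cpg:
                continue
            p_convert = cfg.conversion_rate if methylated else cfg.inverse_failure
        else:
            p_convert = cfg.inverse_failure if methylated else cfg.conversion_rate
        if rng.random() < p_convert:
            out[i] = "T"
    return "".join(out)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4] \
                if out[i] in BASES else "N"
    return "".join(out)


def _take_read(template_conv: str, adapter: str, read_len: int) -> str:
    read = template_conv[:read_len]
    if len(read) < read_len:  # adapter read-through
        read = (read + adapter)[:read_len]
        read = read.ljust(read_len, "A")
    return read


def simulate_reads(ref: ReferenceGenome, truth: pd.DataFrame, cfg: SimConfig
                   ) -> tuple[list[RawRead], Optional[list[RawRead]]]:
    """Simulate reads; returns (R1 list, R2 list or None for single-end)."""
    rng = np.random.default_rng(cfg.seed + 1)
    truth_beta = {(r.chrom, r.pos): r.beta for r in truth.itertuples(index=False)}
    targets = ref.target_chromosomes()
    spikes = sorted(ref.spike_in_names)
    lengths = ref.lengths
    t_weights = np.array([lengths[c] for c in targets], dtype=float)
    t_weights /= t_weights.sum()

    windows: dict[tuple[str, str], list[tuple[int, int]]] = {}
    if cfg.ct_rich:
        for chrom in targets:
            for strand, key in (("watson", "W"), ("crick", "C")):
                w = find_ct_rich_windows(ref.chromosomes[chrom],
                                         cfg.ct_min_fraction, cfg.ct_window, strand)
                if w:
                    windows[(chrom, key)] = w
        if not windows:
            raise ValueError("no CT-rich windows found; lower --ct-min-fraction")
        window_keys = sorted(windows)

    qual_char = chr(cfg.base_quality + 33)
    r1_out: list[RawRead] = []
    r2_out: list[RawRead] = [] if cfg.paired else None
    taps = cfg.chemistry == "taps"
    unmeth_r2_base = "G" if taps else "A"

    for serial in range(cfg.n_fragments):
        use_spike = bool(spikes) and rng.random() < cfg.spike_in_fraction
        strand = "W" if rng.random() < 0.5 else "C"
        for _attempt in range(100):
            flen = int(round(rng.normal(cfg.frag_mu, cfg.frag_sigma)))
            flen = max(cfg.min_frag, flen)
            if use_spike:
                chrom = spikes[rng.integers(0, len(spikes))]
            elif cfg.ct_rich:
                chrom, strand = window_keys[rng.integers(0, len(window_keys))]
            else:
                chrom = targets[rng.choice(len(targets), p=t_weights)]
            L = lengths[chrom]
            if flen > L:
                continue
            if cfg.ct_rich and not use_spike:
                ws, we = windows[(chrom, strand)][
                    rng.integers(0, len(windows[(chrom, strand)]))]
                start = int(rng.integers(ws, we))
                if start + flen > L:
                    continue
            else:
                start = int(rng.integers(0, L - flen + 1))
            break
        else:
            raise RuntimeError("could not place fragment after 100 attempts")

        seq = ref.chromosomes[chrom]
        frag = seq[start:start + flen]
        if strand == "W":
            template = frag
            nxt = seq[start + flen] if start + flen < L else ""
        else:
            template = revcomp(frag)
            nxt = revcomp(seq[start - 1]) if start >= 1 else ""
        conv = _convert_template(template, nxt, truth_beta, chrom,
                                 start, flen, strand, cfg, rng)
        rid = f"r{serial}:{chrom}:{start}:{start + flen}:{strand}"
        r1 = _apply_errors(_take_read(conv, cfg.adapter_r1, cfg.read_len),
                           cfg.error_rate, rng)
        r1_out.append(RawRead(rid, r1, qual_char * len(r1)))
        if cfg.paired:
            r2 = _apply_errors(_take_read(revcomp(conv), cfg.adapter_r2,
                                          cfg.read_len), cfg.error_rate, rng)
            if cfg.r2_head_unmeth_cycles:
                r2 = _force_unmeth_r2_head(r2, template, nxt, flen,
                                           cfg.r2_head_unmeth_cycles,
                                           unmeth_r2_base)
            r2_out.append(RawRead(rid, r2, qual_char * len(r2)))
    return r1_out, r2_out


def _force_unmeth_r2_head(r2: str, template: str, next_base: str, flen: int,
                          n_cycles: int, unmeth_base: str) -> str:
    """Overwrite CpG observations in R2's first cycles with the unmethylated
    call, emulating the end-repair overhang artifact at read-2 heads."""
    out = list(r2)
    ext = template + next_base
    for c in range(min(n_cycles, len(r2))):
        j = flen - 1 - c  # template position read at R2 cycle c
        if 0 <= j < len(template) and template[j] == "C" \
                and j + 1 < len(ext) and ext[j + 1] == "G":
            out[c] = unmeth_base
    return "".join(out)


def expected_meth_fraction(beta: float, cfg: SimConfig) -> float:
    """Closed-form probability that a single observation reads as methylated.

    Bisulfite: retained C = methylated; P = b(1-f) + (1-b)(1-c).
    TAPS: converted T = methylated; P = b*c + (1-b)*f.
    (b = truth beta, c = conversion_rate, f = inverse_failure.)
    """
    c, f = cfg.conversion_rate, cfg.inverse_failure
    if cfg.chemistry == "taps":
        return beta * c + (1 - beta) * f
    return beta * (1 - f) + (1 - beta) * (1 - c)


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
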