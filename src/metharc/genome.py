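"""Reference genome loading and converted pseudo-genome construction.

The pseudo-genome contains, for every chromosome, two converted sequences:
the Watson strand and the reverse complement (Crick strand).  Letter
conversion collapses the strand-asymmetric chemistry of bisulfite/TAPS
libraries so that a read needs only one alignment pass:

* ``three_letter`` — every C becomes T (universal mode; alphabet A/G/T);
* ``four_letter``  — only CpG-context C becomes T, preserving non-CpG
  cytosines and hence sequence complexity (suited to TAPS-like data,
  where non-CpG cytosines survive the chemistry).

A CpG-site index (0-based Watson C positions) drives methylation calling.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from metharc.utils import md5sum, open_text, revcomp

log = logging.getLogger(__name__)

THREE_LETTER = "three_letter"
FOUR_LETTER = "four_letter"
WATSON = "watson"
CRICK = "crick"

#: suffix appended to a chromosome name to form its Crick pseudo-chromosome;
#: '#' is illegal in conventional chromosome names, so no collision is possible
CRICK_SUFFIX = "#rev"

_VALID = set("ACGTN")
_NONSTANDARD = re.compile(r"[^ACGTN]")


class IndexError_(RuntimeError):
    """Raised when a persisted index is missing, tampered or mode-mismatched."""


def normalize_mode(mode) -> str:
    aliases = {
        "3": THREE_LETTER, 3: THREE_LETTER, THREE_LETTER: THREE_LETTER,
        "4": FOUR_LETTER, 4: FOUR_LETTER, FOUR_LETTER: FOUR_LETTER,
    }
    try:
        return aliases[mode]
    except KeyError:
        raise ValueError(f"unknown conversion mode: {mode!r}") from None


@dataclass
class ReferenceGenome:
    """Ordered chromosome name -> uppercase {A,C,G,T,N} sequence."""

    chromosomes: dict[str, str]
    spike_in_names: frozenset[str] = field(default_factory=frozenset)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def target_chromosomes(self) -> list[str]:
        """Chromosome names excluding spike-in controls."""
        return [n for n in self.chromosomes if n not in self.spike_in_names]

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)


@dataclass
class PseudoOrigin:
    chrom: str
    strand: str  # watson | crick
    length: int


@dataclass
class PseudoGenome:
    """Converted Watson+Crick sequences with back-mapping metadata."""

    pseudo_chromosomes: dict[str, str]
    origin: dict[str, PseudoOrigin]
    mode: str

    def watson_name(self, chrom: str) -> str:
        return chrom

    def crick_name(self, chrom: str) -> str:
        return chrom + CRICK_SUFFIX


@dataclass
class CpGIndex:
    """Per-chromosome sorted 0-based positions of the Watson C of each CpG."""

    sites: dict[str, list[int]]

    @property
    def counts(self) -> dict[str, int]:
        return {chrom: len(pos) for chrom, pos in self.sites.items()}

    def site_sets(self) -> dict[str, frozenset[int]]:
        return {chrom: frozenset(pos) for chrom, pos in self.sites.items()}


def load_fasta(path, spike_in_names=()) -> ReferenceGenome:
    """Load a (possibly gzipped) FASTA into a :class:`ReferenceGenome`.

    Sequences are uppercased; characters outside {A,C,G,T,N} are replaced
    by N with a logged warning.  Duplicate record names and empty files
    are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference FASTA not found: {path}")
    chromosomes: dict[str, str] = {}
    with open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in chromosomes:
                raise ValueError(f"duplicate chromosome name in FASTA: {record.id}")
            seq = str(record.seq).upper()
            n_bad = len(_NONSTANDARD.findall(seq))
            if n_bad:
                log.warning("chromosome %s: %d non-ACGTN characters replaced by N",
                            record.id, n_bad)
                seq = _NONSTANDARD.sub("N", seq)
            chromosomes[record.id] = seq
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(chromosomes, frozenset(spike_in_names))


def convert_sequence(seq: str, mode) -> str:
    """Apply genome-side letter conversion.

    three_letter: C->T everywhere.  four_letter: C->T only when the next
    base is G; a C before N or at the sequence end is preserved (context
    unknowable, treated conservatively as non-CpG).
    """
    mode = normalize_mode(mode)
    if mode == THREE_LETTER:
        return seq.replace("C", "T")
    return seq.replace("CG", "TG")


def build_pseudo_genome(ref: ReferenceGenome, mode) -> PseudoGenome:
    """Convert every chromosome on both strands into the pseudo-genome."""
    mode = normalize_mode(mode)
    if not ref.chromosomes:
        raise ValueError("empty reference genome")
    pseudo: dict[str, str] = {}
    origin: dict[str, PseudoOrigin] = {}
    for chrom, seq in ref.chromosomes.items():
        length = len(seq)
        pseudo[chrom] = convert_sequence(seq, mode)
        origin[chrom] = PseudoOrigin(chrom, WATSON, length)
        crick = chrom + CRICK_SUFFIX
        pseudo[crick] = convert_sequence(revcomp(seq), mode)
        origin[crick] = PseudoOrigin(chrom, CRICK, length)
    return PseudoGenome(pseudo, origin, mode)


_CPG = re.compile(r"(?=CG)")


def build_cpg_index(ref: ReferenceGenome) -> CpGIndex:
    """Index the Watson C position of every CG dinucleotide per chromosome."""
    sites = {
        chrom: [m.start() for m in _CPG.finditer(seq)]
        for chrom, seq in ref.chromosomes.items()
    }
    return CpGIndex(sites)


# ---------------------------------------------------------------------------
# persistence

_MANIFEST = "manifest.json"
_PSEUDO_FA = "pseudo.fa"
_GENOME_FA = "genome.fa"
_ORIGIN_TSV = "origin.tsv"
_CPG_BED = "cpg.bed"
_INDEX_VERSION = 1


def _write_fasta(path: Path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in records.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def write_index(pg: PseudoGenome, idx: CpGIndex, ref: ReferenceGenome, out_dir) -> dict:
    """Persist pseudo-genome, origin table, CpG index, normalized reference
    and a checksummed manifest.  Returns the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_fasta(out_dir / _PSEUDO_FA, pg.pseudo_chromosomes)
    _write_fasta(out_dir / _GENOME_FA, ref.chromosomes)
    with open(out_dir / _ORIGIN_TSV, "w") as out:
        out.write("pseudo_name\torig_name\tstrand\tlength\n")
        for pname, o in pg.origin.items():
            out.write(f"{pname}\t{o.chrom}\t{o.strand}\t{o.length}\n")
    with open(out_dir / _CPG_BED, "w") as out:
        for chrom, positions in idx.sites.items():
            for p in positions:
                out.write(f"{chrom}\t{p}\t{p + 1}\n")
    manifest = {
        "format_version": _INDEX_VERSION,
        "mode": pg.mode,
        "spike_in_names": sorted(ref.spike_in_names),
        "chromosomes": list(ref.chromosomes),
        "checksums": {
            f: md5sum(out_dir / f)
            for f in (_PSEUDO_FA, _GENOME_FA, _ORIGIN_TSV, _CPG_BED)
        },
    }
    with open(out_dir / _MANIFEST, "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
    return manifest


def load_index(index_dir, expected_mode=None) -> tuple[PseudoGenome, CpGIndex, ReferenceGenome]:
    """Load a persisted index, verifying checksums and (optionally) mode."""
    index_dir = Path(index_dir)
    manifest_path = index_dir / _MANIFEST
    if not manifest_path.exists():
        raise IndexError_(f"no index manifest at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if expected_mode is not None:
        expected_mode = normalize_mode(expected_mode)
        if manifest["mode"] != expected_mode:
            raise IndexError_(
                f"index was built in {manifest['mode']} mode but "
                f"{expected_mode} was requested; rebuild the index")
    for fname, digest in manifest["checksums"].items():
        actual = md5sum(index_dir / fname)
        if actual != digest:
            raise IndexError_(f"checksum mismatch for {fname}: index is corrupt")

    origin: dict[str, PseudoOrigin] = {}
    with open(index_dir / _ORIGIN_TSV) as fh:
        next(fh)
        for line in fh:
            pname, oname, strand, length = line.rstrip("\n").split("\t")
            origin[pname] = PseudoOrigin(oname, strand, int(length))

    def read_fasta(path: Path) -> dict[str, str]:
        with open(path) as handle:
            return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}

    pg = PseudoGenome(read_fasta(index_dir / _PSEUDO_FA), origin, manifest["mode"])
    ref = ReferenceGenome(read_fasta(index_dir / _GENOME_FA),
                          frozenset(manifest["spike_in_names"]))

    sites: dict[str, list[int]] = {chrom: [] for chrom in ref.chromosomes}
    with open(index_dir / _CPG_BED) as fh:
        for line in fh:
            chrom, start, _ = line.split("\t")
            sites[chrom].append(int(start))
    return pg, CpGIndex(sites), ref
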