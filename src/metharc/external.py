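"""Adapter for running Bowtie2 or Hisat2 over the pseudo-genome FASTA.

The external aligner sees only the converted pseudo-genome and the
letter-converted reads; its SAM output is parsed into
:class:`~metharc.align.PseudoAlignment` records which then flow through
the same restoration path as the builtin aligner.  The adapter expects
the aligner's OWN index to have been built over ``pseudo.fa`` in the
index directory (``bowtie2-build`` / ``hisat2-build``).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from pathlib import Path
from typing import Iterator

from metharc.align import MAPQ_UNIQUE, PseudoAlignment

log = logging.getLogger(__name__)

SUPPORTED = ("bowtie2", "hisat2")


class ExternalAlignerError(RuntimeError):
    pass


def require_binary(aligner: str) -> str:
    if aligner not in SUPPORTED:
        raise ExternalAlignerError(f"unsupported external aligner: {aligner}")
    path = shutil.which(aligner)
    if path is None:
        raise ExternalAlignerError(
            f"{aligner} not found on PATH; install it or use --aligner builtin")
    return path


def build_command(aligner: str, index_prefix, r1, r2=None, threads: int = 1) -> list[str]:
    cmd = [aligner, "-x", str(index_prefix), "--no-unal", "-p", str(threads)]
    if aligner == "bowtie2":
        cmd += ["--end-to-end", "--no-mixed", "--no-discordant"]
    else:
        cmd += ["--no-spliced-alignment", "--no-mixed", "--no-discordant"]
    if r2 is not None:
        cmd += ["-1", str(r1), "-2", str(r2)]
    else:
        cmd += ["-U", str(r1)]
    return cmd


def parse_sam_line(line: str) -> PseudoAlignment | None:
    """Decode one SAM body line into a PseudoAlignment (None for unmapped)."""
    fields = line.rstrip("\n").split("\t")
    flag = int(fields[1])
    if flag & 0x4:
        return None
    mate = 2 if flag & 0x80 else 1
    return PseudoAlignment(
        read_id=fields[0],
        mate=mate,
        pseudo_chrom=fields[2],
        pseudo_pos=int(fields[3]) - 1,
        cigar=fields[5],
        mapq=int(fields[4]),
        reverse_flag=bool(flag & 0x10),
        is_multi=int(fields[4]) == 0,
    )


def external_align(r1_path, index_prefix, aligner: str = "bowtie2",
                   r2_path=None, threads: int = 1) -> Iterator[PseudoAlignment]:
    """Run the external aligner and yield parsed pseudo-alignments."""
    binary = require_binary(aligner)
    try:
        version = subprocess.run([binary, "--version"], capture_output=True,
                                 text=True, check=False).stdout.splitlines()[:1]
        log.info("%s version: %s", aligner, version[0] if version else "?")
    except Exception:  # pragma: no cover - cosmetic only
        log.warning("could not determine %s version", aligner)
    cmd = build_command(aligner, index_prefix, r1_path, r2_path, threads)
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        tail = "\n".join(proc.stderr.splitlines()[-10:])
        raise ExternalAlignerError(f"{aligner} failed (exit {proc.returncode}):\n{tail}")
    for line in proc.stdout.splitlines():
        if line.startswith("@"):
            continue
        pa = parse_sam_line(line)
        if pa is not None:
            yield pa
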