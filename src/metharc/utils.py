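"""Small shared helpers: complements, gzip-transparent IO, checksums."""

from __future__ import annotations

import gzip
import hashlib
import io
from pathlib import Path

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def open_text(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file.

    Writing with a ``.gz`` suffix produces a gzip stream with mtime pinned
    to 0 so identical content yields byte-identical files.
    """
    path = Path(path)
    if path.suffix == ".gz":
        if "r" in mode:
            return gzip.open(path, mode)
        raw = open(path, mode.replace("t", "") + "b" if "b" not in mode else mode)
        gz = gzip.GzipFile(fileobj=raw, mode="wb", mtime=0)
        return io.TextIOWrapper(gz, encoding="ascii", newline="\n")
    return open(path, mode)


def md5sum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
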