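"""Small I/O helpers shared across the pipeline stages.

FASTQ/FASTA reading goes through Biopython's low-level iterators; writing is
done with deterministic gzip (mtime pinned to 0) so that identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import os
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

PHRED_OFFSET = 33


def open_text(path: str, mode: str = "rt"):
    """Open a possibly gzipped text file; gzip output is deterministic."""
    if str(path).endswith(".gz"):
        if "w" in mode:
            raw = open(path, "wb")
            gz = gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
            return io.TextIOWrapper(gz, newline="\n")
        return gzip.open(path, "rt")
    return open(path, mode)


def read_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) tuples from a FASTQ file."""
    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path: str, records: Iterable[tuple[str, str, str]]) -> int:
    n = 0
    with open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"record {rid}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str) -> Iterator[tuple[str, str]]:
    with open_text(path) as fh:
        for name, seq in SimpleFastaParser(fh):
            yield name.split()[0], seq.upper()


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 80) -> int:
    n = 0
    with open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def quals_to_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def string_to_quals(s: str) -> list[int]:
    quals = [ord(c) - PHRED_OFFSET for c in s]
    if any(q < 0 or q > 93 for q in quals):
        raise ValueError("quality string is not Phred+33 decodable")
    return quals


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
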