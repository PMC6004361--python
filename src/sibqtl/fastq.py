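"""Paired-FASTQ plumbing shared by the simulator, demultiplexer and genotyper.

Reads travel through the pipeline as ``ReadPair`` tuples; file round-trips use
plain (or gzipped) FASTQ via pysam.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator, NamedTuple

import pysam


class ReadPair(NamedTuple):
    name: str
    seq1: str
    seq2: str


# constant placeholder qualities (Q30), fixed read length 150
READ_LENGTH = 150
QUAL_CHAR = chr(30 + 33)


def _open_text(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_paired_fastq(pairs: Iterable[ReadPair], path1: str, path2: str) -> int:
    """Write synchronized R1/R2 FASTQ files; returns the pair count."""
    n = 0
    with _open_text(path1, "w") as f1, _open_text(path2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.name}/1\n{pair.seq1}\n+\n{QUAL_CHAR * len(pair.seq1)}\n")
            f2.write(f"@{pair.name}/2\n{pair.seq2}\n+\n{QUAL_CHAR * len(pair.seq2)}\n")
            n += 1
    return n


def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def iter_paired_fastq(path1: str, path2: str) -> Iterator[ReadPair]:
    """Iterate synchronized read pairs; raises on desynchronized inputs."""
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        sentinel = object()
        it2 = iter(f2)
        for rec1 in f1:
            rec2 = next(it2, sentinel)
            if rec2 is sentinel:
                raise ValueError("R2 FASTQ has fewer reads than R1")
            n1, n2 = _strip_mate(rec1.name), _strip_mate(rec2.name)
            if n1 != n2:
                raise ValueError(f"desynchronized FASTQ pair: {n1!r} vs {n2!r}")
            yield ReadPair(n1, rec1.sequence, rec2.sequence)
        if next(it2, sentinel) is not sentinel:
            raise ValueError("R2 FASTQ has more reads than R1")
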