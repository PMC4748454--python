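"""FASTQ input/output helpers (Phred+33, plain or gzipped).

Thin wrappers over Biopython's FastqGeneralIterator so the pipeline stages can
stream millions of reads as lightweight records without per-read object cost.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


class ReadRecord(NamedTuple):
    """A sequencing read: identifier, DNA sequence and Phred+33 quality string."""

    id: str
    sequence: str
    qualities: str

    def phred_scores(self) -> list[int]:
        """Per-base Phred scores as integers."""
        return [ord(c) - PHRED_OFFSET for c in self.qualities]


def encode_phred(scores: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in scores)


def _open_text(path: str | Path, mode: str) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream records from a plain or gzipped FASTQ file.

    Raises ValueError (from Biopython) on malformed records, annotated with the
    file path.
    """
    with _open_text(path, "r") as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield ReadRecord(title.split()[0], seq.upper(), qual)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def write_fastq(path: str | Path, reads: Iterable[ReadRecord]) -> int:
    """Write records to a plain or gzipped FASTQ file; returns the read count."""
    n = 0
    with _open_text(path, "w") as handle:
        for rec in reads:
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.qualities}\n")
            n += 1
    return n
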