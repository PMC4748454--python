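"""Read-level quality control for small-RNA sequencing data.

Three screens, applied in this order:

1. whole-read retention by median Phred quality (reads with median < Q30 are
   dropped; "quality clipping" here means read rejection, not 3' base trimming),
2. 3' adapter removal by exact substring match (full adapter anywhere in the
   read, or a >= ``min_overlap``-base adapter prefix at the read's 3' end),
3. length window filter: only inserts of 15-35 nt (inclusive) are miRNA-sized.

Length is only meaningful after adapter removal, so the length screen runs
last. The QCReport partitions the input exactly:
``reads_in == reads_out + failed_median_q + length_filtered``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._fastq import PHRED_OFFSET, ReadRecord, read_fastq, write_fastq

DEFAULT_MIN_MEDIAN_Q = 30
DEFAULT_MIN_LEN = 15
DEFAULT_MAX_LEN = 35

_VALID_BASES = set("ACGTN")


@dataclass
class QCReport:
    """Per-sample accounting of the QC screens.

    Counts partition the input: every read is either emitted (``reads_out``)
    or attributed to exactly one rejection reason.
    """

    reads_in: int = 0
    failed_median_q: int = 0
    adapter_trimmed: int = 0
    length_filtered: int = 0
    reads_out: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.reads_in != self.reads_out + self.failed_median_q + self.length_filtered:
            raise AssertionError("QCReport counts do not partition the input")
        if sum(self.length_histogram.values()) != self.reads_out:
            raise AssertionError("length histogram does not total reads_out")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["metric\tvalue"]
        for key in ("reads_in", "failed_median_q", "adapter_trimmed",
                    "length_filtered", "reads_out"):
            lines.append(f"{key}\t{getattr(self, key)}")
        for length in sorted(self.length_histogram):
            lines.append(f"length_{length}\t{self.length_histogram[length]}")
        Path(path).write_text("\n".join(lines) + "\n")


def median_quality(qualities: Sequence[int] | str) -> int:
    """Median Phred score of a read; the lower-middle value for even lengths.

    The lower-middle convention keeps the >= Q30 screen integer-exact.
    Accepts either a sequence of integer scores or a Phred+33 string.
    """
    if len(qualities) == 0:
        raise ValueError("median_quality of an empty quality vector")
    if isinstance(qualities, str):
        scores = sorted(ord(c) - PHRED_OFFSET for c in qualities)
    else:
        scores = sorted(qualities)
    return scores[(len(scores) - 1) // 2]


def trim_adapter(read: ReadRecord, adapter: str, min_overlap: int = 5) -> ReadRecord:
    """Remove the 3' sequencing adapter from a read, if present.

    The read is truncated at the leftmost exact occurrence of the full adapter;
    failing that, at the longest read-suffix that exactly equals an adapter
    prefix of length >= ``min_overlap``. Qualities are truncated in lockstep.
    A read without adapter evidence is returned unchanged. Trimming repeats
    until no adapter evidence remains, so the operation is idempotent.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    adapter = adapter.upper()
    seq, qual = read.sequence, read.qualities
    while seq:
        cut = seq.find(adapter)
        if cut < 0:
            cut = len(seq)
            max_k = min(len(adapter) - 1, len(seq))
            for k in range(max_k, min_overlap - 1, -1):
                if seq.endswith(adapter[:k]):
                    cut = len(seq) - k
                    break
        if cut == len(seq):
            break
        seq, qual = seq[:cut], qual[:cut]
    if seq == read.sequence:
        return read
    return ReadRecord(read.id, seq, qual)


def qc_filter(
    reads: Iterable[ReadRecord],
    adapter: str,
    min_median_q: int = DEFAULT_MIN_MEDIAN_Q,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_overlap: int = 5,
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the quality screen, adapter trim and length window, in order.

    Order-preserving. Each input read is counted once in the report, under
    ``reads_out``, ``failed_median_q`` or ``length_filtered``.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    adapter = adapter.upper()
    if not set(adapter) <= _VALID_BASES:
        raise ValueError(f"adapter contains non-ACGTN characters: {adapter!r}")
    report = QCReport()
    out: list[ReadRecord] = []
    hist = report.length_histogram
    for read in reads:
        report.reads_in += 1
        if len(read.sequence) != len(read.qualities):
            raise ValueError(f"malformed read {read.id!r}: sequence/quality length mismatch")
        if median_quality(read.qualities) < min_median_q:
            report.failed_median_q += 1
            continue
        trimmed = trim_adapter(read, adapter, min_overlap)
        if len(trimmed.sequence) < len(read.sequence):
            report.adapter_trimmed += 1
        n = len(trimmed.sequence)
        if n < min_len or n > max_len:
            report.length_filtered += 1
            continue
        out.append(trimmed)
        report.reads_out += 1
        hist[n] = hist.get(n, 0) + 1
    report.check()
    return out, report


def qc_file(
    in_path: str | Path,
    out_path: str | Path,
    adapter: str,
    report_path: str | Path | None = None,
    **kwargs,
) -> QCReport:
    """File-to-file convenience wrapper around :func:`qc_filter`."""
    clean, report = qc_filter(read_fastq(in_path), adapter, **kwargs)
    write_fastq(out_path, clean)
    if report_path is not None:
        report.to_tsv(report_path)
    return report
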