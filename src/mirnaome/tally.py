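"""Condense cleaned reads into unique-sequence count tables.

The "extract and count" step: millions of reads collapse to a table mapping
each distinct insert sequence to its occurrence count, which is what the
mapper consumes. Count conservation holds by construction: the tally counts
sum to the number of input reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._fastq import ReadRecord


@dataclass
class TallyTable:
    """Unique sequence -> count for one sample."""

    sample_id: str
    entries: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def sorted_items(self) -> list[tuple[str, int]]:
        """Descending count, ties broken lexicographically — the serial order."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for seq, count in self.sorted_items():
                handle.write(f"{seq}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "TallyTable":
        path = Path(path)
        if sample_id is None:
            sample_id = path.name.split(".")[0]
        entries: dict[str, int] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    seq, count = line.split("\t")
                    entries[seq] = int(count)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed tally line {line!r}") from exc
        return cls(sample_id, entries)


def build_tally(reads: Iterable[ReadRecord | str], sample_id: str) -> TallyTable:
    """Exact multiset count of read sequences (accepts records or bare strings)."""
    counter: Counter[str] = Counter(
        r.sequence if isinstance(r, ReadRecord) else r for r in reads
    )
    return TallyTable(sample_id, dict(counter))
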