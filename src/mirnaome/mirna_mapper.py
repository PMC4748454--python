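"""Mismatch-tolerant assignment of tally sequences to mature miRNAs.

A query sequence hits a reference entry when the shorter of the two is fully
contained in the longer at some ungapped offset with Hamming distance at most
``max_mismatch`` over the overlap (default 1). Containment tolerates the 3'
length jitter real small-RNA reads exhibit; an exact end-to-end mode
(equal-length, whole-sequence comparison) is available via ``mode``.

Assignment is at minimal distance. When two or more entries tie at the
minimum the sequence is ambiguous, and the policy decides:

* ``discard`` (default) — counted as unmapped, flagged; keeps counts integral,
* ``split``   — its count is divided equally among the tied entries,
* ``first``   — assigned to the lexicographically smallest tied name.

Candidate generation uses an exact-substring hash with a pigeonhole split: if
the shorter sequence matches within the longer with <= 1 mismatch, at least
one of its halves matches exactly. The index is an engineering device only —
its contract is defined (and tested) against an exhaustive all-entries,
all-offsets Hamming scan.

``N`` bases never match anything, so they always count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

UNMAPPED = "UNMAPPED"

MIN_SEQ_LEN = 15
MAX_SEQ_LEN = 35


@dataclass
class MatureReference:
    """Named mature-miRNA sequences the mapper indexes."""

    entries: dict[str, str]
    version: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty reference")
        clean: dict[str, str] = {}
        for name, seq in self.entries.items():
            seq = seq.upper().replace("U", "T")
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"reference entry {name!r} has non-ACGT characters")
            if not MIN_SEQ_LEN <= len(seq) <= MAX_SEQ_LEN:
                raise ValueError(
                    f"reference entry {name!r} length {len(seq)} outside "
                    f"[{MIN_SEQ_LEN},{MAX_SEQ_LEN}]"
                )
            clean[name] = seq
        if len(clean) != len(self.entries):
            raise ValueError("duplicate reference names")
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for name, seq in self.entries.items():
                handle.write(f">{name}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path: str | Path, version: str | None = None) -> "MatureReference":
        entries = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not entries:
            raise ValueError(f"no FASTA records in {path}")
        return cls(entries, version or Path(path).name)


@dataclass(frozen=True)
class Assignment:
    """Outcome of mapping one sequence."""

    sequence: str
    mirna: str                      # a reference name, or UNMAPPED
    mismatches: int | None          # distance used; None when no hit exists
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()


def _hamming_at_most(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, or limit+1 once it exceeds limit.

    An N in either string is always a mismatch.
    """
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _containment_distance(query: str, entry: str, limit: int) -> int | None:
    """Best Hamming distance over all full-containment offsets, or None."""
    if len(query) <= len(entry):
        short, long_ = query, entry
    else:
        short, long_ = entry, query
    n = len(long_) - len(short)
    best: int | None = None
    for off in range(n + 1):
        mm = _hamming_at_most(short, long_[off:off + len(short)], limit)
        if mm <= limit and (best is None or mm < best):
            best = mm
            if best == 0:
                break
    return best


class MirnaMapper:
    """Reusable mapper holding the pigeonhole substring index for a reference."""

    def __init__(
        self,
        reference: MatureReference,
        max_mismatch: int = 1,
        mode: str = "containment",
        ambiguous: str = "discard",
    ) -> None:
        if len(reference) == 0:
            raise ValueError("empty reference")
        if mode not in ("containment", "end_to_end"):
            raise ValueError(f"unknown mode {mode!r}")
        if ambiguous not in ("discard", "split", "first"):
            raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        self.reference = reference
        self.max_mismatch = max_mismatch
        self.mode = mode
        self.ambiguous = ambiguous
        self._build_index()
        self._cache: dict[str, Assignment] = {}

    # -- index ------------------------------------------------------------

    def _build_index(self) -> None:
        # Substrings of entries, length 7..18, -> [(name, start)].  Query
        # halves of 15-35 nt sequences fall in that length band.
        self._sub_index: dict[str, list[tuple[str, int]]] = {}
        # Entry halves -> [(name, half offset, entry length)] for the
        # entry-contained-in-query direction.
        self._half_index: dict[str, list[tuple[str, int, int]]] = {}
        self._half_lengths: set[int] = set()
        for name, seq in self.reference.entries.items():
            L = len(seq)
            for sub_len in range(7, min(18, L) + 1):
                for start in range(L - sub_len + 1):
                    key = seq[start:start + sub_len]
                    self._sub_index.setdefault(key, []).append((name, start))
            mid = L // 2
            for half, off in ((seq[:mid], 0), (seq[mid:], mid)):
                self._half_index.setdefault(half, []).append((name, off, L))
                self._half_lengths.add(len(half))

    def _candidate_offsets(self, seq: str) -> set[tuple[str, int]]:
        """(entry name, alignment offset) pairs to verify by Hamming check.

        Offset is the position of the shorter sequence within the longer, with
        sign conventions handled by the caller via entry length.
        """
        cands: set[tuple[str, int]] = set()
        L = len(seq)
        entries = self.reference.entries
        mid = L // 2
        # query contained in entry: one query half matches a substring exactly
        for half, qoff in ((seq[:mid], 0), (seq[mid:], mid)):
            for name, start in self._sub_index.get(half, ()):
                off = start - qoff
                if 0 <= off <= len(entries[name]) - L:
                    cands.add((name, off))
        # entry contained in query: one entry half appears in the query
        for half_len in self._half_lengths:
            for i in range(L - half_len + 1):
                for name, hoff, elen in self._half_index.get(seq[i:i + half_len], ()):
                    off = i - hoff
                    if elen <= L and 0 <= off <= L - elen:
                        cands.add((name, off))
        return cands

    # -- mapping ----------------------------------------------------------

    def _best_hits(self, seq: str) -> tuple[list[str], int | None]:
        limit = self.max_mismatch
        entries = self.reference.entries
        best: int | None = None
        hits: dict[str, int] = {}
        if self.mode == "end_to_end":
            for name, ref_seq in entries.items():
                if len(ref_seq) != len(seq):
                    continue
                mm = _hamming_at_most(seq, ref_seq, limit)
                if mm <= limit:
                    hits[name] = min(mm, hits.get(name, limit))
        else:
            for name, off in self._candidate_offsets(seq):
                ref_seq = entries[name]
                if len(seq) <= len(ref_seq):
                    mm = _hamming_at_most(seq, ref_seq[off:off + len(seq)], limit)
                else:
                    mm = _hamming_at_most(ref_seq, seq[off:off + len(ref_seq)], limit)
                if mm <= limit:
                    prev = hits.get(name)
                    if prev is None or mm < prev:
                        hits[name] = mm
        if not hits:
            return [], None
        best = min(hits.values())
        return sorted(n for n, mm in hits.items() if mm == best), best

    def map_sequence(self, seq: str) -> Assignment:
        seq = seq.upper()
        if not MIN_SEQ_LEN <= len(seq) <= MAX_SEQ_LEN:
            raise ValueError(
                f"sequence length {len(seq)} outside [{MIN_SEQ_LEN},{MAX_SEQ_LEN}]; "
                "run the QC length filter first"
            )
        cached = self._cache.get(seq)
        if cached is not None:
            return cached
        names, best = self._best_hits(seq)
        if not names:
            result = Assignment(seq, UNMAPPED, None)
        elif len(names) == 1:
            result = Assignment(seq, names[0], best, False, (names[0],))
        else:
            tied = tuple(names)
            if self.ambiguous == "first":
                result = Assignment(seq, names[0], best, True, tied)
            else:  # discard and split both carry the full candidate set
                target = UNMAPPED if self.ambiguous == "discard" else names[0]
                result = Assignment(seq, target, best, True, tied)
        self._cache[seq] = result
        return result


def map_sequence(
    seq: str,
    reference: MatureReference,
    max_mismatch: int = 1,
    mode: str = "containment",
    ambiguous: str = "discard",
) -> Assignment:
    """One-shot convenience wrapper; builds a throwaway index."""
    return MirnaMapper(reference, max_mismatch, mode, ambiguous).map_sequence(seq)


@dataclass
class CountMatrix:
    """miRNA x sample mapped-read counts plus per-sample totals.

    ``counts`` rows are miRNAs, columns samples. With the ``split`` ambiguity
    policy cells may be fractional; otherwise they are integers.
    """

    counts: pd.DataFrame
    unmapped: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unmapped is None:
            self.unmapped = pd.Series(0.0, index=self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def mapped_total(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="miRNA")

    def summary_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"mapped_total": self.mapped_total, "unmapped": self.unmapped}
        ).to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path, summary: str | Path | None = None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        unmapped = None
        if summary is not None:
            unmapped = pd.read_csv(summary, sep="\t", index_col=0)["unmapped"]
        return cls(counts, unmapped)


def count_matrix(
    tallies: Sequence,
    reference: MatureReference,
    max_mismatch: int = 1,
    mode: str = "containment",
    ambiguous: str = "discard",
) -> CountMatrix:
    """Assign every tally sequence and accumulate per-miRNA, per-sample counts.

    ``tallies`` is a sequence of TallyTable-like objects (``sample_id`` plus an
    ``entries`` mapping). The mapper's assignment cache is shared across
    samples, so each distinct sequence is aligned once per cohort.
    """
    sample_ids = [t.sample_id for t in tallies]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids: {sample_ids}")
    mapper = MirnaMapper(reference, max_mismatch, mode, ambiguous)
    names = list(reference.entries)
    counts = pd.DataFrame(0.0, index=names, columns=sample_ids)
    unmapped = pd.Series(0.0, index=sample_ids)
    for table in tallies:
        sid = table.sample_id
        col = counts[sid].to_dict()
        un = 0.0
        for seq, n in table.entries.items():
            asg = mapper.map_sequence(seq)
            if asg.mirna == UNMAPPED:
                un += n
            elif asg.ambiguous and ambiguous == "split":
                share = n / len(asg.candidates)
                for name in asg.candidates:
                    col[name] += share
            else:
                col[asg.mirna] += n
        counts[sid] = pd.Series(col)
        unmapped[sid] = un
    if ambiguous != "split":
        counts = counts.astype(int)
    return CountMatrix(counts, unmapped)
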