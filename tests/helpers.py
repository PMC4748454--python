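"""Independent brute-force oracles the implementation is checked against.

Deliberately naive: exhaustive scans and double loops, sharing no code with
the package internals they verify.
"""

from __future__ import annotations


def oracle_hamming(a: str, b: str) -> int:
    """Mismatches between equal-length strings; N never matches anything."""
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def oracle_best_hits(seq, entries, max_mismatch, mode="containment"):
    """Exhaustive all-entries, all-offsets scan.

    Returns (sorted candidate names at the minimal distance, that distance)
    or ([], None) when nothing is within max_mismatch.
    """
    distances = {}
    for name, ref in entries.items():
        if mode == "end_to_end":
            if len(ref) != len(seq):
                continue
            d = oracle_hamming(seq, ref)
            if d <= max_mismatch:
                distances[name] = d
        else:
            short, long_ = (seq, ref) if len(seq) <= len(ref) else (ref, seq)
            best = None
            for off in range(len(long_) - len(short) + 1):
                d = oracle_hamming(short, long_[off:off + len(short)])
                if d <= max_mismatch and (best is None or d < best):
                    best = d
            if best is not None:
                distances[name] = best
    if not distances:
        return [], None
    dmin = min(distances.values())
    return sorted(n for n, d in distances.items() if d == dmin), dmin


def oracle_detection_filter(counts_df, min_reads, min_subjects):
    """Double-loop reimplementation of the detection filter."""
    survivors = []
    for mirna in counts_df.index:
        total = 0
        present = 0
        for sample in counts_df.columns:
            c = counts_df.loc[mirna, sample]
            total += c
            if c > 0:
                present += 1
        if total >= min_reads and present >= min_subjects:
            survivors.append(mirna)
    return survivors


def oracle_sem(values) -> float:
    """Two-pass sample SD / sqrt(n)."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return (var ** 0.5) / (n ** 0.5)
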