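"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (per-window loops, per-base boolean
arrays) and shares no code with the package's scanners or interval
algebra.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T", "N"},
}

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
         "D": "H", "H": "D", "N": "N"}


def naive_revcomp(pattern: str) -> str:
    return "".join(_COMP[c] for c in reversed(pattern))


def naive_consensus_hits(seq: str, pattern: str, strand_policy: str
                         ) -> list[tuple[int, int, str]]:
    """All (start, end, strand) 1-based windows matching the IUPAC pattern."""
    def window_hits(pat: str, strand: str):
        L = len(pat)
        for i in range(len(seq) - L + 1):
            if all(seq[i + j] in IUPAC_SETS[pat[j]] for j in range(L)):
                yield (i + 1, i + L, strand)

    hits = list(window_hits(pattern, "+"))
    if strand_policy == "both":
        rc = naive_revcomp(pattern)
        if rc != pattern:
            hits.extend(window_hits(rc, "-"))
    return sorted(hits)


def naive_pwm_hits(seq: str, matrix: np.ndarray, threshold_frac: float,
                   strand_policy: str) -> list[tuple[int, int, str, float]]:
    """All windows scoring >= threshold_frac * max attainable score."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    min_score = threshold_frac * sum(max(row) for row in matrix)

    def scan(m: np.ndarray, strand: str):
        L = len(m)
        for i in range(len(seq) - L + 1):
            window = seq[i:i + L]
            if "N" in window:
                continue
            score = sum(m[j][idx[window[j]]] for j in range(L))
            if score >= min_score:
                yield (i + 1, i + L, strand, score)

    hits = list(scan(matrix, "+"))
    if strand_policy == "both":
        rc = matrix[::-1, ::-1]
        if not np.array_equal(rc, matrix):
            hits.extend(scan(rc, "-"))
    return sorted(hits, key=lambda h: h[:3])


class BooleanLayer:
    """Per-base boolean-array model of a single layer on one chromosome."""

    def __init__(self, length: int):
        self.mask = np.zeros(length, dtype=bool)

    def set_present(self, start: int, end: int) -> None:
        self.mask[start - 1:end] = True

    def set_absent(self, start: int, end: int) -> None:
        self.mask[start - 1:end] = False

    def runs(self) -> list[tuple[int, int]]:
        out, start = [], None
        for i, on in enumerate(self.mask):
            if on and start is None:
                start = i + 1
            elif not on and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(self.mask)))
        return out


def naive_coverage(interval_lists: list[list[tuple[int, int]]], length: int
                   ) -> np.ndarray:
    """Per-base count of how many interval lists contain each base."""
    counts = np.zeros(length, dtype=int)
    for ivs in interval_lists:
        mask = np.zeros(length, dtype=bool)
        for s, e in ivs:
            mask[s - 1:e] = True
        counts += mask
    return counts
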