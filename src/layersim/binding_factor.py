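"""Binding factors: sequence profiles, layer predicates, and hit matching.

A binding factor models a molecule (or a piece of regulatory logic) that
recognises a combination of genome sequence and layer states and, where
it matches, applies modifications to the layers.  Sequence recognition
comes in three pattern languages:

``consensus``
    an IUPAC degenerate string; every window that matches is reported,
    overlapping occurrences included, optionally on both strands.
``pwm``
    a position weight matrix of log-odds scores; every window scoring at
    least ``threshold × max attainable score`` is reported with its score.
``regex``
    a grep-style regular expression; non-overlapping leftmost matches on
    the forward strand (the standard regex engine contract).

A profile of kind ``none`` matches by layer state alone: its candidate
sites are the maximal intervals of the first layer its predicate requires
present.  Predicates are conjunctions of (layer, present|absent) terms; a
``present`` term holds when the candidate footprint overlaps the layer by
at least 1 bp (partial-overlap recruitment at mark edges — switchable to
full containment), ``absent`` when the overlap is zero.

Because the genome never changes, sequence scans can be cached on the
layer set and reused across cycles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .genome_io import GenomeRef, reverse_complement
from .layer_model import Interval, LayerSet

IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    # N is a wildcard and is the only profile character an N base matches
    "N": "ACGTN",
}

_CODE = {b: i for i, b in enumerate("ACGTN")}


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceProfile:
    """A sequence pattern in one of the supported languages."""

    kind: str  # consensus | pwm | regex | none
    pattern: Optional[str] = None
    matrix: Optional[np.ndarray] = None  # (L, 4) log-odds, pwm only
    threshold: float = 0.90  # fraction of max attainable score, pwm only
    strand_policy: str = "both"  # forward | both

    def __post_init__(self):
        if self.kind not in ("consensus", "pwm", "regex", "none"):
            raise ProfileError(f"unknown profile kind {self.kind!r}")
        if self.strand_policy not in ("forward", "both"):
            raise ProfileError(f"bad strand_policy {self.strand_policy!r}")
        if self.kind == "consensus":
            if not self.pattern:
                raise ProfileError("consensus pattern must be non-empty")
            bad = set(self.pattern.upper()) - set(IUPAC_CLASSES)
            if bad:
                raise ProfileError(f"non-IUPAC characters in consensus: {bad}")
        elif self.kind == "pwm":
            if self.matrix is None or self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
                raise ProfileError("pwm needs an (L, 4) log-odds matrix")
            if not (0 < self.threshold <= 1):
                raise ProfileError("pwm threshold must be in (0, 1]")
        elif self.kind == "regex":
            if not self.pattern:
                raise ProfileError("regex pattern must be non-empty")
            try:
                re.compile(self.pattern)
            except re.error as exc:
                raise ProfileError(f"invalid regex: {exc}") from exc
        elif self.kind == "none" and (self.pattern or self.matrix is not None):
            raise ProfileError("kind 'none' takes no pattern")

    @classmethod
    def from_counts(cls, counts: np.ndarray, threshold: float = 0.90,
                    strand_policy: str = "both",
                    pseudocount: float = 0.25) -> "SequenceProfile":
        """Build a PWM profile from a JASPAR-style (L, 4) count matrix.

        Log-odds against a uniform background with ``pseudocount`` added
        to every cell.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ProfileError("count matrix must be (L, 4) over A/C/G/T")
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
        logodds = np.log2(probs / 0.25)
        return cls(kind="pwm", matrix=logodds, threshold=threshold,
                   strand_policy=strand_policy)

    def fingerprint(self) -> str:
        if self.kind == "pwm":
            body = self.matrix.tobytes().hex() + f":{self.threshold}"
        else:
            body = self.pattern or ""
        return f"{self.kind}:{body}:{self.strand_policy}"


@dataclass(frozen=True)
class PredicateTerm:
    layer: str
    required: str  # present | absent

    def __post_init__(self):
        if self.required not in ("present", "absent"):
            raise ProfileError(f"predicate term requires present/absent, "
                               f"got {self.required!r}")


@dataclass(frozen=True)
class LayerPredicate:
    """Conjunction of (layer, present|absent) terms; empty = always true."""

    terms: tuple[PredicateTerm, ...] = ()

    def __post_init__(self):
        names = [t.layer for t in self.terms]
        if len(set(names)) != len(names):
            raise ProfileError("duplicate layer in predicate")

    @classmethod
    def of(cls, *pairs: tuple[str, str]) -> "LayerPredicate":
        return cls(tuple(PredicateTerm(l, r) for l, r in pairs))

    @property
    def first_present_layer(self) -> Optional[str]:
        for t in self.terms:
            if t.required == "present":
                return t.layer
        return None


@dataclass(frozen=True)
class Modification:
    layer: str
    new_state: str  # present | absent

    def __post_init__(self):
        if self.new_state not in ("present", "absent"):
            raise ProfileError(f"modification state must be present/absent")


@dataclass(frozen=True, order=True)
class Hit:
    """One candidate match footprint (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float = 1.0


@dataclass
class BindingFactor:
    """Profile + predicate + modifications + placement geometry.

    ``statewidth`` is the width of the modified region around a match,
    independent of the match's own width; it may be an int, a sampler of
    positive ints, or the string ``"match"`` (modify exactly the matched
    footprint).  ``offset_sampler`` displaces the modification centre; by
    default there is no displacement.
    """

    name: str
    profile: SequenceProfile
    predicate: LayerPredicate = LayerPredicate()
    mods: Sequence[Modification] = ()
    statewidth: Union[int, str, "Sampler"] = "match"  # noqa: F821
    offset_sampler: Optional["Sampler"] = None  # noqa: F821
    cacheable: bool = False

    def __post_init__(self):
        if self.profile.kind == "none" and not self.predicate.terms:
            raise ProfileError(
                f"factor {self.name}: needs a sequence profile or a predicate")
        if not self.mods:
            raise ProfileError(f"factor {self.name}: needs at least one modification")


class HitCache:
    """Profile-fingerprint → hit list cache, with a scan counter.

    The genome is immutable, so a cached list always equals a fresh scan.
    """

    def __init__(self):
        self._store: dict[str, list[Hit]] = {}
        self.scan_count = 0

    def get_or_scan(self, genome: GenomeRef, profile: SequenceProfile) -> list[Hit]:
        key = profile.fingerprint()
        if key not in self._store:
            self.scan_count += 1
            self._store[key] = find_sequence_hits(genome, profile)
        return self._store[key]


# ---------------------------------------------------------------------------
# Sequence scanning
# ---------------------------------------------------------------------------

def _consensus_regex(pattern: str) -> str:
    return "".join(f"[{IUPAC_CLASSES[c]}]" for c in pattern.upper())


def _scan_consensus(seq: str, pattern: str) -> list[int]:
    """0-based start positions of every (overlapping) consensus match."""
    rx = re.compile(f"(?=(?:{_consensus_regex(pattern)}))")
    return [m.start() for m in rx.finditer(seq)]


def _scan_pwm(seq: str, matrix: np.ndarray, min_score: float
              ) -> list[tuple[int, float]]:
    """0-based (start, score) of windows scoring >= min_score.

    Windows containing N score -inf and never pass.
    """
    L = matrix.shape[0]
    n = len(seq) - L + 1
    if n <= 0:
        return []
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    codes = lut[codes]
    ext = np.hstack([matrix, np.full((L, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    scores = ext[np.arange(L)[None, :], windows].sum(axis=1)
    idx = np.flatnonzero(scores >= min_score)
    return [(int(i), float(scores[i])) for i in idx]


def find_sequence_hits(genome: GenomeRef, profile: SequenceProfile) -> list[Hit]:
    """Scan the genome for a profile; hits sorted by (chrom, start)."""
    if profile.kind == "none":
        raise ProfileError("kind 'none' has no sequence hits")
    hits: list[Hit] = []
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom)
        if profile.kind == "consensus":
            pat = profile.pattern.upper()
            w = len(pat)
            for i in _scan_consensus(seq, pat):
                hits.append(Hit(chrom, i + 1, i + w, "+"))
            if profile.strand_policy == "both":
                rc = reverse_complement(pat)
                if rc != pat:  # palindromes reported once, on +
                    for i in _scan_consensus(seq, rc):
                        hits.append(Hit(chrom, i + 1, i + w, "-"))
        elif profile.kind == "pwm":
            m = profile.matrix
            max_score = float(m.max(axis=1).sum())
            min_score = profile.threshold * max_score
            w = m.shape[0]
            for i, score in _scan_pwm(seq, m, min_score):
                hits.append(Hit(chrom, i + 1, i + w, "+", score))
            if profile.strand_policy == "both":
                rc_m = m[::-1, ::-1]
                if not np.array_equal(rc_m, m):
                    for i, score in _scan_pwm(seq, rc_m, min_score):
                        hits.append(Hit(chrom, i + 1, i + w, "-", score))
        else:  # regex: non-overlapping leftmost, forward strand
            for m in re.finditer(profile.pattern, seq):
                if m.end() > m.start():
                    hits.append(Hit(chrom, m.start() + 1, m.end(), "+"))
    hits.sort(key=lambda h: (h.chrom, h.start, h.end, h.strand))
    return hits


def count_sequence_hits(genome: GenomeRef, profile: SequenceProfile,
                        overlap: str = "allow") -> int:
    """Count profile hits.

    ``overlap="allow"`` counts every reported hit; ``"disjoint"`` applies a
    greedy left-to-right selection of non-overlapping footprints per
    chromosome (both strands pooled), matching the disjoint-site
    convention some motif counters use.
    """
    hits = find_sequence_hits(genome, profile)
    if overlap == "allow":
        return len(hits)
    if overlap != "disjoint":
        raise ProfileError(f"overlap must be allow/disjoint, got {overlap!r}")
    n = 0
    last_end: dict[str, int] = {}
    for h in hits:
        if h.start > last_end.get(h.chrom, 0):
            n += 1
            last_end[h.chrom] = h.end
    return n


# ---------------------------------------------------------------------------
# Predicate evaluation and factor matching
# ---------------------------------------------------------------------------

def evaluate_predicate(layerset: LayerSet, footprint: Interval,
                       predicate: LayerPredicate,
                       overlap_mode: str = "partial") -> bool:
    """Conjunction over terms; ``present`` = >=1 bp overlap by default.

    ``overlap_mode="containment"`` requires the footprint to lie entirely
    inside the layer for a ``present`` term.
    """
    for term in predicate.terms:
        rs = layerset._layer(term.layer)
        if overlap_mode == "containment" and term.required == "present":
            starts, ends = rs.chrom_runs(footprint.chrom)
            i = int(np.searchsorted(ends, footprint.start, side="left"))
            ok = i < len(starts) and starts[i] <= footprint.start \
                and ends[i] >= footprint.end
        else:
            ok = rs.overlaps(footprint.chrom, footprint.start, footprint.end)
        if (term.required == "present") != ok:
            return False
    return True


def match_binding_factor(layerset: LayerSet, bf: BindingFactor,
                         overlap_mode: str = "partial") -> list[Hit]:
    """Candidate hits for a factor against the current layer state.

    Sequence-profile factors draw candidates from the hit cache (if
    ``cacheable``) or a fresh scan, then filter by the layer predicate.
    Profile-``none`` factors take the maximal intervals of the first
    present-required predicate layer as candidates, filtered by the
    remaining terms.
    """
    if bf.profile.kind != "none":
        if bf.cacheable:
            candidates = layerset.cache.get_or_scan(layerset.genome, bf.profile)
        else:
            layerset.cache.scan_count += 1
            candidates = find_sequence_hits(layerset.genome, bf.profile)
        if bf.predicate.terms:
            candidates = [
                h for h in candidates
                if evaluate_predicate(layerset, Interval(h.chrom, h.start, h.end),
                                      bf.predicate, overlap_mode)]
        return sorted(candidates, key=lambda h: (h.chrom, h.start, h.end, h.strand))

    source = bf.predicate.first_present_layer
    if source is None:
        raise ProfileError(
            f"factor {bf.name}: profile 'none' needs a present-required term")
    rest = LayerPredicate(tuple(t for t in bf.predicate.terms if t.layer != source))
    hits = []
    for iv in layerset._layer(source).intervals():
        if evaluate_predicate(layerset, iv, rest, overlap_mode):
            hits.append(Hit(iv.chrom, iv.start, iv.end, "."))
    hits.sort(key=lambda h: (h.chrom, h.start, h.end))
    return hits
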