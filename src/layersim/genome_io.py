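"""Genome sequence I/O and synthetic genome generation.

A :class:`GenomeRef` is the immutable sequence component of a layer set:
an ordered collection of named chromosomes over the alphabet ``ACGTN``.
Sequences are normalised to upper case on load and any character outside
the alphabet is replaced by ``N`` (real assemblies contain gaps and odd
IUPAC leftovers; ``N`` never matches a profile character other than
``N``).

The synthetic generator plants motif occurrences (single, gapped doubles,
telomere-proximal clusters) and CpG-island-like CG-dense segments into an
i.i.d. background, recording a machine-readable truth list so tests can
check a scanner against known coordinates.

Coordinates everywhere in this package are 1-based and inclusive of both
ends; conversion to 0-based half-open happens only at BED boundaries.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

# IUPAC nucleotide complement table (covers the full degenerate alphabet).
_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenomeValidationError(ValueError):
    """Raised when a genome or synthetic-genome spec violates its contract."""


class PlacementError(RuntimeError):
    """Raised when a planted feature cannot be placed without overlap."""


class GenomeRef:
    """Immutable ordered set of named chromosome sequences.

    Parameters
    ----------
    records:
        Iterable of ``(name, sequence)`` pairs in the desired order.
    """

    __slots__ = ("_names", "_seqs", "_lengths")

    def __init__(self, records: Iterable[tuple[str, str]]):
        names: list[str] = []
        seqs: dict[str, str] = {}
        for name, seq in records:
            if not name:
                raise GenomeValidationError("chromosome name must be non-empty")
            if name in seqs:
                raise GenomeValidationError(f"duplicate chromosome name: {name!r}")
            norm, n_bad = _normalize_sequence(seq)
            if n_bad:
                logger.warning(
                    "chromosome %s: %d non-ACGTN characters replaced with N",
                    name, n_bad,
                )
            names.append(name)
            seqs[name] = norm
        if not names:
            raise GenomeValidationError("genome has no chromosomes")
        self._names = tuple(names)
        self._seqs = seqs
        self._lengths = {n: len(seqs[n]) for n in names}

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return self._names

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeRef)
            and self._names == other._names
            and all(self._seqs[n] == other._seqs[n] for n in self._names)
        )

    def __repr__(self) -> str:
        return f"GenomeRef({len(self._names)} chromosomes, {self.total_bp} bp)"

    def content_hash(self) -> int:
        """Order-sensitive hash of names and sequences (immutability checks)."""
        return hash(tuple((n, self._seqs[n]) for n in self._names))


def _normalize_sequence(seq: str) -> tuple[str, int]:
    up = seq.upper()
    bad = set(up) - VALID_BASES
    if not bad:
        return up, 0
    n_bad = sum(up.count(c) for c in bad)
    table = str.maketrans({c: "N" for c in bad})
    return up.translate(table), n_bad


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, honouring IUPAC degeneracy codes."""
    out = []
    for c in reversed(seq.upper()):
        try:
            out.append(_COMPLEMENT[c])
        except KeyError:
            raise GenomeValidationError(f"cannot complement character {c!r}")
    return "".join(out)


def load_genome(path) -> GenomeRef:
    """Load a (optionally gzipped) FASTA file into a :class:`GenomeRef`.

    Records keep file order; sequences are upper-cased and non-ACGTN
    characters become ``N`` (a warning reports the count per chromosome).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise GenomeValidationError(f"no FASTA records in {path}")
    return GenomeRef(records)


def write_genome(genome: GenomeRef, path) -> None:
    """Write a genome as plain FASTA, 60 columns per line."""
    records = [
        SeqRecord(Seq(genome.sequence(name)), id=name, description="")
        for name in genome.chrom_names
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Synthetic genomes with planted ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPlant:
    """A request to plant ``count`` copies of ``motif``.

    ``region`` selects where copies may land: anywhere (``uniform``),
    within ``telomere_window`` bp of a random chromosome end
    (``telomeric``), or of a specific end (``telomere_start`` /
    ``telomere_end``).  ``double_gap=(lo, hi)`` plants two copies of the
    motif separated by a gap drawn uniformly from ``[lo, hi]`` bp.
    ``positions`` pins copies to explicit ``(chrom, start)`` coordinates
    instead of random placement.
    """

    motif: str
    count: int = 1
    region: str = "uniform"
    double_gap: Optional[tuple[int, int]] = None
    positions: Optional[tuple[tuple[str, int], ...]] = None


@dataclass(frozen=True)
class IslandPlant:
    """A request to plant CG-dense, CpG-island-like segments."""

    count: int
    length: int
    cg_density: float  # fraction of positions starting a CG dinucleotide
    positions: Optional[tuple[tuple[str, int], ...]] = None


@dataclass
class SyntheticGenomeSpec:
    """Recipe for a synthetic genome with planted, recorded features."""

    n_chroms: int = 1
    chrom_length: int = 100_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_motifs: Sequence[MotifPlant] = field(default_factory=list)
    telomere_window: int = 2_000
    cpg_islands: Sequence[IslandPlant] = field(default_factory=list)
    # Fraction of background CG dinucleotides mutated away (C-G -> C-A/T),
    # emulating the CpG depletion of vertebrate genomes so CG-dense planted
    # islands stand out against the background.
    cpg_depletion: float = 0.0
    chrom_prefix: str = "chr"
    max_place_retries: int = 1000

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise GenomeValidationError("n_chroms and chrom_length must be positive")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise GenomeValidationError("base_composition must sum to 1")
        if any(p < 0 for p in self.base_composition):
            raise GenomeValidationError("base_composition must be non-negative")
        if self.telomere_window > self.chrom_length // 2:
            raise GenomeValidationError("telomere_window must be <= chrom_length/2")
        if not (0 <= self.cpg_depletion <= 1):
            raise GenomeValidationError("cpg_depletion must be in [0, 1]")
        for mp in self.planted_motifs:
            if mp.count < 1 or not mp.motif:
                raise GenomeValidationError(f"invalid motif plant {mp}")
            if mp.double_gap is not None:
                lo, hi = mp.double_gap
                if lo < 0 or hi < lo:
                    raise GenomeValidationError(f"invalid double_gap in {mp}")
        for ip in self.cpg_islands:
            if ip.count < 1 or ip.length < 2 or not (0 < ip.cg_density <= 1):
                raise GenomeValidationError(f"invalid island plant {ip}")


@dataclass(frozen=True)
class PlantedFeature:
    """Ground-truth record of one planted feature (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    kind: str  # motif | double_motif | cpg_island
    payload: str


# degenerate-base expansion used when planting IUPAC motifs
_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _concrete_motif(motif: str, rng: np.random.Generator) -> str:
    out = []
    for c in motif.upper():
        choices = _IUPAC_CHOICES.get(c)
        if choices is None:
            raise GenomeValidationError(f"cannot plant character {c!r}")
        out.append(choices[rng.integers(len(choices))] if len(choices) > 1 else choices)
    return "".join(out)


def _island_sequence(length: int, cg_density: float, rng: np.random.Generator) -> str:
    """CG-dense segment: emit 'CG' with probability cg_density, else a GC-leaning base."""
    out: list[str] = []
    bases = "ACGT"
    probs = (0.2, 0.3, 0.3, 0.2)
    while len(out) < length:
        if rng.random() < cg_density and len(out) + 2 <= length:
            out.append("CG")
        else:
            out.append(bases[rng.choice(4, p=probs)])
    return "".join(out)[:length]


def _candidate_start(
    region: str, width: int, chrom_length: int, telomere_window: int,
    rng: np.random.Generator,
) -> int:
    """Draw a 1-based start so the feature fits its region constraint."""
    if region == "uniform":
        return int(rng.integers(1, chrom_length - width + 2))
    if region == "telomeric":
        region = "telomere_start" if rng.integers(2) == 0 else "telomere_end"
    if region == "telomere_start":
        hi = telomere_window - width + 1
        if hi < 1:
            raise PlacementError(f"feature of width {width} exceeds telomere window")
        return int(rng.integers(1, hi + 1))
    if region == "telomere_end":
        lo = chrom_length - telomere_window + 1
        hi = chrom_length - width + 1
        if hi < lo:
            raise PlacementError(f"feature of width {width} exceeds telomere window")
        return int(rng.integers(lo, hi + 1))
    raise GenomeValidationError(f"unknown placement region {region!r}")


def generate_synthetic_genome(
    spec: SyntheticGenomeSpec, seed: int
) -> tuple[GenomeRef, list[PlantedFeature]]:
    """Generate a genome from ``spec``; identical seed gives identical output.

    Background bases are drawn i.i.d. from ``base_composition``; planted
    features are written over the background at collision-free positions
    found by rejection sampling (bounded retries).  Every feature appears
    verbatim at its recorded 1-based coordinates.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    chrom_names = [f"{spec.chrom_prefix}{i + 1}" for i in range(spec.n_chroms)]
    arrays: dict[str, np.ndarray] = {}
    for name in chrom_names:
        codes = rng.choice(4, size=spec.chrom_length, p=np.asarray(spec.base_composition))
        arr = _BASES[codes].copy()
        if spec.cpg_depletion > 0:
            cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
            mutate = cg[rng.random(len(cg)) < spec.cpg_depletion]
            arr[mutate + 1] = np.where(rng.random(len(mutate)) < 0.5,
                                       ord("A"), ord("T"))
        arrays[name] = arr

    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}
    features: list[PlantedFeature] = []

    def _try_place(chrom: str, start: int, text: str) -> bool:
        end = start + len(text) - 1
        if start < 1 or end > spec.chrom_length:
            return False
        for s, e in occupied[chrom]:
            if start <= e and end >= s:
                return False
        arrays[chrom][start - 1:end] = np.frombuffer(text.encode(), dtype=np.uint8)
        occupied[chrom].append((start, end))
        return True

    def _place(kind: str, motif_text_fn, width: int, region: str,
               fixed: Optional[tuple[str, int]], label: str) -> None:
        if fixed is not None:
            chrom, start = fixed
            text = motif_text_fn()
            if not _try_place(chrom, start, text):
                raise PlacementError(f"cannot place {label} at {chrom}:{start}")
            features.append(PlantedFeature(chrom, start, start + len(text) - 1, kind, text))
            return
        for _ in range(spec.max_place_retries):
            chrom = chrom_names[rng.integers(spec.n_chroms)]
            text = motif_text_fn()
            start = _candidate_start(region, len(text), spec.chrom_length,
                                     spec.telomere_window, rng)
            if _try_place(chrom, start, text):
                features.append(
                    PlantedFeature(chrom, start, start + len(text) - 1, kind, text))
                return
        raise PlacementError(f"could not place {label} after "
                             f"{spec.max_place_retries} retries")

    # (kind, text_fn, width, region, fixed position or None, label)
    tasks: list[tuple] = []
    for mp in spec.planted_motifs:
        if mp.double_gap is None:
            def _single(mp=mp):
                return _concrete_motif(mp.motif, rng)
            kind, fn, width, label = "motif", _single, len(mp.motif), mp.motif
        else:
            lo, hi = mp.double_gap

            def _double(mp=mp, lo=lo, hi=hi):
                gap = int(rng.integers(lo, hi + 1))
                filler = "".join("ACGT"[rng.integers(4)] for _ in range(gap))
                return (_concrete_motif(mp.motif, rng) + filler
                        + _concrete_motif(mp.motif, rng))

            kind, fn, width, label = ("double_motif", _double,
                                      2 * len(mp.motif) + hi,
                                      f"double {mp.motif}")
        fixed_list = list(mp.positions) if mp.positions else [None] * mp.count
        tasks.extend((kind, fn, width, mp.region, fixed, label)
                     for fixed in fixed_list)
    for ip in spec.cpg_islands:
        def _island(ip=ip):
            return _island_sequence(ip.length, ip.cg_density, rng)

        fixed_list = list(ip.positions) if ip.positions else [None] * ip.count
        tasks.extend(("cpg_island", _island, ip.length, "uniform", fixed,
                      "cpg_island") for fixed in fixed_list)

    # pinned features first so random placements reject around them,
    # never the reverse (a pinned feature has no retry freedom)
    tasks.sort(key=lambda t: t[4] is None)
    for kind, fn, width, region, fixed, label in tasks:
        _place(kind, fn, width, region, fixed, label)

    genome = GenomeRef((n, arrays[n].tobytes().decode()) for n in chrom_names)
    features.sort(key=lambda f: (f.chrom, f.start, f.end))
    return genome, features


def write_truth_bed(features: Sequence[PlantedFeature], path) -> None:
    """Write planted features as BED6+1 (name=kind, extra column=payload)."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.kind}\t0\t+\t{f.payload}\n")


def read_truth_bed(path) -> list[PlantedFeature]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, kind, _score, _strand, payload = line.rstrip("\n").split("\t")
            out.append(PlantedFeature(chrom, int(start) + 1, int(end), kind, payload))
    return out
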