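"""Binary-state genomic layers: interval sets, history, coverage, snapshots.

A layer is a named binary annotation track over a genome, stored as a
:class:`RangeSet` — per-chromosome sorted, non-overlapping intervals in
1-based inclusive coordinates, with touching runs merged (a presence /
absence mark has no meaningful boundary between adjacent marked bases).

A :class:`LayerSet` bundles the immutable genome with any number of
layers, a hit cache for sequence scans, and a per-cycle history of simple
layer statistics.  Replicate outputs are aggregated into a per-base
:class:`CoverageTrack` counting how many replicates marked each base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .genome_io import GenomeRef


class LayerValidationError(ValueError):
    pass


class BedParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Interval:
    """1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise LayerValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HistoryRecord:
    cycle: int
    layer: str
    n_ranges: int
    covered_bp: int


class RangeSet:
    """Per-chromosome sorted, merged interval set (1-based, inclusive).

    Invariants: intervals sorted by start; consecutive intervals i, j
    satisfy ``j.start > i.end + 1`` (overlapping or touching runs are
    merged on every mutation).
    """

    __slots__ = ("_runs",)

    def __init__(self, intervals: Iterable[Interval] = ()):  # noqa: D401
        self._runs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in by_chrom.items():
            arr = np.array(pairs, dtype=np.int64)
            self._runs[chrom] = _merge(arr[:, 0], arr[:, 1])

    # -- constructors -----------------------------------------------------
    @classmethod
    def _from_runs(cls, runs: dict[str, tuple[np.ndarray, np.ndarray]]) -> "RangeSet":
        rs = cls()
        rs._runs = runs
        return rs

    def copy(self) -> "RangeSet":
        return RangeSet._from_runs(
            {c: (s.copy(), e.copy()) for c, (s, e) in self._runs.items()})

    # -- queries ----------------------------------------------------------
    def intervals(self) -> list[Interval]:
        out = []
        for chrom in sorted(self._runs):
            starts, ends = self._runs[chrom]
            out.extend(Interval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def chrom_runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._runs.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))

    @property
    def n_ranges(self) -> int:
        return sum(len(s) for s, _ in self._runs.values())

    @property
    def covered_bp(self) -> int:
        return int(sum((e - s + 1).sum() for s, e in self._runs.values()))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end] overlaps this set by >= 1 bp."""
        starts, ends = self.chrom_runs(chrom)
        if len(starts) == 0:
            return False
        i = int(np.searchsorted(ends, start, side="left"))
        return i < len(starts) and starts[i] <= end

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos, pos)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RangeSet):
            return NotImplemented
        mine = {c: rs for c, rs in self._runs.items() if len(rs[0])}
        theirs = {c: rs for c, rs in other._runs.items() if len(rs[0])}
        if mine.keys() != theirs.keys():
            return False
        return all(
            np.array_equal(mine[c][0], theirs[c][0])
            and np.array_equal(mine[c][1], theirs[c][1])
            for c in mine)

    def __repr__(self) -> str:
        return f"RangeSet({self.n_ranges} ranges, {self.covered_bp} bp)"

    # -- mutations (in place; LayerSet mediates access) -------------------
    def add(self, chrom: str, start: int, end: int) -> None:
        starts, ends = self.chrom_runs(chrom)
        self._runs[chrom] = _merge(np.append(starts, start), np.append(ends, end))

    def subtract(self, chrom: str, start: int, end: int) -> None:
        starts, ends = self.chrom_runs(chrom)
        if len(starts) == 0:
            return
        keep = (ends < start) | (starts > end)
        new_s, new_e = list(starts[keep]), list(ends[keep])
        for s, e in zip(starts[~keep], ends[~keep]):
            if s < start:
                new_s.append(s)
                new_e.append(start - 1)
            if e > end:
                new_s.append(end + 1)
                new_e.append(e)
        self._runs[chrom] = _merge(
            np.asarray(new_s, np.int64), np.asarray(new_e, np.int64))


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge runs, fusing overlapping and adjacent intervals."""
    if len(starts) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    order = np.argsort(starts, kind="stable")
    starts = np.asarray(starts, np.int64)[order]
    ends = np.asarray(ends, np.int64)[order]
    out_s, out_e = [int(starts[0])], [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + 1:
            if e > out_e[-1]:
                out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)


class LayerSet:
    """A genome plus named binary-state layers, hit cache and history.

    The genome is never mutated by any operation here or in the engine.
    """

    def __init__(self, genome: GenomeRef, layer_names: Sequence[str],
                 initial: Optional[Mapping[str, Iterable[Interval]]] = None):
        from .binding_factor import HitCache  # local import: avoid cycle

        if len(set(layer_names)) != len(layer_names):
            raise LayerValidationError("layer names must be unique")
        self.genome = genome
        self.layers: dict[str, RangeSet] = {}
        for name in layer_names:
            ivs = list((initial or {}).get(name, ()))
            for iv in ivs:
                self._check_bounds(name, iv)
            self.layers[name] = RangeSet(ivs)
        unknown = set(initial or {}) - set(layer_names)
        if unknown:
            raise LayerValidationError(f"initial ranges for undeclared layers: {unknown}")
        self.cache = HitCache()
        self.history: list[HistoryRecord] = []
        self.cycle = 0

    def _check_bounds(self, layer: str, iv: Interval) -> None:
        if iv.chrom not in self.genome:
            raise LayerValidationError(
                f"layer {layer}: unknown chromosome in {iv}")
        if iv.end > self.genome.length(iv.chrom):
            raise LayerValidationError(
                f"layer {layer}: interval {iv} beyond chromosome end "
                f"({self.genome.length(iv.chrom)} bp)")

    def _layer(self, name: str) -> RangeSet:
        try:
            return self.layers[name]
        except KeyError:
            raise LayerValidationError(f"unknown layer {name!r}") from None

    def set_state(self, layer: str, interval: Interval, state: str) -> None:
        """Union (``present``) or subtract (``absent``) an interval."""
        rs = self._layer(layer)
        self._check_bounds(layer, interval)
        if state == "present":
            rs.add(interval.chrom, interval.start, interval.end)
        elif state == "absent":
            rs.subtract(interval.chrom, interval.start, interval.end)
        else:
            raise LayerValidationError(f"state must be present/absent, got {state!r}")

    def covered_bp(self, layer: str) -> int:
        return self._layer(layer).covered_bp

    def record_history(self, cycle: int) -> None:
        for name, rs in self.layers.items():
            self.history.append(HistoryRecord(cycle, name, rs.n_ranges, rs.covered_bp))


def create_layerset(genome: GenomeRef, layer_names: Sequence[str],
                    initial: Optional[Mapping[str, Iterable[Interval]]] = None
                    ) -> LayerSet:
    """Build a LayerSet; layers start empty unless given initial ranges."""
    return LayerSet(genome, layer_names, initial)


# ---------------------------------------------------------------------------
# BED import/export (0-based half-open on disk)
# ---------------------------------------------------------------------------

def export_bed(layerset: LayerSet, layer: str, path) -> None:
    rs = layerset._layer(layer)
    write_bed(rs, path)


def write_bed(rangeset: RangeSet, path) -> None:
    with open(path, "w") as fh:
        for iv in rangeset.intervals():
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def import_bed(path, genome: Optional[GenomeRef] = None) -> RangeSet:
    """Read a BED file (>= 3 columns) into a normalized RangeSet."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates")
            if start < 0 or end <= start:
                raise BedParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            if genome is not None:
                if chrom not in genome:
                    raise LayerValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
                if end > genome.length(chrom):
                    raise LayerValidationError(
                        f"{path}:{lineno}: interval beyond chromosome end")
            intervals.append(Interval(chrom, start + 1, end))
    return RangeSet(intervals)


# ---------------------------------------------------------------------------
# Snapshots: directory of per-layer BEDs + JSON manifest + TSV history
# ---------------------------------------------------------------------------

def snapshot(layerset: LayerSet, path) -> None:
    """Persist layers, history and genome identifiers (names + lengths)."""
    path = Path(path)
    (path / "layers").mkdir(parents=True, exist_ok=True)
    manifest = {
        "chrom_names": list(layerset.genome.chrom_names),
        "chrom_lengths": {c: layerset.genome.length(c)
                          for c in layerset.genome.chrom_names},
        "layer_names": list(layerset.layers),
        "cycle": layerset.cycle,
        "rng_algorithm": "numpy PCG64",
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    for name, rs in layerset.layers.items():
        write_bed(rs, path / "layers" / f"{name}.bed")
    with open(path / "history.tsv", "w") as fh:
        fh.write("cycle\tlayer\tn_ranges\tcovered_bp\n")
        for h in layerset.history:
            fh.write(f"{h.cycle}\t{h.layer}\t{h.n_ranges}\t{h.covered_bp}\n")


def restore(path, genome: GenomeRef) -> LayerSet:
    """Rebuild a LayerSet from a snapshot directory against ``genome``."""
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if list(genome.chrom_names) != manifest["chrom_names"] or any(
            genome.length(c) != manifest["chrom_lengths"][c]
            for c in genome.chrom_names):
        raise LayerValidationError(
            "snapshot genome (names/lengths) does not match supplied genome")
    ls = LayerSet(genome, manifest["layer_names"])
    for name in manifest["layer_names"]:
        rs = import_bed(path / "layers" / f"{name}.bed", genome)
        ls.layers[name] = rs
    with open(path / "history.tsv") as fh:
        next(fh)
        for line in fh:
            cycle, layer, n_ranges, covered = line.split("\t")
            ls.history.append(
                HistoryRecord(int(cycle), layer, int(n_ranges), int(covered)))
    ls.cycle = manifest["cycle"]
    return ls


# ---------------------------------------------------------------------------
# Replicate coverage
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-chromosome run-length-encoded non-negative per-base counts."""

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 chrom_lengths: dict[str, int]):
        # runs[chrom] = (starts 1-based, ends inclusive, counts)
        self.runs = runs
        self.chrom_lengths = chrom_lengths

    def per_base(self, chrom: str) -> np.ndarray:
        """Expand one chromosome to a dense per-base count array."""
        arr = np.zeros(self.chrom_lengths[chrom], dtype=np.int64)
        starts, ends, counts = self.runs[chrom]
        for s, e, c in zip(starts, ends, counts):
            arr[s - 1:e] = c
        return arr

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean count over the 1-based inclusive window [start, end]."""
        return float(self.per_base(chrom)[start - 1:end].mean())


def sum_coverage(rangesets: Sequence[RangeSet],
                 genome: Union[GenomeRef, Mapping[str, int]]) -> CoverageTrack:
    """Per-base count of how many input RangeSets contain each base.

    ``genome`` may be a :class:`GenomeRef` or a chrom -> length mapping.
    """
    if not rangesets:
        raise LayerValidationError("sum_coverage needs at least one RangeSet")
    if isinstance(genome, GenomeRef):
        lengths = {c: genome.length(c) for c in genome.chrom_names}
    else:
        lengths = dict(genome)
    runs = {}
    for chrom, length in lengths.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        for rs in rangesets:
            starts, ends = rs.chrom_runs(chrom)
            if len(starts) and ends.max() > length:
                raise LayerValidationError(
                    f"RangeSet extends beyond {chrom} ({length} bp)")
            np.add.at(diff, starts - 1, 1)
            np.add.at(diff, ends, -1)
        per_base = np.cumsum(diff[:-1])
        runs[chrom] = _rle(per_base)
    return CoverageTrack(runs, lengths)


def _rle(per_base: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(per_base) == 0:
        z = np.empty(0, np.int64)
        return z, z, z
    change = np.flatnonzero(np.diff(per_base)) + 1
    starts0 = np.concatenate(([0], change))
    ends0 = np.concatenate((change, [len(per_base)]))
    return starts0 + 1, ends0.astype(np.int64), per_base[starts0].astype(np.int64)


def export_bedgraph(track: CoverageTrack, path) -> None:
    """Write bedGraph (0-based half-open); zero-count runs omitted."""
    with open(path, "w") as fh:
        for chrom in track.runs:
            starts, ends, counts = track.runs[chrom]
            for s, e, c in zip(starts, ends, counts):
                if c != 0:
                    fh.write(f"{chrom}\t{s - 1}\t{e}\t{c}\n")


def import_bedgraph(path, chrom_lengths: dict[str, int]) -> CoverageTrack:
    """Read a bedGraph back into a CoverageTrack (zero runs reconstructed)."""
    per_chrom: dict[str, np.ndarray] = {
        c: np.zeros(l, dtype=np.int64) for c, l in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, count = line.split("\t")
            per_chrom[chrom][int(start):int(end)] = int(count)
    runs = {c: _rle(arr) for c, arr in per_chrom.items()}
    return CoverageTrack(runs, dict(chrom_lengths))
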