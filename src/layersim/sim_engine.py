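"""The stochastic cycle engine.

A simulation runs a fixed number of cycles over a layer set.  Each cycle
applies every binding factor in declared order: the factor is matched
against the *current* layer state (sequential-asynchronous update — a
factor sees the changes its predecessors made within the same cycle,
which lets recruitment chains such as nucleator → reader → spreader
propagate within one cycle), a subset of its matches of size at most its
*abundance* is drawn uniformly without replacement, and for each chosen
match a modification interval of width *statewidth* is placed around the
match centre, optionally displaced by a sampled offset, and applied to
the target layers.

Modifications are idempotent interval algebra: re-marking an already
marked region changes nothing but still consumes abundance, matching a
finite-molecules interpretation.

All randomness flows from one numpy PCG64 generator seeded from the
configuration; replicate ``r`` uses ``base_seed + r``, so any replicate
can be reproduced in isolation.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .binding_factor import BindingFactor, Hit, match_binding_factor
from .genome_io import GenomeRef
from .layer_model import Interval, LayerSet, RangeSet, create_layerset, snapshot
from .samplers import SamplerError


class ConfigError(ValueError):
    pass


AbundanceValue = Union[int, Sequence[int], Callable[[int], int]]


@dataclass
class SimulationConfig:
    """Everything needed to run one simulation deterministically."""

    genome: GenomeRef
    layer_names: Sequence[str]
    factors: Sequence[BindingFactor]
    abundances: Mapping[str, AbundanceValue]
    n_cycles: int
    snapshot_every: Optional[int] = None
    seed: int = 0
    initial: Optional[Mapping[str, Sequence[Interval]]] = None
    overlap_mode: str = "partial"

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.snapshot_every is not None and self.snapshot_every < 1:
            raise ConfigError("snapshot_every must be >= 1 or None")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ConfigError("factor names must be unique")
        missing = [n for n in names if n not in self.abundances]
        if missing:
            raise ConfigError(f"no abundance for factors: {missing}")
        declared = set(self.layer_names)
        for f in self.factors:
            used = {t.layer for t in f.predicate.terms} | {m.layer for m in f.mods}
            undeclared = used - declared
            if undeclared:
                raise ConfigError(f"factor {f.name} uses undeclared layers {undeclared}")


@dataclass
class SimulationResult:
    final: LayerSet
    snapshots: dict[int, dict[str, RangeSet]]
    history: list
    seed: int
    out_dir: Optional[Path] = None


def abundance_at(value: AbundanceValue, cycle_index: int) -> int:
    """Resolve an abundance entry at a 1-based cycle index."""
    if callable(value):
        n = value(cycle_index)
    elif isinstance(value, (list, tuple, np.ndarray)):
        n = value[cycle_index - 1]
    else:
        n = value
    n = int(n)
    if n < 0:
        raise ConfigError(f"abundance must be >= 0, got {n} at cycle {cycle_index}")
    return n


def sample_hits(hits: Sequence[Hit], n: int, rng: np.random.Generator) -> list[Hit]:
    """Uniform subset of size min(n, len(hits)) without replacement, sorted."""
    if n < 0:
        raise ConfigError("sample size must be >= 0")
    if n >= len(hits):
        chosen = list(hits)
    else:
        idx = rng.choice(len(hits), size=n, replace=False)
        chosen = [hits[i] for i in idx]
    chosen.sort(key=lambda h: (h.chrom, h.start, h.end, h.strand))
    return chosen


def place_modification(hit: Hit, statewidth, offset_sampler,
                       rng: np.random.Generator, chrom_length: int
                       ) -> Optional[Interval]:
    """Place the modification interval for one chosen hit.

    The interval is centred on the match midpoint, displaced by a sampled
    offset (magnitude samplers get a uniformly random sign), sized to
    ``statewidth`` and clipped to the chromosome.  ``statewidth="match"``
    modifies exactly the (offset) matched footprint.  Returns ``None``
    when the placement falls entirely off the chromosome.
    """
    offset = 0
    if offset_sampler is not None:
        d = offset_sampler.draw(rng)
        if getattr(offset_sampler, "signed", True):
            offset = d
        else:
            sign = 1 if rng.integers(2) == 1 else -1
            offset = sign * abs(d)

    if statewidth == "match":
        start, end = hit.start + offset, hit.end + offset
    else:
        if isinstance(statewidth, int):
            width = statewidth
            if width < 1:
                raise SamplerError(f"statewidth must be >= 1, got {width}")
        else:
            width = statewidth.draw(rng)
            tries = 0
            while width < 1:
                tries += 1
                if tries > 100:
                    raise SamplerError(
                        "statewidth sampler produced <1 bp 100 times in a row")
                width = statewidth.draw(rng)
        center = (hit.start + hit.end) // 2 + offset
        start = center - width // 2
        end = start + width - 1

    if end < 1 or start > chrom_length:
        return None
    return Interval(hit.chrom, max(1, start), min(chrom_length, end))


def apply_binding_factor(layerset: LayerSet, bf: BindingFactor, abundance: int,
                         rng: np.random.Generator,
                         overlap_mode: str = "partial") -> int:
    """Match, sample up to ``abundance`` hits, place and apply mods.

    Returns the number of chosen hits (n_applied <= abundance always).
    """
    if abundance == 0:
        return 0
    hits = match_binding_factor(layerset, bf, overlap_mode)
    chosen = sample_hits(hits, abundance, rng)
    for hit in chosen:
        placement = place_modification(
            hit, bf.statewidth, bf.offset_sampler, rng,
            layerset.genome.length(hit.chrom))
        if placement is None:
            continue
        for mod in bf.mods:
            layerset.set_state(mod.layer, placement, mod.new_state)
    return len(chosen)


def run_cycle(layerset: LayerSet, factors: Sequence[BindingFactor],
              abundances: Mapping[str, AbundanceValue],
              rng: np.random.Generator, cycle_index: int,
              overlap_mode: str = "partial") -> dict[str, int]:
    """One cycle: every factor, in order, against the evolving state."""
    applied = {}
    for bf in factors:
        n = abundance_at(abundances[bf.name], cycle_index)
        applied[bf.name] = apply_binding_factor(layerset, bf, n, rng, overlap_mode)
    layerset.cycle = cycle_index
    layerset.record_history(cycle_index)
    return applied


def run_simulation(config: SimulationConfig,
                   out_dir: Optional[Path] = None) -> SimulationResult:
    """Run ``n_cycles`` cycles from the configured initial state.

    Snapshots (in-memory copies of every layer, and on-disk directories
    when ``out_dir`` is given) are taken at every multiple of
    ``snapshot_every``.  A single PCG64 stream seeded from ``config.seed``
    drives all randomness, so identical config + seed gives identical
    results, including byte-identical snapshot files.
    """
    config.validate()
    layerset = create_layerset(config.genome, list(config.layer_names),
                               config.initial)
    rng = np.random.default_rng(config.seed)
    snapshots: dict[int, dict[str, RangeSet]] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        for cycle in range(1, config.n_cycles + 1):
            run_cycle(layerset, config.factors, config.abundances, rng, cycle,
                      config.overlap_mode)
            if config.snapshot_every and cycle % config.snapshot_every == 0:
                snapshots[cycle] = {n: rs.copy() for n, rs in layerset.layers.items()}
                if out_dir is not None:
                    snapshot(layerset, out_dir / f"cycle_{cycle:05d}")
        if out_dir is not None:
            snapshot(layerset, out_dir / "final")
            _write_run_manifest(config, out_dir)
    except Exception:
        if out_dir is not None:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise
    return SimulationResult(layerset, snapshots, list(layerset.history),
                            config.seed, out_dir)


def _write_run_manifest(config: SimulationConfig, out_dir: Path) -> None:
    import json

    manifest = {
        "seed": config.seed,
        "n_cycles": config.n_cycles,
        "snapshot_every": config.snapshot_every,
        "layers": list(config.layer_names),
        "factors": [f.name for f in config.factors],
        "rng_algorithm": "numpy PCG64",
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass
class ReplicateFailure:
    index: int
    error: Exception


def run_replicates(config: SimulationConfig, n_replicates: int, base_seed: int,
                   out_dir: Optional[Path] = None
                   ) -> tuple[list[Optional[SimulationResult]], list[ReplicateFailure]]:
    """Run seeded replicates; replicate ``r`` uses seed ``base_seed + r``.

    Each replicate owns its RNG stream, so results do not depend on
    execution order.  A failed replicate is reported by index without
    aborting the rest; its slot in the result list is ``None``.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    results: list[Optional[SimulationResult]] = []
    failures: list[ReplicateFailure] = []
    for r in range(n_replicates):
        rep_config = SimulationConfig(
            genome=config.genome, layer_names=config.layer_names,
            factors=config.factors, abundances=config.abundances,
            n_cycles=config.n_cycles, snapshot_every=config.snapshot_every,
            seed=base_seed + r, initial=config.initial,
            overlap_mode=config.overlap_mode)
        rep_dir = None if out_dir is None else Path(out_dir) / f"rep_{r:04d}"
        try:
            results.append(run_simulation(rep_config, rep_dir))
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            results.append(None)
            failures.append(ReplicateFailure(r, exc))
    return results, failures
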