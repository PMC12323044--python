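"""YAML/JSON serialization of simulation configurations.

A configuration file declares the genome source (a FASTA path or an
inline synthetic-genome recipe), the layers, the ordered binding factors
with their profiles / predicates / modifications / geometry, the
abundance of each factor, and the run length, snapshot cadence and seed.
Alternatively a ``model`` block instantiates one of the shipped exemplar
bundles.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .binding_factor import (
    BindingFactor,
    LayerPredicate,
    Modification,
    PredicateTerm,
    SequenceProfile,
)
from .genome_io import (
    GenomeRef,
    IslandPlant,
    MotifPlant,
    SyntheticGenomeSpec,
    generate_synthetic_genome,
    load_genome,
)
from .layer_model import import_bed
from .samplers import sampler_from_dict
from .sim_engine import ConfigError, SimulationConfig


# ---------------------------------------------------------------------------
# Binding factors
# ---------------------------------------------------------------------------

def profile_from_dict(d: dict) -> SequenceProfile:
    kind = d.get("kind", "consensus")
    if kind == "pwm":
        counts = d.get("counts")
        if counts is not None:
            return SequenceProfile.from_counts(
                np.asarray(counts, dtype=float),
                threshold=float(d.get("threshold", 0.90)),
                strand_policy=d.get("strand", "both"))
        return SequenceProfile(kind="pwm",
                               matrix=np.asarray(d["matrix"], dtype=float),
                               threshold=float(d.get("threshold", 0.90)),
                               strand_policy=d.get("strand", "both"))
    if kind == "none":
        return SequenceProfile(kind="none")
    default_strand = "both" if kind == "consensus" else "forward"
    return SequenceProfile(kind=kind, pattern=d["pattern"],
                           strand_policy=d.get("strand", default_strand))


def profile_to_dict(p: SequenceProfile) -> dict:
    if p.kind == "none":
        return {"kind": "none"}
    if p.kind == "pwm":
        return {"kind": "pwm", "matrix": p.matrix.tolist(),
                "threshold": p.threshold, "strand": p.strand_policy}
    return {"kind": p.kind, "pattern": p.pattern, "strand": p.strand_policy}


def factor_from_dict(d: dict) -> BindingFactor:
    statewidth = d.get("statewidth", "match")
    if isinstance(statewidth, dict):
        statewidth = sampler_from_dict(statewidth)
    offset = d.get("offset")
    return BindingFactor(
        name=d["name"],
        profile=profile_from_dict(d.get("profile", {"kind": "none"})),
        predicate=LayerPredicate(tuple(
            PredicateTerm(layer, req) for layer, req in d.get("predicate", []))),
        mods=[Modification(layer, state) for layer, state in d["mods"]],
        statewidth=statewidth,
        offset_sampler=sampler_from_dict(offset) if offset else None,
        cacheable=bool(d.get("cacheable", False)),
    )


def factor_to_dict(f: BindingFactor) -> dict:
    d: dict[str, Any] = {
        "name": f.name,
        "profile": profile_to_dict(f.profile),
        "predicate": [[t.layer, t.required] for t in f.predicate.terms],
        "mods": [[m.layer, m.new_state] for m in f.mods],
        "cacheable": f.cacheable,
    }
    if isinstance(f.statewidth, (int, str)):
        d["statewidth"] = f.statewidth
    else:
        d["statewidth"] = f.statewidth.to_dict()
    if f.offset_sampler is not None:
        d["offset"] = f.offset_sampler.to_dict()
    return d


# ---------------------------------------------------------------------------
# Synthetic genome specs
# ---------------------------------------------------------------------------

def synthetic_spec_from_dict(d: dict) -> SyntheticGenomeSpec:
    motifs = []
    for m in d.get("planted_motifs", []):
        motifs.append(MotifPlant(
            motif=m["motif"], count=int(m.get("count", 1)),
            region=m.get("region", "uniform"),
            double_gap=tuple(m["double_gap"]) if m.get("double_gap") else None,
            positions=tuple((c, int(p)) for c, p in m["positions"])
            if m.get("positions") else None))
    islands = []
    for i in d.get("cpg_islands", []):
        islands.append(IslandPlant(
            count=int(i.get("count", 1)), length=int(i["length"]),
            cg_density=float(i["cg_density"]),
            positions=tuple((c, int(p)) for c, p in i["positions"])
            if i.get("positions") else None))
    return SyntheticGenomeSpec(
        n_chroms=int(d.get("n_chroms", 1)),
        chrom_length=int(d["chrom_length"]),
        base_composition=tuple(d.get("base_composition", (0.25,) * 4)),
        planted_motifs=motifs,
        telomere_window=int(d.get("telomere_window", 2000)),
        cpg_islands=islands,
        cpg_depletion=float(d.get("cpg_depletion", 0.0)),
        chrom_prefix=d.get("chrom_prefix", "chr"),
    )


def synthetic_spec_to_dict(spec: SyntheticGenomeSpec) -> dict:
    motifs = []
    for m in spec.planted_motifs:
        md: dict[str, Any] = {"motif": m.motif, "count": m.count, "region": m.region}
        if m.double_gap:
            md["double_gap"] = list(m.double_gap)
        if m.positions:
            md["positions"] = [[c, p] for c, p in m.positions]
        motifs.append(md)
    islands = []
    for i in spec.cpg_islands:
        idic: dict[str, Any] = {"count": i.count, "length": i.length,
                                "cg_density": i.cg_density}
        if i.positions:
            idic["positions"] = [[c, p] for c, p in i.positions]
        islands.append(idic)
    return {
        "n_chroms": spec.n_chroms,
        "chrom_length": spec.chrom_length,
        "base_composition": list(spec.base_composition),
        "planted_motifs": motifs,
        "telomere_window": spec.telomere_window,
        "cpg_islands": islands,
        "cpg_depletion": spec.cpg_depletion,
        "chrom_prefix": spec.chrom_prefix,
    }


# ---------------------------------------------------------------------------
# Whole configurations
# ---------------------------------------------------------------------------

def _resolve_genome(d: dict, base_dir: Path) -> GenomeRef:
    if "fasta" in d:
        return load_genome(base_dir / d["fasta"])
    if "synthetic" in d:
        spec = synthetic_spec_from_dict(d["synthetic"])
        genome, _ = generate_synthetic_genome(spec, int(d.get("seed", 0)))
        return genome
    raise ConfigError("genome block needs 'fasta' or 'synthetic'")


def config_from_dict(d: dict, base_dir: Path = Path(".")) -> SimulationConfig:
    genome = _resolve_genome(d["genome"], base_dir)

    if "model" in d:
        from .exemplar_models import build_oskm_model, build_sir_model

        m = dict(d["model"])
        kind = m.pop("kind")
        if kind == "sir":
            bundle = build_sir_model(**m)
        elif kind == "oskm":
            bundle = build_oskm_model(**m)
        else:
            raise ConfigError(f"unknown model kind {kind!r}")
        layer_names = bundle.layer_names
        factors = bundle.factors
        abundances: dict = dict(bundle.abundances)
        abundances.update(d.get("abundances", {}))
        n_cycles = int(d.get("n_cycles", bundle.n_cycles))
        snapshot_every = d.get("snapshot_every", bundle.snapshot_every)
    else:
        layer_names = list(d["layers"])
        factors = [factor_from_dict(f) for f in d["factors"]]
        abundances = dict(d["abundances"])
        n_cycles = int(d["n_cycles"])
        snapshot_every = d.get("snapshot_every")

    initial = None
    if d.get("initial"):
        initial = {
            layer: import_bed(base_dir / bed, genome).intervals()
            for layer, bed in d["initial"].items()
        }
    config = SimulationConfig(
        genome=genome,
        layer_names=layer_names,
        factors=factors,
        abundances=abundances,
        n_cycles=n_cycles,
        snapshot_every=snapshot_every,
        seed=int(d.get("seed", 0)),
        initial=initial,
        overlap_mode=d.get("overlap_mode", "partial"),
    )
    config.validate()
    return config


def load_config(path) -> SimulationConfig:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d, base_dir=path.parent)


def save_config_dict(d: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
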