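"""Ready-built models: yeast SIR telomere silencing and human OSKM reprogramming.

Two exemplar model families are provided.

**SIR spreading (yeast).**  RAP1 binds GGTGT and marks ``sir3_potential``;
the SIR complex (``Sir3p``) is recruited wherever potential exists but no
SIR is yet bound, marking ``sir3_bound``; ``Sir3.spreader`` then extends
``sir3_bound`` outward from existing marks by normally distributed
distances (mean 147 bp, SD 30 bp — about one nucleosome plus linker, in
either direction).  Model 1 seeds at single GGTGT motifs; Model 2 only at
double motifs gapped by at most 3 bp, which concentrates seeding at
telomeric repeat clusters.

**OSKM vs CpG-island repressor (human).**  The four pluripotency factors
OCT4 / SOX2 / KLF4 / MYC each recognise a literature consensus motif and
mark an ``active`` layer around bound sites (shared ``statewidth``); a
generic repressor recognises CpG islands through the regular expression
``(CG.{0,20}){4}CG`` (five CpG dinucleotides, pairwise within 20 bp) and
marks ``repressed`` — but only where no activating mark is present.  A
repressor-spreader widens repressed domains, and a cleaner resolves
regions that end up carrying both marks.  The activators ignore
repression entirely.

Both models ship as full-scale bundles (requiring a user-supplied
reference FASTA) and as desk-scale demos on synthetic genomes with
planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .binding_factor import (
    BindingFactor,
    LayerPredicate,
    Modification,
    SequenceProfile,
)
from .genome_io import (
    GenomeRef,
    IslandPlant,
    MotifPlant,
    PlantedFeature,
    SyntheticGenomeSpec,
)
from .samplers import NormalSampler, UniformSampler
from .sim_engine import SimulationConfig

# Reference genome sizes the full-scale abundances were chosen for.
SACCER3_BP = 12_000_000
HG38_BP = 3_200_000_000

RAP1_MOTIF = "GGTGT"
RAP1_DOUBLE_REGEX = "GGTGT.{0,3}GGTGT"
OSKM_MOTIFS = {
    "bf_OCT4": "ATGCAAAT",
    "bf_SOX2": "WTTGT",
    "bf_KLF4": "GCCAMGCCTC",
    "bf_MYC": "CACGTG",
}
CPG_ISLAND_REGEX = "(CG.{0,20}){4}CG"


class ModelError(ValueError):
    pass


@dataclass
class ModelBundle:
    """A self-consistent model: layers, ordered factors, abundances, run length."""

    name: str
    layer_names: list[str]
    factors: list[BindingFactor]
    abundances: dict[str, int]
    n_cycles: int
    snapshot_every: Optional[int] = 10

    def validate(self) -> None:
        declared = set(self.layer_names)
        for f in self.factors:
            used = {t.layer for t in f.predicate.terms} | {m.layer for m in f.mods}
            if used - declared:
                raise ModelError(f"factor {f.name} references undeclared layers "
                                 f"{used - declared}")
        missing = [f.name for f in self.factors if f.name not in self.abundances]
        if missing:
            raise ModelError(f"missing abundances for {missing}")

    def to_config(self, genome: GenomeRef, seed: int,
                  n_cycles: Optional[int] = None,
                  snapshot_every: Optional[int] = None) -> SimulationConfig:
        self.validate()
        return SimulationConfig(
            genome=genome,
            layer_names=list(self.layer_names),
            factors=list(self.factors),
            abundances=dict(self.abundances),
            n_cycles=n_cycles if n_cycles is not None else self.n_cycles,
            snapshot_every=(snapshot_every if snapshot_every is not None
                            else self.snapshot_every),
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Model A: SIR recruitment and spreading
# ---------------------------------------------------------------------------

def build_sir_model(variant: int, spread_mean: float = 147.0,
                    spread_sd: float = 30.0,
                    abundances: Optional[dict[str, int]] = None) -> ModelBundle:
    """SIR Model 1 (single-motif seeding) or Model 2 (gapped double motifs).

    Default abundances (500 per factor, sized for a ~12 Mb yeast genome)
    are a package choice — exposed precisely so they can be refined.
    """
    if variant not in (1, 2):
        raise ModelError(f"variant must be 1 or 2, got {variant!r}")
    if variant == 1:
        rap1_profile = SequenceProfile(kind="consensus", pattern=RAP1_MOTIF,
                                       strand_policy="both")
    else:
        rap1_profile = SequenceProfile(kind="regex", pattern=RAP1_DOUBLE_REGEX,
                                       strand_policy="forward")
    factors = [
        BindingFactor(
            name="RAP1", profile=rap1_profile,
            mods=[Modification("sir3_potential", "present")],
            statewidth="match", cacheable=True),
        BindingFactor(
            name="Sir3p", profile=SequenceProfile(kind="none"),
            predicate=LayerPredicate.of(("sir3_potential", "present"),
                                        ("sir3_bound", "absent")),
            mods=[Modification("sir3_bound", "present")],
            statewidth=147),
        BindingFactor(
            name="Sir3.spreader", profile=SequenceProfile(kind="none"),
            predicate=LayerPredicate.of(("sir3_bound", "present")),
            mods=[Modification("sir3_bound", "present")],
            statewidth=147,
            offset_sampler=NormalSampler(spread_mean, spread_sd, signed=False)),
    ]
    bundle = ModelBundle(
        name=f"sir_model_{variant}",
        layer_names=["sir3_potential", "sir3_bound"],
        factors=factors,
        abundances=abundances or {"RAP1": 500, "Sir3p": 500, "Sir3.spreader": 500},
        n_cycles=200,
        snapshot_every=10,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Model B: OSKM activators against a CpG-island repressor
# ---------------------------------------------------------------------------

def build_oskm_model(statewidth: int,
                     abundances: Optional[dict[str, int]] = None,
                     cleaner_mode: str = "active_wins",
                     rep_spread_statewidth: int = 1000) -> ModelBundle:
    """The human reprogramming model: 4 activators, repressor, spreader, cleaner.

    ``statewidth`` is shared by the four OSKM activators (the swept
    parameter).  ``cleaner_mode`` selects how double-marked regions are
    resolved:

    ``active_wins`` (default)
        the repressed mark is erased wherever an active region overlaps
        it — activation overwrites repression.
    ``conflict_erase_both``
        both marks are erased over any active region that overlaps a
        repressed one.
    ``literal``
        every active and every repressed region is erased each cycle
        (two cleaner factors); kept for completeness, rarely useful.
    """
    if statewidth != "match" and int(statewidth) < 1:
        raise ModelError("statewidth must be >= 1")
    layer_names = ["active", "repressed"]
    factors: list[BindingFactor] = []
    for name, motif in OSKM_MOTIFS.items():
        factors.append(BindingFactor(
            name=name,
            profile=SequenceProfile(kind="consensus", pattern=motif,
                                    strand_policy="both"),
            mods=[Modification("active", "present")],  # ignores repression
            statewidth=statewidth, cacheable=True))
    factors.append(BindingFactor(
        name="bf_repressor",
        profile=SequenceProfile(kind="regex", pattern=CPG_ISLAND_REGEX,
                                strand_policy="forward"),
        predicate=LayerPredicate.of(("active", "absent")),
        mods=[Modification("repressed", "present")],
        statewidth="match", cacheable=True))
    factors.append(BindingFactor(
        name="bf.RepSpread", profile=SequenceProfile(kind="none"),
        predicate=LayerPredicate.of(("repressed", "present"),
                                    ("active", "absent")),
        mods=[Modification("repressed", "present")],
        statewidth=rep_spread_statewidth,
        offset_sampler=UniformSampler(1, rep_spread_statewidth, signed=False)))

    if cleaner_mode == "active_wins":
        cleaners = [BindingFactor(
            name="bf.cleaner", profile=SequenceProfile(kind="none"),
            predicate=LayerPredicate.of(("active", "present"),
                                        ("repressed", "present")),
            mods=[Modification("repressed", "absent")],
            statewidth="match")]
    elif cleaner_mode == "conflict_erase_both":
        cleaners = [BindingFactor(
            name="bf.cleaner", profile=SequenceProfile(kind="none"),
            predicate=LayerPredicate.of(("active", "present"),
                                        ("repressed", "present")),
            mods=[Modification("active", "absent"),
                  Modification("repressed", "absent")],
            statewidth="match")]
    elif cleaner_mode == "literal":
        cleaners = [
            BindingFactor(
                name="bf.cleaner", profile=SequenceProfile(kind="none"),
                predicate=LayerPredicate.of(("active", "present")),
                mods=[Modification("active", "absent")],
                statewidth="match"),
            BindingFactor(
                name="bf.cleaner.repressed", profile=SequenceProfile(kind="none"),
                predicate=LayerPredicate.of(("repressed", "present")),
                mods=[Modification("repressed", "absent")],
                statewidth="match"),
        ]
    else:
        raise ModelError(f"unknown cleaner_mode {cleaner_mode!r}")
    factors.extend(cleaners)

    default_abund = {
        "bf_OCT4": 5000, "bf_SOX2": 5000, "bf_KLF4": 5000, "bf_MYC": 5000,
        "bf_repressor": 20_000, "bf.RepSpread": 20_000,
        "bf.cleaner": 10_000_000_000,
    }
    if cleaner_mode == "literal":
        default_abund["bf.cleaner.repressed"] = 10_000_000_000
    bundle = ModelBundle(
        name="oskm_model",
        layer_names=layer_names,
        factors=factors,
        abundances=abundances or default_abund,
        n_cycles=100,
        snapshot_every=10,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Desk-scale demos on synthetic genomes
# ---------------------------------------------------------------------------

@dataclass
class DemoAnnotation:
    """Synthetic annotation shipped with a demo: TSS points and gene lists."""

    tss: list[tuple[str, int, str]] = field(default_factory=list)  # chrom, pos, gene
    gene_lists: dict[str, set[str]] = field(default_factory=dict)
    telomere_windows: list[tuple[str, int, int]] = field(default_factory=list)

    def write_tss_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, pos, gene in self.tss:
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{gene}\n")

    def write_gene_lists(self, path) -> None:
        with open(path, "w") as fh:
            for list_name in sorted(self.gene_lists):
                for gene in sorted(self.gene_lists[list_name]):
                    fh.write(f"{gene}\t{list_name}\n")


def _scaled_abundance(full_value: int, genome_bp: int, full_bp: int,
                      floor: int) -> int:
    return max(floor, round(full_value * genome_bp / full_bp))


def build_sir_demo(chrom_length: int = 100_000, telomere_window: int = 2_000,
                   n_interior_singles: int = 20, variant: int = 2,
                   n_cycles: int = 50
                   ) -> tuple[SyntheticGenomeSpec, ModelBundle, DemoAnnotation]:
    """Desk-scale SIR demo: one 100-kb chromosome, telomeric GGTGT clusters.

    Each 2-kb telomere window carries a cluster of single motifs plus
    three gapped double motifs; the interior gets isolated singles.
    Abundances are rescaled from the yeast-scale defaults by genome
    length (floor 2 so the demo stays stochastic but non-degenerate).
    """
    spec = SyntheticGenomeSpec(
        n_chroms=1,
        chrom_length=chrom_length,
        base_composition=(0.31, 0.19, 0.19, 0.31),  # yeast-like AT richness
        telomere_window=telomere_window,
        planted_motifs=[
            MotifPlant(RAP1_MOTIF, count=5, region="telomere_start"),
            MotifPlant(RAP1_MOTIF, count=5, region="telomere_end"),
            MotifPlant(RAP1_MOTIF, count=3, region="telomere_start",
                       double_gap=(0, 3)),
            MotifPlant(RAP1_MOTIF, count=3, region="telomere_end",
                       double_gap=(0, 3)),
            MotifPlant(RAP1_MOTIF, count=n_interior_singles, region="uniform"),
        ],
    )
    ab = _scaled_abundance(500, chrom_length, SACCER3_BP, floor=2)
    bundle = build_sir_model(
        variant, abundances={"RAP1": ab, "Sir3p": ab, "Sir3.spreader": ab})
    bundle.n_cycles = n_cycles
    bundle.name = f"sir_demo_model_{variant}"
    annotation = DemoAnnotation(
        telomere_windows=[("chr1", 1, telomere_window),
                          ("chr1", chrom_length - telomere_window + 1, chrom_length)])
    return spec, bundle, annotation


def build_oskm_demo(statewidth: int, chrom_length: int = 200_000,
                    n_tss: int = 30, island_fraction: float = 2 / 3,
                    n_cycles: int = 100,
                    cleaner_mode: str = "active_wins"
                    ) -> tuple[SyntheticGenomeSpec, ModelBundle, DemoAnnotation]:
    """Desk-scale OSKM demo: 200-kb chromosome with annotated synthetic TSS.

    TSS are evenly spaced; two-thirds of them sit inside a planted CpG
    island (mirroring the island frequency at human promoters).  Most TSS
    carry a planted OCT4 motif just downstream; a minority have no
    planted activator and rely on background motif occurrences.  The
    background is CpG-depleted (as vertebrate genomes are), so the
    island-detecting regular expression is island-specific.
    """
    chrom = "chr1"
    spacing = chrom_length // (n_tss + 1)
    tss_positions = [spacing * (i + 1) for i in range(n_tss)]
    genes = [f"G{i + 1:03d}" for i in range(n_tss)]

    island_idx = [i for i in range(n_tss) if i % 3 != 2][: round(island_fraction * n_tss)]
    island_set = set(island_idx)
    # OCT4 planted at most TSS; every 4th islanded TSS and the last few
    # island-free TSS are left activator-free so coverage depends on
    # statewidth reach rather than a guaranteed promoter-proximal site.
    oct4_idx = [i for j, i in enumerate(island_idx) if j % 4 != 3]
    free_idx = [i for i in range(n_tss) if i not in island_set]
    oct4_idx += free_idx[: max(0, len(free_idx) - 3)]

    island_len = 500
    spec = SyntheticGenomeSpec(
        n_chroms=1,
        chrom_length=chrom_length,
        base_composition=(0.30, 0.20, 0.20, 0.30),
        telomere_window=1,
        cpg_depletion=0.85,
        planted_motifs=[
            MotifPlant("ATGCAAAT",
                       positions=tuple((chrom, tss_positions[i] + 80)
                                       for i in sorted(oct4_idx))),
            MotifPlant("CACGTG", count=12, region="uniform"),
            MotifPlant("GCCAMGCCTC", count=10, region="uniform"),
        ],
        cpg_islands=[
            IslandPlant(count=len(island_idx), length=island_len, cg_density=0.15,
                        positions=tuple((chrom, tss_positions[i] - (island_len - 50))
                                        for i in sorted(island_idx))),
        ],
    )

    scale_floor = 1
    ab = {
        name: _scaled_abundance(5000, chrom_length, HG38_BP, scale_floor)
        for name in OSKM_MOTIFS
    }
    ab["bf_repressor"] = _scaled_abundance(20_000, chrom_length, HG38_BP, scale_floor)
    ab["bf.RepSpread"] = _scaled_abundance(20_000, chrom_length, HG38_BP, scale_floor)
    ab["bf.cleaner"] = 10_000_000_000
    if cleaner_mode == "literal":
        ab["bf.cleaner.repressed"] = 10_000_000_000
    bundle = build_oskm_model(statewidth, abundances=ab, cleaner_mode=cleaner_mode)
    bundle.n_cycles = n_cycles
    bundle.name = f"oskm_demo_sw{statewidth}"

    annotation = DemoAnnotation(
        tss=[(chrom, tss_positions[i], genes[i]) for i in range(n_tss)],
        gene_lists={
            "island_promoters": {genes[i] for i in island_idx},
            "island_free": {genes[i] for i in range(n_tss) if i not in island_set},
        },
    )
    return spec, bundle, annotation


def build_scaled_demo(model: str, **kwargs
                      ) -> tuple[SyntheticGenomeSpec, ModelBundle, DemoAnnotation]:
    """Dispatch to the SIR or OSKM desk-scale demo builder."""
    if model == "sir":
        return build_sir_demo(**kwargs)
    if model == "oskm":
        return build_oskm_demo(**kwargs)
    raise ModelError(f"model must be 'sir' or 'oskm', got {model!r}")
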