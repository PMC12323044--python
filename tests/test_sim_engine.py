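from pathlib import Path

import numpy as np
import pytest

from layersim import (
    BindingFactor,
    ConstantSampler,
    GenomeRef,
    Hit,
    Interval,
    LayerPredicate,
    Modification,
    NormalSampler,
    SequenceProfile,
    SimulationConfig,
    UniformSampler,
    apply_binding_factor,
    create_layerset,
    place_modification,
    run_cycle,
    run_replicates,
    run_simulation,
    sample_hits,
)
from layersim.samplers import SamplerError
from layersim.sim_engine import ConfigError


def consensus(pattern, strand="forward"):
    return SequenceProfile(kind="consensus", pattern=pattern, strand_policy=strand)


class TestSampleHits:
    def hits(self, n):
        return [Hit("c", i * 10 + 1, i * 10 + 5) for i in range(n)]

    def test_returns_all_when_abundant(self):
        hits = self.hits(10)
        assert sample_hits(hits, 20, np.random.default_rng(0)) == hits

    def test_subset_reproducible_and_distinct(self):
        hits = self.hits(100)
        a = sample_hits(hits, 5, np.random.default_rng(3))
        b = sample_hits(hits, 5, np.random.default_rng(3))
        assert a == b and len(set(a)) == 5
        assert all(h in hits for h in a)
        assert a == sorted(a, key=lambda h: (h.chrom, h.start))

    def test_uniformity_over_many_draws(self):
        """Each of 4 hits drawn with frequency 0.25 +/- 0.02 over 20k draws."""
        hits = self.hits(4)
        rng = np.random.default_rng(12345)
        counts = {h: 0 for h in hits}
        for _ in range(20_000):
            counts[sample_hits(hits, 1, rng)[0]] += 1
        for h in hits:
            assert abs(counts[h] / 20_000 - 0.25) < 0.02

    def test_zero_is_empty(self):
        assert sample_hits(self.hits(3), 0, np.random.default_rng(0)) == []


class TestPlaceModification:
    def test_centering_arithmetic(self):
        iv = place_modification(Hit("c", 101, 105), 147, None,
                                np.random.default_rng(0), 10_000)
        assert (iv.start, iv.end) == (30, 176)
        assert iv.width == 147

    def test_clipping_at_chromosome_start(self):
        iv = place_modification(Hit("c", 8, 12), 147, None,
                                np.random.default_rng(0), 10_000)
        assert (iv.start, iv.end) == (1, 83)

    def test_fully_off_chromosome_is_dropped(self):
        iv = place_modification(Hit("c", 1, 5), "match",
                                ConstantSampler(-100), np.random.default_rng(0), 10_000)
        assert iv is None

    def test_match_statewidth_preserves_footprint(self):
        iv = place_modification(Hit("c", 100, 147), "match", None,
                                np.random.default_rng(0), 10_000)
        assert (iv.start, iv.end) == (100, 147)

    def test_signed_offset_applied_directly(self):
        iv = place_modification(Hit("c", 101, 105), 11, ConstantSampler(50),
                                np.random.default_rng(0), 10_000)
        assert (iv.start, iv.end) == (148, 158)  # center 103+50, width 11

    def test_magnitude_offset_gets_random_sign(self):
        rng = np.random.default_rng(0)
        centers = []
        for _ in range(200):
            iv = place_modification(Hit("c", 5_000, 5_000), 1,
                                    NormalSampler(147, 0, signed=False), rng, 10_000)
            centers.append(iv.start)
        assert set(centers) == {5_000 - 147, 5_000 + 147}

    def test_spreading_sampler_moments(self):
        """Sampled spreading distances recover mean 147 and SD 30."""
        rng = np.random.default_rng(77)
        sampler = NormalSampler(147, 30, signed=False)
        draws = np.array([sampler.draw(rng) for _ in range(20_000)])
        assert abs(draws.mean() - 147) < 1.0
        assert abs(draws.std() - 30) < 1.0

    def test_persistently_invalid_statewidth_errors(self):
        with pytest.raises(SamplerError):
            place_modification(Hit("c", 10, 20), ConstantSampler(0), None,
                               np.random.default_rng(0), 10_000)


class TestApplyBindingFactor:
    @pytest.fixture
    def genome(self):
        return GenomeRef([("c", "A" * 495 + "GGTGT" + "A" * 500)])

    def test_single_placement(self, genome):
        ls = create_layerset(genome, ["A"])
        bf = BindingFactor("f", consensus("GGTGT"),
                           mods=[Modification("A", "present")], statewidth=10)
        n = apply_binding_factor(ls, bf, 1, np.random.default_rng(0))
        assert n == 1
        ivs = ls.layers["A"].intervals()
        assert len(ivs) == 1 and ivs[0].width == 10
        assert ivs[0].start <= 498 <= ivs[0].end  # contains the match center

    def test_zero_abundance_noop(self, genome):
        ls = create_layerset(genome, ["A"])
        bf = BindingFactor("f", consensus("GGTGT"),
                           mods=[Modification("A", "present")], statewidth=10)
        assert apply_binding_factor(ls, bf, 0, np.random.default_rng(0)) == 0
        assert ls.covered_bp("A") == 0

    def test_joint_modifications(self, genome):
        ls = create_layerset(genome, ["A", "B"], {"A": [Interval("c", 1, 100)]})
        bf = BindingFactor(
            "f", SequenceProfile(kind="none"),
            predicate=LayerPredicate.of(("A", "present")),
            mods=[Modification("A", "absent"), Modification("B", "present")],
            statewidth=11)
        apply_binding_factor(ls, bf, 1, np.random.default_rng(0))
        # placement centered on [1,100] midpoint 50 -> [45,55]
        assert ls.layers["A"].intervals() == [Interval("c", 1, 44),
                                              Interval("c", 56, 100)]
        assert ls.layers["B"].intervals() == [Interval("c", 45, 55)]

    def test_n_applied_never_exceeds_abundance(self, genome):
        ls = create_layerset(genome, ["A"])
        bf = BindingFactor("f", consensus("A"),
                           mods=[Modification("A", "present")], statewidth=5)
        for abundance in (0, 1, 7, 10_000):
            n = apply_binding_factor(ls, bf, abundance, np.random.default_rng(1))
            assert n <= abundance


class TestRunCycle:
    def test_recruitment_chain_within_one_cycle(self):
        """A factor whose predicate needs a layer written earlier in the
        same cycle sees those updates (sequential-asynchronous order)."""
        genome = GenomeRef([("c", "A" * 200 + "GGTGT" + "A" * 200)])
        ls = create_layerset(genome, ["potential", "bound"])
        writer = BindingFactor("w", consensus("GGTGT"),
                               mods=[Modification("potential", "present")],
                               statewidth="match")
        reader = BindingFactor("r", SequenceProfile(kind="none"),
                               predicate=LayerPredicate.of(("potential", "present"),
                                                           ("bound", "absent")),
                               mods=[Modification("bound", "present")],
                               statewidth="match")
        applied = run_cycle(ls, [writer, reader], {"w": 10, "r": 10},
                            np.random.default_rng(0), 1)
        assert applied == {"w": 1, "r": 1}
        assert ls.layers["bound"].intervals() == ls.layers["potential"].intervals()

    def test_zero_abundances_only_history(self, toy_genome):
        ls = create_layerset(toy_genome, ["L"])
        bf = BindingFactor("f", consensus("ACGT"),
                           mods=[Modification("L", "present")], statewidth=5)
        run_cycle(ls, [bf], {"f": 0}, np.random.default_rng(0), 1)
        assert ls.covered_bp("L") == 0
        assert len(ls.history) == 1

    def test_factor_order_matters_for_antagonists(self):
        genome = GenomeRef([("c", "GGTGT" + "A" * 95)])
        writer = BindingFactor("writer", consensus("GGTGT"),
                               mods=[Modification("L", "present")], statewidth=20)
        eraser = BindingFactor("eraser", SequenceProfile(kind="none"),
                               predicate=LayerPredicate.of(("L", "present")),
                               mods=[Modification("L", "absent")], statewidth="match")
        outcomes = []
        for order in ([writer, eraser], [eraser, writer]):
            ls = create_layerset(genome, ["L"])
            run_cycle(ls, order, {"writer": 5, "eraser": 5},
                      np.random.default_rng(0), 1)
            outcomes.append(ls.covered_bp("L"))
        assert outcomes[0] == 0 and outcomes[1] > 0


class TestRunSimulation:
    def small_config(self, seed=7, n_cycles=20, snapshot_every=10):
        genome = GenomeRef([("c", ("ACGT" * 50 + "GGTGT") * 4)])
        bf = BindingFactor("f", consensus("GGTGT"),
                           mods=[Modification("L", "present")], statewidth=30,
                           offset_sampler=NormalSampler(40, 10, signed=False),
                           cacheable=True)
        return SimulationConfig(
            genome=genome, layer_names=["L"], factors=[bf],
            abundances={"f": 2}, n_cycles=n_cycles,
            snapshot_every=snapshot_every, seed=seed)

    def test_snapshot_cadence(self):
        res = run_simulation(self.small_config())
        assert sorted(res.snapshots) == [10, 20]

    def test_history_shape(self):
        res = run_simulation(self.small_config())
        assert len(res.history) == 20  # 1 layer x 20 cycles
        assert [h.cycle for h in res.history] == list(range(1, 21))

    def test_determinism_byte_identical_snapshots(self, tmp_path):
        run_simulation(self.small_config(), tmp_path / "a")
        run_simulation(self.small_config(), tmp_path / "b")
        assert _trees_identical(tmp_path / "a", tmp_path / "b")

    def test_different_seed_differs(self):
        r1 = run_simulation(self.small_config(seed=1))
        r2 = run_simulation(self.small_config(seed=2))
        assert r1.final.layers["L"] != r2.final.layers["L"]

    def test_genome_immutable_across_simulation(self):
        config = self.small_config()
        before = config.genome.content_hash()
        run_simulation(config)
        assert config.genome.content_hash() == before

    def test_monotone_accumulation_without_erasers(self):
        res = run_simulation(self.small_config(n_cycles=30, snapshot_every=None))
        covered = [h.covered_bp for h in res.history]
        assert all(b >= a for a, b in zip(covered, covered[1:]))

    def test_invalid_config_rejected(self, toy_genome):
        bf = BindingFactor("f", consensus("GGTGT"),
                           mods=[Modification("ghost", "present")], statewidth=5)
        config = SimulationConfig(genome=toy_genome, layer_names=["L"],
                                  factors=[bf], abundances={"f": 1}, n_cycles=1)
        with pytest.raises(ConfigError):
            run_simulation(config)


class TestRunReplicates:
    def config(self):
        genome = GenomeRef([("c", ("ACGT" * 30 + "GGTGT") * 3)])
        bf = BindingFactor("f", consensus("GGTGT"),
                           mods=[Modification("L", "present")], statewidth=20,
                           offset_sampler=UniformSampler(1, 50, signed=False))
        return SimulationConfig(genome=genome, layer_names=["L"], factors=[bf],
                                abundances={"f": 1}, n_cycles=10,
                                snapshot_every=None, seed=0)

    def test_coverage_bounded_by_replicate_count(self):
        from layersim import sum_coverage

        results, failures = run_replicates(self.config(), 3, base_seed=100)
        assert not failures
        track = sum_coverage([r.final.layers["L"] for r in results],
                             results[0].final.genome)
        assert track.per_base("c").max() <= 3

    def test_replicates_differ(self):
        results, _ = run_replicates(self.config(), 4, base_seed=50)
        layers = [r.final.layers["L"] for r in results]
        assert any(layers[0] != l for l in layers[1:])

    def test_single_replicate_reproducible_in_isolation(self, tmp_path):
        run_replicates(self.config(), 3, base_seed=10, out_dir=tmp_path / "all")
        solo = run_simulation(
            SimulationConfig(**{**self.config().__dict__, "seed": 12}),
            tmp_path / "solo")
        assert _trees_identical(tmp_path / "all" / "rep_0002", tmp_path / "solo")

    def test_failed_replicate_reported_not_fatal(self):
        def flaky(cycle_index):
            raise RuntimeError("boom")

        bad = self.config()
        bad.abundances = {"f": flaky}  # abundance callable that raises
        results, failures = run_replicates(bad, 3, base_seed=0)
        assert len(failures) == 3 and all(r is None for r in results)
        assert [f.index for f in failures] == [0, 1, 2]


def _trees_identical(a: Path, b: Path) -> bool:
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    if files_a != files_b:
        return False
    return all((a / f).read_bytes() == (b / f).read_bytes() for f in files_a)
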