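# Methods

## The simulation model

A *layer set* is an immutable genome (ordered named chromosomes over
`ACGTN`; lower case is upper-cased on load and anything outside the
alphabet becomes `N`) plus named binary layers. A layer is a set of
1-based, inclusive intervals kept sorted, non-overlapping and with
touching runs merged — presence/absence has no meaningful boundary
between adjacent marked bases. Coordinates convert to 0-based half-open
only at BED/bedGraph boundaries.

A *binding factor* matches a combination of sequence and layer state and
applies modifications where it binds:

- **consensus** profiles (IUPAC alphabet) report every matching window,
  overlapping occurrences included; with `strand_policy: both` the
  reverse strand is scanned via the reverse-complemented pattern, and a
  palindromic pattern is reported once per position. A genome `N`
  matches only the profile character `N`.
- **PWM** profiles score every window with a log-odds matrix and report
  those scoring at least `threshold × max attainable score`
  (default threshold 0.90; matrices may be given as JASPAR-style count
  matrices, converted with +0.25 pseudocount per cell against a uniform
  background). Windows containing `N` never pass.
- **regex** profiles use the standard regex-engine contract:
  non-overlapping, leftmost matches, forward strand only (the shipped
  CpG-island pattern is strand-symmetric in practice).
- **none** profiles match by layer state alone: candidates are the
  maximal intervals of the first layer the predicate requires present,
  filtered by the remaining terms.

Predicates are conjunctions of `(layer, present|absent)` terms. A
`present` term holds when the candidate footprint overlaps the layer by
at least 1 bp; spreading models rely on this partial-overlap recruitment
at mark edges. A containment mode (footprint fully inside the layer) is
available per call for stricter reading semantics.

Because the genome never changes, sequence scans for factors marked
`cacheable` are performed once per layer set and reused across cycles; a
scan counter makes cache behaviour observable, and results with and
without the cache are identical by construction.

## The cycle engine

One cycle applies every factor in declared order against the *current*
state (sequential-asynchronous update). This choice is deliberate: the
SIR recruitment chain (nucleator → reader → spreader) propagates within
one cycle, instead of needing three; the cost is that factor order
matters, which the test suite demonstrates on a constructed
writer/eraser pair rather than hiding.

Per factor and cycle, at most *abundance* modifications happen: if more
candidate matches exist, a uniform subset is drawn without replacement.
A modification re-applied to an already-marked region is a no-op by
interval algebra but still consumes abundance — finite molecules are
spent, not refunded. Abundances may be constants, per-cycle sequences,
or callables of the cycle index.

Placement: the modified interval is centred on the match midpoint,
displaced by a sampled offset (magnitude samplers get a uniformly random
sign, giving bidirectional spreading), sized to `statewidth`, and
clipped to the chromosome; a placement falling entirely off-chromosome
is dropped. `statewidth: "match"` modifies exactly the matched
footprint — used by factors whose natural footprint *is* the region to
modify (the reader, repressor and cleaner factors below). A statewidth
sampler yielding < 1 bp is re-drawn up to 100 times, then errors.

All randomness flows from a single numpy PCG64 generator seeded from the
configuration; replicate *r* of a replicate set uses `base_seed + r`, so
any replicate reproduces in isolation and results are independent of
execution order. Snapshots (per-layer BED + JSON manifest + TSV history)
are taken at every multiple of `snapshot_every`; identical config + seed
yields byte-identical files. The history records, per cycle and layer,
the interval count and covered bp — the minimal pair of statistics that
summarises a binary layer (recorded once per cycle; these are the
authoritative records).

## Exemplar models and their parameters

**SIR (yeast).** Layers `sir3_potential`, `sir3_bound`. RAP1 (consensus
`GGTGT`, both strands, cacheable, statewidth `match`) marks potential;
Model 2 replaces the profile with the regex `GGTGT.{0,3}GGTGT` (same
strand, forward), restricting seeding to doubled motifs. Sir3p (profile
none; potential present AND bound absent; statewidth 147 bp ≈ one
nucleosome) converts potential to bound; `Sir3.spreader` (bound present)
re-marks bound with an offset drawn as |N(147, 30²)| bp, random sign.
Defaults: 200 cycles, snapshots every 10. Abundances are not dictated by
the model itself; the defaults (500 per factor, sized for a ~12 Mb
genome) are package choices exposed as configuration.

**OSKM (human).** Layers `active`, `repressed`. The four activator
consensi (`ATGCAAAT`, `WTTGT`, `GCCAMGCCTC`, `CACGTG`; both strands;
abundance 5000 each) share one statewidth — the swept parameter — and
carry empty predicates: activation ignores repression. The repressor
(regex `(CG.{0,20}){4}CG`, five CpGs pairwise within 20 bp; abundance
20,000) marks `repressed` over its matched CpG chain only where nothing
is active. `bf.RepSpread` (repressed present AND active absent;
abundance 20,000) widens repression with statewidth 1,000 bp and a
uniform 1–1,000 bp offset — a package default, exposed as a parameter.
`bf.cleaner` (abundance 10¹⁰, i.e. saturating) resolves doubly marked
regions; it runs last in the cycle.

Cleaner semantics were a genuinely open design point. The default,
`active_wins`, erases the repressed mark over any active interval that
overlaps it: activation overwrites repression, which is the behaviour
consistent with high-statewidth runs driving nearly all promoters active
while early repression is progressively overwritten. Two alternatives
remain available: `conflict_erase_both` (both marks erased over the
conflicted active interval — under this rule island promoters end every
cycle unmarked, so activation can never saturate) and `literal` (all
active and repressed regions erased every cycle). Either can be selected
per model build.

## Synthetic genomes and the desk-scale demos

The generator draws background bases i.i.d. from a base composition,
then writes planted features over the background at collision-free
positions (rejection sampling, 1,000 retries per feature; pinned
positions are placed first since they have no retry freedom). Features —
single motifs, gapped double motifs, CG-dense island segments — are
recorded verbatim with 1-based coordinates in a truth list (BED6+1 on
disk), so scanners can be validated against known ground truth.
Placement regions: uniform, either-end telomeric, or a specific
chromosome end; IUPAC characters in planted motifs are expanded to
concrete bases at random.

Background CpG depletion (`cpg_depletion`: the fraction of background CG
dinucleotides whose G is mutated to A/T) emulates the CpG depletion of
vertebrate genomes. Without it, a uniform background carries a CG every
~16 bp and the island regex matches everywhere; with depletion ~0.85 the
background match rate is negligible and planted islands stand out, as
they do against a real vertebrate background.

**SIR demo** (100-kb chromosome, AT-rich yeast-like composition, 2-kb
telomere windows): five single GGTGT motifs plus three gapped doubles
planted per telomere window, 20 isolated singles in the interior; 50
cycles; abundances rescaled from the yeast-scale defaults by genome
length with a floor of 2.

**OSKM demo** (200-kb chromosome, CpG-depleted background): 30 evenly
spaced annotated TSS; two-thirds sit inside a planted 500-bp CpG island
(island density mirrors its frequency at human promoters); most TSS
carry a planted OCT4 motif 80 bp downstream, while a minority have no
planted activator and can only be reached through background motif
occurrences — this is what makes promoter activation depend on
statewidth reach. Extra MYC and KLF4 sites are scattered uniformly; SOX2
sites occur naturally at background frequency. Abundances rescale the
full-scale values by genome length with a floor of 1 (strict
proportionality would give < 1 per cycle at 200 kb); the cleaner stays
saturating. Annotated gene lists (`island_promoters`, `island_free`)
ship with the demo.

What the demos show — and what they do not: the desk-scale suites
demonstrate the *mechanisms* (telomeric versus chromosome-wide
silencing under double- versus single-motif seeding; activation
increasing with statewidth; repression concentrating at island-bearing
promoters). They do not reproduce numbers tied to a particular reference
genome: real genomes have non-uniform composition, repeat structure and
motif clustering that the i.i.d.-background generator deliberately does
not emulate. Full-genome configurations for both models are provided
under `docs/configs/` and require user-supplied reference FASTA (and a
TSS BED for promoter summaries); site counts there depend on the strand
and overlap conventions, which `motif-count` exposes as flags.

## Numerical and I/O choices

- Interval algebra runs on sorted numpy arrays; every mutation
  re-normalises the affected chromosome. Tests check randomized
  operation sequences against an independent per-base boolean-array
  oracle, and coverage summation against per-base counting.
- Coverage tracks are run-length encoded; bedGraph export omits
  zero-count runs and merges equal-count neighbours.
- Consensus scanning uses a lookahead regex so overlapping occurrences
  are reported; PWM scanning scores all windows vectorised with an
  `N`-column of −∞.
- TSS are treated as 1-bp points; a TSS counts as covered by a state iff
  that base lies inside the state's interval set (an optional `--window`
  widens points symmetrically). Genes named in a list but missing from
  the TSS set are logged and dropped; TSS in no list form the implicit
  `all_other_genes` list.
- Snapshot manifests record genome names/lengths (not sequences); a
  restore validates the supplied genome against them.

## Known limitations

- Binary layers only: no scores, strands or multi-state marks within a
  layer.
- No dynamic feedback from expression state to abundances (abundance
  schedules are static functions of the cycle index only).
- Haploid genomes; no 3D-contact-mediated spreading.
- The sequential factor order is part of the model definition; models
  with antagonistic factors are order-sensitive by design.
- Approximate (mismatch-tolerant) consensus matching is not supported;
  use a PWM with a sub-maximal threshold instead.

## Reproducing the reference quantities

`scripts/acceptance.py --seed S --out results/acceptance.json` rebuilds
the SIR model from its defaults, draws 100,000 spreading-distance
magnitudes from the spreader's offset distribution with the given seed,
and writes the empirical mean in bp. All values in that file are
computed at run time by the package itself.
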