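# evofoot

Phylogenetic footprinting of orthologous non-coding DNA.

`evofoot` aligns one or more test-species sequences to a reference region
with a BLAT-style k-mer seeded local aligner (seeds of 9 and 11 bp on both
strands, diagonal merging, extension, chaining, and bounded DP fill-in at
chain junctions), then projects the per-species conservation calls onto the
reference as a single cased sequence: uppercase where at most `R` test
species fail to conserve a base ("strict" print at `R=0`, the usual relaxed
print at `R=1`). From that mask it extracts conserved sequence blocks
(CSBs) and CSB clusters, and maps CSBs into distantly related contigs to
decide ultraconserved status (uCSBs), linear order (colinearity),
orientation (microinversions) and two-target sharing. A sequence-evolution
simulator with exact ground truth (planted conserved blocks in fast-evolving
spacers, optional inversions/translocations) supports end-to-end testing
without any genome downloads.

## Command line

```sh
# simulate a dataset with known truth
evofoot simulate --length 3000 --blocks 200:40,600:55,1500:35 \
    --n-species 8 --p-block 0.02 --p-spacer 0.30 --indel-rate 0.01 \
    --seed 1 --out-dir sim/
# or a named scenario:
evofoot simulate --preset gambiae-ladder --seed 1 --out-dir sim/

# conservation print + scorecard (R = max species allowed to miss a base)
evofoot evoprint --ref ref.fasta --tests tests.fasta --relax 1 \
    --track --out-prefix out/print

# conserved sequence blocks and clusters
evofoot csbs --ref ref.fasta --tests tests.fasta --relax 1 \
    --min-csb 10 --cluster-gap 100 --out-prefix out/csb

# map CSBs into one or two distant-taxon contigs
evofoot map-ucsb --csbs out/csb.csbs.fasta \
    --target distant1.fasta --target2 distant2.fasta \
    --min-identity 0.8 --min-coverage 0.5 --out-prefix out/map

# per-species conservation scores only
evofoot scorecard --ref ref.fasta --tests tests.fasta
```

All outputs are plain text (wrapped print with a 1-based ruler, TSV tables,
BED6, FASTA); log lines go to stderr. Every subcommand is deterministic
given its inputs, flags and seed.

## Library

The package mirrors the pipeline stages:

- `evofoot.seqio` — FASTA/BED6 I/O, region strings (`"chr3L: 6,821,518-6,823,267"`),
  reverse complement. Coordinates are 0-based half-open; spans are `end - start`.
- `evofoot.align` — `align_species(ref, test, AlignParams())` gives per-base
  conservation calls plus the retained chains.
- `evofoot.conservation` — `build_profile`, `make_evoprint(profile, R)`,
  `render_evoprint`, `scorecard`.
- `evofoot.csb` — `call_csbs(print, CallerParams(L_min, G, max_interruptions))`,
  `cluster_csbs`.
- `evofoot.mapper` — `map_csb`, `analyze_colinearity`, `classify_sharing`.
- `evofoot.simulate` — `SimulationConfig`, `generate_dataset`, `truth_to_bed`.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes independent oracles (a naive Smith-Waterman DP, a
quadratic k-mer enumerator) checked against the production aligner, property
tests for the mask/caller invariants, CLI round trips, and
`tests/test_acceptance.py` with one test per acceptance criterion.
Note: `test_criterion_3_planted_block_recovery` is expected to fail — the
criterion demands 90% planted-block recovery from the strict (R=0) print at
a per-species block substitution rate of 0.02 over 8 species, but the
per-base probability that all 8 species conserve a base is at most
0.98^8 ≈ 0.851, so the bound is unattainable by construction; the relaxed
(R=1) print recovers ≈ 97% on the same data.

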