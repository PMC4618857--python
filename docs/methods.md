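# Methods

## Subsampling model

Mapper behaviour is estimated from reads simulated off randomly sampled
regions rather than the whole genome. The sampling budget is tiered by
genome size `G`:

| condition      | sampled fraction |
|----------------|------------------|
| G < 100 Mb     | 50%              |
| G < 500 Mb     | 25%              |
| otherwise      | 1%               |

with a global floor of 15 Mb (`SamplingConfig.min_total`) so that small
genomes still yield a statistically robust read set. Tier bounds are strict
(`<`), using Mb = 10⁶ bp. When the computed target exceeds the genome's
usable length the target is capped with a warning; genomes below the floor
are therefore sampled in full where possible. Each region is
`region_factor × read_length` long (default 10×; the insert size replaces
the read length for paired-end libraries). Sampling stops at the first
region whose addition meets or exceeds the target, so the total lies within
one region length above it.

**Region placement.** Regions must not overlap. Placing fixed-length
segments uniformly at random and rejecting overlaps jams at ~74.8% density
(the random-sequential-adsorption / Rényi parking limit), while the 15 Mb
floor demands 75% of a 20 Mb genome — we verified empirically that even an
exact gap-indexed sampler (uniform over all remaining feasible starts)
stalls at ~74.9%. The sampler therefore tiles each contig into
region-length windows at a per-contig random phase and draws windows
uniformly without replacement: placement stays random and seed-reproducible,
non-overlap is structural, and any density up to ~100% is reachable.
Windows with more than 10% N (`max_n_fraction`) are rejected — reads
simulated from N runs are meaningless — and 1000 consecutive N-rejections
or an exhausted window pool abort with a diagnostic rather than silently
under-sampling. Contigs shorter than one region are excluded.

**Artificial chromosome.** Sampled regions are concatenated, separated by N
runs of `pad_factor × read_length` (default 2×; insert size when paired).
Because the padding is at least as wide as any simulated span, no read can
bridge two regions. The `RegionMap` records each region's offset and lifts
artificial coordinates back to reference coordinates exactly; positions
inside padding map to an `IN_PADDING` sentinel. All coordinates are 0-based
half-open internally; conversion to SAM's 1-based convention happens only
at SAM boundaries, preventing off-by-one drift.

## Simulation model

A single mutated haplotype is produced from the artificial chromosome
(zygosity is out of scope): each non-N base becomes a SNP with probability
`snp_rate` (alternate drawn uniformly from the other three bases); indel
events start with probability `indel_rate` per base, are insertions with
probability `insertion_fraction` (default 0.5), and have lengths uniform on
[1, `max_indel_length`] (default 10 bp). Deletions are truncated so they
never swallow N bases; N positions are never mutated. The mutation map
stores a piecewise-linear liftover from mutated to original coordinates;
mutated positions inside an insertion, which have no original image, lift
to the nearest preceding original position — deterministic and monotone.

Reads start uniformly on the mutated sequence (spans touching an N are
redrawn); strand is uniform; paired mode emits FR-oriented mates with
insert length ~ Normal(`insert_mean`, `insert_sd`) truncated to ≥ 2× the
read length. Sequencing errors are uniform per-base substitutions at
`error_rate`; base qualities are the constant Phred score
`−10·log₁₀(error_rate)` capped at 41 (41 when the rate is 0).
Platform-specific error modes (e.g. homopolymer indels) are not modelled;
higher-error platforms are emulated by raising `error_rate`, and exact
platform emulation is available through the gold-standard import path
(FASTQ + SAM from any external simulator). The read count is
`round(coverage × sampled bp / read_length)` with `coverage` defaulting to
1× of the sampled regions (rounded down to even in paired mode).

A read's truth position is the leftmost reference coordinate of its span
(SAM-POS-like) on both strands, which makes the positional rule directly
comparable to SAM records. Truth is authoritative in the sidecar TSV keyed
by (read id, mate); read names mirror it
(`sim:<serial>|<contig>|<pos1>|<F/R>|<mate>`) for convenience, and names
not matching that grammar decode as unparseable rather than erroring.

## Evaluation rules

Only primary alignments count (secondary 0x100 and supplementary 0x800
records are dropped). A mapped read passes the quality gate iff
`mapq ≥ mapq_threshold`; the default threshold 0 therefore excludes
nothing. (The gate could equally be read as strictly-greater; we chose ≥ so
the default is a no-op, and the boundary is pinned by tests.) A passing
read is correct iff (1) its reported leftmost position is within
X = `floor(tolerance_fraction × read_length)` bp of the truth — inclusive,
default 50% — and (2) it is on the truth strand, on the truth contig;
otherwise wrong. Failing the gate, or being absent/unmapped, counts as not
mapped. Mates of a pair are classified independently; no proper-pair
condition is imposed. For variable-length real reads X uses the configured
read length, not per-read lengths. 0/0 ratios define to 0.

Note the recall denominator `C + N` excludes wrongly mapped reads; whenever
W > 0 it exceeds the conventional `C / total`, which is reported alongside
as `recall_conventional` rather than silently substituted.

For genuine reads no truth exists, so the evaluator reports the percentage
of reads mapped at/above the threshold, with the FASTQ read count (not the
SAM record count) as denominator; the same number of reads as a simulation
would use is first subsampled, mate pairs kept together.

## Harness

Mappers are command templates with `{reference} {fastq1} {fastq2} {params}
{output}` placeholders, rendered with shell-safe quoting. Indexing runs
first and is excluded from `mapping_wall_time`, which wraps the mapping
command only — mapping-only time extrapolates to large read sets, index
time does not. Peak memory is the maximum resident set summed over the
mapper's process tree, polled from `/proc` every 50 ms; this is a lower
bound on the true peak. Missing executables raise a configuration error
naming the binary; non-zero exits and timeouts are recorded per run.

The built-in baseline mapper indexes the genome's exact k-mers
(k = min(17, read length) by default), collects candidate placements from
the read's first k-mer on both strands, verifies each by full-read Hamming
distance, and reports the best placement with mapq 60 if uniquely best and
0 on ties (leftmost placement wins for determinism). It exists so that the
entire pipeline, including subprocess execution, is testable without
third-party binaries — its recall drops with any error in the first k-mer,
which the worked example in the README exploits deliberately. The oracle
mapper emits each read at its truth coordinates and is used as a test
double: any evaluation of an oracle run must be 100% correct.

## Reporting

`report.json` and `report.tsv` are canonical (floats rounded to 5
significant digits, identical bytes in both); `report.html` is a pure view
over them with a matplotlib SVG scatter (fixed hash salt, no timestamps, so
re-rendering identical inputs is byte-identical). Quadrants relative to the
declared baseline use strict inequality for "+" on both axes — ties are
"−", since a setting that merely equals the baseline is not an improvement.
Exactly one result carries the highest-accuracy marker `A` and one the
highest-throughput marker `S`; ties break toward the lexicographically
smallest parameter label. In real-data mode the vertical axis is percent
mapped and the horizontal axis reads per second.

## What the synthetic fixtures do and do not show

Synthetic genomes are i.i.d. base sequences at a configurable GC content.
They exercise every pipeline contract — tier arithmetic, non-overlap,
liftover exactness, classification rules, rate recovery — but contain no
repeats, segmental duplications, or compositional structure, so absolute
accuracies measured on them overstate what a mapper achieves on a real
genome (on i.i.d. sequence nearly every 17-mer is unique). Conclusions
about *relative* parameter settings transfer better than absolute numbers;
for real references, pass the genome FASTA directly.

Test problem sizes are scaled to the fixtures: suites use 100 kb toy
genomes with correspondingly reduced `min_total` floors (a configuration
parameter, so the tier logic under test is unchanged), 1 Mb sequences for
3σ binomial rate-recovery checks, and 20/60/120 Mb genomes to exercise all
three sampling tiers at their true defaults.

## Known limitations

- No quality-by-cycle profiles, PCR duplicates, structural variants, or
  splicing in the simulator; no CIGAR-aware or interval-overlap evaluation
  (position/strand distance is the method's deliberate, fast criterion).
- Peak memory by polling undercounts short-lived allocation spikes.
- The baseline mapper is a testing instrument, not a competitive aligner.
- SAM only (no BAM/CRAM output); single-machine execution.
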