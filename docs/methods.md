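# Methods

This document records the model, the parameter choices, the numerics, and
the deliberate limitations of `bsalign`.

## 1. Conversion model and strand dispatch

A bisulfite read can originate from four strands. Each strand determines
the read conversion applied before alignment, the converted genome copy to
search, and the orientation of valid hits:

| strand | read conversion | genome copy | orientation | XG | XR (mate 1) |
| --- | --- | --- | --- | --- | --- |
| OT | C→T | C→T | forward | CT | CT |
| OB | C→T | G→A | reverse-complement | GA | CT |
| CTOT | G→A | C→T | reverse-complement | CT | GA |
| CTOB | G→A | G→A | forward | GA | GA |

Directional libraries search OT and OB; non-directional libraries all four.
Mate 2 of a pair always carries the complementary read conversion, so its
XR tag is the flip of mate 1's.

RRBS reduction performs an in-silico MspI digest (`C^CGG`, cut offset 1)
and keeps inter-cut fragments of 40–600 bp (configurable), naming reduced
contigs `chrom:start-end` with 0-based half-open coordinates on the source.

## 2. Scoring scheme and the built-in aligner

End-to-end (ungapped) scoring: a perfect alignment scores 0. A mismatch at
base quality *q* costs `round(2 + 4·min(q, 40)/40)` (2 at Q0 up to 6 at
Q40); any N (in read or reference) costs 1. An alignment is valid iff its
score is at least `min_score(L) = −0.6 − 0.6·L`. These are the standard
defaults of end-to-end short-read alignment; the affine threshold makes the
maximum tolerable penalty `floor(0.6 + 0.6·L)`.

The built-in backend is deterministic and provably exhaustive:

- **Pigeonhole seeding.** With a maximum of `m` tolerable mismatches
  (`m = max_penalty // min effective per-base penalty`), the read is split
  into `m+1` chunks; any valid placement must match at least one chunk
  exactly. Chunk k-mers are looked up in a sorted polynomial-hash index of
  the converted genome and the candidate offsets are verified by an exact
  scorer. When chunks would be shorter than 6 bp the backend falls back to
  a full linear scan. Both paths are numba-compiled; the test suite asserts
  they produce identical top-2 results on randomized reads.
- **Top-2 semantics.** Per strand the backend returns the best hit (ties
  broken by smallest coordinate, then contig name) and the second-best
  score as XS.
- **Pairs.** Mate 1 is aligned genome-wide; mate 2 is searched only inside
  the proper-pair window (opposite orientation, insert ≤ 1000 bp). The pair
  score is the sum of mate scores; the strand's XS is the second-best pair
  total. This windowed search is equivalent to the full cross product of
  valid placements.

An external backend (`align_external`) drives a `bowtie2`-compatible
command over the converted genomes with per-strand `--norc`/`--nofw` flags
and parses its SAM stream; mapped records without an AS tag are rejected.
The built-in backend refuses genomes above a configurable size
(10 Mb default) and points at the external contract instead.

## 3. Arbitration and mapping quality

The per-strand candidates are compared by score. If the maximum is attained
by exactly one strand, that candidate wins and its XS is raised to the best
score among the losing strands; if two or more strands tie, the read is
reported unmapped.

MAPQ is then recalculated from the final (AS, XS) pair on a 0–42 scale.
Scores are normalized to `o = (AS − sc_min)/(0 − sc_min)`, the attained
fraction of the span between the minimum valid score `sc_min` and perfect.
Without a secondary alignment the thresholds 0.8/0.7/0.6/0.5/0.4/0.3 map to
42/40/24/23/8/3 (else 0). With a secondary alignment, a tie (`AS == XS`)
yields at most 3; otherwise the base value `23 + round(19·(AS−XS)/(0−sc_min))`
is capped by an `o`-dependent ceiling (0.8→42, 0.6→30, 0.4→8, 0.3→3).
This table is this package's own monotone heuristic in the style of
end-to-end aligners; it guarantees range [0, 42], monotonicity in AS and in
the gap to XS, ≤3 for ties, and 42 only for well-separated near-perfect
alignments. For pairs, AS/XS are pair totals and `sc_min` is the sum of the
per-mate minima. Extraction treats MAPQ ≥ 10 as confident.

Methylation strings are assigned against the *unconverted* genome, CIGAR
aware (insertions and soft clips yield `.`, deletions advance the
reference), positionally parallel to the SAM-stored (reference-oriented)
sequence. Context is undefined (no call) across Ns and contig edges.

## 4. Extraction, M-bias, duplicates

**Extraction** filters records (primary, non-duplicate, MAPQ ≥ 10) and
calls (Phred ≥ 5, optional per-(strand, mate) inclusion windows in 1-based
positions from the sequencing 5' end). Proper pairs are processed jointly:
for each reference position covered by both mates, agreeing usable calls
count once, a lone usable call is used, and a high-quality disagreement
discards the position. Counts are keyed by (contig, position, strand,
context); `merge_cpg` folds bottom-strand counts onto the top-strand C of
each CpG and conserves totals. Outputs: per-context bedGraph (percent plus
raw counts, so files re-parse losslessly), methylKit and BSseq tables.

**M-bias** tallies CpG calls per (strand, mate, read position) under the
extractor's record/call filters but deliberately without trims. The
suggested inclusion window per stratum is the longest run of positions
whose methylation lies within a tolerance of the median over the central
50 % of covered positions; zero-coverage positions are neutral. The default
tolerance is 2 percentage points; at desk-scale coverage the per-position
sampling noise (sd ≈ 1.5–2 points at a few hundred calls per position)
warrants 5–6 points, which is what the worked examples use. Sparse strata
(< 5 covered positions) get full-length bounds with a warning.

**Duplicate marking** treats pairs as units. The positional signature is
(contig, originating strand, sorted soft-clip-adjusted 5' coordinates) —
forward 5' = alignment start − leading clip, reverse 5' = last aligned base
+ trailing clip. Within a positional bucket, units are greedily grouped in
coordinate-then-name order: a unit joins the first group whose
representative's calls it matches (calls with Phred ≥ 5; positions where at
most one side has a usable call do not differentiate), else founds a new
group. One unit per group — the highest summed base Phred — stays unmarked.
Because grouping only ever splits positional buckets, the method marks a
subset of what position-only marking would mark; methylation-discordant
copies at one position are recognized as distinct molecules.

## 5. Simulator realism and evaluation

Fragments are drawn uniformly over positions, contigs
length-proportionally, strands fairly; paired fragment lengths are normal
(mean 200, sd 30, clamped to [read length, contig]). Per fragment cytosine
(on its originating strand) the methylation state is Bernoulli with a
context-dependent probability (defaults CpG 0.7, CHG 0.01, CHH 0.01 —
mammalian-like); unmethylated cytosines convert to T with the conversion
rate (default 1.0), and uniform substitution errors (default 0.1 %) are
layered last. Base qualities are constant Q40 with an optional linear 3'
decay. `five_prime_unmeth=k` forces the first k read positions' genomic
cytosines to read unmethylated, creating the end-repair artifact that
M-bias analysis is designed to catch. Methylation is drawn per fragment,
not per site, so every extracted call is an independent Bernoulli sample of
the context probability — which is what makes the binomial confidence
intervals in the acceptance tests exact.

Truth is encoded in read names (`sim{i}:{chrom}:{start1}:{strand}:{mask}`);
the decoder splits the index prefix from the left and the three trailing
fields from the right, so contig names containing `:` (RRBS fragments)
survive. Evaluation calls a unit correct iff it maps to the truth contig
with the unit's leftmost coordinate equal to the truth start; pairs use the
minimum mate MAPQ for thresholding. `concordance` compares two runs of the
same reads by (contig, leftmost start).

## 6. Problem sizes and numerics

Problem sizes are this package's own choices, selected so every property is
measured with comfortable statistical power on a desktop machine:

- Parameter recovery: 100 kb genome, 50,000 pairs (~50×), error 0 — about
  125,000 CpG calls, giving a 99 % binomial interval of ±0.0033 around 0.70.
- Duplicated-segment ambiguity: 35 kb genome containing an exact 5 kb
  repeat, 3,000–4,000 single-end reads.
- M-bias: 10 kb genome, 20,000–30,000 single-end reads, so each read
  position carries ~900+ CpG calls per stratum.
- Demos and unit tests: 5–20 kb genomes.

Numerics: alignment kernels work on uint8-encoded sequence (A=0 C=1 G=2
T=3 N=4) with int64 scores; penalty vectors are precomputed per quality
string; the seeded path uses base-4 polynomial k-mer hashes (k ≤ 31,
int64, no collisions since the hash is injective for k-mers without N) and
`numpy.searchsorted` over a sorted index. All randomness flows through
seeded `numpy.random.default_rng` / `random.Random` instances; FASTQ output
is gzipped with fixed mtime-free streams, making simulations byte-identical
across runs.

## 7. Limitations

- The built-in aligner is ungapped (substitutions only); indel support
  exists downstream (CIGAR-aware XM/extraction) for externally produced
  alignments, but the built-in backend will not place indel reads.
- The external backend requires a `bowtie2`-compatible executable at run
  time; it is a subprocess contract, not a bundled aligner.
- MAPQ recalculation matches the published threshold structure of
  end-to-end aligners but is not bit-identical to any specific external
  tool's table.
- The simulator models substitution errors and positional methylation bias
  but not indels, adapter read-through, or quality-dependent error
  profiles.
- Single-threaded by design; genomes are held in memory and capped at
  10 Mb for the built-in backend.
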