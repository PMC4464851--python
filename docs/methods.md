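# Methods

This note documents the models, algorithms and numerical choices behind
phylosites, what the synthetic-data generator does and does not emulate,
and the limitations that follow.

## The core procedure

### Subsampling

Composite-genome assembly deliberately uses only a subset of the data: at
low pooled coverage, only regions shared (conserved) across species
accumulate enough k-mer support to assemble, which is exactly the bias the
composite is meant to have. The subsample is drawn with reservoir sampling
(Algorithm R): the first *q* records fill the reservoir and record *i* > *q*
replaces a uniformly chosen slot with probability *q/i*. The pass is single
and memory is O(q + chunk); slot draws are generated with numpy in chunks
but replacements are applied in stream order, so the semantics are exactly
Algorithm R and the result is deterministic for a given seed regardless of
input chunking. Paired reads are sampled as units so mates are never split.

The per-species quota is `round(depth × G / (read_length × n_species))`
reads, with target depth 10 and G the user's approximate genome size. The
equal split across species is a design choice (the pooled budget could be
split by data volume instead); equal representation biases the composite
toward regions present in all species, which is what downstream site
calling needs.

### Assembly

The built-in assembler is a canonical-k-mer (strand-merged) de Bruijn graph
with conventional short-read cleaning:

- k-mers with count < `min_kmer_count` (default 2) are dropped — this
  removes most sequencing-error k-mers and most species-unique sequence at
  ~1.25× per-species subsample coverage;
- dead-end unitigs shorter than 2k hanging off a junction are clipped;
- parallel unitigs connecting the same junction pair (bubbles — typically
  alternative alleles across species) are popped keeping the
  higher-mean-coverage path, ties broken toward the lexicographically
  smaller sequence. This is what makes the composite carry the most common
  base at variable columns, and makes assembly fully deterministic;
- cleaning rounds repeat until a fixed point (bounded at 24 rounds), then
  maximal unbranched paths ≥ `min_contig_length` (default 100) become
  contigs, sorted by (length desc, sequence) for stable ids.

Defaults k = 31 and `min_kmer_count` = 2 are conventional values for 100 bp
reads; they are configurable. There is no scaffolding or repeat
resolution — conserved-region contigs are sufficient as a coordinate
system for site calling. An adapter contract
(`assemble.external_assembler_adapter`) lets any executable producing
contig FASTA stand in for the built-in assembler.

### Mapping

Reads are mapped by seed-and-extend: exact seed hits (default 25 bp, taken
at non-overlapping offsets plus the read tail, both orientations) against
an every-position index of the composite, then ungapped end-to-end
extension counting mismatches. The best placement wins if mismatches ≤
`max_mismatch_frac × read_length` (default 0.1); reads whose best score is
tied across ≥ 2 placements are discarded as ambiguous, so repeats
contribute nothing rather than noise. Mates are mapped independently —
pairing constraints would not change strict-consensus calls and would
complicate the adapter contract. Ungapped extension suffices because the
simulation is substitution-only and strict consensus makes indel-containing
placements unusable anyway; the external-mapper adapter
(`mapper.external_mapper_adapter`, SAM/BAM via pysam, tested against bwa)
supports gapped mappers, with deleted reference bases receiving nothing and
inserted read bases ignored.

The pileup is a pure per-site sum over accepted reads, so it is invariant
to read order; work is chunked and merged in fixed order, so any worker
count produces byte-identical output. That determinism-under-parallelism
contract is the package's replacement for external parallelization tools.

### Calling and site extraction

Strict consensus with a depth floor: a species' call at a site is the
observed base only if exactly one base was observed and total depth ≥
`min_depth`, else `N`. The floor defaults to 2 because a single-read
"consensus" would pass raw sequencing errors straight through to the
alignment, defeating the purpose of strictness; it is configurable, and
raising it can only convert calls to `N` (monotonicity is tested).
Within-species polymorphism (e.g. pooled individuals) yields `N` by
design — that is missing data, not an error.

Locus filtering drops whole contigs with fewer than `min_callable_sites`
(default 3) sites having ≥ 1 non-N call; the default is small enough to
keep short conserved contigs and large enough to drop junk. "Variable"
requires two distinct *called* bases — sites that vary only through `N` are
excluded. Column order is (contig id lexicographic, offset ascending), so
alignments are reproducible byte for byte. Sweeping `max_unknown` yields
nested site sets, which is tested as an invariant.

## The simulation benchmark

### Trees

Two 8-taxon topologies are fixed with alphabetical tip nesting —
pectinate `(((((((A,B),C),D),E),F),G),H)` and balanced
`(((A,B),(C,D)),((E,F),(G,H)))` — with every branch (terminal and
internal) at 0.01 substitutions/site, times an integer scaler 1..6. The
trees are therefore not ultrametric. Long-deep / short-deep variants
power-transform node heights before scaling: with depths d measured from
the root and H the maximum tip depth, heights h = (H − d)/H are raised to
exponent 2 (long-deep) or ½ (short-deep) and depths rebuilt as
H(1 − hᵉ). The transform preserves topology and total height, keeps all
branch lengths positive for any positive exponent, and is the identity at
exponent 1 (all tested against an independent recursive traversal).

### Genome evolution

Jukes–Cantor, substitution-only: each branch of length d flips each site
independently with p(d) = ¾(1 − e^(−4d/3)), uniformly to one of the three
other bases, compounding along root-to-tip paths (multiple hits and
reversals occur, as in the continuous-time process). The root composition
is uniform. Excluding indels is deliberate: it keeps all taxa on one
coordinate system so the evaluator can match output sites to truth
*exactly* rather than through an alignment heuristic. Genome sizes in tests
and acceptance runs are 4–100 kb — large enough for thousands of variable
sites, small enough for minutes-scale runs on one CPU; all rate and
recovery quantities scale with genome length only through counting noise.

### Read simulation

Fragment lengths are normal(300, 30) truncated to
[read_length, genome_length]; starts are uniform over valid positions; the
fragment strand is random; mate 1 reads the 5′ end and mate 2 the reverse
complement of the 3′ end (swapped on minus-strand fragments). Error is a
uniform per-base substitution at 0.1 % by default, with the quality string
a constant Phred+33 character encoding that rate. This parametric model
replaces empirical sequencer error profiles on purpose: the benchmark's
conclusions turn on coverage and divergence, not on position-dependent
error structure, and a uniform model keeps truth matching exact (no indel
errors). Real-data features *not* emulated: position- and motif-dependent
error rates, quality-score variation, adapter read-through, PCR duplicates,
coverage biases (GC, mappability), rate heterogeneity across sites, and
indel evolution. Passing benchmarks therefore demonstrate correctness of
the pipeline's logic under its stated model, not robustness to every
artifact of real sequencing.

### Evaluation

Composite contigs are anchored to the true coordinate system by exact
31-mer lookups (every ⌊k/4⌋ bases, both strands) in an index of all taxa's
true genomes; a placement is accepted when ≥ 80 % of the anchors that hit
anywhere agree on one (offset, strand). Among anchors with hits, the
denominator excludes anchors spanning variable sites that match nowhere;
contigs with zero hits stay unplaced. Placements were validated against an
independent edit-distance (infix) alignment oracle.

Scoring is deliberately strict: an output site is a true recovery only if
its anchored coordinate is a truly variable position *and* every non-N call
matches the true base there (reverse-complemented for minus-strand
contigs). A real variable position reported with a wrong pattern counts as
a false positive, because it misleads phylogenetic inference exactly as a
positional error would. Sites on unplaced contigs also count as false
positives — they cannot be verified. Missed true sites are attributed to
the first matching category in a fixed order (simulated depth < min_depth
in some taxon → no placed contig covers the position → some species'
mapped depth < min_depth → other), since the categories overlap and an
ordered assignment keeps them a partition.

Clade support uses the clean two-state split rule: all clade members share
one called base, all called non-members share a single different base, and
the site respects the alignment's missing-data ceiling. The looser
alternative ("a state private to the clade, others free to vary") was
considered and rejected as the default because it credits sites that do
not unambiguously separate the clade.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `target_depth` | 10 | fold | pooled subsample depth; conserved regions assemble, unique ones do not |
| `k` | 31 | bp | assembly k-mer; odd, conventional for 100 bp reads |
| `min_kmer_count` | 2 | count | prunes error/unique k-mers |
| `min_contig_length` | 100 | bp | one read length; shorter contigs carry little signal |
| `seed_length` | 25 | bp | mapper seed; 4 non-overlapping seeds per 100 bp read |
| `max_mismatch_frac` | 0.1 | fraction | accepts reads ≤ ~10 % diverged from the composite |
| `min_depth` | 2 | reads | strict-consensus floor; 1 would pass raw errors through |
| `min_callable_sites` | 3 | sites | locus filter |
| `max_unknown` | swept | species | missing-data ceiling per site |
| `insert_mean`, `insert_sd` | 300, 30 | bp | typical short-insert library |
| `error_rate` | 0.001 | per base | typical post-filter substitution error |

## Numerical and degenerate-input choices

- All randomness flows from one master seed through stable
  blake2b-derived per-stage seeds (< 2³¹), so any stage can be reproduced
  in isolation and worker counts never affect results.
- Assembly tie-breaks (bubble winner, contig order, unitig start order) are
  lexicographic on sequence, making composites bit-reproducible.
- Empty inputs degrade softly: no reads → empty composite (warning, not
  error); empty alignment → explicit empty-output warning and a report with
  false-positive rate 0; quota 0 → empty subsample.
- Mapping candidates that would run off a contig end are rejected rather
  than clipped (end-to-end contract).
- The evaluation report enforces its own accounting invariants
  (recoveries + false positives = output; miss categories partition the
  unrecovered truth) at construction time.

## Known limitations

- The built-in assembler handles desk-scale data (≤ a few Mb of pooled
  subsample) in pure Python; for genome-scale work use the external
  assembler adapter.
- Ungapped mapping cannot rescue reads spanning real indels; on empirical
  data an external gapped mapper via the adapter is the right choice.
- Strict consensus discards heterozygous/polymorphic sites by design; the
  pipeline measures between-species variation only.
- Anchoring assumes substitution-only truth; it is a benchmark device, not
  a general-purpose aligner.
- At high divergence (scaler ≥ 3 of the benchmark, i.e. ≥ 6 % per branch)
  conserved 31-mers across all taxa become rare, the composite fragments,
  and recovery drops sharply — this mirrors the method's real sensitivity
  to deep divergence rather than an implementation artifact; in real
  genomes rate variation leaves slowly evolving loci that the benchmark's
  single-rate genomes lack.
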