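# Methods

venomxtend re-implements, as a tested library, the bespoke computational
steps of a deep venom-gland transcriptome pipeline built around very short
cDNA fragments (~170 nt) sequenced with 100-nt paired-end reads: merging the
overlapping mates into long composite reads by a binomial significance test,
completing or assembling transcripts with a greedy hash-table seed-extension
assembler ("the Extender"), clustering near-duplicate transcripts below 1%
nucleotide divergence, and estimating transcript abundance as the percentage
of reads mapping at high identity. A synthetic-data generator reproduces the
library geometry and abundance skew of such an experiment with full per-read
provenance, so every stage can be tested against known truth.

## Paired-read merging

For mates R1 and R2 (R2 reverse-complemented), every relative placement is
scored. A placement implying fragment length f overlaps in
n = min(L1, f) − max(0, f − L2) columns, of which k match exactly (N never
matches). Under the null that bases are independent and uniform,

    P(k | n) = C(n, k) (1/4)^k (3/4)^(n−k),

evaluated in log space (scipy `binom.logpmf`). A pair is merged only when
the minimum-probability placement has p < 1e−10 **and** the second-smallest
probability is at least 1000× larger; the ratio condition rejects
repeat-spanning pairs, and an exact tie for the minimum is a ratio of 1,
hence a rejection. A perfect overlap needs n ≥ 17 to reach 1e−10, so no
separate minimum-overlap heuristic is applied (`min_overlap` = 1).

Placements are enumerated over all fragment lengths f ∈ [1, L1+L2−1], which
includes adaptor read-through geometries (f below the read length); on
acceptance the bases beyond the fragment are deleted and counted in
`trimmed_adaptor_nt`. Overlap qualities recombine additively: agreement
gives base with q1+q2 capped at 60; disagreement keeps the higher-quality
base with quality |q1−q2| (a tie keeps the mate-1 base at quality 0); an N
defers to its partner. Non-overlap qualities are untouched. The additive
rule is one defensible reading of posterior-style quality recombination;
the cap and tie rules make it total and deterministic.

With inserts ~ Normal(170, 30) and 100-nt reads, pairs with insert > 183 nt
overlap by < 17 nt and cannot reach the significance threshold; the merged
fraction of a simulated library (~66%) is therefore a property of the insert
distribution, not a tuning target.

## The Extender

Seeds grow by concatenation. The k-mers at the two ends of every seed are
keys in a 5' table and a 3' table; for each read (then its reverse
complement), the read's end k-mers are looked up and the first hit extends
the matching seed end with the read's non-overlapping bases. The consumed
key is removed and the seed's new end k-mer inserted. Reads are scanned in
fixed order for N full cycles without resetting after an extension. Defaults
follow the published run: k = 100, 20 replicate seeds, 10 cycles, and only
reads whose every base is phred ≥ 30.

Replicate seeds are the seed trimmed by i bases from each end
(i = 0..r−1), each starting from different keys and extending independently;
the final call is a per-column majority across replicates anchored on the
seed. Two design points were settled empirically:

- **Key collisions.** When an extension would insert an end k-mer that is
  already a key (two replicates reaching the same coordinate), the default
  is to *share* the key: the colliding ends are recorded under one key and a
  matching read extends all of them together. The alternative of freezing
  the colliding end (`on_collision="freeze"`) makes replicate ends on the
  same transcript stall each other mid-sequence — ends funnel onto the same
  read-end coordinates — and destroys full-length recovery at realistic
  replicate counts. Initial-seed uniqueness is still enforced: a seed whose
  starting end k-mer duplicates an existing key is dropped with a warning.
- **Consensus coverage.** A column is emitted when covered by at least one
  replicate and contiguous with the seed; the base is the majority over the
  replicates covering that column, ties resolved to the lowest-index
  replicate. A quorum rule (> r/2 of all replicates) is too strict in
  sparse read sets, where only replicates whose trimmed ends happen to sit
  on the read-start grid can extend at all: extension requires a read
  end-k-mer *exactly* equal to a seed end k-mer, i.e. a read starting
  exactly k bases inside the end.

Two intrinsic properties of the algorithm matter for interpreting results:

- **Data hunger.** A growing end advances only via reads starting exactly k
  bases inside it; with λ read starts per coordinate the chain stalls
  permanently at a given step with probability e^(−λ). Full-length recovery
  of a 1.5–2.5 kb transcript (~20 steps per direction) therefore needs
  λ ≳ 4. The demonstration libraries use 300,000 pairs over a 20-transcript
  (~33 kb) transcriptome, matching the coverage regime of the original
  experiment (tens of millions of merged reads over a few Mb); at shallow
  depth the Extender returns honest partial sequences.
- **Allele mosaics.** Near-duplicate transcripts (< 1% divergence) with
  identical stretches longer than a read cannot be phased by exact-k-mer
  extension: chains switch haplotypes inside identical regions and produce
  full-length mosaics of the cluster's alleles. This is the same
  non-identifiability that motivates clustering at < 1% before
  quantification. Recovery of cluster members is accordingly asserted as
  full-length at < 1% divergence; unique transcripts are recovered exactly.

De novo mode seeds the run with `n_denovo_seeds` reads (default 1000) drawn
uniformly without replacement from reads of length ≥ k, and deduplicates
results by exact consensus identity. Seeds too short for 20 replicates use
the feasible maximum.

## Divergence, clustering, naming

Global alignment uses an affine unit-cost scheme (match 0, mismatch 1, gap
run of length L costs 5 + L) through `Bio.Align.PairwiseAligner`; a
hand-written Gotoh dynamic program serves as the oracle in tests. Divergence
is the mismatch fraction over **gap-free** columns only — the one definition
under which a splice-like 48-nt insertion variant is 0% divergent from its
parent and clusters with it. Columns containing N count as mismatches.

Clusters are connected components of the graph with edges at divergence <
1% (single linkage), computed on the annotated CDS when present, otherwise
the full sequence. Members are ordered by descending length then id and
lettered a, b, c…; singletons are unlettered. `name_clusters` assigns
CLASS-number names (e.g. CTL-3) from the members' class labels, numbering
within each class in cluster order; a cluster mixing classes is an error.
`indel_profile` reports the alignment's gap runs (sequence, position,
length), which is how block indels such as a 132-nt deletion between two
variants are called.

## Quantification

Reads are assigned to transcripts at a minimum identity of 95%, mirroring
high-stringency reference mapping. Candidate targets come from a shared
31-mer prefilter in either orientation; each candidate is scored by
semi-global (infix) alignment via edlib with identity defined as
1 − edit_distance / read_length, the "minimum match percentage" convention
of read mappers. Identity ties across different clusters discard the read
as ambiguous (a `fractional_ties` option splits it instead); ties within
one cluster count toward the cluster, which is the point of clustering at
the divergence below which reads cannot be uniquely assigned. Abundance
tables report per-target read counts, % of total reads, and % of
toxin-flagged reads, ranked within the toxin and nontoxin partitions.
Sub-sampling to a fixed number of reads (the original analysis used 10
million) is seeded and reproducible.

## Synthetic data

`simulate_transcriptome` builds random-sequence transcripts (default 20,
900–2400 nt) with `n_clusters` planted near-duplicate pairs: each parent
gets a variant at ~0.4% substitution divergence, and the first variant
additionally carries a 48-nt block insertion (the splice-variant case).
Abundances are geometric shares with the decay solved so the top transcript
takes ~6% of reads (the myotoxin-like skew); for small n where 6% is below
uniform, shares fall back to uniform. A trailing fraction of singletons is
flagged nontoxin. Planted structure is verified at generation time
(intra-cluster divergence < 1%, inter-cluster > 2%, shares summing to 1).
Abundances are fragment shares — the probability a read pair derives from
the transcript — because abundance throughout this pipeline means "% of
reads".

`simulate_reads` draws insert lengths from a rounded Normal(170, 30)
truncated to [50, 300] and to the transcript length. Fragmentation is
boundary-aware: with probability insert_mean/L a fragment is flush with the
transcript 5' or 3' end (every physical molecule's first and last piece are
flush), otherwise uniform in the interior. R1 is the fragment prefix and R2
the reverse-complement suffix; fragments below the read length run through
into a fixed synthetic adaptor (not a vendor sequence). Substitution errors
occur at a per-position rate interpolated linearly from the 5' rate
(default 0.0005, Q33) to the 3' rate (default 0.01, Q20), reproducing the
3'-declining quality profile; qualities are the deterministic phred
transform of that rate. Per-pair truth records source transcript, fragment
interval, error positions and adaptor lengths.

Not emulated: indel sequencing errors (the merger and Extender have no
indel handling, so substitution-only is the regime the methods are defined
for), rRNA/poly-A selection, intron retention, chimeric fragments, and
instrument-specific quality noise. Passing tests therefore demonstrate
correctness of the algorithms under their own model assumptions, not
robustness to artifacts outside them.

## Numerical and determinism choices

- Coordinates are 0-based half-open everywhere; phred+33 FASTQ.
- Binomial probabilities are computed in log space; double precision holds
  to p = (1/4)^300, far below any read-length regime here.
- ORF ties (equal protein length) resolve to forward strand, then smallest
  start, then lowest frame. ORFs without a stop codon are flagged and not
  "full-length". N codons translate to X.
- All stochastic steps (simulation, de novo seed draw, read sub-sampling)
  take explicit integer seeds; identical inputs and seeds give
  byte-identical outputs.
- Alignment traceback is the aligner's first optimal path (deterministic);
  only scores, gap runs and column counts are contract surface.

## Problem sizes in tests

The default test suite and the acceptance script use simulations sized to
exercise the statistical claims they test: 10,000 pairs for merger
correctness, 300,000 pairs (the study's coverage regime scaled to a 20
transcript transcriptome) for de novo assembly, and 100,000 mapped reads
for abundance recovery, where three binomial standard errors is a
sub-0.3-point tolerance on every cluster's percentage.
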