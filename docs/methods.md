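# Methods

This note documents the models and procedures `ssuflash` implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic fixtures do and do not emulate.

## Reference curation

The curation pass runs LSU removal → vector screening → alphabet
normalisation → low-complexity masking, and is idempotent (a second pass
is a byte-level no-op).

**LSU contamination.** Reference entries carrying a large-subunit rRNA
model hit with E ≤ 10⁻¹⁰ covering more than 10 % of the LSU model are
flagged dropped. Hits arrive as a 9-column GFF-like table (1-based
inclusive coordinates on disk, 0-based half-open in memory); model
scanning itself is out of scope — any HMM rRNA scanner's output can be
used. Flags only are changed, never sequence content, so the curation is
auditable.

**Low-complexity masking.** External maskers are parameterised but not
specified; we define the operator fully. A window of length 100 slides in
steps of 1; for every k in [4, 8] the window's k-mer Shannon entropy is
normalised by its maximum attainable value log₂ min(4ᵏ, n) (n = countable
k-mers in the window). If the normalised entropy falls below 0.7 for any
k, the window is low-complexity; within it, positions covered by k-mers
that *dominate* the window — count ≥ max(3, ⌈max-count/2⌉) — are flagged.
Flagging the dominating k-mers rather than whole windows pins the masked
interval to the repeated content itself (slack at most one k-mer length)
and ignores chance duplicates in high-entropy flanks. Flagged positions
merge into runs; only runs ≥ 20 bp are masked. Masking is hard (N), so
downstream k-mer seeding cannot start in masked regions, and k-mers
containing non-ACGT characters never contribute to window entropy — which
is also what makes the pass idempotent (masked runs cannot re-trigger or
grow). An exhaustive per-window oracle in the test suite checks the
rolling implementation position by position on sequences up to 500 bp.

**Vector screening.** Vector k-mers (k = 27, both strands) are matched
anywhere in a reference within Hamming distance 1; shortened k-mers down
to k = 11 are matched only when anchored at a sequence terminus. Matched
positions are trimmed and the longest clean fragment kept; records whose
longest fragment is shorter than 800 bp are dropped. Trimming rather than
wholesale discarding on internal hits follows from the length-after-trim
rule: a discard-only policy would make "after trimming" meaningless.

**Alphabet.** U → T; every IUPAC ambiguity code is replaced by a base
drawn uniformly from the codes it denotes, using one explicit seed, so
curated databases are reproducible. Normalisation runs *before* masking
so that an input N (ambiguity) and a masked N (hard mask) can never be
confused; masked intervals are tracked explicitly.

**Clustering.** NR99/NR96 de-replication is greedy centroid clustering:
records in decreasing length order (ties by id), each joining the first
centroid with global-alignment identity ≥ the threshold. Identity is
matching columns / alignment columns of an affine-gap global alignment
(match 1, mismatch −2, gap open −5, gap extend −2); the tools usually
named for this step define no formula, so the scoring is pinned here and
used consistently for clustering, closest-reference assignment, and
targeted-sequence matching.

## Read extraction

Reads are seeded against a canonical k-mer index (k = 13, odd to avoid
palindromes; masked regions contribute no postings). Candidates with at
least 2 co-linear seeds (same diagonal band, width 16) are extended by
aligning the read against the reference window around the seed diagonal
(infix alignment via edlib); identity is matches / alignment columns
including gap columns, the stringent reading of a minimum-identity mapping
cutoff. Placements below the 70 % floor are never reported. Each read
reports its best placement and all placements tied with it — mapper
semantics ("all ambiguous best-scoring hits"); sub-optimal placements
above the floor can be requested explicitly. A pair is retained iff at
least one mate has a hit, and both mates of retained pairs are written,
so assembly sees complete pairs. Insert size is the outer span of the two
mates' best placements on a shared reference. Identity histograms use 1 %
bins from the floor to 100; insert histograms 10-bp bins.

SAM pairing repair makes paired/proper-pair/mate-unmapped/mate-strand
flags and mate reference/position fields mutually consistent per pair,
strips `/1`/`/2` name suffixes, keeps orphan mates (flagged with an
unmapped mate), and is idempotent.

## Entropy QC

For each read, k-mers (k = 5, literal, not canonical, matching the
formula as stated) are counted over the L−k+1 sliding windows; windows
containing non-ACGT characters are skipped and the denominator adjusted.
H = −Σ pᵢ log₂ pᵢ; the attainable alphabet A is 4ᵏ unless the sequence is
too short to realise it, in which case A = L−k+1; R = 1 − H/log₂ A. R is
dimensionless in [0, 1]; the mean R over extracted reads near 0 indicates
the absence of low-complexity recruitment artifacts.

## Taxonomic summary

The taxonomy path of each hit's reference (semicolon-delimited SILVA-style
header) is a tuple of rank labels, domain first. Per pair, the LCA is the
longest common prefix over the paths of **all** hits of both mates pooled;
disjoint domains reduce to the root ("Unclassified"). Summaries truncate
to the requested level (1 = domain … 7 = species; class = 3 by default);
pairs classified above the level are reported as `(unclassified) <last
rank>` and counted at their own depth, so counts are conserved at every
level and coarser levels are exact roll-ups of finer ones. All hits are
weighted equally; no score-based down-weighting is applied.

## Assembly support

- k-mer ladder: reads ≥ 134 bp use the fixed ladder (99, 111, 127); below
  that, next-lower-odd(read length − 27, −17, −7). The fixed ladder is a
  hard override, not the limit of the subtraction rule (134 − 27 = 107 ≠
  99), so the two branches are implemented independently.
- EM reconstruction mode: reads > 152 bp run single-ended; paired runs
  use the observed mean insert when it exceeds 2.2 × read length, else
  the floor 2.2 × read length + 0.5. 40 iterations. The insert standard
  deviation is not derived from the mapping histogram (only the mean rule
  is defined); wrappers may supply their own.
- SSU regions on contigs: hits with E ≤ 10⁻¹⁰⁰ covering ≥ 0.6 of the
  model are extracted (minus strand reverse-complemented). When passing
  hits on one contig and model overlap by ≥ 50 % of the shorter hit, only
  the lowest-E hit is kept — overlapping-hit behaviour is otherwise
  unspecified.
- Assembled fraction: extracted reads are remapped to the assembled
  sequences with the same aligner at 98 % identity; the statistic is
  mapped reads / extracted reads (mates counted individually).
- Closest reference: best global identity ≥ 70 %, ties to the
  lexicographically first id.

## Multi-sample comparison

The taxonomy is treated as a tree whose nodes are path prefixes at depths
1..d, each with a unit branch. With Aᵢ the pairs of sample A classified
to node i or below and A_T the sample total, u = Σᵢ |Aᵢ/A_T − Bᵢ/B_T| and
u′ = u/(2d). The root is excluded (its term is identically 0), and nodes
with zero counts in both samples are omitted (mathematically identical).
Pairs classified above depth d contribute to their ancestors only, which
keeps u′ ≤ 1. u′ is symmetric, 0 exactly on identical normalised
cumulative profiles, and satisfies the triangle inequality; these are
verified empirically over hundreds of random profile triples, and the
tree computation is checked against a brute-force prefix-node enumeration
oracle. d = 4 (order) is the conventional comparison level.

Heatmaps report percent of classified pairs per taxon and sample; taxa
outside the top 30 are pooled as "Other" after clustering (the pooled row
is excluded from clustering). Samples are ordered by average-linkage
clustering on u′, taxa on the Euclidean distance of their percentage rows.

## Graph fishing

Fastg adjacency records are parsed into an undirected, orientation-blind
graph: a contig and its reverse complement are one node, every adjacency
one edge, because the goal is linking, not path reconstruction.
SPAdes-style `EDGE_n_length_L_cov_C` names yield length and coverage;
other header styles fall back to raw ids. Dangling adjacency targets are
a parse error naming the offending record. Fishing collects the full
connected component around each SSU-bearing contig (no hop limit by
default); components below a size threshold are flagged, never dropped.
Bin linking counts members per bin and reports the majority bin with its
fraction, flagging ties as ambiguous. Matching against targeted-assembly
sequences uses infix alignment identity at 98 %.

## Synthetic fixtures

The generators emulate the study conditions end to end: a ~1,500-bp SSU
gene mutated along a random taxonomy tree with hierarchical divergence
(domains far apart at 0.15 substitutions/site, class-level groups at
0.05, tips at 0.02 — mirroring how SSU identity scales with rank; groups
are populated round-robin so small fixtures always contain distinct
organisms); 100-bp paired-end libraries with 220 ± 110 bp inserts and 1 %
uniform substitution error, a configurable SSU-origin fraction (default
0.1) against a random background genome; planted LSU fragments,
homopolymer runs and vector 27-mers in designated reference records; and
planted-genome Fastg graphs (random connected intra-genome topology, one
SSU-bearing contig per genome, no inter-genome edges) with bin tables.
One global seed fans out to independent per-generator streams, so adding
a generator never perturbs the others; truth tables can regenerate every
error-free read from its reference coordinates.

What the fixtures do **not** emulate: realistic Illumina error profiles
(no quality model, indels, or position-dependent error), chimeras, tRNA
false-positive sources, conserved-region k-mer sharing between distant
taxa, or real SILVA taxonomy idiosyncrasies. Passing tests therefore
demonstrate the correctness of the operators and rules under controlled
conditions, not field performance on real libraries — sensitivity on the
synthetic library is near 100 % because reads sit at ~99 % identity to
their own reference, whereas real-world sensitivity also depends on
database completeness and error structure.

## Numerical choices and problem sizes

- All randomness flows from one explicit integer seed per entry point.
- Floating-point ties in best-hit selection use `np.isclose`; identity
  ties in closest-reference and targeted-matching break lexicographically.
- Degenerate inputs error early: empty sequences, L < k, level out of
  [1, 7], empty profile lists, empty samples in u′.
- Default verification sizes: 10,000 read pairs for extraction statistics,
  1,000 random profile pairs for the u′ oracle, 100 random planted graphs
  for fishing — sizes at which every check runs in seconds on one core
  while exercising the full code paths.

## Known limitations

- The internal seed-and-extend aligner matches external mappers only at
  the identity-cutoff level, not in their seeding or scoring details;
  SAM from external mappers can be substituted directly.
- Greedy clustering is O(n²) alignments in the worst case and is meant
  for curated reference sets, not raw read de-replication.
- `u′` operates on rank-truncated taxonomies; it is not branch-length
  UniFrac on a real phylogeny.
- Assembler and EM-reconstructor invocation is out of scope; the rules
  are exported as machine-readable parameters.
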