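# Methods

## The analysis model

The pipeline treats a dilution-transfer enrichment experiment as a set of
metagenome samples: one source inoculum and one or more consortium samples
derived from it. All inference is read-level and reference-based — no
assembly is performed here; contigs and their gene annotations are inputs.

### Hit filtering and family assignment

Reads arrive with tabular alignments against a family-labelled protein
reference (the blast-tab dialect `qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore [qlen]`). A hit is retained
when e ≤ 1e−15 and the coverage–identity ratio

    ratio = aln_length × %identity / query_length   (> 30, strictly)

exceeds 30%. The ratio mixes an alignment length in amino acids with a read
length in nucleotides; we convert the query length to amino acids
(`floor(qlen_nt / 3)`) for translated searches so a full-length perfect hit
scores ≈100, and use the nucleotide length unchanged for nucleotide
searches (`translated=False`). The strict inequality is kept: a hit at
exactly 30.0 fails. Each read then receives the family of its best
retained hit — highest bitscore, ties broken by lower e-value, then
lexicographic subject id. One family per read; multi-domain splitting is
out of scope. Whether the 30% rule should apply per hit or only to the best
hit is ambiguous; it is applied per hit before best-hit selection, which is
the more conservative reading.

### Profiles, folds, coverage

RA(f) = 100 · count(f) / N, where N is the number of database-matched reads
(a config switch allows normalizing by all quality reads instead). Class
profiles (AA/CBM/CE/GH/GT/PL) roll up by family prefix. The enrichment of a
family is log₁₀(RA_sample / RA_inoculum); when either RA is zero the fold
is undefined and reported as "n.d." — no pseudocounts, since a pseudocount
choice would dominate exactly the rare families the statistic is meant to
rank. Display rounding: 3 d.p. for RA and folds, 2 d.p. for coverage.

Coverage = total_Mb / (n_OTUs × 4 Mb), using 4 Mb as the reference
bacterial genome size and 16S OTUs at 97% identity as the genome-count
proxy. One printed reference value (the 10T sample) is inconsistent with
this formula applied to its printed inputs (198.10/(46×4) = 1.08, not
1.05); the formula is implemented as stated and the discrepancy left
unreconciled.

### Enrichment statistics

Each family yields a 2×2 table (family reads vs other matched reads, sample
vs inoculum). The two-sided Fisher p-value uses the point-probability
convention — the sum over all tables with the observed margins whose
hypergeometric probability does not exceed the observed table's — which is
what `scipy.stats.fisher_exact` implements; the test suite checks it
against an independent exhaustive enumeration. Intervals on the difference
of proportions follow the Newcombe–Wilson construction: with per-arm Wilson
limits (lᵢ, uᵢ) around pᵢ,

    lower = d − √((p₁−l₁)² + (u₂−p₂)²),  upper = d + √((u₁−p₁)² + (p₂−l₂)²).

Multiple testing: BH step-up q-values and Storey q-values with the
single-λ estimator π₀ = #{p > 0.5} / (0.5·m), clipped to (0, 1] (clipped to
1/m with a warning when every p is below λ — common here, where counts are
large and effects strong). λ is fixed at 0.5 rather than spline-smoothed:
deterministic and adequate at the tens-of-families scale. The p < 0.005
flag marks significantly enriched/depleted families. Both corrections are
reported side by side; no result is gated on one of them.

### Clustering and richness

`align_pair` is an exact affine-gap dynamic-programming aligner (match +1,
mismatch −1, gap open −2, gap extend −1; a length-k gap costs 2+(k−1)).
Traceback ties prefer the diagonal, then the vertical, then the horizontal
move, making every alignment deterministic. Pairwise identity is the
identical-column count of the global alignment divided by the shorter
sequence length (the CD-HIT global-identity convention), and clustering is
greedy-incremental: longest read first (ties by id), each read joining the
first representative at ≥97% identity. Representatives are therefore always
the longest members. A sound prescreen skips the DP when the bit-vector
edit distance d already implies no alignment can reach the threshold
(any alignment with m matches admits an edit script of cost ≤ la+lb−2m, so
m ≤ (la+lb−d)/2); the prescreen can only reject, never accept, so results
are identical to exhaustive DP — the oracle-equivalence tests check exactly
this. Reverse-complement matching is off by default because pipeline reads
are orientation-normalized at extraction (minus-orientation hits are
flipped using the subject-coordinate convention sstart > send); a flag
enables it for unoriented input. Richness = clusters/reads per family.

### LCA taxonomy

Per read, hits below score 35 or above expected 0.01 are dropped, the
survivors are banded to within 10% of the best bitscore, and at most 10 are
kept. The read is placed at the deepest taxonomy node on every retained
hit's root path. Sequence complexity is the Shannon entropy of overlapping
trinucleotides normalized by its attainable maximum log₂(min(64, windows));
reads below 0.3 are excluded. Min-support semantics: a node with fewer than
5 directly assigned reads (descendants excluded) passes its reads to its
parent, iterated deepest-first until stable; this push-up variant preserves
read counts, which relative-abundance bars require, and reads that reach
the root unsupported become unassigned. These two definitions (complexity
measure and min-support behaviour) are pinned here as package contracts —
they are tested against this specification, not against any external tool.
The taxonomy input is a 4-column TSV (node, parent, rank, name); a
converter from NCBI-style `nodes.dmp`/`names.dmp` is provided.

### HUL scan

Candidate contigs: length ≥5000 bp with at least one gene of
{GH2, GH3, GH29, GH31, GH43, GH92, GH95}. Hotspot rules (inclusive bounds,
union, each record noting which fired): (1) ≥10 kb and ≥2 GH genes;
(2) ≥35 kb and ≥1 GH gene. Coordinates are 0-based half-open internally
and 1-based inclusive in tabular I/O.

Affiliation combines two signals. ANIb: the contig is cut into 1020 bp
pieces (trailing piece kept at ≥510 bp); each piece is located on the
reference by bit-vector infix edit distance on both strands (an exact
search under unit costs, not a heuristic) and then re-scored by the exact
local aligner within the located window, keeping the full-DP cost
independent of reference length; pieces at ≥30% identity over ≥70% of
their length are hits, ANI is the mean hit identity and the hit fraction is
reported alongside. An exact infix match short-circuits to identity 100.
TTNF: 256-component tetranucleotide frequencies over the sequence plus its
reverse complement (ambiguous windows skipped), compared by Pearson r on
the raw frequencies without z-scoring. The best reference maximizes ANI,
ties broken by higher TTNF r, then id; if no reference produces an ANIb
hit, affiliation falls back to TTNF alone and is flagged. The 1020/30%/70%
fragment convention is the standard ANIb parameterization. Low ANI and
TTNF r against all references is the expected signature of loci from
as-yet-unsequenced genomes, and is reported, not suppressed.

## The synthetic-community generator

The generator emulates the statistical structure the analysis assumes, not
sequence biology:

- **Genomes** are i.i.d. backgrounds at a target G+C with planted gene
  cassettes filled from fixed per-label template sequences (600 bp genes,
  1500 bp 16S), so hits against the family reference are recoverable by
  construction. With `balance_gc` the intergenic composition compensates
  the balanced cassette composition so the genome-wide G+C hits the target
  even in cassette-dense genomes; without it, intergenic bases are drawn at
  the target directly, as the plain contract states.
- **Series**: transfer t has abundances ∝ inoculum × factorᵗ, renormalized
  — a deterministic geometric selection model.
- **Reads** are fixed-length (272 bp, the observed mean; a length
  distribution would add a nuisance parameter with no testing value),
  uniform start, uniform strand, substitution-only errors (no indels, so
  identity arithmetic stays transparent). A read inherits a cassette's
  label when ≥50% of it overlaps the cassette, giving each read at most one
  label.
- **Alignment tables** are synthesized by running the exact local aligner
  on every read that overlaps a cassette by ≥30 bp, emitting rows above a
  score floor of 40, with amino-acid lengths (floor(nt/3)) for the
  family-reference table and nucleotide lengths for the rRNA table, and
  e-values derived from the raw score on a Karlin–Altschul-shaped curve.
  Intergenic reads emit nothing. Subject ids are `<label>|<genome>`, which
  also carries the taxon for the LCA stage.

The bundled study scenario uses five 60 kb genomes at G+C 0.38–0.65, each
carrying three exclusive CAZy families (8 × 600 bp cassettes per family,
plus one 16S), an inoculum of weights (0.12, 0.18, 0.30, 0.22, 0.18) and
per-transfer factors (W series: 1.8, 1.4, 1.0, 0.85, 0.8) chosen so the
low-G+C genomes are enriched — reproducing the G+C selection signal — and
so the rarest family still accumulates a few hundred reads per sample at
50 000 reads, keeping the sampling error of a log₁₀ fold near 0.03.
Families are exclusive to one genome by design: the expected RA of a family
is then analytic (exact position counting of the ≥50%-overlap rule), and
the planted log₁₀ fold is known without simulation. Because every cassette
has the same length, the inflation of assignment counts by
partial-overlap reads (the ratio filter admits reads down to ≈30% overlap)
is the same multiplicative factor for every family and sample, so it
cancels exactly in the fold — this is why fold recovery is unbiased even
though raw counts exceed truth-label counts.

What the generator does **not** emulate: phylogenetically realistic
sequence (templates are random, so cross-family homology is absent and
assignment is easier than on real CAZy data); indels and quality
trajectories; chimeras; copy-number variation of 16S; shared families
across genomes. Passing the recovery tests therefore demonstrates the
correctness of the statistical machinery under its own assumptions, not
annotation accuracy on diverged real sequences. OTU counts from clustering
272 bp fragments of a 16S gene overestimate the OTU count of full-length
genes (random offsets cap pairwise overlap), so synthetic coverage values
are formula-correct but not calibrated to real surveys.

## Problem sizes and numerical choices

- Default recovery runs: 5 genomes, 50 000 reads/sample, error rate 0.01,
  one 3-transfer series; the planted-fold recovery tolerance is ±0.1 in
  log₁₀ units. The acceptance script uses the same scale.
- Pipeline clustering subsamples each family to 150 reads (seeded) and OTU
  clustering to 200 16S reads; richness and OTU counts are reported with
  the subsample size.
- Fisher calibration: 10 000 null replicates at n = 200/arm (p-value cached
  over the discrete count grid); Newcombe coverage: 5000 replicates at
  n = 100/arm, true difference 0.1.
- All randomness flows from a single integer seed; per-stage streams are
  derived as (seed, fixed-offset) seed sequences, and stage outputs are
  byte-identical across reruns of the same configuration.
- Degenerate inputs: zero matched reads → empty profile with warning;
  zero-variance vectors → undefined correlation flag; zero OTUs or empty
  reference sets → errors; a query length under one codon fails the ratio
  filter with a warning.

## Known limitations

- Read assembly within families (contig building) is out of scope; HUL
  inputs are externally assembled contigs with gene annotations.
- The ANIb locator assumes the best infix under unit edit costs coincides
  with the best local-alignment locus; at the divergence levels where ANIb
  is informative (>70% identity) this holds, but for barely related
  sequences the located window may not contain the optimal local alignment
  (such fragments fail the 70% coverage gate either way).
- Richness values depend on the subsample cap and read length and are
  comparable within a run, not across datasets.
- The LCA complexity and min-support definitions are package contracts
  (documented above), not re-implementations of any specific external
  tool's undocumented behaviour.
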