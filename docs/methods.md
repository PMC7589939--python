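# Methods

This note records the scientific and numerical choices behind
`methanocosm`: what each statistic assumes, how the synthetic study is
constructed, and where the design was genuinely open.

## Taxonomic abundance (TA)

Per-scaffold abundance is read signal divided by scaffold length,
rescaled to a per-sample total of 10⁶. Two generalizations of the
uniform-read-length formula are built in:

* **Aligned bases, not read counts.** Internally the numerator is the
  aligned base count of the scaffold (sum of CIGAR M/=/X lengths for SAM
  input). When every read has the same length `rl` this equals
  `rn · rl` exactly, so the classical formula is the special case; with
  ragged read lengths the base-count form remains exact.
* **Summation, not averaging, across scaffolds.** Taxon abundance at a
  rank is the *sum* of member-scaffold TAs. Only summation makes the
  taxon values an exact partition of 10⁶ (the property stacked
  community-dynamics plots rely on). The consequence is documented: at
  equal coverage, a taxon assembled into more scaffolds receives
  proportionally more TA. The synthetic generator therefore uses equal
  scaffold counts per taxon by default, which makes taxon TA equal to
  true abundance in expectation.
* Scaffolds unclassified at the requested rank pool into an
  `unclassified` column rather than being dropped; zero-count scaffolds
  contribute zero but stay in the table. Unmapped reads appear in no
  denominator.
* The core community of these microcosms spans ranks (families
  *Methylococcaceae* and *Methylophilaceae*, order Burkholderiales,
  phylum Bacteroidetes), so `aggregate_guilds` aggregates each guild at
  its native rank into one table.

## TPM and its derivatives

Per-CDS TPM uses the same length-normalize-then-rescale scheme with CDS
length in place of scaffold length; row sums are 10⁶ by construction.
Derived quantities:

* **Family-normalized expression.** Each gene's TPM divided by the
  summed TPM of its *family aggregate* and rescaled to per-million, then
  log₂. The aggregate for the methanol-dehydrogenase analysis is the
  taxonomic family (e.g. all *xoxF* + *mxaF* signal of
  *Methylococcaceae*), so the xoxF:mxaF ratio within a family is
  preserved: a 3:1 normalized ratio is a log₂ difference of log₂ 3 ≈
  1.585. Whether normalization should precede or follow the log is not
  canonically fixed; we normalize on the linear scale and log the
  result (the variant without per-million rescaling is available via
  `rescale=False`). Zero cells are **masked** (NaN), never
  pseudo-counted — a pseudo-count would inject an arbitrary constant
  into log space; masking mirrors the practice of omitting bad samples.
* **Genotype summing.** Transcripts matching the multiple genotypes of a
  family within a taxon (the several *xoxF* copies of *Methylophilaceae*)
  are summed before normalization. Summation is associative, so the
  family total is invariant to how members are split into genotypes —
  asserted as a test property.
* **Consensus genes.** Within a genus scope (e.g. *Acidovorax*), reads
  over all homologs of a group are summed, the group is
  length-normalized by the *arithmetic mean* of member CDS lengths
  (symmetric under member order; the choice of representative length is
  otherwise arbitrary), and values are expressed per million of the
  total genus signal. Ranked lists are sorted by descending value with
  ties broken by ascending group id for determinism.

## Genotype dereplication

Gene-family protein sequences are sorted into genotypes at a >5%
divergence threshold:

* **Identity metric.** Global alignment with match +1, mismatch −1,
  linear gap −2 and free terminal gaps; identity = exact matches over
  alignment columns, excluding columns inside terminal gaps. Terminal
  gaps are free because annotated homologs have ragged ends; penalizing
  overhangs would conflate length with divergence. Two caveats follow
  from this definition: (i) the aligner may trim a terminal mismatch
  into the free end-gap region, so identity can exceed the naive
  Hamming-based value by a fraction of a percent; (ii) for *unrelated*
  sequences the optimal alignment can be a short spurious perfect
  overlap, reporting misleadingly high identity. The metric is meant
  for homologs within a family, where full-length alignments dominate.
* **Clustering.** Edges connect pairs with identity ≥ 95.0 (exactly
  95.000% joins: ">5% divergence" separates, so ≤5% clusters);
  genotypes are the connected components (single linkage) — the unique
  order-independent closure of the pairwise rule. Equivalence with a
  brute-force connected-components oracle is tested exhaustively on
  random families.
* **Representative.** Longest member, ties by ascending id.

## Fragment-based ANI

Average nucleotide identity follows the fragment convention: the query
is cut into consecutive 1020 bp fragments (final fragment kept if ≥ half
length), each fragment is aligned to the subject, and fragments are
accepted at ≥70% identity and ≥0.7 aligned fraction. ANI is the mean
identity of accepted fragments; coverage is accepted aligned query bases
over total fragmented query bases (this denominator makes a
self-comparison exactly 100/100).

The aligner is native: exact 15-mer seeds vote for diagonals; the best
diagonals are scored ungapped (vectorized character comparison); if the
ungapped route fails the thresholds, a gapped local alignment over a
±60 bp window around the diagonal is attempted (indels shift diagonals).
Both orientations of each fragment are tried and the better accepted hit
kept. For substitution-only divergence the ungapped path is exact, and
recovery of |ANI − 100(1−d)| ≤ 0.5 points holds for d ≤ 0.10 on 200 kb
genomes. When zero fragments are accepted the pair is reported as **not
comparable** (NaN) rather than ANI 0 — zero would be a fake measurement.
The dual-triangle export writes ANI in the upper-right triangle,
coverage in the lower-left, 100 on the diagonal, cell (i, j) referring
to genome i as query.

## Ordination and the separation test

PCA is computed on the column-mean-centered core-guild relative
abundance matrix (rows renormalized to sum 1 over the core taxa) via
SVD, without unit-variance scaling — the columns already share the
relative-abundance scale. Sign indeterminacy is resolved by flipping
each loading vector so its largest-magnitude entry is positive.

"Significant separation" between oxygen regimes is made operational by a
distribution-free permutation test: the statistic is the Euclidean
distance between regime centroids in (PC1, PC2), and the p-value is
`(1 + #{permuted ≥ observed}) / (1 + n_perm)` under label permutation
(default 9999 permutations). Samples are labeled by the regime *in
effect at sampling time*: post-switch samples experience the opposite
oxygen tension from their microcosm's initial label, and pooling them
under the initial label would dilute a real regime effect. The test's
null calibration (uniform p-values) and power (a condition effect of
2 noise SD detected at p ≤ 0.01 in ≥95% of replicates) are both asserted
in the acceptance tests.

## The synthetic study

The generator emulates the experimental design, not the sequencing
chemistry:

* **Design.** 2 oxygen regimes (LO/HO) × 4 replicates × weekly samples
  from week 4 through 14 = 88 samples; the regimes are swapped after
  week 10.
* **Community.** Four guild representatives with equal scaffold counts
  (5 × 10 kb scaffolds each): *Methylobacter* (Methylococcaceae;
  *xoxF*, *mxaF*, 2× *pmoA*), *Methylotenera* (Methylophilaceae; three
  *xoxF* copies and one *mxaF*, reflecting the multi-genotype *xoxF*
  complement of this family), *Acidovorax* (Burkholderiales; *icl*, the
  glyoxylate-shunt marker, at elevated expression weight) and
  *Flavobacterium* (Bacteroidetes). Sequences are i.i.d. uniform
  nucleotides; family CDSs are generated as random proteins and
  reverse-translated with a fixed codon choice so protein and
  nucleotide records stay consistent.
* **Dynamics.** Per-sample taxon proportions are
  `softmax(baseline + LO-effect·[regime == LO] + N(0, σ))` with σ = 0.3
  by default. The methylotroph guilds carry positive LO effects and the
  heterotrophs negative ones, echoing the observed tendency of
  *Methylobacter* to dominate under hypoxia. This trend-plus-noise model
  is a stand-in: no quantitative dynamics model exists for such
  microcosms, and the softmax form is chosen for its simplicity and for
  making proportions a valid probability vector by construction.
* **Reads.** Counts are drawn directly — DNA reads multinomial over
  scaffolds ∝ proportion × scaffold length, RNA reads multinomial over
  CDSs ∝ proportion × expression weight × CDS length; aligned bases =
  reads × read length. No sequence-level read simulation and no aligner
  in the loop: the estimators consume counts, so error models, chimeras
  and mapping ambiguity are deliberately **not** emulated. A green
  recovery test therefore establishes correctness of the estimators
  under ideal mapping, not robustness to alignment artifacts.
* **Mutation model.** Substitutions i.i.d. per site, uniform over the
  other symbols; optional 1–3 bp indels at a stated rate. The realized
  substitution fraction is recorded as ground truth, since the binomial
  realization differs from the nominal rate on short sequences.
* **Seeding.** One global integer seed, fanned out as `seed + stage
  index` to independent generator streams (genomes, dynamics, reads,
  mutation), so stages are reproducible independently.

## Numerical and degenerate-input conventions

* Coordinates are 1-based inclusive end-to-end (the SAM convention).
* A read overlapping two CDSs is attributed to the CDS containing its
  leftmost aligned base — deterministic and order-independent; counting
  tools' multi-overlap behavior varies and is rarely documented. Only
  primary alignments count; strand is ignored.
* All-zero count sets are hard errors ("empty profile"), not silent
  zeros.
* Per-million row sums are exact to 1e-9 relative in tests; the
  documented external tolerance is 1e-6.
* Ranked outputs break ties by ascending identifier; cluster members
  and cluster lists are sorted, making every output order-deterministic.

## Known limitations

* The pairwise-identity metric is unreliable for non-homologous inputs
  (see above); genotype clustering should be applied within a gene
  family, as intended.
* The ANI aligner is tuned for closely related genomes (d ≤ ~0.2); for
  heavily rearranged or repeat-rich genomes the single-best-diagonal
  heuristic may under-report coverage relative to a full local aligner.
* The dynamics generator models trends and noise, not ecological
  interactions (no predator–prey coupling, no transfer-dilution
  population genetics).
* The permutation test treats samples as exchangeable under the null;
  repeated measures on the same microcosm violate this mildly, which is
  acceptable for the synthetic study (noise is i.i.d. per sample) but
  should be kept in mind for real longitudinal data.
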