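# Methods

## Similarity model

Peptide-to-window similarity is the ungapped positional PAM30 score sum,
clipped at zero and normalised by the peptide's self-score:

    sim(p, w) = max(0, Σᵢ M[pᵢ, wᵢ]) / Σᵢ M[pᵢ, pᵢ]

PAM30 is diagonally dominant (every diagonal entry is the maximum of its
row), so sim ∈ [0, 1] with sim = 1 exactly for the identity window. The
matrix is taken from the standard NCBI distribution (via Biopython) and
restricted to the 20 standard residues; any NCBI-format matrix can be
substituted with `--matrix`. The hit threshold *h* is applied to the
unrounded value as sim ≥ h, ties included. For 7-mers, h between 0.4 and
0.8 is sensible; 0.6 is the default. Because the same stringency is applied
to the Mock background that is later subtracted, high stringency is not
required — with small repertoires a lower h raises mapping density and
stabilises the m-score distribution.

Peptide–peptide clustering (reported as each peptide's `cluster_size`) uses
a symmetric variant — the clipped score sum over the **larger** of the two
self-scores — so it is bounded by both directed similarities, and
single-linkage connected components at the same h. Peptides are treated as
linear; cyclic-library topology is not modelled.

## Mock repertoire and controls

The Mock repertoire matches the Test in unique-peptide count and length;
residues are drawn i.i.d. from the library amino-acid frequency table
(percentages, validated to sum to 100 ± 0.1), with duplicates redrawn
until the set is unique. Rejection keeps the marginal essentially exact
while |Mock| ≪ 20^L. A repertoire larger than (usable residues)^L raises
an error. `compute_aaf` weights residues by peptide occurrence counts, so a
counts table yields abundance-weighted library frequencies.

When no Control selection exists the pipeline substitutes a single poly-W
placeholder of the Test's peptide length, whose near-empty profile is
subtracted like any other control; `--no-control` skips the Control term
entirely (the two differ only by the placeholder's few spurious hits). An
undersized Control triggers a warning only; explicit padding with unique
Test sequences is available as `balance_control` / the satellite workflow,
and is deliberately not automatic — padding a placeholder with Test
sequences would cancel the Test signal itself.

## Profiles and scoring

Each hit adds 1 to every covered residue of its protein (unweighted by
similarity), giving the aah profile; the profile sum of a protein is
exactly (hits × L). Mock and Control profiles are subtracted position-wise
and clipped at zero, keeping profiles interpretable as hit counts. The
m-score is Σ aah / #{residues with aah > 0} — the mean hit depth over
covered residues; an all-zero profile scores 0. z-scores use the
population standard deviation over proteins with m > 0 only (including the
all-zero mass would make the confidence cut depend on proteome size rather
than on signal); zero-signal proteins carry a −∞ sentinel and can never be
selected. If all nonzero m-scores are equal, all z-scores are 0; fewer
than two nonzero m-scores aborts scoring with a warning. Outliers are
proteins with z ≥ z_cut (default 2.58; 1.5 is still meaningful), sorted by
m-score.

## Enrichment and gene prioritization

The outlier proteins' gene symbols (isoforms collapsed) form the query.
Term over-representation uses the exact hypergeometric upper tail
P(X ≥ k), evaluated in integer arithmetic, over the universe of annotated
genes (query genes without annotation are dropped). Instead of an analytic
multiple-testing correction, B random gene sets of the query's size are
drawn uniformly from the universe and each term's bootstrap score is the
add-one fraction (1 + #{resamples with p ≤ p_obs}) / (B + 1) — a valid
permutation p-value that prioritizes enrichments random queries rarely
reach. A term is significant iff p_hyper ≤ p_cut **and** boot_score ≤
corrected_cut (both default 0.05). When an OBO ontology is supplied, is_a
true-path closure is applied first (each term inherits its descendants'
genes); information-content weighting and other semantic corrections are
out of scope.

Significant terms are clustered into systemic processes by single-linkage
on Jaccard similarity (≥ 0.5) of their query-overlap gene sets, each
process labeled by its lowest-p member. Query genes are ranked by the
number of processes containing them (regulatory-hub principle), ties broken
by the summed −log₁₀ p of those processes, then alphabetically.

## Synthetic benchmark

`synthetic_fixtures` emulates a Test-vs-Control screen at desk scale:
an i.i.d. proteome (default 100 proteins × 300 residues, uniform residue
frequencies), 5 Test-target and 2 Control-target proteins each carrying one
embedded length-7 motif, and 2,000-peptide repertoires of which 10% are
motif-derived copies with 0.1 per-residue substitution, the rest i.i.d.
background. Control-target-derived peptides appear identically in Test and
Control (they model non-specific binders captured by both selections);
the Control is topped up with fresh background to Test size. A GMT file
assigns the Test-target genes to term `T_PLANTED` plus 20 random 10-gene
decoy terms, and a truth table records the planted proteins, positions and
motifs. The defaults were chosen to preserve a realistic peptide-to-residue
ratio while keeping a full run in tens of seconds; they are far below the
≥ 40,000 unique peptides recommended for real proteome-scale runs, with
consequences described below.

What the benchmark does **not** emulate: NNK codon bias, amplification
distortion, sequencing error, cyclic peptide topology, and homology
structure within real proteomes. Passing tests therefore demonstrate the
pipeline's mechanics and statistics, not performance on real screens.

## Numerical and design notes

- Positions are 1-based inclusive everywhere; hit-table similarities are
  printed with 4 decimals and round-trip exactly.
- All randomness derives from one integer seed through domain-separated
  streams (`SeedSequence(seed, spawn_key=crc32(component))` for mock,
  balancing, bootstrap, fixture synthesis). This makes runs pure functions
  of the seed while guaranteeing that, e.g., a Mock generated with the
  same seed that synthesised a benchmark proteome does not replay the
  proteome's own residue stream.
- The scanner runs on integer-encoded sequences with a vectorised
  window-sum over a concatenated proteome; the test suite checks exact
  equivalence against an explicit double-loop reference.
- The hypergeometric tail is exact rational arithmetic converted to float
  (memoised); the bootstrap reuses a per-term lookup table of tail values
  indexed by overlap count, so ties between observed and resampled
  p-values are exact float equalities, never tolerance comparisons.

## Known limitations

- **Outlier selection at sparse coverage is knife-edged.** The z-scores
  are standardised over the m > 0 proteins, and the planted targets
  themselves inflate that standard deviation: with f the fraction of
  targets among nonzero-m proteins, even perfectly homogeneous targets
  cannot exceed z = √((1−f)/f) (≈ 3.2 at the benchmark's f ≈ 5/55). At
  desk-scale mapping density a single stray depth-1 background hit on a
  target doubles its covered residues and roughly halves its m-score, so
  the weakest of several targets frequently lands below a 2.58 cut even
  though all targets dominate the m-score ranking by a wide margin. This
  is the small-repertoire instability that motivates the ≥ 40,000-peptide
  recommendation for real runs; with the benchmark's 2,000 peptides, target
  recovery is robust in m-score rank but not in absolute z-threshold
  selection.
- Abundance (occurrence counts) is reported but deliberately not used in
  scoring: amplification bias makes per-peptide abundance unreliable.
- Gapped alignment, BLAST-style E-values, and per-position peak testing
  are out of scope.
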