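# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the known limitations.

## Synthetic data model

**Species tree.** A rooted binary tree over the configured taxa. The
recipient clade and the fungal outgroup clade are built by random
sequential joining (internal branches U(0.015, 0.035), terminal
branches U(0.07, 0.11) substitutions/site); donor kingdoms (bacteria,
animal, plant by default) attach successively outside the fungal core
with join branches U(0.08, 0.12) and clade stems U(0.10, 0.15). The
recipient stem is set to max(0.15, 5.5 × median internal branch) so the
recipient radiation is recent relative to its isolation — the
characteristic "long naked stem" of the gut-fungus clade. Two
calibration targets drove the branch-length windows: (i) terminal
branches long enough that the closest cross-taxon ortholog pairs sit
below the 90% dereplication identity while redundant transcript variants
(planted at 95%) sit above it; (ii) inter-kingdom distances large enough
that vertical fungal homology always outscores chance donor-group
similarity, which is what gives the alien filter its separation
(measured false-positive rate ≈ 0.1% at 500 families).

**Family presence.** Each family originates on one branch (root for
background and lost families; the recipient stem for planted unique
families; a donor-clade root for transfers, with a second copy planted
at the recipient-clade root) and is then subject to loss: on every
branch below the origin, an independent Bernoulli event with probability
`loss_rate` removes the family from the entire subtree. A leaf therefore
keeps the family with probability (1 − loss_rate)^k, k = branches on
the origin-to-leaf path; the test suite checks per-taxon presence
against this closed form. Planted lost families are forcibly killed on
the recipient stem. Transfer families also carry homologs in one
auxiliary non-donor kingdom, as real transferred domains do (the
animal-donor lectin tree also contained bacterial homologs); without
that third group, a donor-monophyly constraint on a two-group gene tree
would be vacuous, since the recipient stem edge always provides the
donor/recipient bipartition.

**Consequence of the loss model.** Cascading subtree loss is harsh on
the fixed 21-of-26 presence rule: at loss_rate = 0.05 the expected
number of recipient taxa missing a stem-origin family is about 6 (the
total root-to-leaf path count of a 26-leaf binary clade is ≥ ~122
branches), which exceeds the 5-missing allowance, so roughly half of the
planted unique families classify as unclassified rather than unique.
The acceptance script measures this directly (unique recall ≈ 0.5–0.6,
lost recall ≈ 0.65–0.75 at 500 families over 10 seeds). At zero loss
the classification recovers the planted truth exactly; the gap under
loss is a property of the noise model interacting with the fixed
permissive thresholds, not of the classifier.

**Sequences.** Protein sequences evolve along the family's induced gene
tree under the Poisson model: equal exchangeabilities, uniform
frequencies, P(different | t) = (19/20)(1 − e^(−20t/19)). The root
sequence is uniform over the 20 amino acids; there are no indels, so
emitted FASTA files are simultaneously alignments. For transfers, the
induced recipient subtree is grafted onto the midpoint of the first
donor taxon's terminal branch with a 0.05 transfer branch — donor
sequences are most similar to the recipient copies and the recipients
are *nested inside* the donor clade. Redundant variants mutate exactly
5% of sites of their parent gene (identity 95% > the 90% dereplication
cutoff). The generator does **not** emulate indels or alignment
uncertainty, site-rate heterogeneity, codon structure, composition bias,
domain-level HMM score statistics, or assembly artifacts beyond
transcript redundancy — so passing tests demonstrate correct recovery of
planted topology/similarity structure, not robustness to alignment or
annotation error in real data.

**Emitted dialects.** Similarity rows use the 12-column tabular layout
with a documented synthetic score: bitscore = max(0, 2·matches −
1·mismatches) (zero at 1/3 identity, strictly decreasing per mismatch)
and E-value = 0.1·m·n·2^(−bitscore), floored at 1e−180. Rows below the
score floor (default 50) are not emitted; unrelated sequences (~5%
identity) always score 0, so only within-family pairs are enumerated.
Domain rows follow the HMMER3 `--domtblout` column layout (hmmscan
orientation), true domains with independent E-values sampled
log-uniformly in [1e−30, 1e−3], decoys in [10^−1.9, 10] — always above
the 1e−2 analysis cutoff.

## Clustering

* Graph: undirected; edge weight = mean of the best A→B and best B→A
  bitscores, single direction kept as-is; self-hits dropped; isolated
  proteins remain as singletons. An optional reciprocal-best-pair filter
  (`bbh_filter`) prunes one-directional edges.
* MCL: column-stochastic matrix with self-loops at each node's maximum
  incident weight (standard regularization); expansion 2, inflation 1.5,
  convergence when the maximum entry change < 1e−6, at most 200
  iterations (non-convergence returns the current clustering and flags
  the report). Sparse entries below 1e−8 are pruned each iteration;
  clusters are connected components of the converged structure at 1e−6,
  and the suite checks equality with a dense fixed-iteration
  reimplementation on random graphs. Families are named after their
  lexicographically smallest member.
* Dereplication: greedy longest-first (ties by id); a sequence joins the
  first representative with global identity strictly above 0.90, where
  identity = identities / shorter length on a Needleman–Wunsch alignment
  (match 1, mismatch 0, gap −1). A shared-5-mer prescreen (≥ 30% of the
  query's 5-mers) limits alignments to plausible near-duplicates; at the
  >90% regime near-duplicates share ≥ ~60% of their 5-mers, so the
  screen cannot split true variant clusters. Dereplication runs before
  clustering.

## Classification

Thresholds are stored as absolute counts (5/26, 1/5, 21/26, 4/5) and
rescale proportionally for other group sizes (missing allowances round
down, presence requirements round up). The unique rule is inclusive
(≥ 21). For domains, "unique" additionally requires zero copies in every
supplied non-recipient fungal taxon, and "enriched" uses fold ≥ 4 on
group mean copy numbers (descriptive, configurable, not a test).
Multiple hits of one domain on one protein count as multiple copies.
Zeros in the ln heatmap are handled by ln(count + 1). Overlapping
envelopes of the same domain are merged; of different domains, kept and
ordered by envelope start.

## Transfer screen

Absent group scores count as 0, so "no fungal homolog at all" yields the
maximum possible margin — deliberately, since total absence from a
kingdom is itself evidence. All non-fungal groups participate in the
alien maximum by default (per-group toggles exist). Ranking is the Borda
mean of two within-strategy ranks (margin; best non-fungal identity),
ties broken by margin then gene id, candidates missing a strategy
assigned its worst rank + 1. An E-value-based alien-index mode
(ln E_alien − ln E_fungal) is available as an alternative scorer.

## Tree diagnostics

* Monophyly is a bipartition question on the unrooted tree; the stem
  support is the support of that bipartition and is therefore invariant
  to rerooting.
* Sister-lineage extraction midpoint-roots unrooted trees; if the
  midpoint lands inside the clade, the tree is rerooted on the clade's
  stem edge instead. The donor call is the majority group of the sister
  leaves (ties → "ambiguous") and requires stem support ≥ 80 when
  supports are annotated.
* The substitution model is time-reversible with configurable
  exchangeabilities/frequencies (Poisson default), normalized to one
  expected substitution per site per unit branch length and
  diagonalized once via the π-symmetrized generator; optional
  discrete-Gamma rate categories use equal-probability quantile rates
  normalized to mean 1. Gaps and unknown residues are missing data
  (partial likelihood 1 in every state).
* Constrained topologies: maximal intruding subtrees are pruned and
  regrafted onto the group's stem, splitting the stem evenly; only the
  moved branches are re-optimized, by a bounded scalar likelihood search
  on [1e−6, 5] with tolerance 1e−4 (branch lengths live in a bounded
  domain, so a bounded search is safer than an unbounded golden-section
  bracket). All other branch lengths are preserved.
* AU test: scales 0.5–1.4 step 0.1, B = 1000 per scale, ties in
  replicate winners split evenly (so identical site-likelihood rows give
  exactly p = 0.5 each). Selection frequencies are clamped to
  [1/(2B), 1 − 1/(2B)] before the normal-quantile transform; the curve
  z(r) = d√r + c/√r is fit by weighted least squares with the standard
  binomial weights B·φ(z)²/(bp(1−bp)); p = 1 − Φ(d − c), clipped to
  [0, 1]. A topology never (always) selected at any scale gets p = 0
  (p = 1) and a degeneracy flag.
* Gene trees for candidate families are inferred by neighbor joining on
  p-distances (negative NJ branch estimates clamped to 0), with
  bootstrap supports as bipartition frequencies over column resamples.

## Problem sizes

The test suite exercises the reference scale of 26 recipients + 5
outgroups at 500 families for the classification and screen checks, and
a 6 + 3 taxon / 40-family configuration for the per-module tests; the
demo pipeline uses 60 families with 3 + 2 + 2 planted events. The
acceptance script runs the 500-family conditions in about half a minute
on one CPU.

## Known limitations

* The similarity score is a deterministic surrogate, not an
  extreme-value-calibrated BLAST score; only its monotonicity in
  alignment quality is meaningful.
* NJ gene trees (not ML) feed the diagnostics; the AU machinery takes
  any fixed topologies, but the unconstrained tree is as good as NJ is.
* The constrained-topology rearrangement is minimal (prune-and-regraft
  onto the stem), not a constrained ML search, so its likelihood is a
  lower bound on the best constrained tree's.
* Under cascading loss the fixed permissive thresholds lose planted
  unique/lost families at the rate quantified above; with real data the
  analogous effect is incomplete transcriptome sampling, which the
  original permissive rules were designed to absorb at similar rates.
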