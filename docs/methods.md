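# Methods

`nlr-evolkit` re-implements, as a self-contained and testable pipeline, the
standard genome-wide NLR (NB-LRR) survey workflow for annotated plant
genomes: motif-based identification and architecture typing, subgroup
classification by integrating sequence-similarity clustering with a
bootstrapped NB-domain phylogeny, physical cluster calling on gene
coordinates, and duplication dating from synonymous substitution rates
(Ks).  This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data does and does not emulate.

## Motif scanning and architecture typing

NB-ARC motifs (major: P-loop, kinase-2, GLPL, MHDV; minor: RNBS-A/B/C/D),
the TIR core, LRR units and the Solanaceae Domain (SD) are detected with
position-specific scoring matrices (PSSMs) rather than profile HMMs.  Each
PSSM is built from a shipped seed alignment (log₂ odds over a uniform
background, pseudocount 0.5; mostly-gap columns dropped).  Score cutoffs
are not interpretable as E-values without a database context, so each model
is calibrated on a shuffled-sequence null: the cutoff is the 99th
percentile of the per-protein maximum window score over 500 random
uniform-composition proteins of 300 aa (fixed seed).  A shuffled protein
therefore produces any hit at most ~1% of the time; planted consensus
motifs score far above the cutoff (roughly 2–3× in bits).

Hits per motif are greedy best-first non-overlapping windows.  The NB
domain is resolved by a weighted longest-increasing-subsequence dynamic
program over all NB-motif hits: the reported chain is the highest-scoring
subset consistent with the canonical N→C order (P-loop, RNBS-A, kinase-2,
RNBS-B, RNBS-C, GLPL, RNBS-D, MHDV); a second consistent chain among the
leftovers is reported as a secondary (tandem) NB.  The NB span runs from
the first to the last chained motif.

Coiled-coils are scored with a Lupas-style scan: for each 28-residue window
and each of the seven heptad frames, the weighted geometric mean of
per-position propensities (buried a/d positions weighted 2.5×), converted
to a probability by a two-Gaussian (coil vs globular) likelihood ratio with
a 1:30 prior.  The original propensity tables are not redistributable from
any package in this stack, so the table here is an in-package one —
hydrophobics favored at a/d, charged/polar elsewhere, proline strongly
penalized — with the two Gaussians calibrated once (fixed seed) on
propensity-sampled coil windows and uniform-random globular windows.  The
decision threshold is the survey's 0.9.  An ideal leucine-zipper heptad
scores > 0.999; random sequence scores < 0.05.  Because heptad scans are
notoriously confusable with LRR repeats, the pipeline evaluates CC (and
TIR, and SD) only on the region upstream of the NB start.

LRR presence requires ≥ 3 LxxLxLxx unit hits within a 200-aa window — the
survey delegates LRR calling to external domain databases, so this concrete
rule is a documented tunable of this package.

Typing follows the eight-class decision table (TNL, CNL, NL_tir, NL_cc,
TN, CN, N_tir, N_cc).  When both TIR and CC fire, TIR wins (domain identity
over a propensity score); the event is logged.  LRR-less genes without an
N-terminal domain cannot be assigned a lineage from sequence content alone;
they carry `unassigned` until the classification stage backfills the
lineage from subgroup (clade) membership.  *Full-type* (intact) NLRs
require an NB span ≥ 160 aa, ≥ 3 of 4 major motifs and ≥ 3 of 4 minor
motifs; "≥ 3 of the 4 listed" is our reading of "at least three major
motifs".

## Subgroup classification

Three evidence sources are integrated:

1. **Similarity clustering.**  All-by-all Smith–Waterman local alignment
   (BLOSUM62, gap open −11 / extend −1, via Biopython's PairwiseAligner).
   An edge is kept iff the score normalized by the self-score of the
   shorter sequence is ≥ 0.20 *and* the alignment covers ≥ 50% of both
   sequences.  The normalized-score cutoff stands in for a BLAST E-value
   threshold (no database context exists for E-values here); shuffled
   unrelated proteins score < 0.1 essentially always, so 0.20 is
   conservative.  The graph is clustered with Markov clustering (MCL):
   column-normalized walk matrix with unit self-loops, alternating
   expansion (squaring) and inflation 1.5 (elementwise power +
   renormalization) to a 1e-6 fixed point (cap 200 iterations,
   non-convergence returns the current partition with a warning);
   clusters are attractor components, singletons allowed.  Disconnected
   components can never merge.

2. **NB-domain phylogeny.**  Full-type NLRs' NB domains are multiply
   aligned by progressive profile–profile alignment along a
   neighbor-joining guide (profiles merged in NJ join order; sum-of-pairs
   BLOSUM62 column scores, linear gap −8).  This is adequate for the
   conserved NB domain and keeps the package self-contained; it is not a
   general-purpose MSA.  Pairwise distances are maximum-likelihood branch
   lengths under the JTT amino-acid model (the published empirical
   exchangeabilities, embedded as constants; symmetrized
   eigendecomposition; per-pair likelihood maximized on a 220-point
   log-spaced grid over t ∈ [1e-4, 8] with quadratic refinement — accurate
   well below alignment sampling noise).  Gaps are pairwise-deleted; pairs
   sharing < 50 columns are flagged unreliable.  Trees are Saitou–Nei
   neighbor joining with deterministic tie-breaks (lowest index pair) and
   negative branch lengths clamped to zero with the deficit moved to the
   sister branch.  Bootstrap: columns resampled with replacement, one RNG
   stream per replicate derived from (seed, replicate) so results are
   reproducible and order-independent; support = fraction of replicates
   reproducing each bipartition; zero-length internal branches are
   collapsed before supports (they are arbitrary resolutions), and
   branches under 50% support after.

3. **Integration.**  Each non-singleton cluster is anchored to its
   *supported envelope*: the smallest clade with bootstrap support ≥ 70%
   containing all of its full-type members.  Clusters with the same
   envelope are the same phylogenetic subgroup and merge under one label.
   A literal "maximal supported clade" rule degenerates — the deepest
   partitions of a well-resolved tree are also highly supported, which
   would merge everything under the root's children — so the envelope rule
   is this package's resolution of an under-specified step; it reproduces
   the intended behavior on both oversplit clusters (merged via their
   shared envelope) and well-separated subgroups (distinct envelopes).
   Remaining genes (singletons, partial genes absent from the tree) are
   assigned by best local-alignment hit against labeled genes under the
   same similarity/coverage thresholds; unresolvable genes go to
   `none-grouping`.  Labels are G1..Gk by decreasing size unless reference
   sequences with known subgroup names are supplied to pin them.  Finally,
   the NB lineage of LRR-less/N-terminal-less genes is backfilled: a
   subgroup whose members are majority-TIR confers `tir`, else `cc`, and
   the type label is re-derived (a CC-evident gene placed in a TIR-lineage
   subgroup is relabeled by clade membership, mirroring how NB_tir/NB_cc
   are defined by derivation).

## Physical clusters

Within a chromosome, two adjacent NLRs chain when the end-to-start gap is
< 200 kb (strict) and strictly fewer than 8 annotated non-NLR genes lie
strictly between them (nested/overlapping genes count once).  Clusters are
maximal chains of ≥ 2; strand is ignored; genes without coordinates are
excluded from clustering but kept in tallies as unmapped.  A brute-force
chain enumeration over random layouts is the test oracle.

## Ks dating

Paralog pairs are aligned at the protein level (Smith–Waterman) and the
alignment is transferred to codons; gap columns, N-containing codons and
stops are dropped.  Two estimators:

* **NG86** (engineering oracle): Nei–Gojobori site counting (per-position
  fraction of synonymous single-nucleotide changes, stop-excluded
  denominators; multi-hit codons averaged over sense-codon pathways) with
  Jukes–Cantor correction; pS > 3/4 marks saturation.
* **ML-F3×4** (primary): pairwise maximum likelihood under a GY94-style
  61-state codon model, equilibrium frequencies from per-position
  nucleotide frequencies (F3×4, small pseudocount for irreducibility).
  The likelihood over codon-pair counts is maximized over (t, κ, ω) by
  L-BFGS-B in log space from two starts (an NG86-informed and a neutral
  one); transition probabilities use the symmetrized eigendecomposition of
  the reversible rate matrix.  Ks = t·ρS/(3·fS), where ρS is the
  synonymous share of the substitution flux and fS the synonymous share of
  sites (the ω = 1 flux), the standard codon-model bookkeeping.
  Alignments under 20 codons, or optimizer failure, fall back to NG86 with
  a flag.  Parameter-recovery simulations (600 codons, κ = 2, ω = 0.2)
  recover Ks ∈ {0.05 … 0.5} with median bias under 0.01 at Ks = 0.15.

Pairs with Ks > 2 are discarded as saturated.  Within a subgroup and
species, remaining pairs are grouped into gene families by single-linkage
(the same Ks ≤ 2 edge rule; the linkage threshold is a documented tunable),
and each family's UPGMA (average-linkage) dendrogram on the Ks matrix
yields exactly n−1 join heights — the deduplicated duplication-age sample
that replaces the redundant n(n−1)/2 pairwise values.  Missing
within-family pairs enter the matrix at the saturation cap.

The post-speciation test builds, per subgroup, the 2×2 table (subgroup vs
all other subgroups) × (height < 0.3 vs ≥ 0.3) and computes Pearson
chi-square without continuity correction; when any expected cell is < 1 a
Fisher exact p is reported alongside with a warning.  The exact
contingency construction and the multiple-testing handling are not fully
specified by the original survey; this package reports raw and
Benjamini–Hochberg-adjusted p-values across subgroups.  Time calibration
is linear: T = Ks/(2r) with r anchored so Ks = 0.3 ↔ 19.1 Mya (the
pepper–tomato/potato divergence), hence Ks = 0.15 ↔ 9.55 Mya.  Histograms
use fixed-width bins (default 0.025) and call peaks as local maxima of the
3-bin moving average; note two modes closer than three bins merge under
this smoothing, so peak studies use a finer width.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes.
Proteins are assembled from region templates: optional SD, TIR or CC
(5 ideal heptads) N-terminus, the eight NB motif boxes in canonical order
with 30-aa spacers (NB block 291 aa), and 5 LRR units; per-subgroup cores
mutate the motif boxes at 15% per residue (re-validated against the PSSM
cutoffs so a noise-free protein is always fully detectable) and draw all
spacers/linkers fresh, giving within-subgroup identity ≈ 95%+ and
between-subgroup identity ≈ 25–35% — inside the intended ≤ 40% / ≥ 80%
design envelope and strong enough for the similarity graph and MCL to
separate subgroups robustly, which is the stated purpose of these dials.
CC-block variation is restricted to surface (non-a/d) positions from a
polar/charged alphabet so the coil signal survives.  Filler genes are
random ORFs rejection-sampled to be motif-free against every model and
the CC detector.

Family CDS are produced by synonymous-only (ω = 0) Gillespie evolution
under the GY94 model along a random-topology duplication tree with planted
event depths, starting from a reverse-translated ancestor; codons at
noise-substituted residues are then repainted.  Protein-level truth is
therefore exact while pairwise synonymous divergence carries the planted
Ks depths.  Default per-family depths are drawn uniformly from
[0.05, 0.25] — post-speciation ages, matching the surveyed genomes'
duplication regime.  Genome layouts place planted clusters with specified
gaps and intervening filler counts; all other NLRs are isolated by 300-kb
gaps so they can never chain.  Everything is deterministic under
(spec, seed).

What the generator does *not* emulate: intron structure, transposable
elements, whole-genome duplication, assembly artifacts, unanchored
scaffolds, and realistic LRR length variation.  Passing round-trip tests
therefore demonstrates the internal consistency and calibration of the
pipeline under its own model assumptions, not performance on real
annotation sets.

## Numerical and degenerate-input choices

* All thresholds live in `RunConfig`; defaults are the survey's constants
  (COILS 0.9; NB ≥ 160 aa; ≥ 3 major, ≥ 3 minor; < 200 kb; < 8 intervening;
  inflation 1.5; 500 bootstrap replicates; collapse < 0.5; subgroup support
  ≥ 0.7; Ks ≤ 2; speciation Ks 0.3 ↔ 19.1 Mya).
* Tests and the bundled pipeline runs use 100 bootstrap replicates and a
  three-species, five-subgroup, ~60-gene genome with 600-codon/50-replicate
  estimator simulations — sizes chosen so the full validation runs in
  about a minute while keeping every statistical check well-powered.
* Ties: NJ picks the lowest-index pair; MCL clusters sort by size then
  lexical order; greedy hit selection prefers higher score then earlier
  position.
* Percentages print one-decimal half-up with a trailing `.0` trimmed
  (12, 14.4, 82.5).
* Fewer than 3 taxa → trivial/star tree; empty alignments, empty
  histograms, and single-member families return empty results rather than
  erroring; a cluster-free genome reports a clustered fraction of 0.

## Known limitations

PSSM scanning cannot model position-dependent insertions the way profile
HMMs do; the COILS propensity table is calibrated in-package rather than
being the published original; the progressive MSA has no iterative
refinement; the ML Ks estimator is pairwise (no branch models, no Ka/Ks
selection scans); subgroup labels are arbitrary without reference
sequences; and the integration rule for subgroup delimitation is one
consistent reading of an under-specified procedure.
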