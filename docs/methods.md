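# Methods

This note records the models, parameter choices and numerical
conventions behind each module, and what the synthetic benchmarks do
and do not demonstrate about real data.

## Domain detection (family)

The bZIP domain is detected from its sequence definition rather than a
profile HMM: a hit at position *i* requires Asn at *i*, Arg or Lys at
*i + 8* (the N-x7-R/K basic-region core), and a leucine zipper — at
least `min_heptads` consecutive positions, stride 7, occupied by
Leu/Ile/Val/Phe/Met — whose first residue sits exactly nine residues
C-terminal of the R/K. Choices:

* `min_heptads = 2` (default, configurable). A single occupied heptad
  position is not a "repeat"; two is the weakest reading that makes
  the repeat meaningful. Real zippers typically show 4–5.
* The nine-residue spacing is anchored at the R/K by default. The
  literature also describes a ~16-residue basic region, which suggests
  anchoring at its end instead; that alternative is available as
  `zipper_anchor="basic16"`. The two conventions differ by 7 residues,
  i.e. exactly one heptad, so on genuine zippers with ≥ 3 heptads they
  mostly agree.
* This detector is a transparent surrogate, not an HMM equivalent: it
  will miss genuine bZIPs with a degenerate basic region that a
  profile HMM would still score. Counts on real proteomes are
  therefore not comparable to HMM-based catalogues, and no such
  comparison is attempted anywhere in the package.

The identification pipeline stages (candidates → contig removal →
domain verification → exact-duplicate collapse) each report an audit
count, and the counts telescope by construction. "Non-redundant" is
implemented as exact sequence identity — the only assumption-free
reading — keeping the first id in input order. Verification is a
no-op when the candidate scan already used the strict threshold; an
optional looser candidate threshold (`candidate_min_heptads`) mirrors
the common two-step practice of a permissive scan followed by strict
domain confirmation.

Unplaced records (chromosome `uA`, `uD`, …) are named after all placed
records, ordered by id: figures in the source literature distribute
such genes evenly rather than defining an order, so the package picks
the deterministic choice.

Protein properties: molecular weight is the sum of average residue
masses plus one water (via Biopython); the isoelectric point solves
net charge = 0 for a Henderson–Hasselbalch model over the termini and
D, E, C, Y, H, K, R side chains by bisection on pH ∈ [0, 14] to 0.01
pH by default. The pKa set is EMBOSS-style and config-exposed; pI
values are model-dependent and should be compared only within one pKa
convention. When a CDS length is supplied the identity
`protein_length = cds_length/3 − 1` (stop codon untranslated) is
asserted, catching annotation mismatches early.

## Alignment scoring (orthology)

Smith–Waterman local alignment with affine gaps, delegated to
Biopython's `PairwiseAligner` (local mode). A gap of length *k* costs
`open + k·extend` (BLAST convention), with BLOSUM62 and open 11 /
extend 1 by default; raw scores become bits via the Karlin–Altschul
transform `(λS − ln K)/ln 2` with the conventional gapped-protein
constants λ = 0.267, K = 0.041. All parameters live in a
`ScoringScheme` and can be replaced.

The overlap criterion uses the span of the single optimal local
alignment on the longer sequence; the segment-merging of multiple HSPs
that BLAST-based workflows can perform is deliberately not reproduced
(single-alignment engine). Pairs must pass both cutoffs — ≥ 50 bits
and > 50 % overlap — to enter the score table; self-scores are always
recorded because the confidence denominator needs them.

## Ortholog clustering

A deterministic distillation of the InParanoid procedure for one
species pair:

1. seeds = mutually best-scoring cross-species pairs (reciprocal best
   hits), ties broken by lexicographic gene id;
2. in-paralog candidates = same-species genes whose surviving score to
   a seed is ≥ that seed pair's cross-species score (duplicates
   postdating the speciation);
3. confidence = 100·(score_to_seed − seed_cross)/(seed_self −
   seed_cross), clipped to [0, 100]; seeds fixed at 100 %; a
   degenerate denominator (seed self-score ≤ cross score, e.g.
   identical sequences) yields 100 %;
4. a gene eligible for several groups joins the one maximizing its
   confidence, ties resolved toward the higher-scoring seed and then
   the lexicographically smaller seed pair.

The original tool's bootstrap confidences, multi-HSP overlap handling
and outgroup-based group rejection are out of scope; determinism is
what makes the brute-force oracle test exact. Groups are emitted in
descending seed score.

## Orthology statistics and the orthophylogram

`dAB = (total_A − n_orthologous_A_to_B)/total_A` with the convention
that a pair with zero surviving groups has distance 1 (the formula's
limit). The symmetrized matrix (dAB + dBA)/2 is clustered by
*classical* UPGMA — size-weighted arithmetic-mean linkage (WPGMA
rejected), merge height d/2, ties broken by the lexicographically
smallest leaf label of the clusters involved — so the tree is
invariant to input taxon order and ultrametric to machine precision.
Orthology distance is not guaranteed to satisfy the triangle
inequality; UPGMA does not require it. Report output rounds group
sizes to 3 decimals; everything internal is full precision.

## Expression analysis

*2^−ΔΔCt*: per condition, ΔCt = Ct_target − Ct_reference using
replicate-mean Cts; ΔΔCt subtracts the calibrator condition;
replicate-level folds (each sample's ΔCt against the calibrator mean)
are retained for downstream tests.

*DE filter*: per-gene two-sided Welch t-test on log2 values with
Benjamini–Hochberg adjustment across all genes tested. The decision
rule — raw p < α AND adjusted p < α, α = 0.05 — is the published one;
the Welch fit itself is this package's documented choice of test
statistic for replicated log2 intensities (n = 3 qPCR or array
replicates rarely justify equal variances; pooled vs Welch is
switchable only by editing the statistic, deliberately not a flag).
Genes whose two groups both have zero variance get p = 1: a
deterministic degenerate-input rule rather than an infinite t.

*Probe mapping*: a probe maps to a gene iff the nucleotide alignment
against the CDS has E ≤ 1e−5 and the best of the three forward
translation frames against the protein has E ≤ 1e−3, with
E = K·m·n·2^−bits. Nucleotide scoring uses match +1 / mismatch −2,
gap open 2 / extend 2 and λ = 1.28, K = 0.46 (conventional BLASTN-like
constants). Multi-gene hits are all reported and flagged ambiguous.

*Responsiveness*: strong when some post-treatment fold exceeds 10×
the untreated control; otherwise weak when the course leaves the
±2-fold band (max ≥ 2 or min ≤ 0.5 — the conventional responsiveness
threshold, configurable); otherwise unresponsive.

*Expression modes*: two-sided Welch t-tests of F1 against each parent
at α = 0.05. Over-/under-dominance require significance against both
parents with the F1 mean beyond both; dominance requires significance
against exactly one parent, resolved to high- vs low-parent by
whichever parent mean the F1 mean is nearer (an exact tie resolves
toward the high parent iff the F1 mean is at or above the mid-parent
value). Everything else — including significance against both parents
with the F1 *between* them — is "unclassified". All-zero-variance
triples return unclassified with a warning. Replicate-level log2
folds are the intended input scale.

## Synthetic-data generator

*Proteomes.* Ancestral genes (length ~ Poisson around
`mean_protein_length`, floor above the motif length) evolve down a
user-specified species tree. Along each branch every gene spawns
Poisson(`duplication_rate`) extra copies — the simplest memoryless
duplication law, stated so the distributional tests are well-posed —
and each copy's residues mutate independently with probability
`substitution_rate` per site (substitutions only; no indels, no codon
model, no realistic coordinates). A planted bZIP motif (basic core
plus `n_heptads` zipper anchors) is inherited verbatim: carriers are
guaranteed detectable. All non-motif residues, and all substitution
outcomes, are drawn from a 19-letter alphabet *excluding Asn*, so
non-carriers cannot contain the motif's anchor residue and detector
specificity is exact by construction rather than probabilistic.
Contig-derived records are marked with a `contig|` id prefix — the
source annotations never define "contig sequence", so an explicit
marker makes the filter deterministic. Truth groups per species pair
collect genes sharing an ancestral copy at the pair's last common
ancestor, which is precisely the in-paralog definition (duplications
after the relevant speciation stay within a group; earlier ones found
new groups). A single `numpy` generator seeded once drives
everything; identical configs give byte-identical FASTA.

What this does *not* emulate: indels and domain erosion (so real
alignments are harder), gene loss (so truth groups always span both
species), compositional bias, and HMM-vs-motif discrepancies. Passing
benchmarks certify the inference rules, not performance on real
annotations.

*Expression panels.* Per gene, parent means are drawn on the log2
scale (base Uniform(4, 10)); the two parents differ by the gene's
planted log2 excess with random sign; the F1 mean is placed by the
planted mode (above/below both parents by the excess, equal to one
parent, or at the mid-parent value); replicates add N(0, `noise_sd`)
on log2. Defaults — n = 3 replicates, noise_sd = 0.2, log2 excess 2 —
model a typical qPCR validation panel: three biological replicates,
~15 % CV, 4-fold planted effects. With these settings dominance genes
are recovered ≈ 95 % of the time (the 5 % loss is exactly the α-level
false positive against the near parent) and over-/under-dominance
essentially always.

*Ct panels.* The treated-condition mean Ct sits log2(fold) cycles
below the calibrator's after reference correction, so 2^−ΔΔCt
inverts the construction exactly at zero noise (fold 8 ⇒ 3 cycles).
Measurement noise perturbs target-gene Cts only; the reference gene
models the stable internal control a qPCR design selects for and
stays fixed. With noise_sd = 0.1 and n = 3, ~98–99 % of recovered
folds land within 15 % of the planted values.

## Problem sizes used by the checks

The verification suite runs entirely on synthetic data at desk scale,
chosen to exercise every rule while keeping the whole suite under a
minute of compute: oracle-equivalence over 100 random two-species
cohorts of ≤ 20 genes and hundreds of random alignment pairs of ≤ 80
residues; expression-mode recovery over 100 seeded panels of 100
genes; type-I calibration on a 2,000-gene null panel. The published
family-wide count table (five species) is carried as constants and
used as *input* to the statistics; the real genome catalogues and
array gene lists behind it depend on data that was never deposited and
are not reproduction targets.

## Known limitations

* The domain detector is definition-literal; no claim of equivalence
  with profile-HMM searches.
* Single-HSP overlap computation can under-estimate coverage for
  proteins whose similarity is split across distant segments.
* Clustering handles one species pair at a time (no simultaneous
  multi-species clustering, no outgroup filter).
* The DE stand-in is a per-gene Welch test, not an empirical-Bayes
  moderated fit; with n = 3 its power is below limma-style moderation.
* pI and Mw are model conventions (EMBOSS-style pKa, average masses),
  not measurements.
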