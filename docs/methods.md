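# Methods

This note documents the models implemented in `flyimm`, the assumptions of
the synthetic-data generator, and the numerical conventions chosen where the
underlying study design left them open.

## Study design being modelled

One pooled cDNA library per species × condition (fungus-infected vs naïve
larvae), shotgun-pyrosequenced; no biological replicates. All inference is
therefore conditional on read-count sampling: between-condition differences
are tested per gene against endogenous controls, not against a
replicate-based dispersion estimate.

## Read triage

Reads are classified through a fixed cascade — mitochondrial genome, rRNA,
CDS, gene, transcript — with the first hit terminating the search; reads that
hit nothing are *unidentified* and feed novel-gene discovery. Accounting
identities (`mito + rRNA + other = total`, `assigned + unidentified = other`)
are enforced by the `TriageSummary` container on every input.

The matcher is a contract, so an external aligner can be plugged in. The
built-in is exact k-mer seeding (k = 16, seeds at read start/middle/end) with
ungapped extension; a hit needs ≥ 95% identity over ≥ 90% of the read.
These parameters make classification of error-free reads exact and
deterministic, which is what the triage tests require; they are configurable
for noisy data. Ties are broken by score, then aligned span, then
lexicographic target id. Each read counts toward exactly one gene (no
multi-mapping fractions). Coordinates are 0-based half-open; FASTA headers
are parsed up to the first whitespace.

Because assignment totals depend on matcher settings, the number of genes hit
is reported but never treated as a reproducible constant.

## Expression quantification

RPSM (reads per site per million reads) divides a gene's count by the library
total and the transcript length, × 10⁶. The "library total" is the number
of reads assigned to nuclear genes, not the raw read count: mitochondrial and
rRNA fractions differ grossly between libraries and would distort the
per-million scaling. The `CountTable` carries explicit totals for this
reason (they may exceed the table's column sums).

The TMM factor is the canonical trimmed-mean-of-M-values estimator computed
between the two conditions: for genes nonzero in both libraries,
M = log₂ of the ratio of depth-normalised counts and A = mean log₂ abundance;
genes in the extreme 30% tails of M and 5% tails of A are trimmed; the factor
is the inverse-asymptotic-variance weighted mean of the remaining M values,
exponentiated. The factor pair is scaled to product 1 (the naïve library is
the M reference, but the constraint makes results reference-symmetric).
Normalised expression ("TMM value") is RPSM divided by the library's factor,
and IC = TMM_infected / TMM_naive, with `Infinity` when only the infected
library expresses the gene and `Undefined` when neither does. Output tables
round IC to 3 decimals; full precision is kept internally.

Trim fractions and weights are configurable; the defaults are the canonical
ones. With two libraries and strong biological signal concentrated in few
genes, the 30% M-trim is what protects the factor from induced genes.

## Induction testing

Each gene's (infected, naïve) counts form a 2×2 table with the pooled counts
of the endogenous controls (RpL32 + GAPDH). Pooling is justified by a
homogeneity test of the per-control table first — Fisher's exact test for the
two-control case; for more than two controls Pearson's χ² is substituted
(there is no exact r×2 test in scipy), and a single control pools trivially
with P = 1 by convention.

Test selection follows the minimum cell count over all four table cells:
χ² (1 df, *without* Yates continuity correction) when it is ≥ 5, otherwise
the two-sided Fisher exact test under the probability-mass rule (sum of all
fixed-margin tables no more probable than the observed one). Genes with zero
counts in both conditions return P = 1 with a `no-signal` flag. No
multiple-testing correction is applied by default (raw P values mirror the
single-study convention); Benjamini–Hochberg is available behind a flag.
α = 0.05 with a two-star convention (\*P < 0.05, \*\*P < 0.01).

Regulation categories partition genes by IC: infected-only (IC = ∞),
IC > 2, 1 < IC ≤ 2, IC = 1, 0.5 ≤ IC < 1, IC < 0.5, undefined. Boundary
values 2.0 / 0.5 / 1.0 fall in the weak-up / weak-down / unchanged bins.

**Calibration.** Because the test conditions only on count-sampling noise,
calibration experiments in the suite generate null counts with dispersion 0
(Poisson). Under those conditions the fraction of genes with P < 0.05 sits
inside the 99% binomial band of 0.05 (2,098 genes), and power for 4-fold
induced genes with ≥ 50 expected reads exceeds 0.8. With biological
overdispersion the test is anti-conservative — a design limitation of any
single-pooled-library study, not of the implementation (see Limitations).

## Homologue mapping and summaries

Many-to-many homologue tables (multi-copy families) are resolved to
one-to-one pairs by translated-alignment score (local protein alignment of
translated CDS, BLOSUM62, affine gaps 11/1), ties by aligned length then
lexicographic id, picked greedily under the injectivity constraint.
Unresolvable ids go to a rejects report. Immune classes (recognition /
signaling / effector, with AMP/IM effector subtypes) come from a reference
list supplied as a TSV — the list is user-provided, not bundled, to avoid
freezing any particular annotation release. "Expressed" means ≥ 1 assigned
read in the relevant library (configurable). The effector summary piles
expressed effector genes by infected-library TMM with category, significance
stars and cross-species partner; Venn counts tally shared expression via the
resolved pairs and report multi-copy ids separately.

## Novel-gene discovery

Unidentified reads are placed on the genome by the same k-mer contract,
overlapping placements merge into contigs (consensus by per-column majority,
ties toward the reference base), and each contig is extended by 250 bp of
flanking genome on both sides before the homology screen — the contigs are
3′-UTR-sized, so flanks are what pull in coding sequence. The screen
translates the query in six frames and aligns each frame locally
(Smith–Waterman, BLOSUM62, gap open 11 / extend 1) against the protein set;
the e-value is the Karlin–Altschul form K·m·n·e^(−λS) with the standard
gapped-BLOSUM62 constants λ = 0.267, K = 0.041, m the frame's translated
length and n the database residue count. The default threshold is 1e-5. A
null simulation in the suite (100 random 300-nt queries against unrelated
proteins) produces zero hits at that threshold with these constants.

Putative genes are tested for induction exactly like annotated genes; their
IC uses depth-normalised read counts only, because an unannotated unit has no
known transcript length — a deliberate divergence from the RPSM-based IC,
matching how putative-gene results are conventionally reported (read counts
and IC, no TMM column).

## AMP screening

Precursors are segmented by transparent heuristics behind a predictor
interface (external signal-peptide/propeptide tools can be plugged in):

* *Signal peptide*: a hydrophobic core of ≥ 6 consecutive residues with
  Kyte–Doolittle hydropathy ≥ 1.6 each, starting within the first 30
  residues, preceded by an n-region containing ≥ 1 Lys/Arg, followed within
  8 residues by a small residue (Ala/Gly/Ser/Cys) at the −1 cleavage
  position (the latest qualifying position wins). Absence is a valid result.
* *Propeptide*: first dibasic motif (KR/RR/KK/RK) at position ≥ 2 of the
  post-signal sequence; the mature peptide starts after it.

Mature-peptide properties: molecular weight as the sum of average free
amino-acid masses minus one water (18.02 Da) per peptide bond, reported in
kDa (average, not monoisotopic, masses — published AMP tables are on that
scale); net charge at neutral pH by integer side-chain counting
(#K + #R − #D − #E, His excluded, termini ignored); and the most enriched
residue pair with its combined fraction.

The verdict — secreted ∧ net charge ≥ +2 ∧ mature length 10–100 aa — replaces
the consensus of several external AMP predictors with one transparent rule
(published predictor panels disagree with each other anyway); propeptide
presence is reported but not required by default. The verdict is monotone in
net charge, and on synthetic truth-labelled precursors both sensitivity and
specificity exceed 0.85 at the defaults.

## Phylogeny

Pairwise distances use the Poisson correction d = −ln(1 − p) on the
proportion p of differing sites among positions ungapped in both rows
(pairwise deletion by default, complete deletion by flag — the original
figure's choice is unstated). Saturated pairs (p = 1) raise an error naming
the pair. Neighbor joining follows the Saitou–Nei Q-criterion with
deterministic tie-breaking (lowest index pair) and negative branch-length
estimates clamped to 0; on additive matrices the recovery is exact (verified
against an independent NJ implementation on random trees up to 12 taxa).
Bootstrap support resamples alignment columns with replacement, re-distances
and re-joins; support is the percentage of replicates containing each
original bipartition; replicates with undefined distances are redrawn and
counted. Trees serialise to Newick with branch lengths and integer support
labels. Alignment construction is out of scope — the module consumes
pre-aligned FASTA.

## Survival / LT50

Cumulative death fraction by day is modelled as a binomial GLM with a logit
link (probit by flag; either way LT50 = −intercept/slope), fitted by IRLS,
with a delta-method standard error. Day 0 is the transfer day. A series with
no partial-mortality day is completely separated; the estimator returns the
midpoint between the last fully-alive and first fully-dead day, flagged.
Group comparisons average per-replicate LT50s and report the ratio.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
truth labels for recovery tests. Defaults, with units and reasons:

* **Gene catalog** — n ≥ 10 genes; CDS lengths gamma-distributed (shape 4)
  around a 900 bp mean, floored at 150 bp, codon-rounded; transcript length
  adds 100–500 bp of UTR. Immune-class fractions default to a few percent of
  the catalog, echoing the proportion of immune genes in a whole-transcriptome
  catalog. The first two genes are the endogenous controls.
* **Counts** — negative binomial with configurable dispersion (default 0.1,
  variance = μ + 0.1 μ²; 0 gives Poisson), means = depth × lognormal(0,1)
  length-weighted expression × fold change. Default depth 60,000 reads per
  library, the scale of one pyrosequencing run. Control genes get a 50×
  expression boost: housekeeping controls are among the most expressed genes
  in real libraries, and the pooled control counts anchor every contingency
  test — with weak controls the shared control noise, not per-gene noise,
  dominates all tests.  A reserved `INFECTED_ONLY` token forces a zero naïve
  count.
* **Reads** — exact substrings (default 100 bp) of mito / rRNA / CDS /
  unannotated sources in configurable proportions; error-free by default
  (triage correctness is tested exactly before robustness) with an optional
  uniform substitution rate. The genome is one string with annotated 0-based
  half-open segment intervals; unannotated segments optionally carry planted
  "hidden genes" (random proteins back-translated with one fixed codon per
  residue), and unannotated reads are drawn from those transcripts when
  present — unidentified reads in the real study come from unannotated
  transcription units, not random intergenic DNA.
* **Peptides** — AMP-truth precursors carry a positively charged n-region,
  an 8-residue Leu/Ile/Val/Phe core, a Ser/Ala cleavage context, a propeptide
  (6–14 residues avoiding Lys/Arg and small residues so the planted cleavage
  sites are unambiguous) ending in Lys-Arg, and a cationic mature segment of
  15–60 residues with net charge +4 to +8. Non-AMP precursors violate
  exactly one criterion (no signal peptide, or an anionic mature segment).
* **Survival** — per-fly death times logistic with location LT50 and scale
  1/slope (slope default 1.5 day⁻¹; the logistic matches the binomial-GLM
  estimator, which is why it was chosen over a Weibull); infinite slope gives
  the deterministic step curve.

What the generator does **not** emulate: pyrosequencing homopolymer indels
and quality scores, paired-end structure, UTR/intron read origins (gene reads
come from CDS), correlated gene expression, and biological variance between
larval pools. Passing tests therefore demonstrate correctness of the
algorithms under the stated sampling models, not robustness to real 454
noise.

## Problem sizes used in the suite

The shipped tests and the acceptance script run desk-scale versions of each
experiment: 40-gene catalogs with ~3,000 reads for triage/discovery, a
2,100-gene experiment at 200,000 reads per library for calibration and power,
50-gene tables for TMM, trees up to 12 taxa, and 10,000 flies per survival
arm. These sizes give stable statistics while keeping the whole suite fast;
every generator accepts larger values.

## Known limitations

* Without replicates, the control-anchored test treats all extra-Poisson
  variance as signal; its nominal level holds under Poisson sampling only.
* The built-in matcher is exact-seed based: reads whose first, middle and
  last k-mers are all corrupted will not seed, so high error rates need an
  external aligner behind the matcher contract.
* The Karlin–Altschul constants are fixed, not fitted per scoring system;
  e-values are calibrated by simulation for the default BLOSUM62/11/1 setup
  only.
* Printed downstream values that depend on external database or software
  versions (gene-hit counts, contig counts) are reproduced in structure, not
  in number.
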