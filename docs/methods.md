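# Methods

## The detection problem

Synonymous codon usage in prokaryotes is shaped by two forces: the local
mutational/background substitution pattern of the DNA neighborhood, and —
in some genes — selection for translational speed or accuracy, which pulls
codon choice toward the codons best served by the tRNA pool. Ribosomal
protein (RP) genes are taken as the canonical highly expressed,
translationally selected gene class. The question the framework answers,
separately for every genome and for every gene, is whether codon
frequencies carry information about "being RP-like" *beyond* what the
local background composition already predicts.

## The paired classification protocol

For one genome and one window size *w* ∈ {5, 10, 20} kb:

1. **Baseline arm.** Every admitted gene is described by 20 attributes:
   the 4 mononucleotide and 16 dinucleotide frequencies of the non-coding
   DNA within *w* kb upstream of its start codon and *w* kb downstream of
   its stop codon. All annotated genes (protein and RNA) are masked out of
   this background; dinucleotides are counted only inside contiguous
   unmasked runs, so no pair spans a masked gap. Windows are read in the
   gene's reading-strand orientation so strand-specific skew is
   representable, wrap around circular replicons (each base counted at
   most once), and truncate at the ends of linear ones. A Random Forest is
   trained to discriminate RP genes from these 20 attributes in stratified
   4-fold cross-validation, repeated 50 times; each repetition records the
   AUC and each gene's out-of-fold positive-class probability.
2. **Augmented arm.** The same 50 repetitions, with *identical fold
   partitions*, on the same rows extended by 59 codon attributes: the
   within-family frequencies of the 18 degenerate amino-acid families of
   translation table 11, each family normalized to sum to one, with NaN
   marking families absent from the protein (never zero-filled; the trees
   route missing values natively).
3. **Genome-level test.** One-sided sign test on the 50 paired AUCs.
   At the default threshold 1e-15 only 50 wins out of 50 (p = 2^-50 ≈
   8.9e-16) qualifies; 49/50 gives 51·2^-50 ≈ 4.5e-14. A corrected
   resampled t-test (variance term inflated from var/k to
   (1/k + n_test/n_train)·var, here test fraction 1/3) is reported
   alongside as the conservative companion; the sign test is optimistic
   because the 50 repetitions resample the same genes.
4. **Gene-level calls.** The same one-sided sign test on each gene's 50
   probability pairs, per window; the consensus p is the median over the
   three windows (with fallback to the median of the windows where the
   gene had non-zero ncDNA). A gene is OCU at consensus p ≤ 1e-15, which
   requires a probability increase in every run of at least two windows.

## Why hard voting

The ensemble probability is the fraction of trees whose leaf majority is
the positive class ("voting"), not the mean leaf posterior. This choice is
load-bearing for calibration, not cosmetic: the 50 repetitions are
strongly dependent (same data, different partitions), so any *systematic*
probability difference between arms — however tiny — converts into a
perfect 50/50 win streak. Mean leaf posteriors differ systematically
between a 20-attribute and a 79-attribute forest even when the extra
attributes carry no gene-specific signal; in null simulations (bias
strength 0) soft voting mislabels 3–7% of genes as OCU. With hard voting,
genes without codon signal receive probability exactly 0 in both arms;
the pairs tie, ties are dropped by the sign test, and the gene is
conservatively non-OCU. Null %OCU is then ~0.

## Codon-usage metrics (benchmark baselines)

The nearest-centroid benchmark scores each held-out gene against a
reference built from the training-fold RP genes (one pseudo-count per
codon within each family before normalizing, so every reference frequency
is strictly positive):

* CAI = exp( (1/L) Σ ln w_c ), w_c = f_c / max_family f, degenerate
  families only; computed in the log domain; 1 iff every codon is the
  reference-preferred one; invariant to gene length at fixed proportions.
* CB = Σ_a p_a(gene) Σ_{c∈a} |f(c|gene) − f(c|ref)|, the amino-acid-
  weighted Manhattan distance; 0 iff usage matches the reference, ≤ 2.
* MILC = (Σ_a M_a)/L − C, M_a = 2 Σ_c O_c ln(O_c/E_c) with expectations
  from reference frequencies scaled to the family's gene count;
  C = (Σ_a (r_a − 1))/L − 0.5 over the families present in the gene
  (absent families contribute to neither the sum, L, nor C); a gene whose
  counts equal expectation scores exactly −C.

Orientation in the centroid classifier: high CAI is RP-like; CB and MILC
are negated. Met and Trp (non-degenerate) are excluded everywhere.

## Downstream analyses

* **Optimal codons.** For a two-fold degenerate amino acid (Phe, Tyr,
  His, Gln, Asn, Lys, Asp, Glu, Cys under table 11) whose genome encodes
  tRNAs with exactly one of the two anticodons, the optimal codon is the
  Watson-Crick match of that anticodon (no wobble). A two-sided
  Mann-Whitney U test at p < 1e-3 compares the optimal codon's
  within-family frequency between OCU and non-OCU genes; genomes are
  tallied as preferring the optimal codon, the suboptimal one, or
  neither, and a cross-genome sign test summarizes the tallies. Amino
  acids with both (or neither) anticodon present are "undefined".
* **Enrichment.** Fisher's exact tests: Test A contrasts OCU rates inside
  vs outside one gene category pooled over genomes; Test B contrasts, for
  genes of one category, organisms with vs without a lifestyle. Screens
  keep p < 1e-3 *and* enrichment ratio > 1.50 or < 0.67; every test is
  written with a passes_screen flag rather than silently filtered. No
  additional multiple-testing correction is applied at the fixed
  threshold.
* **Expression contrast.** mean(OCU)/mean(non-OCU) of user-supplied
  per-gene values, a two-sided Baumgartner-Weiss-Schindler permutation
  test for distributional shift (exhaustive enumeration when
  C(n+m, n) ≤ 20,000, Monte-Carlo otherwise), and a one-sided label-
  permutation p for the ratio exceeding 1; an RP-excluded variant guards
  against the contrast being driven by the positive class itself.

## The synthetic genome generator

The generator emulates exactly the confound the method must control for.
A single circular replicon carries `n_genes` protein-coding genes
(lognormal lengths, floor 80 sense codons, default mean 200) alternating
between strands, separated by intergenic spacers (geometric, mean 120 nt
so ncDNA is available within 5 kb windows). Local composition is a smooth
GC profile (sinusoid, default 0.50 ± 0.10, 3 periods), an optional step at
the midpoint (a horizontal-transfer-like segment stand-in), and a GC skew
(default 0.10) that flips sign at the replichore boundary. Spacer bases
are drawn i.i.d. from the local composition; background codon choice
within each family is proportional to the product of position-wise
nucleotide probabilities of the local composition on the gene's reading
strand, renormalized per family — codon usage of unselected genes is thus
a pure function of the same background the windows measure. Amino-acid
sequences are i.i.d. from an average-proteome-like composition (first
residue Met), so family presence is realistic.

A planted fraction (default 15%, always including all 55 RP genes) mixes
in selection: each codon is the family's designated optimal codon with
probability `s` (default 0.5) and a background draw otherwise, so `s = 0`
is an exact null and `s = 1` one-hot optimal usage. The default optimal
table uses C-ending codons for two-fold NNY families, G/A-ending for NNR,
and common highly-expressed-gene choices for 4/6-fold families; the
emitted tRNA inventory carries exactly the matching anticodons. What the
generator does *not* emulate: phylogenetic covariance between genomes,
operon structure, amino-acid composition differences between gene
classes, genuine regulatory elements in ncDNA, and RNA genes. Passing
recovery tests therefore demonstrate correctness of the machinery under
the stated generative assumptions, not performance on real genomes.

## Problem sizes and the desk-scale protocol

`CVConfig.desk(seed)` pins the protocol used throughout the tests,
examples and the acceptance script: 50 runs × stratified 4-fold, 100
trees, √(n_attributes) candidate attributes per split, minimum leaf size
10, half-sample bootstraps, hard voting. The leaf and bootstrap caps keep
a full three-window analysis of a 1,000-gene genome to a few minutes on
one core; the library default (`CVConfig()`) is 500 fully grown trees.
Recovery checks run on the standard 1,000-gene genome; the null
calibration suite uses five 400-gene genomes (22 RP genes, preserving the
~5.5% positive-class rate) so that five full three-window protocols stay
tractable, and asserts rates rather than counts. Robustness checks (RP
outlier injection; masking 20 bp upstream of every start codon) compare
per-gene calls at the 10 kb window against the unperturbed analysis using
the same partition seeds, so observed differences reflect the
perturbation rather than seed noise.

## Numerical choices and degenerate inputs

* Sign-test ties are dropped (classical convention); all-tie input
  reports p = 1 with a flag. A gene with any tied run can therefore never
  reach 1e-15 — conservative by construction.
* Zero-variance differences in the corrected t-test: p = 1 when the mean
  is also 0, else p = 0 with a "degenerate" flag.
* Reference smoothing (+1 per codon per family) prevents log(0) in CAI
  and division by zero in MILC expectations.
* Genes with ambiguous bases, length not divisible by 3, or internal
  stops are dropped with a logged warning; trailing stops are removed; N
  in ncDNA is skipped in counts and breaks dinucleotide pairs.
* Genes with zero ncDNA in a window are excluded from that window and
  fall back to the consensus of the remaining windows.
* AUC uses midranks, handling ties exactly; all-tied scores give 0.5.
* Every stochastic step (genome generation, fold partitions, tree
  bootstraps, permutation tests) is seeded; `paired_cv` is reproducible
  bit-for-bit from `base_seed`, and the two arms of a run always share
  the fold partition.

## Known limitations

* The per-gene sign test inherits the dependence of repeated CV runs; the
  1e-15 threshold plus hard-vote ties is what keeps it calibrated here,
  and the corrected t-test p-values are reported alongside for users who
  want the conservative reading.
* GFF3 support covers plain CDS/RNA feature lines (ID/Parent/product
  attributes); complex multi-segment CDS (joins across origin,
  frameshifts) are out of scope — use the TSV gene table for those.
* The optimal-codon analysis ignores wobble rules by design; it asks only
  about exact Watson-Crick matches of the sole present anticodon.
* Whether the original framework truncated or wrapped windows on circular
  replicons is unspecified; wrapping (each base once) was chosen. Fold
  partitions shared between arms are likewise a choice the source leaves
  open; sharing maximizes the pairing of per-gene probabilities.
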