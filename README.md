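# ocuscan

Detect translational selection in prokaryotic genomes and label individual
genes as having **optimized codon usage (OCU)**, while controlling for
local variation in background nucleotide composition.

## The problem

Codon usage bias in prokaryotes is mostly a byproduct of local DNA
substitution patterns, but in highly expressed genes selection favors
codons that translate faster or more accurately. Classical one-dimensional
indices (CAI, Karlin's CB, MILC) score a gene's codon usage against a
reference set — typically the ribosomal protein (RP) genes — but cannot
say whether a high score reflects selection or merely the gene sitting in
a GC-rich, skewed, or otherwise atypical chromosomal neighborhood.

`ocuscan` answers the question discriminatively. For each genome it trains
a Random Forest to recognize RP genes twice, in paired 50×4-fold
stratified cross-validation with identical fold partitions:

* **baseline arm** — 20 attributes: mono- and dinucleotide frequencies of
  the non-coding DNA within 5/10/20 kb of the gene (the local background);
* **augmented arm** — the same plus 59 within-family codon frequencies
  (18 degenerate families of translation table 11, absent families carried
  as missing values).

A one-sided sign test on the 50 paired AUCs detects genome-wide
translational selection; the same test on each gene's 50 paired
out-of-fold probabilities, combined across window sizes by the median
p-value, yields per-gene OCU labels at the threshold p ≤ 1e-15 — i.e. the
codon attributes must raise the gene's RP-probability in *every* run of at
least two window sizes (50/50 wins: p = 2⁻⁵⁰ ≈ 8.9·10⁻¹⁶; 49/50 already
fails at ≈ 4.5·10⁻¹⁴). A corrected resampled t-test is reported alongside
as the conservative companion. Downstream analyses: optimal-codon
preferences of OCU genes for two-fold amino acids given the genome's tRNA
anticodon inventory, Fisher-exact enrichment screens over gene categories
and organism lifestyles, and an expression contrast (BWS permutation
test). A fully seeded synthetic-genome generator with planted selection
provides ground truth for every stage.

## Worked example

```python
from ocuscan import CVConfig, SimParams, analyze_genome, simulate_genome

sim = simulate_genome(SimParams(
    n_genes=300, n_rp=20, ocu_fraction=0.15, bias_strength=0.6, seed=3))
report = analyze_genome(sim.genome, windows=(5, 10),
                        cv=CVConfig(n_runs=50, n_folds=4, n_trees=50,
                                    min_samples_leaf=10, max_samples=0.5,
                                    base_seed=3))
```

Running `python examples/03_detect_selection.py` (the same computation)
prints:

```
window   AUC(no codons)  AUC(+codons)  sign-test p   corrected-t p
   5 kb   0.519          0.955        8.88e-16     4.70e-24
  10 kb   0.511          0.954        8.88e-16     3.26e-27
selection detected: True
```

The baseline forest, seeing only intergenic composition, ranks RP genes at
chance (AUC ≈ 0.5, as it should: the generator places RP genes at random
positions). Adding codon frequencies lifts the AUC to ≈ 0.95 in all 50
runs of both windows — the sign-test p of 8.9·10⁻¹⁶ (= 2⁻⁵⁰) is the
all-wins outcome, below the 10⁻¹⁵ detection threshold, so the genome is
flagged as under translational selection. `examples/04_ocu_calls.py`
continues to per-gene calls and checks them against the planted truth;
the other examples cover the codon metrics, optimal-codon preferences,
enrichment screens and the expression contrast.

The command line mirrors the library:

```sh
ocuscan simulate --out sim/ --n-genes 300 --bias-strength 0.6 --seed 3
ocuscan ocu --fasta sim/genome.fasta --annotation sim/annotation.tsv \
        --trees 100 --min-samples-leaf 10 --max-samples 0.5 --seed 3 --out run
ocuscan codons --fasta sim/genome.fasta --annotation sim/annotation.tsv \
        --trna sim/trna.tsv --ocu-calls run.ocu.tsv --out prefs.tsv
```

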