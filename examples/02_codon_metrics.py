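"""Score genes with CAI, CB and MILC and benchmark their rankings.

The three classical distance measures compare each gene's codon usage with
the pooled ribosomal-protein reference; the cross-validated nearest-
centroid AUC says how well each separates RP from non-RP genes.
"""

from ocuscan import SimParams, simulate_genome, centroid_rank
from ocuscan.codon_metrics import ReferenceUsage, cai, cb, milc

sim = simulate_genome(
    SimParams(n_genes=150, n_rp=15, ocu_fraction=0.15, bias_strength=0.8, seed=7)
)
genome = sim.genome
ref = ReferenceUsage.from_genes([g.codons for g in genome.genes if g.is_rp])

g_rp = next(g for g in genome.genes if g.is_rp)
g_bg = next(g for g in genome.genes if not g.is_rp)
print("            CAI     CB     MILC")
print(f"RP gene    {cai(g_rp.codons, ref):.3f}  {cb(g_rp.codons, ref):.3f}  {milc(g_rp.codons, ref):+.3f}")
print(f"background {cai(g_bg.codons, ref):.3f}  {cb(g_bg.codons, ref):.3f}  {milc(g_bg.codons, ref):+.3f}")
# high CAI / low CB / low MILC = usage close to the RP reference

for metric in ("CAI", "CB", "MILC"):
    _, score = centroid_rank(genome, metric, seed=0)
    print(f"nearest-centroid AUC ({metric}): {score:.3f}")
# AUC ~1 means the metric alone nearly separates RP genes on this strongly
# biased genome; on real genomes with composition confounds the ensemble
# classifier outperforms these one-dimensional rankings.
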