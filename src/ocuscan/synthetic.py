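"""Synthetic prokaryotic genomes with planted translational selection.

The generator encodes the two forces the detection framework has to
disentangle:

* a *background* force — local nucleotide composition that varies along
  the chromosome (smooth GC profile, optional midpoint step, strand
  GC skew flipping sign at the replichore boundary). Background codon
  choice within each synonymous family is proportional to the product of
  position-wise nucleotide probabilities implied by the local composition,
  so codon usage of unselected genes is a pure function of the same local
  background that the intergenic spacers are drawn from;
* a *selection* force — a planted minority of genes (always including all
  "ribosomal protein" genes) whose codons are, with probability ``s`` (the
  bias strength), replaced by the designated optimal codon of their
  family, falling back to the background distribution otherwise. ``s = 0``
  is an exact null; ``s = 1`` gives one-hot optimal usage.

Everything is deterministic given the seed, and the emitted FASTA +
annotation round-trip through :mod:`ocuscan.genome_io` with no gene loss
(all genes have at least 80 sense codons by construction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import genetic_code, revcomp
from .genome_io import GeneRecord, Genome, Replicon

NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NT)}
_COMP_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT order

# One designated optimal codon per degenerate family (table 11). Two-fold
# NNY families get the C-ending codon, NNR families the G-ending one;
# 4/6-fold picks loosely follow codons over-represented in highly expressed
# E. coli genes.
DEFAULT_OPTIMAL_CODONS = {
    "A": "GCT", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG",
    "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCC",
    "T": "ACC", "V": "GTT", "Y": "TAC",
}

# Average proteome-like amino-acid composition (fractions, renormalized).
DEFAULT_AA_FREQS = {
    "A": 0.088, "R": 0.055, "N": 0.039, "D": 0.054, "C": 0.012,
    "Q": 0.039, "E": 0.061, "G": 0.078, "H": 0.021, "I": 0.060,
    "L": 0.100, "K": 0.059, "M": 0.024, "F": 0.041, "P": 0.046,
    "S": 0.066, "T": 0.053, "W": 0.012, "Y": 0.033, "V": 0.069,
}


@dataclass
class SimParams:
    """Study conditions of one simulated genome.

    ``ocu_fraction`` counts all planted genes including the ``n_rp``
    ribosomal-protein genes, which are always planted — the framework's
    core premise is that RP genes are the translationally selected
    exemplar. ``bias_strength`` is the mixture weight s of the optimal-
    codon component in planted genes' codon choice.
    """

    n_genes: int = 1000
    n_rp: int = 55
    ocu_fraction: float = 0.15
    bias_strength: float = 0.5
    mean_gene_len: int = 200  # sense codons; hard floor 80
    spacer_mean: int = 120  # nt
    gc_mean: float = 0.50
    gc_amplitude: float = 0.10
    gc_periods: float = 3.0
    gc_step: float = 0.0  # composition step added past the midpoint
    gc_skew: float = 0.10  # forward-strand (G-C)/(G+C); sign flips at midpoint
    optimal_codons: dict = field(default_factory=lambda: dict(DEFAULT_OPTIMAL_CODONS))
    aa_freqs: dict = field(default_factory=lambda: dict(DEFAULT_AA_FREQS))
    table_id: int = 11
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must lie in [0, 1]")
        if not 0.0 <= self.ocu_fraction <= 1.0:
            raise ValueError("ocu_fraction must lie in [0, 1]")
        if self.n_rp > self.n_genes:
            raise ValueError("n_rp exceeds n_genes")


@dataclass
class SimulatedGenome:
    """A generated genome plus its ground truth."""

    genome: Genome
    truth: pd.DataFrame  # gene_id, is_rp, planted_ocu, bias_strength, local_gc, strand
    trna_inventory: dict  # amino acid -> tuple of anticodons present
    params: SimParams
    aa_sequences: dict  # gene_id -> amino-acid string (enables resampling)


def _local_probs(x, L, p: SimParams):
    """Forward-strand nucleotide probabilities (A, C, G, T) at position(s) x."""
    x = np.asarray(x, dtype=float)
    gc = p.gc_mean + p.gc_amplitude * np.sin(2 * np.pi * p.gc_periods * x / L)
    gc = gc + np.where(x >= L / 2, p.gc_step, 0.0)
    gc = np.clip(gc, 0.05, 0.95)
    skew = np.where(x < L / 2, p.gc_skew, -p.gc_skew)
    pg = gc / 2 * (1 + skew)
    pc = gc / 2 * (1 - skew)
    pa = (1 - gc) / 2
    pt = (1 - gc) / 2
    return np.stack([pa, pc, pg, pt], axis=-1)


_CODONS64 = ["".join(c) for c in itertools.product(NT, repeat=3)]
_CODON64_INDEX = {c: i for i, c in enumerate(_CODONS64)}


def _codon_probs_from_nt(q):
    """64-codon probabilities as products of positionwise nucleotide probs."""
    return np.einsum("i,j,k->ijk", q, q, q).reshape(64)


def _sample_codons(rng, aa_seq, q, code, optimal, s):
    """Sample one codon per residue: mixture of optimal and background choice."""
    p64 = _codon_probs_from_nt(q)
    fam_dist = {}
    for aa, fam in code.families.items():
        w = np.array([p64[_CODON64_INDEX[c]] for c in fam])
        tot = w.sum()
        fam_dist[aa] = w / tot if tot > 0 else np.full(len(fam), 1 / len(fam))
    fixed = {
        aa: codon
        for codon, aa in code.codon_to_aa.items()
        if aa != "*" and aa not in code.families
    }
    codons = [None] * len(aa_seq)
    aa_arr = np.array(list(aa_seq))
    for aa in set(aa_seq):
        idxs = np.flatnonzero(aa_arr == aa)
        if aa in fixed:
            for i in idxs:
                codons[i] = fixed[aa]
            continue
        fam = code.families[aa]
        draws = rng.choice(len(fam), size=idxs.size, p=fam_dist[aa])
        if s > 0 and aa in optimal:
            use_opt = rng.random(idxs.size) < s
            opt_j = fam.index(optimal[aa])
            draws = np.where(use_opt, opt_j, draws)
        for i, j in zip(idxs, draws):
            codons[i] = fam[j]
    return codons


def _sample_spacer(rng, start, length, L, p):
    if length <= 0:
        return ""
    probs = _local_probs(np.arange(start, start + length) % L, L, p)
    u = rng.random(length)
    cum = np.cumsum(probs, axis=1)
    idx = np.minimum((u[:, None] > cum).sum(axis=1), 3)
    return "".join(NT[i] for i in idx)


_RP_NAMES = [f"30S ribosomal protein S{i}" for i in range(1, 22)] + [
    f"50S ribosomal protein L{i}" for i in range(1, 37)
]
_DECOY_PRODUCTS = [
    "ribosomal protein L11 methyltransferase",
    "ribosomal protein S6 modification protein",
    "tRNA pseudouridine synthase B",
]


def simulate_genome(params: SimParams) -> SimulatedGenome:
    """Generate one annotated genome with planted codon-usage selection.

    Genes alternate between the two strands, are separated by intergenic
    spacers drawn from the local background composition, and live on a
    single circular replicon. Returns the in-memory genome, the truth
    table, and a tRNA inventory consistent with the planted optimal codons
    (one anticodon per family, the exact Watson-Crick match).
    """
    rng = np.random.default_rng(params.seed)
    code = genetic_code(params.table_id)
    n = params.n_genes

    lengths = np.maximum(
        80, rng.lognormal(np.log(params.mean_gene_len * 0.85), 0.4, n).astype(int)
    )
    spacers = rng.geometric(1.0 / params.spacer_mean, n)
    L_total = int((3 * (lengths + 1)).sum() + spacers.sum())

    n_planted = int(round(params.ocu_fraction * n))
    if n_planted < params.n_rp:
        raise ValueError("ocu_fraction too small to cover all RP genes")
    order = rng.permutation(n)
    rp_set = set(order[: params.n_rp].tolist())
    planted_set = set(order[:n_planted].tolist())

    aas = np.array(list(params.aa_freqs))
    aa_p = np.array([params.aa_freqs[a] for a in aas], dtype=float)
    aa_p /= aa_p.sum()

    chunks = []
    pos = 0
    genes, truth_rows, aa_sequences = [], [], []
    aa_seq_map = {}
    rp_name_cycle = 0
    non_rp_pool = sorted(set(range(n)) - rp_set)
    n_decoys = min(3, len(non_rp_pool))
    decoys = set(rng.choice(non_rp_pool, n_decoys, replace=False).tolist())
    for i in range(n):
        sp = int(spacers[i])
        chunks.append(_sample_spacer(rng, pos, sp, L_total, params))
        pos += sp
        start = pos
        strand = "+" if i % 2 == 0 else "-"
        L_i = int(lengths[i])
        aa_seq = "M" + "".join(rng.choice(aas, L_i - 1, p=aa_p))
        q_fwd = _local_probs(start + 1.5 * L_i, L_total, params)
        q = q_fwd if strand == "+" else q_fwd[_COMP_INDEX]
        s = params.bias_strength if i in planted_set else 0.0
        codons = _sample_codons(rng, aa_seq, q, code, params.optimal_codons, s)
        stop_w = np.array([_codon_probs_from_nt(q)[_CODON64_INDEX[c]] for c in code.stop_codons])
        stop = code.stop_codons[rng.choice(len(stop_w), p=stop_w / stop_w.sum())]
        cds = "".join(codons) + stop
        chunks.append(cds if strand == "+" else revcomp(cds))
        end = start + len(cds)
        pos = end
        gene_id = f"g{i:04d}"
        if i in rp_set:
            product = _RP_NAMES[rp_name_cycle % len(_RP_NAMES)]
            rp_name_cycle += 1
        elif i in decoys:
            product = _DECOY_PRODUCTS[sorted(decoys).index(i)]
        else:
            product = "hypothetical protein"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                replicon_id="chr",
                start=start,
                end=end,
                strand=strand,
                codons=codons,
                product=product,
                is_rp=i in rp_set,
            )
        )
        gc_local = float(q_fwd[1] + q_fwd[2])
        truth_rows.append(
            {
                "gene_id": gene_id,
                "is_rp": i in rp_set,
                "planted_ocu": i in planted_set,
                "bias_strength": s,
                "local_gc": gc_local,
                "strand": strand,
            }
        )
        aa_seq_map[gene_id] = aa_seq

    sequence = "".join(chunks)
    replicon = Replicon("chr", sequence, "circular")
    genome = Genome(replicons={"chr": replicon}, genes=genes, rna_intervals=[])
    trna = {
        aa: (revcomp(codon),) for aa, codon in params.optimal_codons.items()
    }
    return SimulatedGenome(
        genome=genome,
        truth=pd.DataFrame(truth_rows),
        trna_inventory=trna,
        params=params,
        aa_sequences=aa_seq_map,
    )


def inject_outlier_rp(sim: SimulatedGenome, seed: int = 0) -> SimulatedGenome:
    """Resample one RP gene's codons from the pure background (s = 0).

    Models an annotation error — a positive-class gene with atypical codon
    usage — used to probe robustness of the per-gene calls. The gene keeps
    its amino-acid sequence and coordinates; the replicon sequence is
    spliced accordingly and the truth table updated.
    """
    rng = np.random.default_rng(seed)
    params = sim.params
    code = genetic_code(params.table_id)
    rp_idx = [i for i, g in enumerate(sim.genome.genes) if g.is_rp]
    if not rp_idx:
        raise ValueError("no RP gene to perturb")
    i = int(rng.choice(rp_idx))
    old = sim.genome.genes[i]
    rep = sim.genome.replicons[old.replicon_id]
    L_total = len(rep)
    aa_seq = sim.aa_sequences[old.gene_id]
    q_fwd = _local_probs(old.start + 0.5 * (old.end - old.start), L_total, params)
    q = q_fwd if old.strand == "+" else q_fwd[_COMP_INDEX]
    codons = _sample_codons(rng, aa_seq, q, code, params.optimal_codons, 0.0)
    old_cds_fwd = rep.sequence[old.start : old.end]
    stop = (old_cds_fwd if old.strand == "+" else revcomp(old_cds_fwd))[-3:]
    cds = "".join(codons) + stop
    cds_fwd = cds if old.strand == "+" else revcomp(cds)
    new_seq = rep.sequence[: old.start] + cds_fwd + rep.sequence[old.end :]

    new_replicon = Replicon(rep.id, new_seq, rep.topology)
    new_genes = list(sim.genome.genes)
    new_genes[i] = GeneRecord(
        gene_id=old.gene_id,
        replicon_id=old.replicon_id,
        start=old.start,
        end=old.end,
        strand=old.strand,
        codons=codons,
        product=old.product,
        is_rp=True,
    )
    genome = Genome(
        replicons={rep.id: new_replicon},
        genes=new_genes,
        rna_intervals=list(sim.genome.rna_intervals),
    )
    truth = sim.truth.copy()
    truth.loc[truth.gene_id == old.gene_id, ["planted_ocu", "bias_strength"]] = [False, 0.0]
    return SimulatedGenome(
        genome=genome,
        truth=truth,
        trna_inventory=dict(sim.trna_inventory),
        params=params,
        aa_sequences=dict(sim.aa_sequences),
    )


# ---------------------------------------------------------------------------
# File emission (FASTA + TSV dialect of genome_io)


def write_genome(sim: SimulatedGenome, outdir):
    """Write FASTA, annotation TSV, tRNA inventory TSV and truth TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fasta"
    with open(fasta, "w") as fh:
        for rid, rep in sim.genome.replicons.items():
            fh.write(f">{rid}\n")
            for j in range(0, len(rep.sequence), 70):
                fh.write(rep.sequence[j : j + 70] + "\n")
    ann = outdir / "annotation.tsv"
    with open(ann, "w") as fh:
        fh.write("gene_id\treplicon\tstart\tend\tstrand\tproduct\ttype\n")
        for g in sim.genome.genes:
            fh.write(
                f"{g.gene_id}\t{g.replicon_id}\t{g.start}\t{g.end}\t{g.strand}"
                f"\t{g.product}\tCDS\n"
            )
        for rid, s, e in sim.genome.rna_intervals:
            fh.write(f"rna\t{rid}\t{s}\t{e}\t+\t\trRNA\n")
    trna = outdir / "trna.tsv"
    with open(trna, "w") as fh:
        fh.write("amino_acid\tanticodon\n")
        for aa, anticodons in sorted(sim.trna_inventory.items()):
            for ac in anticodons:
                fh.write(f"{aa}\t{ac}\n")
    truth = outdir / "truth.tsv"
    sim.truth.to_csv(truth, sep="\t", index=False)
    return {"fasta": fasta, "annotation": ann, "trna": trna, "truth": truth}
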