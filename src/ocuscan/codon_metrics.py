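"""Classical codon-usage distance measures and a nearest-centroid classifier.

Three measures compare a gene's codon usage with a reference gene set
(here, pooled ribosomal-protein genes):

* CAI — codon adaptation index: geometric mean over the gene's codons of
  the relative adaptiveness w_c = f_c / max_family f, computed over
  degenerate families only; 1 means every codon is the reference-preferred
  one.
* CB — Karlin's codon bias between gene groups: the gene's amino-acid
  frequencies weighting the per-family Manhattan distance between codon
  frequency vectors, B(g|G) = sum_a p_a(g) * sum_c |f(c|g) - f(c|G)|.
* MILC — measure independent of length and composition: a length-corrected
  G-statistic, MILC = (sum_a M_a)/L - C with M_a = 2 sum_c O_c ln(O_c/E_c),
  expectations from reference frequencies, and correction
  C = (sum_a (r_a - 1))/L - 0.5 over families present in the gene.

Each is wrapped into a cross-validated nearest-centroid ranking so its
ability to single out ribosomal-protein genes can be compared with the
Random Forest on equal footing (AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .codes import GeneticCode, genetic_code
from .features import _codon_index
from .rf import auc


@dataclass
class ReferenceUsage:
    """Smoothed codon usage of a reference gene set.

    ``freqs`` is aligned to ``code.family_codons``; one pseudo-count per
    codon is added within each family before normalizing, so every
    frequency is strictly positive (no log(0) in CAI/MILC).
    """

    code: GeneticCode
    freqs: np.ndarray

    @classmethod
    def from_counts(cls, counts, code: GeneticCode):
        counts = np.asarray(counts, dtype=float)
        freqs = np.empty_like(counts)
        pos = 0
        for fam in code.families.values():
            k = len(fam)
            c = counts[pos : pos + k] + 1.0
            freqs[pos : pos + k] = c / c.sum()
            pos += k
        return cls(code, freqs)

    @classmethod
    def from_genes(cls, gene_codon_lists, table_id: int = 11):
        code = genetic_code(table_id)
        counts = np.zeros(len(code.family_codons))
        for codons in gene_codon_lists:
            counts += codon_counts(codons, code)
        return cls.from_counts(counts, code)


def codon_counts(codons, code: GeneticCode) -> np.ndarray:
    """Counts over ``code.family_codons`` (non-degenerate codons ignored)."""
    idx = _codon_index(code)
    counts = np.zeros(len(code.family_codons))
    for c in codons:
        j = idx.get(c)
        if j is not None:
            counts[j] += 1
    return counts


def _family_slices(code: GeneticCode):
    pos, out = 0, []
    for aa, fam in code.families.items():
        out.append((aa, slice(pos, pos + len(fam)), len(fam)))
        pos += len(fam)
    return out


def cai(codons, reference: ReferenceUsage) -> float:
    """Codon adaptation index of a gene against a reference, in (0, 1]."""
    counts = codons if isinstance(codons, np.ndarray) else codon_counts(codons, reference.code)
    total = counts.sum()
    if total == 0:
        raise ValueError("gene has no codons in degenerate families")
    log_w = np.zeros_like(reference.freqs)
    for _, sl, _ in _family_slices(reference.code):
        f = reference.freqs[sl]
        log_w[sl] = np.log(f) - np.log(f.max())
    return float(np.exp(np.dot(counts, log_w) / total))


def cb(codons, reference: ReferenceUsage) -> float:
    """Karlin's codon bias of a gene relative to a reference, in [0, 2]."""
    counts = codons if isinstance(codons, np.ndarray) else codon_counts(codons, reference.code)
    total = counts.sum()
    if total == 0:
        raise ValueError("gene has no codons in degenerate families")
    b = 0.0
    for _, sl, _ in _family_slices(reference.code):
        n_a = counts[sl].sum()
        if n_a == 0:
            continue
        b += (n_a / total) * np.abs(counts[sl] / n_a - reference.freqs[sl]).sum()
    return float(b)


def milc(codons, reference: ReferenceUsage) -> float:
    """MILC distance of a gene from a reference.

    Families absent from the gene contribute neither to the statistic nor
    to the length or the correction term; zero observed counts contribute
    0 (lim x->0 of x ln x). A gene whose counts exactly match expectation
    scores -C, the negative of its length correction.
    """
    counts = codons if isinstance(codons, np.ndarray) else codon_counts(codons, reference.code)
    if counts.sum() == 0:
        raise ValueError("gene has no codons in degenerate families")
    m_sum, L, r_sum = 0.0, 0.0, 0.0
    for _, sl, r_a in _family_slices(reference.code):
        O = counts[sl]
        n_a = O.sum()
        if n_a == 0:
            continue
        E = reference.freqs[sl] * n_a
        nz = O > 0
        m_sum += 2.0 * np.sum(O[nz] * np.log(O[nz] / E[nz]))
        L += n_a
        r_sum += r_a - 1
    C = r_sum / L - 0.5
    return float(m_sum / L - C)


METRICS = {"CAI": cai, "CB": cb, "MILC": milc}
# orientation: +1 if high values are RP-like, -1 if low values are RP-like
_ORIENT = {"CAI": 1.0, "CB": -1.0, "MILC": -1.0}


def score_genome(genome, metric: str, reference: ReferenceUsage):
    """Metric value for every gene of a genome against one reference."""
    fn = METRICS[metric]
    code = reference.code
    return np.array([fn(codon_counts(g.codons, code), reference) for g in genome.genes])


def centroid_rank(genome, metric: str, *, n_folds: int = 4, seed: int = 0, table_id: int = 11):
    """Cross-validated nearest-centroid ranking of genes by one metric.

    Per fold, the reference usage is pooled from the training-fold RP genes
    and the held-out genes are scored; scores are oriented so RP-like genes
    rank high (CAI as-is, CB/MILC negated). Returns ``(scores, auc)`` with
    one out-of-fold score per gene in genome order.
    """
    code = genetic_code(table_id)
    y = np.array([g.is_rp for g in genome.genes], dtype=bool)
    if y.sum() < 2:
        raise ValueError("need at least 2 RP genes for cross-validated ranking")
    counts = np.vstack([codon_counts(g.codons, code) for g in genome.genes])
    fn = METRICS[metric]
    orient = _ORIENT[metric]
    scores = np.empty(len(y))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(counts, y):
        rp_train = train_idx[y[train_idx]]
        ref = ReferenceUsage.from_counts(counts[rp_train].sum(axis=0), code)
        for i in test_idx:
            scores[i] = orient * fn(counts[i], ref)
    return scores, auc(y, scores)
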