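"""Attribute vectors for the classifiers.

Two aligned datasets are built per genome and window size:

* the *baseline* dataset describes each gene only by the mono- and
  dinucleotide frequencies of the non-coding DNA in its neighborhood
  window (20 attributes), i.e. the local background substitution pattern;
* the *augmented* dataset additionally carries within-family codon
  frequencies for the 18 degenerate amino-acid families (59 attributes
  under translation table 11), normalized to sum to one per family, with
  NaN marking families absent from the protein.

The gap in classification accuracy between the two is the evidence for
selection on synonymous codon choice beyond the mutational background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codes import genetic_code
from .genome_io import Genome, build_coding_mask, ncdna_window

MONO = ("A", "C", "G", "T")
DI = tuple(a + b for a in MONO for b in MONO)

_CHAR_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(MONO):
    _CHAR_CODE[ord(_c)] = _i


@dataclass
class NcWindowFeatures:
    """Composition of the intergenic DNA around one gene."""

    mono: np.ndarray  # 4 frequencies, order A C G T
    di: np.ndarray  # 16 frequencies, order AA AC ... TT
    ncdna_length: int
    window_kb: float


def nc_features(runs, window_kb: float = 0.0) -> NcWindowFeatures:
    """Mono/dinucleotide frequencies over contiguous non-coding runs.

    Dinucleotides are counted only within a run — no pair spans a masked
    gap or an N — and each frequency block is normalized by its own total.
    Zero usable nucleotides yields all-NaN features with length 0.
    """
    total_len = sum(len(r) for r in runs)
    if total_len == 0:
        return NcWindowFeatures(
            np.full(4, np.nan), np.full(16, np.nan), 0, window_kb
        )
    # separator code 4 between runs prevents cross-run pairs
    joined = "\x00".join(runs)
    arr = _CHAR_CODE[np.frombuffer(joined.encode("latin-1"), dtype=np.uint8)]
    valid = arr < 4
    mono_counts = np.bincount(arr[valid], minlength=4).astype(float)
    a, b = arr[:-1], arr[1:]
    pair_ok = (a < 4) & (b < 4)
    di_counts = np.bincount(
        (4 * a[pair_ok] + b[pair_ok]).astype(np.intp), minlength=16
    ).astype(float)
    mono = mono_counts / mono_counts.sum() if mono_counts.sum() else np.full(4, np.nan)
    di = di_counts / di_counts.sum() if di_counts.sum() else np.full(16, np.nan)
    return NcWindowFeatures(mono, di, total_len, window_kb)


def codon_frequencies(codons, table_id: int = 11):
    """Within-family codon frequencies of one gene.

    Returns ``{amino_acid: {codon: frequency}}`` over the degenerate
    families of the genetic code; families whose amino acid is absent from
    the protein are omitted entirely (missing, never zero-filled). Each
    present family's frequencies sum to one.
    """
    if not codons:
        raise ValueError("empty codon list")
    code = genetic_code(table_id)
    counts: dict = {}
    for c in codons:
        aa = code.family_of(c)
        if aa is not None:
            counts.setdefault(aa, {}).setdefault(c, 0)
            counts[aa][c] += 1
    out = {}
    for aa, cc in counts.items():
        tot = sum(cc.values())
        out[aa] = {c: cc.get(c, 0) / tot for c in code.families[aa]}
    return out


def codon_feature_vector(codons, code) -> np.ndarray:
    """Flat codon-attribute vector aligned to ``code.family_codons``.

    NaN marks every codon of an absent family.
    """
    idx = _codon_index(code)
    counts = np.zeros(len(code.family_codons))
    for c in codons:
        j = idx.get(c)
        if j is not None:
            counts[j] += 1
    vec = np.full(len(code.family_codons), np.nan)
    pos = 0
    for aa, fam in code.families.items():
        k = len(fam)
        tot = counts[pos : pos + k].sum()
        if tot > 0:
            vec[pos : pos + k] = counts[pos : pos + k] / tot
        pos += k
    return vec


_codon_index_cache: dict = {}


def _codon_index(code):
    key = code.table_id
    if key not in _codon_index_cache:
        _codon_index_cache[key] = {c: i for i, c in enumerate(code.family_codons)}
    return _codon_index_cache[key]


@dataclass
class Dataset:
    """A feature matrix aligned to a fixed gene order.

    ``X`` is float64 with NaN for missing values; ``n_nc_cols`` marks the
    boundary between the non-coding-composition block and the codon block
    (0 codon columns for the baseline arm).
    """

    gene_ids: list
    y: np.ndarray
    X: np.ndarray
    columns: list
    n_nc_cols: int = 20

    @property
    def n_genes(self):
        return len(self.gene_ids)


def build_datasets(
    genome: Genome,
    window_kb: float,
    *,
    masks=None,
    table_id: int = 11,
    min_rp: int = 2,
    min_nonrp: int = 10,
):
    """Build the aligned baseline and codon-augmented datasets for one window.

    Genes with zero non-coding DNA in the window are excluded from both
    arms and reported. Returns ``(baseline, augmented, excluded_ids)``.
    Raises when fewer than ``min_rp`` RP or ``min_nonrp`` non-RP genes
    remain — the classification task would be degenerate.
    """
    code = genetic_code(table_id)
    if masks is None:
        masks = build_coding_mask(genome)
    nc_rows, codon_rows, gene_ids, labels, excluded = [], [], [], [], []
    for gene in genome.genes:
        runs, n_nc = ncdna_window(gene, window_kb, masks, genome)
        if n_nc == 0:
            excluded.append(gene.gene_id)
            continue
        f = nc_features(runs, window_kb)
        nc_rows.append(np.concatenate([f.mono, f.di]))
        codon_rows.append(codon_feature_vector(gene.codons, code))
        gene_ids.append(gene.gene_id)
        labels.append(gene.is_rp)
    y = np.asarray(labels, dtype=bool)
    n_rp = int(y.sum())
    if n_rp < min_rp or (len(y) - n_rp) < min_nonrp:
        raise ValueError(
            f"degenerate classification task: {n_rp} RP / {len(y) - n_rp} non-RP genes"
        )
    nc_block = np.vstack(nc_rows)
    codon_block = np.vstack(codon_rows)
    nc_cols = [f"nc_{m}" for m in MONO] + [f"nc_{d}" for d in DI]
    codon_cols = [
        f"{aa}:{c}" for aa, fam in code.families.items() for c in fam
    ]
    baseline = Dataset(gene_ids, y, nc_block, nc_cols, n_nc_cols=20)
    augmented = Dataset(
        list(gene_ids),
        y.copy(),
        np.hstack([nc_block, codon_block]),
        nc_cols + codon_cols,
        n_nc_cols=20,
    )
    return baseline, augmented, excluded


def write_dataset_tsv(dataset: Dataset, path):
    """Write a feature matrix as TSV (gene_id, label, attributes; NA missing)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "label", *dataset.columns])
        for gid, yi, row in zip(dataset.gene_ids, dataset.y, dataset.X):
            vals = ["NA" if np.isnan(v) else f"{v:.6g}" for v in row]
            w.writerow([gid, "RP" if yi else "non-RP", *vals])
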