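"""Reading genomes and extracting per-gene intergenic neighborhoods.

The detection framework represents each gene by (a) its codon usage and
(b) the nucleotide composition of the *non-coding* DNA in a fixed-size
window around it. Everything annotated as a gene — protein-coding or RNA
(tRNA, rRNA, ...) — counts as coding DNA and is excluded from that
background, so the window captures only intergenic sequence.

Coordinates are 0-based half-open on the forward strand throughout; GFF3
input (1-based inclusive) is converted at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .codes import genetic_code, revcomp, split_codons

logger = logging.getLogger(__name__)

Interval = tuple  # (replicon_id, start, end), 0-based half-open


@dataclass
class Replicon:
    """One DNA molecule (chromosome or plasmid)."""

    id: str
    sequence: str
    topology: str = "circular"  # or "linear"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"replicon {self.id}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"replicon {self.id}: bad topology {self.topology!r}")

    def __len__(self):
        return len(self.sequence)


@dataclass
class GeneRecord:
    """One admitted protein-coding gene with its sense codons (stop removed)."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    codons: list
    product: str = ""
    is_rp: bool = False

    @property
    def length_codons(self) -> int:
        return len(self.codons)


@dataclass
class Genome:
    """A genome ready for analysis: replicons, admitted genes, RNA intervals."""

    replicons: dict
    genes: list
    rna_intervals: list = field(default_factory=list)

    def replicon_order(self):
        return list(self.replicons)


# ---------------------------------------------------------------------------
# Parsing


def _parse_tsv_annotation(path):
    """Gene table dialect: gene_id, replicon, start, end, strand, product[, type].

    Coordinates are 0-based half-open. Rows whose type is not CDS are
    collected as RNA/other intervals.
    """
    cds_rows, rna_intervals = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for want in ("gene_id", "replicon", "start", "end", "strand"):
            if want not in idx:
                raise ValueError(f"{path}: missing column {want!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                row = {
                    "gene_id": parts[idx["gene_id"]],
                    "replicon": parts[idx["replicon"]],
                    "start": int(parts[idx["start"]]),
                    "end": int(parts[idx["end"]]),
                    "strand": parts[idx["strand"]],
                    "product": parts[idx["product"]] if "product" in idx else "",
                    "type": parts[idx["type"]] if "type" in idx else "CDS",
                }
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row ({exc})") from exc
            if row["type"] == "CDS":
                cds_rows.append(row)
            else:
                rna_intervals.append((row["replicon"], row["start"], row["end"]))
    return cds_rows, rna_intervals

_GFF_RNA_TYPES = {"tRNA", "rRNA", "ncRNA", "tmRNA", "SRP_RNA", "RNase_P_RNA"}


def _parse_gff3(path):
    """Minimal GFF3 reader: CDS features become genes, RNA features masks."""
    cds_rows, rna_intervals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _, ftype, start1, end1, _, strand, _, attrs = parts
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if ftype == "CDS":
                adict = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                gene_id = adict.get("ID") or adict.get("Parent") or f"cds{lineno}"
                cds_rows.append(
                    {
                        "gene_id": gene_id,
                        "replicon": seqid,
                        "start": start,
                        "end": end,
                        "strand": strand,
                        "product": adict.get("product", ""),
                        "type": "CDS",
                    }
                )
            elif ftype in _GFF_RNA_TYPES:
                rna_intervals.append((seqid, start, end))
    return cds_rows, rna_intervals


def read_genome(
    fasta_path,
    annotation_path,
    *,
    topology: str = "circular",
    min_codons: int = 80,
    table_id: int = 11,
) -> Genome:
    """Load sequence + annotation into a :class:`Genome`.

    Protein-coding genes are admitted when their CDS length is divisible by
    3, contains no ambiguous base and no internal stop, and they retain at
    least ``min_codons`` sense codons after removing a trailing stop. Genes
    failing a filter are dropped with a logged warning; a replicon
    referenced by the annotation but absent from the FASTA is a hard error.
    """
    replicons = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        replicons[rec.id] = Replicon(rec.id, str(rec.seq).upper(), topology)
    if not replicons:
        raise ValueError(f"{fasta_path}: no FASTA records")

    path = str(annotation_path)
    if path.endswith((".gff", ".gff3")):
        cds_rows, rna_intervals = _parse_gff3(path)
    else:
        cds_rows, rna_intervals = _parse_tsv_annotation(path)

    code = genetic_code(table_id)
    stops = set(code.stop_codons)
    genes = []
    for row in cds_rows:
        rid = row["replicon"]
        if rid not in replicons:
            raise ValueError(f"annotation references unknown replicon {rid!r}")
        rep = replicons[rid]
        if not (0 <= row["start"] < row["end"] <= len(rep)):
            raise ValueError(
                f"gene {row['gene_id']}: coordinates outside replicon {rid}"
            )
        cds = rep.sequence[row["start"] : row["end"]]
        if row["strand"] == "-":
            cds = revcomp(cds)
        elif row["strand"] != "+":
            raise ValueError(f"gene {row['gene_id']}: bad strand {row['strand']!r}")
        if len(cds) % 3:
            logger.warning("gene %s: length not divisible by 3, dropped", row["gene_id"])
            continue
        if any(c not in "ACGT" for c in cds):
            logger.warning("gene %s: ambiguous bases in CDS, dropped", row["gene_id"])
            continue
        codons = split_codons(cds)
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        if any(c in stops for c in codons):
            logger.warning("gene %s: internal stop codon, dropped", row["gene_id"])
            continue
        if len(codons) < min_codons:
            continue
        genes.append(
            GeneRecord(
                gene_id=row["gene_id"],
                replicon_id=rid,
                start=row["start"],
                end=row["end"],
                strand=row["strand"],
                codons=codons,
                product=row["product"],
            )
        )
    for rid, s, e in rna_intervals:
        if rid not in replicons:
            raise ValueError(f"annotation references unknown replicon {rid!r}")
    return Genome(replicons=replicons, genes=genes, rna_intervals=rna_intervals)


# ---------------------------------------------------------------------------
# Ribosomal-protein flagging

RP_INCLUDE = re.compile(
    r"ribosomal protein|(30S|50S) ribosomal subunit protein", re.IGNORECASE
)
RP_EXCLUDE = re.compile(
    r"methyltransferase|kinase|pseudouridine|modification|hydroxylase",
    re.IGNORECASE,
)


def flag_ribosomal(genes, rp_ids=None, include=RP_INCLUDE, exclude=RP_EXCLUDE):
    """Mark ribosomal-protein genes (the positive class) in place.

    An explicit id list overrides product matching; otherwise a gene is
    flagged when its product matches ``include`` and not ``exclude`` (so
    "30S ribosomal protein S12" is positive but "ribosomal protein L11
    methyltransferase" is not). All copies of multicopy RP genes are kept.
    Raises if no gene is flagged — the positive class would be empty.
    """
    if rp_ids is not None:
        rp_ids = set(rp_ids)
        for g in genes:
            g.is_rp = g.gene_id in rp_ids
    else:
        for g in genes:
            g.is_rp = bool(include.search(g.product)) and not exclude.search(g.product)
    n = sum(g.is_rp for g in genes)
    if n == 0:
        raise ValueError("no ribosomal-protein genes flagged: positive class empty")
    return genes


# ---------------------------------------------------------------------------
# Coding mask and intergenic windows


def build_coding_mask(genome: Genome, extra_masks=()) -> dict:
    """Boolean mask per replicon: True where the base is covered by any gene
    (protein-coding or RNA) or by a user-supplied extra interval."""
    masks = {rid: np.zeros(len(rep), dtype=bool) for rid, rep in genome.replicons.items()}
    intervals = [(g.replicon_id, g.start, g.end) for g in genome.genes]
    intervals += list(genome.rna_intervals) + list(extra_masks)
    for rid, s, e in intervals:
        if rid not in masks:
            raise ValueError(f"mask interval on unknown replicon {rid!r}")
        L = len(masks[rid])
        if not (0 <= s <= e <= L):
            raise ValueError(f"mask interval [{s},{e}) outside replicon {rid}")
        masks[rid][s:e] = True
    return masks


def upstream_intervals(genome: Genome, bp: int = 20):
    """Intervals covering ``bp`` bases upstream of each gene's start codon
    (strand-aware), for masking putative translation-related elements."""
    out = []
    for g in genome.genes:
        L = len(genome.replicons[g.replicon_id])
        circular = genome.replicons[g.replicon_id].topology == "circular"
        if g.strand == "+":
            s, e = g.start - bp, g.start
        else:
            s, e = g.end, g.end + bp
        if circular:
            a = s % L
            b = a + (e - s)
            if b <= L:
                out.append((g.replicon_id, a, b))
            else:
                out.append((g.replicon_id, a, L))
                out.append((g.replicon_id, 0, b - L))
            continue
        s, e = max(s, 0), min(e, L)
        if s < e:
            out.append((g.replicon_id, s, e))
    return out


def _window_segments(start, end, window, L, circular):
    """Forward-coordinate segments of the flanking window of a gene.

    The window is the union of [start-window, start) and [end, end+window).
    Returns merged, non-wrapping, deduplicated [a, b) segments; for circular
    replicons the flanks wrap and each base is counted at most once even
    when the window covers the whole replicon or the two flanks meet.
    """
    flanks = [(start - window, start), (end, end + window)]
    norm = []
    for a, b in flanks:
        if a >= b:
            continue
        if circular:
            if b - a >= L:
                norm.append((0, L))
                continue
            a_m = a % L
            b_m = a_m + (b - a)
            if b_m <= L:
                norm.append((a_m, b_m))
            else:
                norm.append((a_m, L))
                norm.append((0, b_m - L))
        else:
            a_c, b_c = max(a, 0), min(b, L)
            if a_c < b_c:
                norm.append((a_c, b_c))
    merged = []
    for a, b in sorted(norm):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def ncdna_window(gene: GeneRecord, window_kb: float, masks, genome: Genome):
    """Unmasked (intergenic) runs within ``window_kb`` kb of a gene.

    The window spans ``window_kb`` kilobases upstream of the start codon and
    the same downstream of the stop codon. Runs are contiguous stretches of
    non-coding sequence — a dinucleotide never spans a masked gap — and are
    returned read in the gene's reading-strand orientation (reverse
    complemented, order reversed, for minus-strand genes).

    Returns ``(runs, n_nc)``; ``n_nc == 0`` means no intergenic DNA was
    found and the gene should be excluded from classification.
    """
    rep = genome.replicons[gene.replicon_id]
    mask = masks[gene.replicon_id]
    L = len(rep)
    circular = rep.topology == "circular"
    window = int(window_kb * 1000)
    segments = _window_segments(gene.start, gene.end, window, L, circular)

    runs = []
    for a, b in segments:
        sub = mask[a:b]
        if sub.all():
            continue
        nc = ~sub
        # run boundaries within the segment
        idx = np.flatnonzero(np.diff(np.concatenate(([0], nc.view(np.int8), [0]))))
        for s_i, e_i in zip(idx[::2], idx[1::2]):
            runs.append((a + int(s_i), a + int(e_i)))
    # join a run ending at L with one starting at 0 (circular adjacency)
    if circular and len(runs) >= 2:
        runs.sort()
        if runs[0][0] == 0 and runs[-1][1] == L and runs[0] != runs[-1]:
            first, last = runs[0], runs.pop()
            runs[0] = (last[0], first[1] + L)
    seqs = []
    doubled = None
    for a, b in runs:
        if b <= L:
            seqs.append(rep.sequence[a:b])
        else:
            if doubled is None:
                doubled = rep.sequence + rep.sequence
            seqs.append(doubled[a:b])
    if gene.strand == "-":
        seqs = [revcomp(s) for s in reversed(seqs)]
    n_nc = sum(len(s) for s in seqs)
    return seqs, n_nc
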