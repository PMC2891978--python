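"""Genome reading, coding mask and intergenic-window extraction."""

import numpy as np
import pytest

from ocuscan.codes import revcomp, split_codons
from ocuscan.genome_io import (
    GeneRecord,
    Genome,
    Replicon,
    build_coding_mask,
    flag_ribosomal,
    ncdna_window,
    read_genome,
    upstream_intervals,
)


def make_cds(n_codons, stop="TAA"):
    """A CDS of n_codons sense codons (GCT = Ala) plus a stop."""
    return "GCT" * n_codons + stop


def write_inputs(tmp_path, sequence, rows, rep_id="chr"):
    fasta = tmp_path / "g.fasta"
    fasta.write_text(f">{rep_id}\n{sequence}\n")
    ann = tmp_path / "g.tsv"
    lines = ["gene_id\treplicon\tstart\tend\tstrand\tproduct\ttype"]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    ann.write_text("\n".join(lines) + "\n")
    return fasta, ann


def test_plus_strand_cds_codon_count(tmp_path):
    """A 300 nt CDS yields 99 sense codons once the stop is removed."""
    cds = make_cds(99)
    assert len(cds) == 300
    seq = "A" * 50 + cds + "A" * 50
    fasta, ann = write_inputs(tmp_path, seq, [("g1", "chr", 50, 350, "+", "p", "CDS")])
    genome = read_genome(fasta, ann)
    assert len(genome.genes) == 1
    assert genome.genes[0].length_codons == 99
    assert genome.genes[0].codons == ["GCT"] * 99


def test_minus_strand_codons_translation_consistent(tmp_path):
    """Minus-strand codons are the reverse complement of the forward slice."""
    cds = "ATGAAACCCGGG" + "GCT" * 80 + "TAA"
    fwd = revcomp(cds)
    seq = "T" * 30 + fwd + "T" * 30
    fasta, ann = write_inputs(
        tmp_path, seq, [("g1", "chr", 30, 30 + len(fwd), "-", "p", "CDS")]
    )
    genome = read_genome(fasta, ann)
    assert genome.genes[0].codons == split_codons(cds)[:-1]


def test_short_genes_excluded(tmp_path):
    """240 nt and 150 nt CDS = 79 and 49 sense codons, both below 80."""
    c1, c2 = make_cds(79), make_cds(49)
    seq = "A" * 10 + c1 + "A" * 10 + c2 + "A" * 10
    rows = [
        ("g1", "chr", 10, 10 + len(c1), "+", "p", "CDS"),
        ("g2", "chr", 20 + len(c1), 20 + len(c1) + len(c2), "+", "p", "CDS"),
    ]
    assert len(c1) == 240 and len(c2) == 150
    fasta, ann = write_inputs(tmp_path, seq, rows)
    genome = read_genome(fasta, ann)
    assert genome.genes == []


def test_bad_genes_dropped_with_warning(tmp_path, caplog):
    cds_n = "GCN" + make_cds(80)[3:]
    seq = "A" * 10 + cds_n + "A" * 10 + "GCTGC" + "A" * 10
    rows = [
        ("gN", "chr", 10, 10 + len(cds_n), "+", "p", "CDS"),
        ("gF", "chr", 20 + len(cds_n), 25 + len(cds_n), "+", "p", "CDS"),
    ]
    fasta, ann = write_inputs(tmp_path, seq, rows)
    with caplog.at_level("WARNING"):
        genome = read_genome(fasta, ann)
    assert genome.genes == []
    assert "ambiguous" in caplog.text and "divisible" in caplog.text


def test_unknown_replicon_is_hard_error(tmp_path):
    fasta, ann = write_inputs(
        tmp_path, "A" * 100, [("g1", "plasmid", 0, 30, "+", "p", "CDS")]
    )
    with pytest.raises(ValueError, match="unknown replicon"):
        read_genome(fasta, ann)


# ---------------------------------------------------------------------------
# RP flagging


def _gene(gid, product):
    return GeneRecord(gid, "chr", 0, 240, "+", ["GCT"] * 80, product=product)


def test_flag_ribosomal_rules():
    genes = [
        _gene("a", "30S ribosomal protein S12"),
        _gene("b", "ribosomal protein L11 methyltransferase"),
        _gene("c", "50S ribosomal subunit protein L2"),
        _gene("d", "hypothetical protein"),
    ]
    flag_ribosomal(genes)
    assert [g.is_rp for g in genes] == [True, False, True, False]


def test_flag_ribosomal_explicit_list_overrides():
    genes = [_gene(f"g{i}", "hypothetical protein") for i in range(10)]
    ids = [f"g{i}" for i in range(5)]
    flag_ribosomal(genes, rp_ids=ids)
    assert sum(g.is_rp for g in genes) == 5


def test_flag_ribosomal_empty_positive_class_errors():
    genes = [_gene("a", "hypothetical protein")]
    with pytest.raises(ValueError, match="positive class empty"):
        flag_ribosomal(genes)


# ---------------------------------------------------------------------------
# Coding mask


def _toy_genome(length=1000, genes=(), rna=(), topology="linear", fill="A"):
    gene_records = []
    for i, (s, e, strand) in enumerate(genes):
        n = (e - s) // 3
        gene_records.append(
            GeneRecord(f"g{i}", "chr", s, e, strand, ["GCT"] * n)
        )
    rep = Replicon("chr", fill * length, topology)
    return Genome({"chr": rep}, gene_records, [("chr", s, e) for s, e in rna])


def test_mask_single_gene():
    g = _toy_genome(1000, genes=[(100, 200, "+")])
    mask = build_coding_mask(g)
    assert mask["chr"].sum() == 100


def test_mask_union_with_rna():
    g = _toy_genome(1000, genes=[(100, 200, "+")], rna=[(150, 250)])
    mask = build_coding_mask(g)
    assert mask["chr"].sum() == 150


def test_upstream_mask_bound():
    g = _toy_genome(1000, genes=[(100, 200, "+"), (400, 520, "-")])
    extra = upstream_intervals(g, bp=20)
    total = sum(e - s for _, s, e in extra)
    assert total <= 20 * 2
    # plus-strand gene: [80,100); minus-strand: [520,540)
    assert ("chr", 80, 100) in extra and ("chr", 520, 540) in extra


# ---------------------------------------------------------------------------
# ncDNA windows


def test_fully_coding_replicon_flagged():
    g = _toy_genome(999, genes=[(0, 999, "+")])
    mask = build_coding_mask(g)
    runs, n = ncdna_window(g.genes[0], 1, mask, g)
    assert n == 0 and runs == []


def test_window_counts_constructed_intergenic_nt():
    """A layout engineered to leave exactly 142 intergenic nt within 10 kb."""
    # gene at [5000, 5300); other coding blocks cover all but 142 nt around it
    g = _toy_genome(
        30000,
        genes=[(5000, 5300, "+")],
        rna=[(0, 4900), (5400, 30000)],  # leaves [4900,5000) and [5300,5400): 200 nt
        topology="linear",
    )
    # shrink free space to 142: mask 58 more nt
    mask = build_coding_mask(g, extra_masks=[("chr", 4900, 4958)])
    runs, n = ncdna_window(g.genes[0], 10, mask, g)
    assert n == 142
    assert sum(len(r) for r in runs) == 142


def test_circular_window_covers_replicon_once():
    """A 20 kb window on a 5 kb circular replicon sees each base once."""
    g = _toy_genome(5000, genes=[(1000, 1300, "+")], topology="circular")
    mask = build_coding_mask(g)
    runs, n = ncdna_window(g.genes[0], 20, mask, g)
    assert n == 5000 - 300


def test_neighboring_genes_share_window_content():
    """Windows of adjacent genes overlap, so their ncDNA shares sequence."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 8000))
    rep = Replicon("chr", seq, "linear")
    genes = [
        GeneRecord("g1", "chr", 1000, 1300, "+", ["GCT"] * 100),
        GeneRecord("g2", "chr", 2000, 2300, "+", ["GCT"] * 100),
    ]
    genome = Genome({"chr": rep}, genes, [])
    mask = build_coding_mask(genome)
    runs1, _ = ncdna_window(genes[0], 5, mask, genome)
    runs2, _ = ncdna_window(genes[1], 5, mask, genome)
    shared = seq[1300:2000]  # the intergenic gap belongs to both windows
    assert any(shared in r for r in runs1)
    assert any(shared in r for r in runs2)


def test_window_never_returns_coding_sequence():
    """Coding bases are G-only, intergenic A-only: runs must be pure A."""
    seq = "A" * 500 + "G" * 300 + "A" * 500 + "G" * 300 + "A" * 400
    rep = Replicon("chr", seq, "linear")
    genes = [
        GeneRecord("g1", "chr", 500, 800, "+", ["GGG"] * 100),
        GeneRecord("g2", "chr", 1300, 1600, "-", ["CCC"] * 100),
    ]
    genome = Genome({"chr": rep}, genes, [])
    mask = build_coding_mask(genome)
    for gene in genes:
        runs, n = ncdna_window(gene, 5, mask, genome)
        assert n > 0
        joined = "".join(runs)
        assert set(joined) <= {"A", "T"}  # minus-strand runs are complemented


def test_reverse_complement_symmetry():
    """Mirroring the replicon and flipping strands leaves window content
    identical up to reverse complement, hence equal dinucleotide counts."""
    from ocuscan.features import nc_features

    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 6000))
    L = len(seq)
    genes = [(1000, 1600, "+"), (3000, 3900, "-")]
    g_fwd = Genome(
        {"chr": Replicon("chr", seq, "linear")},
        [
            GeneRecord(f"g{i}", "chr", s, e, st, ["GCT"] * ((e - s) // 3))
            for i, (s, e, st) in enumerate(genes)
        ],
        [],
    )
    flipped = [(L - e, L - s, "-" if st == "+" else "+") for s, e, st in genes]
    g_rev = Genome(
        {"chr": Replicon("chr", revcomp(seq), "linear")},
        [
            GeneRecord(f"g{i}", "chr", s, e, st, ["GCT"] * ((e - s) // 3))
            for i, (s, e, st) in enumerate(flipped)
        ],
        [],
    )
    m_fwd, m_rev = build_coding_mask(g_fwd), build_coding_mask(g_rev)
    for i in range(len(genes)):
        runs_f, n_f = ncdna_window(g_fwd.genes[i], 2, m_fwd, g_fwd)
        runs_r, n_r = ncdna_window(g_rev.genes[i], 2, m_rev, g_rev)
        assert n_f == n_r
        f_f, f_r = nc_features(runs_f), nc_features(runs_r)
        np.testing.assert_allclose(f_f.mono, f_r.mono, atol=1e-12)
        np.testing.assert_allclose(f_f.di, f_r.di, atol=1e-12)


def test_gff3_round_trip(tmp_path):
    """GFF3 CDS features (1-based inclusive) convert to the internal
    0-based half-open convention; RNA features go to the mask."""
    cds = make_cds(90)
    seq = "A" * 100 + cds + "A" * 100 + "G" * 80 + "A" * 50
    fasta = tmp_path / "g.fasta"
    fasta.write_text(f">chr\n{seq}\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        f"chr\tsrc\tCDS\t101\t{100 + len(cds)}\t.\t+\t0\t"
        "ID=g1;product=30S ribosomal protein S4\n"
        f"chr\tsrc\ttRNA\t{100 + len(cds) + 101}\t{100 + len(cds) + 180}\t.\t+\t.\tID=t1\n"
    )
    genome = read_genome(fasta, gff)
    assert len(genome.genes) == 1
    g = genome.genes[0]
    assert (g.start, g.end) == (100, 100 + len(cds))
    assert g.length_codons == 90
    assert g.product == "30S ribosomal protein S4"
    assert genome.rna_intervals == [("chr", 100 + len(cds) + 100, 100 + len(cds) + 180)]


def test_upstream_interval_wraps_at_origin():
    """A minus-strand gene ending exactly at the replicon end: its 20 bp
    'upstream' region is [0, 20) on a circular replicon, never the whole
    molecule."""
    g = _toy_genome(999, genes=[(699, 999, "-")], topology="circular")
    extra = upstream_intervals(g, bp=20)
    assert extra == [("chr", 0, 20)]
    # straddling the origin: gene ends 5 nt before the end
    g2 = _toy_genome(999, genes=[(694, 994, "-")], topology="circular")
    extra2 = upstream_intervals(g2, bp=20)
    assert sorted(extra2) == [("chr", 0, 15), ("chr", 994, 999)]
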